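import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msrdf.similarity import (
    CandidatePair,
    Matching,
    ShiftClass,
    SimilarityParams,
    brute_force_best_matching,
    collect_candidate_pairs,
    cosine_greedy,
    cosine_hungarian,
    greedy_assignment,
    modified_cosine,
    optimal_assignment,
    score_from_matching,
)
from msrdf.spectrum_core import Peak, Spectrum

DEFAULTS = SimilarityParams()

# the worked divergence case: greedy locks onto the central 1.0*1.0 pair and
# blocks both 0.9 pairs; the optimal assignment takes the two 0.9 pairs
DIVERGENT_A = Spectrum([(99.94, 0.9), (100.0, 1.0)])
DIVERGENT_B = Spectrum([(100.0, 1.0), (100.05, 0.9)])


def random_spectrum(rng, n_peaks, with_precursor=False):
    mz = np.sort(rng.uniform(50, 500, size=n_peaks))
    intensities = rng.uniform(0.05, 1.0, size=n_peaks)
    precursor = float(mz[-1] + rng.uniform(1, 30)) if with_precursor else None
    return Spectrum(
        [Peak(float(m), float(i)) for m, i in zip(mz, intensities)],
        precursor_mz=precursor,
    )


class TestCandidatePairs:
    def test_within_tolerance_pair_admitted(self):
        pairs = collect_candidate_pairs(Spectrum([(100.0, 1)]), Spectrum([(100.05, 1)]), DEFAULTS)
        assert [(p.index_a, p.index_b, p.shift_class) for p in pairs] == [(0, 0, ShiftClass.ZERO)]

    def test_outside_tolerance_no_pair(self):
        assert collect_candidate_pairs(Spectrum([(100.0, 1)]), Spectrum([(200.0, 1)]), DEFAULTS) == []

    def test_mass_shift_admits_precursor_pair(self):
        pairs = collect_candidate_pairs(
            Spectrum([(150.0, 0.6)]), Spectrum([(160.0, 0.5)]), DEFAULTS, mass_shift=-10.0
        )
        assert [(p.index_a, p.index_b, p.shift_class) for p in pairs] == [
            (0, 0, ShiftClass.PRECURSOR)
        ]
        assert pairs[0].pair_score == pytest.approx(0.3)

    def test_boundary_is_inclusive(self):
        pairs = collect_candidate_pairs(Spectrum([(100.0, 1)]), Spectrum([(100.1, 1)]), DEFAULTS)
        assert len(pairs) == 1

    def test_pair_admissible_under_both_shifts_counted_once_as_zero(self):
        pairs = collect_candidate_pairs(
            Spectrum([(100.0, 1)]), Spectrum([(100.0, 1)]), DEFAULTS, mass_shift=0.05
        )
        assert len(pairs) == 1
        assert pairs[0].shift_class is ShiftClass.ZERO

    def test_pair_score_uses_weight_powers(self):
        params = SimilarityParams(tolerance=0.1, mz_power=1.0, intensity_power=2.0)
        [pair] = collect_candidate_pairs(Spectrum([(100.0, 2)]), Spectrum([(100.0, 3)]), params)
        assert pair.pair_score == pytest.approx((100 * 4) * (100 * 9))


class TestAssignments:
    THREE_PAIRS = [
        CandidatePair(0, 0, 1.0),
        CandidatePair(0, 1, 0.9),
        CandidatePair(1, 0, 0.9),
    ]

    def test_greedy_on_empty_and_single(self):
        assert len(greedy_assignment([])) == 0
        single = [CandidatePair(2, 3, 0.5)]
        assert greedy_assignment(single).pairs == tuple(single)

    def test_greedy_blocks_alternatives(self):
        matching = greedy_assignment(self.THREE_PAIRS)
        assert [(p.index_a, p.index_b) for p in matching.pairs] == [(0, 0)]

    def test_optimal_takes_both_side_pairs(self):
        matching = optimal_assignment(self.THREE_PAIRS)
        assert sorted((p.index_a, p.index_b) for p in matching.pairs) == [(0, 1), (1, 0)]
        assert matching.total() == pytest.approx(1.8)

    def test_optimal_agrees_with_brute_force(self):
        assert optimal_assignment(self.THREE_PAIRS).total() == pytest.approx(
            brute_force_best_matching(self.THREE_PAIRS).total()
        )

    def test_brute_force_rejects_large_instances(self):
        pairs = [CandidatePair(i, i, 1.0) for i in range(25)]
        with pytest.raises(ValueError):
            brute_force_best_matching(pairs)

    def test_matching_rejects_non_injective(self):
        with pytest.raises(ValueError):
            Matching((CandidatePair(0, 0, 1.0), CandidatePair(0, 1, 1.0)))

    def test_oracle_equivalence_on_random_instances(self):
        """Hungarian total equals exhaustive enumeration on 200 seeded
        random small instances."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = random_spectrum(rng, int(rng.integers(1, 9)))
            b = random_spectrum(rng, int(rng.integers(1, 9)))
            params = SimilarityParams(tolerance=float(rng.uniform(0.5, 30)))
            pairs = collect_candidate_pairs(a, b, params)
            if len(pairs) > 16:
                continue
            assert optimal_assignment(pairs).total() == pytest.approx(
                brute_force_best_matching(pairs).total(), abs=1e-12
            )


class TestScores:
    def test_empty_matching_scores_zero(self):
        result = score_from_matching(DIVERGENT_A, DIVERGENT_B, Matching(()), DEFAULTS)
        assert result == type(result)(0.0, 0)

    def test_identity_matching_scores_one(self):
        spectrum = Spectrum([(100, 0.3), (200, 1.0), (300, 0.7)])
        pairs = collect_candidate_pairs(spectrum, spectrum, DEFAULTS)
        identity = Matching(tuple(p for p in pairs if p.index_a == p.index_b))
        assert score_from_matching(spectrum, spectrum, identity, DEFAULTS).score == pytest.approx(
            1.0, abs=1e-12
        )

    def test_zero_norm_scores_zero_not_error(self):
        zero = Spectrum([(100.0, 0.0)])
        assert cosine_greedy(zero, zero, DEFAULTS).score == 0.0

    def test_worked_divergence_case(self):
        """Greedy takes the single 1.0 pair (score 1/1.81); the optimal
        matching pairs both peak pairs (score 1.8/1.81); both verified
        against the exhaustive oracle."""
        greedy = cosine_greedy(DIVERGENT_A, DIVERGENT_B, DEFAULTS)
        hungarian = cosine_hungarian(DIVERGENT_A, DIVERGENT_B, DEFAULTS)
        assert greedy.score == pytest.approx(1.0 / 1.81, abs=1e-12)
        assert greedy.matched_peaks == 1
        assert hungarian.score == pytest.approx(1.8 / 1.81, abs=1e-12)
        assert hungarian.matched_peaks == 2
        pairs = collect_candidate_pairs(DIVERGENT_A, DIVERGENT_B, DEFAULTS)
        oracle = brute_force_best_matching(pairs)
        assert score_from_matching(
            DIVERGENT_A, DIVERGENT_B, oracle, DEFAULTS
        ).score == pytest.approx(hungarian.score, abs=1e-12)

    def test_disjoint_spectra_score_zero(self):
        a, b = Spectrum([(100, 1)]), Spectrum([(200, 1)])
        for fn in (cosine_greedy, cosine_hungarian):
            result = fn(a, b, DEFAULTS)
            assert (result.score, result.matched_peaks) == (0.0, 0)


class TestModifiedCosine:
    def test_single_shifted_pair_scores_one(self):
        a = Spectrum([(100.0, 1.0)], precursor_mz=500)
        b = Spectrum([(110.0, 1.0)], precursor_mz=510)
        result = modified_cosine(a, b, DEFAULTS)
        assert (result.score, result.matched_peaks) == (pytest.approx(1.0), 1)

    def test_equal_precursors_reduce_to_greedy(self, rng):
        a = random_spectrum(rng, 6)
        b = random_spectrum(rng, 6)
        a_p = Spectrum(a.peaks, precursor_mz=400.0)
        b_p = Spectrum(b.peaks, precursor_mz=400.0)
        assert modified_cosine(a_p, b_p, DEFAULTS) == cosine_greedy(a, b, DEFAULTS)

    def test_worked_two_peak_case(self):
        a = Spectrum([(100.0, 1.0), (150.0, 0.6)], precursor_mz=400)
        b = Spectrum([(100.0, 0.8), (160.0, 0.5)], precursor_mz=410)
        result = modified_cosine(a, b, DEFAULTS)
        expected = 1.1 / (math.sqrt(1.36) * math.sqrt(0.89))
        assert result.score == pytest.approx(expected, abs=1e-12)
        assert result.matched_peaks == 2

    def test_missing_precursor_names_side(self):
        with_p = Spectrum([(100, 1)], precursor_mz=200)
        without = Spectrum([(100, 1)])
        with pytest.raises(ValueError, match="spectrum A"):
            modified_cosine(without, with_p, DEFAULTS)
        with pytest.raises(ValueError, match="spectrum B"):
            modified_cosine(with_p, without, DEFAULTS)


ALL_FUNCTIONS = [cosine_greedy, cosine_hungarian, modified_cosine]


class TestInvariants:
    @pytest.mark.parametrize("fn", ALL_FUNCTIONS, ids=["greedy", "hungarian", "modified"])
    def test_self_similarity_is_one(self, fn, rng):
        for _ in range(20):
            s = random_spectrum(rng, int(rng.integers(1, 15)), with_precursor=True)
            for tolerance in (0.01, 0.1, 1.0):
                result = fn(s, s, SimilarityParams(tolerance=tolerance))
                assert result.score == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("fn", ALL_FUNCTIONS, ids=["greedy", "hungarian", "modified"])
    def test_scores_stay_in_unit_interval(self, fn, rng):
        for _ in range(50):
            a = random_spectrum(rng, int(rng.integers(1, 12)), with_precursor=True)
            b = random_spectrum(rng, int(rng.integers(1, 12)), with_precursor=True)
            assert 0.0 <= fn(a, b, SimilarityParams(tolerance=5.0)).score <= 1.0

    def test_greedy_never_beats_hungarian(self, rng):
        for _ in range(100):
            a = random_spectrum(rng, int(rng.integers(1, 10)))
            b = random_spectrum(rng, int(rng.integers(1, 10)))
            params = SimilarityParams(tolerance=float(rng.uniform(0.5, 20)))
            assert cosine_greedy(a, b, params).score <= cosine_hungarian(a, b, params).score + 1e-12

    def test_hungarian_symmetric_exactly(self, rng):
        for _ in range(50):
            a = random_spectrum(rng, int(rng.integers(1, 10)))
            b = random_spectrum(rng, int(rng.integers(1, 10)))
            params = SimilarityParams(tolerance=2.0)
            assert cosine_hungarian(a, b, params).score == pytest.approx(
                cosine_hungarian(b, a, params).score, abs=1e-12
            )

    def test_greedy_and_modified_symmetric_with_distinct_scores(self, rng):
        # random continuous intensities make pair-score ties measure-zero
        for _ in range(50):
            a = random_spectrum(rng, int(rng.integers(1, 10)), with_precursor=True)
            b = random_spectrum(rng, int(rng.integers(1, 10)), with_precursor=True)
            params = SimilarityParams(tolerance=2.0)
            assert cosine_greedy(a, b, params).score == pytest.approx(
                cosine_greedy(b, a, params).score, abs=1e-9
            )
            assert modified_cosine(a, b, params).score == pytest.approx(
                modified_cosine(b, a, params).score, abs=1e-9
            )

    def test_hungarian_monotone_in_tolerance(self, rng):
        for _ in range(30):
            a = random_spectrum(rng, int(rng.integers(2, 10)))
            b = random_spectrum(rng, int(rng.integers(2, 10)))
            scores = [
                cosine_hungarian(a, b, SimilarityParams(tolerance=t)).score
                for t in (0.01, 0.05, 0.1, 0.5, 2.0, 10.0)
            ]
            assert all(s1 <= s2 + 1e-12 for s1, s2 in zip(scores, scores[1:]))

    @pytest.mark.parametrize("scale", [0.1, 3.0, 100.0])
    def test_scale_invariance(self, scale, rng):
        a = random_spectrum(rng, 8, with_precursor=True)
        b = random_spectrum(rng, 8, with_precursor=True)
        b_scaled = Spectrum(
            [Peak(p.mz, p.intensity * scale) for p in b.peaks], precursor_mz=b.precursor_mz
        )
        for fn in ALL_FUNCTIONS:
            assert fn(a, b, DEFAULTS).score == pytest.approx(
                fn(a, b_scaled, DEFAULTS).score, abs=1e-9
            )


class TestReferenceAgreement:
    """The scores must agree with matchms, the reference implementation the
    similarity functions are modelled on (test-only dependency)."""

    @staticmethod
    def to_matchms(spectrum):
        from matchms import Spectrum as MsSpectrum

        metadata = {}
        if spectrum.precursor_mz is not None:
            metadata["precursor_mz"] = spectrum.precursor_mz
        return MsSpectrum(
            mz=np.array(spectrum.mz),
            intensities=np.array(spectrum.intensities),
            metadata=metadata,
            metadata_harmonization=False,
        )

    def test_agreement_on_seeded_pairs(self):
        from matchms.similarity import CosineGreedy, CosineHungarian, ModifiedCosine

        rng = np.random.default_rng(11)
        tolerance = 0.5
        reference = {
            cosine_greedy: CosineGreedy(tolerance=tolerance),
            cosine_hungarian: CosineHungarian(tolerance=tolerance),
            modified_cosine: ModifiedCosine(tolerance=tolerance),
        }
        params = SimilarityParams(tolerance=tolerance)
        for _ in range(100):
            a = random_spectrum(rng, int(rng.integers(2, 12)), with_precursor=True)
            b = random_spectrum(rng, int(rng.integers(2, 12)), with_precursor=True)
            ref_a, ref_b = self.to_matchms(a), self.to_matchms(b)
            for fn, ref in reference.items():
                ours = fn(a, b, params)
                theirs = ref.pair(ref_a, ref_b)
                assert ours.score == pytest.approx(float(theirs["score"]), abs=1e-6)
                assert ours.matched_peaks == int(theirs["matches"])
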