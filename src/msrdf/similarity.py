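"""Peak-matching cosine similarity between centroided mass spectra.

Three scores are provided, mirroring the widely used matchms family:

``cosine_greedy``
    Candidate peak pairs within the m/z tolerance are accepted highest
    pair-score first, each peak used at most once.
``cosine_hungarian``
    Same candidate pairs, but the injective matching maximising the total
    pair score is found exactly (maximum-weight bipartite assignment).
``modified_cosine``
    Greedy assignment over the union of zero-shift pairs and pairs offset by
    the difference of the two precursor m/z values — captures shared
    fragmentation between structurally related compounds whose precursors
    differ by a modification mass.

The pair score of peaks *a*, *b* is ``w(a)·w(b)`` with
``w(p) = mz(p)^mz_power · intensity(p)^intensity_power``, and the final score
divides the total matched weight by the product of the spectra's weight-vector
norms, so identical spectra score exactly 1 (Cauchy–Schwarz) and the score is
invariant under intensity rescaling of either spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectrum_core import Spectrum

__all__ = [
    "SimilarityParams",
    "ShiftClass",
    "CandidatePair",
    "Matching",
    "SimilarityResult",
    "collect_candidate_pairs",
    "greedy_assignment",
    "optimal_assignment",
    "brute_force_best_matching",
    "score_from_matching",
    "cosine_greedy",
    "cosine_hungarian",
    "modified_cosine",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Matching tolerance (Da) and the peak-weighting exponents."""

    tolerance: float = 0.1
    mz_power: float = 0.0
    intensity_power: float = 1.0

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if self.mz_power < 0 or self.intensity_power < 0:
            raise ValueError("powers must be non-negative")

    def weight(self, mz: float, intensity: float) -> float:
        return mz**self.mz_power * intensity**self.intensity_power


class ShiftClass(Enum):
    ZERO = "zero"
    PRECURSOR = "precursor"


@dataclass(frozen=True)
class CandidatePair:
    """A tolerance-admissible peak pair (peak ``index_a`` of spectrum A with
    peak ``index_b`` of spectrum B) and its contribution to the dot product."""

    index_a: int
    index_b: int
    pair_score: float
    shift_class: ShiftClass = ShiftClass.ZERO


@dataclass(frozen=True)
class Matching:
    """An injective set of candidate pairs: no peak index re-used on either side."""

    pairs: tuple[CandidatePair, ...]

    def __post_init__(self) -> None:
        left = [p.index_a for p in self.pairs]
        right = [p.index_b for p in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("matching is not injective")

    def total(self) -> float:
        return float(sum(p.pair_score for p in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class SimilarityResult:
    score: float
    matched_peaks: int


def collect_candidate_pairs(
    a: Spectrum,
    b: Spectrum,
    params: SimilarityParams = SimilarityParams(),
    mass_shift: float | None = None,
) -> list[CandidatePair]:
    """All tolerance-admissible peak pairs between ``a`` and ``b``.

    A pair (i, j) is admissible with shift class *zero* when
    ``|mz_a(i) - mz_b(j)| <= tolerance`` (inclusive boundary) and, when
    ``mass_shift`` is given, with shift class *precursor* when
    ``|mz_a(i) - mz_b(j) - mass_shift| <= tolerance``.  A pair admissible
    under both appears once, as zero-shift — this prevents double matching
    when the two precursors nearly coincide.
    """
    pairs: list[CandidatePair] = []
    seen: set[tuple[int, int]] = set()
    weights_a = [params.weight(p.mz, p.intensity) for p in a.peaks]
    weights_b = [params.weight(p.mz, p.intensity) for p in b.peaks]

    def admit(i: int, j: int, shift_class: ShiftClass) -> None:
        if (i, j) in seen:
            return
        seen.add((i, j))
        pairs.append(CandidatePair(i, j, weights_a[i] * weights_b[j], shift_class))

    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            if abs(pa.mz - pb.mz) <= params.tolerance:
                admit(i, j, ShiftClass.ZERO)
    if mass_shift is not None:
        for i, pa in enumerate(a.peaks):
            for j, pb in enumerate(b.peaks):
                if abs(pa.mz - pb.mz - mass_shift) <= params.tolerance:
                    admit(i, j, ShiftClass.PRECURSOR)
    return pairs


def greedy_assignment(pairs: Sequence[CandidatePair]) -> Matching:
    """Accept pairs highest pair-score first (ties by ascending
    ``(index_a, index_b)``), skipping any pair whose endpoints are taken."""
    ordered = sorted(pairs, key=lambda p: (-p.pair_score, p.index_a, p.index_b))
    used_a: set[int] = set()
    used_b: set[int] = set()
    accepted: list[CandidatePair] = []
    for pair in ordered:
        if pair.index_a in used_a or pair.index_b in used_b:
            continue
        used_a.add(pair.index_a)
        used_b.add(pair.index_b)
        accepted.append(pair)
    return Matching(tuple(accepted))


def optimal_assignment(pairs: Sequence[CandidatePair]) -> Matching:
    """Injective subset of ``pairs`` maximising the total pair score, found
    by maximum-weight bipartite assignment (Hungarian method).

    Only admissible pairs can enter the matching; an assignment cell that is
    not a candidate contributes nothing and is dropped from the result.
    """
    if not pairs:
        return Matching(())
    rows = sorted({p.index_a for p in pairs})
    cols = sorted({p.index_b for p in pairs})
    row_of = {idx: k for k, idx in enumerate(rows)}
    col_of = {idx: k for k, idx in enumerate(cols)}
    weights = np.zeros((len(rows), len(cols)))
    admissible: dict[tuple[int, int], CandidatePair] = {}
    for pair in pairs:
        key = (row_of[pair.index_a], col_of[pair.index_b])
        # keep the best-scoring duplicate if callers pass overlapping pairs
        if key not in admissible or pair.pair_score > admissible[key].pair_score:
            admissible[key] = pair
            weights[key] = pair.pair_score
    assigned_rows, assigned_cols = linear_sum_assignment(weights, maximize=True)
    accepted = [
        admissible[(r, c)]
        for r, c in zip(assigned_rows, assigned_cols)
        if (r, c) in admissible
    ]
    accepted.sort(key=lambda p: (p.index_a, p.index_b))
    return Matching(tuple(accepted))


def brute_force_best_matching(
    pairs: Sequence[CandidatePair], max_pairs: int = 18
) -> Matching:
    """Exhaustive oracle: enumerate every injective subset of ``pairs`` and
    return the one with maximum total score (ties: lexicographically smallest
    sorted index sequence).  Only for small instances."""
    if len(pairs) > max_pairs:
        raise ValueError(f"instance too large for brute force ({len(pairs)} pairs)")
    best: tuple[float, tuple[tuple[int, int], ...]] | None = None
    best_subset: tuple[CandidatePair, ...] = ()
    for size in range(len(pairs) + 1):
        for subset in combinations(pairs, size):
            left = [p.index_a for p in subset]
            right = [p.index_b for p in subset]
            if len(set(left)) != len(left) or len(set(right)) != len(right):
                continue
            ordered = tuple(sorted(subset, key=lambda p: (p.index_a, p.index_b)))
            key = (
                -sum(p.pair_score for p in ordered),
                tuple((p.index_a, p.index_b) for p in ordered),
            )
            if best is None or key < best:
                best = key
                best_subset = ordered
    return Matching(best_subset)


def _norm(spectrum: Spectrum, params: SimilarityParams) -> float:
    return math.sqrt(
        sum(params.weight(p.mz, p.intensity) ** 2 for p in spectrum.peaks)
    )


def score_from_matching(
    a: Spectrum,
    b: Spectrum,
    matching: Matching,
    params: SimilarityParams = SimilarityParams(),
) -> SimilarityResult:
    """Normalised dot product of the matched peak weights.

    Zero-norm spectra (no peaks, or all-zero weights) score 0 rather than
    raising, so that filter-style evaluation stays total.
    """
    norm_a, norm_b = _norm(a, params), _norm(b, params)
    if norm_a == 0 or norm_b == 0:
        return SimilarityResult(0.0, 0)
    for pair in matching.pairs:
        if not (0 <= pair.index_a < len(a.peaks) and 0 <= pair.index_b < len(b.peaks)):
            raise IndexError(f"matching pair ({pair.index_a},{pair.index_b}) out of bounds")
    score = matching.total() / (norm_a * norm_b)
    return SimilarityResult(min(max(score, 0.0), 1.0), len(matching))


def cosine_greedy(
    a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()
) -> SimilarityResult:
    """Cosine similarity with greedy highest-score-first peak assignment."""
    pairs = collect_candidate_pairs(a, b, params)
    return score_from_matching(a, b, greedy_assignment(pairs), params)


def cosine_hungarian(
    a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()
) -> SimilarityResult:
    """Cosine similarity with the exact maximum-weight peak assignment."""
    pairs = collect_candidate_pairs(a, b, params)
    return score_from_matching(a, b, optimal_assignment(pairs), params)


def modified_cosine(
    a: Spectrum, b: Spectrum, params: SimilarityParams = SimilarityParams()
) -> SimilarityResult:
    """Modified cosine: candidate pairs may additionally be offset by the
    precursor m/z difference ``precursor(a) - precursor(b)``; assignment is
    greedy, matching the ported reference."""
    if a.precursor_mz is None:
        raise ValueError("modified cosine requires a precursor m/z on spectrum A")
    if b.precursor_mz is None:
        raise ValueError("modified cosine requires a precursor m/z on spectrum B")
    shift = a.precursor_mz - b.precursor_mz
    pairs = collect_candidate_pairs(a, b, params, mass_shift=shift)
    return score_from_matching(a, b, greedy_assignment(pairs), params)
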