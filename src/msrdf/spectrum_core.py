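"""Peak-list spectra and the ``ms:spectrum`` literal codec.

A mass spectrum is modelled as an ordered list of centroided peaks, each a
(m/z, intensity) pair, optionally accompanied by the precursor m/z of the
fragmented ion.  Spectra are exchanged inside RDF graphs as typed literals
whose lexical form is a space-separated list of ``mz:intensity`` pairs with
m/z ascending — the same textual encoding MoNA uses for its spectrum strings.
The precursor m/z is *not* part of the literal; it travels as record metadata
and, where the modified-cosine function needs it, as an explicit argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "IonMode",
    "Peak",
    "Spectrum",
    "SpectrumCodecError",
    "parse_spectrum_literal",
    "serialize_spectrum_literal",
    "normalize_intensities",
    "validate_spectrum",
]


class IonMode(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z in thomson (dimensionless scale), intensity
    in arbitrary units."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """An ordered peak list.  Peaks must be sorted ascending by m/z
    (duplicate m/z values are permitted — real centroided spectra carry them).
    """

    peaks: tuple[Peak, ...]
    precursor_mz: float | None = None
    ion_mode: IonMode = IonMode.UNKNOWN

    def __init__(
        self,
        peaks: Iterable[Peak | tuple[float, float]],
        precursor_mz: float | None = None,
        ion_mode: IonMode | str = IonMode.UNKNOWN,
    ) -> None:
        normalized = tuple(
            p if isinstance(p, Peak) else Peak(float(p[0]), float(p[1])) for p in peaks
        )
        object.__setattr__(self, "peaks", normalized)
        object.__setattr__(
            self, "precursor_mz", None if precursor_mz is None else float(precursor_mz)
        )
        object.__setattr__(self, "ion_mode", IonMode(ion_mode))

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    def with_peaks(self, peaks: Iterable[Peak | tuple[float, float]]) -> "Spectrum":
        return Spectrum(peaks, precursor_mz=self.precursor_mz, ion_mode=self.ion_mode)


class SpectrumCodecError(ValueError):
    """Raised on a malformed spectrum literal; carries the offending token index."""

    def __init__(self, message: str, token_index: int | None = None):
        super().__init__(message)
        self.token_index = token_index


def _parse_decimal(text: str) -> float:
    value = float(text)  # accepts plain and scientific notation
    if math.isnan(value) or math.isinf(value):
        raise ValueError("non-finite value")
    return value


def parse_spectrum_literal(text: str) -> Spectrum:
    """Parse the lexical form of an ``ms:spectrum`` literal.

    Tokens are whitespace-separated ``mz:intensity`` pairs.  Peaks are
    re-sorted ascending by m/z, so any token order is accepted; the precursor
    m/z is never part of the literal and is left unset.
    """
    tokens = text.split()
    if not tokens:
        raise SpectrumCodecError("empty spectrum literal")
    peaks = []
    for i, token in enumerate(tokens):
        parts = token.split(":")
        if len(parts) != 2:
            raise SpectrumCodecError(
                f"token {i} ({token!r}): expected two ':'-separated decimals", i
            )
        try:
            mz, intensity = _parse_decimal(parts[0]), _parse_decimal(parts[1])
        except ValueError:
            raise SpectrumCodecError(
                f"token {i} ({token!r}): unparsable decimal", i
            ) from None
        if mz <= 0:
            raise SpectrumCodecError(f"token {i} ({token!r}): m/z must be positive", i)
        if intensity < 0:
            raise SpectrumCodecError(
                f"token {i} ({token!r}): negative intensity", i
            )
        peaks.append(Peak(mz, intensity))
    peaks.sort(key=lambda p: p.mz)
    return Spectrum(peaks)


def _format_decimal(value: float) -> str:
    """Shortest decimal representation that round-trips through ``float``."""
    text = repr(float(value))
    if text.endswith(".0"):
        text = text[:-2]
    return text


def serialize_spectrum_literal(spectrum: Spectrum) -> str:
    """Canonical lexical form: single-space-separated ``mz:intensity`` pairs,
    m/z ascending, each number in its shortest value-preserving form.
    ``parse(serialize(s))`` reproduces ``s``'s peaks exactly."""
    if not spectrum.peaks:
        raise SpectrumCodecError("cannot serialize an empty spectrum")
    peaks = sorted(spectrum.peaks, key=lambda p: p.mz)
    return " ".join(
        f"{_format_decimal(p.mz)}:{_format_decimal(p.intensity)}" for p in peaks
    )


def normalize_intensities(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak is 1.0; m/z values are untouched."""
    if not spectrum.peaks:
        raise ValueError("cannot normalize an empty spectrum")
    top = max(p.intensity for p in spectrum.peaks)
    if top <= 0:
        raise ValueError("cannot normalize a spectrum whose intensities are all zero")
    if top == 1.0:
        return spectrum
    return spectrum.with_peaks(Peak(p.mz, p.intensity / top) for p in spectrum.peaks)


def validate_spectrum(spectrum: Spectrum) -> list[str]:
    """Total validation: returns a (possibly empty) list of violation
    descriptors, each naming the field and peak index concerned."""
    violations: list[str] = []
    previous = -math.inf
    for i, peak in enumerate(spectrum.peaks):
        if not (peak.mz > 0) or math.isnan(peak.mz) or math.isinf(peak.mz):
            violations.append(f"non-positive mz @{i}")
        if peak.intensity < 0 or math.isnan(peak.intensity) or math.isinf(peak.intensity):
            violations.append(f"negative intensity @{i}")
        if peak.mz < previous:
            violations.append(f"ordering violated @{i}")
        previous = peak.mz
    if spectrum.precursor_mz is not None and not (spectrum.precursor_mz > 0):
        violations.append("non-positive precursor_mz")
    return violations
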