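"""Readers and writers for spectral-library records.

Two input dialects are supported:

* **MSP** — the NIST-style plain-text exchange format used by most spectral
  libraries: header lines (``NAME:``, ``PRECURSORMZ:``, ...) followed by
  ``Num Peaks: n`` and *n* peak lines.
* **MoNA-style JSON** — a JSON array of record objects with the spectrum
  encoded as a ``mz:intensity`` pair string, a ``compound`` block carrying
  the InChI, plus metaData, submitter, library, tags and peak annotations.

Both produce :class:`SpectrumRecord` values; :func:`write_records_json`
emits the same JSON dialect back, and reading what it wrote reproduces the
records field-wise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable

from .spectrum_core import (
    IonMode,
    Peak,
    Spectrum,
    SpectrumCodecError,
    parse_spectrum_literal,
    serialize_spectrum_literal,
    validate_spectrum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IdentifierScheme",
    "Identifier",
    "Quality",
    "CompoundInfo",
    "ExperimentParam",
    "PeakAnnotation",
    "Submitter",
    "LibraryInfo",
    "SpectrumRecord",
    "ReaderError",
    "validate_record",
    "read_msp",
    "read_mona_json",
    "write_records_json",
]

ANNOTATION_MZ_TOLERANCE = 1e-6


class IdentifierScheme(str, Enum):
    PUBCHEM_CID = "pubchem cid"
    CHEBI = "chebi"
    CAS = "cas"
    OTHER = "other"


@dataclass(frozen=True)
class Identifier:
    scheme: IdentifierScheme
    value: str
    name: str | None = None  # literal scheme name when scheme == OTHER


@dataclass(frozen=True)
class Quality:
    """A chemical quality of the compound (e.g. molecular formula, exact
    mass), named by the quality kind it will be typed with."""

    kind: str
    value: str | float
    unit: str | None = None


@dataclass(frozen=True)
class CompoundInfo:
    inchi: str | None = None
    inchikey: str | None = None
    names: tuple[str, ...] = ()
    identifiers: tuple[Identifier, ...] = ()
    qualities: tuple[Quality, ...] = ()
    classifications: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.inchi is not None and not self.inchi.startswith("InChI="):
            raise ValueError(f"InChI must start with 'InChI=': {self.inchi!r}")


@dataclass(frozen=True)
class ExperimentParam:
    name: str
    value: str | float
    unit: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("experiment parameter name must be non-empty")


@dataclass(frozen=True)
class PeakAnnotation:
    mz: float
    text: str

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError("peak annotation m/z must be positive")


@dataclass(frozen=True)
class Submitter:
    name: str
    email: str | None = None


@dataclass(frozen=True)
class LibraryInfo:
    name: str
    description: str | None = None


@dataclass(frozen=True)
class SpectrumRecord:
    """One spectral-library entry: the spectrum, the measured compound, the
    experiment parameters, and provenance (submitter, library, tags)."""

    record_id: str
    spectrum: Spectrum
    compound: CompoundInfo = CompoundInfo()
    params: tuple[ExperimentParam, ...] = ()
    splash: str | None = None
    submitter: Submitter | None = None
    library: LibraryInfo | None = None
    tags: tuple[str, ...] = ()
    peak_annotations: tuple[PeakAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")


def validate_record(record: SpectrumRecord) -> list[str]:
    """Total record validation; empty list iff the record is well-formed."""
    violations = [f"spectrum: {v}" for v in validate_spectrum(record.spectrum)]
    mzs = record.spectrum.mz
    for i, ann in enumerate(record.peak_annotations):
        if not any(abs(ann.mz - mz) <= ANNOTATION_MZ_TOLERANCE for mz in mzs):
            violations.append(f"peak annotation @{i}: m/z {ann.mz} matches no peak")
    return violations


class ReaderError(ValueError):
    """Raised on malformed input, carrying the entry ordinal (0-based)."""

    def __init__(self, message: str, entry: int | None = None, line: int | None = None):
        super().__init__(message)
        self.entry = entry
        self.line = line


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

_KNOWN_IDENTIFIER_NAMES = {
    "pubchem cid": IdentifierScheme.PUBCHEM_CID,
    "chebi": IdentifierScheme.CHEBI,
    "cas": IdentifierScheme.CAS,
}


def _msp_entry_to_record(
    headers: list[tuple[str, str, int]],
    peak_lines: list[tuple[str, int]],
    ordinal: int,
) -> SpectrumRecord:
    name = None
    precursor_mz = None
    ion_mode = IonMode.UNKNOWN
    inchi = inchikey = splash = None
    qualities: list[Quality] = []
    params: list[ExperimentParam] = []
    declared_peaks: int | None = None
    for key, value, lineno in headers:
        upper = key.upper().replace(" ", "")
        if upper == "NAME":
            name = value
        elif upper == "PRECURSORMZ":
            try:
                precursor_mz = float(value)
            except ValueError:
                raise ReaderError(
                    f"entry {ordinal}, line {lineno}: bad precursor m/z {value!r}",
                    ordinal,
                    lineno,
                )
            params.append(ExperimentParam("precursor m/z", precursor_mz))
        elif upper == "PRECURSORTYPE":
            params.append(ExperimentParam("precursor type", value))
        elif upper == "IONMODE":
            lowered = value.strip().lower()
            if lowered in ("positive", "negative"):
                ion_mode = IonMode(lowered)
            params.append(ExperimentParam("ion mode", lowered))
        elif upper == "INCHIKEY":
            inchikey = value
        elif upper == "INCHI":
            inchi = value
        elif upper == "FORMULA":
            qualities.append(Quality("molecular formula", value))
        elif upper == "SPLASH":
            splash = value
        elif upper == "COMMENT":
            params.append(ExperimentParam("comment", value))
        elif upper == "NUMPEAKS":
            try:
                declared_peaks = int(value)
            except ValueError:
                raise ReaderError(
                    f"entry {ordinal}, line {lineno}: bad peak count {value!r}",
                    ordinal,
                    lineno,
                )
        else:
            params.append(ExperimentParam(key, value))
    if declared_peaks is None:
        raise ReaderError(f"entry {ordinal}: missing 'Num Peaks' header", ordinal)
    if declared_peaks != len(peak_lines):
        raise ReaderError(
            f"entry {ordinal}: Num Peaks declares {declared_peaks} "
            f"but {len(peak_lines)} peak lines found",
            ordinal,
        )
    peaks = []
    for text, lineno in peak_lines:
        fields = text.replace(";", " ").split()
        if len(fields) < 2:
            raise ReaderError(
                f"entry {ordinal}, line {lineno}: unparsable peak line {text!r}",
                ordinal,
                lineno,
            )
        try:
            peaks.append(Peak(float(fields[0]), float(fields[1])))
        except ValueError:
            raise ReaderError(
                f"entry {ordinal}, line {lineno}: unparsable peak line {text!r}",
                ordinal,
                lineno,
            )
    peaks.sort(key=lambda p: p.mz)
    spectrum = Spectrum(peaks, precursor_mz=precursor_mz, ion_mode=ion_mode)
    compound = CompoundInfo(
        inchi=inchi,
        inchikey=inchikey,
        names=(name,) if name else (),
        qualities=tuple(qualities),
    )
    return SpectrumRecord(
        record_id=name or f"msp-{ordinal}",
        spectrum=spectrum,
        compound=compound,
        params=tuple(params),
        splash=splash,
        library=LibraryInfo(name="msp"),
    )


def read_msp(stream: IO[str], strict: bool = True) -> list[SpectrumRecord]:
    """Read blank-line-separated MSP entries.

    Header matching is case-insensitive and whitespace-tolerant; headers the
    reader does not know are preserved as experiment parameters under their
    literal names.  In strict mode (default) any malformed entry raises
    :class:`ReaderError`; in lenient mode it is skipped with a logged warning.
    """
    records: list[SpectrumRecord] = []
    headers: list[tuple[str, str, int]] = []
    peak_lines: list[tuple[str, int]] = []
    in_peaks = False
    ordinal = 0

    def flush() -> None:
        nonlocal headers, peak_lines, in_peaks, ordinal
        if not headers and not peak_lines:
            return
        try:
            records.append(_msp_entry_to_record(headers, peak_lines, ordinal))
        except ReaderError:
            if strict:
                raise
            logger.warning("skipping malformed MSP entry %d", ordinal)
        finally:
            headers, peak_lines, in_peaks = [], [], False
            ordinal += 1

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if in_peaks:
            peak_lines.append((line, lineno))
            continue
        if ":" in line:
            key, _, value = line.partition(":")
            headers.append((key.strip(), value.strip(), lineno))
            if key.strip().upper().replace(" ", "") == "NUMPEAKS":
                in_peaks = True
        else:
            peak_lines.append((line, lineno))
    flush()
    return records


# ---------------------------------------------------------------------------
# MoNA-style JSON
# ---------------------------------------------------------------------------


def _number_or_text(value) -> str | float:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, float)):
        return float(value)
    return str(value)


def _compound_from_json(block: dict) -> CompoundInfo:
    names = tuple(n["name"] for n in block.get("names", []))
    identifiers: list[Identifier] = []
    qualities: list[Quality] = []
    classifications: list[str] = []
    for entry in block.get("metaData", []):
        name = entry["name"]
        category = entry.get("category")
        if category == "classification" or name == "classification":
            classifications.append(str(entry["value"]))
        elif category == "identifier" or name.lower() in _KNOWN_IDENTIFIER_NAMES:
            scheme = _KNOWN_IDENTIFIER_NAMES.get(name.lower(), IdentifierScheme.OTHER)
            identifiers.append(
                Identifier(
                    scheme,
                    str(entry["value"]),
                    name=name if scheme is IdentifierScheme.OTHER else None,
                )
            )
        else:
            qualities.append(
                Quality(name, _number_or_text(entry["value"]), entry.get("unit"))
            )
    return CompoundInfo(
        inchi=block.get("inchi"),
        inchikey=block.get("inchiKey"),
        names=names,
        identifiers=tuple(identifiers),
        qualities=tuple(qualities),
        classifications=tuple(classifications),
    )


def _record_from_json(element: dict, index: int) -> SpectrumRecord:
    if "id" not in element:
        raise ReaderError(f"element {index}: missing 'id'", index)
    if "spectrum" not in element:
        raise ReaderError(f"element {index}: missing 'spectrum'", index)
    try:
        spectrum = parse_spectrum_literal(element["spectrum"])
    except SpectrumCodecError as exc:
        raise ReaderError(f"element {index}: bad spectrum string: {exc}", index) from exc

    params: list[ExperimentParam] = []
    precursor_mz = None
    ion_mode = IonMode.UNKNOWN
    for entry in element.get("metaData", []):
        param = ExperimentParam(
            entry["name"], _number_or_text(entry["value"]), entry.get("unit")
        )
        params.append(param)
        if param.name == "precursor m/z":
            precursor_mz = float(param.value)
        elif param.name == "ion mode" and str(param.value) in ("positive", "negative"):
            ion_mode = IonMode(str(param.value))
    spectrum = Spectrum(spectrum.peaks, precursor_mz=precursor_mz, ion_mode=ion_mode)

    compounds = element.get("compound", [])
    compound = _compound_from_json(compounds[0]) if compounds else CompoundInfo()

    submitter = None
    if "submitter" in element:
        submitter = Submitter(
            element["submitter"]["name"], element["submitter"].get("email")
        )
    library = None
    if "library" in element:
        library = LibraryInfo(
            element["library"]["name"], element["library"].get("description")
        )
    annotations = tuple(
        PeakAnnotation(mz=float(a["value"]), text=str(a["name"]))
        for a in element.get("annotations", [])
    )
    return SpectrumRecord(
        record_id=str(element["id"]),
        spectrum=spectrum,
        compound=compound,
        params=tuple(params),
        splash=element.get("splash", {}).get("splash"),
        submitter=submitter,
        library=library,
        tags=tuple(t["text"] for t in element.get("tags", [])),
        peak_annotations=annotations,
    )


def read_mona_json(stream: IO[str], strict: bool = True) -> list[SpectrumRecord]:
    """Read a JSON array of MoNA-style record objects."""
    data = json.load(stream)
    if not isinstance(data, list):
        raise ReaderError("top-level JSON value must be an array")
    records = []
    for index, element in enumerate(data):
        try:
            records.append(_record_from_json(element, index))
        except ReaderError:
            if strict:
                raise
            logger.warning("skipping malformed JSON element %d", index)
    return records


def _compound_to_json(compound: CompoundInfo) -> dict:
    block: dict = {}
    if compound.inchi is not None:
        block["inchi"] = compound.inchi
    if compound.inchikey is not None:
        block["inchiKey"] = compound.inchikey
    if compound.names:
        block["names"] = [{"name": n} for n in compound.names]
    meta = []
    for ident in compound.identifiers:
        meta.append(
            {
                "name": ident.name if ident.scheme is IdentifierScheme.OTHER else ident.scheme.value,
                "value": ident.value,
                "category": "identifier",
            }
        )
    for quality in compound.qualities:
        entry: dict = {"name": quality.kind, "value": quality.value}
        if quality.unit is not None:
            entry["unit"] = quality.unit
        meta.append(entry)
    for cls in compound.classifications:
        meta.append({"name": "classification", "value": cls, "category": "classification"})
    if meta:
        block["metaData"] = meta
    return block


def write_records_json(records: Iterable[SpectrumRecord], stream: IO[str]) -> None:
    """Write records in the same JSON dialect :func:`read_mona_json` accepts.

    A ``precursor m/z`` metaData entry is synthesised when the spectrum
    carries a precursor that no experiment parameter already states, so the
    precursor survives the round trip.
    """
    elements = []
    for record in records:
        element: dict = {
            "id": record.record_id,
            "spectrum": serialize_spectrum_literal(record.spectrum),
        }
        meta = []
        has_precursor_param = False
        for param in record.params:
            entry = {"name": param.name, "value": param.value}
            if param.unit is not None:
                entry["unit"] = param.unit
            meta.append(entry)
            has_precursor_param = has_precursor_param or param.name == "precursor m/z"
        if record.spectrum.precursor_mz is not None and not has_precursor_param:
            meta.append({"name": "precursor m/z", "value": record.spectrum.precursor_mz})
        if meta:
            element["metaData"] = meta
        compound = _compound_to_json(record.compound)
        if compound:
            element["compound"] = [compound]
        if record.splash is not None:
            element["splash"] = {"splash": record.splash}
        if record.submitter is not None:
            submitter = {"name": record.submitter.name}
            if record.submitter.email is not None:
                submitter["email"] = record.submitter.email
            element["submitter"] = submitter
        if record.library is not None:
            library = {"name": record.library.name}
            if record.library.description is not None:
                library["description"] = record.library.description
            element["library"] = library
        if record.tags:
            element["tags"] = [{"text": t} for t in record.tags]
        if record.peak_annotations:
            element["annotations"] = [
                {"name": a.text, "value": a.mz} for a in record.peak_annotations
            ]
        elements.append(element)
    json.dump(elements, stream, indent=1)
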