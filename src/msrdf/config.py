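"""Runtime configuration: namespaces, parse strictness, similarity defaults.

The ``ms:`` namespace is deliberately configurable.  Locally it defaults to a
placeholder IRI; users who want queries that are portable to a hosted endpoint
exposing the same extension functions can point it at that endpoint's function
namespace instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

DEFAULT_MS_NAMESPACE = "http://example.org/ms/"
DEFAULT_BASE_IRI = "http://example.org/msrdf/"


@dataclass(frozen=True)
class Config:
    """Package-wide settings.

    Parameters
    ----------
    ms_namespace:
        Namespace under which the ``ms:spectrum`` datatype and the three
        similarity extension functions live.
    base_iri:
        Prefix for all minted node IRIs (experiments, compounds, ...).
    strict:
        When true, malformed records or literals raise; when false they are
        skipped with a logged warning.
    tolerance:
        Default peak-matching tolerance in daltons for the SPARQL surface.
    precursor_window:
        Optional prefilter for similarity search: candidate spectra whose
        precursor m/z differs from the query's by more than this many daltons
        are skipped without scoring.  ``None`` disables the prefilter.
    """

    ms_namespace: str = DEFAULT_MS_NAMESPACE
    base_iri: str = DEFAULT_BASE_IRI
    strict: bool = True
    tolerance: float = 0.1
    precursor_window: float | None = None

    @property
    def spectrum_datatype(self) -> str:
        return self.ms_namespace + "spectrum"

    def with_options(self, **kwargs) -> "Config":
        return replace(self, **kwargs)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def load_config(path: str | Path) -> Config:
    """Read a ``key=value`` config file; unknown keys raise ``KeyError``."""
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in ("ms_namespace", "base_iri"):
            values[key] = value
        elif key == "strict":
            values[key] = _BOOL[value.lower()]
        elif key == "tolerance":
            values[key] = float(value)
        elif key == "precursor_window":
            values[key] = None if value.lower() in ("none", "") else float(value)
        else:
            raise KeyError(f"unknown config key {key!r} (line {lineno})")
    return Config(**values)  # type: ignore[arg-type]
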