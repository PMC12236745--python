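"""Diagnostic fragment-ion queries and chemical-class spectrum classifiers.

Implements the MS2PROD subset of the MassQL query language used to
validate compound-class assignments from MS/MS spectra: a query is a
conjunction of product-ion clauses, each requiring a fragment peak within a
m/z tolerance of a target and above an intensity floor expressed as a
percentage of the base peak, e.g.::

    QUERY scaninfo(MS2DATA) WHERE MS2PROD=337.25:TOLERANCEMZ=0.01:INTENSITYPERCENT=5
        AND MS2PROD=319.24:TOLERANCEMZ=0.01:INTENSITYPERCENT=5

Built-in queries cover the five bile-acid steroid-core hydroxylation
states (fragment pairs derived from the C24 core water-loss ladder) and
the acylcarnitine diagnostic cations (trimethylammonium m/z ~60.081 and
acylium m/z ~85.028).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import chem
from .datasets import Spectrum

__all__ = [
    "Ms2ProdClause",
    "DiagnosticQuery",
    "QueryError",
    "parse_query",
    "match_query",
    "bile_acid_queries",
    "carnitine_query",
    "classify_bile_acid",
    "classify_carnitine",
]

_HYDROXYL_LABELS = {
    1: "Monohydroxylated",
    2: "Dihydroxylated",
    3: "Trihydroxylated",
    4: "Tetrahydroxylated",
    5: "Pentahydroxylated",
}


class QueryError(ValueError):
    """Query text outside the supported MS2PROD grammar."""


@dataclass(frozen=True)
class Ms2ProdClause:
    target_mz: float
    tolerance_mz: float = 0.01
    min_intensity_percent: float = 5.0

    def __post_init__(self) -> None:
        if self.tolerance_mz <= 0:
            raise QueryError("TOLERANCEMZ must be positive")
        if not 0.0 <= self.min_intensity_percent <= 100.0:
            raise QueryError("INTENSITYPERCENT must be in [0, 100]")


@dataclass(frozen=True)
class DiagnosticQuery:
    clauses: tuple[Ms2ProdClause, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise QueryError("query needs at least one MS2PROD clause")


_CLAUSE = re.compile(
    r"MS2PROD=(?P<mz>[0-9.]+)"
    r"(?::TOLERANCEMZ=(?P<tol>[0-9.]+))?"
    r"(?::INTENSITYPERCENT=(?P<pct>[0-9.]+))?"
)
_SKIP = re.compile(r"(?:QUERY|scaninfo\(MS2DATA\)|WHERE|AND|\s|-)+", re.IGNORECASE)


def parse_query(text: str) -> DiagnosticQuery:
    """Parse an MS2PROD conjunction, tolerating the run-together spellings
    ``WHEREMS2PROD=``/``ANDMS2PROD=`` that appear in shared query lists.

    An optional leading label (e.g. ``"Trihydroxylated - QUERY ..."``) is
    captured as the query label.
    """
    if not text or not text.strip():
        raise QueryError("empty query")
    label = ""
    body = text.strip()
    if " - QUERY" in body:
        label, body = body.split(" - QUERY", 1)
        label = label.strip()
        body = "QUERY" + body
    clauses: list[Ms2ProdClause] = []
    pos = 0
    while pos < len(body):
        skip = _SKIP.match(body, pos)
        if skip and skip.end() > pos:
            pos = skip.end()
            continue
        m = _CLAUSE.match(body, pos)
        if not m:
            raise QueryError(f"unrecognized query token at: {body[pos:pos + 25]!r}")
        try:
            clauses.append(
                Ms2ProdClause(
                    target_mz=float(m.group("mz")),
                    tolerance_mz=float(m.group("tol") or 0.01),
                    min_intensity_percent=float(m.group("pct") or 5.0),
                )
            )
        except ValueError as exc:
            raise QueryError(f"non-numeric clause value in {m.group(0)!r}") from exc
        pos = m.end()
    if not clauses:
        raise QueryError(f"no MS2PROD clause found in {text!r}")
    return DiagnosticQuery(clauses=tuple(clauses), label=label)


def match_query(spectrum: Spectrum, query: DiagnosticQuery) -> bool:
    """True iff every clause finds a peak within tolerance of its target at
    or above its intensity floor (percent of the base peak).

    Invariant to global intensity scaling of the spectrum.
    """
    base = spectrum.base_peak_intensity
    if base <= 0:
        return False
    for clause in query.clauses:
        floor = clause.min_intensity_percent / 100.0 * base
        near = abs(spectrum.mz - clause.target_mz) <= clause.tolerance_mz
        if not bool((spectrum.intensity[near] >= floor).any()):
            return False
    return True


def bile_acid_queries(
    tolerance_mz: float = 0.01, min_intensity_percent: float = 5.0
) -> list[DiagnosticQuery]:
    """The five built-in hydroxylation-state queries, fragment pairs derived
    from the C24 steroid-core water-loss ladder."""
    queries = []
    for n in range(1, 6):
        first, second = chem.bile_core_diagnostic_ions(n)
        queries.append(
            DiagnosticQuery(
                clauses=(
                    Ms2ProdClause(first, tolerance_mz, min_intensity_percent),
                    Ms2ProdClause(second, tolerance_mz, min_intensity_percent),
                ),
                label=_HYDROXYL_LABELS[n],
            )
        )
    return queries


def carnitine_query(
    tolerance_mz: float = 0.01, min_intensity_percent: float = 5.0
) -> DiagnosticQuery:
    """Acylcarnitine diagnostic query: both the trimethylammonium and
    acylium fragment cations must be present."""
    tma, acylium = chem.CARNITINE_FRAGMENTS
    return DiagnosticQuery(
        clauses=(
            Ms2ProdClause(round(tma, 4), tolerance_mz, min_intensity_percent),
            Ms2ProdClause(round(acylium, 4), tolerance_mz, min_intensity_percent),
        ),
        label="Carnitine",
    )


def classify_bile_acid(spectrum: Spectrum) -> str:
    """Bile-acid hydroxylation label for a spectrum, or ``"none"``.

    Evaluates the five built-in queries; on the (rare) event of multiple
    matches from dense water-loss ladders the most-hydroxylated label wins,
    since higher-water-loss ions are the more specific evidence.
    """
    matches = [
        n for n, q in enumerate(bile_acid_queries(), start=1) if match_query(spectrum, q)
    ]
    if not matches:
        return "none"
    return _HYDROXYL_LABELS[max(matches)]


def classify_carnitine(spectrum: Spectrum) -> bool:
    """True iff both carnitine diagnostic ions are present (0.01 Da, >=5 %
    of base peak)."""
    return match_query(spectrum, carnitine_query())
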