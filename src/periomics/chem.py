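"""Chemical-formula parsing and exact-mass / adduct arithmetic.

Positive-mode small-molecule annotation in untargeted metabolomics rests on
a handful of arithmetic primitives: monoisotopic masses from an isotope
table, electron-corrected adduct deltas, formula addition/subtraction for
conjugation chemistry (e.g. a bile acid glycosidically bound to a hexose
with loss of one water), and the water-loss fragment ladder of the C24
steroid core that underlies the diagnostic-ion queries for bile-acid
hydroxylation states.

Masses are monoisotopic (most abundant isotope), pinned to the IUPAC 2021
atomic-mass evaluation so that computed m/z values are reproducible without
external lookups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "Formula",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "fragment_cation_mz",
    "conjugate",
    "bile_core_diagnostic_ions",
    "ppm_error",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "WATER_MASS",
    "HEXOSE_LOSS",
    "ADDUCTS",
]

# Monoisotopic atomic masses, IUPAC 2021 (Da).
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503190,
    "N": 14.00307400425,
    "O": 15.99491461926,
    "S": 31.97207117354,
    "P": 30.97376199768,
    "Na": 22.98976928195,
    "K": 38.96370648482,
    "Cl": 34.968852694,
    "F": 18.99840316207,
}

ELECTRON_MASS = 0.000548579909
#: m/z shift of protonation, electron-corrected (1.007276 Da).
PROTON_MASS = ISOTOPE_MASS["H"] - ELECTRON_MASS
#: m/z shift of the ammonium adduct, electron-corrected (18.033823 Da).
AMMONIUM_MASS = ISOTOPE_MASS["N"] + 4 * ISOTOPE_MASS["H"] - ELECTRON_MASS
#: Neutral water, 18.010565 Da.
WATER_MASS = 2 * ISOTOPE_MASS["H"] + ISOTOPE_MASS["O"]
#: Neutral loss of a hexose bound via a glycosidic bond (C6H10O5), 162.0528 Da.
HEXOSE_LOSS = 6 * ISOTOPE_MASS["C"] + 10 * ISOTOPE_MASS["H"] + 5 * ISOTOPE_MASS["O"]

#: adduct name -> (mass delta in Da, charge)
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, 1),
    "[M+NH4]+": (AMMONIUM_MASS, 1),
    "[M-H]-": (-PROTON_MASS, -1),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string, unknown element, or negative element count."""


@dataclass(frozen=True)
class Formula:
    """Element-count map with non-negative counts.

    Supports ``+`` and ``-``; subtraction raising :class:`FormulaError`
    whenever it would drive any element count negative.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ISOTOPE_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {el} count ({new})"
                )
            merged[el] = new
        return Formula(merged)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts = []
        order = ["C", "H"] + sorted(set(self.counts) - {"C", "H"})
        for el in order:
            n = self.counts.get(el, 0)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``"C26H45NO7S"``.

    Counts default to 1; repeated element symbols accumulate.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"malformed formula {text!r} at position {pos}: "
                f"{text[pos:match.start()]!r}"
            )
        el, digits = match.groups()
        if not el:
            break
        if el not in ISOTOPE_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r}: trailing {text[pos:]!r}")
    return Formula(counts)


def monoisotopic_mass(f: Formula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return float(sum(ISOTOPE_MASS[el] * n for el, n in f.counts.items()))


def adduct_mz(f: Formula | str, adduct: str = "[M+H]+") -> float:
    """Electron-corrected m/z of a singly charged adduct of ``f``.

    Supported adducts: ``[M+H]+``, ``[M+NH4]+``, ``[M-H]-`` (the Unicode
    minus sign is accepted too).
    """
    name = adduct.replace("−", "-").replace("–", "-")
    if name not in ADDUCTS:
        raise FormulaError(f"unsupported adduct {adduct!r}")
    delta, charge = ADDUCTS[name]
    return (monoisotopic_mass(f) + delta) / abs(charge)


def fragment_cation_mz(f: Formula | str) -> float:
    """m/z of an even-electron fragment cation: formula mass minus one electron.

    Used for diagnostic fragments quoted as cation compositions, e.g. the
    carnitine trimethylammonium fragment C3H10N+ and acylium C4H5O2+.
    """
    return monoisotopic_mass(f) - ELECTRON_MASS


def conjugate(f: Formula | str, g: Formula | str, lose_water: bool = True) -> Formula:
    """Combine two formulas, optionally eliminating one water.

    Models condensation chemistry such as hexose conjugation of a bile acid:
    C26H45NO7S + C6H12O6 - H2O -> C32H55NO12S.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if isinstance(g, str):
        g = parse_formula(g)
    out = f + g
    if lose_water:
        out = out - Formula({"H": 2, "O": 1})
    return out


def bile_core_diagnostic_ions(n_hydroxyl: int) -> tuple[float, float]:
    """Diagnostic fragment pair for a C24 bile-acid steroid core with
    ``n_hydroxyl`` hydroxyl groups.

    The core formula is C24H40O(n+2) (n hydroxyls plus the carboxylic acid's
    two oxygens).  In positive mode the characteristic fragments are the
    protonated core having lost all hydroxyls plus one and two further
    waters: [M+H-(n+1)*H2O]+ and [M+H-(n+2)*H2O]+, reported rounded to two
    decimals as used in fragment-ion queries (e.g. 337.25 / 319.24 for the
    trihydroxylated core).
    """
    if not 1 <= int(n_hydroxyl) <= 5:
        raise ValueError(f"n_hydroxyl must be in 1..5, got {n_hydroxyl}")
    n = int(n_hydroxyl)
    core = Formula({"C": 24, "H": 40, "O": n + 2})
    mh = adduct_mz(core, "[M+H]+")
    return (
        round(mh - (n + 1) * WATER_MASS, 2),
        round(mh - (n + 2) * WATER_MASS, 2),
    )


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# Diagnostic fragment cations of acylcarnitines: the trimethylammonium
# fragment C3H10N+ and the dehydrated carnitine acylium C4H5O2+.
CARNITINE_FRAGMENTS: tuple[float, float] = (
    fragment_cation_mz("C3H10N"),
    fragment_cation_mz("C4H5O2"),
)
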