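"""Chemical formulae, monoisotopic masses, isotope patterns and adducts.

Everything downstream of feature detection reduces to small-molecule mass
arithmetic: parsing a Hill-notation molecular formula, computing its
monoisotopic mass from a packaged isotope table, predicting the coarse
(nominal-mass-aggregated) isotopologue distribution used for isotope
similarity scoring, and turning a neutral mass into an adduct m/z.

The charge-carrier convention is explicit: ``[M+H]+`` adds the mass of a
proton (H atom minus an electron), ``[M-H]-`` removes it, ``[M+Na]+`` adds a
sodium cation (Na minus an electron), and ``[M]+`` is electron loss only.
This convention reproduces printed mass errors of reference identifications
to ~0.1 ppm, whereas the H-atom convention is off by ~2.7 ppm at m/z 206.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ChemicalFormula",
    "AdductSpec",
    "IsotopePattern",
    "ADDUCTS",
    "get_adduct",
    "parse_formula",
    "monoisotopic_mass",
    "isotope_pattern",
    "adduct_mz",
    "ppm_error",
]

#: Mass of a proton in Da (H atom minus one electron).
PROTON_MASS = 1.007276466621
#: Electron rest mass in Da.
ELECTRON_MASS = 0.000548579909


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


# ---------------------------------------------------------------------------
# Packaged element table
# ---------------------------------------------------------------------------

def _load_element_table() -> dict[str, list[tuple[float, float]]]:
    """Read data/elements.tsv into {element: [(isotope mass, abundance), ...]},
    sorted by abundance so the principal (monoisotopic) isotope comes first."""
    table: dict[str, list[tuple[float, float]]] = {}
    text = resources.files("twims4d").joinpath("data/elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        element, mass, abundance = line.split("\t")
        table.setdefault(element, []).append((float(mass), float(abundance)))
    for isotopes in table.values():
        isotopes.sort(key=lambda t: -t[1])
    return table


#: element symbol -> isotopes as (mass, abundance), most abundant first.
ELEMENTS: dict[str, list[tuple[float, float]]] = _load_element_table()

#: element symbol -> principal-isotope (monoisotopic) mass.
ELEMENT_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ELEMENTS.items()}


# ---------------------------------------------------------------------------
# Formulae
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition, e.g. ``ChemicalFormula({"C": 11, ...})``.

    Counts are strictly positive and every symbol must exist in the packaged
    element table. Instances are hashable and compare by composition.
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts:
            raise FormulaError("formula must contain at least one element")
        for el, n in counts.items():
            if el not in ELEMENTS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 1:
                raise FormulaError(f"count for {el} must be a positive integer, got {n!r}")
        object.__setattr__(self, "element_counts", counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.element_counts.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemicalFormula):
            return NotImplemented
        return dict(self.element_counts) == dict(other.element_counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        counts = dict(self.element_counts)
        out = []
        for el in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
            if el in counts:
                n = counts[el]
                out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-notation formula string such as ``"C11H12N2O2"``.

    Parentheses, charges and isotope labels are not supported; charges are the
    business of :class:`AdductSpec`. Repeated element tokens are summed.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = match.groups()
        if el not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: ChemicalFormula | str) -> float:
    """Monoisotopic (principal-isotope) mass of a formula in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return float(
        sum(n * ELEMENT_MASS[el] for el, n in formula.element_counts.items())
    )


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of the M, M+1, M+2, ... isotopologue peaks.

    Aggregated by nominal mass shift (no fine structure) and normalized to
    sum to one.
    """

    relative_abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        abund = tuple(float(a) for a in self.relative_abundances)
        if len(abund) < 2:
            raise ValueError("isotope pattern needs at least two peaks")
        if any(a < 0 or a > 1 for a in abund):
            raise ValueError("abundances must lie in [0, 1]")
        if abs(sum(abund) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1 within 1e-9")
        object.__setattr__(self, "relative_abundances", abund)

    def __len__(self) -> int:
        return len(self.relative_abundances)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.relative_abundances, dtype=float)


def _element_shift_poly(element: str) -> np.ndarray:
    """Abundance polynomial of one atom over nominal mass shifts [p0, p1, ...]."""
    isotopes = ELEMENTS[element]
    principal_mass = isotopes[0][0]
    max_shift = max(int(round(m - principal_mass)) for m, _ in isotopes)
    poly = np.zeros(max_shift + 1)
    for mass, abundance in isotopes:
        shift = int(round(mass - principal_mass))
        if shift < 0:
            raise ValueError(
                f"element {element} has an isotope lighter than its principal one; "
                "nominal-shift aggregation does not apply"
            )
        poly[shift] += abundance
    return poly


def _poly_power(poly: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """poly**n by binary exponentiation, truncating to max_len coefficients."""
    result = np.array([1.0])
    base = poly.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return result


def isotope_pattern(formula: ChemicalFormula | str, n_peaks: int = 4) -> IsotopePattern:
    """Aggregated isotopologue distribution of a formula.

    Computed by polynomial expansion: each element contributes the n-fold
    convolution of its single-atom abundance polynomial over nominal mass
    shifts, and elements are convolved together. The result is truncated to
    ``n_peaks`` entries and renormalized.

    Parameters
    ----------
    formula : ChemicalFormula or str
    n_peaks : int
        Number of isotopologue peaks to keep, between 2 and 4.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if n_peaks < 2:
        raise ValueError("n_peaks must be at least 2")
    if n_peaks > 4:
        raise ValueError("patterns are aggregated up to M+3 only (n_peaks <= 4)")
    dist = np.array([1.0])
    for el, count in formula.element_counts.items():
        dist = np.convolve(dist, _poly_power(_element_shift_poly(el), count, n_peaks))
        dist = dist[:n_peaks]
    if len(dist) < n_peaks:
        dist = np.pad(dist, (0, n_peaks - len(dist)))
    dist = dist / dist.sum()
    return IsotopePattern(tuple(dist.tolist()))


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """A named ionization adduct with its signed mass delta and charge."""

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float  # Da, includes the charge-carrier/electron convention
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


_NA = ELEMENT_MASS["Na"]
_H_ATOM = ELEMENT_MASS["H"]
_H2O = 2 * _H_ATOM + ELEMENT_MASS["O"]

#: Registry of the adducts observed in ESI+ / ESI- small-molecule work.
ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", "positive", PROTON_MASS),
        AdductSpec("[M+Na]+", "positive", _NA - ELECTRON_MASS),
        AdductSpec("[M+H-H2O]+", "positive", PROTON_MASS - _H2O),
        AdductSpec("[M]+", "positive", -ELECTRON_MASS),
        AdductSpec("[M-H]-", "negative", -PROTON_MASS),
        AdductSpec("[M+Na-2H]-", "negative", _NA - 2 * _H_ATOM + ELECTRON_MASS),
    ]
}


def get_adduct(name: str) -> AdductSpec:
    """Look up an adduct by name; Unicode minus signs are normalized."""
    key = name.replace("−", "-").replace("–", "-")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unknown adduct {name!r}; known: {sorted(ADDUCTS)}") from None


def adduct_mz(neutral_mass: float, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of a neutral mass under a given adduct."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return (neutral_mass + adduct.mass_delta) / adduct.charge


def ppm_error(measured_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if measured_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (measured_mz - theoretical_mz) / theoretical_mz
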