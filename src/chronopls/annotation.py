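"""Formula-based mass annotation: monoisotopic masses, adduct m/z, ppm
errors and biotransformation mass-shift matching.

Theoretical m/z values follow the convention common in printed annotation
tables: the neutral monoisotopic mass plus the mass of a neutral hydrogen
atom (or sodium atom) — i.e. the electron mass is ignored. The physically
exact convention (proton / sodium cation masses) is available behind
``electron_correction=True``; the difference is ~0.0005 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: monoisotopic masses of the most abundant isotopes (Da)
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.9897692809,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
    "K": 38.9637069,
    "F": 18.99840320,
    "Br": 78.9183376,
    "I": 126.904468,
    "Si": 27.9769265327,
}

_ELECTRON = 0.0005485799
_H_ATOM = MONOISOTOPIC["H"]
_NA_ATOM = MONOISOTOPIC["Na"]

ADDUCTS = {
    "M+H": (_H_ATOM, _H_ATOM - _ELECTRON),
    "M+Na": (_NA_ATOM, _NA_ATOM - _ELECTRON),
}

#: common microbial biotransformation mass shifts (monoisotopic Da)
DEFAULT_SHIFTS = {
    "hydrogenation": 2 * _H_ATOM,            # +H2, +2.015650
    "dehydrogenation": -2 * _H_ATOM,
    "hydration": 2 * _H_ATOM + MONOISOTOPIC["O"],   # +H2O, +18.010565
    "dehydration": -(2 * _H_ATOM + MONOISOTOPIC["O"]),
    "oxidation": MONOISOTOPIC["O"],           # +O, +15.994915
    "methylation": MONOISOTOPIC["C"] + 2 * _H_ATOM,  # +CH2
    "demethylation": -(MONOISOTOPIC["C"] + 2 * _H_ATOM),
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map with Hill-style text round-tripping."""

    counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        for el in sorted(k for k in d if k not in ("C", "H")):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)


@dataclass(frozen=True)
class MassMatch:
    experimental_mz: float
    formula: Formula
    adduct: str
    theoretical_mz: float
    error_ppm: float


class FormulaError(ValueError):
    """Malformed molecular formula text."""


def parse_formula(text: str) -> Formula:
    """Parse Hill-style formula text such as ``C18H35NO2``."""
    text = text.strip()
    if not text:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}: {text[pos]!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC:
            raise FormulaError(f"unknown element {el!r} at position {pos} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return Formula(tuple(sorted(counts.items())))


def monoisotopic_mass(formula: Formula | str) -> float:
    """Sum of most-abundant-isotope masses (Da)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    d = formula.as_dict()
    if not d or sum(d.values()) == 0:
        raise FormulaError("formula has no atoms")
    return sum(MONOISOTOPIC[el] * n for el, n in d.items())


def adduct_mz(
    formula: Formula | str, adduct: str, electron_correction: bool = False
) -> float:
    """Theoretical m/z of a singly charged adduct ion."""
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    neutral, exact = ADDUCTS[adduct]
    return monoisotopic_mass(formula) + (exact if electron_correction else neutral)


def ppm_error(experimental_mz: float, theoretical_mz: float) -> float:
    """Signed relative error in parts per million."""
    if not theoretical_mz > 0:
        raise ValueError("theoretical m/z must be positive")
    return (experimental_mz - theoretical_mz) / theoretical_mz * 1e6


def match_mass(
    experimental_mz: float,
    formula: Formula | str,
    adduct: str = "M+H",
    tol_ppm: float = 5.0,
    electron_correction: bool = False,
) -> MassMatch | None:
    """Accept a formula/adduct assignment when within the ppm tolerance."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    theo = adduct_mz(formula, adduct, electron_correction)
    err = ppm_error(experimental_mz, theo)
    if abs(err) <= tol_ppm:
        return MassMatch(experimental_mz, formula, adduct, theo, err)
    return None


def match_shift(
    precursor_mz: float,
    product_mz: float,
    hypotheses: dict[str, float] | None = None,
    tol_ppm: float = 5.0,
) -> list[str]:
    """Biotransformation hypotheses consistent with a product/precursor pair.

    A hypothesis matches when its mass delta equals ``product - precursor``
    within ``tol_ppm`` of the product mass. An empty list is a valid result.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be positive")
    hypotheses = DEFAULT_SHIFTS if hypotheses is None else hypotheses
    delta = product_mz - precursor_mz
    tol = tol_ppm * 1e-6 * abs(product_mz)
    return [name for name, d in hypotheses.items() if abs(delta - d) <= tol]
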