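"""Monoisotopic mass arithmetic: formula parsing, adduct rules, ppm errors.

All masses in unified atomic mass units (u); m/z in thomson (Th), singly
charged species only. Charge bookkeeping is done by adding/removing a proton
(hydrogen atom minus electron) so that electron mass is accounted for.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ELEMENT_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCT_RULES",
    "NEUTRAL_DELTAS",
    "AdductRule",
    "parse_formula",
    "monoisotopic_mass",
    "theoretical_mz",
    "ppm_error",
    "normalize_adduct_name",
]

#: Monoisotopic atomic masses (u).
ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "13C": 13.0033548,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "Na": 22.9897693,
}

ELECTRON_MASS: float = 0.0005485799
#: Proton = hydrogen atom minus one electron (exact identity in this table).
PROTON_MASS: float = ELEMENT_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"\((13C)\)(\d*)|(13C)(\d*)|([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a molecular formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula into element counts.

    Supports the elements in :data:`ELEMENT_MASS` plus an explicit one-13C
    marker written ``(13C)`` or ``13C`` (e.g. ``C5(13C)H10O4``).

    >>> parse_formula("C5H8O4")
    {'C': 5, 'H': 8, 'O': 4}
    """
    counts: dict[str, int] = {}
    pos = 0
    clean = formula.strip()
    while pos < len(clean):
        m = _FORMULA_TOKEN.match(clean, pos)
        if m is None:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        sym = m.group(1) or m.group(3) or m.group(5)
        num = m.group(2) or m.group(4) or m.group(6)
        if sym not in ELEMENT_MASS:
            raise FormulaError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if not counts:
        raise FormulaError(f"empty formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass (u) of a neutral molecular formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ELEMENT_MASS[el] * n for el, n in counts.items())


# convenience neutral fragment masses
MASS_H2O = 2 * ELEMENT_MASS["H"] + ELEMENT_MASS["O"]
MASS_NH3 = ELEMENT_MASS["N"] + 3 * ELEMENT_MASS["H"]
MASS_CO = ELEMENT_MASS["C"] + ELEMENT_MASS["O"]
MASS_CO2 = ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["O"]
MASS_HCOOH = ELEMENT_MASS["C"] + 2 * ELEMENT_MASS["H"] + 2 * ELEMENT_MASS["O"]
MASS_13C_SHIFT = ELEMENT_MASS["13C"] - ELEMENT_MASS["C"]


@dataclass(frozen=True)
class AdductRule:
    """A singly charged ionisation form with a fixed mass offset.

    ``mass_delta`` is applied to the neutral monoisotopic mass and already
    contains the electron bookkeeping via the proton mass.
    """

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float

    def mz(self, neutral_mass: float) -> float:
        return neutral_mass + self.mass_delta  # charge magnitude is 1


ADDUCT_RULES: dict[str, AdductRule] = {
    r.name: r
    for r in [
        AdductRule("[M+H]+", "positive", PROTON_MASS),
        AdductRule("[M-H]-", "negative", -PROTON_MASS),
        AdductRule("[M+H2O+H]+", "positive", MASS_H2O + PROTON_MASS),
        AdductRule("[M-H2O+H]+", "positive", -MASS_H2O + PROTON_MASS),
        AdductRule("[M-H2O-H]-", "negative", -MASS_H2O - PROTON_MASS),
        AdductRule("[M+NH4]+", "positive", MASS_NH3 + PROTON_MASS),
        AdductRule("[M+HCOO]-", "negative", MASS_HCOOH - PROTON_MASS),
        AdductRule("[M-CO+H]+", "positive", -MASS_CO + PROTON_MASS),
        AdductRule("[M-CO2+H]+", "positive", -MASS_CO2 + PROTON_MASS),
        AdductRule("[M-NH3+H]+", "positive", -MASS_NH3 + PROTON_MASS),
        AdductRule("[M-HCOOH+H]+", "positive", -MASS_HCOOH + PROTON_MASS),
        AdductRule("[M(C13)-H]-", "negative", MASS_13C_SHIFT - PROTON_MASS),
        AdductRule("[M(C13)+H]+", "positive", MASS_13C_SHIFT + PROTON_MASS),
    ]
}

#: Neutral mass differences used to link isotopologue/adduct/loss satellites.
NEUTRAL_DELTAS: dict[str, float] = {
    "isotope_13C": MASS_13C_SHIFT,
    "H2O": MASS_H2O,
    "NH3": MASS_NH3,
    "CO": MASS_CO,
    "CO2": MASS_CO2,
    "HCOOH": MASS_HCOOH,
}


def normalize_adduct_name(name: str) -> str:
    """Canonicalize spacing variants like ``[M + H]+`` to ``[M+H]+``."""
    return name.replace(" ", "")


def theoretical_mz(formula: str | dict[str, int], adduct: str | AdductRule) -> float:
    """Theoretical m/z (Th) of a formula observed under an ionisation form."""
    if isinstance(adduct, str):
        key = normalize_adduct_name(adduct)
        try:
            adduct = ADDUCT_RULES[key]
        except KeyError:
            raise KeyError(f"unknown adduct rule {key!r}") from None
    return adduct.mz(monoisotopic_mass(formula))


def ppm_error(measured_mz: float, formula: str | dict[str, int], adduct: str | AdductRule) -> float:
    """Relative mass error in ppm, (measured - theoretical) / theoretical x 1e6."""
    theo = theoretical_mz(formula, adduct)
    return (measured_mz - theo) / theo * 1e6
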