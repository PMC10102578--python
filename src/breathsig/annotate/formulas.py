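"""Bounded molecular-formula enumeration for a neutral monoisotopic mass."""
from __future__ import annotations

import numpy as np

from .masses import ELEMENT_MASS

__all__ = ["formula_candidates", "rdbe", "FORMULA_BOUNDS"]

#: Search bounds per element (inclusive).
FORMULA_BOUNDS = {"C": 40, "H": 80, "N": 6, "O": 10, "S": 2}

_MAX_MASS = 600.0


def rdbe(c: int, h: int, n: int) -> float:
    """Ring-plus-double-bond equivalents for a CHNOS formula."""
    return c - h / 2.0 + n / 2.0 + 1.0


def _format(c: int, h: int, n: int, o: int, s: int) -> str:
    parts = []
    for sym, cnt in (("C", c), ("H", h), ("N", n), ("O", o), ("S", s)):
        if cnt == 1:
            parts.append(sym)
        elif cnt > 1:
            parts.append(f"{sym}{cnt}")
    return "".join(parts)


def formula_candidates(neutral_mass: float, tol_ppm: float = 5.0) -> list[str]:
    """Enumerate CHNOS formulas whose monoisotopic mass matches ``neutral_mass``.

    Search space is C 0-40, H 0-80, N 0-6, O 0-10, S 0-2. Retained formulas
    must have RDBE >= 0, integer RDBE (nitrogen rule: H and N of equal
    parity), hydrogen count within the valence bound H <= 2C + N + 2, and
    H/C <= 3.1 for nitrogen-free formulas (the plain H/C screen would
    discard small N-rich molecules such as urea). Sorted by |ppm error|.
    """
    if not 0.0 < neutral_mass <= _MAX_MASS:
        raise ValueError(f"mass must be in (0, {_MAX_MASS}], got {neutral_mass}")
    mH = ELEMENT_MASS["H"]
    tol_u = neutral_mass * tol_ppm * 1e-6

    c = np.arange(FORMULA_BOUNDS["C"] + 1)
    n = np.arange(FORMULA_BOUNDS["N"] + 1)
    o = np.arange(FORMULA_BOUNDS["O"] + 1)
    s = np.arange(FORMULA_BOUNDS["S"] + 1)
    cg, ng, og, sg = np.meshgrid(c, n, o, s, indexing="ij")
    base = (
        cg * ELEMENT_MASS["C"]
        + ng * ELEMENT_MASS["N"]
        + og * ELEMENT_MASS["O"]
        + sg * ELEMENT_MASS["S"]
    )
    # for each heavy-atom skeleton, the window of H counts hitting the mass
    h_lo = np.ceil((neutral_mass - tol_u - base) / mH).astype(int)
    h_hi = np.floor((neutral_mass + tol_u - base) / mH).astype(int)
    h_lo = np.maximum(h_lo, 0)
    h_hi = np.minimum(h_hi, FORMULA_BOUNDS["H"])
    idx = np.argwhere(h_lo <= h_hi)

    out: list[tuple[float, str]] = []
    for ci, ni, oi, si in idx:
        for h in range(h_lo[ci, ni, oi, si], h_hi[ci, ni, oi, si] + 1):
            r = rdbe(ci, h, ni)
            if r < 0 or (h + ni) % 2 != 0:
                continue
            if h > 2 * ci + ni + 2:  # valence bound
                continue
            if ni == 0 and ci > 0 and h / ci > 3.1:
                continue
            mass = base[ci, ni, oi, si] + h * mH
            ppm = (mass - neutral_mass) / neutral_mass * 1e6
            if abs(ppm) <= tol_ppm:
                out.append((abs(ppm), _format(ci, h, ni, oi, si)))
    out.sort(key=lambda t: (t[0], t[1]))
    return [f for _, f in out]
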