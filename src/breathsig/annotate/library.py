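"""Compound library matching, satellite grouping, and ID confidence levels."""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .masses import (
    ADDUCT_RULES,
    NEUTRAL_DELTAS,
    AdductRule,
    monoisotopic_mass,
    normalize_adduct_name,
)

__all__ = [
    "Compound",
    "Pathway",
    "CompoundLibrary",
    "load_default_library",
    "Candidate",
    "AnnotationRecord",
    "match_features",
    "assign_id_level",
    "SatelliteGroup",
    "group_related_features",
    "EVIDENCE_FLAGS",
]

EVIDENCE_FLAGS = frozenset(
    {
        "standard_confirmed",
        "library_ms2_match",
        "insilico_ms2_candidate",
        "formula_only",
        "exact_mass_only",
    }
)

# precedence order of evidence -> Schymanski-style confidence level
_FLAG_LEVEL = [
    ("standard_confirmed", 1),
    ("library_ms2_match", 2),
    ("insilico_ms2_candidate", 3),
    ("formula_only", 4),
]


@dataclass(frozen=True)
class Compound:
    name: str
    formula: str
    pathways: tuple[str, ...] = ()

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class Pathway:
    name: str
    compounds: tuple[Compound, ...]


@dataclass
class CompoundLibrary:
    compounds: list[Compound]

    def __post_init__(self) -> None:
        self._masses = np.array([c.neutral_mass for c in self.compounds])

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def pathways(self) -> list[Pathway]:
        by_name: dict[str, list[Compound]] = {}
        for c in self.compounds:
            for p in c.pathways:
                by_name.setdefault(p, []).append(c)
        return [Pathway(n, tuple(cs)) for n, cs in sorted(by_name.items())]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompoundLibrary":
        df = pd.read_csv(path, sep="\t")
        comps = [
            Compound(
                str(r["compound"]),
                str(r["formula"]),
                tuple(p for p in str(r.get("pathways", "")).split(";") if p and p != "nan"),
            )
            for _, r in df.iterrows()
        ]
        return cls(comps)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "compound": [c.name for c in self.compounds],
                "formula": [c.formula for c in self.compounds],
                "pathways": [";".join(c.pathways) for c in self.compounds],
            }
        ).to_csv(path, sep="\t", index=False)


def load_default_library() -> CompoundLibrary:
    """Bundled library covering the study's annotated metabolites and pathways."""
    with resources.as_file(
        resources.files("breathsig.annotate").joinpath("data/compounds.tsv")
    ) as p:
        return CompoundLibrary.from_tsv(p)


@dataclass(frozen=True)
class Candidate:
    compound: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


@dataclass
class AnnotationRecord:
    feature_mz: float
    polarity: str
    candidates: list[Candidate] = field(default_factory=list)
    evidence_flags: set[str] = field(default_factory=set)
    id_level: int = 5
    pathways: tuple[str, ...] = ()


def match_features(
    feature_mzs,
    polarity: str,
    library: CompoundLibrary,
    tol_ppm: float = 15.0,
    evidence_flags: dict[float, set[str]] | None = None,
) -> list[AnnotationRecord]:
    """Match measured m/z values against all (compound, adduct) pairs.

    Retains candidates with |ppm error| <= ``tol_ppm``, sorted by |ppm|.
    Unless stronger flags are supplied per feature, records carry the
    ``exact_mass_only`` evidence flag.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    rules = [r for r in ADDUCT_RULES.values() if r.polarity == polarity]
    if not rules:
        raise ValueError(f"unknown polarity {polarity!r}")
    records = []
    for mz in feature_mzs:
        cands = []
        for comp in library.compounds:
            neutral = comp.neutral_mass
            for rule in rules:
                theo = rule.mz(neutral)
                ppm = (mz - theo) / theo * 1e6
                if abs(ppm) <= tol_ppm:
                    cands.append(Candidate(comp.name, comp.formula, rule.name, theo, ppm))
        cands.sort(key=lambda c: abs(c.ppm_error))
        flags = set(evidence_flags.get(mz, set())) if evidence_flags else set()
        if not flags & EVIDENCE_FLAGS:
            flags.add("exact_mass_only")
        pw: list[str] = []
        names = {c.compound for c in cands}
        for comp in library.compounds:
            if comp.name in names:
                pw.extend(p for p in comp.pathways if p not in pw)
        rec = AnnotationRecord(
            feature_mz=float(mz),
            polarity=polarity,
            candidates=cands,
            evidence_flags=flags,
            id_level=assign_id_level(flags),
            pathways=tuple(pw),
        )
        records.append(rec)
    return records


def assign_id_level(evidence_flags: set[str]) -> int:
    """Identification confidence level 1 (standard) .. 5 (exact mass only)."""
    if not evidence_flags:
        raise ValueError("evidence flags must be nonempty")
    unknown = evidence_flags - EVIDENCE_FLAGS
    if unknown:
        raise ValueError(f"unknown evidence flags: {sorted(unknown)}")
    for flag, level in _FLAG_LEVEL:
        if flag in evidence_flags:
            return level
    return 5


@dataclass
class SatelliteGroup:
    members: list[int]  # feature indices
    primary: int  # most intense member
    relations: dict[tuple[int, int], str]  # (low-mz idx, high-mz idx) -> delta name


def group_related_features(
    matrix: np.ndarray,
    feature_mzs,
    delta_table: dict[str, float] | None = None,
    tol_mTh: float = 5.0,
    min_corr: float = 0.9,
) -> list[SatelliteGroup]:
    """Link features that look like isotopologue/adduct/loss satellites.

    A pair is linked when its m/z difference matches a known neutral delta
    within ``tol_mTh`` milli-thomson AND the cross-sample Pearson correlation
    of intensities is >= ``min_corr``. Connected components form groups; the
    member with the highest mean intensity is the primary ion.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 3:
        raise ValueError("need >= 3 samples for correlation gating")
    mzs = np.asarray(feature_mzs, dtype=float)
    deltas = dict(delta_table) if delta_table is not None else dict(NEUTRAL_DELTAS)
    tol = tol_mTh * 1e-3

    n = len(mzs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # guard against zero-variance columns in the correlation
    sd = matrix.std(axis=0)
    relations: dict[tuple[int, int], str] = {}
    order = np.argsort(mzs)
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            diff = mzs[j] - mzs[i]
            if diff > max(deltas.values()) + tol:
                break
            name = next((k for k, v in deltas.items() if abs(diff - v) <= tol), None)
            if name is None:
                continue
            if sd[i] == 0 or sd[j] == 0:
                continue
            r = np.corrcoef(matrix[:, i], matrix[:, j])[0, 1]
            if r >= min_corr:
                union(i, j)
                relations[(int(i), int(j))] = name

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    mean_int = matrix.mean(axis=0)
    for members in comps.values():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda k: mzs[k])
        primary = max(members, key=lambda k: mean_int[k])
        rel = {k: v for k, v in relations.items() if k[0] in members and k[1] in members}
        groups.append(SatelliteGroup(members=members, primary=int(primary), relations=rel))
    groups.sort(key=lambda g: mzs[g.members[0]])
    return groups
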