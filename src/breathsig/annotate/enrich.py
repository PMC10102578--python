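"""m/z-level pathway enrichment with a permutation null over detected features.

Features are mapped to library compounds through the adduct rules; for each
pathway the number of distinct member compounds hit by the significant
feature set is compared with the hit counts of random draws of equally many
features from the full detected set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import CompoundLibrary
from .masses import ADDUCT_RULES

__all__ = ["EnrichmentResult", "enrich_pathways"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # pathway, n_compounds, hits, p_value, flag

    def __iter__(self):
        return iter(self.table.itertuples(index=False))


def _map_hits(
    mzs: np.ndarray,
    polarities: np.ndarray,
    library: CompoundLibrary,
    tol_ppm: float,
) -> list[set[str]]:
    """Per feature: set of compound names reachable via any adduct rule."""
    out: list[set[str]] = []
    comp_masses = np.array([c.neutral_mass for c in library.compounds])
    names = [c.name for c in library.compounds]
    rules_by_pol = {
        "positive": [r for r in ADDUCT_RULES.values() if r.polarity == "positive"],
        "negative": [r for r in ADDUCT_RULES.values() if r.polarity == "negative"],
    }
    for mz, pol in zip(mzs, polarities):
        hit: set[str] = set()
        for rule in rules_by_pol[pol]:
            theo = comp_masses + rule.mass_delta
            ppm = np.abs(mz - theo) / theo * 1e6
            for k in np.nonzero(ppm <= tol_ppm)[0]:
                hit.add(names[k])
        out.append(hit)
    return out


def enrich_pathways(
    sig_mzs,
    all_mzs,
    polarity_map,
    library: CompoundLibrary,
    tol_ppm: float = 15.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Permutation-based pathway over-representation on m/z features.

    Parameters
    ----------
    sig_mzs, all_mzs
        Significant feature m/z values and the full detected set
        (``sig_mzs`` must be a subset of ``all_mzs``).
    polarity_map
        Mapping m/z -> "positive"/"negative", or a single polarity string.
    """
    rng = np.random.default_rng(rng)
    all_mzs = np.asarray(list(all_mzs), dtype=float)
    sig_mzs = np.asarray(list(sig_mzs), dtype=float)
    sig_set = set(np.round(sig_mzs, 9))
    if not sig_set <= set(np.round(all_mzs, 9)):
        raise ValueError("sig_mzs must be a subset of all_mzs")

    if isinstance(polarity_map, str):
        pols = np.array([polarity_map] * len(all_mzs))
    else:
        pols = np.array([polarity_map[m] for m in all_mzs])

    hits_per_feature = _map_hits(all_mzs, pols, library, tol_ppm)
    sig_idx = np.array([m in sig_set for m in np.round(all_mzs, 9)])

    pathways = library.pathways
    pw_members = {p.name: {c.name for c in p.compounds} for p in pathways}

    def pathway_hits(mask: np.ndarray) -> dict[str, int]:
        hit_compounds: set[str] = set()
        for i in np.nonzero(mask)[0]:
            hit_compounds |= hits_per_feature[i]
        return {name: len(members & hit_compounds) for name, members in pw_members.items()}

    observed = pathway_hits(sig_idx)
    n_sig = int(sig_idx.sum())

    exceed = {name: 0 for name in pw_members}
    for _ in range(n_perm):
        mask = np.zeros(len(all_mzs), dtype=bool)
        mask[rng.choice(len(all_mzs), size=n_sig, replace=False)] = True
        perm = pathway_hits(mask)
        for name in pw_members:
            if perm[name] >= observed[name]:
                exceed[name] += 1

    rows = []
    for p in pathways:
        n_mappable = sum(1 for hits in hits_per_feature if pw_members[p.name] & hits)
        if n_mappable == 0:
            pval, flag = 1.0, "no_mappable_compounds"
        else:
            pval = (1 + exceed[p.name]) / (n_perm + 1)
            flag = ""
        rows.append(
            {
                "pathway": p.name,
                "n_compounds": len(p.compounds),
                "hits": observed[p.name],
                "p_value": pval,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows).sort_values(["p_value", "pathway"], kind="mergesort")
    return EnrichmentResult(table=table.reset_index(drop=True))
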