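"""Per-trait LD clumping and cross-metabolite merging of GWAS hits into
lead variants.

Clumping is the plink-style greedy procedure: repeatedly promote the
remaining variant with the smallest p-value below the clump threshold to
an index, and absorb every remaining sub-threshold variant within the
window at r^2 above the cutoff.  Indices from all traits are then pooled
and greedily pruned so that no two retained leads sit within the merge
radius in genetic-map distance, keeping the variant with the minimum
p-value; only leads genome-wide significant in at least one trait
survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import SumstatsTable


@dataclass
class LDInfo:
    """Sparse pairwise r-squared lookup; unlisted pairs have r^2 = 0."""

    pairs: dict[frozenset, float]

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        return self.pairs.get(frozenset((id_a, id_b)), 0.0)


def clump(
    sumstats: SumstatsTable,
    ld: LDInfo,
    trait: str,
    clump_p: float = 1e-4,
    clump_r2: float = 0.01,
    clump_window_bp: float = 1e6,
) -> list[str]:
    """Greedy LD clumping for one trait; returns index variant ids in
    discovery order.  Ties in p are broken by (chrom, pos) ascending.
    """
    if ld is None:
        raise ValueError("LD information is required for clumping")
    if trait not in sumstats.metabolites:
        raise KeyError(trait)
    df = sumstats.df
    cand = df[df[f"p_{trait}"] < clump_p]
    cand = cand.sort_values(
        [f"p_{trait}", "chrom", "pos_bp"], kind="mergesort"
    ).reset_index(drop=True)

    assigned: set[str] = set()
    indices: list[str] = []
    ids = cand["variant_id"].to_numpy()
    chroms = cand["chrom"].to_numpy()
    pos = cand["pos_bp"].to_numpy()
    for i in range(len(cand)):
        vid = ids[i]
        if vid in assigned:
            continue
        indices.append(vid)
        assigned.add(vid)
        near = (
            (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= clump_window_bp)
        )
        for j in np.nonzero(near)[0]:
            other = ids[j]
            if other in assigned:
                continue
            if ld.r2(vid, other) > clump_r2:
                assigned.add(other)
    return indices


def merge_leads(
    index_lists: dict[str, list[str]],
    sumstats: SumstatsTable,
    merge_cm: float = 0.1,
    gw_p: float = 5e-8,
    suggestive_p: float = 1e-4,
) -> pd.DataFrame:
    """Merge per-trait clump indices into lead variants.

    Pools indices over traits, sorts by min p across traits (ties by
    chrom, pos), greedily keeps the best and drops anything within
    ``merge_cm`` of an already-kept lead, then retains only leads with a
    genome-wide significant association in at least one trait.

    Returns a leads table with per-metabolite triplets plus ``min_p``,
    ``gw_metabolites`` and ``suggestive_metabolites`` (comma-joined).
    """
    pool = sorted({vid for ids in index_lists.values() for vid in ids})
    mets = sumstats.metabolites
    df = sumstats.df.set_index("variant_id", drop=False)
    missing = [v for v in pool if v not in df.index]
    if missing:
        raise KeyError(f"index variants absent from sumstats: {missing[:5]}")
    sub = df.loc[pool].copy()
    pcols = [f"p_{m}" for m in mets]
    sub["min_p"] = sub[pcols].min(axis=1)
    sub = sub.sort_values(["min_p", "chrom", "pos_bp"], kind="mergesort")

    kept: list[str] = []
    kept_pos: list[tuple[str, float]] = []
    for vid, row in sub.iterrows():
        if any(c == row["chrom"] and abs(row["cm"] - cm) < merge_cm for c, cm in kept_pos):
            continue
        kept.append(vid)
        kept_pos.append((row["chrom"], row["cm"]))

    leads = sub.loc[kept].copy()
    gw_sets, sug_sets = [], []
    for _, row in leads.iterrows():
        gw = {m for m in mets if row[f"p_{m}"] < gw_p}
        sug = {m for m in mets if row[f"p_{m}"] < suggestive_p}
        gw_sets.append(gw)
        sug_sets.append(sug)
    leads["gw_metabolites"] = [",".join(sorted(s)) if s else "" for s in gw_sets]
    leads["suggestive_metabolites"] = [",".join(sorted(s)) if s else "" for s in sug_sets]
    leads = leads.loc[np.fromiter((bool(s) for s in gw_sets), dtype=bool, count=len(gw_sets))]
    return leads.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)


def run_hits(sumstats: SumstatsTable, ld: LDInfo, config: RunConfig | None = None) -> pd.DataFrame:
    """Clump every trait then merge: the full hit-processing stage."""
    config = config or RunConfig()
    index_lists = {
        m: clump(sumstats, ld, m, config.clump_p, config.clump_r2, config.clump_window_bp)
        for m in sumstats.metabolites
    }
    return merge_leads(index_lists, sumstats, config.merge_cm, config.gw_p, config.suggestive_p)
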