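"""Pathway-level local genetic correlation: aggregate per-LD-block local
heritabilities and genetic covariance over the blocks overlapping a
pathway's gene regions, and nonparametric pathway contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .enrichstats import fligner_test, normal_two_sided_p
from .io import GeneTable
from .pathway import region_union


@dataclass
class LocalRgResult:
    pathway: str
    n_blocks: int
    rg_l: float
    se: float
    p: float
    sum_cov: float
    sum_h2_a: float
    sum_h2_b: float
    var_sum_cov: float
    var_sum_h2_a: float
    var_sum_h2_b: float


def blocks_for_pathway(
    blocks: pd.DataFrame,
    gene_ids: list[str],
    genes: GeneTable,
    flank_bp: int,
    chrom_lengths: dict[str, int],
    complement: bool = False,
) -> pd.DataFrame:
    """Blocks whose interval intersects the flanked union of the pathway's
    gene regions (or, with ``complement=True``, the blocks that do not)."""
    regions, _mb = region_union(gene_ids, genes, flank_bp, chrom_lengths)
    hit = []
    for _, blk in blocks.iterrows():
        overlaps = any(
            chrom == blk["chrom"] and s <= blk["end_bp"] and e >= blk["start_bp"]
            for chrom, s, e in regions
        )
        hit.append(overlaps != complement)
    return blocks[hit].reset_index(drop=True)


def aggregate_local_rg(block_subset: pd.DataFrame, pathway: str = "") -> LocalRgResult:
    """Sum block covariances and heritabilities into a pathway-level
    genetic correlation with a delta-method SE.

    ``rg_l = sum(cov) / sqrt(sum(h2_a) * sum(h2_b))``; the three sums are
    treated as independent, so
    ``var(rg_l) = rg_l^2 * [var(Scov)/Scov^2 + var(Sa)/(4 Sa^2) + var(Sb)/(4 Sb^2)]``.
    Non-positive heritability sums are an error, not clipped.
    """
    if len(block_subset) == 0:
        raise ValueError("empty block subset")
    s_cov = float(block_subset["cov_ab"].sum())
    s_a = float(block_subset["h2_a"].sum())
    s_b = float(block_subset["h2_b"].sum())
    v_cov = float(block_subset["var_cov"].sum())
    v_a = float(block_subset["var_h2_a"].sum())
    v_b = float(block_subset["var_h2_b"].sum())
    if s_a <= 0 or s_b <= 0:
        raise ValueError(
            f"non-positive heritability sum for pathway {pathway!r}: "
            f"sum(h2_a)={s_a:.4g}, sum(h2_b)={s_b:.4g}"
        )
    rg_l = s_cov / math.sqrt(s_a * s_b)
    if s_cov == 0:
        var_rg = v_cov / (s_a * s_b)
    else:
        var_rg = rg_l**2 * (v_cov / s_cov**2 + v_a / (4 * s_a**2) + v_b / (4 * s_b**2))
    se = math.sqrt(var_rg)
    p = normal_two_sided_p(rg_l, se) if se > 0 else (1.0 if rg_l == 0 else 0.0)
    return LocalRgResult(
        pathway=pathway, n_blocks=len(block_subset), rg_l=rg_l, se=se, p=p,
        sum_cov=s_cov, sum_h2_a=s_a, sum_h2_b=s_b,
        var_sum_cov=v_cov, var_sum_h2_a=v_a, var_sum_h2_b=v_b,
    )


def pathway_contrast_fligner(
    block_subset: pd.DataFrame, baseline_subset: pd.DataFrame
) -> tuple[float, float]:
    """Fligner-Killeen contrast of per-block genetic covariances between a
    pathway and a baseline block set."""
    return fligner_test(
        block_subset["cov_ab"].to_numpy(), baseline_subset["cov_ab"].to_numpy()
    )


def run_localrg(
    blocks: pd.DataFrame,
    pathways: dict[str, list[str]],
    genes: GeneTable,
    flank_bp: int,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Aggregate local rg for each named pathway gene set."""
    rows = []
    for name, gene_ids in sorted(pathways.items()):
        subset = blocks_for_pathway(blocks, gene_ids, genes, flank_bp, chrom_lengths)
        res = aggregate_local_rg(subset, pathway=name)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
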