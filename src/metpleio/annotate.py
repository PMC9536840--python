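"""Gene assignment for lead variants and biochemical-group assignment for
genes.

Each lead variant receives a single gene by a deterministic priority
rule: known-function genes within the standard window, plus
biologically-relevant enzymes within the (larger) enzyme window, ranked
enzyme > transporter > tf > general; within a tier, by overlap between
the gene's relevant metabolites and the variant's suggestive metabolite
set, then by proximity, then by id.  With no candidates the standard
window is widened once to the fallback size; failing that the variant is
``unknown``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .io import GeneTable

_PRIORITY = {"enzyme": 0, "transporter": 1, "tf": 2, "general": 3}


@dataclass(frozen=True)
class Annotation:
    variant_id: str
    gene_id: str | None
    gene_type: str
    distance_bp: int
    window_used_bp: int
    is_closest_gene: bool


def variant_gene_distance(chrom: str, pos_bp: int, gene: pd.Series) -> float:
    """bp distance from a variant to a gene interval; 0 inside, inf off-chromosome."""
    if gene["chrom"] != chrom:
        return math.inf
    start, end = int(gene["start_bp"]), int(gene["end_bp"])
    if start <= pos_bp <= end:
        return 0
    return min(abs(pos_bp - start), abs(pos_bp - end))


def assign_gene(
    chrom: str,
    pos_bp: int,
    variant_id: str,
    suggestive_metabolites: set[str],
    genes: GeneTable,
    config: RunConfig | None = None,
) -> Annotation:
    config = config or RunConfig()
    gdf = genes.df[genes.df["chrom"] == chrom]
    dists = {
        g["gene_id"]: variant_gene_distance(chrom, pos_bp, g) for _, g in gdf.iterrows()
    }
    closest = min(dists, key=lambda k: (dists[k], k)) if dists else None

    def candidates(window: float, enzyme_window: float | None) -> list[tuple]:
        out = []
        for _, g in gdf.iterrows():
            d = dists[g["gene_id"]]
            gtype = g["gene_type"]
            if gtype == "unknown":
                continue
            relevance = len(set(g["relevant_metabolites"]) & suggestive_metabolites)
            if d <= window:
                out.append((g, d, relevance, window))
            elif (
                enzyme_window is not None
                and gtype == "enzyme"
                and d <= enzyme_window
                and relevance > 0
            ):
                out.append((g, d, relevance, enzyme_window))
        return out

    cands = candidates(config.flank_bp, config.enzyme_flank_bp)
    if not cands:
        cands = candidates(config.fallback_flank_bp, None)
    if not cands:
        return Annotation(variant_id, None, "unknown", 0, int(config.fallback_flank_bp), False)

    def rank(item):
        g, d, relevance, _w = item
        return (_PRIORITY[g["gene_type"]], -relevance, d, g["gene_id"])

    g, d, _rel, window = min(cands, key=rank)
    return Annotation(
        variant_id=variant_id,
        gene_id=g["gene_id"],
        gene_type=g["gene_type"],
        distance_bp=int(d),
        window_used_bp=int(window),
        is_closest_gene=(g["gene_id"] == closest),
    )


def annotate_leads(leads: pd.DataFrame, genes: GeneTable, config: RunConfig | None = None) -> pd.DataFrame:
    """Annotate every lead variant; returns a tidy annotations table."""
    config = config or RunConfig()
    rows = []
    for _, lead in leads.iterrows():
        sug = set(str(lead.get("suggestive_metabolites", "") or "").split(",")) - {""}
        ann = assign_gene(
            lead["chrom"], int(lead["pos_bp"]), lead["variant_id"], sug, genes, config
        )
        rows.append(
            {
                "variant_id": ann.variant_id,
                "chrom": lead["chrom"],
                "pos_bp": int(lead["pos_bp"]),
                "gene_id": ann.gene_id if ann.gene_id is not None else ".",
                "gene_type": ann.gene_type,
                "distance_bp": ann.distance_bp,
                "window_used_bp": ann.window_used_bp,
                "is_closest_gene": ann.is_closest_gene,
            }
        )
    return pd.DataFrame(rows)


def assign_gene_groups(
    annotations: pd.DataFrame,
    leads: pd.DataFrame,
    groups_of_metabolite: dict[str, str],
    suggestive_p: float = 1e-4,
) -> dict[str, frozenset]:
    """Assign each annotated gene to the biochemical group(s) with the
    most suggestive metabolite associations across its variants; all tied
    groups are returned.
    """
    mets = [m for m in groups_of_metabolite]
    leads_by_id = leads.set_index("variant_id")
    counts: dict[str, dict[str, int]] = {}
    for _, ann in annotations.iterrows():
        gene = ann["gene_id"]
        if gene in (None, "."):
            continue
        lead = leads_by_id.loc[ann["variant_id"]]
        tally = counts.setdefault(gene, {})
        for m in mets:
            if lead.get(f"p_{m}", 1.0) < suggestive_p:
                grp = groups_of_metabolite[m]
                tally[grp] = tally.get(grp, 0) + 1
    out = {}
    for gene, tally in counts.items():
        if not tally:
            out[gene] = frozenset()
            continue
        top = max(tally.values())
        out[gene] = frozenset(g for g, c in tally.items() if c == top)
    return out
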