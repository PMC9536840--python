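"""Pathway-graph logic: admissible biochemical paths between metabolite
pairs, gene "between"/upstream/downstream membership, and genomic region
construction for gene sets.

Reaction edges are treated as traversable in both directions: even an
irreversible reaction couples its reactant and product levels, so paths
are enumerated on the undirected graph.  Admissible paths for a pair are
all simple paths no longer than the shortest path plus a configurable
slack (default 1), which also admits near-shortest routes through
colliders.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .io import GeneTable
from .network import MetaboliteNetwork

LABELS = ("between", "upstream", "downstream", "outside")


@dataclass(frozen=True)
class BetweenCall:
    gene_id: str
    met_a: str
    met_b: str
    label: str
    path_length: int  # shortest-path length used (edges); -1 if disconnected


def shortest_paths(network: MetaboliteNetwork, m1: str, m2: str, slack: int = 1) -> list[list[str]]:
    """All simple paths between ``m1`` and ``m2`` of length <= shortest + slack.

    Returns an empty list when the pair is disconnected.
    """
    if m1 == m2:
        raise ValueError("metabolite pair must be distinct")
    g = network.graph()
    for m in (m1, m2):
        if m not in g:
            raise KeyError(m)
    try:
        shortest = nx.shortest_path_length(g, m1, m2)
    except nx.NetworkXNoPath:
        return []
    cutoff = shortest + slack
    return [p for p in nx.all_simple_paths(g, m1, m2, cutoff=cutoff)]


def _path_region(paths: list[list[str]]) -> tuple[set[frozenset], set[str]]:
    """Edge set and node set covered by the admissible paths."""
    edges: set[frozenset] = set()
    nodes: set[str] = set()
    for p in paths:
        nodes.update(p)
        edges.update(frozenset(e) for e in zip(p, p[1:]))
    return edges, nodes


def between_membership(
    network: MetaboliteNetwork, gene_id: str, m1: str, m2: str, slack: int = 1
) -> BetweenCall:
    """Classify a network-attached gene relative to a metabolite pair.

    ``between``: an enzyme on an edge of an admissible path, or a
    transporter whose cargo includes a node of an admissible path
    (endpoints included).  Regulators are ``upstream`` of every pair they
    can reach.  Other genes are ``upstream``/``downstream`` by which
    endpoint of the path region their attachment node is closer to
    (pair canonicalized by sorted id, so the call is symmetric in the
    pair), and ``outside`` when disconnected from both.
    """
    a, b = sorted((m1, m2))
    paths = shortest_paths(network, a, b, slack=slack)
    if not paths:
        return BetweenCall(gene_id, a, b, "outside", -1)
    plen = min(len(p) - 1 for p in paths)
    edges, nodes = _path_region(paths)

    genes = network.attached_genes()
    if gene_id not in genes:
        raise KeyError(f"gene {gene_id!r} not attached to the network")
    mech = genes[gene_id]
    g = network.graph()

    if mech == "enzyme":
        u, v = network.enzyme_edges()[gene_id]
        if frozenset((u, v)) in edges:
            return BetweenCall(gene_id, a, b, "between", plen)
        anchors = (u, v)
    elif mech == "transporter":
        cargo = network.transporters[gene_id]
        if any(c in nodes for c in cargo):
            return BetweenCall(gene_id, a, b, "between", plen)
        anchors = cargo
    else:  # regulator
        entry, _sign = network.regulators[gene_id]
        if nx.has_path(g, entry, a) or nx.has_path(g, entry, b):
            return BetweenCall(gene_id, a, b, "upstream", plen)
        return BetweenCall(gene_id, a, b, "outside", plen)

    # nearest endpoint decides the side; ties go to the lower-id endpoint
    best = None
    for anchor in anchors:
        for endpoint, side in ((a, "upstream"), (b, "downstream")):
            try:
                d = nx.shortest_path_length(g, anchor, endpoint)
            except nx.NetworkXNoPath:
                continue
            key = (d, 0 if side == "upstream" else 1)
            if best is None or key < best[0]:
                best = (key, side)
    if best is None:
        return BetweenCall(gene_id, a, b, "outside", plen)
    return BetweenCall(gene_id, a, b, best[1], plen)


def region_union(
    gene_ids: list[str],
    genes: GeneTable,
    flank_bp: int,
    chrom_lengths: dict[str, int],
) -> tuple[list[tuple[str, int, int]], float]:
    """Flank each gene, clip to chromosome bounds, and union-merge.

    Returns the disjoint sorted interval list (1-based inclusive) and the
    total covered length in Mb.
    """
    flank_bp = int(flank_bp)
    raw: list[tuple[str, int, int]] = []
    for gid in gene_ids:
        g = genes.by_id(gid)
        chrom = g["chrom"]
        if chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {chrom!r}")
        start = max(1, int(g["start_bp"]) - flank_bp)
        end = min(int(chrom_lengths[chrom]), int(g["end_bp"]) + flank_bp)
        if start <= end:
            raw.append((chrom, start, end))
    merged = merge_intervals(raw)
    total_bp = sum(e - s + 1 for _, s, e in merged)
    return merged, total_bp / 1e6


def merge_intervals(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union-merge 1-based inclusive intervals (touching intervals merge)."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            prev = out.pop()
            out.append((chrom, prev[1], max(prev[2], end)))
        else:
            out.append((chrom, start, end))
    return out
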