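"""Synthetic metabolic networks and genetic architectures with known
ground truth.

The generator plants four variant mechanisms on a reaction graph:

* ``enzyme`` — perturbs one reaction; metabolites on the substrate side
  of the edge move opposite to those on the product side, with effects
  decaying geometrically (``d**k``) in graph distance from the edge.
* ``transporter`` — removes its cargo metabolite from plasma (effect
  ``-a``) while everything downstream of the cargo's intracellular
  consumption rises (``+a * d**k``).
* ``tf`` — a regulator at an entry node pushes every reachable
  metabolite in the same direction.
* ``background`` — a small same-signed polygenic effect radiating from a
  random entry node.

Summary statistics, pairwise genetic-correlation estimates and per-LD-block
covariance tables are emitted from the planted truth with configurable
Gaussian noise, so every downstream stage can be validated against a
closed-form answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import RunConfig
from .io import GeneTable, SumstatsTable
from .network import MetaboliteNetwork, Reaction
from .pathway import between_membership

# ---------------------------------------------------------------------------
# default 16-metabolite network (4 glycolysis / 3 BCAA / 6 other AA / 3 ketone)
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = {
    "glucose": "glycolysis",
    "pyruvate": "glycolysis",
    "lactate": "glycolysis",
    "citrate": "glycolysis",
    "isoleucine": "bcaa",
    "leucine": "bcaa",
    "valine": "bcaa",
    "alanine": "other_aa",
    "glycine": "other_aa",
    "glutamine": "other_aa",
    "histidine": "other_aa",
    "phenylalanine": "other_aa",
    "tyrosine": "other_aa",
    "acetoacetate": "ketone",
    "acetone": "ketone",
    "bhb": "ketone",
}

# (u, v, enzyme gene); one enzyme per reaction, one cycle through the
# pyruvate-citrate-acetoacetate-isoleucine hub
DEFAULT_REACTIONS = [
    ("glucose", "pyruvate", "ENZ_GLYCOLYSIS"),
    ("pyruvate", "lactate", "ENZ_LDH"),
    ("pyruvate", "alanine", "ENZ_ALT"),
    ("pyruvate", "citrate", "ENZ_PDH_CS"),
    ("pyruvate", "glycine", "ENZ_SER_GLY"),
    ("pyruvate", "isoleucine", "ENZ_ILE_CAT"),
    ("citrate", "glutamine", "ENZ_TCA_GLN"),
    ("citrate", "valine", "ENZ_VAL_CAT"),
    ("citrate", "acetoacetate", "ENZ_KETOGENESIS"),
    ("glutamine", "histidine", "ENZ_HIS_CAT"),
    ("phenylalanine", "tyrosine", "ENZ_PAH"),
    ("tyrosine", "acetoacetate", "ENZ_TYR_CAT"),
    ("isoleucine", "acetoacetate", "ENZ_ILE_KET"),
    ("leucine", "acetoacetate", "ENZ_LEU_CAT"),
    ("acetoacetate", "acetone", "ENZ_ADC"),
    ("acetoacetate", "bhb", "ENZ_BDH"),
]

DEFAULT_TRANSPORTERS = {
    "TRANS_ALA": ("alanine",),
    "TRANS_GLN": ("glutamine",),
    "TRANS_GLY": ("glycine",),
    "TRANS_BCAA": ("isoleucine", "leucine", "valine"),
}

DEFAULT_REGULATORS = {
    "TF_LIVER1": ("glucose", 1),
    "TF_LIVER2": ("phenylalanine", 1),
    "TF_KETO": ("acetoacetate", 1),
}


def default_network() -> MetaboliteNetwork:
    """The shipped 16-node reaction network."""
    return MetaboliteNetwork(
        groups=dict(DEFAULT_GROUPS),
        reactions=[Reaction(u, v, (e,)) for u, v, e in DEFAULT_REACTIONS],
        transporters=dict(DEFAULT_TRANSPORTERS),
        regulators=dict(DEFAULT_REGULATORS),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Knobs for the synthetic generator (all sizes deliberately modest)."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 25_000_000 for i in range(1, 5)}
    )
    gene_length_bp: int = 40_000
    gene_spacing_bp: int = 1_200_000
    n_decoy_genes: int = 40
    decoy_unknown_frac: float = 0.25

    n_enzyme: int = 60
    n_transporter: int = 20
    n_tf: int = 25
    n_background: int = 120
    n_decoy_variants: int = 2000
    shadow_frac: float = 0.25
    shadow_r2: float = 0.9

    enzyme_scale: float = 0.10
    transporter_scale: float = 0.08
    tf_scale: float = 0.06
    background_scale: float = 0.04
    decay: float = 0.5
    s0: float = 1.0
    slack: int = 1

    # trait-QC outlier rule; upper_rule "median_plus" excludes levels above
    # median + iqr_fold * IQR, "absolute" excludes above iqr_fold * IQR
    iqr_fold: float = 20.0
    below_fold: float = 10.0
    upper_rule: str = "median_plus"

    def __post_init__(self):
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if self.upper_rule not in ("median_plus", "absolute"):
            raise ValueError("upper_rule must be 'median_plus' or 'absolute'")


# ---------------------------------------------------------------------------
# network + genome construction
# ---------------------------------------------------------------------------


def make_network(config: SimConfig | None = None, seed: int = 0) -> tuple[MetaboliteNetwork, GeneTable]:
    """Build the default network and place its genes on a synthetic genome.

    Attached genes (enzymes, transporters, regulators) and decoy
    general/unknown genes receive non-overlapping intervals on a shuffled
    grid of slots spaced ``gene_spacing_bp`` apart.  Raises ``ValueError``
    if the genome cannot hold all genes.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    net = default_network()

    pathway_of_enzyme = _enzyme_pathways(net)
    gene_rows = []
    for r in net.reactions:
        for e in r.enzymes:
            gene_rows.append((e, "enzyme", pathway_of_enzyme[e], frozenset((r.u, r.v))))
    for t, cargo in net.transporters.items():
        gene_rows.append((t, "transporter", frozenset({"transporters"}), frozenset(cargo)))
    for tf, (entry, _s) in net.regulators.items():
        gene_rows.append((tf, "tf", frozenset({"tf"}), frozenset({entry})))
    for i in range(config.n_decoy_genes):
        gtype = "unknown" if rng.random() < config.decoy_unknown_frac else "general"
        gene_rows.append((f"GENE_{i:03d}", gtype, frozenset(), frozenset()))

    slots = []
    for chrom in sorted(config.chrom_lengths):
        length = int(config.chrom_lengths[chrom])
        pos = config.gene_spacing_bp // 2
        while pos + config.gene_length_bp <= length:
            slots.append((chrom, pos))
            pos += config.gene_spacing_bp
    if len(slots) < len(gene_rows):
        raise ValueError(
            f"cannot place {len(gene_rows)} genes in {len(slots)} slots; "
            "increase chromosome lengths or gene spacing"
        )
    order = rng.permutation(len(slots))[: len(gene_rows)]
    rows = []
    for (gene_id, gtype, pathways, relevant), slot_idx in zip(gene_rows, order):
        chrom, start = slots[slot_idx]
        jitter = int(rng.integers(0, config.gene_spacing_bp // 10))
        start_bp = start + jitter + 1
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start_bp": start_bp,
                "end_bp": start_bp + config.gene_length_bp - 1,
                "gene_type": gtype,
                "pathways": pathways,
                "relevant_metabolites": relevant,
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    return net, GeneTable(df)


def _enzyme_pathways(net: MetaboliteNetwork) -> dict[str, frozenset]:
    """Pathway membership for enzymes: the groups their edge touches."""
    out = {}
    for r in net.reactions:
        groups = {net.groups[r.u], net.groups[r.v]}
        for e in r.enzymes:
            out[e] = frozenset(groups)
    return out


# ---------------------------------------------------------------------------
# effect propagation
# ---------------------------------------------------------------------------


def propagate_effect(
    network: MetaboliteNetwork,
    gene_id: str,
    mechanism: str,
    a: float,
    d: float,
    entry: str | None = None,
) -> dict[str, float]:
    """True per-metabolite effect vector for one causal perturbation."""
    if not 0 < d < 1:
        raise ValueError("decay d must be in (0, 1)")
    g = network.graph()
    mets = network.metabolites
    beta = {m: 0.0 for m in mets}

    if mechanism == "enzyme":
        edges = network.enzyme_edges()
        if gene_id not in edges:
            raise KeyError(f"enzyme gene {gene_id!r} not attached to any reaction")
        u, v = edges[gene_id]
        g2 = g.copy()
        g2.remove_edge(u, v)
        du = nx.single_source_shortest_path_length(g2, u)
        dv = nx.single_source_shortest_path_length(g2, v)
        for m in mets:
            ku = du.get(m, math.inf)
            kv = dv.get(m, math.inf)
            if ku < kv:
                beta[m] = -a * d**ku
            elif kv < ku:
                beta[m] = a * d**kv
            # equidistant on a cycle (or unreachable): no net effect
    elif mechanism == "transporter":
        if gene_id not in network.transporters:
            raise KeyError(f"transporter gene {gene_id!r} not attached")
        for cargo in network.transporters[gene_id]:
            dist = nx.single_source_shortest_path_length(g, cargo)
            beta[cargo] += -a
            for m in mets:
                k = dist.get(m, math.inf)
                if 0 < k < math.inf:
                    beta[m] += a * d**k
    elif mechanism in ("tf", "background"):
        if mechanism == "tf":
            if gene_id not in network.regulators:
                raise KeyError(f"regulator gene {gene_id!r} not attached")
            entry, sign = network.regulators[gene_id]
        else:
            if entry is None:
                raise ValueError("background mechanism requires an entry node")
            sign = 1
        dist = nx.single_source_shortest_path_length(g, entry)
        for m in mets:
            k = dist.get(m, math.inf)
            if k < math.inf:
                beta[m] = sign * a * d**k
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return beta


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted architecture: causal records, true effects, rg, labels."""

    network: MetaboliteNetwork
    genes: GeneTable
    config: SimConfig
    variants: pd.DataFrame  # variant_id, chrom, pos_bp, cm, gene_id, mechanism, a, is_causal
    beta_true: pd.DataFrame  # index variant_id, columns metabolites
    rg_true: pd.DataFrame  # metabolites x metabolites; NaN where undefined
    labels: pd.DataFrame  # variant_id, met_a, met_b, label (causal variants only)
    ld_pairs: dict[frozenset, float] = field(default_factory=dict)

    @property
    def metabolites(self) -> list[str]:
        return list(self.beta_true.columns)

    def causal_ids(self) -> list[str]:
        return list(self.variants.loc[self.variants["is_causal"], "variant_id"])


def simulate_architecture(
    network: MetaboliteNetwork,
    genes: GeneTable,
    config: SimConfig | None = None,
    seed: int = 0,
    run: RunConfig | None = None,
) -> SyntheticTruth:
    """Plant causal variants of the four mechanisms, plus LD shadows and
    null decoys, and derive the closed-form truth (effects, rg, labels).

    True pairwise genetic correlation assumes independent causal sites:
    ``rg(m1, m2) = sum_j b_j1 b_j2 / sqrt(sum_j b_j1^2 * sum_j b_j2^2)``
    over causal variants.  LD shadows are excluded from the sums.
    """
    config = config or SimConfig()
    run = run or RunConfig()
    rng = np.random.default_rng(seed)
    mets = network.metabolites
    gdf = genes.df

    enzymes = list(gdf.loc[gdf["gene_type"] == "enzyme", "gene_id"])
    transporters = list(gdf.loc[gdf["gene_type"] == "transporter", "gene_id"])
    tfs = list(gdf.loc[gdf["gene_type"] == "tf", "gene_id"])
    decoy_genes = list(gdf.loc[gdf["gene_type"].isin(["general", "unknown"]), "gene_id"])
    entries = sorted(network.groups)

    plan = [
        ("enzyme", config.n_enzyme, enzymes, config.enzyme_scale),
        ("transporter", config.n_transporter, transporters, config.transporter_scale),
        ("tf", config.n_tf, tfs, config.tf_scale),
        ("background", config.n_background, decoy_genes, config.background_scale),
    ]
    records, betas = [], []
    idx = 0
    for mechanism, count, pool, scale in plan:
        if count and not pool:
            raise ValueError(f"no genes available for mechanism {mechanism!r}")
        for _ in range(count):
            gene_id = pool[int(rng.integers(len(pool)))]
            a = scale * rng.uniform(0.8, 1.6) * (1 if rng.random() < 0.5 else -1)
            entry = entries[int(rng.integers(len(entries)))] if mechanism == "background" else None
            beta = propagate_effect(network, gene_id, mechanism, a, config.decay, entry=entry)
            g = genes.by_id(gene_id)
            lo = max(1, int(g["start_bp"]) - int(run.flank_bp))
            hi = int(g["end_bp"]) + int(run.flank_bp)
            pos = int(rng.integers(lo, hi + 1))
            records.append(
                {
                    "variant_id": f"var_c{idx:04d}",
                    "chrom": g["chrom"],
                    "pos_bp": pos,
                    "gene_id": gene_id,
                    "mechanism": mechanism,
                    "a": a,
                    "entry": entry,
                    "is_causal": True,
                }
            )
            betas.append([beta[m] for m in mets])
            idx += 1

    causal_cols = ["variant_id", "chrom", "pos_bp", "gene_id", "mechanism", "a", "entry", "is_causal"]
    causal = pd.DataFrame(records, columns=causal_cols)
    beta_true = pd.DataFrame(
        np.asarray(betas, dtype=float).reshape(len(causal), len(mets)),
        index=causal["variant_id"],
        columns=mets,
    )

    # LD shadows of causal variants (attenuated effect, declared r^2)
    ld_pairs: dict[frozenset, float] = {}
    shadow_records, shadow_betas = [], []
    r = math.sqrt(config.shadow_r2)
    for _, row in causal.iterrows():
        if rng.random() >= config.shadow_frac:
            continue
        offset = int(rng.integers(1_000, int(run.clump_window_bp) // 2))
        sid = f"{row['variant_id']}_sh"
        shadow_records.append(
            {
                "variant_id": sid,
                "chrom": row["chrom"],
                "pos_bp": row["pos_bp"] + offset,
                "gene_id": row["gene_id"],
                "mechanism": "shadow",
                "a": row["a"] * r,
                "entry": row["entry"],
                "is_causal": False,
            }
        )
        shadow_betas.append(list(beta_true.loc[row["variant_id"]] * r))
        ld_pairs[frozenset((row["variant_id"], sid))] = config.shadow_r2

    # null decoys scattered across the genome
    chroms = sorted(config.chrom_lengths)
    decoy_records = []
    for i in range(config.n_decoy_variants):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, int(config.chrom_lengths[chrom]) + 1))
        decoy_records.append(
            {
                "variant_id": f"var_d{i:05d}",
                "chrom": chrom,
                "pos_bp": pos,
                "gene_id": None,
                "mechanism": "none",
                "a": 0.0,
                "entry": None,
                "is_causal": False,
            }
        )

    frames = [
        df
        for df in (causal, pd.DataFrame(shadow_records, columns=causal_cols),
                   pd.DataFrame(decoy_records, columns=causal_cols))
        if not df.empty
    ]
    variants = pd.concat(frames, ignore_index=True) if frames else causal
    variants["cm"] = variants["pos_bp"] * 1e-6
    extra = pd.DataFrame(
        np.vstack([shadow_betas, np.zeros((len(decoy_records), len(mets)))])
        if shadow_betas
        else np.zeros((len(decoy_records), len(mets))),
        index=[r["variant_id"] for r in shadow_records + decoy_records],
        columns=mets,
    )
    beta_all = pd.concat([beta_true, extra])
    beta_all = beta_all.loc[variants["variant_id"]]

    rg_true = _true_rg(beta_true, mets)
    labels = _truth_labels(network, causal, mets, config.slack)

    return SyntheticTruth(
        network=network,
        genes=genes,
        config=config,
        variants=variants.reset_index(drop=True),
        beta_true=beta_all,
        rg_true=rg_true,
        labels=labels,
        ld_pairs=ld_pairs,
    )


def _true_rg(beta_causal: pd.DataFrame, mets: list[str]) -> pd.DataFrame:
    b = beta_causal[mets].to_numpy()
    cov = b.T @ b
    h = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = cov / np.outer(h, h)
    np.fill_diagonal(rg, np.where(h > 0, 1.0, np.nan))
    return pd.DataFrame(rg, index=mets, columns=mets)


def _truth_labels(
    network: MetaboliteNetwork, causal: pd.DataFrame, mets: list[str], slack: int
) -> pd.DataFrame:
    attached = network.attached_genes()
    pairs = [(a, b) for i, a in enumerate(mets) for b in mets[i + 1 :]]
    cache: dict[tuple[str, str, str], str] = {}
    rows = []
    for _, v in causal.iterrows():
        gene = v["gene_id"]
        for a, b in pairs:
            if gene in attached:
                key = (gene, a, b)
                if key not in cache:
                    cache[key] = between_membership(network, gene, a, b, slack=slack).label
                label = cache[key]
            else:
                label = "outside"
            rows.append({"variant_id": v["variant_id"], "met_a": a, "met_b": b, "label": label})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------


def emit_sumstats(truth: SyntheticTruth, n: float, seed: int = 0) -> SumstatsTable:
    """Noisy GWAS summary statistics at effective sample size ``n``.

    ``se = s0 / sqrt(n)``; ``beta_hat = beta_true + N(0, se^2)``;
    two-sided normal p-values.
    """
    from scipy.stats import norm

    if not n > 0:
        raise ValueError("effective sample size must be positive")
    rng = np.random.default_rng(seed)
    mets = truth.metabolites
    se = truth.config.s0 / math.sqrt(n)
    b_true = truth.beta_true[mets].to_numpy()
    b_hat = b_true + rng.normal(0.0, se, size=b_true.shape)
    z = b_hat / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    df = truth.variants[["variant_id", "chrom", "pos_bp", "cm"]].copy()
    df["effect_allele"] = "A"
    df["other_allele"] = "G"
    for j, m in enumerate(mets):
        df[f"beta_{m}"] = b_hat[:, j]
        df[f"se_{m}"] = se
        df[f"p_{m}"] = p[:, j]
    df = df.sort_values(["chrom", "pos_bp"], kind="mergesort").reset_index(drop=True)
    return SumstatsTable(df, mets)


def emit_pair_rg(truth: SyntheticTruth, noise_sd: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Pairwise genetic-correlation estimates: truth plus Gaussian noise.

    Pairs with undefined truth (a metabolite without causal effects) are
    flagged with ``defined = False`` and NaN estimates.
    """
    rng = np.random.default_rng(seed)
    mets = truth.metabolites
    rows = []
    for i, a in enumerate(mets):
        for b in mets[i + 1 :]:
            rg = truth.rg_true.loc[a, b]
            defined = bool(np.isfinite(rg))
            rg_hat = rg + rng.normal(0.0, noise_sd) if defined and noise_sd > 0 else rg
            rows.append(
                {
                    "met_a": a,
                    "met_b": b,
                    "rg": rg_hat if defined else np.nan,
                    "se": max(noise_sd, 1e-12),
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def make_blocks(chrom_lengths: dict[str, int], block_bp: int = 1_000_000) -> list[tuple[str, int, int]]:
    """Tile the genome into LD blocks of ``block_bp`` (1-based inclusive)."""
    blocks = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        start = 1
        while start <= length:
            blocks.append((chrom, start, min(start + block_bp - 1, length)))
            start += block_bp
    return blocks


def emit_block_stats(
    truth: SyntheticTruth,
    blocks: list[tuple[str, int, int]],
    met_a: str,
    met_b: str,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-LD-block local h2 (both traits) and covariance for one pair.

    Block sums run over causal variants only (independent sites); noise
    is additive Gaussian with the declared variance.
    """
    rng = np.random.default_rng(seed)
    causal = truth.variants[truth.variants["is_causal"]]
    ba = truth.beta_true.loc[causal["variant_id"], met_a].to_numpy()
    bb = truth.beta_true.loc[causal["variant_id"], met_b].to_numpy()
    chrom = causal["chrom"].to_numpy()
    pos = causal["pos_bp"].to_numpy()

    var = noise_sd**2
    rows = []
    for c, s, e in blocks:
        in_block = (chrom == c) & (pos >= s) & (pos <= e)
        h2a = float(np.sum(ba[in_block] ** 2))
        h2b = float(np.sum(bb[in_block] ** 2))
        cov = float(np.sum(ba[in_block] * bb[in_block]))
        if noise_sd > 0:
            h2a += rng.normal(0.0, noise_sd)
            h2b += rng.normal(0.0, noise_sd)
            cov += rng.normal(0.0, noise_sd)
        rows.append(
            {
                "chrom": c,
                "start_bp": s,
                "end_bp": e,
                "h2_a": h2a,
                "var_h2_a": var,
                "h2_b": h2b,
                "var_h2_b": var,
                "cov_ab": cov,
                "var_cov": var,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait QC
# ---------------------------------------------------------------------------


def trait_qc_filter(
    raw_levels: np.ndarray,
    iqr_fold: float = 20.0,
    below_fold: float = 10.0,
    upper_rule: str = "median_plus",
) -> tuple[np.ndarray, np.ndarray]:
    """Outlier exclusion for one metabolite's raw (positive) levels.

    Excludes samples whose raw level exceeds ``median + iqr_fold * IQR``
    (``upper_rule='median_plus'``; the ``'absolute'`` switch instead uses
    ``iqr_fold * IQR``) or falls below ``median / below_fold``.  Returns
    the log-transformed retained levels and the boolean exclusion mask.
    """
    levels = np.asarray(raw_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("raw metabolite levels must be positive")
    med = np.median(levels)
    q1, q3 = np.percentile(levels, [25, 75])
    iqr = q3 - q1
    upper = med + iqr_fold * iqr if upper_rule == "median_plus" else iqr_fold * iqr
    exclude = (levels > upper) | (levels < med / below_fold)
    if upper_rule == "absolute" and iqr == 0:
        # degenerate: an all-equal sample has IQR 0; no upper exclusion
        exclude = levels < med / below_fold
    return np.log(levels[~exclude]), exclude
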