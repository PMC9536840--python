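import numpy as np
import pandas as pd
import pytest

from metpleio.config import RunConfig
from metpleio.io import GeneTable, SumstatsTable
from metpleio.network import MetaboliteNetwork, Reaction
from metpleio import synthetic


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture
def chain_network():
    """A - B - C chain, one enzyme per edge, a transporter for B and a
    regulator entering at A."""
    return MetaboliteNetwork(
        groups={"A": "glycolysis", "B": "glycolysis", "C": "bcaa"},
        reactions=[Reaction("A", "B", ("E_AB",)), Reaction("B", "C", ("E_BC",))],
        transporters={"T_B": ("B",)},
        regulators={"R_A": ("A", 1)},
    )


@pytest.fixture(scope="session")
def default_net_genes():
    return synthetic.make_network(seed=1)


@pytest.fixture(scope="session")
def small_truth(default_net_genes):
    net, genes = default_net_genes
    cfg = synthetic.SimConfig(
        n_enzyme=20, n_transporter=8, n_tf=10, n_background=40,
        n_decoy_variants=200,
    )
    return synthetic.simulate_architecture(net, genes, cfg, seed=11)


def make_sumstats(n_variants=10, metabolites=("m1", "m2"), seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_variants)],
            "chrom": "chr1",
            "pos_bp": np.arange(1, n_variants + 1) * 1000,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )
    df["cm"] = df["pos_bp"] * 1e-6
    for m in metabolites:
        beta = rng.normal(0, 0.1, n_variants)
        se = np.full(n_variants, 0.01)
        from scipy.stats import norm

        df[f"beta_{m}"] = beta
        df[f"se_{m}"] = se
        df[f"p_{m}"] = np.clip(2 * norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    cols = ["variant_id", "chrom", "pos_bp", "cm", "effect_allele", "other_allele"] + [
        f"{s}_{m}" for m in metabolites for s in ("beta", "se", "p")
    ]
    return SumstatsTable(df[cols], list(metabolites))


@pytest.fixture
def toy_sumstats():
    return make_sumstats()


def make_gene_table(rows):
    """rows: (gene_id, chrom, start_bp, end_bp, gene_type, relevant)"""
    recs = []
    for gene_id, chrom, start, end, gtype, relevant in rows:
        recs.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start_bp": start,
                "end_bp": end,
                "gene_type": gtype,
                "pathways": frozenset(),
                "relevant_metabolites": frozenset(relevant),
            }
        )
    return GeneTable(pd.DataFrame(recs, columns=list(GeneTable.COLUMNS)))
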