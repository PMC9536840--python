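"""lfsr-filtered pair selection and discordant / concordant / neither
classification of lead variants, plus disease direction-consistency
scoring.

``ash_lfsr`` is a self-contained normal-mixture adaptive-shrinkage
implementation: the prior is a point mass at zero plus zero-centered
normals on a geometric grid of standard deviations, fitted by penalized
EM on the marginal likelihood; the local false sign rate of each
observation is the smaller posterior tail probability, inclusive of the
point mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


class EMError(RuntimeError):
    pass


@dataclass
class AshFit:
    grid_sd: np.ndarray  # component sds; grid_sd[0] == 0 (point mass)
    weights: np.ndarray
    lfsr: np.ndarray
    lfdr: np.ndarray
    loglik: float
    n_iter: int


def default_grid(estimates: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Geometric sd grid from min(se)/10 up to twice the largest
    moment-based effect sd, in sqrt(2) steps."""
    lo = ses.min() / 10.0
    hi = 2.0 * np.sqrt(np.maximum(estimates**2 - ses**2, 0.0)).max()
    hi = max(hi, lo * 2.0)
    grid = [lo]
    while grid[-1] < hi:
        grid.append(grid[-1] * np.sqrt(2.0))
    return np.array(grid)


def ash_lfsr(
    estimates: np.ndarray,
    ses: np.ndarray,
    grid_sd: np.ndarray | None = None,
    null_penalty: float = 10.0,
    max_iter: int = 20000,
    tol: float = 1e-7,
) -> AshFit:
    """Empirical-Bayes local false sign rates for paired (estimate, se).

    The fitted prior is ``pi0 * delta0 + sum_k pi_k * N(0, sd_k^2)`` with
    a Dirichlet penalty of ``null_penalty`` on the point mass, as in
    standard adaptive shrinkage.  Raises :class:`EMError` if the
    penalized log-likelihood has not stabilized after ``max_iter``
    iterations.
    """
    x = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if x.shape != s.shape or x.ndim != 1:
        raise ValueError("estimates and ses must be matching 1-d arrays")
    if np.any(s <= 0):
        raise ValueError("all ses must be positive")
    if grid_sd is None:
        grid_sd = default_grid(x, s)
    grid_sd = np.asarray(grid_sd, dtype=float)
    sds = np.concatenate([[0.0], grid_sd])  # component 0 = point mass
    K = len(sds)
    n = len(x)

    # marginal likelihood of each observation under each component
    total_var = s[:, None] ** 2 + sds[None, :] ** 2
    L = norm.pdf(x[:, None], loc=0.0, scale=np.sqrt(total_var))

    pi = np.full(K, 1.0 / K)
    prev = -np.inf
    delta = np.inf
    for it in range(1, max_iter + 1):
        mix = L * pi[None, :]
        rowsum = mix.sum(axis=1)
        resp = mix / rowsum[:, None]
        loglik = np.sum(np.log(rowsum)) + (null_penalty - 1.0) * np.log(max(pi[0], 1e-300))
        counts = resp.sum(axis=0)
        counts[0] += null_penalty - 1.0
        pi = counts / counts.sum()
        delta = loglik - prev
        prev = loglik
        if abs(delta) < tol:
            break
    else:
        raise EMError(f"EM did not converge in {max_iter} iterations (last delta {delta:.3g})")

    lfdr, lfsr = posterior_lfsr(x, s, sds, pi)
    return AshFit(grid_sd=grid_sd, weights=pi, lfsr=lfsr, lfdr=lfdr, loglik=prev, n_iter=it)


def posterior_lfsr(
    x: np.ndarray, s: np.ndarray, sds: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior null mass (lfdr) and local false sign rate under a fixed
    mixture prior; ``sds[0]`` must be 0 (the point mass)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    sds = np.asarray(sds, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if sds[0] != 0.0:
        raise ValueError("sds[0] must be the zero point mass")
    total_var = s[:, None] ** 2 + sds[None, :] ** 2
    L = norm.pdf(x[:, None], loc=0.0, scale=np.sqrt(total_var))
    mix = L * pi[None, :]
    resp = mix / mix.sum(axis=1)[:, None]
    lfdr = resp[:, 0]
    # posterior within normal component k: N(mu_ik, tau_ik^2)
    post_var = (sds[None, 1:] ** 2 * s[:, None] ** 2) / total_var[:, 1:]
    post_mean = x[:, None] * sds[None, 1:] ** 2 / total_var[:, 1:]
    p_neg = np.sum(resp[:, 1:] * norm.cdf(0.0, loc=post_mean, scale=np.sqrt(post_var)), axis=1)
    p_pos = 1.0 - lfdr - p_neg
    lfsr = np.minimum(p_neg, p_pos) + lfdr
    return lfdr, lfsr


def add_lfsr(pair_table: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit the shrinkage prior jointly over all defined pairs and attach
    an ``lfsr`` column."""
    out = pair_table.copy()
    ok = out["rg"].notna()
    fit = ash_lfsr(out.loc[ok, "rg"].to_numpy(), out.loc[ok, "se"].to_numpy(), **kwargs)
    out["lfsr"] = np.nan
    out.loc[ok, "lfsr"] = fit.lfsr
    return out


# ---------------------------------------------------------------------------
# pair selection and classification
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceCall:
    variant_id: str
    significant_pairs: list[tuple[str, str]]
    pair_class: dict[tuple[str, str], str]  # discordant / concordant
    variant_class: str  # discordant / concordant / neither


def significant_pairs(
    lead: pd.Series,
    pair_table: pd.DataFrame,
    gw_p: float = 5e-8,
    suggestive_p: float = 1e-4,
    lfsr_cut: float = 0.005,
) -> list[tuple[str, str]]:
    """Metabolite pairs for which this lead is a candidate pleiotropic hit:
    suggestive in both traits, genome-wide in at least one, and the
    pair's genetic correlation passes the lfsr filter."""
    out = []
    for _, row in pair_table.iterrows():
        a, b = row["met_a"], row["met_b"]
        if not np.isfinite(row.get("lfsr", np.nan)) or row["lfsr"] >= lfsr_cut:
            continue
        p1, p2 = lead.get(f"p_{a}"), lead.get(f"p_{b}")
        if p1 is None or p2 is None:
            continue
        if max(p1, p2) < suggestive_p and min(p1, p2) < gw_p:
            out.append(tuple(sorted((a, b))))
    return sorted(set(out))


def classify_variant(
    lead: pd.Series,
    pairs: list[tuple[str, str]],
    pair_table: pd.DataFrame,
) -> ConcordanceCall:
    """Discordant iff, for at least one significant pair, the product of
    the two effect signs disagrees with the sign of the pair's global
    genetic correlation; concordant if there are significant pairs and
    none disagrees; neither if no significant pairs."""
    rg_of = {
        tuple(sorted((r["met_a"], r["met_b"]))): r["rg"] for _, r in pair_table.iterrows()
    }
    pair_class = {}
    for a, b in pairs:
        b1, b2 = lead[f"beta_{a}"], lead[f"beta_{b}"]
        rg = rg_of[(a, b)]
        if b1 == 0 or b2 == 0 or rg == 0:
            raise ValueError(
                f"undefined sign for pair ({a}, {b}) of variant {lead['variant_id']}"
            )
        same_dir = (b1 > 0) == (b2 > 0)
        pair_class[(a, b)] = "discordant" if same_dir != (rg > 0) else "concordant"
    if not pairs:
        v_class = "neither"
    elif any(c == "discordant" for c in pair_class.values()):
        v_class = "discordant"
    else:
        v_class = "concordant"
    return ConcordanceCall(lead["variant_id"], pairs, pair_class, v_class)


def classify_all(
    leads: pd.DataFrame,
    pair_table: pd.DataFrame,
    gw_p: float = 5e-8,
    suggestive_p: float = 1e-4,
    lfsr_cut: float = 0.005,
) -> pd.DataFrame:
    """Classify every lead; returns one row per (variant, significant
    pair) plus a pairless row for 'neither' variants.

    Vectorized equivalent of calling :func:`significant_pairs` and
    :func:`classify_variant` per lead.
    """
    passing = pair_table[
        pair_table["lfsr"].notna()
        & (pair_table["lfsr"] < lfsr_cut)
        & pair_table["rg"].notna()
    ]
    ids = leads["variant_id"].to_numpy()
    rows = []
    sig_counts = np.zeros(len(leads), dtype=int)
    disc_flags = np.zeros(len(leads), dtype=bool)
    per_pair_rows: list[tuple] = []
    for _, pr in passing.iterrows():
        a, b = sorted((pr["met_a"], pr["met_b"]))
        rg = pr["rg"]
        p1 = leads[f"p_{a}"].to_numpy()
        p2 = leads[f"p_{b}"].to_numpy()
        sig = (np.maximum(p1, p2) < suggestive_p) & (np.minimum(p1, p2) < gw_p)
        if not sig.any():
            continue
        b1 = leads[f"beta_{a}"].to_numpy()[sig]
        b2 = leads[f"beta_{b}"].to_numpy()[sig]
        if np.any(b1 == 0) or np.any(b2 == 0) or rg == 0:
            raise ValueError(f"undefined sign for pair ({a}, {b})")
        discordant = ((b1 > 0) == (b2 > 0)) != (rg > 0)
        which = np.nonzero(sig)[0]
        sig_counts[which] += 1
        disc_flags[which] |= discordant
        for i, disc in zip(which, discordant):
            per_pair_rows.append((i, a, b, "discordant" if disc else "concordant"))

    v_class = np.where(sig_counts == 0, "neither", np.where(disc_flags, "discordant", "concordant"))
    for i in np.nonzero(sig_counts == 0)[0]:
        rows.append(
            {"variant_id": ids[i], "met_a": ".", "met_b": ".",
             "pair_class": ".", "variant_class": "neither"}
        )
    for i, a, b, pc in per_pair_rows:
        rows.append(
            {"variant_id": ids[i], "met_a": a, "met_b": b,
             "pair_class": pc, "variant_class": v_class[i]}
        )
    out = pd.DataFrame(rows, columns=["variant_id", "met_a", "met_b", "pair_class", "variant_class"])
    return out.sort_values(["variant_id", "met_a", "met_b"], kind="mergesort").reset_index(drop=True)


def disease_direction_consistency(
    effects: pd.DataFrame,
    risk_directions: dict[str, int],
    p_cut: float = 1e-5,
) -> tuple[float, pd.DataFrame]:
    """Fraction of significantly associated biomarkers whose effect sign
    matches the declared disease-risk direction.

    ``effects`` needs columns biomarker, beta, p.  Biomarkers with
    p >= p_cut or a zero declared direction are excluded; with no
    qualifying biomarker the fraction is NaN.
    """
    rows = []
    for _, r in effects.iterrows():
        direction = risk_directions.get(r["biomarker"], 0)
        if direction == 0 or r["p"] >= p_cut:
            continue
        consistent = (r["beta"] > 0) == (direction > 0)
        rows.append(
            {"biomarker": r["biomarker"], "beta": r["beta"], "p": r["p"],
             "risk_direction": direction, "consistent": consistent}
        )
    table = pd.DataFrame(rows)
    frac = float(table["consistent"].mean()) if len(table) else float("nan")
    return frac, table
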