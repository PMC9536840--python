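"""Exact statistical kernels: Poisson rate-ratio test (conditional
binomial), Fisher exact test with conditional-MLE odds ratio, Wilson
score intervals, and the Fligner-Killeen two-group variance test; plus
construction of the discordant/concordant enrichment tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import binomtest, chi2, norm


@dataclass
class EnrichmentResult:
    statistic: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    inputs: dict = field(default_factory=dict)


def normal_two_sided_p(estimate: float, se: float) -> float:
    """Two-sided normal-approximation p-value for estimate / se."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(2.0 * norm.sf(abs(estimate) / se))


# ---------------------------------------------------------------------------
# Poisson rate-ratio test
# ---------------------------------------------------------------------------


def poisson_rate_test(x1: int, l1_mb: float, x2: int, l2_mb: float, conf: float = 0.95) -> EnrichmentResult:
    """Exact rate-ratio test for two Poisson counts with exposures.

    Conditional on the total, ``x1 ~ Binomial(x1 + x2, q)`` with null
    ``q0 = L1 / (L1 + L2)``; the two-sided p sums binomial outcomes no
    more probable than the observed one, and the CI inverts the
    Clopper-Pearson interval on q through ``RR = q/(1-q) * L2/L1``.
    """
    if x1 < 0 or x2 < 0 or x1 != int(x1) or x2 != int(x2):
        raise ValueError("counts must be non-negative integers")
    if l1_mb <= 0 or l2_mb <= 0:
        raise ValueError("exposures must be positive")
    x1, x2 = int(x1), int(x2)
    total = x1 + x2
    if total == 0:
        raise ValueError("rate ratio undefined with zero counts in both groups")
    q0 = l1_mb / (l1_mb + l2_mb)
    test = binomtest(x1, total, q0, alternative="two-sided")
    ci = test.proportion_ci(confidence_level=conf, method="exact")
    scale = l2_mb / l1_mb

    def rr_of(q: float) -> float:
        if q >= 1.0:
            return math.inf
        return q / (1.0 - q) * scale

    rr = (x1 / l1_mb) / (x2 / l2_mb) if x2 > 0 else math.inf
    return EnrichmentResult(
        statistic=rr,
        ci_low=rr_of(ci.low),
        ci_high=rr_of(ci.high),
        p=float(test.pvalue),
        method="poisson_rate",
        inputs={"x1": x1, "l1_mb": l1_mb, "x2": x2, "l2_mb": l2_mb, "conf": conf},
    )


# ---------------------------------------------------------------------------
# Fisher exact test with conditional-MLE odds ratio
# ---------------------------------------------------------------------------


def _log_hyper_weights(n: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and log central-hypergeometric weights log C(row1,k)C(n-row1,col1-k)."""
    amin = max(0, row1 + col1 - n)
    amax = min(row1, col1)
    ks = np.arange(amin, amax + 1)
    logw = (
        gammaln(row1 + 1) - gammaln(ks + 1) - gammaln(row1 - ks + 1)
        + gammaln(n - row1 + 1) - gammaln(col1 - ks + 1) - gammaln(n - row1 - col1 + ks + 1)
    )
    return ks, logw


def _nc_pmf(ks: np.ndarray, logw: np.ndarray, log_theta: float) -> np.ndarray:
    logp = logw + ks * log_theta
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def fisher_exact(a: int, b: int, c: int, d: int, conf: float | None = 0.95) -> EnrichmentResult:
    """Fisher's exact test on [[a, b], [c, d]].

    Two-sided p sums hypergeometric tables (margins fixed) no more
    probable than the observed; the odds ratio is the conditional MLE
    solving ``E_theta[A] = a`` under Fisher's noncentral hypergeometric,
    with the CI from inverting the one-sided tails at ``(1 - conf)/2``.
    Degenerate margins give p = 1 and an undefined (NaN) odds ratio.
    ``conf=None`` skips the interval inversion (NaN bounds).
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 in (0, n) or col1 in (0, n):
        return EnrichmentResult(
            statistic=math.nan, ci_low=math.nan, ci_high=math.nan, p=1.0,
            method="fisher_exact", inputs={"table": (a, b, c, d), "conf": conf},
        )

    ks, logw = _log_hyper_weights(n, row1, col1)
    pmf = _nc_pmf(ks, logw, 0.0)  # theta = 1
    obs = pmf[ks == a][0]
    p = float(pmf[pmf <= obs * (1 + 1e-12)].sum())
    p = 1.0 if p > 1.0 - 1e-10 else p

    amin, amax = int(ks[0]), int(ks[-1])

    def expectation(log_theta: float) -> float:
        return float((ks * _nc_pmf(ks, logw, log_theta)).sum())

    def upper_tail(log_theta: float) -> float:  # P(A >= a)
        return float(_nc_pmf(ks, logw, log_theta)[ks >= a].sum())

    def lower_tail(log_theta: float) -> float:  # P(A <= a)
        return float(_nc_pmf(ks, logw, log_theta)[ks <= a].sum())

    def solve(fn, target: float) -> float:
        # fn is increasing in log_theta for both tails used here
        lo, hi = -50.0, 50.0
        return math.exp(brentq(lambda t: fn(t) - target, lo, hi, xtol=1e-12, rtol=1e-14))

    if a == amin:
        or_hat = 0.0
    elif a == amax:
        or_hat = math.inf
    else:
        or_hat = solve(expectation, float(a))

    if conf is None:
        ci_low = ci_high = math.nan
    else:
        alpha = (1.0 - conf) / 2.0
        ci_low = 0.0 if a == amin else solve(upper_tail, alpha)
        ci_high = math.inf if a == amax else solve(lambda t: -lower_tail(t), -alpha)

    return EnrichmentResult(
        statistic=or_hat, ci_low=ci_low, ci_high=ci_high, p=p,
        method="fisher_exact", inputs={"table": (a, b, c, d), "conf": conf},
    )


# ---------------------------------------------------------------------------
# Wilson score interval
# ---------------------------------------------------------------------------


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0 or k < 0 or k > n:
        raise ValueError("need 0 <= k <= n with n > 0")
    z = norm.ppf((1.0 + conf) / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    low = 0.0 if k == 0 else max(0.0, center - half)
    high = 1.0 if k == n else min(1.0, center + half)
    return low, high


# ---------------------------------------------------------------------------
# Fligner-Killeen variance test (two groups, normal scores)
# ---------------------------------------------------------------------------


def fligner_test(group1, group2) -> tuple[float, float]:
    """Fligner-Killeen test of equal scale between two groups.

    Absolute deviations from each group's own median are pooled, ranked
    (midranks for ties), and mapped through increasing half-normal
    scores; the chi-squared statistic with 1 df compares group means of
    the scores against their pooled variance.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 values")
    devs = np.concatenate([np.abs(g1 - np.median(g1)), np.abs(g2 - np.median(g2))])
    n_total = len(devs)
    ranks = pd.Series(devs).rank(method="average").to_numpy()
    scores = norm.ppf(0.5 + ranks / (2.0 * (n_total + 1.0)))
    grand = scores.mean()
    v2 = scores.var(ddof=1)
    if v2 == 0:
        return 0.0, 1.0
    sizes = (len(g1), len(g2))
    means = (scores[: len(g1)].mean(), scores[len(g1):].mean())
    stat = sum(nj * (aj - grand) ** 2 for nj, aj in zip(sizes, means)) / v2
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# enrichment tables for discordant vs concordant variants
# ---------------------------------------------------------------------------


def build_enrichment_tables(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    between_labels: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """2x2 enrichment tables over classified variants.

    ``gene_type`` table: {discordant, concordant} x {enzyme-or-transporter,
    other gene type}, over all variants with at least one significant pair.

    ``between`` table (needs ``between_labels``: gene_id, met_a, met_b,
    label): restricted to enzyme-annotated classified variants,
    {discordant, concordant} x {between for >= 1 defining pair, not}.
    Defining pairs are the discordant pairs for discordant variants and
    all significant pairs for concordant variants.
    """
    ann_by_id = annotations.set_index("variant_id")
    classified = calls[calls["variant_class"] != "neither"]
    per_variant = classified.groupby("variant_id")["variant_class"].first()

    table_c = np.zeros((2, 2), dtype=int)
    for vid, v_class in per_variant.items():
        gtype = ann_by_id.loc[vid, "gene_type"]
        i = 0 if v_class == "discordant" else 1
        j = 0 if gtype in ("enzyme", "transporter") else 1
        table_c[i, j] += 1

    out = {"gene_type": table_c}
    if between_labels is None:
        return out

    lab = {
        (r["gene_id"], *sorted((r["met_a"], r["met_b"]))): r["label"]
        for _, r in between_labels.iterrows()
    }
    table_d = np.zeros((2, 2), dtype=int)
    for vid, v_class in per_variant.items():
        if ann_by_id.loc[vid, "gene_type"] != "enzyme":
            continue
        gene = ann_by_id.loc[vid, "gene_id"]
        rows = classified[classified["variant_id"] == vid]
        if v_class == "discordant":
            rows = rows[rows["pair_class"] == "discordant"]
        defining = [tuple(sorted((r["met_a"], r["met_b"]))) for _, r in rows.iterrows()]
        between = any(lab.get((gene, a, b)) == "between" for a, b in defining)
        i = 0 if v_class == "discordant" else 1
        j = 0 if between else 1
        table_d[i, j] += 1
    out["between"] = table_d
    return out
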