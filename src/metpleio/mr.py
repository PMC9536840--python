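"""Pairwise Mendelian randomization with Rucker model selection.

Four candidate estimators are fitted — IVW and MR-Egger, each with fixed
or multiplicative random effects — and one is selected from the
heterogeneity statistics: stay with fixed-effect IVW while its Cochran Q
is compatible with chi-squared(J-1); move to the Egger branch only when
the drop Q - Q' exceeds the chi-squared(1) critical value; within the
chosen branch inflate to random effects when that branch's residual
heterogeneity still exceeds its critical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .enrichstats import normal_two_sided_p


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MRResult:
    exposure: str
    outcome: str
    n_instruments: int
    method: str  # ivw_fe / ivw_re / egger_fe / egger_re
    estimate: float
    se: float
    p: float
    egger_intercept: float
    egger_intercept_se: float
    Q: float
    Q_prime: float


def _ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    w = 1.0 / sy**2
    theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(1.0 / math.sqrt(np.sum(w * bx**2)))
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se, q


def _egger(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    cov = np.linalg.inv(xtwx)
    coef = cov @ xtwy
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    intercept, slope = float(coef[0]), float(coef[1])
    se_intercept, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    return slope, se_slope, intercept, se_intercept, q


def mr_pair(
    leads: pd.DataFrame,
    exposure: str,
    outcome: str,
    gw_p: float = 5e-8,
    min_instruments: int = 3,
) -> MRResult:
    """MR of ``outcome`` on ``exposure`` using the genome-wide significant
    leads of the exposure as instruments."""
    inst = leads[leads[f"p_{exposure}"] < gw_p]
    j = len(inst)
    if j < min_instruments:
        raise InsufficientInstrumentsError(
            f"{exposure}->{outcome}: {j} instruments < {min_instruments}"
        )
    bx = inst[f"beta_{exposure}"].to_numpy(dtype=float)
    by = inst[f"beta_{outcome}"].to_numpy(dtype=float)
    sy = inst[f"se_{outcome}"].to_numpy(dtype=float)
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero: degenerate weights")

    theta_i, se_i, q = _ivw(bx, by, sy)
    slope, se_s, alpha, se_a, q_prime = _egger(bx, by, sy)

    crit_j1 = chi2.ppf(0.95, df=j - 1)
    crit_1 = chi2.ppf(0.95, df=1)
    crit_j2 = chi2.ppf(0.95, df=j - 2)

    if q <= crit_j1:
        method, est, se = "ivw_fe", theta_i, se_i
    elif q - q_prime > crit_1:
        if q_prime > crit_j2:
            method = "egger_re"
            infl = math.sqrt(max(q_prime / (j - 2), 1.0))
            est, se = slope, se_s * infl
        else:
            method, est, se = "egger_fe", slope, se_s
    else:
        method = "ivw_re"
        infl = math.sqrt(max(q / (j - 1), 1.0))
        est, se = theta_i, se_i * infl

    return MRResult(
        exposure=exposure, outcome=outcome, n_instruments=j, method=method,
        estimate=est, se=se, p=normal_two_sided_p(est, se),
        egger_intercept=alpha, egger_intercept_se=se_a, Q=q, Q_prime=q_prime,
    )


def mr_all_pairs(leads: pd.DataFrame, metabolites: list[str], gw_p: float = 5e-8) -> pd.DataFrame:
    """All ordered metabolite pairs; pairs without enough instruments get
    NaN estimates and method 'insufficient'."""
    rows = []
    for exp in metabolites:
        for out in metabolites:
            if exp == out:
                continue
            try:
                r = mr_pair(leads, exp, out, gw_p)
                rows.append(r.__dict__)
            except InsufficientInstrumentsError:
                rows.append(
                    {
                        "exposure": exp, "outcome": out,
                        "n_instruments": int((leads[f"p_{exp}"] < gw_p).sum()),
                        "method": "insufficient",
                        "estimate": np.nan, "se": np.nan, "p": np.nan,
                        "egger_intercept": np.nan, "egger_intercept_se": np.nan,
                        "Q": np.nan, "Q_prime": np.nan,
                    }
                )
    return pd.DataFrame(rows)
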