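"""Normalization of the lead-variant x metabolite effect matrix.

Per column, z-scores (beta/se) are passed through a rank-based inverse
normal transform and standardized; each row is then sign-aligned so its
median across metabolites is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class EffectMatrix:
    scores: pd.DataFrame  # rows: variant ids; columns: metabolites
    flipped: pd.Series  # per-row sign-flip flag


def inverse_normal_transform(values: np.ndarray, offset: float = 0.5) -> np.ndarray:
    """Rank-based INT with midranks for ties: Phi^-1((r - c)/(n - 2c + 1))
    for c = 0.5 reduces to Phi^-1((r - 0.5)/n); Blom uses c = 3/8."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    ranks = pd.Series(v).rank(method="average").to_numpy()
    return norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def normalize_effects(
    leads: pd.DataFrame, metabolites: list[str], rank_offset: float = 0.5
) -> EffectMatrix:
    """Build the normalized effect matrix from a leads table with
    beta_<m>/se_<m> columns."""
    z = np.column_stack(
        [
            leads[f"beta_{m}"].to_numpy(dtype=float) / leads[f"se_{m}"].to_numpy(dtype=float)
            for m in metabolites
        ]
    )
    scores = np.column_stack(
        [inverse_normal_transform(z[:, j], offset=rank_offset) for j in range(z.shape[1])]
    )
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    medians = np.median(scores, axis=1)
    flip = medians < 0
    scores[flip] *= -1.0
    ids = leads["variant_id"].tolist()
    return EffectMatrix(
        scores=pd.DataFrame(scores, index=ids, columns=metabolites),
        flipped=pd.Series(flip, index=ids),
    )
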