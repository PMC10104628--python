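"""Ranked, scaled, binarized and quantile-stratified views of cell scores.

The predictor's probability for each cell is treated as a relative
sensitivity score: min-max scaled for display, split at the median into
sensitive/resistant calls, and stratified into top/bottom quantile groups
(rank_Sens / rank_Res) for downstream biomarker and drug-combination work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def minmax_scale(scores: np.ndarray) -> np.ndarray:
    """(x − min)/(max − min); a constant vector maps to all 0.5."""
    x = np.asarray(scores, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def binarize_median(scores: np.ndarray) -> np.ndarray:
    """'sensitive' above the median, 'resistant' at or below it."""
    x = np.asarray(scores, dtype=float)
    med = np.median(x)
    return np.where(x > med, "sensitive", "resistant")


def stratify_quantiles(
    scores: np.ndarray, low_q: float = 0.10, high_q: float = 0.90
) -> np.ndarray:
    """rank_Sens above the high quantile, rank_Res below the low one.

    Quantiles are linear-interpolation empirical quantiles; cells tied
    exactly on a boundary stay neutral, so strata are invariant under any
    strictly increasing transform of the scores.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    x = np.asarray(scores, dtype=float)
    lo = np.quantile(x, low_q)
    hi = np.quantile(x, high_q)
    out = np.full(x.shape, "neutral", dtype=object)
    out[x > hi] = "rank_Sens"
    out[x < lo] = "rank_Res"
    return out.astype(str)


@dataclass
class CellRanking:
    """All ranking views of one drug's scores over a set of cells."""

    cell_ids: list[str]
    raw_score: np.ndarray
    scaled_score: np.ndarray
    binary_call: np.ndarray
    stratum: np.ndarray
    low_q: float = 0.10
    high_q: float = 0.90

    @classmethod
    def from_scores(
        cls,
        cell_ids,
        scores: np.ndarray,
        low_q: float = 0.10,
        high_q: float = 0.90,
    ) -> "CellRanking":
        scores = np.asarray(scores, dtype=float)
        return cls(
            cell_ids=list(map(str, cell_ids)),
            raw_score=scores,
            scaled_score=minmax_scale(scores),
            binary_call=binarize_median(scores),
            stratum=stratify_quantiles(scores, low_q, high_q),
            low_q=low_q,
            high_q=high_q,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "raw_score": self.raw_score,
                "scaled_score": self.scaled_score,
                "binary_call": self.binary_call,
                "stratum": self.stratum,
            }
        ).sort_values("raw_score", ascending=False, kind="mergesort")


def score_cells(model, X_t) -> np.ndarray:
    """Eval-mode predictor probabilities for the target cells."""
    from .io import ExpressionMatrix

    if isinstance(X_t, ExpressionMatrix):
        X_t = X_t.values
    return model.predict_proba(np.asarray(X_t, dtype=float))


_STRATA = ("rank_Sens", "neutral", "rank_Res")


def cross_drug_overlap(
    ranking_a: CellRanking,
    ranking_b: CellRanking,
    jaccard_threshold: float = 0.5,
) -> dict:
    """3×3 stratum contingency between two drugs over the same cells.

    Also reports the Jaccard index of (A.rank_Res, B.rank_Sens) — cells
    resistant to drug A but sensitive to drug B — and flags a combination
    candidate when it exceeds the threshold.  The flag is exploratory, not
    inferential.
    """
    if ranking_a.cell_ids != ranking_b.cell_ids:
        raise ValueError("rankings cover different cells")
    table = pd.DataFrame(0, index=_STRATA, columns=_STRATA)
    for sa, sb in zip(ranking_a.stratum, ranking_b.stratum):
        table.loc[sa, sb] += 1
    res_a = {c for c, s in zip(ranking_a.cell_ids, ranking_a.stratum) if s == "rank_Res"}
    sens_b = {c for c, s in zip(ranking_b.cell_ids, ranking_b.stratum) if s == "rank_Sens"}
    union = res_a | sens_b
    jaccard = len(res_a & sens_b) / len(union) if union else 0.0
    return {
        "table": table,
        "jaccard_resA_sensB": float(jaccard),
        "combination_candidate": bool(jaccard > jaccard_threshold),
    }
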