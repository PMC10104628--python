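"""Attribution, biomarker discovery and the lineage-stratified exact test.

Integrated gradients attribute the predictor's sensitivity probability to
individual genes along a straight path from a baseline (the all-zero vector
in z-scored space, roughly the cohort-mean cell).  The extreme-attribution
tail genes feed a Wilcoxon differential-expression pass between predicted
sensitive and resistant cells, yielding candidate sensitivity (sc_sens) and
resistance (sc_res) biomarker sets, which can then be scored as single-gene
prognostic classifiers on an external cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .model import SCADModel
from .train import auc as _auc


# --------------------------------------------------------- attribution
def integrated_gradients(
    model: SCADModel,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 50,
    check_completeness: bool = True,
) -> np.ndarray:
    """Per-gene attribution of the sensitivity probability F = P∘M.

    IG_i = (x_i − x'_i) · (1/steps) Σ_{m=1..steps} ∂F/∂x_i at
    x' + (m/steps)(x − x').  Accepts a single vector or a matrix of
    samples; returns attributions of the same shape.  The completeness
    identity Σ_i IG_i ≈ F(x) − F(x') is asserted at a tolerance that
    shrinks as steps grow (Riemann-sum refinement).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if baseline is None:
        baseline = np.zeros(x.shape[1])
    baseline = np.asarray(baseline, dtype=float).reshape(1, -1)
    if baseline.shape[1] != x.shape[1]:
        raise ValueError("baseline and input dimensions differ")
    diff = x - baseline
    grad_sum = np.zeros_like(x)
    for m in range(1, steps + 1):
        point = baseline + (m / steps) * diff
        grad_sum += model.input_gradient(point)
    ig = diff * grad_sum / steps
    if check_completeness:
        total = ig.sum(axis=1)
        delta = model.predict_proba(x) - model.predict_proba(
            np.repeat(baseline, x.shape[0], axis=0)
        )
        tol = max(1e-2, 5.0 / steps)
        if np.any(np.abs(total - delta) > tol):
            worst = float(np.max(np.abs(total - delta)))
            raise AssertionError(
                f"integrated-gradients completeness violated: |ΣIG − ΔF| = {worst:.4f}"
            )
    return ig if ig.shape[0] > 1 else ig.ravel()


def mean_attribution(per_fold: list[np.ndarray]) -> np.ndarray:
    """Average attributions over cells within each fold, then over folds."""
    if not per_fold:
        raise ValueError("no attribution matrices given")
    fold_means = [np.atleast_2d(a).mean(axis=0) for a in per_fold]
    return np.mean(fold_means, axis=0)


def tail_genes(
    mean_attr: np.ndarray, gene_ids: list[str], q: float = 0.05
) -> set[str]:
    """Genes below the q or above the (1−q) attribution quantile."""
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    a = np.asarray(mean_attr, dtype=float)
    lo = np.quantile(a, q)
    hi = np.quantile(a, 1 - q)
    if q == 0.5:
        return set(gene_ids)
    return {g for g, v in zip(gene_ids, a) if v <= lo or v >= hi}


@dataclass
class AttributionResult:
    gene_ids: list[str]
    mean_attr: np.ndarray
    tail: set[str]
    sc_sens: set[str]
    sc_res: set[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_attribution": self.mean_attr,
                "in_tail": [g in self.tail for g in self.gene_ids],
                "sc_sens": [g in self.sc_sens for g in self.gene_ids],
                "sc_res": [g in self.sc_res for g in self.gene_ids],
            }
        )


# ------------------------------------------------- differential expression
def rank_genes_de(
    expr: ExpressionMatrix,
    group_a: set[str],
    group_b: set[str],
    gene_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per gene, BH-adjusted.

    Direction is the sign of mean(group_a) − mean(group_b); a gene constant
    across both groups gets p = 1 and is flagged.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    rows_a = [idx[s] for s in sorted(group_a)]
    rows_b = [idx[s] for s in sorted(group_b)]
    genes = sorted(gene_subset & set(expr.gene_ids)) if gene_subset else list(expr.gene_ids)
    cols = [expr.gene_ids.index(g) for g in genes]

    A = expr.values[np.ix_(rows_a, cols)]
    B = expr.values[np.ix_(rows_b, cols)]
    records = []
    for j, g in enumerate(genes):
        a, b = A[:, j], B[:, j]
        constant = np.ptp(np.concatenate([a, b])) == 0
        if constant:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ranksums(a, b)
        records.append(
            {
                "gene_id": g,
                "direction": float(np.sign(a.mean() - b.mean())),
                "statistic": float(stat),
                "pval": float(p),
                "constant": bool(constant),
            }
        )
    table = pd.DataFrame(records)
    table["pval_adj"] = multipletests(table["pval"], method="fdr_bh")[1]
    return table


def biomarker_sets(de_table: pd.DataFrame, alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Split BH-significant genes by direction: up in predicted-sensitive
    cells (sc_sens) versus up in predicted-resistant cells (sc_res)."""
    if de_table.empty:
        return set(), set()
    sig = de_table[de_table["pval_adj"] <= alpha]
    sc_sens = set(sig.loc[sig["direction"] > 0, "gene_id"])
    sc_res = set(sig.loc[sig["direction"] < 0, "gene_id"])
    return sc_sens, sc_res


def attribute_model(
    model: SCADModel,
    target_folds: list[np.ndarray],
    expr: ExpressionMatrix,
    predicted_groups: tuple[set[str], set[str]],
    gene_ids: list[str] | None = None,
    steps: int = 50,
    tail_q: float = 0.05,
    alpha: float = 0.05,
) -> AttributionResult:
    """Full biomarker pass: IG per fold → mean → tails → DE → sets."""
    gene_ids = gene_ids or list(expr.gene_ids)
    per_fold = [integrated_gradients(model, X, steps=steps) for X in target_folds]
    mean_attr = mean_attribution([np.atleast_2d(a) for a in per_fold])
    tail = tail_genes(mean_attr, gene_ids, q=tail_q)
    de = rank_genes_de(expr, *predicted_groups, gene_subset=tail)
    sc_sens, sc_res = biomarker_sets(de, alpha=alpha)
    return AttributionResult(gene_ids, mean_attr, tail, sc_sens, sc_res)


# --------------------------------------------------- prognostic gene AUC
def single_gene_auc(
    expr: ExpressionMatrix, outcome: np.ndarray, genes: set[str] | list[str]
) -> pd.DataFrame:
    """AUC of each gene's expression as a classifier of a binary outcome.

    Reported oriented so AUC >= 0.5, with the original direction flagged
    (anti-correlated genes have direction −1).
    """
    outcome = np.asarray(outcome, dtype=int)
    records = []
    for g in sorted(set(genes) & set(expr.gene_ids)):
        x = expr.values[:, expr.gene_ids.index(g)]
        raw = _auc(outcome, x)
        records.append(
            {
                "gene_id": g,
                "auc": max(raw, 1 - raw),
                "raw_auc": raw,
                "direction": 1 if raw >= 0.5 else -1,
            }
        )
    return pd.DataFrame(records)


def gene_set_auc_compare(
    aucs_a: np.ndarray, aucs_b: np.ndarray
) -> tuple[float, float, float]:
    """(median_a, median_b, two-sided Mann-Whitney p) for two AUC vectors."""
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty AUC vector")
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(p)


# --------------------------------------------------------- exact test
@dataclass
class ContingencyTable2x2:
    """Rows = lineage (solid, hematopoietic), cols = (sensitive, resistant)."""

    a: int  # solid sensitive
    b: int  # solid resistant
    c: int  # hematopoietic sensitive
    d: int  # hematopoietic resistant

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(t: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass convention).

    Returns (odds ratio a·d/(b·c), p).  A zero in b or c gives an infinite
    odds ratio, reported as ``inf``.
    """
    arr = t.as_array()
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(p)


def sensitive_fraction(t: ContingencyTable2x2, row: str = "solid") -> float:
    """Percentage of sensitive samples in the chosen lineage row."""
    if row == "solid":
        sens, res = t.a, t.b
    elif row == "hematopoietic":
        sens, res = t.c, t.d
    else:
        raise ValueError("row must be 'solid' or 'hematopoietic'")
    if sens + res == 0:
        raise ValueError(f"row {row!r} is empty")
    return 100.0 * sens / (sens + res)
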