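"""Quality control and normalization for the two expression domains.

Bulk (source) profiles are assumed already array/RMA-normalized upstream, so
only :func:`zscore_genes` applies to them.  Single-cell (target) counts run
the full chain: :func:`qc_filter` → :func:`normalize_total` →
:func:`log1p_transform` → :func:`zscore_genes`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import ExpressionMatrix


@dataclass
class QCConfig:
    """Cell- and gene-level filters for raw single-cell counts.

    ``min_*`` thresholds keep a cell/gene when its value is >= the threshold;
    ``max_counts_per_cell`` keeps a cell when its total is <= the threshold.
    Mitochondrial fraction is the count share of genes whose id starts with
    ``mito_prefix``; cells strictly above ``mito_fraction_max`` are removed.
    """

    min_genes_per_cell: int = 0
    min_counts_per_cell: int = 0
    max_counts_per_cell: int | None = None
    min_cells_per_gene: int = 0
    mito_fraction_max: float = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        for name in ("min_genes_per_cell", "min_counts_per_cell", "min_cells_per_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.mito_fraction_max <= 1:
            raise ValueError("mito_fraction_max must be in [0, 1]")


@dataclass
class QCLog:
    """Per-criterion removal counts from one qc_filter run."""

    n_cells_in: int = 0
    n_genes_in: int = 0
    removed_min_genes: int = 0
    removed_min_counts: int = 0
    removed_max_counts: int = 0
    removed_mito: int = 0
    removed_genes_min_cells: int = 0
    n_cells_out: int = 0
    n_genes_out: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def qc_filter(raw: ExpressionMatrix, cfg: QCConfig) -> tuple[ExpressionMatrix, QCLog]:
    """Remove failing cells first, then genes expressed in too few cells.

    A cell is attributed to the first criterion it fails, in the order
    min_genes, min_counts, max_counts, mito fraction; totals in the log are
    therefore disjoint and sum to the number of cells removed.
    """
    if raw.layer_tag != "raw_counts":
        raise ValueError("qc_filter expects raw counts")
    X = raw.values
    log = QCLog(n_cells_in=raw.n_samples, n_genes_in=raw.n_genes)

    genes_per_cell = (X > 0).sum(axis=1)
    counts_per_cell = X.sum(axis=1)
    mito_cols = np.array(
        [g.startswith(cfg.mito_prefix) for g in raw.gene_ids], dtype=bool
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            counts_per_cell > 0, X[:, mito_cols].sum(axis=1) / counts_per_cell, 0.0
        )

    keep = np.ones(raw.n_samples, dtype=bool)
    fail = keep & (genes_per_cell < cfg.min_genes_per_cell)
    log.removed_min_genes = int(fail.sum())
    keep &= ~fail
    fail = keep & (counts_per_cell < cfg.min_counts_per_cell)
    log.removed_min_counts = int(fail.sum())
    keep &= ~fail
    if cfg.max_counts_per_cell is not None:
        fail = keep & (counts_per_cell > cfg.max_counts_per_cell)
        log.removed_max_counts = int(fail.sum())
        keep &= ~fail
    fail = keep & (mito_frac > cfg.mito_fraction_max)
    log.removed_mito = int(fail.sum())
    keep &= ~fail

    if not keep.any():
        raise ValueError("empty after QC: every cell failed a filter")

    filtered = raw.subset_samples(keep)
    cells_per_gene = (filtered.values > 0).sum(axis=0)
    gene_keep = cells_per_gene >= cfg.min_cells_per_gene
    log.removed_genes_min_cells = int((~gene_keep).sum())
    out = filtered.subset_genes(
        [g for g, k in zip(filtered.gene_ids, gene_keep) if k]
    )
    log.n_cells_out, log.n_genes_out = out.n_samples, out.n_genes
    return out, log


def normalize_total(raw: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell so its total count equals ``target_sum`` (1e6 ≡ CPM)."""
    if raw.layer_tag != "raw_counts":
        raise ValueError("normalize_total expects raw counts")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = raw.values.sum(axis=1)
    if np.any(totals <= 0):
        zero = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(
            f"cell {raw.sample_ids[zero]!r} has zero total count; run qc_filter first"
        )
    values = raw.values * (target_sum / totals)[:, None]
    return ExpressionMatrix(values, raw.sample_ids, raw.gene_ids, "normalized")


def log1p_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log(1 + x)."""
    if np.any(m.values < 0):
        raise ValueError("log1p_transform requires non-negative values")
    return ExpressionMatrix(
        np.log1p(m.values), m.sample_ids, m.gene_ids, "log_normalized"
    )


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to zero mean, unit population SD.

    Zero-variance genes map to all-zero columns rather than being dropped,
    keeping the gene space aligned across domains.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0)  # population (ddof=0), StandardScaler semantics
    centered = m.values - mu
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return ExpressionMatrix(z, m.sample_ids, m.gene_ids, "zscored")


def preprocess_target(
    raw: ExpressionMatrix,
    qc: QCConfig | None = None,
    target_sum: float = 1e4,
) -> tuple[ExpressionMatrix, QCLog]:
    """Full single-cell chain: QC → total-count normalize → log1p → z-score."""
    filtered, log = qc_filter(raw, qc or QCConfig())
    return zscore_genes(log1p_transform(normalize_total(filtered, target_sum))), log
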