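"""Feature selection and class rebalancing.

Three feature spaces are supported for training: ``all`` shared genes, the
top-N highly variable genes of the single-cell domain (``tp4k``), or a fixed
gene panel such as a protein-protein-interaction set (``ppi``).  Class
imbalance in the labeled bulk domain is handled either by inverse-frequency
sampling weights (``weight``) or by SMOTE interpolation (``smote``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, GenePanel, ResponseLabelTable


@dataclass
class HVGConfig:
    n_top: int = 4000
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.n_top < 1 or self.n_bins < 1:
            raise ValueError("n_top and n_bins must be >= 1")


@dataclass
class SamplingMode:
    mode: str = "weight"  # "weight" | "smote"
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("weight", "smote"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


def select_hvg(target_log: ExpressionMatrix, cfg: HVGConfig | None = None) -> GenePanel:
    """Top-N highly variable genes by mean-binned normalized dispersion.

    Uses the classic flavor: dispersion = variance/mean of the exponentiated
    log-normalized values, z-normalized within bins of mean expression.
    Computed on the log-normalized layer (before z-scoring).
    """
    import anndata as ad
    import scanpy as sc

    cfg = cfg or HVGConfig()
    if target_log.layer_tag != "log_normalized":
        raise ValueError("select_hvg expects the log_normalized layer")
    n_top = cfg.n_top
    if n_top > target_log.n_genes:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {target_log.n_genes}; returning all genes"
        )
        return GenePanel(set(target_log.gene_ids), "hvg")
    adata = ad.AnnData(
        X=target_log.values.copy(),
        obs={"cell": target_log.sample_ids},
        var={"gene": target_log.gene_ids},
    )
    adata.var_names = target_log.gene_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata, flavor="seurat", n_top_genes=n_top, n_bins=cfg.n_bins
        )
    chosen = set(adata.var_names[adata.var["highly_variable"].to_numpy()])
    return GenePanel(chosen, "hvg")


def apply_panel(m: ExpressionMatrix, panel: GenePanel) -> ExpressionMatrix:
    """Restrict columns to panel ∩ genes, lexicographically sorted."""
    shared = sorted(panel.gene_ids & set(m.gene_ids))
    if not shared:
        raise ValueError(f"panel {panel.name!r} shares no genes with the matrix")
    return m.subset_genes(shared)


def balanced_sample_weights(labels: ResponseLabelTable | np.ndarray) -> np.ndarray:
    """Inverse-class-frequency weights, normalized to sum 1.

    Sampling with replacement under these weights draws each class with
    probability 1/2 in expectation.
    """
    y = labels.to_array() if isinstance(labels, ResponseLabelTable) else np.asarray(labels)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present to balance")
    w = 1.0 / counts[y]
    return w / w.sum()


def smote_oversample(
    X: np.ndarray | ExpressionMatrix,
    labels: ResponseLabelTable | np.ndarray,
    cfg: SamplingMode | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE: balance classes by interpolating minority nearest neighbors.

    Each synthetic sample is x_i + u·(x_nn − x_i) with u ~ Uniform(0,1) and
    x_nn one of the k Euclidean nearest minority neighbors of minority sample
    x_i.  Original rows are preserved unchanged and come first in the output.
    """
    cfg = cfg or SamplingMode(mode="smote")
    if isinstance(X, ExpressionMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = labels.to_array() if isinstance(labels, ResponseLabelTable) else np.asarray(labels)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present")
    minority = int(np.argmin(counts))
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X.copy(), y.copy()
    minority_idx = np.flatnonzero(y == minority)
    if len(minority_idx) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    Xm = X[minority_idx]
    k = min(cfg.smote_k, len(minority_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    # first neighbor is the point itself
    neighbors = nn.kneighbors(Xm, return_distance=False)[:, 1:]
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(minority_idx), size=n_needed)
    pick = rng.integers(0, k, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=n_needed)
    anchors = Xm[base]
    partners = Xm[neighbors[base, pick]]
    synthetic = anchors + u[:, None] * (partners - anchors)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out
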