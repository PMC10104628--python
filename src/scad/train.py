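"""Adversarial training, cross-validation and metrics.

The central objects follow the fitted-model convention: :class:`SCAD` is
built from the two domains' data plus a :class:`TrainConfig`; ``fit()``
returns a :class:`SCADResults` carrying the trained networks, the loss
history and prediction/summary methods.  :func:`cross_validate` wraps the
five-fold × five-seed evaluation protocol and returns a
:class:`MetricsReport` with the 25 per-cell AUC/AUPR values.

One master seed spawns independent sub-seeds for network initialization,
mini-batch sampling and SMOTE, so a fit is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .features import SamplingMode, balanced_sample_weights, smote_oversample
from .io import ExpressionMatrix, ResponseLabelTable
from .model import Adam, ModelConfig, SCADModel, adv_loss, bce_loss, total_loss

logger = logging.getLogger(__name__)

_CLIP = 1e-7


@dataclass
class TrainConfig:
    """Training hyperparameters; architecture fields are forwarded to the model."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    sampling: SamplingMode = field(default_factory=SamplingMode)
    feature_mode: str = "all"  # all | tp4k | ppi
    lambda_adv: float = 1.0
    h_dim: int = 128
    z_dim: int = 64
    dropout: float = 0.5
    cv_folds: int = 5
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.feature_mode not in ("all", "tp4k", "ppi"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")


# --------------------------------------------------------------- metrics
def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random positive is ranked above a random negative.

    Rank-based (Mann-Whitney); ties contribute 1/2.
    """
    labels = np.asarray(labels).ravel()
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores).ravel()))

def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    labels = np.asarray(labels).ravel()
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positives")
    return float(average_precision_score(labels, np.asarray(scores).ravel()))


def make_cv_splits(
    n: int, k: int, labels: np.ndarray | None = None, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint folds covering all indices, stratified when labels given."""
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [
            (tr, te) for tr, te in splitter.split(np.zeros(n), np.asarray(labels))
        ]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n))]


# -------------------------------------------------------- training loop
def _prob_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(probability), to feed the sigmoid head's backward."""
    pc = np.clip(p, _CLIP, 1 - _CLIP)
    return ((pc - y) / (pc * (1 - pc)) / len(y)).reshape(-1, 1)


def train_scad(
    source: tuple[np.ndarray, np.ndarray],
    target_unlabeled: np.ndarray,
    cfg: TrainConfig,
    seed: int = 0,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SCADModel, pd.DataFrame]:
    """Train extractor+predictor(+discriminator) for cfg.epochs.

    ``source`` is (X_s, y_s) with binary labels; ``target_unlabeled`` is the
    cell matrix whose labels are never consumed here.  With
    ``cfg.lambda_adv == 0`` the discriminator is skipped entirely and the
    run is the plain source-only baseline.  Returns the model and a
    per-epoch history (bce loss, adversarial loss, validation AUC).
    """
    X_s, y_s = np.asarray(source[0], float), np.asarray(source[1], int)
    X_t = np.asarray(target_unlabeled, float)
    if X_s.shape[1] != X_t.shape[1]:
        raise ValueError("source and target gene spaces differ")
    if len(set(y_s.tolist())) < 2:
        raise ValueError("source labels must contain both classes")

    ss = np.random.SeedSequence(seed)
    init_seed, batch_seed, smote_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    if cfg.sampling.mode == "smote":
        X_s, y_s = smote_oversample(
            X_s, y_s, replace(cfg.sampling, seed=smote_seed)
        )
        batch_p = None
    else:
        batch_p = balanced_sample_weights(y_s)

    model = SCADModel(
        ModelConfig(
            n_genes=X_s.shape[1],
            h_dim=cfg.h_dim,
            z_dim=cfg.z_dim,
            dropout=cfg.dropout,
            lambda_adv=cfg.lambda_adv,
            seed=init_seed,
        )
    )
    adversarial = cfg.lambda_adv > 0
    opt_mp = Adam(
        model.extractor.params() + model.predictor.params(), lr=cfg.learning_rate
    )
    opt_d = Adam(model.discriminator.params(), lr=cfg.learning_rate)

    rng = np.random.default_rng(batch_seed)
    n_s, n_t = len(X_s), len(X_t)
    steps = max(1, int(np.ceil(n_s / cfg.batch_size)))
    bs = cfg.batch_size
    history = []

    for epoch in range(cfg.epochs):
        ep_bce, ep_adv = [], []
        for _ in range(steps):
            src = rng.choice(n_s, size=min(bs, n_s), replace=True, p=batch_p)
            xb, yb = X_s[src], y_s[src]
            nb = len(xb)

            if adversarial:
                tgt = rng.choice(n_t, size=nb, replace=True)
                xt = X_t[tgt]
                dom = np.concatenate([np.ones(nb), np.zeros(nb)])

                # (i) discriminator step on detached latents
                Z = model.extract(np.vstack([xb, xt]), train=True)
                d = model.discriminate(Z, train=True)
                l_adv = adv_loss(d[:nb], d[nb:])
                model.discriminator.backward(_prob_grad(d, dom))
                opt_d.step()

                # (ii) extractor+predictor step: BCE + λ · flipped-label term
                Z = model.extract(np.vstack([xb, xt]), train=True)
                p = model.predict(Z[:nb], train=True)
                l_bce = bce_loss(yb, p)
                gZ_pred = model.predictor.backward(_prob_grad(p, yb))
                d = model.discriminate(Z, train=True)
                gZ_adv = model.discriminator.backward(_prob_grad(d, 1.0 - dom))
                gZ = cfg.lambda_adv * gZ_adv
                gZ[:nb] += gZ_pred
                model.extractor.backward(gZ)
                opt_mp.step()
            else:
                Z = model.extract(xb, train=True)
                p = model.predict(Z, train=True)
                l_bce = bce_loss(yb, p)
                l_adv = float("nan")
                gZ = model.predictor.backward(_prob_grad(p, yb))
                model.extractor.backward(gZ)
                opt_mp.step()

            if not np.isfinite(l_bce) or (adversarial and not np.isfinite(l_adv)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, bce={l_bce}, adv={l_adv}"
                )
            ep_bce.append(l_bce)
            ep_adv.append(l_adv)

        row = {
            "epoch": epoch,
            "bce_loss": float(np.mean(ep_bce)),
            "adv_loss": float(np.mean(ep_adv)) if adversarial else np.nan,
        }
        if validation is not None:
            row["val_auc"] = auc(validation[1], model.predict_proba(validation[0]))
        history.append(row)

    return model, pd.DataFrame(history)


def train_baseline(
    source: tuple[np.ndarray, np.ndarray], cfg: TrainConfig, seed: int = 0,
    validation=None,
) -> tuple[SCADModel, pd.DataFrame]:
    """Source-only training: discriminator and adversarial term disabled."""
    cfg0 = replace(cfg, lambda_adv=0.0)
    dummy_target = np.zeros((1, np.asarray(source[0]).shape[1]))
    return train_scad(source, dummy_target, cfg0, seed=seed, validation=validation)


# ------------------------------------------------------- model / results
class SCAD:
    """Drug-response transfer model over a bulk source and single-cell target.

    Parameters
    ----------
    source_X : zscored samples × genes array (or ExpressionMatrix)
    source_y : binary labels, 1 = sensitive
    target_X : zscored cells × genes array on the same gene order
    config : TrainConfig

    ``fit(seed)`` trains and returns :class:`SCADResults`.
    """

    def __init__(self, source_X, source_y, target_X, config: TrainConfig | None = None):
        if isinstance(source_X, ExpressionMatrix):
            if isinstance(source_y, ResponseLabelTable):
                source_y = source_y.align(source_X.sample_ids)
            source_X = source_X.values
        if isinstance(source_y, ResponseLabelTable):
            source_y = source_y.known().to_array()
        if isinstance(target_X, ExpressionMatrix):
            self.target_ids = list(target_X.sample_ids)
            self.gene_ids = list(target_X.gene_ids)
            target_X = target_X.values
        else:
            self.target_ids = [str(i) for i in range(len(target_X))]
            self.gene_ids = None
        self.source_X = np.asarray(source_X, float)
        self.source_y = np.asarray(source_y, int)
        self.target_X = np.asarray(target_X, float)
        self.config = config or TrainConfig()

    @classmethod
    def from_matrices(
        cls,
        source: ExpressionMatrix,
        labels: ResponseLabelTable,
        target: ExpressionMatrix,
        config: TrainConfig | None = None,
    ) -> "SCAD":
        from .io import intersect_genes

        s, t = intersect_genes(source, target)
        return cls(s, labels, t, config)

    def fit(self, seed: int = 0, validation=None) -> "SCADResults":
        model, history = train_scad(
            (self.source_X, self.source_y),
            self.target_X,
            self.config,
            seed=seed,
            validation=validation,
        )
        model.gene_ids = self.gene_ids
        return SCADResults(self, model, history, seed)


class SCADResults:
    """A fitted transfer model: trained networks, history, predictions."""

    def __init__(self, model_def: SCAD, network: SCADModel, history: pd.DataFrame, seed: int):
        self.model = model_def
        self.network = network
        self.history = history
        self.seed = seed

    def predict(self, X: np.ndarray | ExpressionMatrix | None = None) -> np.ndarray:
        """Sensitivity probabilities; defaults to the target cells."""
        if X is None:
            X = self.model.target_X
        if isinstance(X, ExpressionMatrix):
            X = X.values
        return self.network.predict_proba(np.asarray(X, float))

    def target_scores(self) -> pd.Series:
        return pd.Series(self.predict(), index=self.model.target_ids, name="score")

    def evaluate(self, target_labels: np.ndarray) -> dict[str, float]:
        scores = self.predict()
        return {
            "auc": auc(target_labels, scores),
            "aupr": aupr(target_labels, scores),
        }

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        lines = [
            "SCAD transfer model results",
            "=" * 40,
            f"source samples: {len(self.model.source_y)} "
            f"({int(self.model.source_y.sum())} sensitive)",
            f"target cells:   {len(self.model.target_X)}",
            f"genes:          {self.model.source_X.shape[1]}",
            f"lambda_adv:     {cfg.lambda_adv}   sampling: {cfg.sampling.mode}",
            f"h_dim/z_dim:    {cfg.h_dim}/{cfg.z_dim}   epochs: {cfg.epochs}",
            f"seed:           {self.seed}",
            f"final BCE loss: {h['bce_loss'].iloc[-1]:.4f}",
        ]
        if np.isfinite(h["adv_loss"].iloc[-1]):
            lines.append(f"final adv loss: {h['adv_loss'].iloc[-1]:.4f}")
        if "val_auc" in h:
            lines.append(f"final source-validation AUC: {h['val_auc'].iloc[-1]:.4f}")
        return "\n".join(lines)


# -------------------------------------------------------- cross-validation
@dataclass
class MetricsReport:
    """Per-(fold, seed) AUC/AUPR with aggregate mean and SD."""

    cells: list[dict]
    config: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells)

    def _valid(self, key: str) -> np.ndarray:
        return np.array(
            [c[key] for c in self.cells if c.get(key) is not None and np.isfinite(c[key])]
        )

    @property
    def mean_auc(self) -> float:
        return float(self._valid("auc").mean())

    @property
    def sd_auc(self) -> float:
        return float(self._valid("auc").std(ddof=1)) if len(self._valid("auc")) > 1 else 0.0

    @property
    def mean_aupr(self) -> float:
        return float(self._valid("aupr").mean())

    @property
    def sd_aupr(self) -> float:
        v = self._valid("aupr")
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "cells": self.cells,
            "config": self.config,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_aupr": self.mean_aupr,
            "sd_aupr": self.sd_aupr,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(cells=d["cells"], config=d["config"])

    def summary(self) -> str:
        return (
            f"MetricsReport: {len(self.cells)} cells "
            f"(folds x seeds)\n"
            f"  AUC  {self.mean_auc:.3f} +/- {self.sd_auc:.3f}\n"
            f"  AUPR {self.mean_aupr:.3f} +/- {self.sd_aupr:.3f}"
        )


def cross_validate(
    source_X: np.ndarray,
    source_y: np.ndarray,
    target_X: np.ndarray,
    target_y_eval: np.ndarray,
    cfg: TrainConfig,
    seeds: tuple[int, ...] | None = None,
) -> MetricsReport:
    """k folds × seeds adversarial training with held-out target evaluation.

    Source and target are each split into ``cfg.cv_folds`` folds, coupled
    per CV iteration: training uses the source train-fold (with labels) and
    the target train-fold (unlabeled); AUC/AUPR are measured on the held-out
    target fold, whose labels are touched only at that point.  A held-out
    fold with a single class yields undefined metrics: recorded as missing
    and excluded from the aggregate.
    """
    source_X, source_y = np.asarray(source_X, float), np.asarray(source_y, int)
    target_X = np.asarray(target_X, float)
    target_y_eval = np.asarray(target_y_eval, int)
    seeds = tuple(seeds if seeds is not None else cfg.seeds)

    cells = []
    for seed in seeds:
        ss = np.random.SeedSequence(int(seed))
        split_seed, fit_base = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
        src_folds = make_cv_splits(
            len(source_y), cfg.cv_folds, labels=source_y, seed=split_seed
        )
        tgt_folds = make_cv_splits(len(target_X), cfg.cv_folds, seed=split_seed)
        for fold, ((s_tr, s_va), (t_tr, t_te)) in enumerate(zip(src_folds, tgt_folds)):
            model, history = train_scad(
                (source_X[s_tr], source_y[s_tr]),
                target_X[t_tr],
                cfg,
                seed=(fit_base + fold) % 2**31,
                validation=(source_X[s_va], source_y[s_va]),
            )
            scores = model.predict_proba(target_X[t_te])
            y_te = target_y_eval[t_te]
            cell = {"fold": fold, "seed": int(seed), "n_test": int(len(t_te))}
            if len(set(y_te.tolist())) < 2:
                logger.warning(
                    "fold %d seed %d: single-class held-out target fold; "
                    "metrics recorded as missing", fold, seed,
                )
                cell["auc"] = None
                cell["aupr"] = None
            else:
                cell["auc"] = auc(y_te, scores)
                cell["aupr"] = aupr(y_te, scores)
            cell["val_auc"] = float(history["val_auc"].iloc[-1])
            cells.append(cell)
    return MetricsReport(cells=cells, config=asdict(cfg))


def grid_search(
    source_X: np.ndarray,
    source_y: np.ndarray,
    target_X: np.ndarray,
    grid: list[dict],
    base_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Pick the config maximizing mean source-validation AUC over the k folds.

    ``grid`` is a list of dicts of TrainConfig field overrides (h_dim, z_dim,
    lambda_adv, learning_rate, batch_size, ...).  Ties break toward the
    smaller model (h_dim, then z_dim).  Target labels are never consulted.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    base_cfg = base_cfg or TrainConfig()
    source_X, source_y = np.asarray(source_X, float), np.asarray(source_y, int)
    ss = np.random.SeedSequence(int(seed))
    split_seed, fit_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    folds = make_cv_splits(len(source_y), base_cfg.cv_folds, labels=source_y, seed=split_seed)
    tgt_folds = make_cv_splits(len(target_X), base_cfg.cv_folds, seed=split_seed)

    rows = []
    for overrides in grid:
        cfg = replace(base_cfg, **overrides)
        val_aucs = []
        for fold, ((s_tr, s_va), (t_tr, _)) in enumerate(zip(folds, tgt_folds)):
            _, history = train_scad(
                (source_X[s_tr], source_y[s_tr]),
                target_X[t_tr],
                cfg,
                seed=(fit_seed + fold) % 2**31,
                validation=(source_X[s_va], source_y[s_va]),
            )
            val_aucs.append(float(history["val_auc"].iloc[-1]))
        rows.append({**overrides, "mean_val_auc": float(np.mean(val_aucs)),
                     "h_dim": cfg.h_dim, "z_dim": cfg.z_dim})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mean_val_auc", "h_dim", "z_dim"], ascending=[False, True, True]
    )
    best = grid[order.index[0]]
    return replace(base_cfg, **best), table
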