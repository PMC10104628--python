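"""The three networks and their losses.

A shared feature extractor M maps expression vectors from either domain into
a latent space; a drug-response predictor P maps latents to a sensitivity
probability; a domain discriminator D maps latents to the probability that a
sample came from the labeled bulk (source) domain.  Training is adversarial:
D learns to tell the domains apart while M learns features D cannot
attribute, so the predictor trained on bulk labels transfers to cells.

The stack is a small, fully deterministic numpy implementation: affine
layers with ReLU and inverted dropout, sigmoid heads, mean-reduced losses,
and an Adam optimizer.  Backpropagation also returns input gradients, which
the attribution module reuses for integrated gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

EPS = 1e-7  # clip bound for every log argument


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    h_dim sets the extractor's hidden width and the discriminator's layer
    width; z_dim sets the latent dimension and the predictor's layer width.
    """

    n_genes: int
    h_dim: int = 128
    z_dim: int = 64
    dropout: float = 0.5
    lambda_adv: float = 1.0
    predictor_depth: int = 5
    discriminator_depth: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h_dim < 1 or self.z_dim < 1:
            raise ValueError("h_dim and z_dim must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be >= 0")


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialization, suited to the ReLU nonlinearity
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        # in-place: the optimizer holds references to these gradient arrays
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.uniform(size=x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask

    def params(self):
        return []


class Sigmoid:
    def forward(self, x, train, rng):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        # keep outputs strictly inside (0,1) even under float saturation
        out = np.clip(out, EPS, 1.0 - EPS)
        self._out = out
        return out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def weights(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _mlp_head(n_in: int, width: int, depth: int, dropout: float, rng) -> Sequential:
    """depth affine layers of constant hidden width, sigmoid head (1 output)."""
    layers: list = []
    d = n_in
    for _ in range(depth - 1):
        layers += [Linear(d, width, rng), ReLU(), Dropout(dropout)]
        d = width
    layers += [Linear(d, 1, rng), Sigmoid()]
    return Sequential(layers)


class SCADModel:
    """Shared extractor + predictor + discriminator with one parameter set.

    The extractor is n_genes → h_dim → z_dim (ReLU + dropout after the first
    affine layer); predictor and discriminator are five affine layers of
    constant width (z_dim and h_dim respectively) ending in a sigmoid.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.gene_ids: list[str] | None = None  # training gene order, if known
        rng = np.random.default_rng(config.seed)
        c = config
        self.extractor = Sequential(
            [
                Linear(c.n_genes, c.h_dim, rng),
                ReLU(),
                Dropout(c.dropout),
                Linear(c.h_dim, c.z_dim, rng),
            ]
        )
        self.predictor = _mlp_head(c.z_dim, c.z_dim, c.predictor_depth, c.dropout, rng)
        self.discriminator = _mlp_head(
            c.z_dim, c.h_dim, c.discriminator_depth, c.dropout, rng
        )
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

    # ------------------------------------------------------------------ API
    def extract(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.config.n_genes:
            raise ValueError(
                f"expected {self.config.n_genes} genes, got {X.shape[1]}"
            )
        return self.extractor.forward(X, train, self._dropout_rng)

    def predict(self, Z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.predictor.forward(Z, train, self._dropout_rng).ravel()

    def discriminate(self, Z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.discriminator.forward(Z, train, self._dropout_rng).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Eval-mode sensitivity probabilities for expression rows."""
        return self.predict(self.extract(X))

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d(sensitivity probability)/d(input) per sample, eval mode."""
        X = np.asarray(X, dtype=float)
        Z = self.extract(X)
        self.predict(Z)
        gZ = self.predictor.backward(np.ones((X.shape[0], 1)))
        gX = self.extractor.backward(gZ)
        if not np.all(np.isfinite(gX)):
            raise FloatingPointError("non-finite input gradient")
        return gX

    def all_weights(self) -> list[np.ndarray]:
        return (
            self.extractor.weights()
            + self.predictor.weights()
            + self.discriminator.weights()
        )

    # ------------------------------------------------------- serialization
    def save(self, path: str | Path) -> None:
        meta = {"config": asdict(self.config), "gene_ids": self.gene_ids}
        arrays = {f"w{i}": w for i, w in enumerate(self.all_weights())}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "SCADModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(ModelConfig(**meta["config"]))
            model.gene_ids = meta["gene_ids"]
            for i, w in enumerate(model.all_weights()):
                w[...] = data[f"w{i}"]
        return model


def init_model(cfg: ModelConfig) -> SCADModel:
    return SCADModel(cfg)


# ------------------------------------------------------------------ losses
def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def bce_loss(
    y: np.ndarray,
    p: np.ndarray,
    weights: np.ndarray | None = None,
    reduction: str = "mean",
) -> float:
    """Binary cross-entropy −Σ y log p + (1−y) log(1−p), mean by default."""
    y = np.asarray(y, dtype=float).ravel()
    p = _clip(np.asarray(p, dtype=float).ravel())
    if y.shape != p.shape:
        raise ValueError("label and probability vectors differ in length")
    terms = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()
        terms = terms * (w / w.mean())
    return float(terms.mean() if reduction == "mean" else terms.sum())


def adv_loss(d_source: np.ndarray, d_target: np.ndarray, reduction: str = "mean") -> float:
    """Discriminator objective: −Σ log d̂_s − Σ log(1 − d̂_t).

    Identical to BCE with domain labels 1 (source) / 0 (target).  The
    extractor's adversarial term uses the label-flipped version of the same
    expression.
    """
    ds = _clip(np.asarray(d_source, dtype=float).ravel())
    dt = _clip(np.asarray(d_target, dtype=float).ravel())
    terms = np.concatenate([-np.log(ds), -np.log(1.0 - dt)])
    return float(terms.mean() if reduction == "mean" else terms.sum())


def total_loss(l_bce: float, l_adv: float, lambda_adv: float) -> float:
    """L = L_BCE + λ · L_adv."""
    return l_bce + lambda_adv * l_adv
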