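import numpy as np
import pytest

from scad import (
    ExpressionMatrix,
    SimConfig,
    TrainConfig,
    intersect_genes,
    preprocess_target,
    simulate_source,
    simulate_target,
    zscore_genes,
)
from scad.train import train_scad


@pytest.fixture(scope="session")
def small_sim():
    """A small paired dataset: preprocessed source/target + labels."""
    cfg = SimConfig(
        n_genes=80,
        n_signal_genes=16,
        n_source=120,
        n_target=90,
        n_mito_genes=4,
        seed=42,
    )
    src, y_s = simulate_source(cfg)
    tgt_raw, y_t = simulate_target(cfg)
    tgt, qclog = preprocess_target(tgt_raw)
    s, t = intersect_genes(zscore_genes(src), tgt)
    return {
        "cfg": cfg,
        "source": s,
        "source_y": np.array(y_s.align(s.sample_ids).labels, dtype=int),
        "target": t,
        "target_y": np.array(y_t.align(t.sample_ids).labels, dtype=int),
        "qclog": qclog,
    }


@pytest.fixture(scope="session")
def quick_cfg():
    """A fast training configuration for unit tests."""
    return TrainConfig(epochs=5, h_dim=32, z_dim=16)


@pytest.fixture(scope="session")
def trained_small(small_sim, quick_cfg):
    """A model trained briefly on the small dataset."""
    model, history = train_scad(
        (small_sim["source"].values, small_sim["source_y"]),
        small_sim["target"].values,
        quick_cfg,
        seed=1,
    )
    return model, history


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def toy_matrix(values, sample_prefix="s", gene_prefix="g", tag="raw_counts"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"{sample_prefix}{i}" for i in range(values.shape[0])],
        [f"{gene_prefix}{j}" for j in range(values.shape[1])],
        tag,
    )
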