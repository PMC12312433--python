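import numpy as np
import pytest

from clpnet import SimulationConfig


def make_config(
    n=500,
    p=6,
    B=None,
    corr=0.3,
    residual=0.85,
    seed=0,
    missing_rate=0.0,
    mechanism="MCAR",
    means=0.0,
    sds=1.0,
):
    """Single-group simulation config with sensible defaults for tests."""
    names = [f"N{i}" for i in range(p)]
    if B is None:
        B = np.zeros((p, p))
    C = np.full((p, p), corr)
    np.fill_diagonal(C, 1.0)
    return SimulationConfig(
        node_names=names,
        n_per_group={"g": n},
        baseline_means={"g": np.full(p, float(means))},
        baseline_sds={"g": np.full(p, float(sds))},
        baseline_corr=C,
        true_B={"g": np.asarray(B, dtype=float)},
        residual_sds=np.full(p, float(residual)),
        missing_rate=missing_rate,
        mechanism=mechanism,
        seed=seed,
    )


def sparse_B(p=6, auto=0.35):
    """Sparse 6-node coefficient matrix with 8 cross-lagged paths, |b| in [0.10, 0.19]."""
    B = np.zeros((p, p))
    np.fill_diagonal(B, auto)
    for i, j, w in [
        (0, 2, -0.19),
        (0, 3, 0.15),
        (4, 3, 0.13),
        (4, 1, 0.10),
        (5, 3, 0.10),
        (0, 1, -0.12),
        (1, 0, -0.12),
        (2, 0, -0.10),
    ]:
        B[i, j] = w
    return B


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
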