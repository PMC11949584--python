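import numpy as np
import pytest

from calltif import TimeSeriesPanel


def make_ar1_null_panel(n_nodes: int, t_points: int, coeff: float, seed: int,
                        tr: float = 1.0) -> TimeSeriesPanel:
    """Mutually independent AR(1) nodes with unit Gaussian innovations."""
    rng = np.random.default_rng(seed)
    x = np.zeros((t_points, n_nodes))
    eps = rng.standard_normal((t_points, n_nodes))
    x[0] = eps[0]
    for t in range(1, t_points):
        x[t] = coeff * x[t - 1] + eps[t]
    return TimeSeriesPanel(x, [f"n{i}" for i in range(n_nodes)], tr_seconds=tr)


def make_white_panel(n_nodes: int, t_points: int, seed: int) -> TimeSeriesPanel:
    rng = np.random.default_rng(seed)
    return TimeSeriesPanel(
        rng.standard_normal((t_points, n_nodes)),
        [f"n{i}" for i in range(n_nodes)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    return TimeSeriesPanel(
        rng.standard_normal((60, 3)), ["a", "b", "c"], tr_seconds=0.72
    )
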