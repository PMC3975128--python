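import numpy as np
import pytest

from telokin import (
    InputSpec,
    LengthDistribution,
    LengthGrid,
    default_parameters,
    input_density,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def open_grid():
    """Coarser-than-default grid: plenty for ~0.1% accuracy, much faster."""
    return LengthGrid(-2000.0, 20000.0, 10.0)


@pytest.fixture(scope="session")
def gaussian_input(open_grid, params):
    spec = InputSpec(kind="gaussian", L=params.L0, sigma=params.sigma0)
    return LengthDistribution(open_grid, input_density(open_grid.x, spec))


def rel_l2(a: np.ndarray, b: np.ndarray, x: np.ndarray) -> float:
    """Relative L2 distance integral((a-b)^2)^0.5 / integral(b^2)^0.5."""
    return float(np.sqrt(np.trapezoid((a - b) ** 2, x)
                         / np.trapezoid(b ** 2, x)))
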