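"""Length-dependent rate kernels and input length distributions.

The t-loop capping rate k_c(x) = delta / (1 + exp((alpha - x)/beta)) is the
one length-dependent rate in the model: long telomeres loop and leave the
extendible pool readily, short ones hardly at all.  For analytic work it is
replaced by its sharp-interface limit delta * H(x - alpha).

Input length distributions are gamma (matching the HT Q-FISH histogram fit)
or Gaussian (its large-shape/central-limit approximation, evaluated on the
whole real line).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ParameterSet

__all__ = ["InputSpec", "capping_rate", "capping_rate_step", "input_density"]


def capping_rate(x, params: ParameterSet):
    """Sigmoidal t-loop formation rate k_c(x), in s^-1.

    Monotone increasing, k_c(alpha) = delta/2 exactly, limits 0 and delta.
    Accepts scalars or arrays; negative lengths are in-domain.
    """
    x = np.asarray(x, dtype=float)
    # scipy's expit is numerically safe for large |argument|
    from scipy.special import expit

    out = params.delta * expit((x - params.alpha) / params.beta)
    return out if out.ndim else float(out)


def capping_rate_step(x, params: ParameterSet):
    """Sharp-interface capping rate delta * H(x - alpha), with H(0) = 1/2.

    The midpoint convention matches the sigmoid's exact value delta/2 at
    x = alpha, so midpoint quadrature across the step is unbiased.
    """
    x = np.asarray(x, dtype=float)
    out = params.delta * np.where(
        x > params.alpha, 1.0, np.where(x < params.alpha, 0.0, 0.5)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InputSpec:
    """Input telomere-length distribution: gamma or Gaussian.

    For the gamma kind the shape and scale are derived from the requested
    mean and SD as gamma_shape = L^2/sigma^2 and theta = sigma^2/L; the shape
    must exceed 1 so the density vanishes at x = 0.
    """

    kind: str = "gamma"
    L: float = 3440.0
    sigma: float = 800.0

    def __post_init__(self) -> None:
        if self.kind not in ("gamma", "gaussian"):
            raise ValueError(f"kind must be 'gamma' or 'gaussian', got {self.kind!r}")
        if not self.L > 0:
            raise ValueError("mean length L must be > 0")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.kind == "gamma" and self.gamma_shape <= 1.0:
            raise ValueError(
                f"gamma shape L^2/sigma^2 = {self.gamma_shape:g} must exceed 1"
            )

    @property
    def gamma_shape(self) -> float:
        return self.L**2 / self.sigma**2

    @property
    def theta(self) -> float:
        return self.sigma**2 / self.L

    def frozen(self):
        """The underlying scipy distribution object."""
        if self.kind == "gamma":
            return stats.gamma(self.gamma_shape, scale=self.theta)
        return stats.norm(loc=self.L, scale=self.sigma)


def input_density(x, spec: InputSpec):
    """Probability density (bp^-1) of the input length distribution at x.

    Gamma densities are zero for x <= 0; Gaussian densities are evaluated on
    the full real line without truncation.
    """
    x = np.asarray(x, dtype=float)
    out = spec.frozen().pdf(x)
    if spec.kind == "gamma":
        out = np.where(x > 0, out, 0.0)
    return out if out.ndim else float(out)
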