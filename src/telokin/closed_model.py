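"""Long-run steady states of the closed model and the (T0, R0) feasibility map.

Over many generations the exit flux is recycled: telomeres leaving the pool
(t-loop formation or drug locking) re-enter mu bp shorter at the next
replication.  The steady state then satisfies a linear advance-delay
equation in the open-state density U(x).  Expanding the shift operators
exp(+-(mu/2) d/dy) to first order in the small lengths mu and rho/k_off (the
quasicontinuum approximation) collapses the delay equation to a separable
first-order ODE whose solution is the closed form

    U(x) = A exp(lambda x) sech^(beta delta / (c0 cT)) ((x - alpha)/(2 beta)),

with composite constants

    c0 = mu/2 + rho/k_off          (length scale, nt)
    cT = k_on T0 rho / (mu k_off)  (telomerase supply rate, s^-1)
    cR = k_f k_s k_r R0 / (k_u k_d + k_r (k_u + k_s R0))   (drug locking, s^-1)
    lambda = (2 cT - 2 cR - delta) / (2 c0 cT)             (skewness, bp^-1)

U is normalisable precisely when cR < cT < cR + delta; rearranged, this
gives lower and upper bounds on T0 (for given R0) and on R0 (for given T0)
separating length homeostasis from erosion and unbounded growth.

The exact delay equation, discretised as a linear system, serves as an
independent oracle for the quasicontinuum closed form (see tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import LengthDistribution, LengthGrid, StateDensities
from .kernels import capping_rate
from .open_model import drug_locking_rate
from .params import ParameterSet

__all__ = [
    "QCConstants",
    "FeasibilityBounds",
    "InfeasibleRegimeError",
    "qc_constants",
    "steady_U",
    "steady_BGC",
    "exit_density_closed",
    "exit_moments",
    "feasibility_bounds",
    "feasibility_region",
    "mean_length_surface",
    "delay_steady_state",
]


class InfeasibleRegimeError(ValueError):
    """(T0, R0) lies outside the steady-state feasibility region."""


@dataclass(frozen=True)
class QCConstants:
    """Composite constants of the quasicontinuum steady state."""

    cR: float            #: drug-locking composite rate (s^-1)
    cT: float            #: telomerase supply composite rate (s^-1)
    c0: float            #: length-scale composite mu/2 + rho/k_off (nt)
    lam: float           #: exponential tilt / skewness exponent (bp^-1)
    sech_exponent: float  #: beta*delta/(c0*cT), dimensionless

    def g(self, x, params: ParameterSet):
        """Combined exit kernel g(x) = k_c(x) + cR, in (cR, cR + delta)."""
        return capping_rate(x, params) + self.cR


def qc_constants(T0: float, R0: float, params: ParameterSet) -> QCConstants:
    """Composite constants c0, cT, cR, lambda for given molecule counts."""
    if T0 <= 0:
        raise ValueError("quasicontinuum constants require T0 > 0 (cT = 0 "
                         "degenerates the steady-state ODE)")
    if R0 < 0:
        raise ValueError("R0 must be >= 0")
    cR = drug_locking_rate(R0, params)
    cT = params.k_on * T0 * params.rho / (params.mu * params.k_off)
    c0 = 0.5 * params.mu + params.rho / params.k_off
    lam = (2.0 * cT - 2.0 * cR - params.delta) / (2.0 * c0 * cT)
    return QCConstants(cR=cR, cT=cT, c0=c0, lam=lam,
                       sech_exponent=params.beta * params.delta / (c0 * cT))


def _log_sech(z: np.ndarray) -> np.ndarray:
    """log(sech z), numerically safe for large |z|."""
    az = np.abs(z)
    return math.log(2.0) - az - np.log1p(np.exp(-2.0 * az))


def steady_U(grid: LengthGrid, T0: float, R0: float,
             params: ParameterSet, check_feasible: bool = True,
             ) -> LengthDistribution:
    """Quasicontinuum steady-state open density, normalised to a pdf.

    U(x) = A e^{lambda x} sech^q((x - alpha)/(2 beta)) with
    q = beta delta/(c0 cT); the amplitude A absorbs the free constant so
    that the density integrates to one.

    Raises :class:`InfeasibleRegimeError` outside the feasibility window
    (where the tails fail to decay and U is not normalisable).
    """
    qc = qc_constants(T0, R0, params)
    if check_feasible:
        b = feasibility_bounds(params, R0=R0)
        if not (b.T_tilde_min < T0 < b.T_max):
            regime = ("erosion" if T0 <= b.T_tilde_min else "unbounded growth")
            raise InfeasibleRegimeError(
                f"(T0={T0:g}, R0={R0:g} molecules) is in the {regime} regime: "
                f"feasible window is T_tilde_min={b.T_tilde_min:.4g} < T0 < "
                f"T_max={b.T_max:.4g}")
    # tail decay rates: right tail needs q/(2 beta) > lambda, left tail
    # q/(2 beta) > -lambda; equivalent to cR < cT < cR + delta
    q = qc.sech_exponent
    if q / (2.0 * params.beta) <= abs(qc.lam):
        raise InfeasibleRegimeError(
            "steady density is not normalisable on the real line "
            "(tail decay rate <= |lambda|)")
    x = grid.x
    log_u = qc.lam * x + q * _log_sech((x - params.alpha) / (2.0 * params.beta))
    log_u -= log_u.max()
    return LengthDistribution(grid, np.exp(log_u), normalize=True)


def steady_BGC(U: LengthDistribution, T0: float, R0: float,
               params: ParameterSet) -> StateDensities:
    """Recover the bound, G4 and drug-locked densities from the open one.

    B comes from the exact (pre-expansion) flux relation
    B(x) = [(g(x) + k_on T0) U(x) - g(x + mu) U(x + mu)] / k_off, with the
    advanced term evaluated by interpolation (zero beyond the grid); G and C
    follow algebraically, with k_r C(x) = cR U(x) as an identity.
    """
    qc = qc_constants(T0, R0, params)
    grid = U.grid
    x = grid.x
    g_here = qc.g(x, params)
    U_adv = np.interp(x + params.mu, x, U.pdf, left=0.0, right=0.0)
    g_adv = qc.g(x + params.mu, params)
    B = ((g_here + params.k_on * T0) * U.pdf - g_adv * U_adv) / params.k_off
    denom = params.k_u * (params.k_d + params.k_r) + params.k_r * params.k_s * R0
    G = params.k_f * (params.k_d + params.k_r) * U.pdf / denom
    C = params.k_s * R0 * G / (params.k_d + params.k_r)
    return StateDensities(grid=grid, U=U.pdf.copy(), B=B, G=G, C=C)


def exit_density_closed(U: LengthDistribution, T0: float, R0: float,
                        params: ParameterSet) -> LengthDistribution:
    """Normalised exit length density p_hat(x) ~ (k_c(x) + cR) U(x).

    Uses the identity k_r C = cR U, so p_hat = g U / integral(g U).
    """
    qc = qc_constants(T0, R0, params)
    weighted = qc.g(U.x, params) * U.pdf
    total = U.grid.integrate(weighted)
    if total <= 0:
        raise ValueError("exit flux integral is zero")
    return LengthDistribution(U.grid, weighted / total)


def exit_moments(p_hat: LengthDistribution) -> tuple[float, float, float]:
    """(mean, SD, skewness) of an exit density by grid quadrature."""
    return p_hat.mean(), p_hat.sd(), p_hat.skewness()


@dataclass(frozen=True)
class FeasibilityBounds:
    """Bounds on T0 (at given R0) and on R0 (at given T0) for homeostasis.

    ``T_min < T_tilde_min < T_max``; the window of steady states is
    T_tilde_min < T0 < T_max.  ``R_min``/``R_max`` are populated when the
    bounds are requested for a given T0; R_max is +inf when T0 >= T_inf_min
    (enough telomerase to outpace any drug dose) and R_min is clamped at 0.
    T_inf_min/T_inf_max are the R0 -> infinity limits, evaluated
    analytically.
    """

    T_min: float
    T_tilde_min: float
    T_max: float
    T_inf_min: float
    T_inf_max: float
    R_min: float | None = None
    R_max: float | None = None

    def integer_T_range(self) -> tuple[int, int]:
        """Smallest and largest integer molecule counts inside the window."""
        return math.ceil(self.T_tilde_min), math.floor(self.T_max)


def feasibility_bounds(params: ParameterSet, R0: float | None = None,
                       T0: float | None = None) -> FeasibilityBounds:
    """Feasibility bounds of the closed model.

    With ``R0`` given (molecules), returns the telomerase window
    (T_min, T_tilde_min, T_max).  With ``T0`` also (or only) given, fills in
    the drug window (R_min, R_max) in molecules.  The R0 -> infinity limits
    T_inf_min = mu k_off k_f/(rho k_on) and
    T_inf_max = mu k_off (delta + k_f)/(rho k_on) are always reported.
    """
    pr = params
    scale = pr.mu * pr.k_off / (pr.k_on * pr.rho)  # molecules per unit rate
    T_inf_min = scale * pr.k_f
    T_inf_max = scale * (pr.delta + pr.k_f)

    if R0 is None and T0 is None:
        R0 = 0.0
    T_min = T_tilde_min = T_max = math.nan
    if R0 is not None:
        cR = drug_locking_rate(R0, pr)
        T_min = scale * cR
        T_tilde_min = T_min + scale * pr.delta / (1.0 + math.exp(pr.alpha / pr.beta))
        T_max = scale * (pr.delta + cR)

    R_min = R_max = None
    if T0 is not None:
        kt = pr.k_on * pr.rho * T0
        mk = pr.mu * pr.k_off
        if kt >= mk * (pr.k_f + pr.delta):  # T0 >= T_inf_max / scale ... no steady state
            R_min = math.inf
            R_max = math.inf
        else:
            num = pr.k_u * (kt - mk * pr.delta) * (pr.k_d + pr.k_r)
            den = pr.k_s * pr.k_r * (mk * (pr.k_f + pr.delta) - kt)
            R_min = max(0.0, num / den)
            if mk * pr.k_f > kt:  # T0 < T_inf_min: drug can always kill homeostasis
                R_max = (kt * pr.k_u * (pr.k_d + pr.k_r)
                         / (pr.k_s * pr.k_r * (mk * pr.k_f - kt)))
            else:
                R_max = math.inf

    return FeasibilityBounds(T_min=T_min, T_tilde_min=T_tilde_min, T_max=T_max,
                             T_inf_min=T_inf_min, T_inf_max=T_inf_max,
                             R_min=R_min, R_max=R_max)


def classify(T0: float, R0: float, params: ParameterSet) -> str:
    """Classify a (T0, R0 molecules) cell: 'steady', 'erosion' or 'unbounded'."""
    b = feasibility_bounds(params, R0=R0)
    if T0 <= b.T_tilde_min:
        return "erosion"
    if T0 >= b.T_max:
        return "unbounded"
    return "steady"


def feasibility_region(params: ParameterSet, T0_values, R0_values,
                       ) -> np.ndarray:
    """Classification grid over T0 (rows) and R0 (columns, molecules)."""
    T0_values = np.asarray(T0_values, dtype=float)
    R0_values = np.asarray(R0_values, dtype=float)
    out = np.empty((T0_values.size, R0_values.size), dtype=object)
    for j, r in enumerate(R0_values):
        b = feasibility_bounds(params, R0=float(r))
        for i, t in enumerate(T0_values):
            if t <= b.T_tilde_min:
                out[i, j] = "erosion"
            elif t >= b.T_max:
                out[i, j] = "unbounded"
            else:
                out[i, j] = "steady"
    return out


def mean_length_surface(params: ParameterSet, T0_values, R0_values,
                        grid: LengthGrid | None = None,
                        adaptive: bool = True) -> np.ndarray:
    """Mean exit length L_hat(T0, R0) over a parameter sweep.

    Infeasible cells yield NaN (the sweep completes rather than raising).
    R0 values are molecule counts.
    """
    if grid is None:
        grid = LengthGrid.default_closed()
    T0_values = np.asarray(T0_values, dtype=float)
    R0_values = np.asarray(R0_values, dtype=float)
    out = np.full((T0_values.size, R0_values.size), np.nan)
    for i, t in enumerate(T0_values):
        for j, r in enumerate(R0_values):
            if classify(float(t), float(r), params) != "steady":
                continue
            mean, _, _ = closed_exit_moments(float(t), float(r), params,
                                             grid=grid, adaptive=adaptive)
            out[i, j] = mean
    return out


def closed_exit_moments(T0: float, R0: float, params: ParameterSet,
                        grid: LengthGrid | None = None,
                        adaptive: bool = True,
                        rtol: float = 1e-3) -> tuple[float, float, float]:
    """(mean, SD, skewness) of the closed-model exit density.

    With ``adaptive`` the right edge of the grid is doubled until the mean
    and SD change by less than ``rtol``, so slowly-decaying near-critical
    tails are fully captured rather than silently truncated.
    """
    if grid is None:
        grid = LengthGrid.default_closed()
    moments = _moments_on(grid, T0, R0, params)
    if not adaptive:
        return moments
    while True:
        wider = LengthGrid(grid.x_min, grid.x_min + 2 * (grid.x_max - grid.x_min),
                           grid.dx)
        new = _moments_on(wider, T0, R0, params)
        if (abs(new[0] - moments[0]) <= rtol * abs(moments[0])
                and abs(new[1] - moments[1]) <= rtol * abs(moments[1])):
            return new
        grid, moments = wider, new
        if grid.x_max > 5e6:
            raise InfeasibleRegimeError(
                "exit moments did not converge under domain doubling; "
                "the regime is effectively non-normalisable")


def _moments_on(grid: LengthGrid, T0: float, R0: float,
                params: ParameterSet) -> tuple[float, float, float]:
    U = steady_U(grid, T0, R0, params)
    return exit_moments(exit_density_closed(U, T0, R0, params))


def delay_steady_state(grid: LengthGrid, T0: float, R0: float,
                       params: ParameterSet) -> LengthDistribution:
    """Discretised *exact* delay-equation steady state (oracle for steady_U).

    Builds the advance-delay equation
        (rho/k_off)[(g + k_on T0) U'](x) - (rho/k_off) g(x+mu) U'(x+mu)
        + [g + (rho/k_off) g'] U(x) - [g + (rho/k_off) g'](x + mu) U(x + mu) = 0
    on the grid with central differences and an interpolated mu-advance
    (U = 0 beyond the right edge), and solves the near-singular linear
    system under the normalisation integral(U) = 1 by least squares.
    """
    pr = params
    x = grid.x
    n = grid.n
    dx = grid.dx
    cR = drug_locking_rate(R0, pr)
    g = capping_rate(x, pr) + cR
    # analytic derivative of the sigmoid
    s = 1.0 / (1.0 + np.exp((pr.alpha - x) / pr.beta))
    g_prime = pr.delta * s * (1.0 - s) / pr.beta
    r = pr.rho / pr.k_off

    # first-derivative matrix (central inside, one-sided at the edges)
    D1 = np.zeros((n, n))
    for i in range(1, n - 1):
        D1[i, i - 1] = -0.5 / dx
        D1[i, i + 1] = 0.5 / dx
    D1[0, 0], D1[0, 1] = -1.0 / dx, 1.0 / dx
    D1[-1, -2], D1[-1, -1] = -1.0 / dx, 1.0 / dx

    # advance operator S: (S U)(x) = U(x + mu), linear interpolation
    S = np.zeros((n, n))
    pos = (x + pr.mu - grid.x_min) / dx
    for i in range(n):
        j = int(math.floor(pos[i]))
        w = pos[i] - j
        if j < n:
            S[i, j] = 1.0 - w
        if j + 1 < n:
            S[i, j + 1] = w
    g_adv = capping_rate(x + pr.mu, pr) + cR
    s_adv = 1.0 / (1.0 + np.exp((pr.alpha - x - pr.mu) / pr.beta))
    g_prime_adv = pr.delta * s_adv * (1.0 - s_adv) / pr.beta

    A = (r * np.diag(g + pr.k_on * T0) @ D1
         - r * np.diag(g_adv) @ S @ D1
         + np.diag(g + r * g_prime)
         - np.diag(g_adv + r * g_prime_adv) @ S)

    # weight rows uniformly, then append the normalisation constraint
    w_quad = np.full(n, dx)
    w_quad[[0, -1]] = dx / 2.0
    scale = np.abs(A).max()
    rows = np.vstack([A / scale, w_quad])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    U, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
    return LengthDistribution(grid, np.maximum(U, 0.0), normalize=True)
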