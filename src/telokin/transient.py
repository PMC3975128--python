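"""Time-dependent method-of-lines solver for the open and closed systems.

The four state densities evolve under the reaction kinetics plus advection
of the bound state toward larger x at speed rho.  Advection is discretised
first-order upwind (transport is rightward, so upwind = backward
difference); time stepping is explicit with automatic sub-stepping so that
both the CFL number rho dt/dx and the fastest reaction rate times dt stay
below safe limits.  Free telomerase T(t) and free drug R(t) are eliminated
algebraically through the conservation laws

    T(t) = T0 - integral B dx,   R(t) = R0 - integral C dx,

which holds them exact to quadrature accuracy rather than letting ODE drift
accumulate.

The solver is a validation instrument for the steady-state modules: run
long enough, the open system converges to the per-replication steady state
and the closed system (which recycles every exiting telomere mu bp shorter)
converges to the quasicontinuum steady profile when (T0, R0) is feasible.

The steady-state theory never needs these equations integrated in time; the
initial-condition conventions here (open system starts empty; closed system
starts from a supplied U profile) are this package's own choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import LengthDistribution, LengthGrid, StateDensities
from .kernels import capping_rate
from .params import ParameterSet

__all__ = ["TransientState", "simulate_open", "simulate_closed"]

#: safety factor applied to both the CFL and reaction stability limits
_SAFETY = 0.5


@dataclass
class TransientState:
    """Snapshot of the system at time t (seconds)."""

    t: float
    states: StateDensities
    T_free: float
    R_free: float

    def total_telomeres(self) -> float:
        return sum(self.states.totals().values())

    def mean_length_U(self) -> float:
        g = self.states.grid
        tot = g.integrate(self.states.U)
        return g.integrate(g.x * self.states.U) / tot if tot > 0 else np.nan


def _stable_dt(grid: LengthGrid, T0: float, R0: float,
               params: ParameterSet) -> float:
    # worst-case loss rates per state; free T, R can never exceed T0, R0
    rate_U = params.delta + params.k_on * T0 + params.k_f
    rate_B = params.k_off
    rate_G = params.k_u + params.k_s * R0
    rate_C = params.k_d + params.k_r
    rate_in = params.k_e
    max_rate = max(rate_U, rate_B, rate_G, rate_C, rate_in)
    dt_cfl = grid.dx / params.rho
    return _SAFETY * min(dt_cfl, 1.0 / max_rate)


def _advect_upwind(B: np.ndarray, dx: float) -> np.ndarray:
    """Backward-difference d/dx for rightward transport; inflow B=0 at left."""
    dB = np.empty_like(B)
    dB[0] = B[0] / dx
    dB[1:] = (B[1:] - B[:-1]) / dx
    return dB


def _simulate(p_or_none, U0, T0: float, R0: float, params: ParameterSet,
              grid: LengthGrid, t_end: float, dt_out: float,
              closed: bool) -> list[TransientState]:
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if dt_out <= 0:
        raise ValueError("dt_out must be > 0")
    pr = params
    x = grid.x
    dx = grid.dx
    kc = capping_rate(x, pr)
    if closed:
        kc_adv = capping_rate(x + pr.mu, pr)
        # index/weight for linear interpolation of the advanced densities
        pos = (x + pr.mu - grid.x_min) / dx
        j = np.floor(pos).astype(int)
        w = pos - j
        valid0 = j < grid.n
        valid1 = j + 1 < grid.n
        j0 = np.clip(j, 0, grid.n - 1)
        j1 = np.clip(j + 1, 0, grid.n - 1)

        def advance(arr):
            return (np.where(valid0, arr[j0], 0.0) * (1.0 - w)
                    + np.where(valid1, arr[j1], 0.0) * w)

    if U0 is None:
        U = np.zeros(grid.n)
    else:
        U = np.array(U0, dtype=float)
    B = np.zeros(grid.n)
    G = np.zeros(grid.n)
    C = np.zeros(grid.n)

    dt = _stable_dt(grid, T0, R0, pr)
    out: list[TransientState] = []
    t = 0.0

    def record():
        T_free = T0 - grid.integrate(B)
        R_free = R0 - grid.integrate(C)
        out.append(TransientState(
            t=t,
            states=StateDensities(grid=grid, U=U.copy(), B=B.copy(),
                                  G=G.copy(), C=C.copy()),
            T_free=T_free, R_free=R_free))

    record()
    next_out = dt_out
    while t < t_end - 1e-9:
        step = min(dt, t_end - t, next_out - t)
        T_free = max(T0 - grid.integrate(B), 0.0)
        R_free = max(R0 - grid.integrate(C), 0.0)
        if closed:
            influx = kc_adv * advance(U) + pr.k_r * advance(C)
        else:
            influx = pr.k_e * p_or_none
        dU = (influx + pr.k_off * B + pr.k_u * G
              - (kc + pr.k_on * T_free + pr.k_f) * U)
        dB = (pr.k_on * T_free * U - pr.k_off * B
              - pr.rho * _advect_upwind(B, dx))
        dG = pr.k_f * U + pr.k_d * C - (pr.k_u + pr.k_s * R_free) * G
        dC = pr.k_s * R_free * G - (pr.k_d + pr.k_r) * C
        U += step * dU
        B += step * dB
        G += step * dG
        C += step * dC
        t += step
        if t >= next_out - 1e-9:
            record()
            next_out += dt_out
    if out[-1].t < t_end - 1e-9:
        record()
    return out


def simulate_open(p_in: LengthDistribution, T0: float, R0: float,
                  params: ParameterSet, grid: LengthGrid | None = None,
                  t_end: float = 2e5, dt_out: float = 2e4,
                  ) -> list[TransientState]:
    """Integrate the open system from an empty initial state.

    Telomeres flow in at rate k_e with length density ``p_in``; snapshots
    are recorded every ``dt_out`` seconds (plus t = 0 and t = t_end).
    """
    if grid is None:
        grid = p_in.grid
    return _simulate(p_in.pdf, None, T0, R0, params, grid, t_end, dt_out,
                     closed=False)


def simulate_closed(U_init: LengthDistribution, T0: float, R0: float,
                    params: ParameterSet, grid: LengthGrid | None = None,
                    t_end: float = 2e6, dt_out: float = 2e5,
                    ) -> list[TransientState]:
    """Integrate the closed (recycling) system from an initial open density.

    Every telomere leaving by capping or drug locking re-enters mu bp
    shorter in the open state; the total telomere number is conserved up to
    the (small) advance mass falling outside the grid.
    """
    if grid is None:
        grid = U_init.grid
    return _simulate(None, U_init.pdf, T0, R0, params, grid, t_end, dt_out,
                     closed=True)
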