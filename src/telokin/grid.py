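"""Discretised telomere-length axis and densities living on it.

Telomere length x (bp) is treated as a continuous variable; everything in
this module is plumbing for representing number densities and probability
densities on a uniform grid.  Negative lengths are deliberately in-domain:
the models produce (small) mass at x < 0, interpreted as telomeres that have
lost all functional repeats, and that mass is reported as a diagnostic
rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LengthGrid", "LengthDistribution", "StateDensities"]


@dataclass(frozen=True)
class LengthGrid:
    """Uniform grid over telomere length (bp)."""

    x_min: float = -2000.0
    x_max: float = 30000.0
    dx: float = 5.0

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise ValueError("dx must be > 0")
        if not self.x_min < self.x_max:
            raise ValueError("x_min must be < x_max")
        n_cells = (self.x_max - self.x_min) / self.dx
        if abs(n_cells - round(n_cells)) > 1e-9:
            raise ValueError("(x_max - x_min) must be an integral multiple of dx")

    @property
    def n(self) -> int:
        return round((self.x_max - self.x_min) / self.dx) + 1

    @property
    def x(self) -> np.ndarray:
        return self.x_min + self.dx * np.arange(self.n)

    def integrate(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values, dx=self.dx))

    @classmethod
    def default_open(cls) -> "LengthGrid":
        """Default axis for per-replication (open-model) solves."""
        return cls(-2000.0, 30000.0, 5.0)

    @classmethod
    def default_closed(cls) -> "LengthGrid":
        """Default axis for long-run (closed-model) moments; wider right tail."""
        return cls(-2000.0, 60000.0, 5.0)


class LengthDistribution:
    """A probability density over telomere length on a :class:`LengthGrid`."""

    def __init__(self, grid: LengthGrid, pdf: np.ndarray, normalize: bool = False):
        pdf = np.asarray(pdf, dtype=float)
        if pdf.shape != (grid.n,):
            raise ValueError(f"pdf shape {pdf.shape} does not match grid ({grid.n},)")
        if not np.all(np.isfinite(pdf)):
            raise ValueError("pdf contains non-finite values")
        if normalize:
            total = grid.integrate(pdf)
            if total <= 0:
                raise ValueError("cannot normalise a density with non-positive mass")
            pdf = pdf / total
        self.grid = grid
        self.pdf = pdf

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    def total_mass(self) -> float:
        return self.grid.integrate(self.pdf)

    def mean(self) -> float:
        return self.grid.integrate(self.x * self.pdf) / self.total_mass()

    def var(self) -> float:
        m = self.mean()
        return self.grid.integrate((self.x - m) ** 2 * self.pdf) / self.total_mass()

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def skewness(self) -> float:
        """Standardised third central moment."""
        m, s = self.mean(), self.sd()
        third = self.grid.integrate((self.x - m) ** 3 * self.pdf) / self.total_mass()
        return third / s**3

    def negative_length_mass(self) -> float:
        """Probability mass at x < 0 (diagnostic for non-functional telomeres)."""
        mask = self.x < 0
        if not mask.any():
            return 0.0
        return float(np.trapezoid(np.where(self.x <= 0, self.pdf, 0.0), self.x))

    def shifted(self, shift: float) -> "LengthDistribution":
        """Evaluate p(x + shift) on the same grid by linear interpolation.

        Mass transported past either grid edge is dropped (the caller is
        responsible for checking :meth:`total_mass` afterwards).
        """
        pdf = np.interp(self.x + shift, self.x, self.pdf, left=0.0, right=0.0)
        return LengthDistribution(self.grid, pdf)


@dataclass
class StateDensities:
    """Per-length number densities of the four telomere states.

    U: open (uncapped, unfolded); B: telomerase-bound; G: G-quadruplex;
    C: drug-locked complex.  Units: telomeres per bp.
    """

    grid: LengthGrid
    U: np.ndarray
    B: np.ndarray
    G: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        for name in ("U", "B", "G", "C"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.grid.n,):
                raise ValueError(f"{name} shape does not match grid")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    def totals(self) -> dict[str, float]:
        return {name: self.grid.integrate(getattr(self, name))
                for name in ("U", "B", "G", "C")}

    def min_density(self) -> float:
        """Most negative value across all states (solver-quality diagnostic)."""
        return float(min(arr.min() for arr in (self.U, self.B, self.G, self.C)))
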