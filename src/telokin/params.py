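"""Model parameters, validation, and concentration/molecule-count conversion.

All kinetic rates are per second; lengths are in basepairs (bp), which for
single-stranded overhang synthesis we use interchangeably with nucleotides
(nt).  Telomerase and drug amounts are carried internally as molecule counts
per nucleus (real-valued -- the model equations are continuum ODEs); the
conversion to and from nanomolar concentrations uses the HeLa nuclear
volume.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ParameterSet",
    "default_parameters",
    "nM_to_molecules",
    "molecules_to_nM",
    "load_parameters",
    "save_parameters",
]

#: Relative tolerance for the k_d == k_s / K detailed-balance consistency check.
_KD_CONSISTENCY_RTOL = 1e-2


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic and shape constants of the telomere-state model.

    Attributes
    ----------
    k_on
        Telomerase binding rate (s^-1 per free molecule).
    k_off
        Telomerase dissociation rate (s^-1).
    rho
        Nucleotide addition (processivity) rate of bound telomerase (nt s^-1).
        This is the advection speed of the bound state in length space.
    k_f, k_u
        G-quadruplex folding and unfolding rates (s^-1).
    K
        RHPS4 equilibrium binding constant (dimensionless); k_d = k_s / K.
    k_s, k_d
        RHPS4 binding (s^-1 per free molecule) and dissociation (s^-1) rates.
    k_e
        Telomere influx rate into the open pool (s^-1).
    k_r
        Rate at which drug-locked complexes leave the cycling pool (s^-1).
    delta
        Maximum t-loop formation rate (s^-1); plateau of the sigmoid k_c(x).
    alpha, beta
        Midpoint (bp) and width (bp) of the sigmoidal capping rate.
    mu
        Telomere loss per replication from the end-replication problem and
        post-replicative processing (bp).
    L0, sigma0
        Mean and SD (bp) of the HeLa telomere length distribution used as the
        reference input.
    N_A, V_n
        Avogadro constant (mol^-1) and HeLa nuclear volume (l); these fix the
        nM <-> molecules-per-nucleus bridge.
    """

    k_on: float = 2.6e-7
    k_off: float = 2.2e-4
    rho: float = 6.287e-2
    k_f: float = 1.6e-2
    k_u: float = 3.8e-3
    K: float = 1.4e-5
    k_s: float = 1e-7
    k_d: float = 7.1e-3
    k_e: float = 1.5e-2
    k_r: float = 5e-6
    delta: float = 5e-5
    alpha: float = 1775.0
    beta: float = 300.0
    mu: float = 45.0
    L0: float = 3440.0
    sigma0: float = 800.0
    N_A: float = 6.022e23
    V_n: float = 6.9e-13

    def __post_init__(self) -> None:
        rates = {
            "k_on": self.k_on, "k_off": self.k_off, "rho": self.rho,
            "k_f": self.k_f, "k_u": self.k_u, "K": self.K,
            "k_s": self.k_s, "k_d": self.k_d, "k_e": self.k_e,
            "k_r": self.k_r, "delta": self.delta,
        }
        for name, value in rates.items():
            if not value >= 0.0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        for name in ("alpha", "beta", "mu", "sigma0", "L0", "N_A", "V_n"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        if self.K > 0 and self.k_d > 0:
            rel = abs(self.k_d - self.k_s / self.K) / self.k_d
            if rel > _KD_CONSISTENCY_RTOL:
                warnings.warn(
                    f"k_d={self.k_d:g} deviates from k_s/K={self.k_s / self.K:g} "
                    f"by {rel:.1%}; the equilibrium constant K will be ignored "
                    "in favour of the explicit rates",
                    stacklevel=3,
                )

    @classmethod
    def from_K(cls, **kwargs) -> "ParameterSet":
        """Construct with the drug dissociation rate derived as k_d = k_s / K."""
        base = cls(**{k: v for k, v in kwargs.items() if k != "k_d"})
        return dataclasses.replace(base, k_d=base.k_s / base.K)

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_parameters() -> ParameterSet:
    """Reference parameter set for telomerase-positive HeLa cells."""
    return ParameterSet()


def nM_to_molecules(conc_nM: float, params: ParameterSet | None = None) -> float:
    """Convert a nanomolar nuclear concentration to molecules per nucleus.

    1 nM corresponds to 1e-9 * N_A * V_n ~= 415 molecules in a HeLa nucleus.
    """
    if params is None:
        params = default_parameters()
    if conc_nM < 0:
        raise ValueError(f"concentration must be >= 0 nM, got {conc_nM!r}")
    return conc_nM * 1e-9 * params.N_A * params.V_n


def molecules_to_nM(count: float, params: ParameterSet | None = None) -> float:
    """Inverse of :func:`nM_to_molecules`."""
    if params is None:
        params = default_parameters()
    if count < 0:
        raise ValueError(f"molecule count must be >= 0, got {count!r}")
    return count / (1e-9 * params.N_A * params.V_n)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}


def _from_mapping(data: dict) -> ParameterSet:
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(
            f"unknown parameter name(s): {sorted(unknown)}; "
            f"expected a subset of {sorted(_FIELD_NAMES)}"
        )
    return ParameterSet(**{k: float(v) for k, v in data.items()})


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a ParameterSet from JSON or flat ``key: value`` text.

    The format is sniffed: files whose first non-blank character is ``{`` are
    parsed as a JSON object; anything else is parsed one ``key: value`` (or
    ``key = value``) pair per line, with ``#`` comments allowed.  Unknown keys
    are an error so typos do not silently fall back to defaults.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _from_mapping(json.loads(text))
    data: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        data[key.strip()] = value.strip()
    return _from_mapping(data)


def save_parameters(params: ParameterSet, path: str | Path, fmt: str = "json") -> None:
    """Write a ParameterSet as JSON (default) or flat key:value text."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(params.to_dict(), indent=2) + "\n")
    elif fmt == "text":
        lines = [f"{k}: {v!r}" for k, v in params.to_dict().items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"fmt must be 'json' or 'text', got {fmt!r}")
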