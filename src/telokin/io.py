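"""Tab-separated and JSON writers/readers for model outputs.

All outputs are plain text: TSV with a header row and '.' decimals, and
JSON sidecars carrying the fully resolved configuration so any run can be
reproduced from its outputs alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grid import LengthDistribution, LengthGrid, StateDensities

__all__ = [
    "write_states_tsv",
    "read_states_tsv",
    "write_summary_json",
    "write_generation_trace_tsv",
    "write_table_tsv",
]

_FLOAT_FMT = "%.17g"  # repr-level round trip


def _write_tsv(path: str | Path, header: list[str], columns: list[np.ndarray]) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, fmt=_FLOAT_FMT, delimiter="\t",
               header="\t".join(header), comments="")


def write_states_tsv(path: str | Path, states: StateDensities,
                     p_exit: LengthDistribution | None = None) -> None:
    """Write per-length state densities (and optionally the exit density)."""
    header = ["x", "U", "B", "G", "C"]
    cols = [states.x, states.U, states.B, states.G, states.C]
    if p_exit is not None:
        header.append("p_exit")
        cols.append(p_exit.pdf)
    _write_tsv(path, header, cols)


def read_states_tsv(path: str | Path) -> StateDensities:
    """Round-trip reader for :func:`write_states_tsv` output."""
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    x = data[:, 0]
    dx = x[1] - x[0]
    grid = LengthGrid(float(x[0]), float(x[-1]), float(round(dx, 12)))
    return StateDensities(grid=grid, U=data[:, 1], B=data[:, 2],
                          G=data[:, 3], C=data[:, 4])


def write_summary_json(path: str | Path, summary: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default,
                                     allow_nan=True) + "\n")


def write_generation_trace_tsv(path: str | Path, trace) -> None:
    """Per-generation mean and SD table for a GenerationTrace."""
    gens = np.arange(len(trace.means))
    _write_tsv(path, ["generation", "mean", "sd"],
               [gens, np.asarray(trace.means), np.asarray(trace.sds)])


def write_table_tsv(path: str | Path, header: list[str], rows: list[list]) -> None:
    """Generic small-table writer (mixed str/float cells)."""
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(
            c if isinstance(c, str) else (_FLOAT_FMT % c) for c in row))
    Path(path).write_text("\n".join(lines) + "\n")
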