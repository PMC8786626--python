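"""One- and two-parameter bifurcation scans with limit-cycle envelopes.

Every grid point is an independent 1000 h solve from the same canonical
initial condition (no continuation or warm-starting, so multistability is
never masked); the per-output minimum and maximum over the trailing 200 h
distinguish steady states (min = max) from limit cycles (min < max), and
the dynamical classification of each point is recorded alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import build_network
from .parameters import ParameterSet
from .simulate import TRACKED_OUTPUTS, SimulationError, solve

__all__ = ["BifurcationDiagram", "sweep_1d", "sweep_2d"]

log = logging.getLogger(__name__)


@dataclass
class BifurcationDiagram:
    """Envelope surfaces over a 1D or 2D parameter grid.

    ``table`` is long-format with columns (x, [y,] output, env_min, env_max,
    classification); failed grid points carry NaN envelopes.
    """

    axes: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    outputs: tuple[str, ...]
    table: pd.DataFrame
    t_end: float
    window: float
    failures: list[dict] = field(default_factory=list)

    def envelope(self, output: str) -> pd.DataFrame:
        """Wide (grid-indexed) min/max frame for one output."""
        sub = self.table[self.table["output"] == output]
        if len(self.axes) == 1:
            return sub.set_index("x")[["env_min", "env_max", "classification"]]
        return sub.set_index(["x", "y"])[["env_min", "env_max", "classification"]]

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.table.to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {
                "axes": list(self.axes),
                "grids": [list(map(float, g)) for g in self.grids],
                "outputs": list(self.outputs),
                "t_end_h": self.t_end,
                "window_h": self.window,
                "n_failures": len(self.failures),
            }
            Path(meta_path).write_text(json.dumps(meta, indent=1))


def _solve_point(params: ParameterSet, outputs, t_end, window, solve_kw):
    res = solve(params, t_end=t_end, window=window, **solve_kw)
    rows = []
    for out in outputs:
        lo, hi = res.envelope.get(out, (np.nan, np.nan))
        if out not in res.envelope:
            m = res.trailing_mask()
            lo, hi = float(res[out][m].min()), float(res[out][m].max())
        rows.append((out, lo, hi, res.classification))
    return rows


def _set(params: ParameterSet, name: str, value: float) -> ParameterSet:
    return params.replace(**{name: value})


def sweep_1d(
    param_name: str,
    values: Sequence[float],
    params: ParameterSet,
    outputs: Sequence[str] = ("pmTORC1", "pmTORC2"),
    *,
    t_end: float = 1000.0,
    window: float = 200.0,
    **solve_kw,
) -> BifurcationDiagram:
    """Sweep one parameter; each point is solved independently.

    Failed points are recorded with NaN envelopes and the sweep continues.
    The diagram is identical regardless of the order of ``values``.
    """
    grid = np.sort(np.asarray(values, dtype=float))
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("values must be a non-empty 1D sequence")
    rows, failures = [], []
    for v in grid:
        try:
            for out, lo, hi, cls in _solve_point(
                    _set(params, param_name, v), outputs, t_end, window, solve_kw):
                rows.append((v, out, lo, hi, cls))
        except SimulationError as exc:
            log.warning("sweep point %s=%g failed: %s", param_name, v, exc)
            failures.append({"x": float(v), "error": str(exc)})
            for out in outputs:
                rows.append((v, out, np.nan, np.nan, "failed"))
    table = pd.DataFrame(rows, columns=["x", "output", "env_min", "env_max", "classification"])
    return BifurcationDiagram(
        axes=(param_name,), grids=(grid,), outputs=tuple(outputs),
        table=table, t_end=t_end, window=window, failures=failures,
    )


def sweep_2d(
    xname: str,
    xvalues: Sequence[float],
    yname: str,
    yvalues: Sequence[float],
    params: ParameterSet,
    outputs: Sequence[str] = ("pmTORC1", "pmTORC2"),
    *,
    t_end: float = 1000.0,
    window: float = 200.0,
    **solve_kw,
) -> BifurcationDiagram:
    """Full-mesh 2D scan; row/column slices agree bit-for-bit with sweep_1d.

    Desk-scale meshes (tens per axis) are the default use; the mesh size is
    whatever ``xvalues``/``yvalues`` specify.
    """
    xg = np.sort(np.asarray(xvalues, dtype=float))
    yg = np.sort(np.asarray(yvalues, dtype=float))
    if len(xg) < 1 or len(yg) < 1:
        raise ValueError("mesh axes must be non-empty")
    rows, failures = [], []
    for xv in xg:
        for yv in yg:
            p = _set(_set(params, xname, xv), yname, yv)
            try:
                for out, lo, hi, cls in _solve_point(p, outputs, t_end, window, solve_kw):
                    rows.append((xv, yv, out, lo, hi, cls))
            except SimulationError as exc:
                log.warning("mesh point (%g, %g) failed: %s", xv, yv, exc)
                failures.append({"x": float(xv), "y": float(yv), "error": str(exc)})
                for out in outputs:
                    rows.append((xv, yv, out, np.nan, np.nan, "failed"))
    table = pd.DataFrame(
        rows, columns=["x", "y", "output", "env_min", "env_max", "classification"])
    return BifurcationDiagram(
        axes=(xname, yname), grids=(xg, yg), outputs=tuple(outputs),
        table=table, t_end=t_end, window=window, failures=failures,
    )
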