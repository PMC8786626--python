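"""Local and global sensitivity analysis of steady-state outputs.

Local analysis perturbs each kinetic constant by a small fraction (default
0.5%) and reports the normalized derivative

    L[p, S] = (p0 / S(p0)) * (S(p0 + dp) - S(p0)) / dp ,

a dimensionless elasticity of the steady output S with respect to the
parameter p.

Global analysis draws parameter sets from the physiological box by Latin
hypercube sampling (one draw per equal-probability bin per parameter,
log-uniform within each kind's range), evaluates the steady-state (or
cycle-averaged) outputs for every draw, and summarizes each
parameter-output dependence by the partial rank correlation coefficient
(PRCC): the Pearson correlation of rank residuals after regressing out the
ranks of all other parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .network import SPECIES, build_network
from .parameters import KIND_RANGES, PARAM_KINDS, ParameterSet
from .simulate import SimulationError, steady_state

__all__ = [
    "OUTPUTS",
    "SensitivityReport",
    "local_sensitivity",
    "lhs_sample",
    "global_outputs",
    "prcc",
    "bootstrap_prcc",
    "sample_parallel_coordinates",
]

log = logging.getLogger(__name__)

#: activated forms reported by both analyses
OUTPUTS: tuple[str, ...] = (
    "IRSa", "pAKT", "pAMPK", "pULK1", "SIRT1a", "pmTORC1", "pmTORC2",
)

#: the seven mTORC/DEPTOR species of the parallel-coordinate view
MTORC_DEPTOR_SPECIES: tuple[str, ...] = (
    "mTORC1", "pmTORC1", "pmTORC1_DEPTOR",
    "mTORC2", "pmTORC2", "pmTORC2_DEPTOR", "pDEPTOR",
)


@dataclass
class SensitivityReport:
    """Container for local and/or global sensitivity results."""

    outputs: tuple[str, ...]
    parameters: tuple[str, ...]
    local: pd.DataFrame | None = None          # parameters x outputs
    prcc: pd.DataFrame | None = None           # parameters x outputs
    prcc_ci: pd.DataFrame | None = None        # long form: parameter, output, lo, hi
    n_samples: int = 0
    seed: int | None = None
    samples: pd.DataFrame | None = None        # draws + outputs, row-aligned

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long table (parameter, output, prcc, ci_lo, ci_hi)."""
        if self.prcc is None:
            raise ValueError("no global results in this report")
        rows = self.prcc.stack().rename("prcc").reset_index()
        rows.columns = ["parameter", "output", "prcc"]
        if self.prcc_ci is not None:
            rows = rows.merge(self.prcc_ci, on=["parameter", "output"], how="left")
        return rows


# ---------------------------------------------------------------------------
# local
# ---------------------------------------------------------------------------

def normalized_sensitivity(f, p0: float, delta_frac: float = 0.005):
    """Normalized forward-difference derivative (p0/S)(dS/dp) of ``f`` at p0.

    ``f`` maps a parameter value to a steady output (scalar or array).  For
    the linear relaxation system dS/dt = p - S the steady state is S = p and
    this quantity is exactly 1.
    """
    s0 = np.asarray(f(p0), dtype=float)
    dp = delta_frac * p0
    s1 = np.asarray(f(p0 + dp), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (p0 / s0) * (s1 - s0) / dp


def local_sensitivity(
    params: ParameterSet,
    outputs: Sequence[str] = OUTPUTS,
    delta_frac: float = 0.005,
    *,
    parameters: Sequence[str] | None = None,
    t_relax: float = 1000.0,
) -> pd.DataFrame:
    """Normalized forward-difference sensitivities at the baseline steady state.

    One forward difference per parameter (perturbation ``delta_frac * p0``,
    default 0.5%).  Outputs with a zero baseline value yield NaN entries
    (with a warning); parameters with value 0 have exactly zero sensitivity
    and are not perturbed.
    """
    names = list(parameters) if parameters is not None else params.kinetic_names()
    base = steady_state(params, t_relax=t_relax)
    s0 = np.array([base[o] for o in outputs])
    L = np.zeros((len(names), len(outputs)))
    for i, name in enumerate(names):
        p0 = params[name]
        if p0 == 0.0:
            continue
        dp = delta_frac * p0
        pert = steady_state(params.replace(**{name: p0 + dp}), t_relax=t_relax)
        s1 = np.array([pert[o] for o in outputs])
        with np.errstate(divide="ignore", invalid="ignore"):
            L[i] = (p0 / s0) * (s1 - s0) / dp
        if np.any(s0 == 0):
            log.warning("zero steady output(s) %s: local sensitivity NaN",
                        [o for o, v in zip(outputs, s0) if v == 0])
    return pd.DataFrame(L, index=names, columns=list(outputs))


# ---------------------------------------------------------------------------
# global: LHS draws
# ---------------------------------------------------------------------------

def parameter_ranges(parameters: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Physiological sampling range per parameter, from its kind tag."""
    out = {}
    for name in parameters:
        kind = PARAM_KINDS[name]
        if kind == "total":
            raise ValueError(f"pool total {name!r} is not part of the sampling box")
        out[name] = KIND_RANGES[kind]
    return out


def lhs_sample(
    parameters: Sequence[str],
    n: int,
    seed: int,
    *,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Latin hypercube draws over the physiological box.

    Each parameter's range is divided into ``n`` equal-probability bins and
    each bin receives exactly one draw (the LHS stratification property).
    Ranges spanning several decades are sampled log-uniformly by default.
    """
    if n < 2:
        raise ValueError("need at least 2 LHS samples")
    ranges = parameter_ranges(parameters)
    sampler = qmc.LatinHypercube(d=len(parameters), seed=seed)
    u = sampler.random(n)
    cols = {}
    for j, name in enumerate(parameters):
        lo, hi = ranges[name]
        if log_scale:
            cols[name] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
        else:
            cols[name] = lo + u[:, j] * (hi - lo)
    return pd.DataFrame(cols)


def global_outputs(
    draws: pd.DataFrame,
    params: ParameterSet,
    outputs: Sequence[str] = OUTPUTS,
    *,
    t_relax: float = 400.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    progress: bool = False,
) -> pd.DataFrame:
    """Steady-state outputs for every LHS draw.

    Each draw replaces the sampled kinetic constants in ``params`` and is
    relaxed to its long-run state; oscillatory draws contribute their
    trailing-window time average.  Draws whose integration fails yield NaN
    rows (dropped, and counted, by :func:`prcc`).
    """
    rows = np.full((len(draws), len(outputs)), np.nan)
    items = draws.to_dict("records")
    for i, draw in enumerate(items):
        try:
            ss = steady_state(
                params.replace(**draw), t_relax=t_relax, rtol=rtol, atol=atol,
                residual_rtol=np.inf,
            )
            rows[i] = [ss[o] for o in outputs]
        except (SimulationError, ValueError):
            pass
        if progress and (i + 1) % 250 == 0:
            log.info("global SA: %d / %d draws", i + 1, len(draws))
    return pd.DataFrame(rows, columns=list(outputs), index=draws.index)


# ---------------------------------------------------------------------------
# global: PRCC
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def prcc(draws: pd.DataFrame, outputs_table: pd.DataFrame) -> pd.DataFrame:
    """Partial rank correlation of each parameter with each output.

    All columns are rank-transformed; for each (parameter, output) pair the
    ranks of the remaining parameters are regressed out of both, and the
    Pearson correlation of the residuals is reported.  Rows with non-finite
    outputs are dropped (logged).  Rank-deficient regressions yield NaN.
    """
    if len(draws) != len(outputs_table):
        raise ValueError("draws and outputs must be row-aligned")
    keep = np.isfinite(outputs_table.to_numpy()).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("prcc: dropping %d non-finite rows of %d", dropped, len(draws))
    X = _rank(draws.to_numpy()[keep])
    Y = _rank(outputs_table.to_numpy()[keep])
    n, p = X.shape
    out = np.full((p, Y.shape[1]), np.nan)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        q, _ = np.linalg.qr(others)
        rx = X[:, j] - q @ (q.T @ X[:, j])
        if np.linalg.norm(rx) < 1e-10 * np.sqrt(n):
            log.warning("prcc: rank-deficient regression for %s", draws.columns[j])
            continue
        ry = Y - q @ (q.T @ Y)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry, axis=0)
        with np.errstate(invalid="ignore"):
            out[j] = (rx @ ry) / denom
    return pd.DataFrame(out, index=draws.columns, columns=outputs_table.columns)


def bootstrap_prcc(
    draws: pd.DataFrame,
    outputs_table: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap confidence intervals for every PRCC entry (long form)."""
    rng = np.random.default_rng(seed)
    keep = np.isfinite(outputs_table.to_numpy()).all(axis=1)
    d = draws.loc[keep].reset_index(drop=True)
    y = outputs_table.loc[keep].reset_index(drop=True)
    stats_ = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(d), len(d))
        stats_.append(prcc(d.iloc[idx], y.iloc[idx]).to_numpy())
    arr = np.array(stats_)
    lo = np.nanquantile(arr, alpha / 2, axis=0)
    hi = np.nanquantile(arr, 1 - alpha / 2, axis=0)
    rows = []
    for i, pname in enumerate(draws.columns):
        for j, oname in enumerate(outputs_table.columns):
            rows.append((pname, oname, lo[i, j], hi[i, j]))
    return pd.DataFrame(rows, columns=["parameter", "output", "ci_lo", "ci_hi"])


def sample_parallel_coordinates(
    draws: pd.DataFrame,
    species_table: pd.DataFrame,
    n: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded subsample of the seven mTORC/DEPTOR species for plotting.

    Returns all valid rows (with a warning) when fewer than ``n`` remain.
    """
    keep = np.isfinite(species_table.to_numpy()).all(axis=1)
    tbl = species_table.loc[keep]
    if len(tbl) <= n:
        if len(tbl) < n:
            log.warning("only %d valid rows < requested %d; returning all", len(tbl), n)
        return tbl.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(tbl.index.to_numpy(), size=n, replace=False)
    return tbl.loc[np.sort(idx)].copy()


def run_global_analysis(
    params: ParameterSet,
    n: int = 5000,
    seed: int = 0,
    *,
    parameters: Sequence[str] | None = None,
    outputs: Sequence[str] = OUTPUTS,
    n_boot: int = 200,
    t_relax: float = 400.0,
    track_species: Sequence[str] = MTORC_DEPTOR_SPECIES,
) -> SensitivityReport:
    """End-to-end LHS + PRCC analysis with bootstrap CIs.

    Pool totals are excluded from the sampled box; the default sample size
    is desk-scale (n = 5000) and can be raised for production runs.
    """
    names = list(parameters) if parameters is not None else params.kinetic_names()
    draws = lhs_sample(names, n, seed)
    species_cols = tuple(dict.fromkeys((*outputs, *track_species)))
    table = global_outputs(draws, params, species_cols, t_relax=t_relax, progress=True)
    out_tbl = table[list(outputs)]
    matrix = prcc(draws, out_tbl)
    ci = bootstrap_prcc(draws, out_tbl, n_boot=n_boot, seed=seed + 1)
    return SensitivityReport(
        outputs=tuple(outputs), parameters=tuple(names),
        prcc=matrix, prcc_ci=ci, n_samples=n, seed=seed,
        samples=pd.concat([draws, table], axis=1),
    )
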