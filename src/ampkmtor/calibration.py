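"""Multi-criteria parameter calibration.

The baseline parameter set is constrained by three simultaneous criteria:

(i)   under energetic stress the model shows ~24 h oscillations of
      pmTORC1, pAMPK and pULK1 matching an observed (or synthetic)
      time course;
(ii)  when the fractional activation of AMPK is imposed over 0.1-1.0, the
      steady phosphorylated-to-unphosphorylated mTORC1 ratio follows an
      observed dose-response curve (declining overall: full AMPK
      activation suppresses the ratio relative to 10% activation);
(iii) a pharmacological AMPK activator (AICAR-like: a multiplicative
      increase of the basal AMPK activation velocity) reproduces observed
      pAMPK and pAKT levels - AKT responds because AMPK promotes mTORC2
      and mTORC2 phosphorylates AKT.

``fit`` alternates bounded minimization of the criterion-(i) loss over a
configurable set of free kinetic constants with minimization of the
criterion-(ii)+(iii) losses over {K_AMPK, K_AMPK_by_SIRT1}, until all three
losses fall below their thresholds or the round budget is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .network import IDX, SPECIES, build_network, default_initial_state
from .parameters import (
    KIND_RANGES,
    PARAM_KINDS,
    SECONDS_PER_HOUR,
    ParameterSet,
    scale_param,
    apply_intervention,
)
from .simulate import SimulationError, solve, steady_state

__all__ = [
    "CalibrationTarget",
    "ENERGETIC_STRESS_V_IR",
    "objective_timecourse",
    "objective_ampk_response",
    "objective_activator",
    "clamped_ampk_ratio",
    "ampk_activator_levels",
    "fit",
    "FitReport",
]

log = logging.getLogger(__name__)

#: insulin-receptor activation velocity of the energetic-stress scenario
#: (the sustained-oscillation regime), nM/s
ENERGETIC_STRESS_V_IR = 0.002687

#: free parameters of the criterion-(i) stage (oscillator core), by default
DEFAULT_FREE_TIMECOURSE: tuple[str, ...] = (
    "K_mTORC1_by_pAKT", "K_pmTORC1", "K_pAMPK_by_pmTORC1",
    "K_mTORC2_by_pAMPK", "V_pmTORC2",
)

#: parameters adjusted by the criterion-(ii)/(iii) stage
AMPK_STAGE_PARAMS: tuple[str, ...] = ("K_AMPK", "K_AMPK_by_SIRT1")


@dataclass(frozen=True)
class CalibrationTarget:
    """One calibration dataset.

    kind:
        ``timecourse``        observations (time_h, species, value, weight);
                              values normalized to peak = 1 per species;
        ``dose_response``     observations (activation, value, weight) with
                              the imposed fractional AMPK activation in
                              [0.1, 1] and value = pmTORC1/mTORC1 ratio;
        ``activation_level``  observations (quantity in {pAMPK, pAKT},
                              condition in {control, treated}, value,
                              weight), absolute nM.
    """

    kind: str
    observations: pd.DataFrame
    v_ir: float = ENERGETIC_STRESS_V_IR
    activation_factor: float = 4.0  # AICAR-like scaling of K_AMPK (kind iii)

    def __post_init__(self) -> None:
        if self.kind not in ("timecourse", "dose_response", "activation_level"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        obs = self.observations
        if "weight" not in obs.columns:
            obs = obs.assign(weight=1.0)
        if (obs["weight"] <= 0).any():
            raise ValueError("observation weights must be > 0")
        if not np.isfinite(obs["value"]).all():
            raise ValueError("observations must be finite")
        if self.kind == "timecourse":
            obs = obs.sort_values(["species", "time_h"], kind="stable").reset_index(drop=True)
        if self.kind == "dose_response":
            a = obs["activation"]
            if ((a < 0.1 - 1e-9) | (a > 1.0 + 1e-9)).any():
                raise ValueError("imposed AMPK activation must lie in [0.1, 1.0]")
        object.__setattr__(self, "observations", obs)

    # -- CSV dialect ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = self.observations.copy()
        df.insert(0, "kind", self.kind)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "CalibrationTarget":
        df = pd.read_csv(path)
        kind = df.pop("kind").iloc[0]
        return cls(kind=kind, observations=df, **kw)


# ---------------------------------------------------------------------------
# predicted quantities
# ---------------------------------------------------------------------------

def clamped_ampk_ratio(
    params: ParameterSet,
    activation: float,
    *,
    t_relax: float = 400.0,
    rtol: float = 1e-6,
) -> float:
    """Steady pmTORC1/mTORC1 ratio with pAMPK pinned at a fixed fraction.

    The AMPK pool is removed from the dynamics (its two state derivatives
    are zeroed) and pAMPK is held at ``activation * total_AMPK``,
    representing an imposed rather than emergent activation level.  The
    remaining network is relaxed; the trailing 100 h means give the ratio.
    """
    if not (0.0 < activation <= 1.0):
        raise ValueError("activation fraction must lie in (0, 1]")
    net = build_network(params)
    y0 = default_initial_state(params)
    i_a, i_pa = IDX["AMPK"], IDX["pAMPK"]
    total = params.total("AMPK")
    y0[i_pa] = activation * total
    y0[i_a] = total - y0[i_pa]

    def rhs(t, y):
        dy = net.rhs(t, y)
        dy[i_a] = 0.0
        dy[i_pa] = 0.0
        return dy

    t_end = t_relax * SECONDS_PER_HOUR
    t_eval = np.linspace(0.7 * t_end, t_end, 120)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=1e-8)
    if not sol.success:
        raise SimulationError(f"clamped-AMPK relaxation failed: {sol.message}")
    pm1 = float(sol.y[IDX["pmTORC1"]].mean())
    m1 = float(sol.y[IDX["mTORC1"]].mean())
    return pm1 / max(m1, 1e-12)


def ampk_activator_levels(
    params: ParameterSet,
    activation_factor: float,
    *,
    v_ir: float | None = None,
    t_relax: float = 500.0,
) -> dict[str, dict[str, float]]:
    """Steady pAMPK/pAKT levels without and with an AMPK activator.

    The activator multiplies the basal AMPK activation velocity ``K_AMPK``
    (the direct, SIRT1-independent route) by ``activation_factor``; the
    identity factor 1.0 reproduces the control levels exactly.
    """
    if activation_factor < 1.0:
        raise ValueError("activation_factor must be >= 1")
    p = params if v_ir is None else params.replace(V_IR=v_ir)
    control = steady_state(p, t_relax=t_relax, residual_rtol=np.inf)
    treated = steady_state(
        apply_intervention(p, scale_param("K_AMPK", activation_factor)),
        t_relax=t_relax, residual_rtol=np.inf,
    )
    return {
        "control": {"pAMPK": control["pAMPK"], "pAKT": control["pAKT"]},
        "treated": {"pAMPK": treated["pAMPK"], "pAKT": treated["pAKT"]},
    }


# ---------------------------------------------------------------------------
# objectives (weighted least squares; zero iff exact match)
# ---------------------------------------------------------------------------

def _wls(pred: np.ndarray, obs: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * (pred - obs) ** 2))


def objective_timecourse(
    params: ParameterSet,
    target: CalibrationTarget,
    *,
    t_end: float = 500.0,
    rtol: float = 1e-6,
) -> float:
    """Criterion (i): weighted least squares on peak-normalized time courses
    of the oscillatory species under the energetic-stress scenario."""
    if target.kind != "timecourse":
        raise ValueError("target.kind must be 'timecourse'")
    obs = target.observations
    try:
        res = solve(params.replace(V_IR=target.v_ir), t_end=t_end,
                    rtol=rtol, atol=1e-8, conservation_check=False)
    except SimulationError as exc:
        log.warning("timecourse objective: simulation failed (%s)", exc)
        return np.inf
    loss = 0.0
    for species, grp in obs.groupby("species"):
        traj = res[species]
        peak = float(np.max(traj))
        if peak <= 0:
            return np.inf
        pred = np.interp(grp["time_h"].to_numpy(), res.t, traj / peak)
        loss += _wls(pred, grp["value"].to_numpy(), grp["weight"].to_numpy())
    return loss


def objective_ampk_response(
    params: ParameterSet,
    target: CalibrationTarget,
) -> float:
    """Criterion (ii): least squares on the imposed-AMPK dose-response of
    the pmTORC1/mTORC1 ratio."""
    if target.kind != "dose_response":
        raise ValueError("target.kind must be 'dose_response'")
    obs = target.observations
    try:
        pred = np.array([
            clamped_ampk_ratio(params.replace(V_IR=target.v_ir), a)
            for a in obs["activation"]
        ])
    except SimulationError as exc:
        log.warning("dose-response objective: simulation failed (%s)", exc)
        return np.inf
    return _wls(pred, obs["value"].to_numpy(), obs["weight"].to_numpy())


def objective_activator(
    params: ParameterSet,
    target: CalibrationTarget,
) -> float:
    """Criterion (iii): least squares on steady pAMPK/pAKT levels under an
    AMPK-activator intervention (and its untreated control)."""
    if target.kind != "activation_level":
        raise ValueError("target.kind must be 'activation_level'")
    obs = target.observations
    try:
        levels = ampk_activator_levels(
            params, target.activation_factor, v_ir=target.v_ir)
    except (SimulationError, ValueError) as exc:
        log.warning("activator objective: simulation failed (%s)", exc)
        return np.inf
    pred = np.array([
        levels[row.condition][row.quantity] for row in obs.itertuples()
    ])
    return _wls(pred, obs["value"].to_numpy(), obs["weight"].to_numpy())


OBJECTIVES = {
    "timecourse": objective_timecourse,
    "dose_response": objective_ampk_response,
    "activation_level": objective_activator,
}


def evaluate_losses(params: ParameterSet, targets: Sequence[CalibrationTarget]) -> dict[str, float]:
    losses: dict[str, float] = {}
    for t in targets:
        losses[t.kind] = losses.get(t.kind, 0.0) + OBJECTIVES[t.kind](params, t)
    return losses


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    """Outcome of the alternating calibration loop."""

    params: ParameterSet
    losses: dict[str, float]
    rounds: list[dict[str, float]]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "converged": self.converged,
            "losses": self.losses,
            "rounds": self.rounds,
            "parameters": self.params.to_dict(),
        }


def _bounds_for(names: Sequence[str], bounds: Mapping[str, tuple[float, float]] | None):
    out = []
    for n in names:
        if bounds and n in bounds:
            lo, hi = bounds[n]
        else:
            lo, hi = KIND_RANGES[PARAM_KINDS[n]]
        if lo <= 0 or hi <= lo:
            raise ValueError(f"infeasible bounds for {n}: ({lo}, {hi})")
        out.append((np.log10(lo), np.log10(hi)))
    return out


def _minimize_over(params, names, loss_fn, bounds, maxiter):
    """Deterministic bounded local minimization in log10 parameter space."""
    x0 = np.array([np.log10(max(params[n], 1e-300)) for n in names])
    lb = _bounds_for(names, bounds)
    x0 = np.clip(x0, [b[0] for b in lb], [b[1] for b in lb])

    def f(x):
        p = params.replace(**{n: 10.0 ** v for n, v in zip(names, x)})
        val = loss_fn(p)
        return val if np.isfinite(val) else 1e12

    res = minimize(f, x0, method="L-BFGS-B", bounds=lb,
                   options=dict(maxiter=maxiter, eps=1e-3))
    x_best = res.x if res.fun <= f(x0) else x0
    return params.replace(**{n: 10.0 ** v for n, v in zip(names, x_best)})


def fit(
    params_init: ParameterSet,
    targets: Sequence[CalibrationTarget],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    max_rounds: int = 3,
    *,
    free_timecourse: Sequence[str] = DEFAULT_FREE_TIMECOURSE,
    loss_threshold_frac: float = 0.05,
    maxiter: int = 25,
) -> FitReport:
    """Alternating three-criteria calibration.

    Each round runs (a) bounded minimization of the time-course loss over
    ``free_timecourse`` and (b) minimization of the dose-response plus
    activator losses over {K_AMPK, K_AMPK_by_SIRT1}; both stages use a
    deterministic bounded quasi-Newton method in log space.  A criterion
    counts as satisfied when its loss falls below ``loss_threshold_frac``
    times the weighted variance of its target values.  Non-convergence is
    reported on the FitReport, not raised.
    """
    if not targets:
        raise ValueError("no calibration targets given")
    _bounds_for((*free_timecourse, *AMPK_STAGE_PARAMS), bounds)  # fail fast
    by_kind: dict[str, list[CalibrationTarget]] = {}
    for t in targets:
        by_kind.setdefault(t.kind, []).append(t)

    def threshold(kind: str) -> float:
        tot = 0.0
        for t in by_kind.get(kind, []):
            v = t.observations["value"].to_numpy()
            w = t.observations["weight"].to_numpy()
            tot += float(np.sum(w * (v - np.average(v, weights=w)) ** 2))
        return loss_threshold_frac * max(tot, 1e-12)

    thresholds = {k: threshold(k) for k in by_kind}

    def satisfied(losses: dict[str, float]) -> bool:
        return all(losses[k] <= thresholds[k] for k in by_kind)

    params = params_init
    history: list[dict[str, float]] = []
    losses = evaluate_losses(params, targets)
    history.append(dict(losses))
    best = (max(losses.values()), params, dict(losses))
    if satisfied(losses):
        return FitReport(params, losses, history, converged=True)

    for _ in range(max_rounds):
        if free_timecourse and "timecourse" in by_kind:
            def tc_loss(p):
                return sum(objective_timecourse(p, t) for t in by_kind["timecourse"])
            params = _minimize_over(params, list(free_timecourse), tc_loss, bounds, maxiter)
        if ("dose_response" in by_kind) or ("activation_level" in by_kind):
            def ampk_loss(p):
                v = 0.0
                for t in by_kind.get("dose_response", []):
                    v += objective_ampk_response(p, t)
                for t in by_kind.get("activation_level", []):
                    v += objective_activator(p, t)
                return v
            params = _minimize_over(params, list(AMPK_STAGE_PARAMS), ampk_loss, bounds, maxiter)
        losses = evaluate_losses(params, targets)
        history.append(dict(losses))
        if max(losses.values()) < best[0]:
            best = (max(losses.values()), params, dict(losses))
        if satisfied(losses):
            return FitReport(params, losses, history, converged=True)

    _, params, losses = best
    return FitReport(params, losses, history, converged=False)
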