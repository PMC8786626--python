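"""Integration and long-run classification of the signaling ODE system.

The network is integrated with a stiff, variable-order solver over horizons
of hundreds to a thousand hours.  The long-run behaviour of each solve is
classified from its trailing window as a time-independent steady state, a
damped oscillation, or a sustained (limit-cycle) oscillation; envelopes
(per-output min/max over the trailing window) are the raw material of the
bifurcation diagrams, and peak-to-peak spacing in the trailing window gives
the oscillation period.

Time is seconds internally and hours at this interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.signal import find_peaks

from .network import (
    CONSERVATION_GROUPS,
    IDX,
    SPECIES,
    ReactionNetwork,
    build_network,
    default_initial_state,
)
from .parameters import SECONDS_PER_HOUR, ParameterSet

__all__ = [
    "SimulationResult",
    "SimulationError",
    "solve",
    "trailing_envelope",
    "estimate_period",
    "steady_state",
    "SteadyState",
    "TRACKED_OUTPUTS",
    "STEADY",
    "DAMPED",
    "SUSTAINED",
]

#: outputs used for dynamical classification (activated forms)
TRACKED_OUTPUTS: tuple[str, ...] = (
    "pmTORC1", "pmTORC2", "pAMPK", "pULK1", "pAKT", "IRSa", "SIRT1a",
)

STEADY = "steady_state"
DAMPED = "damped_oscillation"
SUSTAINED = "sustained_oscillation"

#: classification thresholds (configurable via solve(..., steady_rtol=, decay_ratio=))
STEADY_RTOL = 1e-3     # trailing relative amplitude below which a trace is flat
DECAY_RATIO = 0.95     # last-half/first-half amplitude ratio above which a cycle is sustained


class SimulationError(RuntimeError):
    """Integrator failure; carries the failing time (h) and state."""

    def __init__(self, message: str, t_fail: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.t_fail = t_fail
        self.state = state


@dataclass
class SimulationResult:
    """Trajectory plus trailing-window diagnostics.

    Attributes
    ----------
    t : time grid in hours.
    y : (n_species, n_times) concentrations in nM, ordered as ``species``.
    classification : one of {steady_state, damped_oscillation,
        sustained_oscillation} from the trailing window.
    envelope : per tracked output, (min, max) over the trailing window.
    period : oscillation period in hours (None unless sustained).
    period_sd : standard deviation of peak-to-peak spacings (quality metric).
    """

    t: np.ndarray
    y: np.ndarray
    species: tuple[str, ...]
    params: ParameterSet
    classification: str
    envelope: dict[str, tuple[float, float]]
    window: float
    period: float | None = None
    period_sd: float | None = None
    tracked: tuple[str, ...] = TRACKED_OUTPUTS

    def __getitem__(self, name: str) -> np.ndarray:
        return self.y[self.species.index(name)]

    def trailing_mask(self, window: float | None = None) -> np.ndarray:
        w = self.window if window is None else window
        return self.t >= self.t[-1] - w

    def trailing_mean(self, name: str, window: float | None = None) -> float:
        m = self.trailing_mask(window)
        return float(np.trapezoid(self[name][m], self.t[m]) / (self.t[m][-1] - self.t[m][0]))

    # -- writers --------------------------------------------------------
    def to_frame(self):
        """Tidy (time, species, value) DataFrame of the trajectory."""
        import pandas as pd

        n = len(self.t)
        return pd.DataFrame({
            "time_h": np.tile(self.t, len(self.species)),
            "species": np.repeat(self.species, n),
            "value_nM": self.y.reshape(-1),
        })

    def summary(self) -> dict:
        """JSON-ready classification/envelope summary."""
        out = {
            "classification": self.classification,
            "window_h": self.window,
            "envelope": {k: {"min": v[0], "max": v[1]} for k, v in self.envelope.items()},
        }
        if self.period is not None:
            out["period_h"] = self.period
            out["period_sd_h"] = self.period_sd
        return out

    def write(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            import json as _json

            Path(json_path).write_text(_json.dumps(self.summary(), indent=1))


def _classify(t: np.ndarray, y: np.ndarray, tracked_idx: Sequence[int],
              window: float, steady_rtol: float, decay_ratio: float) -> str:
    """Classify the trailing window of a trajectory.

    Sustained if at least one tracked output keeps a relative amplitude above
    ``steady_rtol`` without decaying (last-half amplitude >= decay_ratio x
    first-half amplitude); damped if the amplitude is above threshold but
    shrinking; steady otherwise.
    """
    m = t >= t[-1] - window
    half = t >= t[-1] - window / 2.0
    first = m & ~half
    oscillating = decaying = False
    for i in tracked_idx:
        seg = y[i, m]
        hi, lo = float(seg.max()), float(seg.min())
        scale = max(abs(hi), abs(lo), 1e-12)
        if (hi - lo) / scale <= steady_rtol:
            continue
        amp_late = float(y[i, half].max() - y[i, half].min())
        amp_early = float(y[i, first].max() - y[i, first].min())
        if amp_early <= 0 or amp_late >= decay_ratio * amp_early:
            oscillating = True
        else:
            decaying = True
    if oscillating:
        return SUSTAINED
    if decaying:
        return DAMPED
    return STEADY


def solve(
    params: ParameterSet,
    init: np.ndarray | Mapping[str, float] | None = None,
    t_end: float = 1000.0,
    *,
    network: ReactionNetwork | None = None,
    window: float = 200.0,
    dt: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    steady_rtol: float = STEADY_RTOL,
    decay_ratio: float = DECAY_RATIO,
    tracked: tuple[str, ...] = TRACKED_OUTPUTS,
    conservation_check: bool = True,
) -> SimulationResult:
    """Integrate the network for ``t_end`` hours and classify the outcome.

    The output grid has spacing ``dt`` hours (default 0.5 h, i.e. 48 samples
    per 24 h period).  Deterministic for fixed inputs and tolerances.

    Raises
    ------
    SimulationError
        if the integrator fails, or if any concentration falls below
        ``-1e-6 * max(state)`` (a sign of tolerance misconfiguration: the
        reaction fluxes vanish at zero concentration, so the exact flow
        preserves non-negativity).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive (hours)")
    if window > t_end:
        window = t_end
    net = network if network is not None else build_network(params)
    if init is None:
        y0 = default_initial_state(params)
    elif isinstance(init, Mapping):
        y0 = np.zeros(len(SPECIES))
        for name, v in init.items():
            y0[IDX[name]] = v
    else:
        y0 = np.asarray(init, dtype=float)

    t_eval = np.arange(0.0, t_end + dt / 2, dt) * SECONDS_PER_HOUR
    sol = solve_ivp(
        net.rhs, (0.0, t_end * SECONDS_PER_HOUR), y0,
        method=method, t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) / SECONDS_PER_HOUR if sol.t.size else 0.0
        state = sol.y[:, -1] if sol.y.size else y0
        raise SimulationError(
            f"integration failed at t = {t_fail:.2f} h: {sol.message}",
            t_fail=t_fail, state=state,
        )
    t_h = sol.t / SECONDS_PER_HOUR
    y = sol.y

    floor = -1e-6 * max(1.0, float(np.max(y)))
    if float(y.min()) < floor:
        i, j = np.unravel_index(int(np.argmin(y)), y.shape)
        raise SimulationError(
            f"negative concentration {y[i, j]:.3e} nM for {SPECIES[i]} at "
            f"t = {t_h[j]:.2f} h; tighten tolerances",
            t_fail=float(t_h[j]), state=y[:, j],
        )
    if conservation_check:
        for pool, members in CONSERVATION_GROUPS.items():
            rows = [IDX[s] for s in members]
            sums = y[rows].sum(axis=0)
            ref = sums[0] if sums[0] > 0 else 1.0
            drift = float(np.max(np.abs(sums - sums[0]))) / ref
            if drift > 1e-5:
                raise SimulationError(
                    f"conservation drift {drift:.2e} in pool {pool}; tighten tolerances"
                )

    tracked_idx = [IDX[s] for s in tracked]
    cls = _classify(t_h, y, tracked_idx, window, steady_rtol, decay_ratio)
    m = t_h >= t_h[-1] - window
    envelope = {
        s: (float(y[IDX[s], m].min()), float(y[IDX[s], m].max())) for s in tracked
    }
    result = SimulationResult(
        t=t_h, y=y, species=SPECIES, params=params, classification=cls,
        envelope=envelope, window=window, tracked=tuple(tracked),
    )
    if cls == SUSTAINED:
        try:
            result.period, result.period_sd = _period(result)
        except ValueError:
            result.period = result.period_sd = None
    return result


def trailing_envelope(result: SimulationResult, window: float = 200.0,
                      outputs: Sequence[str] | None = None) -> dict[str, tuple[float, float]]:
    """Per-output (min, max) over samples with ``t >= t_end - window``."""
    if window > result.t[-1] - result.t[0]:
        raise ValueError(
            f"window {window} h exceeds simulated horizon {result.t[-1] - result.t[0]} h"
        )
    m = result.t >= result.t[-1] - window
    names = tuple(outputs) if outputs is not None else result.tracked
    return {s: (float(result[s][m].min()), float(result[s][m].max())) for s in names}


def _period(result: SimulationResult, output: str | None = None) -> tuple[float, float]:
    m = result.trailing_mask()
    t = result.t[m]
    if output is None:
        # most strongly oscillating tracked output
        def rel_amp(s: str) -> float:
            seg = result[s][m]
            return float((seg.max() - seg.min()) / max(abs(seg.max()), 1e-12))

        output = max(result.tracked, key=rel_amp)
    x = result[output][m]
    amp = x.max() - x.min()
    peaks, _ = find_peaks(x, prominence=0.1 * amp)
    if len(peaks) < 3:
        raise ValueError("insufficient cycles: fewer than 3 peaks in the trailing window")
    spacing = np.diff(t[peaks])
    return float(spacing.mean()), float(spacing.std())


def estimate_period(result: SimulationResult, output: str | None = None) -> float:
    """Mean peak-to-peak period (hours) over the trailing window.

    Requires a sustained oscillation with at least 3 peaks in the window;
    the spacing standard deviation is stored on ``result.period_sd``.
    """
    if result.classification != SUSTAINED:
        raise ValueError(
            f"period is defined only for sustained oscillations, not {result.classification}"
        )
    period, sd = _period(result, output)
    result.period, result.period_sd = period, sd
    return period


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

#: independent coordinates (the active/bound forms); inactive partners follow
#: from pool conservation
_FREE_COORDS = ("IRa", "IRSa", "pAKT", "pmTORC1", "pmTORC1_DEPTOR",
                "pmTORC2", "pmTORC2_DEPTOR", "pDEPTOR", "pAMPK", "SIRT1a", "pULK1")


def _expand(reduced: np.ndarray, totals: dict[str, float]) -> np.ndarray:
    y = np.zeros(len(SPECIES))
    for name, v in zip(_FREE_COORDS, reduced):
        y[IDX[name]] = v
    for pool, members in CONSERVATION_GROUPS.items():
        y[IDX[members[0]]] = totals[pool] - sum(y[IDX[s]] for s in members[1:])
    return y


@dataclass
class SteadyState:
    """Steady (or cycle-averaged) state with residual diagnostics."""

    state: np.ndarray
    residual: float
    from_oscillation: bool = False
    species: tuple[str, ...] = SPECIES

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.species.index(name)])


def steady_state(
    params: ParameterSet,
    init: np.ndarray | None = None,
    *,
    network: ReactionNetwork | None = None,
    t_relax: float = 1000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    residual_rtol: float = 1e-8,
) -> SteadyState:
    """Locate the steady state by long relaxation plus root refinement.

    Integrates for ``t_relax`` hours; if the trajectory has settled, the
    endpoint is polished with a damped Newton solve in the reduced
    coordinates (active forms only, inactive partners eliminated through
    pool conservation) until ``||rhs||_inf <= residual_rtol * ||state||_inf``.
    For oscillatory regimes the trailing-window time average is returned
    with ``from_oscillation=True``.
    """
    net = network if network is not None else build_network(params)
    res = solve(params, init, t_relax, network=net, rtol=rtol, atol=atol)
    totals = {pool: float(sum(res.y[IDX[s], 0] for s in members))
              for pool, members in CONSERVATION_GROUPS.items()}

    if res.classification != STEADY:
        tm = res.trailing_mask()
        span = float(res.t[tm][-1] - res.t[tm][0])
        avg = np.array([
            float(np.trapezoid(res.y[i, tm], res.t[tm])) / span
            for i in range(len(SPECIES))
        ])
        resid = float(np.max(np.abs(net.rhs(0.0, avg))))
        return SteadyState(avg, resid, from_oscillation=True)

    y_end = res.y[:, -1]

    def reduced_rhs(r: np.ndarray) -> np.ndarray:
        y = _expand(r, totals)
        dy = net.rhs(0.0, y)
        return np.array([dy[IDX[s]] for s in _FREE_COORDS])

    r0 = np.array([y_end[IDX[s]] for s in _FREE_COORDS])
    sol = root(reduced_rhs, r0, method="hybr", tol=1e-13)
    y_ref = _expand(sol.x, totals) if sol.success else y_end
    if np.any(y_ref < 0):
        y_ref = y_end
    scale = max(float(np.max(np.abs(y_ref))), 1e-12)
    resid = float(np.max(np.abs(net.rhs(0.0, y_ref)))) / scale
    if resid > residual_rtol:
        raise SimulationError(
            f"steady-state refinement did not converge: residual {resid:.2e} "
            f"exceeds {residual_rtol:.0e} (relative)"
        )
    return SteadyState(y_ref, resid, from_oscillation=False)
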