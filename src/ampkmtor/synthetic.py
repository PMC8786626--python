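"""Synthetic calibration datasets.

Generators for pseudo-experimental targets with the statistical structure
of the data the model is calibrated against: noisy oscillatory time courses
of pmTORC1/pAMPK/pULK1 under energetic stress, an imposed-AMPK-activation
dose-response curve of the pmTORC1/mTORC1 ratio, and pAMPK/pAKT levels
under an AMPK-activator treatment.  Noise is additive Gaussian with a
standard deviation proportional to the signal range; every generator is
bit-reproducible for a fixed seed.  Values are unitless for the time-course
target (each species normalized to peak = 1) and in nM for the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    ENERGETIC_STRESS_V_IR,
    CalibrationTarget,
    ampk_activator_levels,
    clamped_ampk_ratio,
)
from .parameters import ParameterSet
from .simulate import SUSTAINED, SimulationError, solve

__all__ = [
    "SyntheticDataset",
    "make_oscillation_target",
    "make_dose_response_target",
    "make_activator_target",
]


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated target plus its provenance (true parameters, noise, seed)."""

    target: CalibrationTarget
    true_params: ParameterSet
    noise_sd: float
    seed: int

    @property
    def observations(self) -> pd.DataFrame:
        return self.target.observations


def _noise(rng: np.random.Generator, values: np.ndarray, noise_sd: float) -> np.ndarray:
    if noise_sd == 0.0:
        return values
    scale = noise_sd * float(values.max() - values.min() or values.max() or 1.0)
    return values + rng.normal(0.0, scale, size=values.shape)


def make_oscillation_target(
    true_params: ParameterSet,
    times: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    species: tuple[str, ...] = ("pmTORC1", "pAMPK", "pULK1"),
    v_ir: float = ENERGETIC_STRESS_V_IR,
    t_end: float = 500.0,
) -> SyntheticDataset:
    """Noisy samples of the stress-regime oscillation, peak-normalized.

    Raises if the true parameters do not oscillate under the energetic
    stress scenario (check the scenario/V_IR in that case).
    """
    times = np.asarray(times if times is not None
                       else np.arange(t_end - 96.0, t_end + 1e-9, 2.0), dtype=float)
    if times.min() < 0 or times.max() > 1000.0:
        raise ValueError("sampling times must lie within [0, 1000] h")
    res = solve(true_params.replace(V_IR=v_ir), t_end=max(t_end, times.max()),
                rtol=1e-7, atol=1e-9)
    if res.classification != SUSTAINED:
        raise SimulationError(
            f"true parameters give {res.classification} under V_IR={v_ir}; "
            "the oscillation target needs the energetic-stress regime"
        )
    rng = np.random.default_rng(seed)
    frames = []
    for sp in species:
        traj = res[sp]
        pred = np.interp(times, res.t, traj / traj.max())
        frames.append(pd.DataFrame({
            "time_h": times, "species": sp,
            "value": _noise(rng, pred, noise_sd), "weight": 1.0,
        }))
    target = CalibrationTarget("timecourse", pd.concat(frames, ignore_index=True),
                               v_ir=v_ir)
    return SyntheticDataset(target, true_params, noise_sd, seed)


def make_dose_response_target(
    true_params: ParameterSet,
    activations: np.ndarray | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    v_ir: float = ENERGETIC_STRESS_V_IR,
) -> SyntheticDataset:
    """Imposed-AMPK dose-response of the pmTORC1/mTORC1 ratio, plus noise.

    The noise-free curve ends below where it starts (full AMPK activation
    suppresses the mTORC1 ratio relative to 10% activation); at mid
    activation the indirect AMPK->mTORC2->AKT route can transiently raise
    the ratio, so the curve need not be monotone point-by-point.
    """
    acts = np.asarray(activations if activations is not None
                      else np.linspace(0.1, 1.0, 10), dtype=float)
    ratios = np.array([
        clamped_ampk_ratio(true_params.replace(V_IR=v_ir), a) for a in acts
    ])
    rng = np.random.default_rng(seed)
    obs = pd.DataFrame({
        "activation": acts, "value": _noise(rng, ratios, noise_sd), "weight": 1.0,
    })
    target = CalibrationTarget("dose_response", obs, v_ir=v_ir)
    return SyntheticDataset(target, true_params, noise_sd, seed)


def make_activator_target(
    true_params: ParameterSet,
    activation_factor: float = 4.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    v_ir: float = ENERGETIC_STRESS_V_IR,
) -> SyntheticDataset:
    """pAMPK and pAKT steady levels with and without an AMPK activator."""
    if activation_factor <= 1.0:
        raise ValueError("activation_factor must exceed 1")
    levels = ampk_activator_levels(true_params, activation_factor, v_ir=v_ir)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in ("control", "treated"):
        for qty in ("pAMPK", "pAKT"):
            rows.append((qty, cond, levels[cond][qty]))
    obs = pd.DataFrame(rows, columns=["quantity", "condition", "value"])
    vals = obs["value"].to_numpy(dtype=float)
    obs["value"] = _noise(rng, vals, noise_sd)
    obs["weight"] = 1.0 / np.maximum(vals, 1e-9) ** 2  # relative weighting
    target = CalibrationTarget("activation_level", obs, v_ir=v_ir,
                               activation_factor=activation_factor)
    return SyntheticDataset(target, true_params, noise_sd, seed)
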