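"""Scripted virtual experiments on the AMPK--mTORC network.

Each scenario applies a small set of interventions (pool-total scalings or
rate edits) to the baseline parameter set, solves the paired or gridded
conditions, and reports derived quantities with fixed definitions:

* percent change = 100 * (treated - control) / control,
* fold change    = treated / control,

both computed on trailing-window means whenever either condition is
oscillatory.  Every ScenarioResult stores the raw per-condition outputs so
all derived quantities can be recomputed from the result file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bifurcation import sweep_2d
from .parameters import ParameterSet, baseline_parameters
from .simulate import SimulationError, solve

__all__ = [
    "ScenarioResult",
    "run_ampk_nutrient_scan",
    "run_sirt1_inhibition",
    "run_deptor_ampk_grid",
    "run_mtorc2_inhibitor_combo",
    "run_diabetes_validation",
    "ENERGETIC_STRESS_V_IR",
]

log = logging.getLogger(__name__)

ENERGETIC_STRESS_V_IR = 0.002687
#: Fig-4-style nutrient levels: low (oscillation-adjacent) and high
LOW_NUTRIENT_V_IR = 0.00737
HIGH_NUTRIENT_V_IR = 0.02
#: alternate high-nutrient value reported inconsistently in some sources
HIGH_NUTRIENT_V_IR_ALT = 0.2

OUTPUTS = ("pmTORC1", "pmTORC2", "pAMPK", "pAKT")


@dataclass
class ScenarioResult:
    """Conditions, per-condition outputs, and derived comparisons."""

    scenario: str
    interventions: dict
    conditions: pd.DataFrame       # one row per condition: labels + outputs + class
    derived: dict[str, float]
    surfaces: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict[str, float] | None = None

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.conditions.to_csv(d / f"{self.scenario}_conditions.csv", index=False)
        for name, surf in self.surfaces.items():
            surf.to_csv(d / f"{self.scenario}_{name}.csv", index=False)
        payload = {
            "scenario": self.scenario,
            "interventions": self.interventions,
            "derived": self.derived,
            "parameters": self.params,
        }
        (d / f"{self.scenario}.json").write_text(json.dumps(payload, indent=1))


def _condition_means(params: ParameterSet, *, t_end: float = 1000.0,
                     rtol: float = 1e-7, atol: float = 1e-9) -> tuple[dict, str]:
    res = solve(params, t_end=t_end, rtol=rtol, atol=atol)
    means = {o: res.trailing_mean(o) for o in OUTPUTS}
    return means, res.classification


def percent_change(treated: float, control: float) -> float:
    return 100.0 * (treated - control) / control


def fold_change(treated: float, control: float) -> float:
    return treated / control


def _conditions_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def run_ampk_nutrient_scan(
    params: ParameterSet | None = None,
    *,
    ampk_levels: tuple[float, float] = (20.0, 480.0),
    v_ir_levels: tuple[float, float] = (LOW_NUTRIENT_V_IR, HIGH_NUTRIENT_V_IR),
    grid: tuple[int, int] | None = None,
    t_end: float = 1000.0,
) -> ScenarioResult:
    """AMPK abundance x nutrient level scan.

    Whether raising AMPK promotes or suppresses the combined mTORC signal
    (pmTORC1 + pmTORC2, the proliferation-plus-survival proxy) depends on
    the nutrient level: at low V_IR the AMPK->mTORC2 pro-survival edge
    dominates, at high V_IR the anti-proliferative mTORC1 inhibition wins.
    Reports the pmTORC2 fold change and the percent change of
    pmTORC1 + pmTORC2 between the low and high AMPK conditions, per V_IR;
    optionally attaches a full envelope surface on a ``grid`` mesh.
    """
    p0 = params if params is not None else baseline_parameters()
    rows, derived = [], {}
    for v_ir in v_ir_levels:
        per_level = {}
        for ampk in ampk_levels:
            cond = p0.replace(V_IR=v_ir, total_AMPK=ampk)
            means, cls = _condition_means(cond, t_end=t_end)
            rows.append({"V_IR": v_ir, "total_AMPK": ampk, **means,
                         "classification": cls})
            per_level[ampk] = means
        lo, hi = (per_level[a] for a in ampk_levels)
        key = f"vir_{v_ir:g}"
        derived[f"{key}_pmTORC2_fold"] = fold_change(hi["pmTORC2"], lo["pmTORC2"])
        derived[f"{key}_pAMPK_fold"] = fold_change(hi["pAMPK"], lo["pAMPK"])
        derived[f"{key}_sum_percent"] = percent_change(
            hi["pmTORC1"] + hi["pmTORC2"], lo["pmTORC1"] + lo["pmTORC2"])
    surfaces = {}
    if grid is not None:
        nx, ny = grid
        diagram = sweep_2d(
            "V_IR", np.linspace(min(v_ir_levels), max(v_ir_levels), nx),
            "total_AMPK", np.linspace(min(ampk_levels), max(ampk_levels), ny),
            p0, outputs=("pmTORC1", "pmTORC2"), t_end=t_end,
        )
        surfaces["surface"] = diagram.table
    return ScenarioResult(
        scenario="ampk_nutrient_scan",
        interventions={"total_AMPK": list(ampk_levels), "V_IR": list(v_ir_levels)},
        conditions=_conditions_frame(rows), derived=derived,
        surfaces=surfaces, params=p0.to_dict(),
    )


def run_sirt1_inhibition(
    v_ir: float | Sequence[float] = (0.1, 0.005, ENERGETIC_STRESS_V_IR),
    params: ParameterSet | None = None,
    *,
    sirt1_factor: float = 0.10,
    t_end: float = 1000.0,
) -> ScenarioResult:
    """SIRT1-inhibitor scenario: SIRT1 bioavailability reduced to 10%.

    Paired solves (control vs. scaled total_SIRT1) at each nutrient level;
    percent changes of pAMPK, pmTORC1, pmTORC2 are computed on
    trailing-window means, and the dynamical class of each condition is
    reported (the regime sequence steady -> damped -> sustained as V_IR
    falls is part of the scenario's read-out).
    """
    p0 = params if params is not None else baseline_parameters()
    v_irs = [v_ir] if np.isscalar(v_ir) else list(v_ir)
    rows, derived = [], {}
    for v in v_irs:
        ctrl_p = p0.replace(V_IR=v)
        trt_p = ctrl_p.replace(total_SIRT1=p0.total("SIRT1") * sirt1_factor)
        ctrl, c_cls = _condition_means(ctrl_p, t_end=t_end)
        trt, t_cls = _condition_means(trt_p, t_end=t_end)
        rows.append({"V_IR": v, "SIRT1_factor": 1.0, **ctrl, "classification": c_cls})
        rows.append({"V_IR": v, "SIRT1_factor": sirt1_factor, **trt, "classification": t_cls})
        key = f"vir_{v:g}"
        for out in ("pAMPK", "pmTORC1", "pmTORC2"):
            derived[f"{key}_{out}_percent"] = percent_change(trt[out], ctrl[out])
        derived[f"{key}_class_control"] = c_cls
        derived[f"{key}_class_treated"] = t_cls
    return ScenarioResult(
        scenario="sirt1_inhibition",
        interventions={"total_SIRT1_factor": sirt1_factor, "V_IR": v_irs},
        conditions=_conditions_frame(rows), derived=derived, params=p0.to_dict(),
    )


def run_deptor_ampk_grid(
    v_ir: float = 0.01,
    params: ParameterSet | None = None,
    *,
    deptor_values: Sequence[float] | None = None,
    ampk_values: Sequence[float] | None = None,
    t_end: float = 1000.0,
) -> ScenarioResult:
    """DEPTOR x AMPK abundance grid at a fixed nutrient level.

    Reports pmTORC1, pmTORC2, their ratio (the proliferation/survival
    balance) and the sustained-oscillation mask over the grid, plus the
    DEPTOR abundance that maximizes pmTORC1 at the baseline AMPK level.
    """
    p0 = params if params is not None else baseline_parameters()
    dept = np.asarray(deptor_values if deptor_values is not None
                      else np.linspace(0.0, 1000.0, 11))
    ampk = np.asarray(ampk_values if ampk_values is not None
                      else np.linspace(20.0, 480.0, 7))
    rows = []
    for d in dept:
        for a in ampk:
            cond = p0.replace(V_IR=v_ir, total_DEPTOR=d, total_AMPK=a)
            try:
                means, cls = _condition_means(cond, t_end=t_end)
            except SimulationError as exc:
                log.warning("DEPTOR/AMPK point (%g, %g) failed: %s", d, a, exc)
                means, cls = {o: np.nan for o in OUTPUTS}, "failed"
            ratio = means["pmTORC1"] / means["pmTORC2"] if means["pmTORC2"] else np.nan
            rows.append({"total_DEPTOR": d, "total_AMPK": a, **means,
                         "ratio": ratio, "classification": cls})
    surface = pd.DataFrame(rows)
    mid_ampk = ampk[np.argmin(np.abs(ampk - p0.total("AMPK")))]
    slice_ = surface[surface["total_AMPK"] == mid_ampk]
    argmax_deptor = float(slice_.loc[slice_["pmTORC1"].idxmax(), "total_DEPTOR"])
    derived = {
        "argmax_pmTORC1_deptor": argmax_deptor,
        "n_sustained": int((surface["classification"] == "sustained_oscillation").sum()),
        "ampk_slice": float(mid_ampk),
    }
    return ScenarioResult(
        scenario="deptor_ampk_grid",
        interventions={"V_IR": v_ir, "total_DEPTOR": list(map(float, dept)),
                       "total_AMPK": list(map(float, ampk))},
        conditions=surface, derived=derived,
        surfaces={"surface": surface}, params=p0.to_dict(),
    )


def run_mtorc2_inhibitor_combo(
    params: ParameterSet | None = None,
    *,
    v_ir: float = ENERGETIC_STRESS_V_IR,
    vp_factors: Sequence[float] = (1.0, 2.0, 4.0, 8.0),
    ampk_values: Sequence[float] = (50.0, 200.0, 480.0),
    t_end: float = 1000.0,
) -> ScenarioResult:
    """mTORC2 inhibitor x AMPK activator combination under nutrient stress.

    The inhibitor raises the mTORC2 deactivation velocity ``V_pmTORC2``;
    AMPK activation is represented by the conserved AMPK abundance.
    Surfaces of pmTORC1 + pmTORC2 (sum) and pmTORC1/pmTORC2 (ratio) are
    reported together with the grid corner minimizing each.
    """
    p0 = params if params is not None else baseline_parameters()
    vp0 = p0["V_pmTORC2"]
    rows = []
    for f in vp_factors:
        for a in ampk_values:
            cond = p0.replace(V_IR=v_ir, V_pmTORC2=vp0 * f, total_AMPK=a)
            try:
                res = solve(cond, t_end=t_end, rtol=1e-7, atol=1e-9)
            except SimulationError as exc:
                log.warning("combo point (%g, %g) failed: %s", f, a, exc)
                continue
            means = {o: res.trailing_mean(o) for o in OUTPUTS}
            s_lo = res.envelope["pmTORC1"][0] + res.envelope["pmTORC2"][0]
            s_hi = res.envelope["pmTORC1"][1] + res.envelope["pmTORC2"][1]
            rows.append({
                "V_pmTORC2_factor": f, "total_AMPK": a, **means,
                "sum": means["pmTORC1"] + means["pmTORC2"],
                "ratio": means["pmTORC1"] / means["pmTORC2"],
                "sum_env_min": s_lo, "sum_env_max": s_hi,
                "classification": res.classification,
            })
    surface = pd.DataFrame(rows)
    amin_sum = surface.loc[surface["sum"].idxmin()]
    amin_ratio = surface.loc[surface["ratio"].idxmin()]
    derived = {
        "argmin_sum_vp_factor": float(amin_sum["V_pmTORC2_factor"]),
        "argmin_sum_ampk": float(amin_sum["total_AMPK"]),
        "argmin_ratio_vp_factor": float(amin_ratio["V_pmTORC2_factor"]),
        "argmin_ratio_ampk": float(amin_ratio["total_AMPK"]),
    }
    return ScenarioResult(
        scenario="mtorc2_inhibitor_combo",
        interventions={"V_IR": v_ir, "V_pmTORC2_factors": list(vp_factors),
                       "total_AMPK": list(ampk_values)},
        conditions=surface, derived=derived,
        surfaces={"surface": surface}, params=p0.to_dict(),
    )


def run_diabetes_validation(
    params: ParameterSet | None = None,
    *,
    v_ir: float = 0.1,
    ir_factor: float = 0.5,
    t_end: float = 1000.0,
) -> ScenarioResult:
    """Diabetes scenario: insulin-receptor abundance halved.

    Reports pmTORC1 in the reduced-IR condition normalized by the
    full-IR condition (the expected read-out is a reduction of mTORC1
    activation, i.e. a normalized value below 1).
    """
    p0 = params if params is not None else baseline_parameters()
    healthy_p = p0.replace(V_IR=v_ir)
    diabetic_p = healthy_p.replace(total_IR=p0.total("IR") * ir_factor)
    healthy, h_cls = _condition_means(healthy_p, t_end=t_end)
    diabetic, d_cls = _condition_means(diabetic_p, t_end=t_end)
    rows = [
        {"condition": "healthy", "IR_factor": 1.0, **healthy, "classification": h_cls},
        {"condition": "diabetic", "IR_factor": ir_factor, **diabetic, "classification": d_cls},
    ]
    derived = {
        "pmTORC1_normalized": fold_change(diabetic["pmTORC1"], healthy["pmTORC1"]),
        "pmTORC2_normalized": fold_change(diabetic["pmTORC2"], healthy["pmTORC2"]),
    }
    return ScenarioResult(
        scenario="diabetes_validation",
        interventions={"total_IR_factor": ir_factor, "V_IR": v_ir},
        conditions=_conditions_frame(rows), derived=derived, params=p0.to_dict(),
    )


SCENARIOS = {
    "ampk_nutrient_scan": run_ampk_nutrient_scan,
    "sirt1_inhibition": run_sirt1_inhibition,
    "deptor_ampk_grid": run_deptor_ampk_grid,
    "mtorc2_inhibitor_combo": run_mtorc2_inhibitor_combo,
    "diabetes_validation": run_diabetes_validation,
}
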