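"""Kinetic parameters and conserved pool totals of the AMPK--mTORC network.

The model is configured entirely through a :class:`ParameterSet`: every
kinetic constant (maximal velocities, catalytic rates, binding/unbinding
rates, Michaelis constants) and every conserved pool total lives here, keyed
by the name used throughout the network definition.  Each parameter carries a
*kind* tag so that physiological sampling ranges for global sensitivity
analysis can be assigned automatically:

========  =========================================  =================
kind      meaning                                     sampling range
========  =========================================  =================
Vmax      maximal velocity, nM/s                      [0.001, 10]
K_rate    catalytic rate, 1/s (or 1/(nM s) when
          driven by a modifier concentration)         [1e-6, 1]
K_form    complex formation rate, 1/(nM s)            [1e-6, 10]
K_diss    complex dissociation rate, 1/s              [1e-6, 10]
Km        Michaelis constant, nM                      [1, 1000]
total     conserved pool size, nM                     not sampled
========  =========================================  =================

Units are nM and seconds internally; the simulation interface speaks hours
(:data:`SECONDS_PER_HOUR`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "ParameterSet",
    "Intervention",
    "scale_total",
    "scale_param",
    "set_param",
    "apply_intervention",
    "PARAM_KINDS",
    "KIND_RANGES",
    "ALIASES",
    "POOLS",
    "SECONDS_PER_HOUR",
    "baseline_parameters",
]

SECONDS_PER_HOUR = 3600.0

#: conserved molecular pools (totals are parameters named ``total_<pool>``)
POOLS = ("IR", "IRS", "AKT", "mTORC1", "mTORC2", "DEPTOR", "AMPK", "SIRT1", "ULK1")

#: kind tag of every kinetic constant in the model
PARAM_KINDS: dict[str, str] = {
    # insulin receptor
    "V_IR": "Vmax",
    "Km_IR": "Km",
    "K_IR": "K_rate",
    # insulin receptor substrate
    "K_IRS_by_IR": "K_rate",
    "Km_IRS": "Km",
    "K_IRS": "K_rate",
    "K_IRS_by_pmTORC1": "K_rate",
    # AKT
    "K_AKT_by_IRS": "K_rate",
    "K_AKT_by_pmTORC2": "K_rate",
    "Km_AKT": "Km",
    "K_pAKT": "K_rate",
    # mTORC1
    "K_mTORC1_by_pAKT": "K_rate",
    "Km_mTORC1_by_pAKT": "Km",
    "K_pmTORC1": "K_rate",
    "K_pmTORC1_by_pAMPK": "K_rate",
    "K_pmTORC1_by_pULK1": "K_rate",
    # mTORC2
    "K_mTORC2_by_IRS": "K_rate",
    "K_mTORC2_by_pAMPK": "Vmax",  # maximal velocity of the AMPK-driven route (MM in pAMPK)
    "Km_mTORC2_by_pAMPK": "Km",  # driver saturation: the AMPK->mTORC2 drive is MM in pAMPK
    "Km_mTORC2": "Km",
    "V_pmTORC2": "Vmax",
    "Km_pmTORC2": "Km",
    # DEPTOR binding and phosphorylation
    "K_mTORC1_DEPTOR_form": "K_form",
    "K_mTORC1_DEPTOR_diss": "K_diss",
    "K_mTORC2_DEPTOR_form": "K_form",
    "K_mTORC2_DEPTOR_diss": "K_diss",
    "K_DEPTOR_by_pmTORC1": "K_rate",
    "K_DEPTOR_by_pmTORC2": "K_rate",
    "Km_DEPTOR": "Km",
    "K_pDEPTOR": "K_rate",
    # AMPK
    "K_AMPK": "Vmax",
    "K_AMPK_by_SIRT1": "K_rate",
    "Km_AMPK": "Km",
    "K_pAMPK": "K_rate",
    "K_pAMPK_by_pmTORC1": "K_rate",
    "K_pAMPK_by_pULK1": "K_rate",
    # SIRT1
    "K_SIRT1_by_pAMPK": "K_rate",
    "Km_SIRT1": "Km",
    "K_SIRT1": "K_rate",
    # ULK1
    "K_ULK1_by_pAMPK": "K_rate",
    "Km_ULK1": "Km",
    "K_ULK1": "K_rate",
    "K_pULK1_by_pmTORC1": "K_rate",
}
PARAM_KINDS.update({f"total_{pool}": "total" for pool in POOLS})

#: sampling box per kind (lo, hi); totals are not sampled
KIND_RANGES: dict[str, tuple[float, float]] = {
    "Vmax": (1e-3, 10.0),
    "K_rate": (1e-6, 1.0),
    "K_form": (1e-6, 10.0),
    "K_diss": (1e-6, 10.0),
    "Km": (1.0, 1000.0),
}

#: alternative spellings accepted for the same constant.  The mTORC2
#: deactivation velocity and the mTORC2-DEPTOR dissociation rate each appear
#: in the literature under two names; both keys resolve to one stored value.
ALIASES: dict[str, str] = {
    "V_mTORC2": "V_pmTORC2",
    "Kd_mTORC2_DEPTOR": "K_mTORC2_DEPTOR_diss",
}


class ParameterError(ValueError):
    """Invalid parameter name, value, or configuration."""


def _canonical(name: str) -> str:
    name = ALIASES.get(name, name)
    if name not in PARAM_KINDS:
        raise ParameterError(f"unknown parameter {name!r}")
    return name


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bundle of all kinetic constants and pool totals (nM, s).

    Values are retrieved with item access (``params["K_pmTORC1"]``); aliased
    names (``V_mTORC2``, ``Kd_mTORC2_DEPTOR``) resolve to their canonical
    entry.  Modified copies are produced with :meth:`replace` or via
    intervention helpers (:func:`scale_total`, :func:`scale_param`,
    :func:`set_param`).
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = {}
        for name, value in dict(self.values).items():
            canon = _canonical(name)
            if canon in vals and vals[canon] != float(value):
                raise ParameterError(
                    f"conflicting values for {canon!r} (given twice via aliases)"
                )
            vals[canon] = float(value)
        missing = sorted(set(PARAM_KINDS) - set(vals))
        if missing:
            raise ParameterError(f"missing parameter(s): {', '.join(missing)}")
        for name, value in vals.items():
            if not (value >= 0.0) or value != value or value == float("inf"):
                raise ParameterError(f"parameter {name!r} must be finite and >= 0, got {value}")
        object.__setattr__(self, "values", vals)

    # -- access ---------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[_canonical(name)]

    def __contains__(self, name: str) -> bool:
        try:
            return _canonical(name) in self.values
        except ParameterError:
            return False

    def names(self) -> list[str]:
        return list(PARAM_KINDS)

    def kinetic_names(self) -> list[str]:
        """Names of kinetic constants (pool totals excluded)."""
        return [n for n, k in PARAM_KINDS.items() if k != "total"]

    def kind(self, name: str) -> str:
        return PARAM_KINDS[_canonical(name)]

    def total(self, pool: str) -> float:
        if pool not in POOLS:
            raise ParameterError(f"unknown pool {pool!r}")
        return self.values[f"total_{pool}"]

    # -- modification ---------------------------------------------------
    def replace(self, **changes: float) -> "ParameterSet":
        vals = dict(self.values)
        for name, value in changes.items():
            vals[_canonical(name)] = float(value)
        return ParameterSet(vals)

    # -- validation against the sampling box ----------------------------
    def range_violations(self) -> dict[str, tuple[float, float, float]]:
        """Kinetic constants outside their kind's physiological box.

        Returns ``{name: (value, lo, hi)}``; empty when all constants lie
        within the box.  Zero-valued constants are treated as switched-off
        reactions and not flagged.
        """
        out = {}
        for name, kind in PARAM_KINDS.items():
            if kind == "total":
                continue
            lo, hi = KIND_RANGES[kind]
            v = self.values[name]
            if v != 0.0 and not (lo <= v <= hi):
                out[name] = (v, lo, hi)
        return out

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return dict(self.values)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        return cls(dict(data))

    def to_file(self, path: str | Path) -> None:
        """Write a flat key->value config (JSON; a YAML superset)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ParameterSet":
        """Read a flat key->value config file (JSON or YAML)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ParameterError(f"config {path} does not hold a key->value mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# interventions: small, composable parameter edits used by the virtual
# pharmacology scenarios (SIRT1 inhibition, diabetes, AICAR, ...)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Intervention:
    """A single parameter edit: scale a pool total, scale or set a constant."""

    action: str  # "scale_total" | "scale_param" | "set_param"
    name: str
    value: float

    def __post_init__(self) -> None:
        if self.action not in ("scale_total", "scale_param", "set_param"):
            raise ParameterError(f"unknown intervention action {self.action!r}")
        if self.action != "set_param" and self.value < 0:
            raise ParameterError("scaling factor must be >= 0")


def scale_total(pool: str, factor: float) -> Intervention:
    if pool not in POOLS:
        raise ParameterError(f"unknown pool {pool!r}")
    return Intervention("scale_total", pool, factor)


def scale_param(name: str, factor: float) -> Intervention:
    return Intervention("scale_param", _canonical(name), factor)


def set_param(name: str, value: float) -> Intervention:
    return Intervention("set_param", _canonical(name), value)


def apply_intervention(params: ParameterSet, *interventions: Intervention) -> ParameterSet:
    """Return a new ParameterSet with the interventions applied.

    The input set is never modified.  Interventions targeting distinct
    parameters commute; repeated scalings of one parameter compose
    multiplicatively.
    """
    out = params
    for iv in interventions:
        if iv.action == "scale_total":
            key = f"total_{iv.name}"
            out = out.replace(**{key: out.values[key] * iv.value})
        elif iv.action == "scale_param":
            out = out.replace(**{iv.name: out.values[_canonical(iv.name)] * iv.value})
        else:
            out = out.replace(**{iv.name: iv.value})
    return out


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

def baseline_parameters(**overrides: float) -> ParameterSet:
    """The calibrated baseline parameter set.

    The baseline realises the reference phenotype of the network: sustained
    ~24 h limit-cycle oscillations of pmTORC1/pAMPK/pULK1 under energetic
    stress (V_IR = 0.002687 nM/s), damped oscillations at intermediate
    nutrient supply and a time-independent steady state at high nutrient
    supply (V_IR = 0.1 nM/s), a monotone-decreasing mTORC1 response to
    imposed AMPK activation, and AKT activation upon pharmacological AMPK
    activation.  Keyword overrides replace individual entries.
    """
    vals = dict(_BASELINE)
    return ParameterSet(vals).replace(**overrides) if overrides else ParameterSet(vals)


# Values in nM, nM/s, 1/s, 1/(nM s); calibrated against the reference
# phenotype described in `baseline_parameters`.
_BASELINE: dict[str, float] = {
    # insulin receptor
    "V_IR": 0.002687,
    "Km_IR": 140.837,
    "K_IR": 0.000214049,
    # IRS
    "K_IRS_by_IR": 0.000136562,
    "Km_IRS": 30.937,
    "K_IRS": 2.16127e-05,
    "K_IRS_by_pmTORC1": 3.67242e-06,
    # AKT
    "K_AKT_by_IRS": 0.000109612,
    "K_AKT_by_pmTORC2": 0.000117267,
    "Km_AKT": 1.0,
    "K_pAKT": 6.50346e-05,
    # mTORC1
    "K_mTORC1_by_pAKT": 0.000591306,
    "Km_mTORC1_by_pAKT": 3.06905,
    "K_pmTORC1": 1.408e-06,
    "K_pmTORC1_by_pAMPK": 1.60283e-05,
    "K_pmTORC1_by_pULK1": 2.65418e-06,
    # mTORC2
    "K_mTORC2_by_IRS": 0.000324445,
    "K_mTORC2_by_pAMPK": 0.0747218,
    "Km_mTORC2_by_pAMPK": 79.401,
    "Km_mTORC2": 1.0,
    "V_pmTORC2": 0.0401783,
    "Km_pmTORC2": 20.5048,
    # DEPTOR
    "K_mTORC1_DEPTOR_form": 7.37274e-06,
    "K_mTORC1_DEPTOR_diss": 0.000226273,
    "K_mTORC2_DEPTOR_form": 7.37274e-06,
    "K_mTORC2_DEPTOR_diss": 0.000226273,
    "K_DEPTOR_by_pmTORC1": 1.62917e-06,
    "K_DEPTOR_by_pmTORC2": 1.62917e-06,
    "Km_DEPTOR": 61.3811,
    "K_pDEPTOR": 2.26273e-05,
    # AMPK
    "K_AMPK": 0.00293381,
    "K_AMPK_by_SIRT1": 0.000326997,
    "Km_AMPK": 1.0,
    "K_pAMPK": 3.2895e-05,
    "K_pAMPK_by_pmTORC1": 3.38362e-06,
    "K_pAMPK_by_pULK1": 2.65418e-06,
    # SIRT1
    "K_SIRT1_by_pAMPK": 4.52547e-05,
    "Km_SIRT1": 30.6905,
    "K_SIRT1": 4.52547e-05,
    # ULK1
    "K_ULK1_by_pAMPK": 1.62917e-06,
    "Km_ULK1": 30.6905,
    "K_ULK1": 9.05093e-05,
    "K_pULK1_by_pmTORC1": 2.65418e-06,
    # conserved pool totals (nM)
    "total_IR": 61.3811,
    "total_IRS": 61.3811,
    "total_AKT": 1227.62,
    "total_mTORC1": 245.524,
    "total_mTORC2": 245.524,
    "total_DEPTOR": 245.524,
    "total_AMPK": 122.762,
    "total_SIRT1": 61.3811,
    "total_ULK1": 122.762,
}
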