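"""Reaction network of the AMPK--mTORC signaling model.

The wiring follows the canonical interaction diagram of the insulin ->
IR -> IRS -> AKT -> mTORC1 axis with its feedback loops:

* insulin receptor (IR) activation at velocity ``V_IR`` (the nutrient proxy),
  first-order deactivation;
* IRS activation by active IR; deactivation enhanced by pmTORC1 (the
  mTORC1 -> IRS negative feedback);
* AKT activation by active IRS and by pmTORC2 (mTORC2 phosphorylates AKT);
* mTORC1 phosphorylation by pAKT (Michaelis--Menten); dephosphorylation
  basal plus pAMPK-driven and pULK1-driven routes;
* mTORC2 phosphorylation driven by active IRS and by pAMPK (the
  AMPK -> mTORC2 pro-survival edge); saturable dephosphorylation at
  velocity ``V_pmTORC2``;
* DEPTOR reversibly binds the phosphorylated mTOR complexes and is itself
  phosphorylated (inactivated) by both, reversibly;
* AMPK activation with Vmax ``K_AMPK + K_AMPK_by_SIRT1 * SIRT1_active``;
  deactivation basal plus pmTORC1- and pULK1-driven routes;
* ULK1 activation by pAMPK, deactivation basal plus pmTORC1-driven
  (mTORC1 and AMPK compete for ULK1);
* SIRT1 activation by pAMPK, first-order deactivation.

Each reaction is a declarative record; the ODE right-hand side and the SBML
export are assembled from the same list, so the integrated system and the
exported model cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .parameters import ParameterSet, ParameterError, POOLS

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "rhs",
    "SPECIES",
    "CONSERVATION_GROUPS",
    "default_initial_state",
]

#: state-vector ordering (concentrations in nM)
SPECIES: tuple[str, ...] = (
    "IR", "IRa",
    "IRS", "IRSa",
    "AKT", "pAKT",
    "mTORC1", "pmTORC1", "pmTORC1_DEPTOR",
    "mTORC2", "pmTORC2", "pmTORC2_DEPTOR",
    "DEPTOR", "pDEPTOR",
    "AMPK", "pAMPK",
    "SIRT1", "SIRT1a",
    "ULK1", "pULK1",
)

IDX = {name: i for i, name in enumerate(SPECIES)}

#: members of each conserved pool; the group sums are invariants of the flow.
#: DEPTOR molecules sequestered in the mTORC-DEPTOR complexes belong to the
#: DEPTOR pool as well as to the respective mTORC pool.
CONSERVATION_GROUPS: dict[str, tuple[str, ...]] = {
    "IR": ("IR", "IRa"),
    "IRS": ("IRS", "IRSa"),
    "AKT": ("AKT", "pAKT"),
    "mTORC1": ("mTORC1", "pmTORC1", "pmTORC1_DEPTOR"),
    "mTORC2": ("mTORC2", "pmTORC2", "pmTORC2_DEPTOR"),
    "DEPTOR": ("DEPTOR", "pDEPTOR", "pmTORC1_DEPTOR", "pmTORC2_DEPTOR"),
    "AMPK": ("AMPK", "pAMPK"),
    "SIRT1": ("SIRT1", "SIRT1a"),
    "ULK1": ("ULK1", "pULK1"),
}


@dataclass(frozen=True)
class Reaction:
    """One elementary step of the network.

    kinetic_law:
        ``mass_action``       rate = k * [substrate] * ([modifier])
        ``michaelis_menten``  rate = V * [S]/(Km+[S]), with V either a
                              velocity constant or k * [modifier]
        ``binding``           rate = k * [A] * [B]
        ``unbinding``         rate = k * [complex]
    modifier:
        driving species (activator when it raises an active form, inhibitor
        when it drives a deactivation), or None for basal steps.
    """

    id: str
    kinetic_law: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    rate_param: str
    km_param: str | None = None
    modifier: str | None = None
    modifier_role: str | None = None  # "activator" | "inhibitor"
    ka_param: str | None = None  # driver saturation: modifier enters as M/(Ka+M)


def _mk_reactions() -> tuple[Reaction, ...]:
    R = Reaction
    return (
        # insulin receptor
        R("IR_activation", "michaelis_menten", ("IR",), ("IRa",), "V_IR", "Km_IR"),
        R("IR_deactivation", "mass_action", ("IRa",), ("IR",), "K_IR"),
        # IRS
        R("IRS_activation_by_IR", "michaelis_menten", ("IRS",), ("IRSa",),
          "K_IRS_by_IR", "Km_IRS", "IRa", "activator"),
        R("IRS_deactivation", "mass_action", ("IRSa",), ("IRS",), "K_IRS"),
        R("IRS_deactivation_by_pmTORC1", "mass_action", ("IRSa",), ("IRS",),
          "K_IRS_by_pmTORC1", None, "pmTORC1", "inhibitor"),
        # AKT
        R("AKT_activation_by_IRS", "michaelis_menten", ("AKT",), ("pAKT",),
          "K_AKT_by_IRS", "Km_AKT", "IRSa", "activator"),
        R("AKT_activation_by_pmTORC2", "michaelis_menten", ("AKT",), ("pAKT",),
          "K_AKT_by_pmTORC2", "Km_AKT", "pmTORC2", "activator"),
        R("AKT_deactivation", "mass_action", ("pAKT",), ("AKT",), "K_pAKT"),
        # mTORC1
        R("mTORC1_activation_by_pAKT", "michaelis_menten", ("mTORC1",), ("pmTORC1",),
          "K_mTORC1_by_pAKT", "Km_mTORC1_by_pAKT", "pAKT", "activator"),
        R("pmTORC1_deactivation", "mass_action", ("pmTORC1",), ("mTORC1",), "K_pmTORC1"),
        R("pmTORC1_deactivation_by_pAMPK", "mass_action", ("pmTORC1",), ("mTORC1",),
          "K_pmTORC1_by_pAMPK", None, "pAMPK", "inhibitor"),
        R("pmTORC1_deactivation_by_pULK1", "mass_action", ("pmTORC1",), ("mTORC1",),
          "K_pmTORC1_by_pULK1", None, "pULK1", "inhibitor"),
        R("mTORC1_DEPTOR_binding", "binding", ("pmTORC1", "DEPTOR"), ("pmTORC1_DEPTOR",),
          "K_mTORC1_DEPTOR_form"),
        R("mTORC1_DEPTOR_unbinding", "unbinding", ("pmTORC1_DEPTOR",), ("pmTORC1", "DEPTOR"),
          "K_mTORC1_DEPTOR_diss"),
        # mTORC2
        R("mTORC2_activation_by_IRS", "michaelis_menten", ("mTORC2",), ("pmTORC2",),
          "K_mTORC2_by_IRS", "Km_mTORC2", "IRSa", "activator"),
        R("mTORC2_activation_by_pAMPK", "michaelis_menten", ("mTORC2",), ("pmTORC2",),
          "K_mTORC2_by_pAMPK", "Km_mTORC2", "pAMPK", "activator",
          ka_param="Km_mTORC2_by_pAMPK"),
        R("pmTORC2_deactivation", "michaelis_menten", ("pmTORC2",), ("mTORC2",),
          "V_pmTORC2", "Km_pmTORC2"),
        R("mTORC2_DEPTOR_binding", "binding", ("pmTORC2", "DEPTOR"), ("pmTORC2_DEPTOR",),
          "K_mTORC2_DEPTOR_form"),
        R("mTORC2_DEPTOR_unbinding", "unbinding", ("pmTORC2_DEPTOR",), ("pmTORC2", "DEPTOR"),
          "K_mTORC2_DEPTOR_diss"),
        # DEPTOR phosphorylation (inactivation) by the mTOR complexes
        R("DEPTOR_phosphorylation_by_pmTORC1", "michaelis_menten", ("DEPTOR",), ("pDEPTOR",),
          "K_DEPTOR_by_pmTORC1", "Km_DEPTOR", "pmTORC1", "inhibitor"),
        R("DEPTOR_phosphorylation_by_pmTORC2", "michaelis_menten", ("DEPTOR",), ("pDEPTOR",),
          "K_DEPTOR_by_pmTORC2", "Km_DEPTOR", "pmTORC2", "inhibitor"),
        R("pDEPTOR_dephosphorylation", "mass_action", ("pDEPTOR",), ("DEPTOR",), "K_pDEPTOR"),
        # AMPK
        R("AMPK_activation_basal", "michaelis_menten", ("AMPK",), ("pAMPK",),
          "K_AMPK", "Km_AMPK"),
        R("AMPK_activation_by_SIRT1", "michaelis_menten", ("AMPK",), ("pAMPK",),
          "K_AMPK_by_SIRT1", "Km_AMPK", "SIRT1a", "activator"),
        R("pAMPK_deactivation", "mass_action", ("pAMPK",), ("AMPK",), "K_pAMPK"),
        R("pAMPK_deactivation_by_pmTORC1", "mass_action", ("pAMPK",), ("AMPK",),
          "K_pAMPK_by_pmTORC1", None, "pmTORC1", "inhibitor"),
        R("pAMPK_deactivation_by_pULK1", "mass_action", ("pAMPK",), ("AMPK",),
          "K_pAMPK_by_pULK1", None, "pULK1", "inhibitor"),
        # SIRT1
        R("SIRT1_activation_by_pAMPK", "michaelis_menten", ("SIRT1",), ("SIRT1a",),
          "K_SIRT1_by_pAMPK", "Km_SIRT1", "pAMPK", "activator"),
        R("SIRT1_deactivation", "mass_action", ("SIRT1a",), ("SIRT1",), "K_SIRT1"),
        # ULK1
        R("ULK1_activation_by_pAMPK", "michaelis_menten", ("ULK1",), ("pULK1",),
          "K_ULK1_by_pAMPK", "Km_ULK1", "pAMPK", "activator"),
        R("pULK1_deactivation", "mass_action", ("pULK1",), ("ULK1",), "K_ULK1"),
        R("pULK1_deactivation_by_pmTORC1", "mass_action", ("pULK1",), ("ULK1",),
          "K_pULK1_by_pmTORC1", None, "pmTORC1", "inhibitor"),
    )


REACTIONS: tuple[Reaction, ...] = _mk_reactions()


class NetworkConfigurationError(ParameterError):
    """Network assembly failed (unknown species or unbound parameter)."""


@dataclass
class ReactionNetwork:
    """Assembled reaction network bound to a concrete :class:`ParameterSet`.

    Holds the declarative reaction list, the species index, the conservation
    groups, and the precomputed index arrays used by the vectorized
    right-hand side.
    """

    params: ParameterSet
    reactions: tuple[Reaction, ...] = REACTIONS
    species: tuple[str, ...] = SPECIES
    conservation_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CONSERVATION_GROUPS)
    )

    def __post_init__(self) -> None:
        self._compile()

    # -- assembly -------------------------------------------------------
    def _compile(self) -> None:
        n_r = len(self.reactions)
        idx = {name: i for i, name in enumerate(self.species)}
        k = np.empty(n_r)
        km = np.zeros(n_r)
        has_km = np.zeros(n_r, dtype=bool)
        s1 = np.empty(n_r, dtype=np.intp)
        s2 = np.full(n_r, -1, dtype=np.intp)
        mod = np.full(n_r, -1, dtype=np.intp)
        ka = np.zeros(n_r)
        has_ka = np.zeros(n_r, dtype=bool)
        stoich = np.zeros((len(self.species), n_r))
        for j, r in enumerate(self.reactions):
            for sp in (*r.substrates, *r.products, *( (r.modifier,) if r.modifier else () )):
                if sp not in idx:
                    raise NetworkConfigurationError(
                        f"reaction {r.id!r} references unknown species {sp!r}"
                    )
            if r.rate_param not in self.params:
                raise NetworkConfigurationError(
                    f"reaction {r.id!r}: unbound parameter {r.rate_param!r}"
                )
            k[j] = self.params[r.rate_param]
            if r.km_param is not None:
                if r.km_param not in self.params:
                    raise NetworkConfigurationError(
                        f"reaction {r.id!r}: unbound parameter {r.km_param!r}"
                    )
                km[j] = self.params[r.km_param]
                has_km[j] = True
            s1[j] = idx[r.substrates[0]]
            if len(r.substrates) > 1:
                s2[j] = idx[r.substrates[1]]
            if r.modifier is not None:
                mod[j] = idx[r.modifier]
            if r.ka_param is not None:
                if r.ka_param not in self.params:
                    raise NetworkConfigurationError(
                        f"reaction {r.id!r}: unbound parameter {r.ka_param!r}"
                    )
                ka[j] = self.params[r.ka_param]
                has_ka[j] = True
            for sp in r.substrates:
                stoich[idx[sp], j] -= 1.0
            for sp in r.products:
                stoich[idx[sp], j] += 1.0
        self._k, self._km, self._has_km = k, km, has_km
        self._ka, self._has_ka = ka, has_ka
        self._s1, self._s2, self._mod = s1, s2, mod
        self._stoich = stoich
        self._has_s2 = s2 >= 0
        self._has_mod = mod >= 0

    # -- queries --------------------------------------------------------
    def bound_parameters(self) -> set[str]:
        out = set()
        for r in self.reactions:
            out.add(r.rate_param)
            if r.km_param:
                out.add(r.km_param)
            if r.ka_param:
                out.add(r.ka_param)
        return out

    def edge_set(self) -> set[tuple[str, str, str]]:
        """(source, target-pool, sign) regulatory edges implied by the wiring."""
        edges = set()
        for r in self.reactions:
            if r.modifier is None:
                continue
            target = next(g for g, members in self.conservation_groups.items()
                          if r.substrates[0] in members)
            sign = "activation" if r.modifier_role == "activator" else "inhibition"
            edges.add((r.modifier, target, sign))
        for r in self.reactions:
            if r.kinetic_law == "binding":
                edges.add((r.substrates[1], r.substrates[0], "complex_formation"))
        return edges

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction rate vector at state ``y`` (nM/s)."""
        v = self._k * y[self._s1]
        if self._has_mod.any():
            mod_val = y[np.clip(self._mod, 0, None)]
            denom_ka = np.where(self._has_ka, self._ka + mod_val, 1.0)
            v = np.where(self._has_mod,
                         v * mod_val / np.where(denom_ka > 0, denom_ka, 1.0), v)
        if self._has_s2.any():
            v = np.where(self._has_s2, v * y[np.clip(self._s2, 0, None)], v)
        denom = self._km + y[self._s1]
        v = np.where(self._has_km, v / np.where(denom > 0, denom, 1.0), v)
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """ODE right-hand side dy/dt (nM/s); ``t`` in seconds (autonomous)."""
        return self._stoich @ self.rates(y)

    # -- serialization / interop ---------------------------------------
    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "parameters": self.params.to_dict(),
            "reactions": [
                {
                    "id": r.id,
                    "kinetic_law": r.kinetic_law,
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "rate_param": r.rate_param,
                    "km_param": r.km_param,
                    "modifier": r.modifier,
                    "modifier_role": r.modifier_role,
                    "ka_param": r.ka_param,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        reactions = tuple(
            Reaction(
                id=r["id"],
                kinetic_law=r["kinetic_law"],
                substrates=tuple(r["substrates"]),
                products=tuple(r["products"]),
                rate_param=r["rate_param"],
                km_param=r.get("km_param"),
                modifier=r.get("modifier"),
                modifier_role=r.get("modifier_role"),
                ka_param=r.get("ka_param"),
            )
            for r in data["reactions"]
        )
        return cls(
            params=ParameterSet.from_dict(data["parameters"]),
            reactions=reactions,
            species=tuple(data["species"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def build_network(params: ParameterSet, *, drop_reactions: Sequence[str] = ()) -> ReactionNetwork:
    """Assemble the reaction network for a parameter set.

    Deterministic: equal parameter sets yield equal networks.  Reactions
    named in ``drop_reactions`` are omitted (used for structural
    perturbation tests, e.g. removing the AMPK -> mTORC2 edge).
    """
    reactions = tuple(r for r in REACTIONS if r.id not in drop_reactions)
    unknown = set(drop_reactions) - {r.id for r in REACTIONS}
    if unknown:
        raise NetworkConfigurationError(f"unknown reaction id(s): {sorted(unknown)}")
    return ReactionNetwork(params=params, reactions=reactions)


def rhs(state: np.ndarray, t: float, network: ReactionNetwork) -> np.ndarray:
    """Functional wrapper around :meth:`ReactionNetwork.rhs`.

    Raises a domain error for negative input concentrations beyond numerical
    noise; solver callbacks use the method form, which does not check.
    """
    state = np.asarray(state, dtype=float)
    floor = -1e-9 * max(1.0, float(np.max(np.abs(state))))
    if np.any(state < floor):
        bad = [SPECIES[i] for i in np.where(state < floor)[0]]
        raise ValueError(f"negative concentration(s) for {bad}")
    return network.rhs(t, state)


def default_initial_state(params: ParameterSet) -> np.ndarray:
    """Canonical initial condition: every pool fully inactive/unbound."""
    y0 = np.zeros(len(SPECIES))
    for pool in POOLS:
        y0[IDX[pool]] = params.total(pool)
    return y0
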