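"""Network assembly, conservation structure, and the ODE right-hand side."""

import numpy as np
import pytest

from ampkmtor.network import (
    CONSERVATION_GROUPS,
    IDX,
    SPECIES,
    NetworkConfigurationError,
    ReactionNetwork,
    build_network,
    default_initial_state,
    rhs,
)
from ampkmtor.parameters import POOLS, ParameterSet
from ampkmtor.simulate import solve


@pytest.fixture(scope="module")
def network(baseline):
    return build_network(baseline)


class TestAssembly:
    def test_required_regulatory_edges_present(self, network):
        edges = network.edge_set()
        required = {
            ("IRSa", "mTORC2", "activation"),
            ("pAMPK", "mTORC2", "activation"),
            ("pAMPK", "mTORC1", "inhibition"),
            ("pmTORC1", "ULK1", "inhibition"),
            ("pmTORC1", "IRS", "inhibition"),
            ("pmTORC1", "AMPK", "inhibition"),
            ("pULK1", "AMPK", "inhibition"),
            ("SIRT1a", "AMPK", "activation"),
            ("DEPTOR", "pmTORC1", "complex_formation"),
            ("DEPTOR", "pmTORC2", "complex_formation"),
        }
        assert required <= edges

    def test_every_kinetic_parameter_bound_to_a_reaction(self, baseline, network):
        assert set(baseline.kinetic_names()) <= network.bound_parameters()

    def test_deterministic_assembly(self, baseline):
        assert build_network(baseline) == build_network(baseline)

    def test_serialization_round_trip(self, network):
        again = ReactionNetwork.from_dict(network.to_dict())
        assert again == network

    def test_unknown_dropped_reaction_rejected(self, baseline):
        with pytest.raises(NetworkConfigurationError, match="no_such_reaction"):
            build_network(baseline, drop_reactions=["no_such_reaction"])


class TestRHS:
    def test_zero_rates_give_zero_derivative(self, baseline):
        zeroed = baseline.replace(**{n: 0.0 for n in baseline.kinetic_names()})
        net = build_network(zeroed)
        y = default_initial_state(zeroed)
        assert np.all(net.rhs(0.0, y) == 0.0)

    def test_conservation_group_derivatives_vanish_exactly(self, network, baseline):
        rng = np.random.default_rng(42)
        for _ in range(5):
            y = rng.uniform(0.0, 50.0, len(SPECIES))
            dy = network.rhs(0.0, y)
            for pool, members in CONSERVATION_GROUPS.items():
                scale = max(np.max(np.abs(dy)), 1e-12)
                assert abs(sum(dy[IDX[s]] for s in members)) <= 1e-12 * scale

    def test_negative_state_rejected_by_wrapper(self, network):
        y = default_initial_state(network.params)
        y[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            rhs(y, 0.0, network)

    def test_rhs_matches_finite_difference_of_trajectory(self, baseline, network):
        """Central finite differences on the integrated trajectory agree
        with the assembled right-hand side at interior grid points."""
        res = solve(baseline, t_end=100.0, dt=0.02, rtol=1e-10, atol=1e-12)
        t_s = res.t * 3600.0
        idx = np.linspace(500, len(res.t) - 500, 10).astype(int)
        for j in idx:
            fd = (res.y[:, j + 1] - res.y[:, j - 1]) / (t_s[j + 1] - t_s[j - 1])
            an = network.rhs(0.0, res.y[:, j])
            scale = np.max(np.abs(an))
            assert np.max(np.abs(fd - an)) <= 1e-4 * max(scale, 1e-12)


class TestStructure:
    def test_removing_ampk_mtorc2_edge_collapses_mtorc2_activation(self, baseline):
        """The AMPK->mTORC2 reaction is the dominant mTORC2 activation
        route: raising total AMPK increases steady pmTORC2 through it, and
        deleting it collapses pmTORC2 several-fold at any AMPK level (a
        weaker indirect route via mTORC1's feedback on IRS remains)."""
        levels = [50.0, 400.0]
        with_edge, without_edge = [], []
        for total in levels:
            p = baseline.replace(total_AMPK=total, V_IR=0.02)
            res = solve(p, t_end=400.0, rtol=1e-6, atol=1e-8)
            with_edge.append(res.trailing_mean("pmTORC2"))
            net = build_network(p, drop_reactions=["mTORC2_activation_by_pAMPK"])
            res2 = solve(p, t_end=400.0, network=net, rtol=1e-6, atol=1e-8,
                         conservation_check=False)
            without_edge.append(res2.trailing_mean("pmTORC2"))
        assert with_edge[1] > with_edge[0]
        for w, wo in zip(with_edge, without_edge):
            assert wo < 0.5 * w


class TestInitialState:
    def test_default_state_fills_pools_inactive(self, baseline):
        y0 = default_initial_state(baseline)
        for pool in POOLS:
            assert y0[IDX[pool]] == baseline.total(pool)
        assert y0.sum() == pytest.approx(sum(baseline.total(p) for p in POOLS))
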