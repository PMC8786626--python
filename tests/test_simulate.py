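"""Integration, classification, envelopes, period estimation, steady states."""

import numpy as np
import pytest

from ampkmtor.network import SPECIES, IDX
from ampkmtor.parameters import SECONDS_PER_HOUR
from ampkmtor.simulate import (
    DAMPED,
    STEADY,
    SUSTAINED,
    SimulationError,
    SimulationResult,
    estimate_period,
    solve,
    steady_state,
    trailing_envelope,
)


def _zero_rate(baseline):
    return baseline.replace(**{n: 0.0 for n in baseline.kinetic_names()})


def synthetic_result(period_h: float, t_end: float = 600.0, dt: float = 0.25,
                     amplitude: float = 1.0, offset: float = 2.0):
    """SimulationResult carrying an injected sinusoid in pmTORC1."""
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = np.zeros((len(SPECIES), len(t)))
    y[IDX["pmTORC1"]] = offset + amplitude * np.sin(2 * np.pi * t / period_h)
    window = 200.0
    m = t >= t[-1] - window
    return SimulationResult(
        t=t, y=y, species=SPECIES, params=None,
        classification=SUSTAINED,
        envelope={"pmTORC1": (float(y[IDX["pmTORC1"], m].min()),
                              float(y[IDX["pmTORC1"], m].max()))},
        window=window, tracked=("pmTORC1",),
    )


class TestSolve:
    def test_zero_rates_hold_initial_state(self, baseline):
        res = solve(_zero_rate(baseline), t_end=100.0)
        assert res.classification == STEADY
        assert np.allclose(res.y, res.y[:, [0]])

    def test_deterministic_for_fixed_inputs(self, baseline, fast_solve):
        a = solve(baseline, t_end=50.0, **fast_solve)
        b = solve(baseline, t_end=50.0, **fast_solve)
        assert np.array_equal(a.y, b.y)

    def test_grid_resolves_24h_period(self, baseline, fast_solve):
        res = solve(baseline, t_end=100.0, **fast_solve)
        step = np.diff(res.t).max()
        assert 24.0 / step >= 20

    def test_invalid_horizon_rejected(self, baseline):
        with pytest.raises(ValueError):
            solve(baseline, t_end=-1.0)

    def test_conservation_along_trajectory(self, baseline):
        from ampkmtor.network import CONSERVATION_GROUPS

        res = solve(baseline, t_end=1000.0)
        for pool, members in CONSERVATION_GROUPS.items():
            sums = sum(res[s] for s in members)
            assert np.max(np.abs(sums - sums[0])) <= 1e-6 * sums[0]


class TestEnvelope:
    def test_constant_trajectory_min_equals_max(self, baseline):
        res = solve(_zero_rate(baseline), t_end=250.0)
        env = trailing_envelope(res, window=200.0)
        for lo, hi in env.values():
            assert lo == hi

    def test_injected_sinusoid_extrema(self):
        res = synthetic_result(period_h=24.0)
        env = trailing_envelope(res, window=200.0, outputs=("pmTORC1",))
        lo, hi = env["pmTORC1"]
        assert lo == pytest.approx(1.0, abs=5e-3)
        assert hi == pytest.approx(3.0, abs=5e-3)

    def test_window_longer_than_run_rejected(self, baseline):
        res = solve(_zero_rate(baseline), t_end=100.0)
        with pytest.raises(ValueError):
            trailing_envelope(res, window=150.0)


class TestPeriod:
    @pytest.mark.parametrize("period", [24.0, 7.0])
    def test_injected_sinusoid_period_recovered(self, period):
        res = synthetic_result(period_h=period)
        est = estimate_period(res, output="pmTORC1")
        assert est == pytest.approx(period, abs=0.25)  # one grid step
        assert res.period_sd <= 0.3

    def test_period_undefined_off_limit_cycle(self, baseline):
        res = solve(_zero_rate(baseline), t_end=250.0)
        with pytest.raises(ValueError, match="sustained"):
            estimate_period(res)

    def test_too_few_cycles_rejected(self):
        res = synthetic_result(period_h=150.0)  # ~1.3 peaks in the window
        with pytest.raises(ValueError, match="insufficient cycles"):
            estimate_period(res, output="pmTORC1")


class TestSteadyState:
    def test_zero_rate_system_returns_init(self, baseline):
        ss = steady_state(_zero_rate(baseline), t_relax=50.0)
        assert ss.residual == 0.0
        assert not ss.from_oscillation

    def test_high_nutrient_steady_residual_small(self, baseline):
        ss = steady_state(baseline.replace(V_IR=0.1), t_relax=600.0)
        assert not ss.from_oscillation
        assert ss.residual <= 1e-8

    def test_two_start_agreement(self, baseline):
        """The steady state in the tested regime is unique: a run started
        half-activated (same pool totals) lands on the same state."""
        from ampkmtor.network import CONSERVATION_GROUPS, default_initial_state

        p = baseline.replace(V_IR=0.1)
        a = steady_state(p, t_relax=600.0)
        y0 = default_initial_state(p)
        for pool, members in CONSERVATION_GROUPS.items():
            if pool == "DEPTOR":
                continue  # complexes shared with the mTORC pools stay empty
            total = p.total(pool)
            y0[IDX[members[0]]] = 0.5 * total
            y0[IDX[members[1]]] = 0.5 * total
        b = steady_state(p, init=y0, t_relax=600.0)
        assert np.allclose(a.state, b.state, rtol=1e-6, atol=1e-8)


class TestClassificationInvariance:
    def test_envelope_stable_under_tolerance_halving(self, baseline):
        tight = solve(baseline, t_end=600.0, rtol=1e-8, atol=1e-10)
        tighter = solve(baseline, t_end=600.0, rtol=5e-9, atol=5e-11)
        for out in ("pmTORC1", "pAMPK"):
            for a, b in zip(tight.envelope[out], tighter.envelope[out]):
                assert a == pytest.approx(b, rel=1e-3)
        assert tight.classification == tighter.classification
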