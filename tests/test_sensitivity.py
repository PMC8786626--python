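"""LHS stratification, PRCC against brute-force oracles, local sensitivity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ampkmtor.sensitivity import (
    lhs_sample,
    normalized_sensitivity,
    parameter_ranges,
    prcc,
    sample_parallel_coordinates,
    bootstrap_prcc,
)


def brute_force_partial_rank_corr(draws: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Independent oracle: residual-on-residual Pearson correlation of ranks,
    computed with explicit least-squares fits (no shared code with prcc)."""
    X = np.column_stack([stats.rankdata(draws[c]) for c in draws.columns])
    ry = stats.rankdata(y)
    out = []
    for j in range(X.shape[1]):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        bx, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = X[:, j] - others @ bx
        ey = ry - others @ by
        out.append(np.corrcoef(ex, ey)[0, 1])
    return np.array(out)


class TestLHS:
    def test_exact_stratification(self):
        names = ["K_pmTORC1", "Km_AMPK", "V_IR"]
        n = 10
        draws = lhs_sample(names, n, seed=7)
        for name in names:
            lo, hi = parameter_ranges([name])[name]
            u = (np.log(draws[name]) - np.log(lo)) / (np.log(hi) - np.log(lo))
            bins = np.floor(u * n).astype(int)
            assert sorted(bins) == list(range(n))  # one draw per decile

    def test_seed_determinism(self):
        a = lhs_sample(["K_pmTORC1", "Km_AMPK"], 50, seed=3)
        b = lhs_sample(["K_pmTORC1", "Km_AMPK"], 50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_marginals_approximately_uniform(self):
        draws = lhs_sample(["Km_AMPK"], 1000, seed=11)
        lo, hi = parameter_ranges(["Km_AMPK"])["Km_AMPK"]
        u = (np.log(draws["Km_AMPK"]) - np.log(lo)) / (np.log(hi) - np.log(lo))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(["Km_AMPK"], 1, seed=0)

    def test_totals_not_sampled(self):
        with pytest.raises(ValueError):
            lhs_sample(["total_AMPK"], 10, seed=0)


class TestPRCC:
    def test_perfect_monotone_dependence(self):
        rng = np.random.default_rng(5)
        draws = pd.DataFrame({
            "a": rng.uniform(size=200), "b": rng.uniform(size=200),
            "c": rng.uniform(size=200),
        })
        out = pd.DataFrame({"S": np.exp(draws["a"])})  # monotone in a only
        m = prcc(draws, out)
        assert m.loc["a", "S"] == pytest.approx(1.0, abs=1e-9)
        assert abs(m.loc["b", "S"]) < 0.2
        assert abs(m.loc["c", "S"]) < 0.2

    def test_matches_brute_force_oracle_on_toy_model(self):
        rng = np.random.default_rng(17)
        n = 400
        draws = pd.DataFrame({
            "x1": rng.uniform(size=n), "x2": rng.uniform(size=n),
            "x3": rng.uniform(size=n),
        })
        y = 2 * draws["x1"] - draws["x2"] + 0.1 * rng.normal(size=n)
        m = prcc(draws, pd.DataFrame({"y": y}))
        oracle = brute_force_partial_rank_corr(draws, y.to_numpy())
        assert np.allclose(m["y"].to_numpy(), oracle, atol=1e-10)
        assert m.loc["x1", "y"] > 0.9 and m.loc["x2", "y"] < -0.9
        assert abs(m.loc["x3", "y"]) < 0.2

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        n = 300
        draws = pd.DataFrame({"a": rng.uniform(size=n), "b": rng.uniform(size=n)})
        y = pd.DataFrame({"S": draws["a"] - 0.5 * draws["b"] + 0.05 * rng.normal(size=n)})
        m1 = prcc(draws, y)
        transformed = pd.DataFrame({"a": np.exp(draws["a"]), "b": draws["b"] ** 3})
        m2 = prcc(transformed, y)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(31)
        draws = pd.DataFrame(rng.uniform(size=(100, 4)), columns=list("abcd"))
        y = pd.DataFrame({"S": rng.uniform(size=100)})
        m = prcc(draws, y)
        assert (m.abs() <= 1.0 + 1e-12).all().all()

    def test_nonfinite_rows_dropped(self):
        rng = np.random.default_rng(37)
        draws = pd.DataFrame({"a": rng.uniform(size=50), "b": rng.uniform(size=50)})
        y = pd.DataFrame({"S": draws["a"].to_numpy().copy()})
        y.iloc[::10] = np.nan
        m = prcc(draws, y)
        assert m.loc["a", "S"] == pytest.approx(1.0, abs=1e-9)

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(41)
        n = 150
        draws = pd.DataFrame({"a": rng.uniform(size=n), "b": rng.uniform(size=n)})
        y = pd.DataFrame({"S": draws["a"] + 0.3 * rng.normal(size=n)})
        m = prcc(draws, y)
        ci = bootstrap_prcc(draws, y, n_boot=50, seed=1)
        row = ci[(ci.parameter == "a") & (ci.output == "S")].iloc[0]
        assert row.ci_lo <= m.loc["a", "S"] <= row.ci_hi


class TestLocal:
    def test_linear_toy_closed_form(self):
        """dS/dt = p - S has steady state S = p: normalized sensitivity 1."""
        val = normalized_sensitivity(lambda p: p, 3.7)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_toy_closed_form(self):
        val = normalized_sensitivity(lambda p: p ** 2, 2.0, delta_frac=1e-6)
        assert val == pytest.approx(2.0, rel=1e-4)


class TestSubsample:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(9)
        return pd.DataFrame(rng.uniform(size=(200, 3)), columns=["m1", "m2", "m3"])

    def test_identity_when_n_equals_rows(self, table):
        out = sample_parallel_coordinates(None, table, n=len(table), seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_seed_determinism(self, table):
        a = sample_parallel_coordinates(None, table, n=50, seed=4)
        b = sample_parallel_coordinates(None, table, n=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_short_table_returned_whole(self, table):
        out = sample_parallel_coordinates(None, table.head(20), n=150, seed=0)
        assert len(out) == 20
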