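"""Estimator closed forms, oracle equivalences and recovery simulations."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import biogaps as bg
from biogaps.exceptions import (
    EstimationError,
    InvalidDesignError,
    SubsamplingError,
    WeightingError,
)


def _obs(counts, **cols):
    table = pd.DataFrame({"cell_id": np.arange(len(counts)), "count": counts, **cols})
    return bg.AbundanceData(table=table, unit_cols=("cell_id",), meta={})


class TestNaive:
    def test_point_is_sample_mean(self):
        est = bg.estimate_naive(_obs([3, 8]))
        assert est.point == pytest.approx(5.5, abs=1e-9)

    def test_census_recovers_population_mean(self, dense_counts):
        x = dense_counts.table.set_index("cell_id")["x_true"]
        m = bg.draw_mask(bg.inclusion_probs(x, "constant", {}, 1.0), seed=1)
        obs = bg.apply_mask(dense_counts, m)
        est = bg.estimate_naive(obs)
        assert est.point == pytest.approx(dense_counts.table["count"].mean(), abs=1e-9)

    def test_single_observation_interval(self):
        # SE on log scale = 1/sqrt(sum mu) = 1/2 for a single y=4
        est = bg.estimate_naive(_obs([4]))
        assert est.point == pytest.approx(4.0, abs=1e-9)
        assert est.ci_low == pytest.approx(np.exp(np.log(4) - 1.959963984540054 / 2), rel=1e-6)
        assert est.ci_high == pytest.approx(np.exp(np.log(4) + 1.959963984540054 / 2), rel=1e-6)
        assert est.ci_low <= est.point <= est.ci_high

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            bg.estimate_naive(_obs([]))


class TestIPW:
    def test_hajek_worked_example(self):
        # y=(3,8), pi=(0.5,0.25): (6+32)/(2+4) = 6.3333...
        est = bg.estimate_ipw(_obs([3, 8]), np.array([0.5, 0.25]))
        assert est.point == pytest.approx(19 / 3, abs=1e-9)

    def test_equal_weights_match_naive(self):
        counts = [2, 5, 7, 1]
        ipw = bg.estimate_ipw(_obs(counts), np.full(4, 0.4))
        naive = bg.estimate_naive(_obs(counts))
        assert ipw.point == pytest.approx(naive.point, abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(min_value=0, max_value=30),
                      st.floats(min_value=0.05, max_value=1.0)),
            min_size=1, max_size=10,
        ).filter(lambda rows: sum(r[0] for r in rows) > 0)
    )
    def test_hajek_oracle_equivalence(self, rows):
        # estimate equals sum(y/pi)/sum(1/pi) to 1e-10 on any small input
        y = [r[0] for r in rows]
        pi = np.array([r[1] for r in rows])
        est = bg.estimate_ipw(_obs(y), pi)
        oracle = np.sum(np.array(y) / pi) / np.sum(1 / pi)
        assert est.point == pytest.approx(oracle, abs=1e-10)

    def test_nonpositive_pi_rejected(self):
        with pytest.raises(WeightingError):
            bg.estimate_ipw(_obs([1, 2]), np.array([0.5, 0.0]))

    def test_sandwich_se_tracks_empirical_sd(self):
        # mean reported SE within 15% of the sd of points across replicates
        rng = np.random.default_rng(7)
        points, ses = [], []
        n = 400
        x = bg.standardize(np.tile(np.arange(20), 20))
        pi = 1 / (1 + np.exp(-(-0.8 + 1.5 * x)))
        lam = np.exp(1.0 + 0.6 * x)
        for _ in range(1000):
            inc = rng.random(n) < pi
            y = rng.poisson(lam[inc])
            est = bg.estimate_ipw(_obs(y), pi[inc])
            points.append(est.point)
            ses.append(est.se)
        ratio = np.mean(ses) / np.std(points, ddof=1)
        assert 0.85 < ratio < 1.15


class TestPoststrat:
    def test_two_stratum_worked_example(self):
        obs = _obs([2, 4, 6], stratum=["A", "A", "B"])
        est = bg.estimate_poststrat(obs, obs.table["stratum"], {"A": 2, "B": 2})
        assert est.point == pytest.approx(4.5, abs=1e-12)

    def test_census_identity(self):
        rng = np.random.default_rng(3)
        strata = np.repeat([1, 2, 3, 4], 5)
        y = rng.poisson(4, 20)
        obs = _obs(y, stratum=strata)
        pop = pd.Series(5, index=[1, 2, 3, 4])
        est = bg.estimate_poststrat(obs, strata, pop)
        assert est.point == pytest.approx(y.mean(), abs=1e-12)

    def test_unrepresented_stratum_renormalizes_and_warns(self):
        obs = _obs([2, 4], stratum=["A", "A"])
        est = bg.estimate_poststrat(obs, obs.table["stratum"], {"A": 2, "B": 3})
        assert est.point == pytest.approx(3.0, abs=1e-12)
        assert any(w.startswith("unrepresented_strata:") and "B" in w
                   for w in est.warnings)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_stratified_mean_oracle(self, data):
        # brute-force stratified mean on <=5 strata to 1e-12
        n_strata = data.draw(st.integers(min_value=1, max_value=5))
        pop, ys, labels = {}, [], []
        for h in range(n_strata):
            pop[h] = data.draw(st.integers(min_value=1, max_value=30))
            n_h = data.draw(st.integers(min_value=0, max_value=4))
            for _ in range(n_h):
                ys.append(data.draw(st.integers(min_value=0, max_value=20)))
                labels.append(h)
        if not ys:
            return
        est = bg.estimate_poststrat(_obs(ys), np.array(labels), pop)
        obs_strata = sorted(set(labels))
        tot = sum(pop[h] for h in obs_strata)
        oracle = sum(
            pop[h] * np.mean([y for y, l in zip(ys, labels) if l == h])
            for h in obs_strata
        ) / tot
        assert est.point == pytest.approx(oracle, abs=1e-12)

    def test_singleton_collapse_warning(self):
        obs = _obs([1, 2, 9], stratum=["A", "A", "B"])
        est = bg.estimate_poststrat(obs, obs.table["stratum"], {"A": 2, "B": 2})
        assert any(w.startswith("singleton_stratum_collapsed") for w in est.warnings)
        assert est.se >= 0


class TestSubsample:
    @pytest.fixture()
    def stratified_obs(self):
        rng = np.random.default_rng(5)
        strata = np.repeat(np.arange(12), 4)
        return _obs(rng.poisson(3, 48), stratum=strata)

    def test_one_per_stratum(self, stratified_obs):
        out = bg.subsample_balanced(stratified_obs,
                                    stratified_obs.table["stratum"], k=1, seed=2)
        assert len(out.table) == 12
        assert out.table["stratum"].is_unique

    def test_determinism(self, stratified_obs):
        s = stratified_obs.table["stratum"]
        a = bg.subsample_balanced(stratified_obs, s, k=2, seed=9).table
        b = bg.subsample_balanced(stratified_obs, s, k=2, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_large_k_noop(self, stratified_obs):
        out = bg.subsample_balanced(stratified_obs,
                                    stratified_obs.table["stratum"], k=10, seed=0)
        assert len(out.table) == len(stratified_obs.table)

    def test_empty_rejected(self):
        with pytest.raises(SubsamplingError):
            bg.subsample_balanced(_obs([]), np.array([]), k=1)


class TestSamplingModel:
    def test_null_covariate_recovers_flat_fraction(self, default_landscape):
        x = default_landscape.table.set_index("cell_id")["x_true"]
        cov = default_landscape.table.set_index("cell_id")[["x_proxy"]]
        errs = []
        for s in range(200):
            m = bg.draw_mask(bg.inclusion_probs(x, "constant", {}, 0.35), seed=s)
            fit = bg.fit_sampling_model(m, cov)
            errs.append(np.mean(np.abs(fit.pi_hat.to_numpy() - 0.35)))
        assert np.mean(errs) < 0.05

    def test_beats_constant_baseline_under_mar(self, default_landscape):
        # with a perfect covariate the fitted pi should beat a flat fit in MSE
        land = bg.attach_proxy(bg.make_landscape(400, 20, seed=2), 1.0, seed=3)
        x = land.table.set_index("cell_id")["x_true"]
        cov = land.table.set_index("cell_id")[["x_proxy"]]
        d = bg.inclusion_probs(x, "logistic", {"slope": 2.0}, 0.35)
        mse_fit, mse_flat = [], []
        for s in range(200):
            m = bg.draw_mask(d, seed=s)
            fit = bg.fit_sampling_model(m, cov)
            mse_fit.append(np.mean((fit.pi_hat.to_numpy() - d.pi.to_numpy()) ** 2))
            mse_flat.append(np.mean((m.realized_fraction - d.pi.to_numpy()) ** 2))
        assert np.mean(mse_fit) < np.mean(mse_flat)

    def test_all_included_separation_and_unit_pi(self, default_landscape):
        x = default_landscape.table.set_index("cell_id")["x_true"]
        cov = default_landscape.table.set_index("cell_id")[["x_proxy"]]
        m = bg.draw_mask(bg.inclusion_probs(x, "constant", {}, 1.0), seed=1)
        fit = bg.fit_sampling_model(m, cov)
        assert fit.separation
        assert np.all(fit.pi_hat.to_numpy() > 0.99)


class TestTrend:
    def test_single_year_rejected(self):
        panel = bg.simulate_trend_panel(bg.TrendPanelSpec(n_sites=5, n_years=2),
                                        seed=1)
        one_year = bg.AbundanceData(
            panel.table[panel.table["year"] == 1], panel.unit_cols, {})
        with pytest.raises(InvalidDesignError):
            bg.estimate_trend(one_year)

    def test_mcar_matches_dense_estimate(self):
        # annual MCAR retention 0.5: masked estimate unbiased for dense one
        spec = bg.TrendPanelSpec(n_sites=20, n_years=10, b1=0.0)
        diffs = []
        for s in range(200):
            panel = bg.simulate_trend_panel(spec, seed=s)
            dense_pt = bg.estimate_trend(panel).point
            idx = pd.MultiIndex.from_frame(panel.table[["site_id", "year"]])
            u = pd.Series(0.0, index=idx)
            d = bg.inclusion_probs(u + 0.0, "constant", {}, 0.5)
            m = bg.draw_mask(d, dimension="annual", seed=s + 1)
            obs = bg.apply_mask(panel, m)
            diffs.append(bg.estimate_trend(obs).point - dense_pt)
        diffs = np.array(diffs)
        mc_se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * mc_se

    def test_year_factor_slope_close_to_linear(self):
        panel = bg.simulate_trend_panel(
            bg.TrendPanelSpec(n_sites=30, n_years=10, b1=0.0, b0=0.05), seed=4)
        lin = bg.estimate_trend(panel).point
        fac = bg.estimate_trend(panel, year_as_factor=True).point
        assert fac == pytest.approx(lin, abs=0.01)
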