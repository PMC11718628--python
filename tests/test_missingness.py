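"""Mechanism calibration, mask semantics and diagnostics."""
import numpy as np
import pandas as pd
import pytest

import biogaps as bg
from biogaps.exceptions import AlignmentError, CalibrationError
from biogaps.missingness import MNAR_CAVEAT


@pytest.fixture(scope="module")
def cov400():
    land = bg.make_landscape(400, 20, seed=1)
    return land.table.set_index("cell_id")["x_true"]


class TestCalibration:
    @pytest.mark.parametrize("mechanism,params", [
        ("constant", {}),
        ("logistic", {"slope": 3.0}),
        ("logistic", {"slope": -1.5}),
        ("linear", {"slope": -0.7}),
        ("threshold_high", {}),
        ("preferential", {"slope": 2.0}),
    ])
    @pytest.mark.parametrize("f", [0.15, 0.35, 0.75])
    def test_mean_pi_hits_target(self, cov400, mechanism, params, f):
        if mechanism == "threshold_high" and f == 0.75:
            # infeasible: more than the below-mean half would be needed
            with pytest.raises(CalibrationError):
                bg.inclusion_probs(cov400, mechanism, params, f)
            return
        d = bg.inclusion_probs(cov400, mechanism, params, f)
        assert abs(d.mean_pi - f) <= 1e-6
        assert d.pi.between(0, 1).all()

    def test_constant_is_flat(self, cov400):
        d = bg.inclusion_probs(cov400, "constant", {}, 0.35)
        assert (d.pi == 0.35).all()

    def test_threshold_derived_example(self):
        # half of units above the mean, f=0.25 -> p=0.5 below, 0 above
        cov = pd.Series([-1.0, -0.5, 0.5, 1.0] * 25)
        d = bg.inclusion_probs(cov, "threshold_high", {}, 0.25)
        pi = d.pi.to_numpy()
        assert np.all(pi[cov.to_numpy() <= 0] == 0.5)
        assert np.all(pi[cov.to_numpy() > 0] == 0.0)

    def test_logistic_strictly_increasing(self, cov400):
        d = bg.inclusion_probs(cov400, "logistic", {"slope": 3.0}, 0.35)
        order = np.argsort(cov400.to_numpy())
        pi_sorted = d.pi.to_numpy()[order]
        assert np.all(np.diff(pi_sorted) >= 0)
        assert pi_sorted[-1] > pi_sorted[0]

    def test_closed_form_constant_intercept(self, cov400):
        from scipy.special import logit
        g0 = bg.calibrate_intercept("constant", {}, cov400, 0.35)
        assert g0 == pytest.approx(float(logit(0.35)), abs=1e-12)
        # zero slope under logistic degenerates to the same closed form
        g0z = bg.calibrate_intercept("logistic", {"slope": 0.0}, cov400, 0.35)
        assert g0z == pytest.approx(float(logit(0.35)), abs=1e-12)

    def test_census_target(self, cov400):
        d = bg.inclusion_probs(cov400, "logistic", {"slope": 3.0}, 1.0)
        assert (d.pi == 1.0).all()

    def test_bad_fraction_rejected(self, cov400):
        with pytest.raises(ValueError):
            bg.inclusion_probs(cov400, "constant", {}, 0.0)


class TestMask:
    def test_degenerate_probabilities(self, cov400):
        all_in = bg.draw_mask(bg.inclusion_probs(cov400, "constant", {}, 1.0), seed=1)
        assert all_in.included.all()
        d = bg.inclusion_probs(cov400, "constant", {}, 0.5)
        d.pi.values[:] = 0.0
        none_in = bg.draw_mask(d, seed=1)
        assert not none_in.included.any()

    def test_realized_fraction_binomial(self):
        cov = pd.Series(np.zeros(100_000))
        d = bg.inclusion_probs(cov, "constant", {}, 0.35)
        m = bg.draw_mask(d, seed=7)
        tol = 3 * np.sqrt(0.35 * 0.65 / 100_000)
        assert abs(m.realized_fraction - 0.35) < tol

    def test_apply_identity_census(self, dense_counts):
        x = dense_counts.table.set_index("cell_id")["x_true"]
        m = bg.draw_mask(bg.inclusion_probs(x, "constant", {}, 1.0), seed=1)
        obs = bg.apply_mask(dense_counts, m)
        assert len(obs.table) == len(dense_counts.table)
        assert "lambda" not in obs.table.columns
        assert (obs.table["count"].to_numpy()
                == dense_counts.table["count"].to_numpy()).all()

    def test_spatial_mask_broadcasts_to_all_years(self):
        panel = bg.simulate_trend_panel(bg.TrendPanelSpec(n_sites=10, n_years=5),
                                        seed=3)
        u_site = pd.Series(
            bg.standardize(np.linspace(0, 1, 10)),
            index=pd.Index(range(10), name="site_id"))
        d = bg.inclusion_probs(u_site, "constant", {}, 0.5)
        m = bg.draw_mask(d, dimension="spatial", seed=4)
        obs = bg.apply_mask(panel, m).table
        # a site is either fully present (all 5 years) or fully absent
        per_site = obs.groupby("site_id").size()
        assert set(per_site) <= {5}
        excluded = set(range(10)) - set(per_site.index)
        assert excluded == set(m.included[~m.included].index)

    def test_key_mismatch_raises(self, dense_counts):
        pi = pd.Series(0.5, index=pd.Index(range(10), name="cell_id"))
        d = bg.SamplingDesign(pi=pi, mechanism="constant", params={},
                              covariate_name="x", target_fraction=0.5)
        m = bg.draw_mask(d, seed=0)
        with pytest.raises(AlignmentError):
            bg.apply_mask(dense_counts, m)

    def test_mask_determinism(self, cov400):
        d = bg.inclusion_probs(cov400, "logistic", {"slope": 2.0}, 0.35)
        a = bg.draw_mask(d, seed=9).included
        b = bg.draw_mask(d, seed=9).included
        assert (a == b).all()


class TestDiagnostics:
    def test_detects_covariate_driven_gaps(self, cov400):
        d = bg.inclusion_probs(cov400, "logistic", {"slope": 3.0}, 0.35)
        m = bg.draw_mask(d, seed=5)
        rep = bg.diagnose_missingness(m, cov400.to_frame("x"))
        assert not rep.separation
        assert rep.lrt_pvalue < 1e-6
        assert rep.coefficients.loc["x", "coef"] > 0
        assert rep.caveat == MNAR_CAVEAT

    def test_separation_flag_threshold_certain(self, cov400):
        # threshold with p=1 below the mean: inclusion deterministic in x
        d = bg.inclusion_probs(cov400, "threshold_high", {}, 0.5)
        assert d.params["p_keep"] == pytest.approx(1.0)
        m = bg.draw_mask(d, seed=5)
        rep = bg.diagnose_missingness(m, cov400.to_frame("x"))
        assert rep.separation
        assert rep.coefficients["coef"].isna().all()

    def test_gap_proportion_simple(self, cov400):
        d = bg.inclusion_probs(cov400, "constant", {}, 0.35)
        inc = pd.Series(False, index=cov400.index)
        inc.iloc[:140] = True
        m = bg.Mask(included=inc, design=d, dimension="spatial", seed=0)
        rep = bg.diagnose_missingness(m, cov400.to_frame("x"))
        assert rep.gap_summary["spatial"] == pytest.approx(0.65)

    def test_gap_proportions_panel_dimensions(self):
        idx = pd.MultiIndex.from_product(
            [range(4), range(3)], names=["site_id", "year"])
        inc = pd.Series(True, index=idx)
        inc.loc[(0,)] = False           # site 0: spatial gap
        inc.loc[(1, 2)] = False         # one annual gap among observed sites
        d = bg.SamplingDesign(pi=pd.Series(0.5, index=idx), mechanism="constant",
                              params={}, covariate_name="u", target_fraction=0.5)
        m = bg.Mask(included=inc, design=d, dimension="annual", seed=0)
        gp = bg.gap_proportions(m)
        assert gp["spatial"] == pytest.approx(0.25)
        assert gp["annual"] == pytest.approx(1 / 9)

    def test_mcar_null_pvalues_roughly_uniform(self, cov400):
        # under a constant mechanism the LRT should not systematically reject
        d = bg.inclusion_probs(cov400, "constant", {}, 0.35)
        pvals = []
        for s in range(300):
            m = bg.draw_mask(d, seed=s)
            pvals.append(bg.diagnose_missingness(m, cov400.to_frame("x")).lrt_pvalue)
        pvals = np.array(pvals)
        # coarse uniformity: mean near 0.5 and mild rejection rate
        assert abs(pvals.mean() - 0.5) < 0.1
        assert 0.005 < (pvals < 0.05).mean() < 0.12
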