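"""Multivariate Cox fitting, nomogram, discrimination and calibration."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from _oracles import harrells_c_bruteforce
from ntriplenet.prognosis import (
    build_nomogram,
    calibration_table,
    harrells_c,
    model_discrimination,
    multivariate_cox,
)


def simulate(n, betas, seed=0, censor=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, len(betas))),
                     columns=[f"x{i}" for i in range(len(betas))])
    lp = X.to_numpy() @ np.asarray(betas)
    t = rng.exponential(np.exp(-lp))
    if censor:
        c = rng.exponential(np.quantile(t, 0.8), n)
        return X, pd.Series(np.minimum(t, c)), pd.Series((t <= c).astype(int))
    return X, pd.Series(t), pd.Series(np.ones(n, int))


class TestMultivariateCox:
    def test_binary_covariate_hazard_ratio_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 1000).astype(float)
        t = rng.exponential(np.exp(-np.log(2.0) * x))
        m = multivariate_cox(pd.DataFrame({"x": x}), pd.Series(t),
                             pd.Series(np.ones(1000, int)))
        assert 1.7 <= m.summary.loc["x", "hr"] <= 2.3
        lo, hi = m.summary.loc["x", ["hr_ci_lower", "hr_ci_upper"]]
        assert lo < hi

    def test_duplicated_covariate_rejected(self):
        X, t, e = simulate(100, [0.5], seed=1)
        X["dup"] = X["x0"]
        with pytest.raises(ValueError, match="collinear"):
            multivariate_cox(X, t, e)

    def test_constant_covariate_rejected(self):
        X, t, e = simulate(100, [0.5], seed=2)
        X["flat"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            multivariate_cox(X, t, e)


class TestNomogram:
    def fit(self, seed=3):
        X, t, e = simulate(400, [1.0, -0.5, 0.2], seed=seed)
        model = multivariate_cox(X, t, e)
        times = tuple(tt for tt in (0.2, 0.5, 1.0) if tt <= model.max_time)
        return model, build_nomogram(model, times=times), X

    def test_scale_anchors(self):
        model, nomo, X = self.fit()
        # covariate at its reference end contributes 0 points
        for c in model.covariates:
            ref = nomo.point_scales.loc[c, "ref"]
            assert nomo.points(c, ref) == 0.0
        # the dominant covariate reaches 100 at its far end
        dom = nomo.point_scales["max_points"].idxmax()
        beta = nomo.point_scales.loc[dom, "beta"]
        far = model.maxs[dom] if beta >= 0 else model.mins[dom]
        assert nomo.points(dom, far) == pytest.approx(100.0)

    def test_lookup_consistent_with_direct_model_prediction(self):
        model, nomo, X = self.fit()
        t0 = nomo.times[0]
        direct = model.predict_survival(X, t0)
        via_points = nomo.survival_at(nomo.total_points(X), t0, model)
        assert np.allclose(direct.to_numpy(), via_points, atol=1e-9)

    def test_survival_monotone_decreasing_in_total_points(self):
        _, nomo, _ = self.fit()
        tbl = nomo.total_points_table
        for col in tbl.columns[1:]:
            assert np.all(np.diff(tbl[col]) <= 1e-12)

    def test_extrapolation_refused(self):
        model, _, _ = self.fit()
        with pytest.raises(ValueError, match="follow-up"):
            build_nomogram(model, times=(model.max_time * 2,))

    def test_points_invariant_to_affine_covariate_rescaling(self):
        X, t, e = simulate(400, [1.0, -0.5], seed=4)
        m1 = multivariate_cox(X, t, e)
        X2 = X.copy()
        X2["x0"] = X2["x0"] * 10 + 3
        m2 = multivariate_cox(X2, t, e)
        n1 = build_nomogram(m1, times=(0.2,))
        n2 = build_nomogram(m2, times=(0.2,))
        p1 = n1.points("x0", X["x0"].iloc[0])
        p2 = n2.points("x0", X2["x0"].iloc[0])
        assert p1 == pytest.approx(p2, rel=1e-6)


class TestDiscrimination:
    def test_perfect_ordering_without_censoring_gives_one(self):
        time = pd.Series([1.0, 2, 3, 4, 5])
        event = pd.Series([1] * 5)
        scores = pd.Series([5.0, 4, 3, 2, 1])  # higher score = earlier death
        assert harrells_c(scores, time, event) == 1.0

    def test_toy_set_matches_all_pairs_count(self):
        time = [2.0, 4, 3, 5, 1]
        event = [1, 0, 1, 1, 1]
        scores = [0.9, 0.1, 0.5, 0.5, 0.7]
        got = harrells_c(pd.Series(scores), pd.Series(time), pd.Series(event))
        assert got == pytest.approx(
            harrells_c_bruteforce(scores, time, event), abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        time = pd.Series(rng.exponential(1, 500))
        event = pd.Series(np.ones(500, int))
        scores = pd.Series(rng.normal(size=500))
        c = harrells_c(scores, time, event)
        assert abs(c - 0.5) < 0.05

    def test_c_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        time = pd.Series(rng.exponential(1, 100))
        event = pd.Series(rng.integers(0, 2, 100))
        scores = pd.Series(rng.normal(size=100))
        a = harrells_c(scores, time, event)
        b = harrells_c(np.exp(3 * scores), time, event)
        assert a == pytest.approx(b, abs=1e-12)

    def test_auc_without_censoring_equals_binary_auc(self):
        rng = np.random.default_rng(7)
        X, t, e = simulate(400, [1.0], seed=7, censor=False)
        scores = X["x0"]
        horizon = float(np.median(t))
        res = model_discrimination(scores, t, e, horizon=horizon)
        binary = roc_auc_score((t <= horizon).astype(int), scores)
        assert res["auc"] == pytest.approx(binary, abs=0.01)


class TestCalibration:
    def test_well_specified_model_sits_on_diagonal(self):
        X, t, e = simulate(1000, [1.0, -0.5], seed=8)
        model = multivariate_cox(X, t, e)
        t0 = float(np.quantile(t, 0.4))
        pred = model.predict_survival(X, t0)
        tbl = calibration_table(pred, t, e, t0)
        gap = (tbl["mean_predicted"] - tbl["observed_km"]).abs().mean()
        assert gap < 0.05

    def test_constant_predictor_collapses_to_single_bin(self):
        t = pd.Series(np.arange(1.0, 21.0))
        e = pd.Series(np.ones(20, int))
        tbl = calibration_table(pd.Series(np.full(20, 0.7)), t, e, 5.0)
        assert len(tbl) == 1

    def test_miscalibrated_model_detected(self):
        X, t, e = simulate(1000, [1.5], seed=9)
        model = multivariate_cox(X, t, e)
        t0 = float(np.quantile(t, 0.4))
        good = calibration_table(model.predict_survival(X, t0), t, e, t0)
        bad_model = multivariate_cox(X, t, e)
        bad_model.summary["coef"] *= 0.3  # deliberately shrunk coefficients
        bad = calibration_table(bad_model.predict_survival(X, t0), t, e, t0)
        gap_good = (good["mean_predicted"] - good["observed_km"]).abs().mean()
        gap_bad = (bad["mean_predicted"] - bad["observed_km"]).abs().mean()
        assert gap_bad > gap_good
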