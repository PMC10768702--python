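"""Rating scales, PCA, forward-AIC regression, and ellipse tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from chronolux import perception as per


def _ratings(rows):
    return pd.DataFrame(rows, columns=["observer_id", "image_id", "category"])


class TestScales:
    def test_seven_point_chronology(self):
        s = per.SEVEN_POINT
        assert [s.score(c) for c in per.CHRONOLOGICAL_ORDER] == [1, 2, 3, 4, 5, 6, 7]
        assert s.score("sunset") == 5 and s.score("evening") == 6

    def test_four_point_merging(self):
        s = per.FOUR_POINT_MERGED
        assert s.score("sunrise") == s.score("morning") == 1
        assert s.score("noon") == s.score("afternoon") == 3
        assert s.score("evening") == s.score("sunset") == 5
        assert s.score("night") == 7

    def test_binary(self):
        assert per.BINARY.score("morning") == 0
        assert per.BINARY.score("evening") == 1
        assert per.BINARY.divisor == 1.0


class TestFilterObservers:
    @staticmethod
    def _catch_table(n_correct):
        rows = []
        for i in range(4):
            rows.append(("obs_a", f"catch{i}", "night" if i < n_correct else "noon"))
            rows.append(("obs_b", f"catch{i}", "night"))
        rows += [("obs_a", "img0", "morning"), ("obs_b", "img0", "evening")]
        return _ratings(rows)

    def test_perfect_observer_retained(self):
        out = per.filter_observers(
            self._catch_table(4), {f"catch{i}" for i in range(4)}, "night"
        )
        assert set(out["observer_id"]) == {"obs_a", "obs_b"}

    def test_below_threshold_removed(self):
        # 3/4 = 0.75 < 0.8
        out = per.filter_observers(
            self._catch_table(3), {f"catch{i}" for i in range(4)}, "night"
        )
        assert set(out["observer_id"]) == {"obs_b"}

    def test_empty_catch_set_warns(self, caplog):
        table = self._catch_table(0)
        with caplog.at_level("WARNING"):
            out = per.filter_observers(table, set(), "night")
        assert out.equals(table)
        assert any("empty catch set" in r.message for r in caplog.records)

    def test_observer_without_catch_trials_retained(self, caplog):
        table = _ratings(
            [("obs_a", "catch0", "night"), ("obs_a", "img0", "noon"),
             ("obs_c", "img0", "noon")]
        )
        with caplog.at_level("WARNING"):
            out = per.filter_observers(table, {"catch0"}, "night")
        assert "obs_c" in set(out["observer_id"])
        assert any("no catch trials" in r.message for r in caplog.records)


class TestScoreRatings:
    def test_unanimous_night(self):
        table = _ratings([(f"o{i}", "img0", "night") for i in range(5)])
        out = per.score_ratings(table, per.FOUR_POINT_MERGED)
        row = out.loc["img0"]
        assert row["mean_score"] == 7.0
        assert row["normalized_mean"] == pytest.approx(1.0)
        assert row["prop_night"] == 1.0
        assert row["categorical"] == "night"

    def test_merged_scale_mean(self):
        table = _ratings(
            [("o1", "img0", "sunrise"), ("o2", "img0", "morning"),
             ("o3", "img0", "night")]
        )
        row = per.score_ratings(table, per.FOUR_POINT_MERGED).loc["img0"]
        assert row["mean_score"] == pytest.approx(3.0)  # {1, 1, 7}
        # the mode pools merged categories: score 1 has two votes
        assert row["modal_score"] == 1
        assert row["categorical"] == "sunrise"
        assert not bool(row["mode_tied"])

    def test_binary_proportion(self):
        rows = [(f"o{i}", "img0", "evening" if i < 6 else "morning") for i in range(10)]
        row = per.score_ratings(_ratings(rows), per.BINARY).loc["img0"]
        assert row["mean_score"] == pytest.approx(0.6)
        assert row["prop_evening"] == pytest.approx(0.6)

    def test_proportions_sum_to_one(self, rng):
        cats = list(per.SEVEN_POINT.categories)
        rows = [
            (f"o{i}", f"img{j}", cats[rng.integers(len(cats))])
            for j in range(4)
            for i in range(11)
        ]
        out = per.score_ratings(_ratings(rows), per.SEVEN_POINT)
        props = out[[f"prop_{c}" for c in cats]].sum(axis=1).to_numpy()
        assert props == pytest.approx(np.ones(4))

    def test_unknown_category_rejected(self, caplog):
        table = _ratings([("o1", "img0", "midnight"), ("o2", "img0", "noon")])
        with caplog.at_level("WARNING"):
            out = per.score_ratings(table, per.SEVEN_POINT)
        assert out.loc["img0", "n_ratings"] == 1

    def test_mode_tie_breaks_chronologically(self):
        table = _ratings([("o1", "img0", "night"), ("o2", "img0", "noon")])
        row = per.score_ratings(table, per.SEVEN_POINT).loc["img0"]
        assert row["categorical"] == "noon"
        assert bool(row["mode_tied"])


class TestPCA:
    def test_eigenvalue_trace_conservation(self, rng):
        X = rng.standard_normal((50, 8))
        model = per.fit_pca(X)
        assert model.eigenvalues.sum() == pytest.approx(8.0, rel=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_two_correlated_variables_closed_form(self, rng):
        x = rng.standard_normal(500)
        X = np.column_stack([x, 2.0 * x + 1.0])  # perfectly correlated
        model = per.fit_pca(X)
        assert model.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_loadings_match_brute_force_eigendecomposition(self, rng):
        X = rng.standard_normal((10, 5))
        model = per.fit_pca(X)
        corr = np.corrcoef(X.T)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert model.eigenvalues == pytest.approx(evals, abs=1e-10)
        for j in range(5):
            dot = abs(evecs[:, j] @ model.loadings[:, j])
            assert dot == pytest.approx(1.0, abs=1e-10)

    def test_orthonormal_loadings(self, rng):
        model = per.fit_pca(rng.standard_normal((30, 6)))
        gram = model.loadings.T @ model.loadings
        assert gram == pytest.approx(np.eye(model.loadings.shape[1]), abs=1e-10)

    def test_sign_orientation_anchors(self, rng):
        n = 60
        lum = rng.uniform(0, 1, n)
        sat = rng.uniform(0, 1, n)
        X = pd.DataFrame(
            {
                "mean_luminance": lum,
                "lum_proxy": lum + 0.01 * rng.standard_normal(n),
                "mean_saturation": sat,
                "sat_proxy": sat + 0.01 * rng.standard_normal(n),
            }
        )
        model = per.fit_pca(X)
        names = list(model.feature_names)
        assert model.loadings[names.index("mean_luminance"), 0] < 0
        assert model.loadings[names.index("mean_saturation"), 1] < 0

    def test_projection_consistency(self, rng):
        X = rng.standard_normal((40, 6))
        model = per.fit_pca(X)
        pcs = model.transform(X, n_components=6)
        # feature-mean vector projects to the origin
        assert per.project(model, X.mean(axis=0)) == pytest.approx(
            np.zeros(model.n_retained), abs=1e-10
        )
        # training PC variances equal the eigenvalues
        assert pcs.var(axis=0, ddof=1) == pytest.approx(model.eigenvalues, abs=1e-10)

    def test_reconstruction_with_all_components(self, rng):
        X = rng.standard_normal((25, 5))
        model = per.fit_pca(X)
        Z = (X - model.means) / model.sds
        pcs = model.transform(X, n_components=5)
        assert pcs @ model.loadings.T == pytest.approx(Z, abs=1e-10)

    def test_constant_column_dropped_and_nan_imputed(self, caplog, rng):
        X = rng.standard_normal((20, 3))
        X[3, 1] = np.nan
        X = np.column_stack([X, np.full(20, 2.0)])
        with caplog.at_level("WARNING"):
            model = per.fit_pca(X, feature_names=("a", "b", "c", "const"))
        assert model.dropped_features == ("const",)
        assert model.n_imputed == 1

    def test_json_roundtrip(self, tmp_path, rng):
        X = rng.standard_normal((30, 4))
        model = per.fit_pca(X)
        model.to_json(tmp_path / "pca.json")
        back = per.PCAModel.from_json(tmp_path / "pca.json")
        assert np.array_equal(back.transform(X), model.transform(X))


class TestForwardAic:
    def test_tiny_fit_matches_hand_aic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([0.1, 1.2, 1.9, 3.2, 3.9])
        models, _ = per.forward_aic_regression(x[:, None], y)
        m = models[0]
        slope, intercept = np.polyfit(x, y, 1)
        rss = float(np.sum((y - (intercept + slope * x)) ** 2))
        assert m.intercept == pytest.approx(intercept, abs=1e-9)
        assert m.aic == pytest.approx(5 * np.log(rss / 5) + 2 * 2, abs=1e-9)

    def test_noise_predictor_penalty(self, rng):
        n = 2000
        x1 = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y = 1.0 + 0.5 * x1 + 0.01 * rng.standard_normal(n)
        models, _ = per.forward_aic_regression(np.column_stack([x1, noise]), y)
        # the saturated fit gains ~nothing; AIC rises by about the 2-unit penalty
        assert models[1].aic - models[0].aic == pytest.approx(2.0, abs=1.5)

    def test_selection_excludes_noise_components(self, rng):
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            X = rng.standard_normal((100, 5))
            y = 0.5 + 0.1 * X[:, 0] + 0.01 * rng.standard_normal(100)
            _, sel = per.forward_aic_regression(X, y)
            if "PC1" in sel.predictors and "PC4" not in sel.predictors and (
                "PC5" not in sel.predictors
            ):
                hits += 1
        assert hits / n_rep >= 0.95

    def test_akaike_weights_normalize_and_select_minimum(self, rng):
        # strong signal on the first two components: the forward stop and
        # the global AIC minimum coincide
        X = rng.standard_normal((50, 3))
        y = 0.2 + 0.3 * X[:, 0] - 0.1 * X[:, 1] + 0.05 * rng.standard_normal(50)
        models, sel = per.forward_aic_regression(X, y)
        weights = np.array([m.akaike_weight for m in models])
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert sel.predictors == ("PC1", "PC2")
        assert sel.aic == min(m.aic for m in models)
        assert sel.akaike_weight == max(weights)

    def test_selection_invariant_to_affine_response_rescale(self, rng):
        X = rng.standard_normal((80, 4))
        y = 0.3 + 0.2 * X[:, 0] + 0.1 * X[:, 1] + 0.02 * rng.standard_normal(80)
        _, sel_a = per.forward_aic_regression(X, y)
        _, sel_b = per.forward_aic_regression(X, 7.0 * y - 3.0)
        assert sel_a.predictors == sel_b.predictors

    def test_rank_deficiency_raises(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(ValueError):
            per.forward_aic_regression(np.column_stack([x, x]), x)


class TestPublishedModel:
    def test_origin_gives_intercept(self):
        assert per.predict_time_of_day(0.0, 0.0) == 0.583

    def test_unit_steps(self):
        assert per.predict_time_of_day(1.0, 0.0) == pytest.approx(0.617, abs=1e-12)
        assert per.predict_time_of_day(0.0, 1.0) == pytest.approx(0.600, abs=1e-12)
        assert per.predict_time_of_day(-1.0, -1.0) == pytest.approx(0.532, abs=1e-12)

    def test_frozen_metadata(self):
        m = per.load_published_model()
        assert m.predictors == ("PC1", "PC2")
        assert m.r2 == pytest.approx(0.760)


class TestCovarianceEllipse:
    def test_isotropic_radius_matches_chi2_quantile(self, rng):
        pts = rng.standard_normal((20000, 2))
        ell = per.covariance_ellipse(pts, coverage=0.68)
        expected = np.sqrt(chi2.ppf(0.68, 2))  # ~1.5096 per unit SD
        sd = pts.std(axis=0, ddof=1).mean()
        assert ell.semi_axes == pytest.approx([expected * sd] * 2, rel=0.05)

    def test_rotation_equivariance(self, rng):
        pts = rng.standard_normal((200, 2)) * np.array([3.0, 0.5])
        theta = np.radians(30.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = per.covariance_ellipse(pts)
        b = per.covariance_ellipse(pts @ R.T)
        diff = (b.angle_deg - a.angle_deg - 30.0) % 180.0
        assert min(diff, 180.0 - diff) < 1e-6
        assert b.semi_axes == pytest.approx(a.semi_axes, rel=1e-9)

    def test_monte_carlo_coverage(self, rng):
        pts = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.7], [0.7, 1.0]], 10000)
        ell = per.covariance_ellipse(pts, coverage=0.68)
        assert ell.contains(pts).mean() == pytest.approx(0.68, abs=0.03)

    def test_collinear_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert per.covariance_ellipse(pts).degenerate


class TestClassifyMorningEvening:
    def test_threshold_labels(self):
        summary = pd.DataFrame(
            {"mean_score": [0.2, 0.95, 0.5]},
            index=["a", "b", "c"],
        )
        labels = per.classify_morning_evening(summary)
        assert labels["a"] == "morning"
        assert labels["b"] == "evening"
        assert labels["c"] == "tie"
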