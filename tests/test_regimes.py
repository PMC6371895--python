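"""Imputation, clustering, screening, and tree-ensemble extrapolation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from streamclass.errors import (
    ConfigError,
    DegenerateInputError,
    ImputationError,
    InsufficientDataError,
)
from streamclass.regimes import (
    cluster_ward,
    compute_expected_probability,
    elbow_candidates,
    fit_class_extrapolator,
    fit_temperature_regressor,
    impute_missing,
    nesting_map,
    predict_class_membership,
    reduce_dimensions,
    screen_reference_sites,
    select_cluster_counts,
    summarize_assignment_probabilities,
    within_cluster_sse,
)
from streamclass.synth import generate_gage_panel


class TestImputation:
    def test_identity_on_complete_data(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert impute_missing(df).equals(df)

    def test_single_donor_value_imputed(self):
        df = pd.DataFrame({"a": [5.0, 5.0, 5.0, np.nan],
                           "b": [1.0, 2.0, 3.0, 4.0]})
        out = impute_missing(df, seed=0)
        assert out["a"].iloc[3] == 5.0

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ImputationError):
            impute_missing(df)

    def test_beats_column_mean_fill_on_correlated_panel(self):
        """2% MCAR on correlated columns: PMM RMSE < mean-fill RMSE."""
        rng = np.random.default_rng(31)
        n = 400
        z = rng.normal(0, 2, n)
        full = pd.DataFrame({
            "x1": z + rng.normal(0, 0.3, n),
            "x2": -z + rng.normal(0, 0.3, n),
            "x3": 2 * z + rng.normal(0, 0.3, n),
        })
        holes = full.copy()
        mask = rng.random(full.shape) < 0.02
        holes = holes.mask(mask)
        imputed = impute_missing(holes, seed=1)
        err_pmm = ((imputed - full)[mask.astype(bool)] ** 2).sum().sum()
        meanfill = holes.fillna(holes.mean())
        err_mean = ((meanfill - full)[mask.astype(bool)] ** 2).sum().sum()
        assert err_pmm < err_mean

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        df = df.mask(rng.random(df.shape) < 0.1)
        assert impute_missing(df, seed=9).equals(impute_missing(df, seed=9))


class TestPCA:
    def test_rank_two_data_reconstructed_exactly(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(40, 2)) @ basis
        scores, frac = reduce_dimensions(X, 2)
        assert frac.sum() == pytest.approx(1.0)
        cov = np.cov(scores.T)
        assert abs(cov[0, 1]) < 1e-8

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            reduce_dimensions(np.ones((10, 3)), 2)

    def test_variance_fractions_sorted(self):
        rng = np.random.default_rng(1)
        _, frac = reduce_dimensions(rng.normal(size=(60, 5)), 4)
        assert all(b <= a for a, b in zip(frac, frac[1:])) and frac.sum() <= 1


def exhaustive_min_sse_partition(X, k):
    """Independent oracle: minimal within-cluster SSE over all set
    partitions of the rows into k non-empty clusters."""
    n = len(X)
    best, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        labels = np.array(labels)
        sse = sum(
            float(((X[labels == c] - X[labels == c].mean(0)) ** 2).sum())
            for c in range(k)
        )
        if sse < best - 1e-12:
            best, best_labels = sse, labels
    return best, best_labels


class TestWard:
    def test_two_tight_pairs(self):
        X = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])
        sol = cluster_ward(X, [2])[0]
        assert sol.labels[0] == sol.labels[1] != sol.labels[2]
        assert sol.labels[2] == sol.labels[3]

    def test_duplicate_points_merge_at_zero_height(self):
        X = np.zeros((5, 2))
        sol = cluster_ward(X, [1])[0]
        assert np.allclose(sol.linkage_matrix[:, 2], 0.0)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_ward(np.zeros((3, 2)), [4])

    def test_cut_equals_exhaustive_min_sse_partition(self):
        """For separated draws with n <= 8, the Ward cut attains the global
        minimum-SSE partition found by enumerating all partitions."""
        rng = np.random.default_rng(2024)
        for _ in range(10):
            k = int(rng.integers(2, 4))
            centers = rng.normal(0, 8, (k, 2))
            X = np.vstack([c + rng.normal(0, 0.5, (rng.integers(2, 4), 2))
                           for c in centers])[:8]
            sol = cluster_ward(X, [k])[0]
            ward_sse = sum(
                float(((X[sol.labels == c] - X[sol.labels == c].mean(0)) ** 2).sum())
                for c in np.unique(sol.labels))
            best, _ = exhaustive_min_sse_partition(X, k)
            assert ward_sse == pytest.approx(best, abs=1e-8)

    def test_cuts_are_nested(self, generated_network):
        panel = generate_gage_panel(generated_network, n_sites=120, seed=4)
        X = panel[panel.attrs["score_columns"]].to_numpy()
        sols = cluster_ward(X, [2, 4, 8])
        for coarse, fine in zip(sols, sols[1:]):
            assert fine.parent_map is not None
            assert nesting_map(coarse.labels, fine.labels) == fine.parent_map

    def test_sse_from_heights_matches_direct_computation(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        sol = cluster_ward(X, [4])[0]
        sse = within_cluster_sse(sol.linkage_matrix, 30)
        direct = sum(
            float(((X[sol.labels == c] - X[sol.labels == c].mean(0)) ** 2).sum())
            for c in np.unique(sol.labels))
        assert sse[4] == pytest.approx(direct, rel=1e-9)
        assert sse[1] == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)


class TestClusterCountSelection:
    def test_sharp_elbow_detected_first(self):
        sse = {1: 100.0, 2: 90.0, 3: 80.0, 4: 70.0, 5: 20.0, 6: 15.0, 7: 11.0}
        # curvature peaks at k=5 (the drop happens going 4 -> 5)
        assert elbow_candidates(sse)[0] == 5

    def test_linear_decline_has_no_candidates(self):
        sse = {k: 100.0 - 10.0 * k for k in range(1, 9)}
        assert elbow_candidates(sse) == []

    def test_true_k_among_top_candidates(self, generated_network):
        panel = generate_gage_panel(generated_network, n_sites=300,
                                    k_clusters=4, separation=6.0, seed=6)
        X = panel[panel.attrs["score_columns"]].to_numpy()
        sol = cluster_ward(X, [2])[0]
        cands = select_cluster_counts(sol.linkage_matrix, k_max=10)
        assert 4 in cands[:2]


class TestScreening:
    def _site(self, **kw):
        base = {"site_id": "s", "disturbance": "low", "dor_percent": 2.0,
                "rec_start": 2000, "rec_end": 2005, "jul_aug_consec_days": 62}
        base.update(kw)
        return pd.DataFrame([base])

    def test_reference_site_kept(self):
        assert len(screen_reference_sites(self._site())) == 1

    @pytest.mark.parametrize("kw", [
        {"dor_percent": 4.0},                    # strict inequality
        {"disturbance": "moderate"},
        {"jul_aug_consec_days": 59},
        {"rec_start": 1994},
        {"rec_end": 2016},
        {"dor_percent": np.nan},                 # missing attribute
    ])
    def test_rejections(self, kw):
        kept = screen_reference_sites(self._site(**kw))
        assert len(kept) == 0
        assert len(kept.attrs["screen_log"]) == 1

    def test_window_bounds_inclusive(self):
        assert len(screen_reference_sites(
            self._site(rec_start=1995, rec_end=2015))) == 1


@pytest.fixture(scope="module")
def separable(generated_network):
    panel = generate_gage_panel(generated_network, n_sites=300,
                                k_clusters=4, separation=8.0, seed=13)
    cols = [c for c in generated_network.reaches.columns
            if c.startswith("hydro_cov_")]
    feats = panel[["comid"]].merge(
        generated_network.reaches[["comid"] + cols], on="comid")[cols]
    return feats, panel["true_label"].to_numpy(), generated_network, cols


class TestExtrapolation:
    def test_separable_panel_low_oob(self, separable):
        feats, y, _, _ = separable
        model = fit_class_extrapolator(feats, y, seed=1)
        assert model.oob_error <= 0.05

    def test_permuted_labels_are_chance_level(self, separable):
        feats, y, _, _ = separable
        rng = np.random.default_rng(8)
        yp = rng.permutation(y)
        model = fit_class_extrapolator(feats, yp, seed=1)
        k = len(np.unique(y))
        p = 1 - 1 / k
        sd = np.sqrt(p * (1 - p) / len(y))
        assert abs(model.oob_error - p) < 5 * sd

    def test_importances_normalized_to_unit_interval(self, separable):
        feats, y, _, _ = separable
        model = fit_class_extrapolator(feats, y, seed=1)
        norm = model.normalized_importances
        assert norm.min() >= 0 and norm.max() == 1.0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        with pytest.raises(DegenerateInputError):
            fit_class_extrapolator(X, np.ones(10, dtype=int))

    def test_small_class_rejected(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = np.array([1] * 8 + [2] * 2)
        with pytest.raises(InsufficientDataError):
            fit_class_extrapolator(X, y)

    def test_vote_fractions_sum_to_one(self, separable):
        feats, y, net, cols = separable
        model = fit_class_extrapolator(feats, y, seed=1)
        assign = predict_class_membership(model, net.reaches[cols],
                                          comids=net.reaches["comid"])
        probs = assign[[c for c in assign.columns if c.startswith("prob_")
                        and c != "prob_max"]]
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (assign["label"] != "unclassified").all()

    def test_missing_features_yield_unclassified(self, separable):
        feats, y, net, cols = separable
        model = fit_class_extrapolator(feats, y, seed=1)
        X = net.reaches[cols].copy()
        X.iloc[0, 0] = np.nan
        assign = predict_class_membership(model, X)
        assert assign["label"].iloc[0] == "unclassified"
        assert np.isnan(assign["prob_max"].iloc[0])

    def test_extrapolated_reach_labels_match_ground_truth(self, separable):
        feats, y, net, cols = separable
        model = fit_class_extrapolator(feats, y, seed=1)
        assign = predict_class_membership(model, net.reaches[cols])
        truth = net.reaches["true_hydro_class"].to_numpy()
        acc = (assign["label"].to_numpy() == truth).mean()
        assert acc >= 0.9


class TestExpectedProbability:
    @pytest.mark.parametrize("k, expected", [
        (1, 1.0), (2, 0.5), (4, 0.25), (6, 0.17), (8, 0.13), (15, 0.07),
        (30, 0.03),
    ])
    def test_one_over_k_half_up(self, k, expected):
        assert compute_expected_probability(k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            compute_expected_probability(0)


class TestTemperatureRegression:
    def test_qwsa_guard(self):
        df = pd.DataFrame({"qwsa": [1.0] * 10, "x": range(10),
                           "july_august_temp": range(10)})
        with pytest.raises(ConfigError):
            fit_temperature_regressor(df, ["qwsa", "x"])

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=40),
                           "july_august_temp": 15.0})
        model = fit_temperature_regressor(df, ["x"], seed=2)
        assert np.allclose(model.predict(df), 15.0)

    def test_noiseless_smooth_target_high_oob_r2(self):
        rng = np.random.default_rng(44)
        n = 500
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        df = pd.DataFrame({
            "x1": x1, "x2": x2,
            "july_august_temp": 10 + 8 * x1 + 5 * x2,
        })
        model = fit_temperature_regressor(df, ["x1", "x2"], seed=3)
        assert model.oob_r2 >= 0.9


class TestSummaries:
    def test_probability_summary_table(self):
        assign = pd.DataFrame({"prob_max": [0.7]})
        rows = summarize_assignment_probabilities([
            {"solution": "W2", "k": 2, "n_obs": 10, "oob_error": 0.049,
             "assignment": assign}])
        row = rows.iloc[0]
        assert row["median_prob"] == 0.7
        assert row["accuracy_pct"] + row["oob_error_pct"] == 100.0
        assert row["expected_prob"] == 0.5
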