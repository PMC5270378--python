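import numpy as np
import pandas as pd
import pytest

from plrwave import (
    AMPLITUDE_ONLY,
    CohortSpec,
    DataError,
    ParameterError,
    build_feature_rows,
    condition_distances,
    fe_vector,
    feature_importance,
    proximity_cluster,
    rf_classify,
    simulate_cohort,
    weight_sweep,
)
from plrwave.classify import DEFAULT_W_GRID, rf_proximity
from plrwave.distances import FE_COMPONENTS
from plrwave.features import compute_fd, shape_vector
from plrwave.io import CONDITIONS, analysis_window


def planted_rows(rng, n_per_class=12, shift=2.0, informative="r10-b10"):
    """Feature rows where only one FE component separates the classes."""
    rows = []
    for label in ("H", "D"):
        for i in range(n_per_class):
            feats = dict(zip(FE_COMPONENTS, rng.normal(1.0, 0.3, size=6)))
            if label == "D":
                feats[informative] += shift
            rows.append(
                {"subject": f"{label}{i}", "eye": "left", "label": label, "w": 1.0, **feats}
            )
    return pd.DataFrame(rows)


class TestBuildFeatureRows:
    def test_paper_scale_cohort_yields_24_rows_of_6_features(self, default_rows):
        assert len(default_rows) == 24
        assert all(c in default_rows.columns for c in FE_COMPONENTS)
        assert default_rows["label"].value_counts().to_dict() == {
            "H": 12, "N": 6, "D": 6,
        }

    def test_zero_weight_rows_equal_shape_only_distances(self, default_cohort):
        rows = build_feature_rows(default_cohort, w=0.0)
        sid, eye = rows.iloc[0]["subject"], rows.iloc[0]["eye"]
        shapes = {
            c: shape_vector(
                compute_fd(analysis_window(default_cohort.get(sid, eye, c)))
            )
            for c in CONDITIONS
        }
        expected = fe_vector(condition_distances(shapes))
        np.testing.assert_allclose(
            rows.iloc[0][list(FE_COMPONENTS)].to_numpy(dtype=float), expected
        )

    def test_rebuilding_is_deterministic(self, default_cohort):
        a = build_feature_rows(default_cohort, w=1.5)
        b = build_feature_rows(default_cohort, w=1.5)
        pd.testing.assert_frame_equal(a, b)

    def test_incomplete_subject_reported_with_missing_pairs(self, default_cohort):
        import copy

        rs = copy.deepcopy(default_cohort)
        del rs.records[("H01", "left", "b100")]
        with pytest.raises(DataError, match=r"H01.*b100"):
            build_feature_rows(rs, w=1.0)

    def test_amplitude_only_rows_use_fd0_distances_alone(self, default_cohort):
        rows = build_feature_rows(default_cohort, w=AMPLITUDE_ONLY)
        assert len(rows) == 24
        assert np.isinf(rows["w"]).all()


class TestRFClassify:
    def test_separable_cohort_has_low_two_class_errors(self, default_rows):
        report = rf_classify(default_rows, scheme="two_class", seed=1)
        assert report.class_error_mean["D"] < 0.15
        assert report.class_error_mean["HN"] < 0.15

    def test_contingency_rows_sum_to_tested_counts(self, default_rows):
        report = rf_classify(default_rows, scheme="three_class", seed=2)
        # stratified 1/3 test split of 24 eyes over `repeats` repeats
        assert report.contingency.to_numpy().sum() == 8 * report.repeats
        for c in report.classes:
            row = report.contingency.loc[c]
            off_diag = row.sum() - report.contingency.loc[c, c]
            assert 0 <= off_diag <= row.sum()

    def test_reproducible_from_seed(self, default_rows):
        a = rf_classify(default_rows, seed=7, n_trees=50, repeats=3)
        b = rf_classify(default_rows, seed=7, n_trees=50, repeats=3)
        pd.testing.assert_frame_equal(a.contingency, b.contingency)
        pd.testing.assert_series_equal(a.class_error_mean, b.class_error_mean)

    def test_permuted_labels_score_near_chance(self, default_rows):
        # under the permutation null the forest carries no signal; mean
        # error should sit near the chance rate for the class mix
        rng = np.random.default_rng(0)
        y = default_rows["label"].to_numpy()
        priors = pd.Series(y).value_counts(normalize=True)
        p_hn = priors["H"] + priors["N"]
        chance = 1.0 - (p_hn**2 + priors["D"] ** 2)
        errs = []
        for _ in range(20):
            rows = default_rows.copy()
            rows["label"] = rng.permutation(y)
            if rows["label"].map({"H": "HN", "N": "HN", "D": "D"}).nunique() < 2:
                continue
            rep = rf_classify(rows, scheme="two_class", seed=3, n_trees=100, repeats=3)
            errs.append(rep.overall_error_mean)
        assert abs(np.mean(errs) - chance) <= 0.15

    def test_single_class_rejected(self, default_rows):
        rows = default_rows[default_rows.label == "H"]
        with pytest.raises(ParameterError):
            rf_classify(rows, scheme="three_class")


class TestWeightSweep:
    def test_single_point_grid_equals_direct_call(self, default_cohort):
        sweep = weight_sweep(
            default_cohort, grid=(0.0,), seed=4, n_trees=50, repeats=3
        )
        assert list(sweep.reports) == [0.0]
        direct = rf_classify(
            build_feature_rows(default_cohort, w=0.0), seed=4, n_trees=50, repeats=3
        )
        assert sweep.reports[0.0].overall_error_mean == direct.overall_error_mean
        pd.testing.assert_frame_equal(sweep.reports[0.0].contingency, direct.contingency)

    def test_same_seed_gives_identical_sweep(self, default_cohort):
        kw = dict(grid=(0.0, 1.5), seed=5, n_trees=50, repeats=3)
        a = weight_sweep(default_cohort, **kw)
        b = weight_sweep(default_cohort, **kw)
        for w in kw["grid"]:
            assert a.reports[w].overall_error_mean == b.reports[w].overall_error_mean

    def test_fusion_helps_when_shape_and_amplitude_both_carry_signal(self):
        # a noisy cohort with mild effects: neither shape-only (w=0) nor
        # amplitude-only should beat the best intermediate fusion weight
        spec = CohortSpec(
            seed=21,
            noise_sd=0.30,
            disease_amplitude_reduction=0.15,
            disease_sustain_reduction=0.10,
        )
        rs = simulate_cohort(spec)
        sweep = weight_sweep(rs, scheme="two_class", seed=6, n_trees=200, repeats=5)
        errors = {w: r.overall_error_mean for w, r in sweep.reports.items()}
        intermediate = [w for w in DEFAULT_W_GRID if 0 < w < np.inf]
        best_mid = min(errors[w] for w in intermediate)
        assert best_mid <= errors[0.0]
        assert best_mid <= errors[AMPLITUDE_ONLY]
        assert sweep.best_w in errors


class TestFeatureImportance:
    def test_planted_informative_component_ranks_first(self):
        rng = np.random.default_rng(10)
        wins = 0
        for _ in range(20):
            rows = planted_rows(rng)
            imp = feature_importance(rows, scheme="two_class", seed=1, n_trees=200)
            if imp.sort_values("importance_mean").iloc[-1]["feature"] == "r10-b10":
                wins += 1
        assert wins >= 18  # >= 90% of replicates

    def test_null_rows_have_near_zero_importances(self):
        rng = np.random.default_rng(11)
        means = []
        for _ in range(10):
            rows = planted_rows(rng, shift=0.0)
            imp = feature_importance(rows, scheme="two_class", seed=1, n_trees=200)
            means.append(imp["importance_mean"].to_numpy())
        np.testing.assert_allclose(np.mean(means, axis=0), 0.0, atol=0.05)

    def test_output_schema_has_six_rows_in_fe_order(self, default_rows):
        imp = feature_importance(default_rows, seed=0, n_trees=50)
        assert imp["feature"].tolist() == list(FE_COMPONENTS)


class TestProximityClustering:
    def test_proximity_matrix_is_symmetric_with_unit_diagonal(self, default_rows):
        prox = rf_proximity(default_rows, seed=0, n_trees=100)
        np.testing.assert_allclose(prox, prox.T)
        np.testing.assert_allclose(np.diag(prox), 1.0)
        assert np.all((prox >= 0) & (prox <= 1))

    def test_same_seed_gives_identical_tree(self, default_rows):
        a = proximity_cluster(default_rows, seed=3, n_trees=100)
        b = proximity_cluster(default_rows, seed=3, n_trees=100)
        np.testing.assert_array_equal(a.linkage_matrix, b.linkage_matrix)
        assert a.labels == b.labels

    def test_k2_cut_separates_diseased_from_healthy_eyes(self):
        separated = 0
        total = 0
        for rep in range(20):
            rs = simulate_cohort(CohortSpec(seed=400 + rep))
            rows = build_feature_rows(rs, w=1.5)
            dend = proximity_cluster(rows, seed=rep, n_trees=200)
            cut = dend.cut(2)
            labels = rows["label"].to_numpy()
            d_cluster = pd.Series(cut[labels == "D"]).mode()[0]
            h_cluster = pd.Series(cut[labels == "H"]).mode()[0]
            if d_cluster != h_cluster:
                sep = np.mean(cut[labels == "D"] != h_cluster)
                separated += sep >= 0.8
            total += 1
        assert separated / total >= 0.8
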