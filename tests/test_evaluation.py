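import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrnet import (
    NETWORK_FEATURE_COLUMNS,
    PipelineConfig,
    SimulationConfig,
    SmoteConfig,
    aggregate_report,
    all_features,
    assemble_features,
    concat_one_hot,
    crossval_auroc,
    filter_adrs,
    fit_pca,
    lr_feature_pvalues,
    normalize_weights,
    project_bipartite,
    rank_auroc,
    run_evaluation,
    simulate_dataset,
    transform_pca,
)

FAST = PipelineConfig(
    min_frequency=10,
    n_folds=10,
    feature_ladder=("", "DW"),
    classifiers=("LR",),
    smote=SmoteConfig(seed=0),
    seed=0,
)


class TestFilterAdrs:
    def test_worked_incidence_threshold_three(self, worked_incidence):
        assert filter_adrs(worked_incidence, 3) == ["a1"]

    def test_zero_threshold_keeps_all(self, worked_incidence):
        assert filter_adrs(worked_incidence, 0) == ["a1", "a2", "a3", "a4"]

    def test_threshold_above_drug_count_empty(self, worked_incidence):
        assert filter_adrs(worked_incidence, 5) == []


class TestAssembleFeatures:
    @pytest.fixture
    def frames(self, worked_graph):
        net = all_features(worked_graph)
        pca = pd.DataFrame(
            np.arange(8, dtype=float).reshape(4, 2),
            index=worked_graph.node_ids,
            columns=["pc01", "pc02"],
        )
        return pca, net

    def test_empty_letters_is_baseline(self, frames):
        pca, net = frames
        out = assemble_features(pca, net, "")
        assert list(out.columns) == ["pc01", "pc02"]

    def test_dw_appends_degree_and_weighted_degree(self, frames):
        pca, net = frames
        out = assemble_features(pca, net, "DW")
        assert list(out.columns) == ["pc01", "pc02", "degree", "weighted_degree"]
        np.testing.assert_allclose(out["weighted_degree"], net["weighted_degree"])

    def test_all_ten_letters_give_full_width(self, frames):
        pca, net = frames
        out = assemble_features(pca, net, "DWEOCBAHTP")
        assert out.shape[1] == 12
        assert list(out.columns[2:]) == list(NETWORK_FEATURE_COLUMNS)

    def test_unknown_letter_rejected(self, frames):
        pca, net = frames
        with pytest.raises(ValueError, match="unknown"):
            assemble_features(pca, net, "DX")


class TestRankAuroc:
    def test_true_labels_as_scores_is_one(self):
        y = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
        assert rank_auroc(y.astype(float), y) == 1.0

    def test_constant_scores_is_half_by_tie_convention(self):
        y = np.r_[np.ones(4, dtype=int), np.zeros(6, dtype=int)]
        assert rank_auroc(np.zeros(10), y) == pytest.approx(0.5)

    def test_matches_brute_force_pairwise_comparison(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(5, 40)
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 1, 0
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            expected = _brute_force_auroc(scores, y)
            assert rank_auroc(scores, y) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.normal(size=50)
        assert rank_auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auroc(np.arange(4.0), np.ones(4, dtype=int))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_invariant_under_monotone_transformation(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, size=n)
        y[0], y[1] = 0, 1
        s = rng.normal(size=n)
        base = rank_auroc(s, y)
        assert rank_auroc(3 * s + 7, y) == pytest.approx(base, abs=1e-12)
        assert rank_auroc(np.exp(s), y) == pytest.approx(base, abs=1e-12)


def _brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(
        n_drugs=80, n_adrs=40, block_widths=(10, 4, 8, 4, 10, 4), n_latent=8, seed=21
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def small_xy(small_dataset):
    ds = small_dataset
    onehot = concat_one_hot(ds.features).to_numpy(float)
    model = fit_pca(onehot, 5)
    pca = transform_pca(model, onehot, ds.incidence.drug_ids)
    net = all_features(normalize_weights(project_bipartite(ds.incidence)))
    x = assemble_features(pca, net, "DW").to_numpy(float)
    eligible = filter_adrs(ds.incidence, 10)
    j = ds.incidence.adr_ids.index(eligible[0])
    y = ds.incidence.values[:, j].astype(int)
    return x, y


class TestCrossval:
    def test_reproducible_under_fixed_seed(self, small_xy):
        x, y = small_xy
        a = crossval_auroc(x, y, "LR", FAST)
        b = crossval_auroc(x, y, "LR", FAST)
        assert a.fold_aurocs == b.fold_aurocs
        assert a.mean_accuracy == b.mean_accuracy

    def test_seed_changes_fold_assignment(self, small_xy):
        x, y = small_xy
        a = crossval_auroc(x, y, "LR", FAST)
        b = crossval_auroc(x, y, "LR", dataclasses.replace(FAST, seed=99))
        assert a.fold_aurocs != b.fold_aurocs

    def test_metrics_within_unit_interval(self, small_xy):
        x, y = small_xy
        res = crossval_auroc(x, y, "LR", FAST)
        assert 0.0 <= res.mean_auroc <= 1.0
        assert 0.0 <= res.mean_accuracy <= 1.0
        assert len(res.fold_aurocs) + res.single_class_folds + res.failed_folds == FAST.n_folds

    @pytest.mark.parametrize("name", ["LR", "DT", "XGB", "RF", "SVM", "KNN", "ANN"])
    def test_every_classifier_completes_all_folds(self, small_xy, name):
        x, y = small_xy
        cfg = dataclasses.replace(FAST, n_folds=4, min_frequency=4)
        res = crossval_auroc(x, y, name, cfg)
        assert res.failed_folds == 0
        assert 0.0 <= res.mean_auroc <= 1.0

    def test_single_class_overall_rejected(self, small_xy):
        x, _ = small_xy
        with pytest.raises(ValueError, match="both classes"):
            crossval_auroc(x, np.zeros(len(x), dtype=int), "LR", FAST)

    def test_smote_isolation_test_folds_contain_no_synthetic_rows(self, small_xy):
        """Synthetic rows are appended to the training portion only, so
        every test-fold row must be one of the original rows."""
        from sklearn.model_selection import KFold

        x, y = small_xy
        originals = {tuple(row) for row in x}
        kf = KFold(n_splits=FAST.n_folds, shuffle=True, random_state=FAST.seed)
        for _, te in kf.split(x):
            for row in x[te]:
                assert tuple(row) in originals


class TestPvalues:
    def test_perfect_predictor_has_tiny_pvalue_or_is_flagged(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
        x = pd.DataFrame(
            {"signal": y + 0.05 * rng.normal(size=n), "noise": rng.normal(size=n)}
        )
        pvals = lr_feature_pvalues(x, y, FAST)
        if pvals is not None:
            assert pvals["signal"] < 0.01
            assert pvals["noise"] > pvals["signal"]

    def test_pure_noise_pvalues_approximately_uniform(self):
        """Monte-Carlo calibration: for a noise feature the fraction of
        p-values below 0.05 should be near 0.05."""
        rng = np.random.default_rng(4)
        n, reps = 500, 200
        hits = 0
        used = 0
        for _ in range(reps):
            y = rng.integers(0, 2, size=n)
            x = pd.DataFrame({"noise": rng.normal(size=n)})
            pvals = lr_feature_pvalues(x, y, FAST)
            if pvals is None:
                continue
            used += 1
            hits += pvals["noise"] < 0.05
        assert used > reps * 0.9
        assert abs(hits / used - 0.05) < 0.03

    def test_likelihood_ratio_option_agrees_in_order_of_magnitude(self):
        rng = np.random.default_rng(5)
        n = 300
        y = rng.integers(0, 2, size=n)
        x = pd.DataFrame(
            {"weak": y * 0.5 + rng.normal(size=n), "noise": rng.normal(size=n)}
        )
        wald = lr_feature_pvalues(x, y, FAST, method="wald")
        lrt = lr_feature_pvalues(x, y, FAST, method="lr")
        assert wald is not None and lrt is not None
        assert (wald["weak"] < 0.05) == (lrt["weak"] < 0.05)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            lr_feature_pvalues(pd.DataFrame({"a": [0.0, 1.0]}), np.array([0, 1]), FAST, method="bad")


@pytest.fixture(scope="module")
def report(small_dataset):
    cfg = PipelineConfig(
        min_frequency=10,
        feature_ladder=("", "DW"),
        classifiers=("LR", "DT"),
        seed=0,
    )
    onehot = concat_one_hot(small_dataset.features)
    return run_evaluation(small_dataset.incidence, onehot, cfg)


class TestAggregateAndPipeline:
    def test_ladder_table_shape_and_bounds(self, report):
        assert list(report.ladder_table.columns) == ["baseline", "baseline+DW"]
        assert set(report.ladder_table.index) == {"LR", "DT"}
        vals = report.ladder_table.to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))

    def test_improvement_column_is_with_minus_without(self, report):
        r = report.adr_ranking
        np.testing.assert_allclose(
            r["improvement"], r["auroc_with_network"] - r["auroc_without_network"], atol=1e-12
        )
        assert r["auroc_with_network"].is_monotonic_decreasing

    def test_correlation_matrix_symmetric_unit_diagonal(self, report):
        c = report.feature_correlation
        assert list(c.columns) == list(NETWORK_FEATURE_COLUMNS)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        np.testing.assert_allclose(c.to_numpy(), c.to_numpy().T, atol=1e-12)

    def test_pvalue_summary_within_unit_interval(self, report):
        s = report.pvalue_summary
        if len(s):
            assert ((s["mean_p_value"] >= 0) & (s["mean_p_value"] <= 1)).all()

    def test_single_adr_single_classifier_report_shape(self, small_dataset):
        results = pd.DataFrame(
            [
                {"adr_id": "a", "classifier": "LR", "feature_set": "", "mean_auroc": 0.6,
                 "mean_accuracy": 0.9},
                {"adr_id": "a", "classifier": "LR", "feature_set": "DW", "mean_auroc": 0.8,
                 "mean_accuracy": 0.92},
            ]
        )
        net = all_features(
            normalize_weights(project_bipartite(small_dataset.incidence))
        )
        rep = aggregate_report(results, pd.DataFrame(), net, ladder=("", "DW"))
        assert rep.ladder_table.shape == (1, 2)
        assert rep.adr_ranking.loc[0, "improvement"] == pytest.approx(0.2)

    def test_report_written_to_disk(self, report, tmp_path):
        from adrnet import write_report

        write_report(report, tmp_path)
        assert (tmp_path / "ladder_auroc.tsv").exists()
        assert (tmp_path / "report.json").exists()
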