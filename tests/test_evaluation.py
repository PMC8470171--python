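"""Evaluation protocol: splits, per-class accuracy, rank tests, summaries."""

import numpy as np
import pandas as pd
import pytest

from ojiptox.evaluation import (
    RunResult,
    TaskDefinition,
    kruskal_wallis,
    per_class_accuracy,
    prepare_inputs,
    render_reports,
    run_experiment,
    select_best_model,
    select_median_model,
    split,
    summarize,
)
from ojiptox.models.base import ModelSpec


def manual_kruskal_h(groups):
    """Independent oracle: rank-sum H with tie correction, computed by hand."""
    flat = np.concatenate(groups)
    order = np.argsort(flat, kind="mergesort")
    ranks = np.empty(len(flat))
    i = 0
    sorted_vals = flat[order]
    while i < len(flat):
        j = i
        while j < len(flat) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    n = len(flat)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(flat, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


class TestSplit:
    def test_printed_design_arithmetic(self):
        labels = np.repeat(np.arange(13), 150)  # 1950 samples
        train, test = split(labels, 0.2, seed=0)
        assert len(test) == 390
        assert len(train) == 1560

    def test_partition_exhaustive_and_disjoint(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        train, test = split(labels, 0.25, seed=3)
        assert len(np.intersect1d(train, test)) == 0
        assert np.array_equal(np.sort(np.r_[train, test]), np.arange(20))

    def test_same_seed_identical_partition(self):
        labels = np.repeat(["a", "b", "c"], 20)
        a = split(labels, 0.2, seed=5)
        b = split(labels, 0.2, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_stratification_keeps_every_class_in_test(self):
        labels = np.repeat(np.arange(5), 30)  # subtask-sized classes
        for seed in range(5):
            _, test = split(labels, 0.2, seed=seed)
            assert set(labels[test]) == set(range(5))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split(np.array(["a", "a", "b"]), 0.2, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split(np.repeat(["a", "b"], 5), 1.5, seed=0)


class TestPerClassAccuracy:
    def test_all_correct(self):
        y = np.array(["x", "y", "x"])
        assert per_class_accuracy(y, y) == {"x": 1.0, "y": 1.0}

    def test_hand_counted_example(self):
        truth = np.array(["A", "A", "B", "B"])
        pred = np.array(["A", "B", "B", "B"])
        acc = per_class_accuracy(truth, pred)
        assert acc["A"] == 0.5
        assert acc["B"] == 1.0

    def test_balanced_mean_equals_overall(self):
        rng = np.random.default_rng(0)
        truth = np.repeat(["a", "b", "c", "d"], 25)
        pred = truth.copy()
        flip = rng.choice(100, 30, replace=False)
        pred[flip] = rng.choice(["a", "b", "c", "d"], 30)
        acc = per_class_accuracy(truth, pred)
        assert np.mean(list(acc.values())) == pytest.approx(np.mean(pred == truth))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            per_class_accuracy(np.array(["a"]), np.array(["a", "b"]))


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)
        assert not res.significant

    def test_printed_size_example_matches_manual_ranks(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(manual_kruskal_h(groups))

    def test_ties_handled_like_manual_correction(self):
        groups = [np.array([1.0, 2.0, 2.0, 3.0]), np.array([2.0, 4.0, 4.0, 5.0])]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(manual_kruskal_h(groups))

    def test_all_values_identical_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.degenerate
        assert res.pvalue == 1.0
        assert not res.significant

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])

    def test_null_rejection_rate_within_binomial_tolerance(self):
        """Type-I simulation: two same-distribution groups, alpha=0.01."""
        rng = np.random.default_rng(123)
        n_sims = 1000
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            if kruskal_wallis([a, b]).significant:
                rejections += 1
        rate = rejections / n_sims
        tol = 3 * np.sqrt(0.01 * 0.99 / n_sims)
        assert abs(rate - 0.01) <= tol


def _fake_results(accs, train=None):
    train = train if train is not None else accs
    return [
        RunResult(
            run_index=i + 1, seed=i, train_accuracy=tr, test_accuracy=te,
            per_class={"a": te, "b": te},
        )
        for i, (tr, te) in enumerate(zip(train, accs))
    ]


class TestSummaries:
    def test_constant_results_median_equals_best(self):
        runs = _fake_results([0.8] * 5)
        assert select_median_model(runs).test_accuracy == 0.8
        assert select_best_model(runs).test_accuracy == 0.8

    def test_median_rank_convention_even_count(self):
        accs = [round(0.1 * k, 10) for k in range(1, 31)]  # 0.1 .. 3.0 scaled
        accs = [a / 3.0 for a in accs]
        runs = _fake_results(accs)
        med = select_median_model(runs)
        # 30 runs: the lower of the two middle ranks, i.e. rank 15
        assert med.test_accuracy == pytest.approx(sorted(accs)[14])
        assert select_best_model(runs).test_accuracy == pytest.approx(max(accs))

    def test_median_tie_breaks_to_lower_run_index(self):
        runs = _fake_results([0.5, 0.7, 0.7, 0.7, 0.9, 0.2])
        med = select_median_model(runs)
        assert med.test_accuracy == 0.7
        assert med.run_index == 2  # first of the tied middle runs

    def test_summary_table_shape_and_pvalues(self):
        results = {
            "rocket": _fake_results(list(np.linspace(0.9, 1.0, 10))),
            "rf": _fake_results(list(np.linspace(0.5, 0.6, 10))),
        }
        summary = summarize(results)
        assert list(summary.table.index) == ["rocket", "rf"]
        for col in ("train_median", "test_median", "test_best"):
            assert col in summary.table.columns
        assert summary.pvalues.loc["rocket", "rf"] == summary.pvalues.loc["rf", "rocket"]
        assert bool(summary.significant.loc["rocket", "rf"]) is True

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            summarize({})


class TestRunExperiment:
    def test_run_count_and_order(self, two_class_dataset):
        spec = ModelSpec(family="rocket", hyperparameters={"n_kernels": 30})
        results = run_experiment(
            two_class_dataset, TaskDefinition(kind="contaminant"), spec,
            n_runs=3, base_seed=5,
        )
        assert [r.run_index for r in results] == [1, 2, 3]
        assert [r.seed for r in results] == [6, 7, 8]

    def test_single_run_supported(self, two_class_dataset):
        spec = ModelSpec(family="rf", hyperparameters={"cv_folds": 2})
        results = run_experiment(
            two_class_dataset, TaskDefinition(kind="contaminant"), spec,
            n_runs=1, base_seed=1,
        )
        assert len(results) == 1
        assert set(results[0].per_class) == {"ecA", "ecB"}

    def test_deterministic_families_reproduce(self, two_class_dataset):
        spec = ModelSpec(family="rocket", hyperparameters={"n_kernels": 30})
        task = TaskDefinition(kind="contaminant")
        a = run_experiment(two_class_dataset, task, spec, n_runs=2, base_seed=9)
        b = run_experiment(two_class_dataset, task, spec, n_runs=2, base_seed=9)
        assert [r.test_accuracy for r in a] == [r.test_accuracy for r in b]
        assert [r.train_accuracy for r in a] == [r.train_accuracy for r in b]

    def test_concentration_task_selects_one_ec(self, two_class_dataset):
        task = TaskDefinition(kind="concentration", ec_filter="ecA")
        X, y = prepare_inputs(two_class_dataset, task)
        assert len(y) == 60  # 3 doses x 20 replicates
        # doses are categorical class labels, not a continuous target
        assert set(y) == {"0", "5", "20"}
        # min-max representation: every row spans [0, 1]
        assert np.allclose(X.min(axis=1), 0.0) and np.allclose(X.max(axis=1), 1.0)

    def test_every_family_beats_chance_on_easy_config(self, two_class_dataset):
        """All six families outperform a majority-class baseline with p<0.01
        over repeated splits of an easy two-contaminant dataset."""
        from sklearn.dummy import DummyClassifier

        n_runs = 10
        task = TaskDefinition(kind="contaminant")
        X, y = prepare_inputs(two_class_dataset, task)
        baseline = []
        for i in range(1, n_runs + 1):
            tr, te = split(y, 0.2, seed=3 + i)
            dummy = DummyClassifier(strategy="most_frequent").fit(X[tr], y[tr])
            baseline.append(float(np.mean(dummy.predict(X[te]) == y[te])))

        specs = {
            "rf": (ModelSpec(family="rf", hyperparameters={"cv_folds": 2}), None),
            "xgb": (ModelSpec(family="xgb", hyperparameters={"cv_folds": 2}), None),
            "rocket": (ModelSpec(family="rocket", hyperparameters={"n_kernels": 50}), None),
            "ann": (ModelSpec(family="ann", epochs=30,
                              hyperparameters={"widths": (32, 16, 16, 8, 8),
                                               "dropout": 0.3}), None),
            "cnn1d": (ModelSpec(family="cnn1d", epochs=30,
                                hyperparameters={"filters": (8, 8, 16),
                                                 "dense_width": 16}), None),
            "cnn2d": (ModelSpec(family="cnn2d", epochs=30,
                                hyperparameters={"filters": (4, 4, 8, 8, 8),
                                                 "dropout": 0.1}), "image_linear"),
        }
        for name, (spec, rep) in specs.items():
            runs = run_experiment(
                two_class_dataset, task, spec, n_runs=n_runs, base_seed=3,
                representation=rep, image_hw=(32, 32),
            )
            accs = [r.test_accuracy for r in runs]
            kw = kruskal_wallis([accs, baseline])
            assert np.median(accs) > np.median(baseline), name
            assert kw.significant, (name, kw)

    def test_relabeling_invariance(self, two_class_dataset):
        """Renaming classes permutes per-class keys but not accuracies."""
        spec = ModelSpec(family="rocket", hyperparameters={"n_kernels": 30})
        task = TaskDefinition(kind="contaminant")
        base = run_experiment(two_class_dataset, task, spec, n_runs=1, base_seed=2)
        renamed = two_class_dataset.subset(np.arange(len(two_class_dataset)))
        renamed.meta["ec_label"] = renamed.meta["ec_label"].map(
            {"ecA": "zz_1", "ecB": "aa_2"}
        )
        perm = run_experiment(renamed, task, spec, n_runs=1, base_seed=2)
        assert base[0].test_accuracy == pytest.approx(perm[0].test_accuracy)


class TestReports:
    def test_report_files_and_csv_shapes(self, tmp_path):
        results = {
            "rocket": _fake_results(list(np.linspace(0.9, 1.0, 6))),
            "rf": _fake_results(list(np.linspace(0.5, 0.6, 6))),
        }
        summary = summarize(results)
        paths = render_reports(summary, tmp_path, use="median")
        for key in ("summary", "per_class", "pvalues", "heatmap", "spider", "boxplot"):
            assert key in paths
        per_class = pd.read_csv(paths["per_class"])
        assert len(per_class) == 2 * 2  # methods x classes
        table = pd.read_csv(paths["summary"], index_col=0)
        assert list(table.index) == ["rocket", "rf"]

    def test_rerendering_reproduces_csv_bytes(self, tmp_path):
        results = {"rocket": _fake_results([0.9, 0.95, 1.0])}
        summary = summarize(results)
        render_reports(summary, tmp_path / "a")
        render_reports(summary, tmp_path / "b")
        for name in ("summary.csv", "per_class.csv", "pvalues.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_empty_summary_rejected(self, tmp_path):
        from ojiptox.evaluation import ExperimentSummary

        empty = ExperimentSummary(
            results={}, table=pd.DataFrame(), pvalues=pd.DataFrame(),
            significant=pd.DataFrame(),
        )
        with pytest.raises(ValueError):
            render_reports(empty, tmp_path)
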