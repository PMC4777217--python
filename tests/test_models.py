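"""Tests for cluster-score toxicity models, AUC and evaluation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import toxprofiler as tp
from toxprofiler.models import Correlation, _endpoint_seed
from toxprofiler.som import ClusterAssignment


def brute_force_auc(scores, truth):
    """Pairwise concordance: (concordant + 0.5 * ties) / (nT * nN)."""
    pos = [scores[c] for c in scores if truth[c]]
    neg = [scores[c] for c in scores if not truth[c]]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplitTrainTest:
    @pytest.mark.parametrize("n", [100, 101, 7])
    def test_half_sizes(self, n):
        comps = [f"c{i}" for i in range(n)]
        train, test = tp.split_train_test(comps, seed=1)
        assert abs(len(train) - len(test)) <= 1
        assert train | test == set(comps)
        assert not train & test

    def test_determinism(self):
        comps = [f"c{i}" for i in range(50)]
        assert tp.split_train_test(comps, 9) == tp.split_train_test(comps, 9)

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            tp.split_train_test(["a", "b", "c"], 1)


class TestScoreClusters:
    def _assign(self, labels):
        return ClusterAssignment(labels=labels, map_kind="activity")

    def test_all_toxic_cluster_hypergeometric(self):
        """10-compound all-toxic cluster in a half-toxic training set of
        100: score = -log10 of the upper hypergeometric tail at a=10."""
        labels = {f"c{i}": ("kA" if i < 10 else "kB") for i in range(100)}
        calls = {f"c{i}": i < 50 for i in range(100)}  # c0..c49 toxic
        table = tp.score_clusters(calls, self._assign(labels))
        expect = -math.log10(hypergeom.sf(9, 100, 50, 10))
        assert table["kA"] == pytest.approx(expect, rel=1e-12)

    def test_deficient_cluster_mirror_score(self):
        labels = {f"c{i}": ("kA" if i >= 90 else "kB") for i in range(100)}
        calls = {f"c{i}": i < 50 for i in range(100)}  # kA all non-toxic
        table = tp.score_clusters(calls, self._assign(labels))
        expect = math.log10(hypergeom.cdf(0, 100, 50, 10))
        assert table["kA"] == pytest.approx(expect, rel=1e-12)
        assert table["kA"] < 0

    def test_balanced_design_symmetry(self):
        """All-toxic and all-non-toxic clusters of equal size score with
        equal magnitude and opposite sign in a balanced training set."""
        labels = {}
        for i in range(100):
            labels[f"c{i}"] = {True: "kT", False: "kN"}[i < 10] \
                if i < 20 else "kRest"
        calls = {f"c{i}": (i < 10 or 20 <= i < 60) for i in range(100)}
        table = tp.score_clusters(calls, self._assign(labels))
        assert table["kT"] == pytest.approx(-table["kN"], rel=1e-9)

    def test_no_enrichment_scores_zero(self):
        """Whole library as one cluster: no enrichment is possible."""
        labels = dict.fromkeys((f"c{i}" for i in range(60)), "kAll")
        calls = {f"c{i}": i < 30 for i in range(60)}
        table = tp.score_clusters(calls, self._assign(labels))
        assert table["kAll"] == 0.0

    def test_unlabelled_compound_raises(self):
        with pytest.raises(KeyError):
            tp.score_clusters({"ghost": True}, self._assign({}))


class TestPredict:
    def _setup(self):
        labels = {"tr1": "kA", "tr2": "kA", "tr3": "kC", "te1": "kA",
                  "te2": "kB", "te3": "kA"}
        assign = ClusterAssignment(labels=labels, map_kind="activity")
        table = tp.score_clusters(
            {"tr1": True, "tr2": True, "tr3": False}, assign
        )
        return assign, table

    def test_cluster_score_inherited(self):
        assign, table = self._setup()
        preds = tp.predict(["te1", "te3"], assign, table)
        assert preds["te1"] == preds["te3"] == table["kA"]
        assert preds["te1"] > 0

    def test_missing_cluster_neutral_zero(self):
        assign, table = self._setup()
        assert tp.predict(["te2"], assign, table)["te2"] == 0.0

    def test_missing_cluster_abstain_drops(self):
        assign, table = self._setup()
        assert tp.predict(["te2"], assign, table,
                          missing_policy="abstain") == {}

    def test_unclustered_compound_raises(self):
        assign, table = self._setup()
        with pytest.raises(KeyError):
            tp.predict(["nowhere"], assign, table)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 3.0, "b": 2.0, "c": -1.0, "d": -2.0}
        truth = {"a": True, "b": True, "c": False, "d": False}
        assert tp.roc_auc(scores, truth) == 1.0

    def test_all_ties_half(self):
        scores = dict.fromkeys("abcd", 0.0)
        truth = {"a": True, "b": False, "c": True, "d": False}
        assert tp.roc_auc(scores, truth) == 0.5

    def test_hand_example(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.3, "d": 0.1}
        truth = {"a": True, "b": False, "c": True, "d": False}
        assert tp.roc_auc(scores, truth) == pytest.approx(0.75)

    def test_single_class_nan(self):
        assert math.isnan(tp.roc_auc({"a": 1.0, "b": 0.0},
                                     {"a": True, "b": True}))

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(200):
            n = int(rng.integers(4, 51))
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            scores = {f"c{i}": float(s[i]) for i in range(n)}
            truth = {f"c{i}": bool(y[i]) for i in range(n)}
            auc = tp.roc_auc(scores, truth)
            assert auc == pytest.approx(brute_force_auc(scores, truth),
                                        abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_antisymmetry(self, rng):
        """Negating all scores maps AUC to 1 - AUC."""
        for _ in range(50):
            n = 30
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            s = rng.normal(size=n)
            scores = {f"c{i}": float(s[i]) for i in range(n)}
            neg = {c: -v for c, v in scores.items()}
            truth = {f"c{i}": bool(y[i]) for i in range(n)}
            assert tp.roc_auc(neg, truth) == pytest.approx(
                1.0 - tp.roc_auc(scores, truth), abs=1e-12
            )


class TestEvaluateModel:
    def _planted(self, seed=0):
        lib = tp.generate_library(200, 2, n_assays=10, n_bits=32,
                                  signal_strength=1.0, seed=seed)
        model = tp.train_som(lib.profiles, 4, 4, seed=seed)
        assign = tp.assign_clusters(model, lib.profiles)
        spec = tp.EndpointSpec("ld50", "dose", {0: 0.9, 1: 0.1})
        calls = tp.build_calls(tp.generate_endpoints(lib, [spec], seed=seed))
        return assign, calls.endpoint_calls("ld50")

    def test_planted_signal_high_auc(self):
        assign, calls = self._planted(seed=3)
        ev = tp.evaluate_model(calls, assign, "ld50", n_repeats=30, seed=5)
        assert ev.auc_mean >= 0.8
        assert not ev.unmodelable

    def test_permuted_labels_null_auc(self):
        assign, calls = self._planted(seed=4)
        rng = np.random.default_rng(11)
        comps = sorted(calls)
        vals = [calls[c] for c in comps]
        perm = {c: vals[i] for c, i in zip(comps, rng.permutation(len(comps)))}
        ev = tp.evaluate_model(perm, assign, "ld50", n_repeats=50, seed=5)
        se = ev.auc_sd / math.sqrt(ev.n_splits_used)
        assert abs(ev.auc_mean - 0.5) < max(3 * se, 0.05)

    def test_determinism(self):
        assign, calls = self._planted(seed=6)
        e1 = tp.evaluate_model(calls, assign, "ld50", n_repeats=1, seed=9)
        e2 = tp.evaluate_model(calls, assign, "ld50", n_repeats=1, seed=9)
        assert e1.auc_per_split == e2.auc_per_split

    def test_endpoint_seed_stable_and_bounded(self):
        assert _endpoint_seed(7, "acute_oral") == _endpoint_seed(7, "acute_oral")
        assert _endpoint_seed(7, "a") != _endpoint_seed(7, "b")
        assert 0 <= _endpoint_seed(2**20, "x" * 50) < 2**31


class TestSignalStrengthMonotonicity:
    def test_mean_model_auc_non_decreasing_in_signal(self):
        """Mean activity-model AUC is non-decreasing over signal strengths
        {0, 0.5, 1} within Monte-Carlo error (10 seeds)."""
        means = {}
        for s in (0.0, 0.5, 1.0):
            aucs = []
            for seed in range(10):
                lib = tp.generate_library(150, 2, n_assays=10, n_bits=16,
                                          signal_strength=s, seed=200 + seed)
                assign = tp.assign_clusters(
                    tp.train_som(lib.profiles, 5, 5, seed=seed), lib.profiles
                )
                spec = tp.EndpointSpec("ld50", "dose", {0: 0.9, 1: 0.1})
                calls = tp.build_calls(
                    tp.generate_endpoints(lib, [spec], seed=seed)
                ).endpoint_calls("ld50")
                ev = tp.evaluate_model(calls, assign, "ld50",
                                       n_repeats=10, seed=seed)
                aucs.append(ev.auc_mean)
            means[s] = float(np.mean(aucs))
        tol = 0.03  # Monte-Carlo slack at 10 seeds x 10 splits
        assert means[0.5] >= means[0.0] - tol
        assert means[1.0] >= means[0.5] - tol
        assert means[1.0] > means[0.0]


class TestSingleAssayAuc:
    def test_informative_column_beats_noise(self, rng):
        n = 200
        toxic = rng.random(n) < 0.5
        informative = np.where(toxic, 8, 0) + rng.integers(0, 2, n)
        noise = rng.integers(-9, 10, n)
        profiles = pd.DataFrame(
            {"assay00": informative, "assay01": noise},
            index=[f"c{i}" for i in range(n)],
        )
        calls = {f"c{i}": bool(toxic[i]) for i in range(n)}
        res = tp.single_assay_auc(profiles, calls).set_index("assay")
        assert res.loc["assay00", "auc"] > res.loc["assay01", "auc"]
        assert bool(res.loc["assay00", "predictive"])

    def test_constant_column_half(self):
        profiles = pd.DataFrame({"assay00": [0] * 10},
                                index=[f"c{i}" for i in range(10)])
        calls = {f"c{i}": i < 5 for i in range(10)}
        res = tp.single_assay_auc(profiles, calls)
        assert res["auc"].iloc[0] == 0.5

    def test_sign_flip_invariant(self, rng):
        n = 60
        ranks = rng.integers(-9, 10, n)
        calls = {f"c{i}": bool(rng.integers(0, 2)) for i in range(n)}
        if len(set(calls.values())) < 2:
            calls["c0"], calls["c1"] = True, False
        a = tp.single_assay_auc(
            pd.DataFrame({"x": ranks}, index=list(calls)), calls)
        b = tp.single_assay_auc(
            pd.DataFrame({"x": -ranks}, index=list(calls)), calls)
        assert a["auc"].iloc[0] == pytest.approx(b["auc"].iloc[0])


class TestCorrelation:
    def test_identity_r_one(self):
        x = {f"e{i}": v for i, v in enumerate([0.1, 0.4, 0.5, 0.8, 0.9])}
        res = tp.correlate_repro_performance(x, dict(x))
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        y = {"a": 2.0, "b": 1.0, "c": 4.0, "d": 3.0, "e": 6.0}
        res = tp.correlate_repro_performance(x, y)
        xs, ys = np.array(list(x.values())), np.array(list(y.values()))
        r_closed = (
            ((xs - xs.mean()) * (ys - ys.mean())).sum()
            / np.sqrt(((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum())
        )
        assert res.r == pytest.approx(r_closed, rel=1e-12)

    def test_null_r_small(self, rng):
        x = {f"e{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        y = {f"e{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
        res = tp.correlate_repro_performance(x, y)
        assert abs(res.r) < 0.4

    def test_zero_variance_flagged(self):
        x = dict.fromkeys(("a", "b", "c"), 0.5)
        y = {"a": 0.1, "b": 0.2, "c": 0.3}
        res = tp.correlate_repro_performance(x, y)
        assert isinstance(res, Correlation) and not res.defined

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            tp.correlate_repro_performance({"a": 1.0}, {"a": 1.0})
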