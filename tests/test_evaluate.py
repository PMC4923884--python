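from __future__ import annotations

import numpy as np
import pytest

from modulenet import (
    ConfusionMatrix,
    DataError,
    ExpressionMatrix,
    SampleAnnotation,
    cluster_two_groups,
    confusion_from_predictions,
    logrank,
    make_model,
    metrics,
    random_geneset_null,
    resample_evaluate,
    sample_expression,
    svm_rfe_select,
)

from conftest import make_annotations


class TestMetrics:
    def test_published_neuroblastoma_test_set_row(self):
        m = metrics(ConfusionMatrix(tp=13, fn=13, tn=192, fp=19))
        assert round(m.sen, 3) == 0.500
        assert round(m.spc, 3) == 0.910
        assert round(m.acc, 3) == 0.865
        assert round(m.mcc, 3) == 0.375

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=10, tn=10, fp=0, fn=0))
        assert (m.sen, m.spc, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_chance_classifier(self):
        m = metrics(ConfusionMatrix(tp=5, tn=5, fp=5, fn=5))
        assert m.mcc == 0.0
        assert m.acc == 0.5

    def test_zero_denominator_metrics_undefined_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fn=0, tn=5, fp=5))
        assert m.sen is None
        assert m.mcc is None
        assert m.spc == 0.5

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError, match="empty"):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_matches_brute_force_from_prediction_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            truth = ["high" if b else "low" for b in rng.integers(0, 2, n)]
            pred = ["high" if b else "low" for b in rng.integers(0, 2, n)]
            cm = confusion_from_predictions(truth, pred)
            assert cm.total == n
            m = metrics(cm)
            correct = sum(t == p for t, p in zip(truth, pred))
            assert m.acc == pytest.approx(correct / n)
            pos = sum(t == "high" for t in truth)
            if pos:
                tp = sum(t == p == "high" for t, p in zip(truth, pred))
                assert m.sen == pytest.approx(tp / pos)
            if m.mcc is not None:
                assert -1.0 <= m.mcc <= 1.0
            for v in (m.sen, m.spc, m.acc):
                if v is not None:
                    assert 0.0 <= v <= 1.0


def blob_matrix(n_per_blob=10, n_genes=8, shift=5.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_genes, n_per_blob))
    b = rng.standard_normal((n_genes, n_per_blob)) + shift * np.sign(
        rng.standard_normal((n_genes, 1))
    )
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"a{i}" for i in range(n_per_blob)] + [f"b{i}" for i in range(n_per_blob)]
    return ExpressionMatrix(genes, samples, np.hstack([a, b]))


class TestClustering:
    def test_separated_blobs_recovered_exactly(self):
        mat = blob_matrix()
        res = cluster_two_groups(mat, metric="euclidean")
        groups = {}
        for s, c in res.assignment.items():
            groups.setdefault(c, set()).add(s[0])
        assert sorted(groups.values(), key=len) == [{"a"}, {"b"}] or sorted(
            groups.values(), key=len
        ) == [{"b"}, {"a"}]

    def test_sample_order_invariant_up_to_label_swap(self):
        mat = blob_matrix(seed=3)
        perm = list(np.random.default_rng(1).permutation(mat.sample_ids))
        res1 = cluster_two_groups(mat, metric="euclidean")
        res2 = cluster_two_groups(mat.subset_samples(perm), metric="euclidean")
        a1 = {s: res1.assignment[s] for s in mat.sample_ids}
        a2 = {s: res2.assignment[s] for s in mat.sample_ids}
        same = all(a1[s] == a2[s] for s in a1)
        flipped = all(a1[s] == 3 - a2[s] for s in a1)
        assert same or flipped

    def test_two_identical_pairs_form_the_clusters(self):
        mat = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2", "s3", "s4"],
            [[0.0, 0.0, 5.0, 5.0], [1.0, 1.0, -4.0, -4.0]],
        )
        res = cluster_two_groups(mat, metric="euclidean")
        assert res.assignment["s1"] == res.assignment["s2"]
        assert res.assignment["s3"] == res.assignment["s4"]
        assert res.assignment["s1"] != res.assignment["s3"]

    def test_constant_matrix_rejected(self):
        mat = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2", "s3", "s4"], np.ones((2, 4))
        )
        with pytest.raises(DataError, match="constant|undefined"):
            cluster_two_groups(mat)

    def test_high_risk_cluster_has_shorter_event_survival(self):
        mat = blob_matrix(seed=5)
        # blob 'a' samples die early, blob 'b' late
        ann = [
            SampleAnnotation(s, survival_days=100 if s[0] == "a" else 2000, event=True)
            for s in mat.sample_ids
        ]
        res = cluster_two_groups(mat, ann, metric="euclidean")
        high = [c for c, r in res.risk_by_cluster.items() if r == "high"][0]
        high_samples = {s for s, c in res.assignment.items() if c == high}
        assert high_samples == {s for s in mat.sample_ids if s[0] == "a"}
        assert res.p_value < 0.01


def hand_logrank_chi2(times_a, events_a, times_b, events_b):
    """Direct O-E / variance computation of the two-group log-rank test."""
    data = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in data if e})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in data if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_curves_give_null_statistic(self):
        ann = make_annotations([(100, True), (200, True), (300, False)] * 2)
        groups = {a.sample_id: (0 if i < 3 else 1) for i, a in enumerate(ann)}
        stat, p = logrank(groups, ann)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_matches_hand_computed_o_minus_e(self):
        times_a, events_a = [6, 13, 21, 30, 37, 38], [1, 1, 1, 1, 1, 1]
        times_b, events_b = [10, 25, 40, 45, 50, 55], [1, 1, 1, 0, 1, 0]
        ann = make_annotations(
            list(zip(times_a, map(bool, events_a))) + list(zip(times_b, map(bool, events_b)))
        )
        groups = {a.sample_id: (0 if i < 6 else 1) for i, a in enumerate(ann)}
        stat, _ = logrank(groups, ann)
        expected = hand_logrank_chi2(times_a, events_a, times_b, events_b)
        assert stat == pytest.approx(expected, rel=1e-6)

    def test_null_p_values_roughly_uniform_under_permutation(self):
        rng = np.random.default_rng(7)
        days = rng.exponential(500, size=40).astype(int) + 1
        events = rng.random(40) < 0.7
        ann = make_annotations(list(zip(days, events)))
        ids = [a.sample_id for a in ann]
        ps = []
        for _ in range(300):
            perm = rng.permutation(40)
            groups = {ids[i]: (0 if j < 20 else 1) for j, i in enumerate(perm)}
            ps.append(logrank(groups, ann)[1])
        ps = np.asarray(ps)
        assert 0.35 <= np.mean(ps < 0.5) <= 0.65
        assert 0.02 <= np.mean(ps < 0.1) <= 0.2

    def test_single_group_rejected(self):
        ann = make_annotations([(100, True), (200, True)])
        with pytest.raises(DataError, match="2 groups"):
            logrank({a.sample_id: 1 for a in ann}, ann)


@pytest.fixture(scope="module")
def signal_cohort():
    """Small cohort with survival signal planted in module 0's genes."""
    model = make_model(p=20, n_hubs=2, hub_degree=4, seed=21, effect_size=3.0)
    mat, ann, labels = sample_expression(model, n_per_class=40, seed=21)
    return model, mat, ann, labels


class TestRandomGenesetNull:
    def test_degenerate_all_genes_replicates_observed(self, signal_cohort):
        _, mat, ann, _ = signal_cohort
        res = random_geneset_null(
            mat, ann, mat.gene_ids, m=mat.n_genes, reps=5, seed=1,
            module_genes=mat.gene_ids,
        )
        assert all(p == pytest.approx(res.observed_p) for p in res.p_values)

    def test_same_seed_same_p_values(self, signal_cohort):
        _, mat, ann, _ = signal_cohort
        a = random_geneset_null(mat, ann, mat.gene_ids, m=5, reps=10, seed=3)
        b = random_geneset_null(mat, ann, mat.gene_ids, m=5, reps=10, seed=3)
        assert a.p_values == b.p_values

    def test_signal_module_beats_random_gene_sets(self, signal_cohort):
        model, mat, ann, _ = signal_cohort
        module0 = sorted(model.module_genes(0))
        res = random_geneset_null(
            mat, ann, mat.gene_ids, m=len(module0), reps=50, seed=4,
            module_genes=module0,
        )
        assert res.observed_p < res.mean_p

    def test_oversized_geneset_rejected(self, signal_cohort):
        _, mat, ann, _ = signal_cohort
        with pytest.raises(DataError, match="exceeds"):
            random_geneset_null(mat, ann, mat.gene_ids, m=mat.n_genes + 1)


class TestSvmRfe:
    def informative_matrix(self, seed, n_informative=2, n_noise=28, shift=3.0):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.standard_normal((n_informative + n_noise, n))
        x[:n_informative, n // 2:] += shift
        genes = [f"inf{i}" for i in range(n_informative)] + [
            f"noise{i:02d}" for i in range(n_noise)
        ]
        samples = [f"s{j:02d}" for j in range(n)]
        labels = {s: ("low" if j < n // 2 else "high") for j, s in enumerate(samples)}
        return ExpressionMatrix(genes, samples, x), labels

    def test_informative_genes_selected_in_almost_all_runs(self):
        hits = 0
        for seed in range(100):
            mat, labels = self.informative_matrix(seed)
            top = svm_rfe_select(mat, labels, n_features=2)
            hits += set(top) == {"inf0", "inf1"}
        assert hits >= 95

    def test_requesting_all_genes_returns_identity_order(self):
        mat, labels = self.informative_matrix(0)
        assert svm_rfe_select(mat, labels, n_features=mat.n_genes) == mat.gene_ids

    def test_duplicated_gene_gets_adjacent_rank(self):
        mat, labels = self.informative_matrix(1, n_informative=2, n_noise=10)
        dup_values = np.vstack([mat.values, mat.values[[0]]])
        dup = ExpressionMatrix(mat.gene_ids + ["inf0_copy"], mat.sample_ids, dup_values)
        ranking = svm_rfe_select(dup, labels, n_features=dup.n_genes - 1)
        i = ranking.index("inf0")
        j = ranking.index("inf0_copy")
        assert abs(i - j) == 1

    def test_too_many_features_rejected(self):
        mat, labels = self.informative_matrix(0)
        with pytest.raises(DataError, match="exceeds"):
            svm_rfe_select(mat, labels, n_features=mat.n_genes + 1)


class TestResampleEvaluate:
    def separable_cohort(self, shift=5.0, n=50, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((10, 2 * n))
        x[:4, n:] += shift
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{j:03d}" for j in range(2 * n)]
        labels = {s: ("low" if j < n else "high") for j, s in enumerate(samples)}
        return ExpressionMatrix(genes, samples, x), labels

    def test_separable_classes_classified_nearly_perfectly(self):
        mat, labels = self.separable_cohort()
        report = resample_evaluate(mat, labels, reps=8, seed=5, n_features=4)
        assert report.averages["acc"] >= 0.95
        assert report.averages["mcc"] >= 0.9

    def test_permuted_labels_give_chance_mcc(self):
        mat, labels = self.separable_cohort(seed=2)
        rng = np.random.default_rng(9)
        shuffled = dict(zip(labels.keys(), rng.permutation(list(labels.values()))))
        report = resample_evaluate(mat, shuffled, reps=10, seed=5, n_features=4)
        assert abs(report.averages["mcc"]) <= 0.25

    def test_same_seed_identical_report(self):
        mat, labels = self.separable_cohort(seed=3)
        r1 = resample_evaluate(mat, labels, reps=2, seed=11, n_features=4)
        r2 = resample_evaluate(mat, labels, reps=2, seed=11, n_features=4)
        assert r1.to_json() == r2.to_json()

    def test_feature_selection_uses_training_data_only(self):
        mat, labels = self.separable_cohort(seed=4)
        report = resample_evaluate(mat, labels, reps=2, seed=7, n_features=4)
        for it in report.per_iteration:
            recomputed = svm_rfe_select(
                mat.subset_samples(it.train_ids), labels, n_features=4
            )
            assert recomputed == it.selected_genes
            assert not set(it.train_ids) & set(it.valid_ids)

    def test_averages_equal_mean_of_iterations(self):
        mat, labels = self.separable_cohort(seed=6)
        report = resample_evaluate(mat, labels, reps=4, seed=1, n_features=4)
        for key in ("sen", "spc", "acc", "mcc"):
            per = [getattr(it.metrics, key) for it in report.per_iteration]
            per = [v for v in per if v is not None]
            assert report.averages[key] == pytest.approx(np.mean(per), abs=1e-12)

    def test_small_class_rejected(self):
        mat, labels = self.separable_cohort(n=4)
        with pytest.raises(DataError, match=">=5"):
            resample_evaluate(mat, labels, reps=1)
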