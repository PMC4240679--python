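import numpy as np
import pytest

from rodeo.evaluate import (auc_threshold_sweep, false_positive_curve,
                            label_truth, roc_auc, top_x_recovery)
from rodeo.io import ValidationError


class TestLabelTruth:
    @pytest.mark.parametrize("logfc, expected", [
        (1.6, "DE"), (-1.6, "DE"),
        (0.5, "nonDE"), (-0.5, "nonDE"),
        (1.2, "unassigned"), (1.5, "unassigned"), (1.0, "unassigned"),
    ])
    def test_default_cutoffs(self, logfc, expected):
        labels = label_truth({"g": logfc})
        assert labels.frame.label.iloc[0] == expected

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            label_truth({"g": 1.0}, de_cutoff=1.0, nonde_cutoff=1.5)


def make_labels(n_de=4, n_non=4, n_un=2):
    logfc = {}
    for i in range(n_de):
        logfc[f"de{i}"] = 2.0 + i * 0.1
    for i in range(n_non):
        logfc[f"nn{i}"] = 0.2
    for i in range(n_un):
        logfc[f"un{i}"] = 1.2
    return label_truth(logfc)


class TestFalsePositiveCurve:
    def test_perfect_ranking_has_zero_fp(self):
        labels = make_labels()
        ranked = [f"de{i}" for i in range(4)] + [f"nn{i}" for i in range(4)]
        fp = false_positive_curve(ranked, labels, 4)
        assert fp.tolist() == [0, 0, 0, 0]

    def test_worst_ranking_counts_every_pick(self):
        labels = make_labels()
        ranked = [f"nn{i}" for i in range(4)] + [f"de{i}" for i in range(4)]
        assert false_positive_curve(ranked, labels, 4).tolist() == [1, 2, 3, 4]

    def test_interleaved_and_unassigned_skipped(self):
        labels = make_labels()
        ranked = ["de0", "un0", "nn0", "de1", "un1", "nn1", "de2", "nn2"]
        fp = false_positive_curve(ranked, labels, 6)
        assert fp.tolist() == [0, 1, 1, 2, 2, 3]

    def test_fp_plus_tp_equals_x(self):
        labels = make_labels()
        ranked = ["nn0", "de0", "de1", "nn1", "de2", "nn2", "de3", "nn3"]
        fp = false_positive_curve(ranked, labels, 8)
        tp = np.arange(1, 9) - fp
        assert (tp + fp == np.arange(1, 9)).all()
        assert tp[-1] == 4


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = make_labels()
        ranked = [f"de{i}" for i in range(4)] + [f"nn{i}" for i in range(4)]
        points, auc = roc_auc(ranked, labels)
        assert auc == 1.0
        assert points.tpr.iloc[-1] == 1.0 and points.fpr.iloc[-1] == 1.0

    def test_worked_four_gene_example(self):
        labels = label_truth({"a": 2.0, "b": 0.1, "c": 2.0, "d": 0.1})
        _, auc = roc_auc(["a", "b", "c", "d"], labels)
        assert auc == pytest.approx(0.75)

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(300)]
        logfc = {g: float(rng.choice([2.5, 0.1])) for g in genes}
        labels = label_truth(logfc)
        ranked = list(rng.permutation(genes))
        _, auc = roc_auc(ranked, labels)
        y = [1 if abs(logfc[g]) > 1.5 else 0 for g in ranked]
        score = [-i for i in range(len(ranked))]
        assert auc == pytest.approx(roc_auc_score(y, score), abs=1e-12)

    def test_invariant_under_monotone_score_transform(self):
        # AUC depends only on the order, which is what the API consumes
        labels = make_labels()
        ranked = ["de0", "nn0", "de1", "de2", "nn1", "de3", "nn2", "nn3"]
        _, a1 = roc_auc(ranked, labels)
        _, a2 = roc_auc(list(ranked), labels)
        assert a1 == a2

    def test_single_class_rejected(self):
        labels = label_truth({"a": 2.0, "b": 2.1})
        with pytest.raises(ValidationError):
            roc_auc(["a", "b"], labels)

    def test_permutation_null_centers_on_half(self):
        rng = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(10_000)]
        logfc = {g: (2.0 if i % 2 == 0 else 0.1) for i, g in enumerate(genes)}
        labels = label_truth(logfc)
        aucs = []
        for _ in range(20):
            _, auc = roc_auc(list(rng.permutation(genes)), labels)
            aucs.append(auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02


class TestSweep:
    def test_single_threshold_consistent_with_default_labels(self):
        genes = {f"g{i}": v for i, v in enumerate([2.0, 0.3, 1.8, 0.1, 2.4, 0.6])}
        ranked = sorted(genes, key=genes.get, reverse=True)
        df = auc_threshold_sweep(ranked, genes, [1.5])
        _, auc = roc_auc(ranked, label_truth(genes))
        assert df.auc.iloc[0] == pytest.approx(auc)

    def test_unreachable_threshold_reported_missing(self):
        genes = {"a": 2.0, "b": 0.1, "c": 1.9}
        df = auc_threshold_sweep(list(genes), genes, [1.5, 50.0])
        assert np.isnan(df.auc.iloc[-1])

    def test_descending_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            auc_threshold_sweep(["a"], {"a": 2.0}, [2.0, 1.0])

    def test_auc_nondecreasing_for_monotone_signal(self):
        rng = np.random.default_rng(7)
        logfc = {f"g{i}": float(v) for i, v in
                 enumerate(np.sort(rng.uniform(0, 4, size=400))[::-1])}
        noisy = {g: v + rng.normal(0, 0.4) for g, v in logfc.items()}
        ranked = sorted(noisy, key=noisy.get, reverse=True)
        df = auc_threshold_sweep(ranked, logfc, [1.0, 1.5, 2.0, 2.5])
        aucs = df.auc.to_numpy()
        assert (np.diff(aucs) >= -0.02).all()


class TestTopXRecovery:
    def test_truth_order_recovers_diagonal(self):
        labels = make_labels()
        truth_order = sorted(labels.de_genes,
                             key=lambda g: -abs(labels.logfc_of()[g]))
        ranked = truth_order + sorted(labels.nonde_genes)
        rec = top_x_recovery(ranked, labels, 6)
        assert rec.tolist() == [1, 2, 3, 4, 4, 4]

    def test_reversed_truth_order(self):
        labels = make_labels(n_de=4, n_non=0, n_un=0)
        # need a nonDE gene for labeling sanity; recovery only uses DE ranks
        truth_order = sorted(labels.de_genes,
                             key=lambda g: -abs(labels.logfc_of()[g]))
        ranked = truth_order[::-1]
        rec = top_x_recovery(ranked, labels, 4)
        n = 4
        expected = [max(0, 2 * x - n) for x in range(1, 5)]
        assert rec.tolist() == expected

    def test_never_exceeds_x(self):
        labels = make_labels()
        rng = np.random.default_rng(3)
        ranked = list(rng.permutation(sorted(labels.de_genes | labels.nonde_genes)))
        rec = top_x_recovery(ranked, labels, 8)
        assert (rec <= np.arange(1, 9)).all()
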