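import numpy as np
import pytest

from maap.metrics import ConfusionCounts, confusion, evaluate, macro_f1, macro_report, ovr_auc


def brute_force_report(y_true, y_pred, n_classes=3):
    """Independent oracle: explicit per-sample loops for every metric."""
    out = {"recall": [], "precision": [], "f1": [], "specificity": [], "fpr": []}
    for c in range(n_classes):
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
            else:
                tn += 1
        rec = tp / (tp + fn) if tp + fn else 0.0
        pre = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
        spe = tn / (tn + fp) if tn + fp else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        for key, v in zip(out, (rec, pre, f1, spe, fpr)):
            out[key].append(v)
    return out


def brute_force_auc(y_true, scores_c, positive):
    """Pairwise comparison AUC oracle (ties count 1/2)."""
    pos = [s for s, t in zip(scores_c, y_true) if t == positive]
    neg = [s for s, t in zip(scores_c, y_true) if t != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


HAND_CASE = (np.array([0, 0, 1, 1, 2, 2]), np.array([0, 0, 1, 2, 2, 2]))


class TestConfusion:
    def test_perfect_diagonal(self):
        c = confusion([0, 1, 2], [0, 1, 2])
        assert c.tp.tolist() == [1, 1, 1]
        assert c.fp.tolist() == [0, 0, 0]
        assert c.fn.tolist() == [0, 0, 0]

    def test_hand_counted_six_samples(self):
        c = confusion(*HAND_CASE)
        assert (c.tp[1], c.fn[1], c.fp[1], c.tn[1]) == (1, 1, 0, 4)
        assert (c.tp[2], c.fp[2], c.tn[2], c.fn[2]) == (2, 1, 3, 0)

    def test_empty_and_out_of_range_error(self):
        with pytest.raises(ValueError):
            confusion([], [])
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1])


class TestMacroReport:
    def test_perfect_predictions_all_ones(self):
        r = evaluate([0, 1, 2, 0], [0, 1, 2, 0],
                     scores=np.eye(3)[[0, 1, 2, 0]])
        assert r.macro_f1 == 1.0
        assert r.macro_recall == 1.0
        assert r.macro_specificity == 1.0
        assert r.macro_auc == 1.0

    def test_hand_case_macro_values(self):
        r = evaluate(*HAND_CASE)
        assert r.macro_f1 == pytest.approx((1 + 2 / 3 + 0.8) / 3, abs=1e-4)
        assert r.macro_f1 == pytest.approx(0.8222, abs=1e-4)
        assert r.macro_specificity == pytest.approx((1 + 1 + 0.75) / 3, abs=1e-4)
        assert r.macro_specificity == pytest.approx(0.9167, abs=1e-4)

    def test_binary_toy_auc_perfect_ranking(self):
        scores = np.array([[0.8, 0.2, 0.0], [0.2, 0.8, 0.0]])
        aucs, _ = ovr_auc([0, 1], scores)
        assert aucs[1] == 1.0

    def test_score_rows_must_sum_to_one(self):
        counts = confusion([0, 1, 2], [0, 1, 2])
        bad = np.full((3, 3), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            macro_report(counts, scores=bad, y_true=[0, 1, 2])

    def test_empty_class_cells_are_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            r = evaluate([0, 0, 1], [0, 0, 0])
        assert r.recall[2] == 0.0
        assert r.f1[2] == 0.0


class TestOracleEquivalence:
    def test_random_label_score_sets(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            n = int(rng.integers(3, 25))
            y_true = rng.integers(0, 3, size=n)
            y_pred = rng.integers(0, 3, size=n)
            r = evaluate(y_true, y_pred)
            o = brute_force_report(y_true, y_pred)
            np.testing.assert_allclose(r.recall, o["recall"], atol=1e-12)
            np.testing.assert_allclose(r.precision, o["precision"], atol=1e-12)
            np.testing.assert_allclose(r.f1, o["f1"], atol=1e-12)
            np.testing.assert_allclose(r.specificity, o["specificity"], atol=1e-12)
            np.testing.assert_allclose(r.fpr, o["fpr"], atol=1e-12)
            assert r.macro_f1 == pytest.approx(float(np.mean(o["f1"])))

    def test_auc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 3, size=n)
            if len(set(y.tolist())) < 2:
                continue
            scores = rng.dirichlet(np.ones(3), size=n)
            aucs, _ = ovr_auc(y, scores)
            for c in range(3):
                if (y == c).sum() in (0, n):
                    continue
                assert aucs[c] == pytest.approx(
                    brute_force_auc(y, scores[:, c], c), abs=1e-12)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import f1_score, recall_score, roc_auc_score

        rng = np.random.default_rng(29)
        for _ in range(50):
            n = int(rng.integers(12, 40))
            y_true = rng.integers(0, 3, size=n)
            if len(set(y_true.tolist())) < 3:
                continue
            y_pred = rng.integers(0, 3, size=n)
            scores = rng.dirichlet(np.ones(3), size=n)
            r = evaluate(y_true, y_pred, scores=scores)
            assert r.macro_f1 == pytest.approx(
                f1_score(y_true, y_pred, average="macro", zero_division=0))
            assert r.macro_recall == pytest.approx(
                recall_score(y_true, y_pred, average="macro", zero_division=0))
            assert r.macro_auc == pytest.approx(
                roc_auc_score(y_true, scores, multi_class="ovr",
                              average="macro"), abs=1e-10)


class TestInvariances:
    def test_auc_monotone_transform_invariant(self):
        rng = np.random.default_rng(31)
        y = rng.integers(0, 3, size=30)
        scores = rng.dirichlet(np.ones(3), size=30)
        a1, m1 = ovr_auc(y, scores)
        a2, m2 = ovr_auc(y, np.exp(3 * scores))  # strictly monotone map
        np.testing.assert_allclose(a1, a2)

    def test_auc_constant_scores_is_half(self):
        y = [0, 1, 2, 0, 1, 2]
        aucs, macro = ovr_auc(y, np.full((6, 3), 1 / 3))
        np.testing.assert_allclose(aucs, 0.5)

    def test_macro_f1_class_relabelling_invariant(self):
        rng = np.random.default_rng(37)
        y_true = rng.integers(0, 3, size=40)
        y_pred = rng.integers(0, 3, size=40)
        perm = np.array([2, 0, 1])
        assert macro_f1(y_true, y_pred) == pytest.approx(
            macro_f1(perm[y_true], perm[y_pred]))
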