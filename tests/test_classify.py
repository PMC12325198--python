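import numpy as np
import pandas as pd
import pytest

from vrgamma.classify import (
    gini_importance,
    repeat_protocol,
    stratified_split,
    subset_accuracy_curve,
    train_eval_svm,
    verify_no_leakage,
)
from vrgamma.epochs import FeatureTable


def make_table(n_subj=4, per_class=10, n_feat=6, sep=0.0, seed=0, constant=False):
    """Two-class Gaussian table; ``sep`` shifts class means apart (in SDs)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for lab, sign in (("positive", +1), ("negative", -1)):
            X = rng.standard_normal((per_class, n_feat)) + sign * sep / 2.0
            if constant:
                X = np.zeros_like(X)
            for x in X:
                rows.append(dict({f"f{i}": v for i, v in enumerate(x)},
                                 subject=f"S{s:02d}", label=lab))
    return FeatureTable(pd.DataFrame(rows))


class TestStratifiedSplit:
    def test_40_40_splits_28_12(self):
        table = make_table(n_subj=1, per_class=40)
        split = stratified_split(table, 0.7, seed=1)
        assert split.train_idx.size == 56 and split.test_idx.size == 24
        labels = table.frame["label"].to_numpy()
        assert (labels[split.train_idx] == "positive").sum() == 28
        assert (labels[split.test_idx] == "positive").sum() == 12

    def test_same_seed_same_split(self):
        table = make_table()
        a = stratified_split(table, seed=5)
        b = stratified_split(table, seed=5)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_class_ratio_preserved_within_one_trial(self):
        table = make_table(n_subj=3, per_class=7)
        split = stratified_split(table, 0.7, seed=2)
        df = table.frame
        for subj in df["subject"].unique():
            for cls in ("positive", "negative"):
                stratum = np.flatnonzero((df["subject"] == subj) & (df["label"] == cls))
                in_train = np.intersect1d(stratum, split.train_idx).size
                assert abs(in_train - 0.7 * stratum.size) <= 1.0

    def test_single_trial_class_fatal(self):
        table = make_table(n_subj=1, per_class=5)
        frame = table.frame.drop(index=range(4)).reset_index(drop=True)
        with pytest.raises(ValueError, match="need >= 2"):
            stratified_split(FeatureTable(frame))


class TestSVMProtocol:
    def test_separable_blobs_are_perfect(self):
        table = make_table(per_class=20, sep=10.0, seed=3)
        res = train_eval_svm(table, stratified_split(table, seed=3))
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    def test_confusion_marginals_match_test_counts(self):
        table = make_table(per_class=9, sep=1.0, seed=4)
        split = stratified_split(table, seed=4)
        res = train_eval_svm(table, split)
        labels = table.labels01()[split.test_idx]
        assert res.confusion[0].sum() == (labels == 0).sum()
        assert res.confusion[1].sum() == (labels == 1).sum()

    def test_null_features_near_chance(self):
        accs = [repeat_protocol(make_table(per_class=25, sep=0.0, seed=s),
                                n_reps=2, seed=s).accuracy_mean
                for s in range(5)]
        assert abs(np.mean(accs) - 0.5) <= 0.10

    def test_degenerate_scores_give_diagonal_roc(self):
        table = make_table(per_class=6, constant=True)
        res = train_eval_svm(table, stratified_split(table, seed=0))
        assert res.auc == 0.5

    def test_single_repetition_has_zero_sd(self):
        report = repeat_protocol(make_table(per_class=8, seed=6), n_reps=1, seed=6)
        assert report.accuracy_sd == 0.0 and report.auc_sd == 0.0

    def test_repetitions_vary_under_null(self):
        report = repeat_protocol(make_table(per_class=20, seed=7), n_reps=6, seed=7)
        assert report.accuracy_sd > 0.0


class TestGiniImportance:
    def _informative_table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(3):
            for lab, y in (("positive", 1.0), ("negative", 0.0)):
                for _ in range(15):
                    feats = {f"noise{i}": rng.standard_normal() for i in range(8)}
                    feats["signal"] = y + 0.05 * rng.standard_normal()
                    rows.append(dict(feats, subject=f"S{s}", label=lab))
        return FeatureTable(pd.DataFrame(rows))

    def test_informative_feature_ranks_first_every_repetition(self):
        table = self._informative_table()
        rep = gini_importance(table, n_reps=5, seed=1, n_trees=100)
        assert rep.ranking[0] == "signal"
        signal_col = rep.feature_names.index("signal")
        assert np.all(rep.per_repetition.argmax(axis=1) == signal_col)

    def test_importances_sum_to_one_per_fit(self):
        rep = gini_importance(self._informative_table(), n_reps=3, seed=2, n_trees=50)
        assert np.allclose(rep.per_repetition.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_noise_importances_roughly_uniform(self):
        table = make_table(n_subj=2, per_class=80, n_feat=59, sep=0.0, seed=8)
        rep = gini_importance(table, n_reps=5, seed=3, n_trees=200)
        assert rep.importances.max() < 3.0 * rep.importances.min()

    def test_top_n_bounds(self):
        rep = gini_importance(self._informative_table(), n_reps=2, seed=4, n_trees=50)
        with pytest.raises(ValueError):
            rep.top(1000)


class TestSubsetCurve:
    def test_informative_subset_suffices(self):
        table = self._table = TestGiniImportance()._informative_table(seed=5)
        rep = gini_importance(table, n_reps=3, seed=5, n_trees=100)
        curve = subset_accuracy_curve(table, rep.ranking, sizes=(3, 9), n_reps=4, seed=5)
        full = repeat_protocol(table, n_reps=4, seed=5).accuracy_mean
        assert curve[9] == pytest.approx(full)  # identity subset, same seeds
        assert curve[3] >= full - 0.05  # signal captured by the top features

    def test_noise_curve_near_chance(self):
        table = make_table(n_subj=2, per_class=20, n_feat=10, sep=0.0, seed=9)
        rep = gini_importance(table, n_reps=2, seed=6, n_trees=50)
        curve = subset_accuracy_curve(table, rep.ranking, sizes=(5, 10), n_reps=4, seed=6)
        for acc in curve.values():
            assert abs(acc - 0.5) <= 0.15

    def test_oversized_subset_fatal(self):
        table = make_table(n_feat=4)
        rep = gini_importance(table, n_reps=1, seed=0, n_trees=20)
        with pytest.raises(ValueError, match="exceeds"):
            subset_accuracy_curve(table, rep.ranking, sizes=(10,), n_reps=1, seed=0)


class TestLeakage:
    def test_shuffled_test_labels_do_not_move_the_model(self):
        assert verify_no_leakage(make_table(per_class=12, sep=1.0, seed=10), seed=10)
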