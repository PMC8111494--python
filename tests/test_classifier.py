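import numpy as np
import pandas as pd
import pytest

from complexmap import cv_grid_search, precision_recall, train_and_score
from complexmap.copairs_classifier import score_precision_calibration
from complexmap.core import ScoredNetwork
from complexmap.feature_matrix import FeatureMatrix
from complexmap.gold_standard import LabeledPairs


def labeled_matrix(n_pos=30, n_neg=30, separation=3.0, noise=0.5, seed=0, n_features=2):
    """Labeled matrix with a controllable signal-to-noise."""
    rng = np.random.default_rng(seed)
    pairs = [(f"a{i:03d}", f"b{i:03d}") for i in range(n_pos + n_neg)]
    y = np.array([1] * n_pos + [-1] * n_neg)
    X = rng.normal(0, noise, size=(len(pairs), n_features))
    X[:n_pos, 0] += separation
    df = pd.DataFrame(
        X,
        index=pd.MultiIndex.from_tuples(pairs, names=["accession_A", "accession_B"]),
        columns=[f"f{i}" for i in range(n_features)],
    )
    m = FeatureMatrix(df)
    m.labels = pd.Series(y, index=df.index)
    return m


class TestCvGridSearch:
    def test_separable_data_all_combos_perfect_and_tiebreak(self):
        m = labeled_matrix(separation=50.0, noise=0.01)
        res = cv_grid_search(m, (2.0, 8.0), (0.01, 0.1), k_folds=3, seed=1)
        assert (res.table["mean_auprc"] > 0.999).all()
        assert (res.best_C, res.best_gamma) == (2.0, 0.01)  # smallest on tie

    def test_permuted_labels_give_baseline_auprc(self):
        rng = np.random.default_rng(5)
        m = labeled_matrix(n_pos=40, n_neg=120, separation=2.0, seed=5)
        m.labels = pd.Series(
            rng.permutation(m.labels.to_numpy()), index=m.labels.index
        )
        res = cv_grid_search(m, (8.0,), (0.01,), k_folds=4, seed=5)
        pos_frac = (m.labels == 1).mean()
        assert res.table["mean_auprc"].iloc[0] == pytest.approx(pos_frac, abs=0.12)

    def test_single_class_rejected(self):
        m = labeled_matrix()
        m.labels[:] = 1
        with pytest.raises(ValueError):
            cv_grid_search(m, (2.0,), (0.01,), k_folds=2)


class TestTrainAndScore:
    def test_scores_every_pair_in_matrix(self):
        m = labeled_matrix()
        net = train_and_score(m, 8.0, 0.1, seed=0)
        assert len(net) == len(m)
        assert all(0.0 <= s <= 1.0 for _, s in net.items())

    def test_all_zero_features_give_flat_scores(self):
        m = labeled_matrix()
        m.data.iloc[:, :] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            net = train_and_score(m, 2.0, 0.01, seed=0)
        scores = np.array([s for _, s in net.items()])
        assert scores.std() == 0.0
        assert scores[0] == pytest.approx(0.5)  # positive fraction

    def test_planted_signal_separates_classes(self):
        m = labeled_matrix(separation=4.0, noise=1.0, seed=3)
        net = train_and_score(m, 32.0, 0.1, seed=0)
        pos = [net[p] for p in m.labels[m.labels == 1].index]
        neg = [net[p] for p in m.labels[m.labels == -1].index]
        assert np.median(pos) > np.median(neg)


class TestPrecisionRecall:
    def make_net(self, scores):
        return ScoredNetwork({(f"x{i}", f"y{i}"): s for i, s in enumerate(scores)})

    def labels_for(self, net, y):
        pairs = sorted(net.scores)
        pos = {p for p, lab in zip(pairs, y) if lab}
        neg = {p for p, lab in zip(pairs, y) if not lab}
        return LabeledPairs(pos, neg, "test")

    def test_perfect_ranking_auprc_one(self):
        net = self.make_net([0.9] * 5 + [0.1] * 5)
        lab = self.labels_for(net, [1] * 5 + [0] * 5)
        assert precision_recall(net, lab).auprc == pytest.approx(1.0)

    def test_reversed_ranking_precision_at_full_recall(self):
        net = self.make_net([0.1] * 5 + [0.9] * 5)
        lab = self.labels_for(net, [1] * 5 + [0] * 5)
        pr = precision_recall(net, lab)
        # at full recall every pair is predicted: precision = 5/10
        full_recall_precision = pr.precision[np.argmax(pr.recall >= 1.0)]
        assert full_recall_precision == pytest.approx(0.5)

    def test_leakage_asserted(self):
        net = self.make_net([0.5, 0.6])
        lab = self.labels_for(net, [1, 0])
        with pytest.raises(ValueError, match="shared"):
            precision_recall(net, lab, train_labels=lab)

    def test_no_scored_test_pairs_errors(self):
        net = self.make_net([0.5])
        lab = LabeledPairs({("q", "z")}, set(), "test")
        with pytest.raises(ValueError, match="no labeled"):
            precision_recall(net, lab)


class TestCalibration:
    def test_threshold_zero_recovers_overall_precision(self):
        net = ScoredNetwork({(f"x{i}", f"y{i}"): s for i, s in
                             enumerate([0.9, 0.8, 0.3, 0.2])})
        pairs = sorted(net.scores)
        lab = LabeledPairs(set(pairs[:2]), set(pairs[2:]), "test")
        table = score_precision_calibration(net, lab, score_bins=np.array([0.0, 0.5]))
        at_zero = table.loc[table["score_threshold"] == 0.0, "precision"].iloc[0]
        assert at_zero == pytest.approx(0.5)

    def test_calibrated_scores_map_to_identity(self):
        # scores equal to the true class probability: precision(>=t) ~ mean
        # score above t for a well-calibrated score
        rng = np.random.default_rng(7)
        scores = rng.uniform(0.05, 0.95, size=4000)
        y = rng.random(4000) < scores
        net = ScoredNetwork({(f"x{i:04d}", f"y{i:04d}"): float(s)
                             for i, s in enumerate(scores)})
        lab = LabeledPairs(
            {(f"x{i:04d}", f"y{i:04d}") for i in range(4000) if y[i]},
            {(f"x{i:04d}", f"y{i:04d}") for i in range(4000) if not y[i]},
            "test",
        )
        table = score_precision_calibration(net, lab)
        for _, row in table.iterrows():
            t = row["score_threshold"]
            if row["n_pairs"] > 200 and t < 0.9:
                expected = np.mean(scores[scores >= t])
                assert row["precision"] == pytest.approx(expected, abs=0.05)

    def test_descending_threshold_sweep(self):
        net = self.make_simple()
        table = score_precision_calibration(net[0], net[1])
        assert (np.diff(table["score_threshold"]) <= 0).all()

    @staticmethod
    def make_simple():
        net = ScoredNetwork({("a", "b"): 0.9, ("c", "d"): 0.1})
        lab = LabeledPairs({("a", "b")}, {("c", "d")}, "test")
        return net, lab
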