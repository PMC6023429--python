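"""Random-forest training, hyperparameter search, model families, voting, nested CV."""

import numpy as np
import pandas as pd
import pytest

import mwdiag as m
from mwdiag.errors import ConfigError, DataError


def gaussian_classes(seed=0, n=200, dim=30, sep=3.0):
    """Two well-separated Gaussian clouds in 30-D."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    y = np.array(["benign"] * (n // 2) + ["malignant"] * (n - n // 2))
    X[y == "malignant", :3] += sep
    return X, y


def toy_table(n_scans=10, n_channels_per_angle=4, seed=0, informative=True):
    """Observation table with synthetic per-channel features at angles 0/30/60."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_scans):
        label = "benign" if i % 2 == 0 else "malignant"
        for angle in (0.0, 30.0, 60.0):
            for c in range(n_channels_per_angle):
                feats = rng.normal(size=5)
                if informative and label == "malignant":
                    feats[0] += 2.5
                rows.append({
                    "scan_id": f"s{i:02d}", "tx": c, "rx": c + int(angle) // 30,
                    "angle": angle, "label": label,
                    **{f"f{j:02d}": feats[j] for j in range(5)},
                })
    return pd.DataFrame(rows)


class TestTrainForest:
    def test_separable_classes_low_oob_error(self):
        X, y = gaussian_classes()
        tf = m.train_forest(X, y, m.ForestConfig(100, 5, 1), seed=0)
        assert tf.oob_error < 0.1
        assert 0.0 <= tf.oob_error <= 1.0
        assert tf.importances.shape == (30,)
        assert set(tf.classes) == {"benign", "malignant"}

    def test_permuted_labels_oob_near_half(self):
        X, y = gaussian_classes(seed=1)
        rng = np.random.default_rng(0)
        errs = [
            m.train_forest(X, rng.permutation(y), m.ForestConfig(100, 5, 1), seed=s).oob_error
            for s in range(3)
        ]
        assert 0.4 <= np.mean(errs) <= 0.6

    def test_deterministic_under_seed(self):
        X, y = gaussian_classes(seed=2)
        a = m.train_forest(X, y, m.ForestConfig(50, 5, 1), seed=3)
        b = m.train_forest(X, y, m.ForestConfig(50, 5, 1), seed=3)
        assert a.oob_error == b.oob_error
        assert np.array_equal(a.estimator.predict(X), b.estimator.predict(X))

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(DataError):
            m.train_forest(X, ["benign"] * 10, m.ForestConfig(10, 1, 1))

    def test_too_many_split_features_rejected(self):
        X, y = gaussian_classes(n=40)
        with pytest.raises(ConfigError):
            m.train_forest(X, y, m.ForestConfig(10, 31, 1))


class TestHyperparameterSearch:
    SPACE = {"n_trees": (20, 80), "n_features_per_split": (1, 10), "min_leaf_size": (1, 10)}

    def test_returns_argmin_of_evaluated_set(self):
        X, y = gaussian_classes(n=80)
        cfg, history = m.optimise_hyperparameters(
            X, y, search_space=self.SPACE, budget=8, seed=0, return_history=True
        )
        errs = {c: e for c, e in history}
        assert errs[cfg] <= min(errs.values()) + 1e-12
        # ties break to the smaller tree count
        best_err = min(errs.values())
        ties = [c for c, e in errs.items() if e == best_err]
        assert cfg.n_trees == min(t.n_trees for t in ties)

    def test_beats_midpoint_on_separable_data(self):
        X, y = gaussian_classes(n=120, sep=2.0)
        cfg = m.optimise_hyperparameters(X, y, search_space=self.SPACE, budget=10, seed=1)
        mid = m.ForestConfig(50, 5, 5)
        err_best = m.train_forest(X, y, cfg, seed=1).oob_error
        err_mid = m.train_forest(X, y, mid, seed=1).oob_error
        assert err_best <= err_mid + 1e-12

    def test_deterministic_under_seed(self):
        X, y = gaussian_classes(n=60)
        a = m.optimise_hyperparameters(X, y, search_space=self.SPACE, budget=6, seed=5)
        b = m.optimise_hyperparameters(X, y, search_space=self.SPACE, budget=6, seed=5)
        assert a == b

    def test_budget_and_space_validation(self):
        X, y = gaussian_classes(n=40)
        with pytest.raises(ConfigError):
            m.optimise_hyperparameters(X, y, budget=4)
        with pytest.raises(ConfigError):
            m.optimise_hyperparameters(X, y, search_space={}, budget=5)


class TestModelFamilies:
    def test_family_sizes(self, ring12):
        assert len(m.model_family("EA", ring12)) == 7
        assert len(m.model_family("MA", ring12)) == 6
        assert len(m.model_family("EAC", ring12)) == 6

    def test_ea_uses_only_its_angle(self):
        table = toy_table()
        model = m.build_model("EA", 0.0, table, m.ForestConfig(20, 2, 1), seed=0)
        assert model.member_angles == [0.0]
        # every training row the forest saw is at angle 0
        assert model.forests[0.0].X_train.shape[0] == len(table[table.angle == 0.0])

    def test_ma_pools_range_and_eac_has_member_per_angle(self):
        table = toy_table()
        ma = m.build_model("MA", 30.0, table, m.ForestConfig(20, 2, 1), seed=0)
        assert ma.forests[30.0].X_train.shape[0] == len(table[table.angle <= 30.0])
        eac = m.build_model("EAC", 30.0, table, m.ForestConfig(20, 2, 1), seed=0)
        assert eac.member_angles == [0.0, 30.0]

    def test_ea_channel_census_on_simulated_table(self, permutation_base):
        _, table, _ = permutation_base
        per_scan = table[table.angle == 0.0].groupby("scan_id").size()
        assert (per_scan == 12).all()
        all_ch = table.groupby("scan_id").size()
        assert (all_ch == 78).all()

    def test_missing_angle_rejected(self):
        table = toy_table()
        with pytest.raises(DataError):
            m.build_model("EA", 150.0, table, m.ForestConfig(10, 2, 1))


class TestAntennaGrouping:
    @staticmethod
    def ranking(ring, channels, pos=(5.0, 5.0)):
        return m.rank_channels_by_proximity(channels, pos, ring)

    def test_small_vote_examples(self, ring12, channels12):
        rk = self.ranking(ring12, channels12)
        closest3 = [(c.tx, c.rx) for c in rk.channels[:3]]
        votes = dict(zip(closest3, ["malignant", "malignant", "benign"]))
        d = m.antenna_grouping(votes, rk, 3, scan_id="s")
        assert d.fused_label == "malignant" and d.fused_score == pytest.approx(2 / 3)
        d1 = m.antenna_grouping(votes, rk, 1)
        assert d1.fused_label == votes[closest3[0]]

    def test_tie_goes_to_malignant(self, ring12, channels12):
        rk = self.ranking(ring12, channels12)
        keys = [(c.tx, c.rx) for c in rk.channels[:4]]
        votes = dict(zip(keys, ["malignant", "benign", "malignant", "benign"]))
        assert m.antenna_grouping(votes, rk, 4).fused_label == "malignant"

    def test_every_w_matches_direct_count(self, ring12, channels12):
        rng = np.random.default_rng(0)
        rk = self.ranking(ring12, channels12, pos=(-11.0, 3.0))
        labels = rng.choice(["benign", "malignant"], size=78)
        votes = {(c.tx, c.rx): l for c, l in zip(rk.channels, labels)}
        for w in range(1, 79):
            d = m.antenna_grouping(votes, rk, w)
            direct = sum(
                votes[(c.tx, c.rx)] == "malignant" for c in rk.channels[:w]
            ) / w
            assert d.fused_score == pytest.approx(direct)

    def test_w_out_of_range(self, ring12, channels12):
        rk = self.ranking(ring12, channels12)
        votes = {(0, 0): "benign"}
        with pytest.raises(DataError):
            m.antenna_grouping(votes, rk, 2)
        with pytest.raises(DataError):
            m.antenna_grouping(votes, rk, 0)


class TestNestedCV:
    def test_partition_stratification_and_leakage_ban(self, ring12, channels12):
        table = toy_table(n_scans=10)
        rankings = {
            f"s{i:02d}": m.rank_channels_by_proximity(channels12, (5.0, 5.0), ring12)
            for i in range(10)
        }
        cv = m.nested_cv(
            table, rankings, kind="EA", angle=0.0, k=5, seed=0,
            config=m.ForestConfig(20, 2, 1),
        )
        preds = cv.predictions
        # union of test folds is the full scan set, each exactly once
        assert sorted(preds.scan_id) == sorted(table.scan_id.unique())
        assert preds.groupby("fold").size().eq(2).all()
        # stratification: one scan of each class per fold
        per_fold = preds.groupby(["fold", "true_label"]).size()
        assert per_fold.eq(1).all()

    def test_class_below_k_rejected(self, ring12, channels12):
        table = toy_table(n_scans=6)
        rankings = {
            f"s{i:02d}": m.rank_channels_by_proximity(channels12, (5.0, 5.0), ring12)
            for i in range(6)
        }
        with pytest.raises(DataError):
            m.nested_cv(table, rankings, kind="EA", angle=0.0, k=5,
                        config=m.ForestConfig(10, 2, 1))

    def test_fold_plan_balance(self):
        ids = [f"s{i}" for i in range(23)]
        labels = ["benign"] * 11 + ["malignant"] * 12
        plan = m.make_fold_plan(ids, labels, k=5, seed=0)
        counts = pd.DataFrame(
            {"fold": [plan.assignment[i] for i in ids], "label": labels}
        ).groupby(["fold", "label"]).size().unstack()
        assert (counts.max() - counts.min()).max() <= 1
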