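import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from elytra_id import featselect as fs


class TestMutualInformation:
    def test_identical_binary_variables_give_one_bit(self, rng):
        x = rng.integers(0, 2, 2000)
        assert fs.mutual_information(x, x) == pytest.approx(
            -(x.mean() * np.log2(x.mean())
              + (1 - x.mean()) * np.log2(1 - x.mean())))

    def test_independent_variables_near_zero(self, rng):
        x = rng.integers(0, 2, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert fs.mutual_information(x, y) <= 0.01

    def test_symmetry_and_nonnegativity(self, rng):
        x = rng.integers(0, 4, 500)
        y = rng.integers(0, 3, 500)
        mi = fs.mutual_information(x, y)
        assert mi >= 0.0
        assert mi == pytest.approx(fs.mutual_information(y, x))

    def test_matches_independent_estimator(self, rng):
        x = rng.integers(0, 5, 300)
        y = (x + rng.integers(0, 3, 300)) % 5
        assert fs.mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y) / np.log(2), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            fs.mutual_information([0, 1], [0, 1, 0])


class TestDiscretization:
    def test_zscore_ternary_states(self, rng):
        x = rng.normal(0, 1, (5000, 1))
        d = fs.discretize(x)
        assert set(np.unique(d)) == {0, 1, 2}
        # +-1 sigma thresholds put ~68% of a normal sample in the middle state
        assert 0.6 < (d == 1).mean() < 0.75

    def test_quantile_bins_balanced(self, rng):
        x = rng.uniform(size=(900, 1))
        d = fs.discretize(x, fs.DiscretizationSpec(method="quantile", bins=3))
        counts = np.bincount(d.ravel())
        assert counts.size == 3
        assert counts.min() >= 250


class TestMrmr:
    def test_k1_is_most_relevant_feature(self, rng):
        y = rng.integers(0, 2, 400)
        X = pd.DataFrame({
            "noise": rng.normal(size=400),
            "signal": y + rng.normal(0, 0.1, 400),
        })
        res = fs.mrmr_select(X, y, k=1)
        assert res.features == ["signal"]

    def test_redundant_copy_skipped_for_novel_feature(self):
        # hand-computable 8-sample table: y = f1 with one flipped bit,
        # f3 balanced and independent of f1.  MID step 2:
        #   f2: I(f2;y) - I(f2;f1) = 0.549 - 1 = -0.451
        #   f3: I(f3;y) - I(f3;f1) = 0.049 - 0  = 0.049  -> picks f3
        f1 = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        f3 = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        y = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        X = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": f3})
        res = fs.mrmr_select(X, y, k=2, scheme="MID",
                             disc=fs.DiscretizationSpec(method="quantile", bins=2))
        assert res.features == ["f1", "f3"]

    def test_mid_and_miq_agree_on_first_pick(self, rng):
        y = rng.integers(0, 3, 300)
        X = pd.DataFrame(rng.normal(size=(300, 6)),
                         columns=[f"f{i}" for i in range(6)])
        X["f2"] += y
        mid = fs.mrmr_select(X, y, k=3, scheme="MID")
        miq = fs.mrmr_select(X, y, k=3, scheme="MIQ")
        assert mid.features[0] == miq.features[0] == "f2"

    def test_no_duplicates_and_requested_length(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 8)))
        y = rng.integers(0, 2, 100)
        res = fs.mrmr_select(X, y, k=5)
        assert len(res.features) == 5
        assert len(set(res.features)) == 5

    def test_k_out_of_range_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        with pytest.raises(ValueError, match="k must"):
            fs.mrmr_select(X, np.zeros(20, dtype=int), k=4)


class TestCfs:
    def brute_force_best_subset(self, X, y):
        D = fs.discretize(np.asarray(X, dtype=float))
        n = D.shape[1]
        su_fc = np.array([fs.symmetric_uncertainty(D[:, j], y) for j in range(n)])
        su_ff = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            su_ff[i, j] = su_ff[j, i] = fs.symmetric_uncertainty(D[:, i], D[:, j])
        best, best_merit = None, -1.0
        for r in range(1, n + 1):
            for subset in itertools.combinations(range(n), r):
                merit = fs.cfs_merit(subset, su_fc, su_ff)
                if merit > best_merit + 1e-12:
                    best, best_merit = subset, merit
        return set(best), best_merit

    def test_single_feature_merit_is_class_correlation(self, rng):
        y = rng.integers(0, 2, 200)
        x = y + rng.normal(0, 0.2, 200)
        D = fs.discretize(x[:, None])
        su = fs.symmetric_uncertainty(D[:, 0], y)
        assert fs.cfs_merit([0], np.array([su]), np.zeros((1, 1))) == pytest.approx(su)

    def test_informative_feature_kept_both_directions(self, rng):
        y = rng.integers(0, 2, 300)
        X = pd.DataFrame(rng.normal(size=(300, 4)),
                         columns=["n1", "n2", "n3", "sig"])
        X["sig"] = y.astype(float)
        for direction in ("forward", "backward"):
            res = fs.cfs_select(X, y, direction=direction)
            assert "sig" in res.features

    def test_duplicate_informative_feature_not_added_forward(self, rng):
        y = rng.integers(0, 2, 300)
        sig = y + rng.normal(0, 0.05, 300)
        X = pd.DataFrame({"sig": sig, "dup": sig.copy(),
                          "noise": rng.normal(size=300)})
        res = fs.cfs_select(X, y, direction="forward")
        assert len({"sig", "dup"} & set(res.features)) == 1

    def test_forward_search_matches_brute_force_on_small_matrices(self, rng):
        y = rng.integers(0, 2, 150)
        X = pd.DataFrame({
            "a": y + rng.normal(0, 0.3, 150),
            "b": y + rng.normal(0, 0.3, 150),
            "c": rng.normal(size=150),
            "d": rng.normal(size=150),
            "e": y * 2.0 + rng.normal(0, 0.1, 150),
        })
        expected, expected_merit = self.brute_force_best_subset(X, y)
        res = fs.cfs_select(X, y, direction="forward")
        names = list(X.columns)
        assert {names.index(f) for f in res.features} == expected
        assert res.scores[-1] == pytest.approx(expected_merit)


class TestTopkEval:
    def test_curve_shape_and_plateau_on_sparse_signal(self):
        # two complementary indicator features carry all the label signal;
        # mRMR ranks them first despite their mutual redundancy, and the
        # accuracy curve plateaus once both are included
        rng = np.random.default_rng(11)
        rows, labels, groups = [], [], []
        for sp in range(1, 4):
            for spec in range(3):
                for _ in range(20):
                    signal = np.array([5.0 * (sp == 1), 5.0 * (sp == 2)])
                    noise = rng.normal(0, 1, 10)
                    rows.append(np.concatenate([signal + rng.normal(0, 0.3, 2), noise]))
                    labels.append(sp)
                    groups.append(f"s{sp}_{spec}")
        feats = pd.DataFrame(rows, columns=[f"stat_f{i}" for i in range(12)])
        ds = fs.SpecimenDataset(feats, pd.Series(labels), pd.Series(groups))
        ranked = fs.mrmr_select(ds.features, ds.labels, k=8, scheme="MID")
        assert set(ranked.features[:2]) == {"stat_f0", "stat_f1"}
        # a longer stopping window keeps training stable on these tiny sets
        cfg = fs.ANNConfig(patience=20)
        curve = fs.topk_eval(ds, ranked, ks=(2, 5, 8), rounds=2, seed=0, cfg=cfg)
        assert list(curve.index) == [2, 5, 8]
        assert curve.loc[2, "accuracy_mean"] == 1.0
        # all the signal is inside the top 2: the curve plateaus there
        assert (curve["accuracy_mean"] >= curve.loc[2, "accuracy_mean"] - 0.1).all()
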