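import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synlet.features import SL_NETWORK_NAME
from synlet.learn import (
    EnsembleModel,
    SLDependentConfig,
    cross_validate,
    impute_missing,
    least_connected_split,
    noisy_and_score,
    train_ensemble,
    undersample,
)
from synlet.networks import GenePair, WeightedNetwork, network_from_pairs

FAST = ("logistic", "tree")


def pair_index(pairs):
    return pd.MultiIndex.from_tuples([(p.a, p.b) for p in pairs], names=["geneA", "geneB"])


def toy_dataset(n_pos=20, n_neg=200, seed=0):
    """Linearly separable-ish dataset over synthetic gene pairs."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    y = np.array([1] * n_pos + [0] * n_neg)
    x1 = rng.normal(0, 1, n) + 3.0 * y
    x2 = rng.normal(0, 1, n)
    pairs = [GenePair(f"g{2*i}", f"g{2*i+1}") for i in range(n)]
    m = pd.DataFrame({"x1": x1, "x2": x2}, index=pair_index(pairs))
    return m, pd.Series(y, index=m.index)


class TestUndersample:
    def test_ratio_one(self):
        m, y = toy_dataset(10, 100)
        ms, ys = undersample(m, y, ratio=1, seed=0)
        assert int((ys == 1).sum()) == 10 and int((ys == 0).sum()) == 10

    def test_ratio_five(self):
        m, y = toy_dataset(10, 100)
        _, ys = undersample(m, y, ratio=5, seed=0)
        assert int((ys == 0).sum()) == 50

    def test_all_positives_retained(self):
        m, y = toy_dataset(13, 87)
        ms, ys = undersample(m, y, ratio=2.5, seed=3)
        assert int((ys == 1).sum()) == 13
        assert int((ys == 0).sum()) == int(np.floor(2.5 * 13))

    def test_seed_reproducibility(self):
        m, y = toy_dataset(10, 100)
        a = undersample(m, y, ratio=1, seed=5)[0]
        b = undersample(m, y, ratio=1, seed=5)[0]
        c = undersample(m, y, ratio=1, seed=6)[0]
        pd.testing.assert_frame_equal(a, b)
        assert not a.index.equals(c.index)

    def test_infeasible_ratio_names_max(self):
        m, y = toy_dataset(10, 50)
        with pytest.raises(ValueError, match="max feasible"):
            undersample(m, y, ratio=6, seed=0)


class TestImpute:
    def test_training_mean_substituted(self):
        idx = pd.MultiIndex.from_tuples([("a", "b"), ("c", "d"), ("e", "f")])
        train = pd.DataFrame({"f": [1.0, 3.0, np.nan]}, index=idx)
        test = pd.DataFrame({"f": [np.nan]}, index=idx[:1])
        out = impute_missing(train, test)
        assert out["f"].iloc[0] == 2.0

    def test_identity_without_missing(self):
        m, _ = toy_dataset()
        pd.testing.assert_frame_equal(impute_missing(m, m), m)

    def test_all_missing_column_zero(self):
        idx = pd.MultiIndex.from_tuples([("a", "b"), ("c", "d")])
        train = pd.DataFrame({"f": [np.nan, np.nan]}, index=idx)
        out = impute_missing(train, train)
        assert (out["f"] == 0.0).all()


class TestNoisyAnd:
    def test_all_ones(self):
        assert noisy_and_score([1, 1, 1]) == 1.0

    def test_all_halves_any_count(self):
        for k in (1, 2, 5):
            assert noisy_and_score([0.5] * k) == pytest.approx(0.0)

    def test_hand_value(self):
        assert noisy_and_score([0.9, 0.8]) == pytest.approx(0.70)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            noisy_and_score([0.5, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_bounded_and_antisymmetric(self, probs):
        s = noisy_and_score(probs)
        assert -1.0 <= s <= 1.0
        assert noisy_and_score([1 - p for p in probs]) == pytest.approx(-s, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=5),
        st.integers(0, 4),
        st.floats(0, 1),
    )
    def test_monotone_in_each_probability(self, probs, i, bump):
        i = i % len(probs)
        higher = list(probs)
        higher[i] = min(1.0, probs[i] + bump)
        assert noisy_and_score(higher) >= noisy_and_score(probs) - 1e-12


class TestEnsemble:
    def test_separable_fixture_trains_and_separates(self):
        m, y = toy_dataset(seed=1)
        model = train_ensemble(m, y, classifiers=FAST, seed=1)
        scores = model.predict_scores(m)
        assert scores[y == 1].mean() > scores[y == 0].mean()

    def test_six_family_ensemble_trains_six(self):
        m, y = toy_dataset(seed=2)
        model = train_ensemble(m, y, seed=2)
        assert len(model.classifiers) == 6

    def test_single_class_error(self):
        m, y = toy_dataset()
        with pytest.raises(ValueError):
            train_ensemble(m, (y * 0), classifiers=FAST)

    def test_prediction_matches_noisy_and_of_member_probabilities(self):
        m, y = toy_dataset(seed=3)
        model = train_ensemble(m, y, classifiers=FAST, seed=3)
        from synlet.learn import _positive_proba

        X = m.fillna(model.impute_means).to_numpy()
        probs = np.column_stack(
            [_positive_proba(c, X) for _, c in model.classifiers]
        )
        expect = [noisy_and_score(row) for row in probs]
        got = model.predict_scores(m).to_numpy()
        assert np.allclose(got, expect)

    def test_column_mismatch_named(self):
        m, y = toy_dataset()
        model = train_ensemble(m, y, classifiers=FAST)
        with pytest.raises(ValueError, match="x2"):
            model.predict_scores(m[["x1"]])

    def test_empty_matrix_empty_scores(self):
        m, y = toy_dataset()
        model = train_ensemble(m, y, classifiers=FAST)
        assert len(model.predict_scores(m.iloc[:0])) == 0

    def test_save_load_round_trip(self, tmp_path):
        m, y = toy_dataset(seed=4)
        model = train_ensemble(m, y, classifiers=FAST, seed=4)
        model.save(tmp_path / "model")
        back = EnsembleModel.load(tmp_path / "model")
        assert np.allclose(
            back.predict_scores(m).to_numpy(), model.predict_scores(m).to_numpy()
        )


class TestCrossValidate:
    def test_every_example_scored_once(self):
        m, y = toy_dataset(30, 170, seed=5)
        res = cross_validate(m, y, n_folds=10, classifiers=FAST, seed=5)
        assert res.scores.notna().all()
        assert set(res.fold) == set(range(10))

    def test_test_folds_keep_class_skew(self):
        m, y = toy_dataset(30, 270, seed=6)
        res = cross_validate(m, y, n_folds=10, classifiers=FAST, seed=6)
        for k in range(10):
            frac = y.to_numpy()[res.fold == k].mean()
            assert abs(frac - 0.1) < 0.05

    def test_too_few_positives_error(self):
        m, y = toy_dataset(3, 100)
        with pytest.raises(ValueError):
            cross_validate(m, y, n_folds=10, classifiers=FAST)

    def test_sl_dependent_network_excludes_test_positives(self):
        """Per-fold SL networks are rebuilt from training positives only:
        no test-fold positive pair may appear as an edge."""
        m, y = toy_dataset(20, 80, seed=7)
        aux = WeightedNetwork("aux")
        for (a, b) in m.index:
            aux.add_edge(a, b, 0.5)
        res = cross_validate(
            m,
            y,
            n_folds=5,
            classifiers=FAST,
            seed=7,
            sl_dependent=SLDependentConfig({"aux": aux}),
        )
        pairs = [GenePair(a, b) for a, b in m.index]
        for k, net in enumerate(res.fold_sl_networks):
            test_pos = [
                p for p, in_fold, lab in zip(pairs, res.fold == k, y)
                if in_fold and lab == 1
            ]
            assert test_pos, "stratification guarantees positives per fold"
            for p in test_pos:
                assert not net.has_edge(p.a, p.b)


class TestLeastConnectedSplit:
    def build(self):
        # (g1,g2) is the unique least-connected positive pair
        pos = [GenePair("g1", "g2"), GenePair("h1", "h2"), GenePair("h1", "h3")]
        extra = [GenePair("h2", "h3"), GenePair("h2", "h4"), GenePair("h3", "h4")]
        sl_net = network_from_pairs(pos + extra)
        neg = [GenePair("g1", "h4"), GenePair("g2", "g3"), GenePair("h4", "h5")]
        pairs = pos + neg
        idx = pair_index(pairs)
        y = pd.Series([1, 1, 1, 0, 0, 0], index=idx)
        m = pd.DataFrame({"f": np.arange(6.0)}, index=idx)
        return m, y, sl_net, pairs

    def test_least_connected_pair_held_out(self):
        m, y, sl_net, pairs = self.build()
        split = least_connected_split(m, y, sl_net, k=1)
        test_pairs = [pairs[i] for i in split.test_index]
        assert GenePair("g1", "g2") in test_pairs

    def test_train_positives_share_no_gene_with_test(self):
        m, y, sl_net, pairs = self.build()
        split = least_connected_split(m, y, sl_net, k=1)
        test_genes = {
            g for i in split.test_index if y.iloc[i] == 1 for g in pairs[i]
        }
        for i in split.train_index:
            if y.iloc[i] == 1:
                assert not (set(pairs[i]) & test_genes)

    def test_negative_test_set_within_test_positive_genes(self):
        m, y, sl_net, pairs = self.build()
        split = least_connected_split(m, y, sl_net, k=2)
        pos_genes = {
            g for i in split.test_index if y.iloc[i] == 1 for g in pairs[i]
        }
        for i in split.test_index:
            if y.iloc[i] == 0:
                assert set(pairs[i]) <= pos_genes

    def test_k_too_large_error(self):
        m, y, sl_net, _ = self.build()
        with pytest.raises(ValueError):
            least_connected_split(m, y, sl_net, k=4)

    def test_k_all_positives_empties_positive_train(self):
        m, y, sl_net, pairs = self.build()
        split = least_connected_split(m, y, sl_net, k=3)
        assert all(y.iloc[i] == 0 for i in split.train_index)
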