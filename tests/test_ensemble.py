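"""Balanced resampling, forest training, metrics and probability averaging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

import rlooppred as rp
from rlooppred import ensemble as es
from rlooppred.features import FEATURE_COLUMNS


def metrics_oracle(tp, fp, tn, fn):
    """Independent oracle: materialize the confusion matrix as label
    vectors and score them with scikit-learn."""
    y_true = [1] * tp + [0] * fp + [0] * tn + [1] * fn
    y_pred = [1] * tp + [1] * fp + [0] * tn + [0] * fn
    return {"accuracy": accuracy_score(y_true, y_pred),
            "f1": f1_score(y_true, y_pred, zero_division=0),
            "mcc": matthews_corrcoef(y_true, y_pred)}


class TestClassificationMetrics:
    def test_perfect_and_chance(self):
        perfect = rp.classification_metrics(10, 0, 10, 0)
        assert perfect == {"accuracy": 1.0, "f1": 1.0, "mcc": 1.0}
        chance = rp.classification_metrics(5, 5, 5, 5)
        assert chance["accuracy"] == 0.5
        assert chance["mcc"] == 0.0

    def test_worked_example(self):
        m = rp.classification_metrics(8, 3, 7, 2)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(0.7619, abs=1e-4)
        assert m["mcc"] == pytest.approx(0.5025, abs=1e-4)

    def test_agrees_with_sklearn_on_random_quadruples(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 50, 4))
            if tp + fp + tn + fn == 0:
                continue
            ours = rp.classification_metrics(tp, fp, tn, fn)
            ref = metrics_oracle(tp, fp, tn, fn)
            for key in ("accuracy", "f1", "mcc"):
                assert ours[key] == pytest.approx(ref[key], abs=1e-12), \
                    (tp, fp, tn, fn, key)

    def test_zero_margin_mcc_defined_as_zero(self):
        assert rp.classification_metrics(0, 0, 5, 5)["mcc"] == 0.0

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            rp.classification_metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            rp.classification_metrics(-1, 0, 1, 0)


class TestSampleBalanced:
    @pytest.fixture
    def pools(self, separable_benchmark):
        table, labels = separable_benchmark
        pos = table[table["label"] == 1]
        neg = table[table["label"] == 0]
        return pos, neg

    def test_row_count_is_positives_plus_n_neg(self, pools):
        pos, neg = pools
        sample = rp.sample_balanced(pos, neg, 55, seed=1)
        assert len(sample) == len(pos) + 55

    def test_same_seed_same_sample(self, pools):
        pos, neg = pools
        s1 = rp.sample_balanced(pos, neg, 40, seed=9)
        s2 = rp.sample_balanced(pos, neg, 40, seed=9)
        assert list(s1.index) == list(s2.index)
        s3 = rp.sample_balanced(pos, neg, 40, seed=10)
        assert list(s1.index) != list(s3.index)

    def test_pool_too_small_errors(self, pools):
        pos, neg = pools
        with pytest.raises(ValueError, match="pool"):
            rp.sample_balanced(pos, neg, len(neg) + 1, seed=0)

    def test_negatives_sampled_without_replacement(self, pools):
        pos, neg = pools
        sample = rp.sample_balanced(pos, neg, 100, seed=2)
        neg_ids = sample.index[sample["label"] == 0]
        assert len(set(neg_ids)) == 100


class TestTrainOne:
    def test_separable_data_perfect_heldout(self, separable_benchmark,
                                            small_config):
        table, labels = separable_benchmark
        pos = table[table["label"] == 1]
        neg = table[table["label"] == 0]
        balanced = rp.sample_balanced(pos, neg, 60, seed=0)
        _, mtry, cv_auc, metrics = rp.train_one(balanced, small_config, seed=0)
        assert mtry in small_config.mtry_grid
        assert metrics["accuracy"] >= 0.95
        assert cv_auc >= 0.95

    def test_null_labels_near_chance(self, null_benchmark, small_config):
        table, labels = null_benchmark
        pos = table[table["label"] == 1]
        neg = table[table["label"] == 0]
        accs = []
        for seed in range(4):
            balanced = rp.sample_balanced(pos, neg, 60, seed=seed)
            _, _, _, metrics = rp.train_one(balanced, small_config, seed=seed)
            accs.append(metrics["accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_single_class_table_errors(self, separable_benchmark, small_config):
        table, _ = separable_benchmark
        pos_only = table[table["label"] == 1]
        with pytest.raises(ValueError, match="both classes"):
            rp.train_one(pos_only, small_config, seed=0)

    def test_too_few_per_fold_errors(self, separable_benchmark):
        table, _ = separable_benchmark
        pos = table[table["label"] == 1].head(6)
        neg = table[table["label"] == 0].head(6)
        tiny = pd.concat([pos, neg])
        config = rp.EnsembleConfig(n_models=1, n_negatives_per_model=6,
                                   cv_folds=10, n_trees=10)
        with pytest.raises(ValueError, match="larger"):
            rp.train_one(tiny, config, seed=0)


class TestTrainEnsemble:
    def test_one_record_per_model(self, trained_ensemble, small_config):
        assert len(trained_ensemble.models) == small_config.n_models
        for m in trained_ensemble.models:
            assert m.mtry in small_config.mtry_grid
            for v in m.metrics.values():
                assert -1.0 <= v <= 1.0

    def test_reproducible_given_base_seed(self, separable_benchmark,
                                          small_config):
        table, labels = separable_benchmark
        positives = set(labels.index[labels == 1])
        a = rp.train_ensemble(table, positives, small_config)
        b = rp.train_ensemble(table, positives, small_config)
        pd.testing.assert_frame_equal(a.summary(), b.summary())
        pa = rp.predict_proteome(a, table).mean_probability
        pb = rp.predict_proteome(b, table).mean_probability
        pd.testing.assert_series_equal(pa, pb)

    def test_separable_data_high_mcc(self, trained_ensemble):
        assert trained_ensemble.summary().loc["mcc", "mean"] > 0.9

    def test_model_seeds_are_consecutive(self, trained_ensemble, small_config):
        seeds = [m.seed for m in trained_ensemble.models]
        assert seeds == list(range(small_config.base_seed,
                                   small_config.base_seed + len(seeds)))


class _ConstantForest:
    """Stub estimator emitting a fixed positive-class probability."""

    classes_ = np.array([0, 1])

    def __init__(self, prob):
        self.prob = prob

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.prob),
                                np.full(len(X), self.prob)])


def _stub_ensemble(probs):
    config = rp.EnsembleConfig(n_models=len(probs), n_trees=1, cv_folds=2,
                               n_negatives_per_model=1)
    models = [es.ModelRecord(i, i, _ConstantForest(p), [], 2, 1.0, {})
              for i, p in enumerate(probs)]
    return es.EnsembleModel(config=config, models=models)


def _one_row_features():
    return pd.DataFrame([np.zeros(len(FEATURE_COLUMNS))],
                        columns=FEATURE_COLUMNS,
                        index=pd.Index(["P1"], name="id"))


class TestPredictProteome:
    def test_mean_and_threshold_semantics(self):
        result = rp.predict_proteome(_stub_ensemble([0.9, 0.7, 0.8]),
                                     _one_row_features())
        assert result.mean_probability["P1"] == pytest.approx(0.8)
        assert bool(result.candidate["P1"])
        assert not bool(result.high_confidence["P1"])

    def test_unanimous_extremes(self):
        all_one = rp.predict_proteome(_stub_ensemble([1.0, 1.0]),
                                      _one_row_features())
        assert all_one.mean_probability["P1"] == 1.0
        assert bool(all_one.candidate["P1"]) and bool(all_one.high_confidence["P1"])
        all_zero = rp.predict_proteome(_stub_ensemble([0.0, 0.0]),
                                       _one_row_features())
        assert not bool(all_zero.candidate["P1"])
        assert not bool(all_zero.high_confidence["P1"])

    def test_exact_half_is_candidate(self):
        result = rp.predict_proteome(_stub_ensemble([0.5, 0.5]),
                                     _one_row_features())
        assert bool(result.candidate["P1"])

    def test_schema_mismatch_lists_missing_columns(self, trained_ensemble):
        bad = pd.DataFrame({"length": [100.0]}, index=["P1"])
        with pytest.raises(ValueError, match="gravy"):
            rp.predict_proteome(trained_ensemble, bad)

    def test_mean_bounded_and_order_invariant(self, trained_ensemble,
                                              separable_benchmark):
        table, _ = separable_benchmark
        result = rp.predict_proteome(trained_ensemble, table)
        probs = result.probabilities
        assert (result.mean_probability >= probs.min(axis=1) - 1e-12).all()
        assert (result.mean_probability <= probs.max(axis=1) + 1e-12).all()
        reordered = es.EnsembleModel(
            config=trained_ensemble.config,
            models=list(reversed(trained_ensemble.models)))
        again = rp.predict_proteome(reordered, table)
        assert np.allclose(result.mean_probability, again.mean_probability)

    def test_adding_mean_model_leaves_mean_unchanged(self):
        base = [0.2, 0.6, 0.7]
        mean = float(np.mean(base))
        with_extra = rp.predict_proteome(_stub_ensemble(base + [mean]),
                                         _one_row_features())
        assert with_extra.mean_probability["P1"] == pytest.approx(mean)

    def test_high_confidence_implies_candidate(self, trained_ensemble,
                                               separable_benchmark):
        table, _ = separable_benchmark
        result = rp.predict_proteome(trained_ensemble, table)
        assert (result.high_confidence <= result.candidate).all()


class TestCompareToScreens:
    def _result(self, called_ids, universe):
        mean = pd.Series(0.0, index=pd.Index(universe, name="id"))
        mean[list(called_ids)] = 0.95
        return es.PredictionResult(pd.DataFrame(index=mean.index), mean,
                                   mean >= 0.5, mean > 0.8)

    def test_screen_subset_fully_recovered(self):
        universe = [f"P{i}" for i in range(50)]
        called = set(universe[:20])
        pred = self._result(called, universe)
        frame = rp.compare_to_screens(pred, {"s": universe[:10]}, 50)
        assert frame.loc["s", "recovered"] == 10

    def test_disjoint_screen_recovers_zero(self):
        universe = [f"P{i}" for i in range(50)]
        pred = self._result(set(universe[:20]), universe)
        frame = rp.compare_to_screens(pred, {"s": universe[30:40]}, 50)
        assert frame.loc["s", "recovered"] == 0

    def test_empty_screen_errors(self):
        pred = self._result({"P1"}, ["P1", "P2"])
        with pytest.raises(ValueError, match="empty"):
            rp.compare_to_screens(pred, {"s": []}, 2)

    def test_random_overlap_matches_hypergeometric_mean(self):
        # 10-member call set vs 10-member screen in background 100:
        # E[overlap] = 10*10/100 = 1
        rng = np.random.default_rng(17)
        universe = [f"P{i}" for i in range(100)]
        overlaps = []
        for _ in range(400):
            called = set(rng.choice(universe, 10, replace=False))
            screen = set(rng.choice(universe, 10, replace=False))
            pred = self._result(called, universe)
            frame = rp.compare_to_screens(pred, {"s": screen}, 100)
            overlaps.append(frame.loc["s", "recovered"])
        assert np.mean(overlaps) == pytest.approx(1.0, abs=0.2)


class TestEnsembleConfig:
    def test_presets(self):
        assert rp.EnsembleConfig.preset("ipms").n_negatives_per_model == 300
        assert rp.EnsembleConfig.preset("proxms").n_negatives_per_model == 100
        with pytest.raises(ValueError, match="preset"):
            rp.EnsembleConfig.preset("other")

    def test_validation(self):
        with pytest.raises(ValueError):
            rp.EnsembleConfig(train_fraction=1.2)
        with pytest.raises(ValueError):
            rp.EnsembleConfig(cv_folds=1)
        with pytest.raises(ValueError):
            rp.EnsembleConfig(mtry_grid=(0, 5))
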