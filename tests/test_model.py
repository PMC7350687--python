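"""Nested CV bookkeeping, selection-frequency collation, step-down search."""

import warnings

import numpy as np
import pytest

import stavarsel.model as m
from stavarsel import (
    RatioFeature,
    RatioMatrix,
    StaVarSel,
    TwoStageCV,
    collate_selection_frequencies,
    generate_ct_dataset,
    preprocess_ct,
    run_stavarsel,
    run_two_stage,
    stepdown_cutoff_search,
)
from stavarsel.model import SelectionFrequencyTable, _TrainingSetAnalysis


@pytest.fixture(scope="module")
def filtered_small(small_config):
    ct, truth = generate_ct_dataset(small_config, seed=11)
    filtered, _ = preprocess_ct(ct)
    return filtered, truth


def _fit_small(filtered, seed=11, repeats=3, k=5):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_stavarsel(filtered, repeats=repeats, k=k, seed=seed)


class TestTwoStage:
    @pytest.fixture(scope="class")
    def fitted(self, filtered_small):
        filtered, _ = filtered_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_two_stage(filtered, rule="lambda_min", repeats=3, k=5, seed=2)

    def test_one_heldout_prediction_per_sample(self, filtered_small, fitted):
        filtered, _ = filtered_small
        preds, fits = fitted
        assert len(preds.sample_ids) == filtered.n_samples
        assert len(set(preds.sample_ids)) == filtered.n_samples
        assert np.all((preds.probability >= 0) & (preds.probability <= 1))

    def test_heldout_sample_never_in_training_set(self, fitted):
        _, fits = fitted
        for f in fits:
            assert f.held_out_sample not in f.training_sample_ids

    def test_one_se_lambda_at_least_lambda_min(self, fitted):
        _, fits = fitted
        for f in fits:
            assert f.lambda_1se_mean >= f.lambda_min_mean

    def test_separable_signal_predicts_held_out_accurately(self, filtered_small, fitted):
        preds, _ = fitted
        assert preds.accuracy() > 0.9

    def test_model_results_object(self, filtered_small):
        filtered, _ = filtered_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = TwoStageCV(filtered, rule="one_se", repeats=2, k=5).fit(seed=3)
        assert 0.0 <= res.auc <= 1.0
        assert "one_se" in res.summary()


class TestSelectionFrequencies:
    def test_toy_collation_hand_count(self):
        """3 training sets x 2 repeats; a feature selected in 3 of 6 fits
        must come out at exactly 50%."""
        feats = [RatioFeature("a", "b"), RatioFeature("c", "d")]
        values = np.abs(np.random.default_rng(0).normal(5, 1, size=(2, 12))) + 0.1
        ratios = RatioMatrix(feats, values, [f"s{i}" for i in range(12)], np.array([0, 1] * 6))
        analyses = [
            _TrainingSetAnalysis(0, [], None, [np.array([0]), np.array([0, 1])]),
            _TrainingSetAnalysis(1, [], None, [np.array([1]), np.array([0])]),
            _TrainingSetAnalysis(2, [], None, [np.array([], dtype=int), np.array([1])]),
        ]
        freq = collate_selection_frequencies(ratios, analyses=analyses)
        pct = dict(zip([f.name for f in freq.features], freq.percent))
        assert freq.total_fits == 6
        assert pct["a/b"] == pytest.approx(50.0)
        assert pct["c/d"] == pytest.approx(50.0)

    def test_never_selected_feature_absent(self):
        feats = [RatioFeature("a", "b"), RatioFeature("c", "d")]
        values = np.full((2, 12), 2.0)
        values[0] += np.linspace(0, 1, 12)
        ratios = RatioMatrix(feats, values, [f"s{i}" for i in range(12)], np.array([0, 1] * 6))
        analyses = [_TrainingSetAnalysis(0, [], None, [np.array([0])])]
        freq = collate_selection_frequencies(ratios, analyses=analyses)
        assert [f.name for f in freq.features] == ["a/b"]

    def test_always_selected_feature_at_100_percent(self):
        feats = [RatioFeature("a", "b")]
        values = np.abs(np.random.default_rng(1).normal(5, 1, (1, 12))) + 0.1
        ratios = RatioMatrix(feats, values, [f"s{i}" for i in range(12)], np.array([0, 1] * 6))
        analyses = [
            _TrainingSetAnalysis(i, [], None, [np.array([0]), np.array([0])])
            for i in range(3)
        ]
        freq = collate_selection_frequencies(ratios, analyses=analyses)
        assert freq.percent[0] == 100.0

    def test_invariant_to_feature_order_on_independent_toy(self):
        """With independent features the lasso solution is unique, so the
        frequency table cannot depend on feature ordering."""
        rng = np.random.default_rng(12)
        n, p = 40, 8
        y = np.array([0, 1] * (n // 2))
        values = rng.lognormal(1, 0.5, size=(p, n))
        values[0] *= np.where(y == 1, 3.0, 1.0)
        values[1] *= np.where(y == 1, 1.0, 2.0)
        feats = [RatioFeature(f"n{i}", f"d{i}") for i in range(p)]
        ratios = RatioMatrix(feats, values, [f"s{i}" for i in range(n)], y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = collate_selection_frequencies(ratios, repeats=2, k=5, seed=9)
            perm = np.random.default_rng(0).permutation(p)
            f2 = collate_selection_frequencies(
                ratios.subset_features(perm), repeats=2, k=5, seed=9
            )
        d1 = dict(zip([f.name for f in f1.features], f1.percent))
        d2 = dict(zip([f.name for f in f2.features], f2.percent))
        assert d1 == d2


class TestStepdownCutoff:
    def _freq_and_ratios(self, percents, n=40, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        feats = [RatioFeature(f"n{i}", f"d{i}") for i in range(len(percents))]
        values = np.abs(rng.normal(5, 1, size=(len(percents), n))) + 0.1
        values[0] *= np.where(y == 1, 3.0, 1.0)  # one informative feature
        ratios = RatioMatrix(feats, values, [f"s{i}" for i in range(n)], y)
        total = 100
        counts = (np.asarray(percents) * total / 100).astype(int)
        freq = SelectionFrequencyTable(feats, counts, total)
        return freq, ratios

    def test_all_features_at_100_with_single_cutoff(self):
        freq, ratios = self._freq_and_ratios([100, 100, 100])
        model = stepdown_cutoff_search(freq, ratios, cutoff_grid=np.array([100.0]), repeats=2, k=5, seed=0)
        assert model.cutoff_percent == 100.0
        assert len(model.features) == 3

    def test_tie_breaks_to_highest_cutoff(self, monkeypatch):
        freq, ratios = self._freq_and_ratios([100, 80, 60])
        monkeypatch.setattr(m, "_cv_misclassification", lambda *a, **k: 0.25)
        model = stepdown_cutoff_search(freq, ratios, repeats=2, k=5, seed=0)
        assert model.cutoff_percent == 100.0
        assert len(model.features) == 1

    def test_empty_cutoffs_skipped_and_floor_respected(self):
        freq, ratios = self._freq_and_ratios([40, 40])
        model = stepdown_cutoff_search(
            freq, ratios, cutoff_grid=np.array([100.0, 70.0, 40.0]), repeats=2, k=5, seed=0
        )
        assert model.cutoff_percent == 40.0

    def test_all_cutoffs_empty_raises(self):
        freq, ratios = self._freq_and_ratios([10])
        with pytest.raises(ValueError, match="no cutoff"):
            stepdown_cutoff_search(freq, ratios, cutoff_grid=np.array([100.0, 50.0]), repeats=2, k=5, seed=0)


class TestStaVarSel:
    def test_n_predictions_and_determinism(self, filtered_small):
        filtered, _ = filtered_small
        stable1, preds1 = _fit_small(filtered, seed=11)
        stable2, preds2 = _fit_small(filtered, seed=11)
        assert len(preds1.sample_ids) == filtered.n_samples
        assert [f.name for f in stable1.features] == [f.name for f in stable2.features]
        assert np.array_equal(preds1.probability, preds2.probability)

    def test_stable_set_carries_planted_signal(self, filtered_small):
        """The stable panel need not touch every informative assay (a sparse
        model can classify with a subset), but it must be built on planted
        signal and separate the classes."""
        filtered, truth = filtered_small
        stable, preds = _fit_small(filtered, seed=11)
        informative = set(truth.informative_ids)
        touched = {
            a
            for f in stable.features
            for a in (f.numerator_assay, f.denominator_assay)
            if a in informative
        }
        assert len(touched) >= 2
        from stavarsel import roc_curve

        assert roc_curve(preds.probability, preds.y_true).auc >= 0.9

    def test_stable_under_fewer_repeats(self, filtered_small):
        """Halving the inner repeats must not lose the planted signal."""
        filtered, truth = filtered_small
        informative = set(truth.informative_ids)
        for repeats in (2, 4):
            stable, _ = _fit_small(filtered, seed=11, repeats=repeats)
            touched = {
                a
                for f in stable.features
                for a in (f.numerator_assay, f.denominator_assay)
                if a in informative
            }
            assert len(touched) >= 2

    def test_outer_refit_excludes_held_out_row(self, filtered_small, monkeypatch):
        """Every outer logistic refit must see a design matrix without the
        held-out sample's row."""
        filtered, _ = filtered_small
        n = filtered.n_samples
        seen_sizes = []
        orig = m.fit_logistic

        def spy(X, y, ridge=1e-8):
            seen_sizes.append(X.shape[0])
            return orig(X, y, ridge=ridge)

        monkeypatch.setattr(m, "fit_logistic", spy)
        _fit_small(filtered, seed=3, repeats=2, k=5)
        # the last n calls are the outer LOO refits
        assert seen_sizes[-n:] == [n - 1] * n

    def test_strictly_nested_selection_variant(self, filtered_small):
        """The leakage-sensitivity variant re-derives the stable set inside
        each outer training set; it must still produce one probability per
        sample, and its global stable model matches the default mode's."""
        filtered, _ = filtered_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stable_g, preds_g = run_stavarsel(filtered, repeats=2, k=5, seed=6)
            stable_n, preds_n = run_stavarsel(
                filtered, repeats=2, k=5, seed=6, nested_selection=True
            )
        assert [f.name for f in stable_n.features] == [f.name for f in stable_g.features]
        assert len(preds_n.sample_ids) == filtered.n_samples
        assert np.all((preds_n.probability >= 0) & (preds_n.probability <= 1))
        # nested predictions come from differently-selected models
        assert not np.array_equal(preds_n.probability, preds_g.probability)

    def test_model_class_summary_and_roc(self, filtered_small):
        filtered, _ = filtered_small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = StaVarSel(filtered, repeats=2, k=5).fit(seed=1)
        s = res.summary()
        assert "stable features" in s and "AUC" in s
        assert res.auc > 0.8
        assert res.frequency_table.total_fits == filtered.n_samples * 2
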