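"""Training-loop and evaluation machinery: loss closed forms, early-stopping
arithmetic, stratified split sizes and hygiene, metric oracles, regimes."""

import numpy as np
import pytest

from connectogcn.models import ModelSpec
from connectogcn.synthetic import SyntheticConfig, generate_dataset
from connectogcn.training import (
    EarlyStopper,
    TrainConfig,
    assert_no_leakage,
    class_weights_from_labels,
    evaluate_on,
    make_splits,
    run_regime,
    train_model,
    weighted_bce,
)


class StubModel:
    """Returns canned scores; lets metric paths be tested in isolation."""

    is_deep = False

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def predict_scores(self, graphs):
        return self._scores[: len(graphs)]


class TestWeightedBCE:
    def test_half_score_is_ln2(self):
        assert weighted_bce([0.5], [1]) == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_scores_vanish(self):
        assert weighted_bce([1.0, 0.0], [1, 0]) < 1e-10

    def test_unit_weights_equal_unweighted(self, rng):
        s = rng.random(20)
        y = rng.integers(0, 2, 20)
        manual = -np.mean(y * np.log(s) + (1 - y) * np.log(1 - s))
        assert weighted_bce(s, y, (1.0, 1.0)) == pytest.approx(manual, rel=1e-9)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce([0.5], [2])

    def test_inverse_frequency_weights_normalized_to_mean_one(self):
        w0, w1 = class_weights_from_labels([0, 0, 0, 1])
        assert (w0 + w1) / 2 == pytest.approx(1.0)
        assert w1 / w0 == pytest.approx(3.0)  # minority upweighted
        assert class_weights_from_labels([0, 1]) == (1.0, 1.0)


class TestEarlyStopper:
    def test_constant_loss_stops_after_patience_epochs(self):
        stopper = EarlyStopper(35)
        stops = [stopper.update(1.0, epoch) for epoch in range(40)]
        # epoch 0 sets the best; epochs 1..35 are stale -> stop at epoch 35,
        # i.e. the 36th epoch overall, keeping the first epoch's weights
        assert stops.index(True) == 35
        assert stopper.best_epoch == 0

    def test_decreasing_loss_never_stops(self):
        stopper = EarlyStopper(5)
        assert not any(stopper.update(1.0 / (e + 1), e) for e in range(100))

    def test_patience_cannot_exceed_epochs(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, early_stopping_patience=35)


@pytest.fixture(scope="module")
def dataset100():
    return generate_dataset(SyntheticConfig(n_regions=8, n_adult=100, n_pediatric=0, seed=1))


@pytest.fixture(scope="module")
def signal_data():
    return generate_dataset(
        SyntheticConfig(n_regions=12, n_adult=60, n_pediatric=0,
                        sex_effect_size=1.2, noise_sd=0.2, seed=4)
    )


@pytest.fixture(scope="module")
def two_cohort_data():
    return generate_dataset(
        SyntheticConfig(n_regions=10, n_adult=60, n_pediatric=135,
                        female_fraction_pediatric=0.563, seed=6)
    )


class TestSplits:
    def test_deep_splits_are_70_10_20(self, dataset100):
        plan = make_splits(dataset100, model_family="deep", seed=0)
        for f in plan.folds:
            assert len(f.test) == 20
            assert len(f.val) == 10
            assert len(f.train) == 70

    def test_shallow_splits_are_80_20(self, dataset100):
        plan = make_splits(dataset100, model_family="shallow", seed=0)
        for f in plan.folds:
            assert len(f.test) == 20
            assert len(f.train) == 80
            assert len(f.val) == 0

    def test_every_subject_in_exactly_one_test_fold(self, dataset100):
        plan = make_splits(dataset100, model_family="deep", seed=3)
        tests = np.concatenate([f.test for f in plan.folds])
        assert sorted(tests.tolist()) == list(range(100))
        assert_no_leakage(plan)

    def test_enriched_folds_preserve_cohort_ratio(self):
        data = generate_dataset(
            SyntheticConfig(n_regions=8, n_adult=309, n_pediatric=135, seed=2)
        )
        plan = make_splits(data, mode="enriched", model_family="deep", seed=0)
        cohorts = np.array([g.cohort == "adult" for g in data])
        for f in plan.folds:
            # 309/444 = 69.6% adults, within 1 subject of exact per fold
            n_adult_exact = len(f.test) * 309 / 444
            assert abs(cohorts[f.test].sum() - n_adult_exact) <= 1

    def test_determinism(self, dataset100):
        a = make_splits(dataset100, model_family="deep", seed=7)
        b = make_splits(dataset100, model_family="deep", seed=7)
        for fa, fb in zip(a.folds, b.folds):
            np.testing.assert_array_equal(fa.train, fb.train)
            np.testing.assert_array_equal(fa.val, fb.val)
            np.testing.assert_array_equal(fa.test, fb.test)

    def test_small_stratum_warns(self):
        data = generate_dataset(
            SyntheticConfig(n_regions=8, n_adult=40, n_pediatric=6, seed=5)
        )
        with pytest.warns(UserWarning, match="fewer than 5"):
            make_splits(data, mode="enriched", model_family="deep", seed=0)

    def test_enriched_requires_both_cohorts(self, dataset100):
        with pytest.raises(ValueError, match="both cohorts"):
            make_splits(dataset100, mode="enriched")


class TestMetrics:
    def test_perfect_scores_give_full_marks(self, tiny_dataset):
        graphs = tiny_dataset[:10]
        labels = [g.label for g in graphs]
        frag = evaluate_on(StubModel(labels), graphs, strata=("overall",))
        assert frag["overall"]["accuracy"] == 100.0
        assert frag["overall"]["auc"] == 1.0

    def test_constant_scores_give_prevalence_accuracy_and_tied_auc(self):
        data = generate_dataset(
            SyntheticConfig(n_regions=6, n_adult=0, n_pediatric=135,
                            female_fraction_pediatric=0.563, seed=9)
        )
        frag = evaluate_on(StubModel([0.7] * 135), data, strata=("overall",))
        assert frag["overall"]["accuracy"] == pytest.approx(100 * 76 / 135)
        assert frag["overall"]["auc"] == pytest.approx(0.5)  # all ties counted half

    def test_auc_matches_pairwise_enumeration(self, tiny_dataset):
        graphs = tiny_dataset[:3]
        # labels of the stub test: [1, 0, 0]; scores [0.9, 0.8, 0.3]
        stub_graphs = [g for g in graphs]
        labels = [1, 0, 0]
        stub_graphs = [type(g)(g.adjacency, g.node_features, l, g.cohort, g.subject_id)
                       for g, l in zip(graphs, labels)]
        frag = evaluate_on(StubModel([0.9, 0.8, 0.3]), stub_graphs, strata=("overall",))
        assert frag["overall"]["auc"] == 1.0  # both (pos, neg) pairs correctly ordered
        assert frag["overall"]["accuracy"] == pytest.approx(100 * 2 / 3)

    def test_single_class_stratum_flags_auc_undefined(self, tiny_dataset):
        g = tiny_dataset[0]
        males = [type(g)(g.adjacency, g.node_features, 0, g.cohort, f"m{i}")
                 for i in range(4)]
        frag = evaluate_on(StubModel([0.6, 0.4, 0.2, 0.9]), males, strata=("overall",))
        assert frag["overall"]["auc"] is None


class TestTrainModel:
    def test_training_reduces_loss_on_learnable_signal(self, signal_data):
        plan = make_splits(signal_data, model_family="deep", seed=0)
        spec = ModelSpec(name="gcn_simple", n_regions=12)
        _, curves = train_model(spec, signal_data, plan, 0, TrainConfig(seed=0))
        assert curves["train_loss"][-1] < curves["train_loss"][0]

    def test_identical_seeds_reproduce_metrics(self, signal_data):
        plan = make_splits(signal_data, model_family="deep", seed=1)
        spec = ModelSpec(name="gcn_simple", n_regions=12)
        cfg = TrainConfig(seed=9, epochs=5, early_stopping_patience=5)
        m1, c1 = train_model(spec, signal_data, plan, 0, cfg)
        m2, c2 = train_model(spec, signal_data, plan, 0, cfg)
        assert c1 == c2
        g = signal_data[plan.folds[0].test[0]]
        assert m1.predict_scores([g])[0] == m2.predict_scores([g])[0]

    def test_shallow_models_ignore_epoch_machinery(self, signal_data):
        plan = make_splits(signal_data, model_family="shallow", seed=0)
        spec = ModelSpec(name="rf", n_regions=12)
        model, curves = train_model(spec, signal_data, plan, 0)
        assert curves == {"train_loss": [], "val_loss": []}
        assert model.fitted


class TestRegimes:
    def test_pediatric_regime_has_five_27_subject_test_sets(self, two_cohort_data):
        report = run_regime("pediatric_pediatric",
                            [ModelSpec(name="rf", n_regions=10)], two_cohort_data)
        rows = report.rows
        assert (rows[rows.stratum == "overall"].n == 27).all()
        assert len(rows[rows.stratum == "overall"]) == 5

    def test_adult_to_pediatric_never_trains_on_pediatric(self, two_cohort_data):
        n_adult = sum(g.cohort == "adult" for g in two_cohort_data)
        report = run_regime("adult_to_pediatric",
                            [ModelSpec(name="rf", n_regions=10)], two_cohort_data)
        plan = report.plans["shallow"]
        # plan indices address the adult subset only
        assert plan.n == n_adult
        for f in plan.folds:
            assert f.train.max(initial=-1) < n_adult
        # every fold's model is evaluated on the full pediatric cohort
        assert (report.rows[report.rows.stratum == "pediatric"].n == 135).all()

    def test_enriched_each_subject_tested_exactly_once(self, two_cohort_data):
        report = run_regime("enriched", [ModelSpec(name="rf", n_regions=10)],
                            two_cohort_data)
        plan = report.plans["shallow"]
        tests = np.concatenate([f.test for f in plan.folds])
        assert len(np.unique(tests)) == len(two_cohort_data)

    def test_unknown_regime_rejected(self, two_cohort_data):
        with pytest.raises(ValueError, match="unknown regime"):
            run_regime("transfer", [ModelSpec(name="rf", n_regions=10)], two_cohort_data)

    def test_summary_aggregates_mean_and_sample_sd(self, two_cohort_data):
        report = run_regime("pediatric_pediatric",
                            [ModelSpec(name="rf", n_regions=10)], two_cohort_data)
        s = report.summary()
        row = s[s.stratum == "overall"].iloc[0]
        per_fold = report.rows[report.rows.stratum == "overall"].accuracy
        assert row.accuracy_mean == pytest.approx(per_fold.mean())
        assert row.accuracy_sd == pytest.approx(per_fold.std(ddof=1))
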