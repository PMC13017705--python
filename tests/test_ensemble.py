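import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from floracast.ensemble import (
    LEARNER_KINDS,
    EnsembleModel,
    Learner,
    auc,
    build_ensemble,
    cross_validated_auc,
    fit_learner,
    fit_species_ensemble,
    learner_from_params,
    max_tss_threshold,
    tss_at_threshold,
)
from floracast.errors import (
    FitFailureError,
    UndefinedAUCError,
    UnmodelableSpeciesError,
)
from floracast.prep import ModelingDataset


# ------------------------------------------------------------------ oracles
def auc_pair_count(sp, sb):
    """Brute-force Mann-Whitney AUC: loop over all presence x background pairs."""
    total = 0.0
    for p in sp:
        for b in sb:
            total += 1.0 if p > b else (0.5 if p == b else 0.0)
    return total / (len(sp) * len(sb))


def tss_exhaustive_argmax(sp, sb):
    """Scan every candidate (unique scores + midpoints), lowest argmax wins."""
    uniq = np.unique(np.concatenate([sp, sb]))
    cands = np.unique(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2]))
    best_t, best = None, -np.inf
    for t in cands:
        v = (np.mean(sp >= t)) + (np.mean(sb < t)) - 1.0
        if v > best + 1e-15:
            best_t, best = t, v
    return best_t


class TestAUC:
    def test_hand_example(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_perfect_ranking(self):
        assert auc([0.8, 0.9], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_empty_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc([], [0.5])

    def test_oracle_equivalence_200_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_p = int(rng.integers(1, 12))
            n_b = int(rng.integers(1, 12))
            # discrete values force ties
            sp = rng.integers(0, 5, n_p) / 4.0
            sb = rng.integers(0, 5, n_b) / 4.0
            assert abs(auc(sp, sb) - auc_pair_count(sp, sb)) < 1e-12

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, sp, sb):
        assert abs(auc(sp, sb) - auc_pair_count(sp, sb)) < 1e-12


class TestLearners:
    def test_envelope_inside_box(self, separable_dataset):
        learner = fit_learner("envelope", separable_dataset)
        center = separable_dataset.X_presence.mean(axis=0, keepdims=True)
        assert learner.predict_suitability(center)[0] == pytest.approx(1.0)

    def test_mahalanobis_at_mean(self, separable_dataset):
        learner = fit_learner("mahalanobis", separable_dataset)
        center = separable_dataset.X_presence.mean(axis=0, keepdims=True)
        assert learner.predict_suitability(center)[0] == pytest.approx(1.0, abs=1e-9)

    def test_logistic2_separable_training_auc(self, separable_dataset):
        learner = fit_learner("logistic2", separable_dataset)
        sp = learner.predict_suitability(separable_dataset.X_presence)
        sb = learner.predict_suitability(separable_dataset.X_background)
        assert auc(sp, sb) >= 0.99

    @pytest.mark.parametrize("kind", LEARNER_KINDS)
    def test_outputs_in_unit_interval(self, kind, separable_dataset):
        learner = fit_learner(kind, separable_dataset, seed=0)
        X = np.linspace(-5, 10, 50).reshape(-1, 1)
        s = learner.predict_suitability(X)
        assert np.all(s >= 0) and np.all(s <= 1)

    @pytest.mark.parametrize("kind", LEARNER_KINDS)
    def test_params_roundtrip(self, kind, separable_dataset):
        learner = fit_learner(kind, separable_dataset, seed=0)
        clone = learner_from_params(learner.to_params())
        X = np.linspace(-3, 8, 40).reshape(-1, 1)
        np.testing.assert_allclose(
            clone.predict_suitability(X), learner.predict_suitability(X), atol=1e-12
        )

    def test_too_few_cells_rejected(self):
        ds = ModelingDataset(
            "tiny",
            presence_cells=np.array([0]),
            background_cells=np.array([5, 6]),
            X_presence=np.array([[1.0]]),
            X_background=np.array([[0.0], [0.2]]),
            covariate_names=["x"],
        )
        with pytest.raises(FitFailureError):
            fit_learner("envelope", ds)


class TestCrossValidatedAUC:
    @pytest.mark.parametrize("kind", LEARNER_KINDS)
    def test_separable(self, kind, separable_dataset):
        # the envelope's [p5, p95] box trims 10% of presences by construction
        floor = 0.9 if kind == "envelope" else 0.95
        assert cross_validated_auc(kind, separable_dataset, 5, seed=0) >= floor

    def test_separable_fold_robustness(self, separable_dataset):
        for folds in (2, 5):
            assert cross_validated_auc("logistic2", separable_dataset, folds, seed=0) >= 0.99

    def test_permutation_null(self):
        rng = np.random.default_rng(3)
        ds = ModelingDataset(
            "null",
            presence_cells=np.arange(500),
            background_cells=np.arange(1000, 1500),
            X_presence=rng.normal(size=(500, 2)),
            X_background=rng.normal(size=(500, 2)),
            covariate_names=["a", "b"],
        )
        assert cross_validated_auc("logistic2", ds, 5, seed=0) == pytest.approx(0.5, abs=0.1)

    def test_fold_reduction_warning(self, caplog):
        rng = np.random.default_rng(0)
        ds = ModelingDataset(
            "few",
            presence_cells=np.arange(3),
            background_cells=np.arange(10, 40),
            X_presence=rng.normal(5, 1, size=(3, 1)),
            X_background=rng.normal(0, 1, size=(30, 1)),
            covariate_names=["x"],
        )
        with caplog.at_level("WARNING"):
            cross_validated_auc("envelope", ds, 5, seed=0)
        assert any("reducing folds" in r.message for r in caplog.records)


class _Stub(Learner):
    kind = "stub"

    def __init__(self, column):
        self.column = column

    def predict_suitability(self, X):
        return np.clip(X[:, self.column], 0, 1)


class TestBuildEnsemble:
    def test_single_passing_learner(self):
        model = build_ensemble("sp", {"a": _Stub(0), "b": _Stub(0)}, {"a": 0.9, "b": 0.6})
        assert model.weights["a"] == 1.0 and model.weights["b"] == 0.0

    def test_two_learner_weights(self):
        model = build_ensemble("sp", {"a": _Stub(0), "b": _Stub(0)}, {"a": 0.9, "b": 0.7})
        assert model.weights["a"] == pytest.approx(2 / 3)
        assert model.weights["b"] == pytest.approx(1 / 3)

    def test_equal_aucs_equal_weights(self):
        learners = {k: _Stub(0) for k in LEARNER_KINDS}
        model = build_ensemble("sp", learners, {k: 0.8 for k in LEARNER_KINDS})
        for w in model.weights.values():
            assert w == pytest.approx(0.2)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            aucs = {k: float(rng.uniform(0.4, 1.0)) for k in LEARNER_KINDS}
            learners = {k: _Stub(0) for k in LEARNER_KINDS}
            try:
                model = build_ensemble("sp", learners, aucs, auc_cutoff=0.7)
            except UnmodelableSpeciesError:
                assert max(aucs.values()) < 0.7
                continue
            assert sum(model.weights.values()) == pytest.approx(1.0, abs=1e-9)
            for k, a in aucs.items():
                if a < 0.7:
                    assert model.weights[k] == 0.0

    def test_no_learner_passes(self):
        with pytest.raises(UnmodelableSpeciesError):
            build_ensemble("sp", {"a": _Stub(0)}, {"a": 0.55}, auc_cutoff=0.7)

    def test_ensemble_monotone_in_learner_scores(self):
        # two stub learners reading different columns; raising both columns
        # cannot lower the ensemble score
        model = build_ensemble(
            "sp", {"a": _Stub(0), "b": _Stub(1)}, {"a": 0.9, "b": 0.8},
            train_min=np.array([0.0, 0.0]), train_max=np.array([1.0, 1.0]),
        )
        lo = model.predict(np.array([[0.2, 0.3]]))
        hi = model.predict(np.array([[0.4, 0.6]]))
        assert hi[0] >= lo[0]


class TestMaxTSS:
    def test_separable_lowest_winner(self):
        sp = np.array([0.8, 0.85, 0.9])
        sb = np.array([0.1, 0.2, 0.3])
        t = max_tss_threshold(sp, sb)
        assert 0.3 < t <= 0.8
        assert t == tss_exhaustive_argmax(sp, sb)
        assert tss_at_threshold(sp, sb, t) == pytest.approx(1.0)

    def test_hand_example_matches_oracle(self):
        sp = np.array([0.9, 0.6, 0.4])
        sb = np.array([0.5, 0.2])
        assert max_tss_threshold(sp, sb) == tss_exhaustive_argmax(sp, sb)

    def test_single_pair(self):
        t = max_tss_threshold([1.0], [0.0])
        assert 0.0 < t <= 1.0
        assert tss_at_threshold(np.array([1.0]), np.array([0.0]), t) == 1.0

    def test_returned_threshold_is_global_max(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            sp = rng.integers(0, 10, rng.integers(1, 10)) / 9.0
            sb = rng.integers(0, 10, rng.integers(1, 10)) / 9.0
            t = max_tss_threshold(sp, sb)
            best = tss_at_threshold(sp, sb, t)
            uniq = np.unique(np.concatenate([sp, sb]))
            cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2])
            assert all(tss_at_threshold(sp, sb, c) <= best + 1e-12 for c in cands)


class TestSpeciesEnsemble:
    def test_full_fit(self, dataset_small):
        model = fit_species_ensemble(dataset_small, seed=0)
        assert sum(model.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= model.threshold_tss <= 1.0
        scores = model.predict(dataset_small.X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_serialization_roundtrip(self, dataset_small):
        model = fit_species_ensemble(dataset_small, seed=0)
        clone = EnsembleModel.from_dict(model.to_dict())
        np.testing.assert_allclose(
            clone.predict(dataset_small.X), model.predict(dataset_small.X), atol=1e-12
        )

    def test_recovery_against_truth(self, species_small, dataset_small, current_grid):
        model = fit_species_ensemble(dataset_small, seed=0)
        suit = model.predict(current_grid.covariate_matrix(model.covariate_names))
        truth = species_small[0].range_true.ravel()
        assert auc(suit[truth], suit[~truth]) >= 0.9
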