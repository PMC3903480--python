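"""Decoding primitives: folds, weights, normalization, SVM+Platt, AUC."""

import numpy as np
import pytest

import tgdecode as tg
from tgdecode.decoding import _platt_fit


def _toy_contrast(subclasses, y=None):
    subclasses = np.asarray(subclasses, dtype=object)
    if y is None:
        y = np.where(np.char.startswith(subclasses.astype(str), "LD"), 1, -1)
    return tg.ContrastSpec(
        name="local",
        trial_indices=np.arange(len(subclasses)),
        y=y,
        subclass=subclasses,
    )


class TestStratifiedFolds:
    def test_imbalanced_global_contrast_fold_sizes(self):
        # 600 standards (LSGS) vs 180 deviants (LDGD), k=10
        sub = np.array(["LSGS"] * 600 + ["LDGD"] * 180, dtype=object)
        contrast = _toy_contrast(sub, y=np.array([-1] * 600 + [1] * 180))
        folds = tg.stratified_folds(contrast, k=10, seed=0)
        for f in range(10):
            test = folds.fold_index == f
            assert (sub[test] == "LSGS").sum() == 60
            assert (sub[test] == "LDGD").sum() == 18

    def test_two_subclasses_of_ten(self):
        contrast = _toy_contrast(["LSGS"] * 10 + ["LDGD"] * 10)
        folds = tg.stratified_folds(contrast, k=10, seed=1)
        for f in range(10):
            assert (folds.fold_index == f).sum() == 2

    def test_deterministic(self):
        contrast = _toy_contrast(["LSGS"] * 30 + ["LDGD"] * 30)
        a = tg.stratified_folds(contrast, k=5, seed=3)
        b = tg.stratified_folds(contrast, k=5, seed=3)
        assert np.array_equal(a.fold_index, b.fold_index)

    def test_small_subclass_errors_with_name(self):
        contrast = _toy_contrast(["LSGS"] * 20 + ["LDGD"] * 5)
        with pytest.raises(ValueError, match="LDGD"):
            tg.stratified_folds(contrast, k=10)


class TestSubclassWeights:
    def test_hand_computed_ratios(self):
        sub = (["LSGS"] * 300 + ["LDGS"] * 300 + ["LSGD"] * 90 + ["LDGD"] * 90)
        w = tg.subclass_weights(np.array(sub, dtype=object))
        sub = np.array(sub)
        # per-trial weights in ratio 1/300 : 1/300 : 1/90 : 1/90
        assert w[sub == "LSGD"][0] / w[sub == "LSGS"][0] == pytest.approx(300 / 90)
        # equal total weight per subclass
        totals = [w[sub == s].sum() for s in ("LSGS", "LDGS", "LSGD", "LDGD")]
        assert np.allclose(totals, totals[0])
        assert w.sum() == pytest.approx(len(sub))

    def test_equal_counts_give_equal_weights(self):
        w = tg.subclass_weights(np.array(["LSGS"] * 5 + ["LDGD"] * 5, dtype=object))
        assert np.allclose(w, 1.0)

    def test_single_subclass_degenerate(self):
        w = tg.subclass_weights(np.array(["LSGS"] * 8, dtype=object))
        assert np.allclose(w, 1.0)


class TestNormalizer:
    def test_zscores_own_training_data(self, rng):
        X = rng.standard_normal((30, 5)) * 3 + 1
        norm = tg.fit_normalizer(X)
        Z = norm.transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_no_leakage_on_shifted_test_set(self, rng):
        X = rng.standard_normal((30, 5))
        norm = tg.fit_normalizer(X)
        Z_test = norm.transform(X + 5.0)
        assert (np.abs(Z_test.mean(axis=0)) > 1).all()

    def test_constant_channel_maps_to_zero(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.2
        Z = tg.fit_normalizer(X).transform(X)
        assert np.allclose(Z[:, 1], 0.0)


class TestTimepointModel:
    def test_separable_training_auc_is_one(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)) + 4,
                       rng.standard_normal((20, 2)) - 4])
        y = np.array([1] * 20 + [-1] * 20)
        model = tg.train_timepoint(X, y)
        probs = tg.predict_probability(model, X)
        assert tg.auc(probs, y) == 1.0
        assert model.regularization_constant == 1.0

    def test_boundary_probability_near_half(self, rng):
        X = np.vstack([rng.standard_normal((50, 2)) + 2,
                       rng.standard_normal((50, 2)) - 2])
        y = np.array([1] * 50 + [-1] * 50)
        model = tg.train_timepoint(X, y)
        # a point on the hyperplane in normalized space
        z0 = -model.intercept * model.weights / (model.weights @ model.weights)
        x0 = z0 * model.normalizer.sd + model.normalizer.mean
        p = tg.predict_probability(model, x0[None, :])
        assert abs(p[0] - 0.5) < 0.05

    def test_probability_preserves_decision_ranking(self, rng):
        X = np.vstack([rng.standard_normal((30, 3)) + 1,
                       rng.standard_normal((30, 3)) - 1])
        y = np.array([1] * 30 + [-1] * 30)
        model = tg.train_timepoint(X, y)
        X_new = rng.standard_normal((40, 3)) * 2
        f = model.decision_values(X_new)
        p = tg.predict_probability(model, X_new)
        order = np.argsort(f)
        assert (np.diff(p[order]) >= 0).all()

    def test_high_snr_probabilities_cluster_at_extremes(self, rng):
        X = np.vstack([rng.standard_normal((30, 4)) + 6,
                       rng.standard_normal((30, 4)) - 6])
        y = np.array([1] * 30 + [-1] * 30)
        model = tg.train_timepoint(X, y)
        p = tg.predict_probability(model, X)
        assert (p[y == 1] > 0.8).all() and (p[y == -1] < 0.2).all()

    def test_single_class_errors(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="both classes"):
            tg.train_timepoint(X, np.ones(10))

    def test_channel_mismatch_errors(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([1, -1] * 10)
        model = tg.train_timepoint(X, y)
        with pytest.raises(ValueError, match="expected"):
            tg.predict_probability(model, rng.standard_normal((5, 4)))

    def test_platt_fit_is_deterministic_and_sane(self, rng):
        f = np.concatenate([rng.standard_normal(30) + 1.5,
                            rng.standard_normal(30) - 1.5])
        y = np.array([1] * 30 + [-1] * 30)
        a1, b1 = _platt_fit(f, y)
        a2, b2 = _platt_fit(f, y)
        assert (a1, b1) == (a2, b2)
        assert a1 < 0  # probability increases with the decision value


def auc_bruteforce(scores, y):
    """Independent oracle: count correctly ordered pairs, ties at 1/2."""
    pos = scores[y > 0]
    neg = scores[y <= 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_spec_examples(self):
        assert tg.auc(np.array([0.9, 0.8, 0.1, 0.2]),
                      np.array([1, 1, -1, -1])) == 1.0
        assert tg.auc(np.array([0.5, 0.5, 0.5, 0.5]),
                      np.array([1, 1, -1, -1])) == 0.5
        # deviant {0.8, 0.6}, standard {0.7, 0.1}: 3 of 4 pairs correct
        assert tg.auc(np.array([0.8, 0.6, 0.7, 0.1]),
                      np.array([1, 1, -1, -1])) == 0.75

    def test_matches_bruteforce_oracle_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(4, 51)
            scores = rng.integers(0, 8, size=n).astype(float)  # many ties
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if (y > 0).all() or (y < 0).all():
                y[0] *= -1
            assert tg.auc(scores, y) == auc_bruteforce(scores, y)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.standard_normal(40)
        y = np.array([1, -1] * 20)
        assert tg.auc(scores, y) == pytest.approx(
            tg.auc(np.exp(3 * scores), y), abs=1e-12
        )

    def test_class_flip_complement(self, rng):
        scores = rng.integers(0, 5, 30).astype(float)
        y = np.array([1, -1] * 15)
        assert tg.auc(scores, y) + tg.auc(scores, -y) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            tg.auc(np.array([1.0, 2.0]), np.array([1, 1]))


def test_permuted_labels_decode_at_chance(rng):
    """Mean held-out AUC under label permutation stays within 0.5 +/- 0.02."""
    cfg = tg.SimulationConfig(
        scenario=tg.sustained_scenario(duration=3, start=1, n_samples=5),
        n_trials=20, n_channels=5, n_samples=5, snr=1.0, seed=21,
    )
    epochs = tg.simulate_subject(cfg, 0)
    aucs = []
    for run in range(100):
        perm = rng.permutation(epochs.n_trials)
        shuffled = tg.EpochsSet(
            data=epochs.data,
            times=epochs.times,
            sample_rate=epochs.sample_rate,
            labels=[epochs.labels[i] for i in perm],
            subject_id=epochs.subject_id,
        )
        contrast = tg.make_contrast(shuffled, "local")
        curve = tg.decode_diagonal(shuffled, contrast, k=5, seed=run)
        aucs.append(curve.mean())
    assert abs(np.mean(aucs) - 0.5) < 0.02


def test_training_parameters_ignore_heldout_trials(rng):
    """No leakage: models depend only on training-fold trials."""
    cfg = tg.SimulationConfig(
        scenario=tg.sustained_scenario(duration=4, start=0, n_samples=4),
        n_trials=20, n_channels=4, n_samples=4, snr=1.0, seed=33,
    )
    epochs = tg.simulate_subject(cfg, 0)
    contrast = tg.make_contrast(epochs, "local")
    folds = tg.stratified_folds(contrast, k=5, seed=0)
    test_mask = folds.fold_index == 0
    train_idx = contrast.trial_indices[~test_mask]
    y_train = contrast.y[~test_mask]
    w = tg.subclass_weights(contrast.subclass[~test_mask])

    model_a = tg.train_timepoint(epochs.data[train_idx, :, 2], y_train, w)
    mutated = epochs.data.copy()
    mutated[contrast.trial_indices[test_mask]] += 100.0
    model_b = tg.train_timepoint(mutated[train_idx, :, 2], y_train, w)
    assert np.array_equal(model_a.weights, model_b.weights)
    assert model_a.intercept == model_b.intercept
    assert model_a.platt_a == model_b.platt_a
    assert np.array_equal(model_a.normalizer.mean, model_b.normalizer.mean)
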