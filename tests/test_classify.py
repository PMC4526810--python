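"""Difference features, pooled-covariance LDA, greedy selection, and CV."""

import numpy as np
import pytest

import tempotag as tt
from tempotag.classify import (
    DifferenceFeatureSet,
    build_difference_dataset,
    cross_validate,
    evaluate_on_subject_averages,
    forward_select,
    lda_fit,
)
from tempotag.errors import InvalidInputError
from test_stats import pair_from_arrays


def pair_with_channels(diffs: dict[str, float], subject=0, trial=0,
                       paradigm="comprehension") -> tt.TrialPair:
    base = {c: 1.0 for c in diffs}
    p = pair_from_arrays([1.0, 2.0], [1.0, 2.0], subject=subject, trial=trial,
                         paradigm=paradigm)
    p.channel_amplitudes_a = base
    p.channel_amplitudes_b = {c: base[c] + d for c, d in diffs.items()}
    return p


def toy_gaussian(n=400, d=2, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.zeros(d)
    mu[0] = sep / 2
    X = np.vstack([rng.normal(mu, 1.0, (n, d)), rng.normal(-mu, 1.0, (n, d))])
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    return X, y


class TestDifferenceDataset:
    def test_single_pair_yields_antisymmetric_rows(self):
        p = pair_with_channels({"Fz": 1.0, "Cz": 0.0})
        ds = build_difference_dataset([p], "comprehension")
        assert ds.X.shape == (2, 2)
        assert np.allclose(ds.X[0], -ds.X[1])
        assert ds.y.tolist() == [1, -1]
        assert set(zip(map(tuple, ds.X), ds.y)) == {((1.0, 0.0), 1), ((-1.0, 0.0), -1)}

    def test_column_means_are_exactly_zero(self):
        rng = np.random.default_rng(0)
        pairs = [pair_with_channels({"Fz": rng.normal(), "F6": rng.normal()},
                                    subject=s, trial=t)
                 for s in range(4) for t in range(4)]
        ds = build_difference_dataset(pairs, "comprehension")
        assert np.allclose(ds.X.mean(axis=0), 0.0, atol=1e-15)

    def test_thirtyone_trials_give_sixtytwo_rows(self):
        # one of 32 trials discarded, as when a recording is non-responsive
        pairs = [pair_with_channels({"Fz": 0.1}, subject=s, trial=t)
                 for s in range(8) for t in range(4)][:31]
        ds = build_difference_dataset(pairs, "comprehension")
        assert ds.X.shape[0] == 62

    def test_subject_average_level_has_two_rows_per_subject(self):
        pairs = [pair_with_channels({"Fz": 0.1 * (s + 1)}, subject=s, trial=t)
                 for s in range(3) for t in range(4)]
        ds = build_difference_dataset(pairs, "comprehension", level="subject_average")
        assert ds.X.shape == (6, 1)

    def test_missing_channel_rejected(self):
        p1 = pair_with_channels({"Fz": 1.0, "Cz": 0.5})
        p2 = pair_with_channels({"Fz": 1.0})
        with pytest.raises(InvalidInputError):
            build_difference_dataset([p1, p2], "comprehension")


class TestLDAFit:
    def test_matches_closed_form_discriminant_on_gaussian_toy(self):
        X, y = toy_gaussian(n=20000, sep=2.0, seed=1)
        model = lda_fit(X, y)
        # population discriminant: w ~ Sigma^-1 (mu+ - mu-) = (2, 0) for I cov
        w = model.weights / np.abs(model.weights[0])
        assert w[0] == pytest.approx(1.0)
        assert abs(w[1]) < 0.05
        assert abs(model.bias) < 0.05

    def test_matches_sklearn_lda_oracle(self):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis").LinearDiscriminantAnalysis
        X, y = toy_gaussian(n=200, d=3, sep=1.5, seed=2)
        model = lda_fit(X, y)
        ref = sklearn_lda(solver="lsqr").fit(X, y)
        ratio = model.weights / ref.coef_.ravel()
        assert np.allclose(ratio, ratio[0], rtol=1e-6)
        assert np.array_equal(model.predict(X), ref.predict(X))

    def test_antisymmetric_data_gives_zero_bias(self):
        rng = np.random.default_rng(3)
        D = rng.normal(size=(20, 4))
        X = np.vstack([D, -D])
        y = np.concatenate([np.ones(20), -np.ones(20)]).astype(int)
        model = lda_fit(X, y)
        assert abs(model.bias) < 1e-9
        # boundary through origin: prediction(-x) = -prediction(x)
        probes = rng.normal(size=(50, 4))
        assert np.array_equal(model.predict(-probes), -model.predict(probes))

    def test_duplicated_column_predictions_unchanged_with_ridge(self):
        X, y = toy_gaussian(n=100, d=2, sep=2.0, seed=4)
        Xdup = np.hstack([X, X[:, :1]])
        m1 = lda_fit(X, y, regularization_eps=1e-8)
        m2 = lda_fit(Xdup, y, regularization_eps=1e-8)
        assert np.array_equal(m1.predict(X), m2.predict(Xdup))

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            lda_fit(np.ones((4, 2)), np.ones(4))


class TestCrossValidate:
    def test_perfect_separation_gives_accuracy_one(self):
        X, y = toy_gaussian(n=30, sep=30.0, seed=5)
        res = cross_validate(X, y, folds=10, iterations=10, seed=0)
        assert res.mean_accuracy == 1.0

    def test_random_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(6)
        y = np.concatenate([np.ones(30), -np.ones(30)]).astype(int)
        accs = [cross_validate(rng.normal(size=(60, 3)), y,
                               folds=10, iterations=20, seed=s).mean_accuracy
                for s in range(10)]
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_identical_seed_is_bit_reproducible(self):
        X, y = toy_gaussian(n=40, sep=1.0, seed=7)
        r1 = cross_validate(X, y, folds=5, iterations=20, seed=3)
        r2 = cross_validate(X, y, folds=5, iterations=20, seed=3)
        assert np.array_equal(r1.per_iteration, r2.per_iteration)
        assert r1.mean_accuracy == r2.mean_accuracy

    def test_label_flip_equivariance(self):
        X, y = toy_gaussian(n=40, sep=1.0, seed=8)
        r1 = cross_validate(X, y, folds=5, iterations=20, seed=4)
        r2 = cross_validate(-X, -y, folds=5, iterations=20, seed=4)
        assert np.array_equal(r1.per_iteration, r2.per_iteration)

    def test_matches_leave_one_out_brute_force(self):
        # with folds = n units and paired rows, the partition is deterministic,
        # so repeated CV must equal a hand-rolled leave-one-pair-out loop
        rng = np.random.default_rng(9)
        D = rng.normal(0.8, 1.0, size=(12, 2))
        X = np.vstack([D, -D])
        y = np.concatenate([np.ones(12), -np.ones(12)]).astype(int)
        pair_ids = np.concatenate([np.arange(12), np.arange(12)])
        res = cross_validate(X, y, folds=12, iterations=5, seed=0, pair_ids=pair_ids)
        correct = 0
        for i in range(12):
            test = pair_ids == i
            model = lda_fit(X[~test], y[~test])
            correct += int(np.sum(model.predict(X[test]) == y[test]))
        assert res.mean_accuracy == pytest.approx(correct / 24, abs=1e-12)

    def test_too_few_samples_reduces_folds_with_warning(self):
        X, y = toy_gaussian(n=3, sep=5.0, seed=10)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = cross_validate(X, y, folds=10, iterations=3, seed=0)
        assert res.folds == 6


class TestForwardSelect:
    def test_perfect_channel_selected_first(self):
        rng = np.random.default_rng(11)
        n = 30
        sep = np.concatenate([np.ones(n), -np.ones(n)])
        X = rng.normal(size=(2 * n, 5))
        X[:, 3] = sep * 10 + rng.normal(scale=0.01, size=2 * n)
        y = sep.astype(int)
        sel = forward_select(X, y, max_features=2, folds=5, iterations=5, seed=0)
        assert sel[0] == 3

    def test_pure_noise_selection_is_bounded_and_near_chance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 6))
        y = np.concatenate([np.ones(30), -np.ones(30)]).astype(int)
        sel = forward_select(X, y, max_features=3, folds=5, iterations=10, seed=1)
        assert 1 <= len(sel) <= 3
        acc = cross_validate(X[:, sel], y, folds=5, iterations=20, seed=2).mean_accuracy
        assert 0.4 <= acc <= 0.65

    def test_two_informative_channels_found_before_noise(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            n = 24
            labels = np.concatenate([np.ones(n), -np.ones(n)]).astype(int)
            X = rng.normal(size=(2 * n, 6))
            X[:, 1] += labels * 1.0
            X[:, 4] += labels * 1.0
            sel = forward_select(X, labels, max_features=2, folds=5,
                                 iterations=10, seed=seed)
            hits += set(sel) == {1, 4}
        assert hits >= 27  # informative pair beats noise in >= 90% of runs

    def test_labels_returned_when_given(self):
        X, y = toy_gaussian(n=30, sep=4.0, seed=13)
        sel = forward_select(X, y, max_features=1, folds=5, iterations=5,
                             seed=0, channel_labels=("Fz", "Cz"))
        assert sel == ["Fz"]

    def test_max_features_below_one_rejected(self):
        with pytest.raises(InvalidInputError):
            forward_select(np.ones((4, 2)), np.array([1, 1, -1, -1]), max_features=0)


class TestSubjectAverageEvaluation:
    def test_perfectly_separated_subject_averages(self):
        pairs = [pair_with_channels({"Fz": 1.0 + 0.01 * t, "Cz": 0.0},
                                    subject=s, trial=t)
                 for s in range(4) for t in range(4)]
        trial_ds = build_difference_dataset(pairs, "comprehension")
        subj_ds = build_difference_dataset(pairs, "comprehension",
                                           level="subject_average")
        model = lda_fit(trial_ds.columns(["Fz"]), trial_ds.y, channel_labels=["Fz"])
        assert evaluate_on_subject_averages(model, subj_ds) == 1.0

    def test_channel_mismatch_rejected(self):
        pairs = [pair_with_channels({"Fz": 1.0}, subject=s, trial=t)
                 for s in range(2) for t in range(2)]
        subj_ds = build_difference_dataset(pairs, "comprehension",
                                           level="subject_average")
        model = lda_fit(np.vstack([np.ones((3, 1)), -np.ones((3, 1))]),
                        np.array([1, 1, 1, -1, -1, -1]), channel_labels=["T8"])
        with pytest.raises(InvalidInputError):
            evaluate_on_subject_averages(model, subj_ds)
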