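"""LDA, one-vs-one voting, blocked cross-validation, sweeps, grand averages."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import nirsload as nl
from nirsload.classify import LDAModel, blocked_folds, fit_lda, predict_ovo
from nirsload.features import FeatureMatrix
from nirsload.protocol import SessionTimeline, TimelineEvent
from nirsload.recording import Recording


class TestLDA:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(5, 0.3, (30, 4))])
        y = np.repeat([0, 1], 30)
        model = fit_lda(X, y)
        pred = np.where(model.margin(X) > 0, model.classes[1], model.classes[0])
        assert (pred == y).all()

    def test_identical_distributions_near_chance(self, rng):
        X = rng.standard_normal((400, 4))
        y = np.tile([0, 1], 200)  # arbitrary relabeling of one distribution
        model = fit_lda(X[:200], y[:200])
        pred = np.where(model.margin(X[200:]) > 0, 1, 0)
        acc = (pred == y[200:]).mean()
        assert abs(acc - 0.5) < 0.15

    def test_coefficients_match_closed_form(self, rng):
        # direct linear-algebra oracle: w = Sigma^-1 (mu1 - mu0)
        X = np.vstack([rng.normal([0, 0], [1.0, 2.0], (40, 2)),
                       rng.normal([2, 1], [1.0, 2.0], (40, 2))])
        y = np.repeat([0, 1], 40)
        model = fit_lda(X, y)
        mu0, mu1 = X[:40].mean(0), X[40:].mean(0)
        scatter = ((X[:40] - mu0).T @ (X[:40] - mu0)
                   + (X[40:] - mu1).T @ (X[40:] - mu1))
        cov = scatter / (80 - 2)
        eps = max(1e-6 * np.trace(cov) / 2, 1e-12)
        w = np.linalg.solve(cov + eps * np.eye(2), mu1 - mu0)
        np.testing.assert_allclose(model.coef, w, rtol=1e-9)

    def test_agrees_with_sklearn_lda(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(0.8, 1, (100, 5))])
        y = np.repeat([0, 1], 100)
        Xt = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(0.8, 1, (50, 5))])
        model = fit_lda(X, y)
        ours = np.where(model.margin(Xt) > 0, 1, 0)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(Xt)
        assert (ours == ref).mean() >= 0.98

    def test_degenerate_class_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        with pytest.raises(ValueError):
            fit_lda(X, np.array([0, 0, 0, 0, 1]))


def _const_model(a, b, margin):
    """Pairwise model with constant signed margin (positive favors b)."""
    d = 2
    return LDAModel(classes=np.array([a, b]), means=np.zeros((2, d)),
                    covariance=np.eye(d), priors=np.array([0.5, 0.5]),
                    coef=np.zeros(d), intercept=float(margin))


def _vote_oracle(m12, m13, m23):
    """Exhaustive re-derivation of the OvO rule for 3 classes."""
    votes = {1: 0, 2: 0, 3: 0}
    margins = {1: 0.0, 2: 0.0, 3: 0.0}
    for (a, b), m in [((1, 2), m12), ((1, 3), m13), ((2, 3), m23)]:
        votes[b if m > 0 else a] += 1
        margins[b] += m
        margins[a] -= m
    return min(votes, key=lambda c: (-votes[c], -margins[c], c))


class TestOneVsOne:
    def _predict(self, m12, m13, m23):
        models = {(1, 2): _const_model(1, 2, m12),
                  (1, 3): _const_model(1, 3, m13),
                  (2, 3): _const_model(2, 3, m23)}
        return predict_ovo(models, np.zeros((1, 2)), np.array([1, 2, 3]))[0]

    def test_majority_wins(self):
        # class 1 beats 2 and 3; the 2-3 outcome is irrelevant
        assert self._predict(-1.0, -1.0, +1.0) == 1
        assert self._predict(-1.0, -1.0, -1.0) == 1

    def test_unanimous_class(self):
        assert self._predict(+2.0, +0.5, +1.0) in (2, 3)
        assert self._predict(-0.5, +3.0, +3.0) == 3  # 3 beats both 1 and 2

    @pytest.mark.parametrize("m12,m13,m23", [
        (-1.0, +2.0, -1.5),   # cycle: 1>2, 3>1, 2>3
        (-0.5, +0.5, -0.5),
        (+1.0, -2.0, +0.3),
        (-1.0, +1.0, -1.0),   # symmetric cycle, margin sums tie -> lowest label
    ])
    def test_cyclic_votes_resolved_by_margin_oracle(self, m12, m13, m23):
        assert self._predict(m12, m13, m23) == _vote_oracle(m12, m13, m23)

    def test_missing_pair_model_rejected(self):
        models = {(1, 2): _const_model(1, 2, 1.0)}
        with pytest.raises(ValueError, match="missing pairwise"):
            predict_ovo(models, np.zeros((1, 2)), np.array([1, 2, 3]))

    def test_classifier_interface(self, rng):
        X = np.vstack([rng.normal(i * 3, 0.5, (30, 4)) for i in range(3)])
        y = np.repeat([1, 2, 3], 30)
        clf = nl.PairwiseLDA().fit(X, y)
        assert len(clf.models_) == 3
        assert (clf.predict(X) == y).all()
        assert clf.decision_function(X).shape == (90, 3)
        four = nl.PairwiseLDA().fit(np.vstack([X, rng.normal(9, 0.5, (30, 4))]),
                                    np.concatenate([y, np.full(30, 4)]))
        assert len(four.models_) == 6


def _matrix(rng, n_classes=3, trials_per_class=10, per_trial=2, informative=True):
    rows, labels, trial_ids = [], [], []
    tid = 0
    for c in range(1, n_classes + 1):
        for _ in range(trials_per_class):
            for _ in range(per_trial):
                x = rng.standard_normal(16)
                if informative:
                    x[:4] += 3.0 * c
                rows.append(x)
                labels.append(c)
                trial_ids.append(tid)
            tid += 1
    return FeatureMatrix(np.array(rows), np.array(labels), np.array(trial_ids),
                         [(i % 8, "HbO" if i < 8 else "HbR") for i in range(16)],
                         0.0, 10.0)


class TestCrossValidation:
    def test_blocked_folds_keep_trials_together(self, rng):
        fm = _matrix(rng, per_trial=3)
        folds = blocked_folds(fm.labels, fm.trial_ids, 10)
        assert sum(len(f) for f in folds) == fm.n_instances
        for fold in folds:
            fold_trials = set(fm.trial_ids[fold].tolist())
            for t in fold_trials:  # every window of a trial is inside the fold
                assert set(np.flatnonzero(fm.trial_ids == t)) <= set(fold.tolist())

    def test_fold_sizes_balanced_within_one_trial_per_class(self, rng):
        fm = _matrix(rng, n_classes=2, trials_per_class=15, per_trial=1)
        folds = blocked_folds(fm.labels, fm.trial_ids, 10)
        for c in (1, 2):
            sizes = [np.sum(fm.labels[f] == c) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_too_few_trials_rejected(self, rng):
        fm = _matrix(rng, trials_per_class=5)
        with pytest.raises(ValueError, match="fewer than"):
            blocked_folds(fm.labels, fm.trial_ids, 10)

    def test_informative_features_classified_perfectly(self, rng):
        res = nl.crossvalidate(_matrix(rng))
        assert res.mean_accuracy == 1.0
        assert res.chance == pytest.approx(1 / 3)
        assert res.confusion.sum() == res.n_instances
        np.testing.assert_array_equal(res.confusion.sum(axis=1), [20, 20, 20])

    def test_permuted_labels_at_chance(self, rng):
        fm = _matrix(rng, n_classes=2, trials_per_class=20, per_trial=1)
        perm = rng.permutation(fm.n_instances)
        fm.labels = fm.labels[perm]  # break any label-feature association
        fm.trial_ids = np.arange(fm.n_instances)
        res = nl.crossvalidate(fm)
        half_width = 1.96 * np.sqrt(0.25 / fm.n_instances)
        assert abs(res.mean_accuracy - 0.5) <= half_width + 0.05

    def test_corrupting_held_out_rows_never_changes_the_model(self, rng):
        fm = _matrix(rng)
        res = nl.crossvalidate(fm, return_details=True)
        test0 = res.details[0]["test_idx"]
        fm.values[test0] += 1e3  # poison evaluation rows of fold 0
        res2 = nl.crossvalidate(fm, return_details=True)
        assert np.array_equal(res.details[0]["selected"], res2.details[0]["selected"])
        for pair, model in res.details[0]["model"].models_.items():
            np.testing.assert_array_equal(model.coef,
                                          res2.details[0]["model"].models_[pair].coef)

    def test_accuracies_bounded(self, rng):
        res = nl.crossvalidate(_matrix(rng, informative=False))
        assert np.all((res.fold_accuracies >= 0) & (res.fold_accuracies <= 1))


class TestSweeps:
    def test_offset_sweep_bookkeeping(self, default_session):
        _, _, trials = default_session
        results = nl.sweep_offset(trials, [0.0, 10.0])
        assert len(results) == 8  # 2 offsets x 4 scenarios
        four_class = [r for r in results if r.classes.size == 4]
        assert len(four_class) == 2
        for r in four_class:
            assert r.chance == pytest.approx(0.25)
            assert r.n_instances == 45  # 30 task windows + 15 relax, unbalanced
        for r in results:
            if r.classes.size == 2:
                assert r.chance == pytest.approx(0.5)
                assert r.n_instances == 25

    def test_offset_beyond_trial_rejected(self, default_session):
        _, _, trials = default_session
        with pytest.raises(ValueError):
            nl.sweep_offset(trials, [40.0])

    def test_window_sweep_instance_counts(self, default_session):
        _, _, trials = default_session
        results = nl.sweep_window(trials, [5.0, 30.0])
        assert len(results) == 8  # 2 lengths x (3 pairs + 3-class)
        for r in results:
            per_class = int(44.0 // r.length_s) * 10
            np.testing.assert_array_equal(r.confusion.sum(axis=1),
                                          [per_class] * r.classes.size)

    def test_window_longer_than_trial_rejected(self, default_session):
        _, _, trials = default_session
        with pytest.raises(ValueError):
            nl.sweep_window(trials, [45.0])


class TestGrandAverage:
    def test_single_trial_is_its_own_baselined_average(self, rng):
        fs = 25.0
        rec = Recording(rng.standard_normal((8, 2, int(70 * fs))), sampling_rate=fs)
        tl = SessionTimeline(events=[
            TimelineEvent(0.0, 15.0, "rest"),
            TimelineEvent(15.0, 44.0, "task", 2),
            TimelineEvent(59.0, 11.0, "rest"),
        ])
        avg = nl.grand_average((rec, tl))
        lo, hi = int(15 * fs), int(59 * fs)
        baseline = rec.data[:, :, lo - int(10 * fs): lo].mean(axis=2, keepdims=True)
        np.testing.assert_allclose(avg[2].curves, rec.data[:, :, lo:hi] - baseline,
                                   atol=1e-12)
        assert avg[2].n_trials == 1

    def test_onset_value_zero_for_noise_free_trial(self):
        cfg = nl.noise_free_config(0)
        tl = SessionTimeline(events=[
            TimelineEvent(0.0, 15.0, "rest"),
            TimelineEvent(15.0, 44.0, "task", 3),
            TimelineEvent(59.0, 11.0, "rest"),
        ])
        rec = nl.simulate_recording(tl, cfg)
        avg = nl.grand_average((rec, tl))
        assert np.abs(avg[3].channel_mean[:, 0]).max() < 1e-6

    def test_peak_ordering_follows_amplitudes(self, noise_free_session):
        ds, _, _, _ = noise_free_session
        avg = nl.grand_average((ds.recording, ds.timeline))
        peaks = {c: avg[c].channel_mean[0].max() for c in (1, 2, 3)}  # HbO
        assert peaks[1] < peaks[2] < peaks[3]
        troughs = {c: avg[c].channel_mean[1].min() for c in (1, 2, 3)}  # HbR
        assert troughs[3] < troughs[2] < troughs[1]

    def test_trial_without_baseline_skipped_with_warning(self, default_session):
        ds, _, _ = default_session
        with pytest.warns(UserWarning, match="pre-trial baseline"):
            avg = nl.grand_average((ds.recording, ds.timeline))
        assert sum(a.n_trials for a in avg.values()) == 29  # first trial lacks 10 s
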