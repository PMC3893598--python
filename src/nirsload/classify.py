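"""Single-trial workload classification and the evaluation protocols.

The classifier is linear discriminant analysis (class means + pooled
within-class covariance with a small ridge) trained pairwise and combined
one-vs-one by majority vote; vote ties fall back to summed signed
discriminant margins, then to the lowest class label.

Evaluation follows a blocked 10-fold cross-validation: instances of each
class are split into temporally contiguous blocks at trial granularity, so
windows of one trial never straddle the train/test boundary — important
because fNIRS signals are strongly autocorrelated and adjacent windows
would otherwise leak.  Mutual-information feature selection runs inside
each fold on the training rows only.

Two experiment sweeps mirror the study design: classifying each workload
level (and all levels jointly) against relax with 10 s windows at varying
trial offsets, and discriminating workload levels from each other with
varying window lengths.  Grand-average curves with a 10 s pre-trial
baseline visualize the underlying hemodynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FeatureMatrix, extract_features, select_top_k
from .protocol import (RELAX_LABEL, CONDITIONS, TASK_S, Trial, Window, WindowSpec,
                       extract_windows)
from .recording import Recording

DEFAULT_RIDGE_REL = 1e-6


# ---------------------------------------------------------------------------
# LDA and one-vs-one voting


@dataclass
class LDAModel:
    """Binary linear discriminant: means, pooled covariance, priors."""

    classes: np.ndarray
    means: np.ndarray          # (2, d)
    covariance: np.ndarray     # (d, d), ridge-regularized
    priors: np.ndarray         # (2,)
    coef: np.ndarray           # (d,) = Sigma^-1 (mu_1 - mu_0)
    intercept: float

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Signed discriminant: positive favors ``classes[1]``."""
        return X @ self.coef + self.intercept


def fit_lda(X: np.ndarray, y: np.ndarray, ridge_rel: float = DEFAULT_RIDGE_REL) -> LDAModel:
    """Fit a two-class LDA with pooled covariance and relative ridge.

    The ridge is ``ridge_rel x trace(Sigma)/d`` (with an absolute floor so
    a zero within-class scatter still inverts), keeping the pooled
    covariance positive definite for small training folds.
    """
    X, y = check_X_y(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"binary base learner requires 2 classes, got {classes.size}")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 training instances")
    d = X.shape[1]
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for c, mu in zip(classes, means):
        diff = X[y == c] - mu
        scatter += diff.T @ diff
    cov = scatter / (X.shape[0] - 2)
    eps = max(ridge_rel * np.trace(cov) / d, 1e-12)
    cov_reg = cov + eps * np.eye(d)
    try:
        cov_inv = np.linalg.inv(cov_reg)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular covariance after ridge") from exc
    priors = counts / counts.sum()
    coef = cov_inv @ (means[1] - means[0])
    intercept = float(
        -0.5 * (means[1] @ cov_inv @ means[1] - means[0] @ cov_inv @ means[0])
        + np.log(priors[1] / priors[0])
    )
    return LDAModel(classes=classes, means=means, covariance=cov_reg,
                    priors=priors, coef=coef, intercept=intercept)


def predict_ovo(models: dict[tuple, LDAModel], X: np.ndarray,
                classes: np.ndarray) -> np.ndarray:
    """One-vs-one prediction by majority vote over the pairwise models.

    Ties are broken by the summed signed margins accumulated for each
    class, then by the lowest class label.
    """
    X = check_array(X)
    classes = np.asarray(classes)
    for pair in combinations(sorted(classes.tolist()), 2):
        if pair not in models:
            raise ValueError(f"missing pairwise model for classes {pair}")
    votes = np.zeros((X.shape[0], classes.size))
    margins = np.zeros((X.shape[0], classes.size))
    index = {c: i for i, c in enumerate(classes.tolist())}
    for (a, b), model in models.items():
        m = model.margin(X)  # positive favors b
        winner_b = m > 0
        votes[winner_b, index[b]] += 1
        votes[~winner_b, index[a]] += 1
        margins[:, index[b]] += m
        margins[:, index[a]] -= m
    # lexicographic: votes, then total margin, then lower label
    out = np.empty(X.shape[0], dtype=classes.dtype)
    order = np.argsort(classes)  # ascending labels; first wins final ties
    for i in range(X.shape[0]):
        best = max(order, key=lambda j: (votes[i, j], margins[i, j], -_rank(classes[j], classes)))
        out[i] = classes[best]
    return out


def _rank(label, classes) -> int:
    return int(np.searchsorted(np.sort(classes), label))


class PairwiseLDA(ClassifierMixin, BaseEstimator):
    """One-vs-one LDA multiclass classifier (scikit-learn interface).

    Parameters
    ----------
    ridge_rel : float
        Relative ridge added to the pooled covariance of each pairwise
        model, as a fraction of the mean covariance eigenvalue.
    """

    def __init__(self, ridge_rel: float = DEFAULT_RIDGE_REL):
        self.ridge_rel = ridge_rel

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        self.models_ = {}
        for a, b in combinations(self.classes_.tolist(), 2):
            mask = (y == a) | (y == b)
            self.models_[(a, b)] = fit_lda(X[mask], y[mask], self.ridge_rel)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "models_")
        return predict_ovo(self.models_, X, self.classes_)

    def decision_function(self, X):
        """Summed signed margins per class (columns follow ``classes_``)."""
        check_is_fitted(self, "models_")
        X = check_array(X)
        margins = np.zeros((X.shape[0], self.classes_.size))
        index = {c: i for i, c in enumerate(self.classes_.tolist())}
        for (a, b), model in self.models_.items():
            m = model.margin(X)
            margins[:, index[b]] += m
            margins[:, index[a]] -= m
        return margins


# ---------------------------------------------------------------------------
# blocked cross-validation


@dataclass
class CVResult:
    """Outcome of one cross-validated classification scenario."""

    scenario: str
    classes: np.ndarray
    offset_s: float
    length_s: float
    fold_accuracies: np.ndarray
    chance: float
    confusion: np.ndarray  # true class x predicted class counts
    n_instances: int
    details: list = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def blocked_folds(labels: np.ndarray, trial_ids: np.ndarray, k: int) -> list[np.ndarray]:
    """Per-class contiguous blocks at trial granularity.

    For each class, its trials (in order of appearance) are split into k
    contiguous groups of near-equal size; fold f tests on group f of every
    class.  All windows of one trial land in the same group.
    """
    labels = np.asarray(labels)
    trial_ids = np.asarray(trial_ids)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        rows = np.flatnonzero(labels == c)
        trials_in_order = list(dict.fromkeys(trial_ids[rows].tolist()))
        if len(trials_in_order) < k:
            raise ValueError(
                f"class {c!r} has {len(trials_in_order)} trials, fewer than {k} folds"
            )
        for f, chunk in enumerate(np.array_split(np.array(trials_in_order), k)):
            chunk_set = set(chunk.tolist())
            folds[f].extend(int(r) for r in rows if trial_ids[r] in chunk_set)
    return [np.array(sorted(f), dtype=int) for f in folds]


def crossvalidate(matrix: FeatureMatrix, k: int = 10, select_k: int = 8,
                  scenario: str = "", ridge_rel: float = DEFAULT_RIDGE_REL,
                  return_details: bool = False) -> CVResult:
    """Blocked k-fold CV with in-fold MI feature selection.

    Each fold: select the top ``select_k`` features by mutual information
    on the training rows, fit the one-vs-one LDA, evaluate on the held-out
    block.  Returns per-fold accuracies and the pooled confusion matrix.
    """
    X, y = matrix.values, matrix.labels
    classes = np.unique(y)
    folds = blocked_folds(y, matrix.trial_ids, k)
    all_idx = np.arange(matrix.n_instances)
    fold_acc = np.empty(k)
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    cindex = {c: i for i, c in enumerate(classes.tolist())}
    details = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        selected = select_top_k(matrix, select_k, train_idx)
        clf = PairwiseLDA(ridge_rel=ridge_rel).fit(X[np.ix_(train_idx, selected)],
                                                   y[train_idx])
        pred = clf.predict(X[np.ix_(test_idx, selected)])
        truth = y[test_idx]
        fold_acc[f] = float(np.mean(pred == truth))
        for p, tr in zip(pred, truth):
            confusion[cindex[tr], cindex[p]] += 1
        if return_details:
            details.append({"fold": f, "selected": selected, "model": clf,
                            "test_idx": test_idx})
    return CVResult(
        scenario=scenario or "-vs-".join(str(c) for c in classes),
        classes=classes,
        offset_s=matrix.offset_s,
        length_s=matrix.length_s,
        fold_accuracies=fold_acc,
        chance=1.0 / classes.size,
        confusion=confusion,
        n_instances=matrix.n_instances,
        details=details,
    )


# ---------------------------------------------------------------------------
# experiment sweeps


def _scenario_name(conds: tuple) -> str:
    names = {RELAX_LABEL: "relax"}
    return "-vs-".join(names.get(c, f"{c}-back") for c in conds)


def _matrix_from_windows(windows: list[Window], fs: float, offset_s: float,
                         length_s: float) -> FeatureMatrix:
    fm = extract_features(windows, fs)
    fm.offset_s = offset_s
    fm.length_s = length_s
    return fm


def sweep_offset(trials: list[Trial], offsets: list[float], window_s: float = 10.0,
                 k: int = 10, select_k: int = 8) -> list[CVResult]:
    """n-back-vs-relax classification as a function of trial offset.

    For every offset a 10 s window is cut from each task trial and
    classified against the dedicated 10 s relax probes, for the scenarios
    1-, 2-, 3-back vs relax and the joint 4-class problem.  Relax probes
    enter unbalanced (15 probes vs 10 trials per condition).
    """
    fs = trials[0].sampling_rate
    relax_windows = [
        extract_windows(t, WindowSpec(0.0, window_s))[0]
        for t in trials if t.label == RELAX_LABEL
    ]
    results: list[CVResult] = []
    for offset in offsets:
        if offset + window_s > TASK_S:
            raise ValueError(f"offset {offset} s + {window_s} s exceeds {TASK_S} s trial")
        spec = WindowSpec(offset, window_s)
        task_windows = {
            n: [extract_windows(t, spec)[0] for t in trials if t.label == n]
            for n in CONDITIONS
        }
        for n in CONDITIONS:
            fm = _matrix_from_windows(task_windows[n] + relax_windows, fs, offset, window_s)
            results.append(crossvalidate(fm, k, select_k,
                                         scenario=_scenario_name((n, RELAX_LABEL))))
        all_windows = sum((task_windows[n] for n in CONDITIONS), []) + relax_windows
        fm = _matrix_from_windows(all_windows, fs, offset, window_s)
        results.append(crossvalidate(fm, k, select_k,
                                     scenario=_scenario_name(CONDITIONS + (RELAX_LABEL,))))
    return results


def sweep_window(trials: list[Trial], lengths: list[float],
                 k: int = 10, select_k: int = 8) -> list[CVResult]:
    """Workload-vs-workload classification as a function of window length.

    For every length, trials are tiled into non-overlapping windows
    (floor(44/L) per trial, all inheriting the trial label) and the
    pairwise scenarios 1v2, 1v3, 2v3 plus the 3-class problem are
    cross-validated.
    """
    fs = trials[0].sampling_rate
    results: list[CVResult] = []
    for length in lengths:
        if length > TASK_S:
            raise ValueError(f"window length {length} s exceeds {TASK_S} s trial")
        spec = WindowSpec(0.0, length)
        windows_by_cond = {
            n: sum((extract_windows(t, spec, tiling=True)
                    for t in trials if t.label == n), [])
            for n in CONDITIONS
        }
        for pair in combinations(CONDITIONS, 2):
            fm = _matrix_from_windows(windows_by_cond[pair[0]] + windows_by_cond[pair[1]],
                                      fs, 0.0, length)
            results.append(crossvalidate(fm, k, select_k, scenario=_scenario_name(pair)))
        fm = _matrix_from_windows(sum((windows_by_cond[n] for n in CONDITIONS), []),
                                  fs, 0.0, length)
        results.append(crossvalidate(fm, k, select_k, scenario=_scenario_name(CONDITIONS)))
    return results


# ---------------------------------------------------------------------------
# grand averages


@dataclass
class ConditionAverage:
    """Mean baselined time course for one condition."""

    condition: int
    curves: np.ndarray        # (n_channels, 2, n_samples)
    channel_mean: np.ndarray  # (2, n_samples): mean over channels
    n_trials: int


def grand_average(sessions, pre_baseline_s: float = 10.0,
                  conditions: tuple[int, ...] = CONDITIONS) -> dict[int, ConditionAverage]:
    """Condition-wise mean curves after per-trial pre-onset baselining.

    Every task trial is baselined by subtracting the mean of the
    ``pre_baseline_s`` seconds before its onset (per channel and
    chromophore), then averaged within condition across trials and
    sessions.  Trials without a full pre-trial baseline are skipped with a
    warning.  ``sessions`` is a ``(Recording, SessionTimeline)`` pair or a
    list of them.
    """
    if isinstance(sessions, tuple) and isinstance(sessions[0], Recording):
        sessions = [sessions]
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {c: 0 for c in conditions}
    for recording, timeline in sessions:
        fs = recording.sampling_rate
        pre = int(round(pre_baseline_s * fs))
        for event in timeline.task_events():
            cond = int(event.condition)
            if cond not in conditions:
                continue
            start = int(round(event.onset_s * fs))
            stop = int(round(event.end_s * fs))
            if start - pre < 0 or stop > recording.n_samples:
                warnings.warn(
                    f"trial at {event.onset_s} s lacks a full {pre_baseline_s} s "
                    "pre-trial baseline; skipped")
                continue
            baseline = recording.data[:, :, start - pre:start].mean(axis=2, keepdims=True)
            trial = recording.data[:, :, start:stop] - baseline
            if cond not in sums:
                sums[cond] = np.zeros_like(trial)
            sums[cond] += trial
            counts[cond] += 1
    out: dict[int, ConditionAverage] = {}
    for cond in conditions:
        if counts[cond] == 0:
            continue
        curves = sums[cond] / counts[cond]
        out[cond] = ConditionAverage(condition=cond, curves=curves,
                                     channel_mean=curves.mean(axis=0),
                                     n_trials=counts[cond])
    return out
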