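"""Slope features and mutual-information feature selection.

For every analysis window we fit a least-squares line to each channel's
HbO and HbR trace and keep its slope (concentration change per second):
16 features per window for the 8-channel montage.  Features are then
ranked by their mutual information with the condition labels, estimated
from Parzen-window (Gaussian kernel) densities, and the top 8 are kept.
MI is computed on training instances only, so selection can never see
evaluation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .protocol import Window
from .recording import CHROMOPHORES

N_GRID: int = 512  # integration grid for the density-based entropies


@dataclass
class FeatureMatrix:
    """Window instances x slope features, with labels and provenance."""

    values: np.ndarray          # (n_instances, n_features)
    labels: np.ndarray          # (n_instances,)
    trial_ids: np.ndarray       # (n_instances,) trial each window came from
    feature_meta: list[tuple[int, str]]  # (channel index, chromophore)
    offset_s: float
    length_s: float

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FeatureScore:
    feature: int
    mi: float  # nats


# ---------------------------------------------------------------------------
# slope feature


def slope_feature(window: np.ndarray, sampling_rate: float) -> float:
    """OLS slope of a single-channel window against time in seconds.

    Closed form: sum((t - t_mean) * y) / sum((t - t_mean)^2).
    """
    y = np.asarray(window, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("window must be a 1-D series with >= 2 samples")
    t = np.arange(y.size) / sampling_rate
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    if denom == 0.0:
        raise ValueError("degenerate time axis")
    return float(np.dot(tc, y) / denom)


def extract_features(windows: list[Window], sampling_rate: float) -> FeatureMatrix:
    """Slope of HbO and HbR for every channel of every window.

    Column order: ch1..chN HbO, then ch1..chN HbR.
    """
    if not windows:
        raise ValueError("no windows given")
    n_channels = windows[0].data.shape[0]
    meta = [(ch, chromo) for chromo in CHROMOPHORES for ch in range(n_channels)]
    values = np.empty((len(windows), len(meta)))
    for i, w in enumerate(windows):
        for j, (ch, chromo) in enumerate(meta):
            values[i, j] = slope_feature(w.data[ch, CHROMOPHORES.index(chromo)], sampling_rate)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    return FeatureMatrix(
        values=values,
        labels=np.array([w.label for w in windows]),
        trial_ids=np.array([w.trial_id for w in windows]),
        feature_meta=meta,
        offset_s=windows[0].offset_s,
        length_s=windows[0].length_s,
    )


# ---------------------------------------------------------------------------
# Parzen-window mutual information


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb, robust spread via min(std, IQR/1.34)."""
    n = x.size
    std = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = (q75 - q25) / 1.34
    spread = min(s for s in (std, iqr) if s > 0) if max(std, iqr) > 0 else 0.0
    if spread <= 0:
        return 0.0
    return 0.9 * spread * n ** (-1.0 / 5.0)


def _parzen_density(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))


def _entropy(p: np.ndarray, grid: np.ndarray) -> float:
    logp = np.zeros_like(p)
    np.log(p, out=logp, where=p > 0)
    return float(-np.trapezoid(p * logp, grid))


def mutual_information(feature: np.ndarray, labels: np.ndarray) -> FeatureScore:
    """MI (nats) between a continuous feature and discrete labels.

    ``MI = H(f) - sum_y p(y) H(f | y)`` with class-conditional densities
    estimated by Gaussian Parzen windows (Silverman bandwidth per class),
    the marginal as their prior-weighted mixture, and entropies integrated
    on a 512-point grid spanning the data range +/- 3 bandwidths.
    Degenerate (zero-spread) features score 0 rather than erroring, which
    keeps pathological cross-validation folds running.
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise ValueError("feature and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 instances")
    priors = counts / counts.sum()

    bandwidths = {}
    for c in classes:
        h = _silverman_bandwidth(x[y == c])
        bandwidths[c] = h
    h_max = max(bandwidths.values())
    if h_max <= 0 or np.ptp(x) == 0:
        return FeatureScore(feature=-1, mi=0.0)
    # classes whose values are all identical still need a finite kernel width
    h_floor = 1e-3 * np.ptp(x)
    for c in classes:
        if bandwidths[c] <= 0:
            bandwidths[c] = h_floor

    grid = np.linspace(x.min() - 3 * h_max, x.max() + 3 * h_max, N_GRID)
    cond = np.empty((classes.size, N_GRID))
    for i, c in enumerate(classes):
        cond[i] = _parzen_density(x[y == c], grid, bandwidths[c])
    marginal = priors @ cond
    mi = _entropy(marginal, grid) - sum(
        priors[i] * _entropy(cond[i], grid) for i in range(classes.size)
    )
    label_entropy = float(-(priors * np.log(priors)).sum())
    mi = min(max(mi, 0.0), label_entropy)  # clip numerical noise to the information bounds
    return FeatureScore(feature=-1, mi=mi)


def mi_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-column MI of a feature matrix with the labels."""
    values = np.asarray(values, dtype=float)
    return np.array([mutual_information(values[:, j], labels).mi
                     for j in range(values.shape[1])])


def select_top_k(matrix: FeatureMatrix, k: int, training_indices: np.ndarray) -> np.ndarray:
    """Indices of the k features with highest MI on the training rows.

    Ties break deterministically toward the lower feature index.
    """
    if k > matrix.n_features:
        raise ValueError(f"k={k} exceeds {matrix.n_features} features")
    tr = np.asarray(training_indices)
    scores = mi_scores(matrix.values[tr], matrix.labels[tr])
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:k])


class MutualInfoSelector(SelectorMixin, BaseEstimator):
    """Keep the k features with the highest Parzen-window MI with the labels.

    scikit-learn selector: ``fit(X, y)`` computes ``scores_`` (nats) and the
    support mask; ``transform`` drops the rest.
    """

    def __init__(self, k: int = 8):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.k > X.shape[1]:
            raise ValueError(f"k={self.k} exceeds {X.shape[1]} features")
        self.n_features_in_ = X.shape[1]
        self.scores_ = mi_scores(X, y)
        order = np.argsort(-self.scores_, kind="stable")
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[: self.k]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
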