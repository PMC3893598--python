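"""Three-stage artifact attenuation for continuous fNIRS recordings.

Stage order is fixed: (1) moving-average detrend — subtract from every
sample the mean of the 120 s before and after it, attenuating slow trends
and Mayer-wave-like drifts; (2) zero-phase elliptic IIR low-pass at 0.5 Hz,
order 6, removing heart beat and faster components; (3) wavelet motion-
artifact removal — zero detail coefficients that are improbable under a
Gaussian model with robust (MAD-based) scale.

Each stage is available as a function on a 1-D series, as a scikit-learn
transformer operating column-wise on an ``(n_samples, n_series)`` matrix,
and the composed pipeline as :func:`preprocess_pipeline` on a
:class:`~nirsload.recording.Recording`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_array

from .recording import Recording


class InvalidSpecError(ValueError):
    """Raised for infeasible filter or wavelet specifications."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FilterSpec:
    """Elliptic IIR low-pass design.

    ``order`` is the order of the designed filter; with ``zero_phase`` it is
    applied forward and backward (offline analysis), which squares the
    magnitude response.
    """

    cutoff_hz: float = 0.5
    order: int = 6
    passband_ripple_db: float = 0.5
    stopband_atten_db: float = 40.0
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if self.order < 1:
            raise InvalidSpecError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < sampling_rate / 2:
            raise InvalidSpecError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, {sampling_rate / 2}) Hz"
            )

    def design_sos(self, sampling_rate: float) -> np.ndarray:
        self.validate(sampling_rate)
        return sps.ellip(self.order, self.passband_ripple_db, self.stopband_atten_db,
                         self.cutoff_hz, btype="lowpass", output="sos", fs=sampling_rate)


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet artifact-removal parameters.

    ``alpha`` is the two-sided Gaussian tail probability below which a
    detail coefficient is declared an outlier and zeroed; scale per level is
    estimated robustly as 1.4826 x MAD so that artifacts do not inflate it.
    """

    family: str = "db5"
    levels: int = 5
    alpha: float = 0.1
    mode: str = "periodization"

    def validate(self, n_samples: int) -> None:
        if self.levels < 1:
            raise InvalidSpecError("levels must be >= 1")
        if not 0.0 <= self.alpha < 1.0:
            raise InvalidSpecError("alpha must lie in [0, 1)")
        if n_samples < 2 ** self.levels:
            raise InvalidSpecError(
                f"signal of {n_samples} samples too short for {self.levels} levels"
            )


# ---------------------------------------------------------------------------
# stage functions (1-D)


def moving_average_detrend(x: np.ndarray, sampling_rate: float,
                           half_window_s: float = 120.0) -> np.ndarray:
    """Subtract the mean over [i - W, i + W] samples from each sample.

    W = ``half_window_s`` x fs; the window is truncated at the recording
    edges.  Implemented with a cumulative sum (O(N)).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    n = x.size
    w = int(round(half_window_s * sampling_rate))
    c = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w)
    hi = np.minimum(n - 1, idx + w)
    means = (c[hi + 1] - c[lo]) / (hi + 1 - lo)
    return x - means


def lowpass(x: np.ndarray, sampling_rate: float,
            spec: FilterSpec | None = None) -> np.ndarray:
    """Elliptic low-pass; zero-phase (forward-backward) by default."""
    spec = spec or FilterSpec()
    sos = spec.design_sos(sampling_rate)
    x = np.asarray(x, dtype=float)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def wavelet_artifact_removal(x: np.ndarray, spec: WaveletSpec | None = None) -> np.ndarray:
    """Zero improbable detail coefficients and reconstruct.

    Within each detail level, a coefficient whose two-sided tail probability
    under N(median, (1.4826 MAD)^2) falls below ``spec.alpha`` is set to
    zero.  The approximation level is kept, so slow hemodynamics survive
    while spike-like transients (which produce few, large detail
    coefficients at every scale) are suppressed.  Output length equals
    input length.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(x, dtype=float)
    spec.validate(x.size)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(spec.family).dec_len)
    if spec.levels > max_level:
        raise InvalidSpecError(
            f"{spec.levels} levels infeasible for {x.size} samples with {spec.family}"
        )
    coeffs = pywt.wavedec(x, spec.family, level=spec.levels, mode=spec.mode)
    if spec.alpha > 0.0:
        for d in coeffs[1:]:  # detail levels only
            med = np.median(d)
            sigma = 1.4826 * np.median(np.abs(d - med))
            if sigma <= 0:
                continue
            tail_p = 2.0 * stats.norm.sf(np.abs(d - med) / sigma)
            d[tail_p < spec.alpha] = 0.0
    out = pywt.waverec(coeffs, spec.family, mode=spec.mode)
    return out[: x.size]


# ---------------------------------------------------------------------------
# scikit-learn transformers (column-wise on (n_samples, n_series) matrices)


class _ColumnwiseTransform(TransformerMixin, BaseEstimator):
    """Stateless per-column signal transform."""

    def fit(self, X, y=None):
        check_array(X, ensure_2d=True)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = check_array(X, ensure_2d=True)
        return np.column_stack([self._transform_series(X[:, j]) for j in range(X.shape[1])])

    def _transform_series(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MovingAverageDetrend(_ColumnwiseTransform):
    def __init__(self, sampling_rate: float = 25.0, half_window_s: float = 120.0):
        self.sampling_rate = sampling_rate
        self.half_window_s = half_window_s

    def _transform_series(self, x):
        return moving_average_detrend(x, self.sampling_rate, self.half_window_s)


class EllipticLowpass(_ColumnwiseTransform):
    def __init__(self, sampling_rate: float = 25.0, cutoff_hz: float = 0.5, order: int = 6,
                 passband_ripple_db: float = 0.5, stopband_atten_db: float = 40.0,
                 zero_phase: bool = True):
        self.sampling_rate = sampling_rate
        self.cutoff_hz = cutoff_hz
        self.order = order
        self.passband_ripple_db = passband_ripple_db
        self.stopband_atten_db = stopband_atten_db
        self.zero_phase = zero_phase

    def _spec(self) -> FilterSpec:
        return FilterSpec(self.cutoff_hz, self.order, self.passband_ripple_db,
                          self.stopband_atten_db, self.zero_phase)

    def _transform_series(self, x):
        return lowpass(x, self.sampling_rate, self._spec())


class WaveletArtifactRemoval(_ColumnwiseTransform):
    def __init__(self, family: str = "db5", levels: int = 5, alpha: float = 0.1,
                 mode: str = "periodization"):
        self.family = family
        self.levels = levels
        self.alpha = alpha
        self.mode = mode

    def _transform_series(self, x):
        return wavelet_artifact_removal(x, WaveletSpec(self.family, self.levels,
                                                       self.alpha, self.mode))


def make_preprocessing_pipeline(sampling_rate: float = 25.0,
                                filter_spec: FilterSpec | None = None,
                                wavelet_spec: WaveletSpec | None = None) -> Pipeline:
    """Detrend -> low-pass -> wavelet removal as a scikit-learn Pipeline."""
    fspec = filter_spec or FilterSpec()
    wspec = wavelet_spec or WaveletSpec()
    return Pipeline([
        ("detrend", MovingAverageDetrend(sampling_rate=sampling_rate)),
        ("lowpass", EllipticLowpass(sampling_rate=sampling_rate, cutoff_hz=fspec.cutoff_hz,
                                    order=fspec.order,
                                    passband_ripple_db=fspec.passband_ripple_db,
                                    stopband_atten_db=fspec.stopband_atten_db,
                                    zero_phase=fspec.zero_phase)),
        ("wavelet", WaveletArtifactRemoval(family=wspec.family, levels=wspec.levels,
                                           alpha=wspec.alpha, mode=wspec.mode)),
    ])


def preprocess_pipeline(recording: Recording,
                        half_window_s: float = 120.0,
                        filter_spec: FilterSpec | None = None,
                        wavelet_spec: WaveletSpec | None = None) -> Recording:
    """Apply all three stages to every channel/chromophore independently."""
    fs = recording.sampling_rate
    out = np.empty_like(recording.data)
    for ch in range(recording.data.shape[0]):
        for cm in range(recording.data.shape[1]):
            x = moving_average_detrend(recording.data[ch, cm], fs, half_window_s)
            x = lowpass(x, fs, filter_spec)
            x = wavelet_artifact_removal(x, wavelet_spec)
            out[ch, cm] = x
    return Recording(data=out, sampling_rate=fs, channel_meta=list(recording.channel_meta))
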