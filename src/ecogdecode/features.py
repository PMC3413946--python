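"""Sliding-window spectral feature extraction.

Raw multichannel signals are re-referenced with a common average reference
(CAR), then converted, for every 300 ms window advanced by 100 ms, into
autoregressive (Burg, order 25) amplitude spectra on a 0-200 Hz / 1 Hz-bin
grid. Band features are the mean amplitudes over mu (8-12 Hz), beta
(18-26 Hz), and high gamma (70-170 Hz); the local motor potential (LMP) is
the plain time-domain mean of the same window. Windows are left-aligned and
half-open, and each step is stamped with its window end, so the features at
step time t depend only on the past — the extraction is causal and usable
online.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import GroupKFold, KFold, cross_val_score
from sklearn.svm import LinearSVC
from statsmodels.regression.linear_model import burg

BANDS = {"mu": (8, 12), "beta": (18, 26), "gamma": (70, 170)}
BAND_ORDER = ("mu", "beta", "gamma", "lmp")
F_MAX_HZ = 200
DEFAULT_AR_ORDER = 25
WINDOW_S = 0.3
STEP_S = 0.1


@dataclass
class FeatureSeries:
    """Per-step feature matrix with (channel, band) column labels."""

    values: np.ndarray            # (n_steps, M), M = 4 * n_channels
    step_times: np.ndarray        # window-end times, 0.1 s spacing
    feature_labels: list[tuple[int, str]]

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"ch{c}_{b}" for c, b in self.feature_labels]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "step_time", self.step_times)
        return df


def apply_car(signal: np.ndarray) -> np.ndarray:
    """Common average reference: subtract the across-channel mean per sample."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[0] < 2:
        raise ValueError("CAR requires a (channels, samples) array with >= 2 "
                         "channels")
    return signal - signal.mean(axis=0, keepdims=True)


@lru_cache(maxsize=8)
def _freq_response_matrix(order: int, fs: float) -> np.ndarray:
    freqs = np.arange(F_MAX_HZ + 1)
    return np.exp(-2j * np.pi * np.outer(freqs / fs, np.arange(1, order + 1)))


def ar_spectrum(window: np.ndarray, order: int = DEFAULT_AR_ORDER,
                fs: float = 1200.0) -> np.ndarray:
    """Burg AR amplitude spectrum at integer frequencies 0..200 Hz.

    Returns the square root of the AR power spectral density. A constant
    (zero-variance) window has no AR representation; it yields an all-zero
    amplitude vector rather than an error so that streaming extraction
    survives flat segments.
    """
    window = np.asarray(window, dtype=float).ravel()
    if order >= window.size:
        raise ValueError("AR order must be below the window length")
    if np.ptp(window) == 0 or np.var(window) < 1e-30:
        return np.zeros(F_MAX_HZ + 1)
    coeffs, sigma2 = burg(window - window.mean(), order)
    E = _freq_response_matrix(order, fs)
    denom = np.abs(1.0 - E @ coeffs) ** 2
    return np.sqrt(np.maximum(sigma2, 0.0) / np.maximum(denom, 1e-300))


def band_features(spectrum: np.ndarray) -> tuple[float, float, float]:
    """Mean amplitude over the inclusive integer-Hz mu/beta/gamma bins."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != F_MAX_HZ + 1:
        raise ValueError("expected 201 amplitude bins (0-200 Hz)")
    out = []
    for name in ("mu", "beta", "gamma"):
        lo, hi = BANDS[name]
        out.append(float(spectrum[..., lo:hi + 1].mean()))
    return tuple(out)


def lmp(window: np.ndarray) -> float:
    """Local motor potential: the time-domain mean of the window."""
    return float(np.mean(window))


def _window_starts(n_samples: int, fs: float) -> np.ndarray:
    win = int(round(WINDOW_S * fs))
    step = int(round(STEP_S * fs))
    if n_samples < win:
        raise ValueError("signal shorter than one 300 ms analysis window")
    n_steps = (n_samples - win) // step + 1
    return np.arange(n_steps) * step


def extract_features(session_or_signal, fs: float | None = None,
                     ar_order: int = DEFAULT_AR_ORDER,
                     exclude_channels: tuple[int, ...] = ()) -> FeatureSeries:
    """Turn a raw session into the per-100 ms (mu, beta, gamma, LMP) series.

    ``exclude_channels`` drops channels (e.g. occipital contacts) before the
    CAR filter is applied. Features are ordered channel-major; channel
    indices in the labels refer to positions after exclusion.
    """
    if hasattr(session_or_signal, "signal"):
        signal = session_or_signal.signal
        fs = session_or_signal.sampling_rate
    else:
        signal = np.asarray(session_or_signal, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
    if exclude_channels:
        keep = [c for c in range(signal.shape[0])
                if c not in set(exclude_channels)]
        signal = signal[keep]
    car = apply_car(signal)
    win = int(round(WINDOW_S * fs))
    starts = _window_starts(car.shape[1], fs)
    n_channels = car.shape[0]
    values = np.empty((starts.size, 4 * n_channels))
    for i, s in enumerate(starts):
        seg = car[:, s:s + win]
        for c in range(n_channels):
            spec = ar_spectrum(seg[c], order=ar_order, fs=fs)
            mu, beta, gamma = band_features(spec)
            base = 4 * c
            values[i, base:base + 4] = (mu, beta, gamma, lmp(seg[c]))
    step_times = (starts + win) / fs
    labels = [(c, b) for c in range(n_channels) for b in BAND_ORDER]
    return FeatureSeries(values=values, step_times=step_times,
                         feature_labels=labels)


def normalize_to_rest(features: FeatureSeries,
                      rest_steps: np.ndarray) -> FeatureSeries:
    """Divide each spectral feature by its mean over the rest steps.

    A normalized value of 1 means no task-related modulation; 2 means the
    amplitude doubled relative to rest. The LMP is a signed time-domain
    average, not an amplitude, and is left unscaled.
    """
    rest_steps = np.asarray(rest_steps, dtype=int)
    if rest_steps.size == 0:
        raise ValueError("rest step set is empty")
    values = features.values.copy()
    for j, (_, band) in enumerate(features.feature_labels):
        if band == "lmp":
            continue
        denom = values[rest_steps, j].mean()
        if denom == 0:
            raise ValueError(f"zero rest mean for feature column {j}")
        values[:, j] = values[:, j] / denom
    return FeatureSeries(values=values, step_times=features.step_times.copy(),
                         feature_labels=list(features.feature_labels))


class ForwardFeatureSelector(BaseEstimator):
    """Greedy forward feature selection by cross-validated accuracy.

    Starting from the empty set, each iteration adds the feature whose
    inclusion maximizes the mean 5-fold cross-validated score of the scoring
    classifier; ties break toward the lower feature index, which makes the
    selection order reproducible. Folds are grouped (trial-wise) when groups
    are supplied, to avoid leakage across temporally overlapping windows.

    The default scorer is a fast class-weighted linear SVM on single-step
    feature vectors; pass any sklearn classifier via ``estimator`` to score
    with the downstream model instead.
    """

    def __init__(self, k: int = 20, cv: int = 5, estimator=None,
                 scoring: str = "accuracy", random_state: int = 0):
        self.k = k
        self.cv = cv
        self.estimator = estimator
        self.scoring = scoring
        self.random_state = random_state

    def _make_estimator(self):
        if self.estimator is not None:
            from sklearn.base import clone
            return clone(self.estimator)
        return LinearSVC(class_weight="balanced", dual=True, max_iter=5000,
                         random_state=self.random_state)

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_features = X.shape[1]
        if self.k > n_features:
            raise ValueError("k exceeds the number of available features")
        if np.unique(y).size < 2:
            raise ValueError("forward selection needs >= 2 classes")
        if groups is not None:
            groups = np.asarray(groups)
            splitter = GroupKFold(n_splits=self.cv)
        else:
            splitter = KFold(n_splits=self.cv, shuffle=True,
                             random_state=self.random_state)
        selected: list[int] = []
        remaining = list(range(n_features))
        scores: list[float] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(self.k):
                best_j, best_score = None, -np.inf
                for j in remaining:
                    cols = selected + [j]
                    cv_scores = cross_val_score(
                        self._make_estimator(), X[:, cols], y,
                        groups=groups, cv=splitter, scoring=self.scoring)
                    score = float(np.mean(cv_scores))
                    if score > best_score + 1e-12:
                        best_j, best_score = j, score
                selected.append(best_j)
                remaining.remove(best_j)
                scores.append(best_score)
        self.selected_ = np.asarray(selected, dtype=int)
        self.scores_ = np.asarray(scores)
        self.n_features_in_ = n_features
        return self

    def get_support(self, indices: bool = True):
        if indices:
            return self.selected_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask

    def transform(self, X):
        return np.asarray(X)[:, self.selected_]


def forward_feature_selection(features: FeatureSeries, labels: np.ndarray,
                              k: int = 20, groups=None, cv: int = 5,
                              scoring: str = "accuracy",
                              random_state: int = 0) -> np.ndarray:
    """Functional wrapper over :class:`ForwardFeatureSelector`.

    ``labels`` may contain negative entries marking unlabeled steps; those
    steps are dropped before selection.
    """
    if k == 0:
        return np.asarray([], dtype=int)
    labels = np.asarray(labels)
    mask = labels >= 0
    X = features.values[mask]
    y = labels[mask]
    g = None if groups is None else np.asarray(groups)[mask]
    sel = ForwardFeatureSelector(k=k, cv=cv, scoring=scoring,
                                 random_state=random_state)
    sel.fit(X, y, groups=g)
    return sel.selected_
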