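"""Asynchronous movement-onset detection with a class-weighted SVM.

A detector watches a 1 s FIFO buffer (10 feature steps) and, once the buffer
is full, emits every 100 ms the probability that the *next* step is a
movement onset. Onsets are scarce — one step per trial against hundreds of
rest steps — so the SVM penalties are weighted by the inverse class-size
ratio, probabilities come from a Platt-style sigmoid, and performance is
summarized by the F1 score, which ignores the overwhelming true-negative
count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GroupKFold, ParameterGrid
from sklearn.svm import SVC

from .features import FeatureSeries, STEP_S, WINDOW_S, _window_starts

UNLABELED = -1
DEFAULT_THRESHOLD = 0.3
DEFAULT_BUFFER_LEN = 10
NEAR_ONSET_STEPS = 2  # 200 ms


@dataclass
class OnsetLabels:
    """Per-step onset labels on the 10 Hz step grid.

    ``labels`` holds 1 at each trial's single onset step, 0 at the steps from
    the trial start up to the onset, and -1 everywhere else (post-onset
    movement, inter-trial gaps, and trials whose joystick never crossed the
    threshold — those trials are excluded).
    """

    labels: np.ndarray         # (n_steps,) in {-1, 0, 1}
    onset_steps: np.ndarray    # one step index per valid trial
    trial_of_step: np.ndarray  # trial id per labeled step, -1 elsewhere

    @property
    def n_steps(self) -> int:
        return self.labels.size


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    FP_far: int = 0  # false positives > 200 ms from any true onset

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN, self.FP_far) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.FP_far > self.FP:
            raise ValueError("FP_far cannot exceed FP")


def f1_score(counts: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); true negatives never enter."""
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); returning 0.0")
        return 0.0
    return 2.0 * counts.TP / denom


def downsample_joystick(joystick_xy: np.ndarray,
                        fs: float = 1200.0) -> np.ndarray:
    """Moving-average the joystick to 10 Hz and return its radial extension.

    Uses the same 300 ms windows with 200 ms overlap as the feature
    extraction, so the radial series aligns step-for-step with the features.
    """
    joystick_xy = np.asarray(joystick_xy, dtype=float)
    win = int(round(WINDOW_S * fs))
    starts = _window_starts(joystick_xy.shape[1], fs)
    means = np.empty((starts.size, 2))
    for i, s in enumerate(starts):
        means[i] = joystick_xy[:, s:s + win].mean(axis=1)
    return np.hypot(means[:, 0], means[:, 1])


def label_onset(radial: np.ndarray, max_extension: float,
                trial_bounds: list[tuple[int, int]]) -> OnsetLabels:
    """Label each trial's first crossing of one eighth of full extension.

    ``trial_bounds`` gives, per trial, the half-open step range
    ``[start, stop)`` beginning at the trial's start. The onset is the first
    step with radial strictly above ``max_extension / 8``; earlier steps in
    the trial are labeled not-onset. Trials that never cross are excluded
    entirely.
    """
    if max_extension <= 0:
        raise ValueError("max_extension must be positive")
    radial = np.asarray(radial, dtype=float)
    labels = np.full(radial.size, UNLABELED, dtype=int)
    trial_of_step = np.full(radial.size, -1, dtype=int)
    onset_steps = []
    thresh = max_extension / 8.0
    for k, (lo, hi) in enumerate(trial_bounds):
        seg = radial[lo:hi]
        above = np.flatnonzero(seg > thresh)
        if above.size == 0:
            continue  # excluded trial
        onset = lo + int(above[0])
        labels[lo:onset] = 0
        labels[onset] = 1
        trial_of_step[lo:onset + 1] = k
        onset_steps.append(onset)
    return OnsetLabels(labels=labels,
                       onset_steps=np.asarray(onset_steps, dtype=int),
                       trial_of_step=trial_of_step)


def trial_step_bounds(trials, step_times: np.ndarray,
                      n_steps: int) -> list[tuple[int, int]]:
    """Map trial (target_time) boundaries onto the feature step grid."""
    step_times = np.asarray(step_times)
    bounds = []
    starts = [tt for (_, tt, _) in trials]
    for k, tt in enumerate(starts):
        nxt = starts[k + 1] if k + 1 < len(starts) else np.inf
        lo = int(np.searchsorted(step_times, tt, side="left"))
        hi = int(np.searchsorted(step_times, nxt, side="left"))
        bounds.append((lo, min(hi, n_steps)))
    return bounds


def make_buffers(values: np.ndarray, labels: OnsetLabels,
                 buffer_len: int = DEFAULT_BUFFER_LEN,
                 selected: np.ndarray | None = None):
    """Flatten FIFO buffers for every labeled step with a full buffer.

    A step is usable when its ``buffer_len`` predecessor steps all belong to
    the same trial, mirroring the online rule that each trial starts with an
    empty buffer. Returns (X, y, groups, step_indices).
    """
    values = np.asarray(values, dtype=float)
    if selected is not None and len(selected) > 0:
        values = values[:, np.asarray(selected, dtype=int)]
    X, y, groups, steps = [], [], [], []
    lab, trial = labels.labels, labels.trial_of_step
    for s in range(buffer_len, labels.n_steps):
        if lab[s] == UNLABELED:
            continue
        if not np.all(trial[s - buffer_len:s] == trial[s]):
            continue
        X.append(values[s - buffer_len:s].ravel())
        y.append(lab[s])
        groups.append(trial[s])
        steps.append(s)
    return (np.asarray(X), np.asarray(y, dtype=int),
            np.asarray(groups, dtype=int), np.asarray(steps, dtype=int))


class OnsetDetector(BaseEstimator, ClassifierMixin):
    """Class-weighted RBF-kernel SVM onset detector on flattened buffers.

    The penalty on the onset class is the inverse class-size ratio
    (#not-onset / #onset). Kernel hyperparameters are chosen by a small
    grid search on training folds (grouped by trial when groups are given),
    maximizing F1. Probabilities are Platt-sigmoid calibrated; predicted
    onsets are steps whose probability exceeds ``threshold`` (default 0.3).
    """

    def __init__(self, C_grid=(1.0, 10.0, 100.0), gamma_grid=("scale",),
                 threshold: float = DEFAULT_THRESHOLD, cv: int = 3,
                 random_state: int = 0):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.threshold = threshold
        self.cv = cv
        self.random_state = random_state

    def _fit_one(self, X, y, C, gamma, weight):
        # Platt-style sigmoid probability calibration on training folds
        base = SVC(kernel="rbf", C=C, gamma=gamma,
                   class_weight={0: 1.0, 1: weight},
                   random_state=self.random_state)
        n_cal = min(3, int(np.sum(y == 1)), int(np.sum(y == 0)))
        if n_cal < 2:
            raise ValueError("too few samples in a class to calibrate "
                             "probabilities")
        return CalibratedClassifierCV(base, method="sigmoid", cv=n_cal,
                                      ensemble=False).fit(X, y)

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = classes
        n_neg, n_pos = counts[classes == 0][0], counts[classes == 1][0]
        self.class_weight_ratio_ = n_neg / n_pos
        # feature z-scoring learned on training data only
        self.scale_mean_ = X.mean(axis=0)
        self.scale_std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.scale_mean_) / self.scale_std_

        grid = list(ParameterGrid({"C": list(self.C_grid),
                                   "gamma": list(self.gamma_grid)}))
        if len(grid) == 1:
            self.best_params_ = grid[0]
        else:
            if groups is not None:
                splits = list(GroupKFold(n_splits=min(
                    self.cv, np.unique(groups).size)).split(Xs, y, groups))
            else:
                from sklearn.model_selection import StratifiedKFold
                splits = list(StratifiedKFold(
                    n_splits=self.cv, shuffle=True,
                    random_state=self.random_state).split(Xs, y))
            best, best_f1 = grid[0], -np.inf
            for params in grid:
                f1s = []
                for tr, te in splits:
                    if np.unique(y[tr]).size < 2:
                        continue
                    svm = self._fit_one(Xs[tr], y[tr], params["C"],
                                        params["gamma"],
                                        (y[tr] == 0).sum() /
                                        max((y[tr] == 1).sum(), 1))
                    pred = (svm.predict_proba(Xs[te])[:, 1]
                            > self.threshold).astype(int)
                    tp = int(np.sum((pred == 1) & (y[te] == 1)))
                    fp = int(np.sum((pred == 1) & (y[te] == 0)))
                    fn = int(np.sum((pred == 0) & (y[te] == 1)))
                    denom = 2 * tp + fp + fn
                    f1s.append(2 * tp / denom if denom else 0.0)
                mean_f1 = float(np.mean(f1s)) if f1s else 0.0
                if mean_f1 > best_f1 + 1e-12:
                    best, best_f1 = params, mean_f1
            self.best_params_ = best
        self.svm_ = self._fit_one(Xs, y, self.best_params_["C"],
                                  self.best_params_["gamma"],
                                  self.class_weight_ratio_)
        self.buffer_dim_ = X.shape[1]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        Xs = (X - self.scale_mean_) / self.scale_std_
        return self.svm_.predict_proba(Xs)

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > self.threshold).astype(int)


def predict_onset_probability(model: OnsetDetector, buffer: np.ndarray,
                              buffer_len: int = DEFAULT_BUFFER_LEN):
    """Probability that the next step is an onset, or None if not ready.

    ``buffer`` is a (steps, features) window; a prediction is made only once
    the FIFO buffer holds the full ``buffer_len`` steps.
    """
    buffer = np.asarray(buffer, dtype=float)
    if buffer.ndim != 2 or buffer.shape[0] < buffer_len:
        return None
    flat = buffer[-buffer_len:].ravel()[None, :]
    return float(model.predict_proba(flat)[0, 1])


def threshold_onsets(p_series: np.ndarray,
                     threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Steps whose onset probability strictly exceeds the threshold."""
    return np.flatnonzero(np.asarray(p_series, dtype=float) > threshold)


def evaluate_onsets(predicted_steps: np.ndarray, truth: OnsetLabels,
                    scored_steps: np.ndarray | None = None) -> ConfusionCounts:
    """Per-step scoring of predicted onsets against the labeled grid.

    Every labeled step is one classification event: a prediction at the true
    onset step is a TP, a miss there is an FN, predictions at not-onset steps
    are FP (counted in FP_far when more than 200 ms, i.e. two steps, from any
    true onset). ``scored_steps`` restricts scoring to the steps on which the
    detector actually emitted predictions (full-buffer steps).
    """
    predicted = set(int(s) for s in np.asarray(predicted_steps).ravel())
    onset_set = set(int(s) for s in truth.onset_steps)
    if scored_steps is None:
        scored = np.flatnonzero(truth.labels != UNLABELED)
    else:
        scored = np.asarray(scored_steps, dtype=int)
    tp = fp = fn = tn = fp_far = 0
    onsets = np.asarray(sorted(onset_set))
    for s in scored:
        is_onset = int(s) in onset_set
        is_pred = int(s) in predicted
        if is_onset and is_pred:
            tp += 1
        elif is_onset:
            fn += 1
        elif is_pred:
            fp += 1
            if onsets.size == 0 or np.min(np.abs(onsets - s)) > NEAR_ONSET_STEPS:
                fp_far += 1
        else:
            tn += 1
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, FP_far=fp_far)


def train_onset(features: FeatureSeries, labels: OnsetLabels,
                selected: np.ndarray | None = None,
                buffer_len: int = DEFAULT_BUFFER_LEN,
                **detector_params) -> tuple[OnsetDetector, np.ndarray]:
    """Fit an :class:`OnsetDetector` on a session's labeled buffers.

    Returns the fitted detector and the step indices of the buffers used.
    """
    X, y, groups, steps = make_buffers(features.values, labels,
                                       buffer_len=buffer_len,
                                       selected=selected)
    det = OnsetDetector(**detector_params)
    det.fit(X, y, groups=groups)
    return det, steps


def feature_confidence_map(features: FeatureSeries, labels: OnsetLabels,
                           feature_indices: np.ndarray | None = None,
                           n_repeats: int = 20, cv: int = 5,
                           buffer_len: int = DEFAULT_BUFFER_LEN,
                           random_state: int = 0):
    """Per-feature onset-detection confidence indices -log(p).

    For each feature alone, the 5-fold cross-validation is repeated
    ``n_repeats`` times with random trial-wise refolds; each repetition
    yields one pooled F1 score. A one-sided t-test of the F1 sample against
    zero gives a p-value, reported as the natural-log confidence index
    -log(p) (so p < 0.05 corresponds to an index above 3). Zero-variance F1
    samples cannot be t-tested: an all-positive sample is flagged and
    reported as +inf, an all-zero sample as index 0.

    Returns (confidence, flags) arrays over the requested features.
    """
    if feature_indices is None:
        feature_indices = np.arange(features.n_features)
    feature_indices = np.asarray(feature_indices, dtype=int)
    confidence = np.empty(feature_indices.size)
    flags = np.zeros(feature_indices.size, dtype=bool)
    for i, j in enumerate(feature_indices):
        # identical refold sequence per feature, so duplicated features
        # receive identical confidence
        rng = np.random.default_rng(random_state)
        X, y, groups, _ = make_buffers(features.values, labels,
                                       buffer_len=buffer_len, selected=[j])
        f1s = np.empty(n_repeats)
        uniq = np.unique(groups)
        for r in range(n_repeats):
            # random trial-wise refold
            perm = rng.permutation(uniq)
            fold_of = {g: f for f, gs in
                       enumerate(np.array_split(perm, cv)) for g in gs}
            fold = np.array([fold_of[g] for g in groups])
            preds = np.empty_like(y)
            for f in range(cv):
                tr, te = fold != f, fold == f
                if np.unique(y[tr]).size < 2 or not te.any():
                    preds[te] = 0
                    continue
                det = OnsetDetector(C_grid=(1.0,), gamma_grid=("scale",),
                                    random_state=random_state)
                det.fit(X[tr], y[tr])
                preds[te] = det.predict(X[te])
            tp = int(np.sum((preds == 1) & (y == 1)))
            fpc = int(np.sum((preds == 1) & (y == 0)))
            fnc = int(np.sum((preds == 0) & (y == 1)))
            denom = 2 * tp + fpc + fnc
            f1s[r] = 2 * tp / denom if denom else 0.0
        if np.ptp(f1s) == 0:
            if f1s[0] > 0:
                confidence[i] = np.inf
                flags[i] = True
            else:
                confidence[i] = 0.0
        else:
            res = stats.ttest_1samp(f1s, 0.0, alternative="greater")
            confidence[i] = -np.log(max(res.pvalue, 1e-300))
    return confidence, flags
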