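"""End-to-end decoding pipeline: session -> features -> onset -> direction
-> targeting simulation.

The pipeline reproduces the offline analysis flow: sliding-window feature
extraction, trial-wise cross-validated onset detection with pooled
confusion counts and F1, per-direction MTVDBN classification of the 1 s
pre-onset windows with angular-error statistics, and the alpha-repositioning
targeting simulation at the session's average movement speed. Everything is
deterministic given the configuration (including its seeds), and all fitted
hyperparameters are recorded in the returned report.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold

from .config import PipelineConfig
from .features import extract_features, forward_feature_selection
from .io import read_session
from .mtvdbn import (MtvdbnDirectionClassifier, angular_error, select_lambda)
from .onset import (OnsetDetector, downsample_joystick, evaluate_onsets,
                    f1_score, label_onset, make_buffers, threshold_onsets,
                    trial_step_bounds)
from .synthetic import generate_session
from .targeting import (TargetLayout, average_speed, chance_angular_stats,
                        compare_with_without, movement_time, optimize_alpha,
                        reposition_cursor)


def _hit_times(session, onset_times: np.ndarray) -> np.ndarray:
    """First time after each onset at which the joystick reaches (nearly)
    full radial extension."""
    fs = session.sampling_rate
    radial = np.hypot(session.joystick_xy[0], session.joystick_xy[1])
    hits = np.empty(onset_times.size)
    thresh = 0.99 * session.max_radial_extension
    for i, ot in enumerate(onset_times):
        start = int(ot * fs)
        rel = np.flatnonzero(radial[start:] >= thresh)
        hits[i] = (start + rel[0]) / fs if rel.size else np.nan
    return hits


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full decoding stack and return an evaluation report."""
    report: dict = {"config": config.to_dict(), "stages": {}}

    # -- session ----------------------------------------------------------
    if config.session_path:
        session = read_session(config.session_path)
    else:
        session = generate_session(config.sim)

    # -- features ---------------------------------------------------------
    features = extract_features(session, ar_order=config.ar_order,
                                exclude_channels=config.exclude_channels)
    report["stages"]["features"] = {
        "n_steps": features.n_steps, "n_features": features.n_features}

    # -- onset labeling ---------------------------------------------------
    radial = downsample_joystick(session.joystick_xy, fs=session.sampling_rate)
    bounds = trial_step_bounds(session.trials, features.step_times,
                               features.n_steps)
    labels = label_onset(radial, session.max_radial_extension, bounds)
    if labels.onset_steps.size < config.n_folds:
        raise RuntimeError("onset labeling: too few valid trials")

    # -- feature selection (single-step, trial-wise folds) ----------------
    k = min(config.n_selected_features, features.n_features)
    selected = forward_feature_selection(
        features, labels.labels, k=k, groups=labels.trial_of_step,
        cv=config.n_folds, scoring="f1", random_state=config.seed)
    report["stages"]["feature_selection"] = {
        "k": int(k), "selected": [int(j) for j in selected]}

    # -- onset detection (pooled trial-wise CV) ---------------------------
    X, y, groups, steps = make_buffers(features.values, labels,
                                       buffer_len=config.buffer_len,
                                       selected=selected)
    gkf = GroupKFold(n_splits=config.n_folds)
    pooled_pred = np.zeros_like(y)
    fitted_params = []
    for tr, te in gkf.split(X, y, groups):
        det = OnsetDetector(C_grid=config.svm_C_grid,
                            gamma_grid=config.svm_gamma_grid,
                            threshold=config.onset_threshold,
                            random_state=config.seed)
        det.fit(X[tr], y[tr], groups=groups[tr])
        p = det.predict_proba(X[te])[:, 1]
        pooled_pred[te[threshold_onsets(p, config.onset_threshold)]] = 1
        fitted_params.append(dict(det.best_params_,
                                  weight=float(det.class_weight_ratio_)))
    predicted_steps = steps[pooled_pred == 1]
    counts = evaluate_onsets(predicted_steps, labels, scored_steps=steps)
    onset_f1 = f1_score(counts)
    report["stages"]["onset"] = {
        "confusion": {"TP": counts.TP, "FP": counts.FP, "FN": counts.FN,
                      "TN": counts.TN, "FP_far": counts.FP_far},
        "f1": onset_f1, "n_events": int(y.size),
        "svm_params_per_fold": fitted_params,
        "threshold": config.onset_threshold,
    }

    # -- direction classification ----------------------------------------
    dir_feats = (selected if config.direction_feature_set == "selected"
                 else np.arange(features.n_features))
    onset_steps = labels.onset_steps
    usable = onset_steps >= config.T
    onset_steps = onset_steps[usable]
    true_dirs = np.array([session.trials[labels.trial_of_step[s]][0]
                          for s in onset_steps])
    windows = np.stack([features.values[s - config.T:s][:, dir_feats]
                        for s in onset_steps])

    # penalty selected once on the full set, then fixed across eval folds
    mean = windows.mean(axis=0)
    std = np.where(windows.std(axis=0) > 0, windows.std(axis=0), 1.0)
    # plain max-accuracy selection: with few folds on modest sessions the
    # one-SE rule's standard error is wide enough to prune real structure
    lam = select_lambda((windows - mean) / std, true_dirs,
                        config.lambda_grid, cv=config.n_folds, one_se=False,
                        random_state=config.seed, prestandardized=True)

    n_dir_folds = min(config.n_folds,
                      int(np.min(np.bincount(true_dirs))) or 1)
    n_dir_folds = max(2, n_dir_folds)
    skf = StratifiedKFold(n_splits=n_dir_folds, shuffle=True,
                          random_state=config.seed)
    pred_dirs = np.empty_like(true_dirs)
    for tr, te in skf.split(windows[:, 0, 0], true_dirs):
        clf = MtvdbnDirectionClassifier(lam=lam, T=config.T)
        clf.fit(windows[tr], true_dirs[tr])
        pred_dirs[te] = clf.predict(windows[te])
    errs = np.array([angular_error(p, t, session.n_directions)
                     for p, t in zip(pred_dirs, true_dirs)])
    chance_mean, chance_sd = chance_angular_stats(session.n_directions)
    report["stages"]["direction"] = {
        "lambda": float(lam), "n_trials": int(true_dirs.size),
        "accuracy": float(np.mean(pred_dirs == true_dirs)),
        "chance_accuracy": 1.0 / session.n_directions,
        "angular_error_mean": float(errs.mean()),
        "angular_error_sd": float(errs.std()),
        "chance_angular_mean": chance_mean,
        "chance_angular_sd": chance_sd,
    }

    # -- targeting simulation --------------------------------------------
    valid_trial_ids = np.array([labels.trial_of_step[s] for s in onset_steps])
    onset_times = features.step_times[onset_steps]
    hit_times = _hit_times(session, onset_times)
    ok = np.isfinite(hit_times) & (hit_times > onset_times)
    layout = TargetLayout(n_targets=session.n_directions,
                          radius=session.max_radial_extension)
    speed = average_speed(onset_times[ok], hit_times[ok], layout.radius)
    pairs = list(zip(true_dirs, pred_dirs))
    alpha_star, curve = optimize_alpha(pairs, layout, speed,
                                       alpha_grid=config.alpha_grid)
    baseline = np.full(len(pairs),
                       movement_time((0.0, 0.0), layout.target_position(0),
                                     speed))
    assisted = np.array([
        movement_time(reposition_cursor(p, alpha_star, layout),
                      layout.target_position(t), speed) for t, p in pairs])
    comparison = compare_with_without(baseline, assisted)
    report["stages"]["targeting"] = {
        "average_speed": float(speed),
        "alpha_star": float(alpha_star),
        "mean_time_curve": {str(a): float(v) for a, v in
                            zip(config.alpha_grid, curve)},
        "observed_movement_time_mean": float(
            np.mean(hit_times[ok] - onset_times[ok])),
        **comparison,
    }
    report["n_valid_trials"] = int(valid_trial_ids.size)
    return report
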