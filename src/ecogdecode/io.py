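"""Session, feature, and model persistence.

Sessions are exchanged as HDF5 files with groups ``/signal``, ``/joystick``,
``/trials`` and (for synthetic sessions) ``/truth``; trial events also round
trip through a plain CSV table. Direction model sets serialize to a
documented JSON structure (per direction, per slice, per node: parent
indices and coefficients, plus the penalty and the standardization scaler).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FeatureSeries
from .mtvdbn import MtvdbnModel, MtvdbnDirectionClassifier
from .synthetic import RawSession


class SessionFormatError(ValueError):
    """Raised when an HDF5 session file does not match the documented layout."""


def write_session(path, session: RawSession) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = session.sampling_rate
        f.attrs["max_radial_extension"] = session.max_radial_extension
        f.attrs["n_directions"] = session.n_directions
        f.create_dataset("signal/data", data=session.signal)
        f.create_dataset("joystick/xy", data=session.joystick_xy)
        g = f.create_group("trials")
        g.create_dataset("target_index",
                         data=np.array([t[0] for t in session.trials]))
        g.create_dataset("target_time_s",
                         data=np.array([t[1] for t in session.trials]))
        g.create_dataset("cursor_time_s",
                         data=np.array([t[2] for t in session.trials]))
        if session.truth is not None:
            tr = f.create_group("truth")
            tr.create_dataset("onset_times",
                              data=np.asarray(session.truth["onset_times"]))
            tr.create_dataset("hit_times",
                              data=np.asarray(session.truth["hit_times"]))
            tr.create_dataset("directions",
                              data=np.asarray(session.truth["directions"]))
            tr.create_dataset(
                "latent_windows",
                data=np.asarray(session.truth["latent_windows"]))


def read_session(path) -> RawSession:
    with h5py.File(path, "r") as f:
        for group in ("signal", "joystick", "trials"):
            if group not in f:
                raise SessionFormatError(
                    f"session file is missing the /{group} group")
        signal = f["signal/data"][()]
        joystick = f["joystick/xy"][()]
        g = f["trials"]
        trials = [(int(d), float(tt), float(ct)) for d, tt, ct in zip(
            g["target_index"][()], g["target_time_s"][()],
            g["cursor_time_s"][()])]
        truth = None
        if "truth" in f:
            truth = {k: f["truth"][k][()]
                     for k in ("onset_times", "hit_times", "directions",
                               "latent_windows") if k in f["truth"]}
        session = RawSession(
            signal=signal, joystick_xy=joystick, trials=trials,
            max_radial_extension=float(f.attrs["max_radial_extension"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            n_directions=int(f.attrs["n_directions"]), truth=truth)
    if joystick.shape[0] != 2 or joystick.shape[1] != signal.shape[1]:
        raise SessionFormatError("joystick and signal lengths disagree")
    try:
        session.validate()
    except ValueError as exc:
        raise SessionFormatError(str(exc)) from exc
    return session


def write_events_csv(path, session: RawSession) -> None:
    df = pd.DataFrame(
        [(k, d, tt, ct) for k, (d, tt, ct) in enumerate(session.trials)],
        columns=["trial", "target_index", "target_time_s", "cursor_time_s"])
    df.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features_tsv(path, features: FeatureSeries) -> None:
    features.to_frame().to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> FeatureSeries:
    df = pd.read_csv(path, sep="\t")
    labels = []
    for col in df.columns[1:]:
        ch, band = col.split("_", 1)
        labels.append((int(ch[2:]), band))
    return FeatureSeries(values=df.iloc[:, 1:].to_numpy(dtype=float),
                         step_times=df["step_time"].to_numpy(dtype=float),
                         feature_labels=labels)


# -- direction model JSON ---------------------------------------------------

def _model_to_dict(model: MtvdbnModel) -> dict:
    return {
        "direction": model.direction, "T": model.T, "M": model.M,
        "lambda": model.lam,
        "slices": [
            {str(m): {
                "temporal_parents": [int(p) for p in
                                     model.temporal_parents[t][m]],
                "temporal_coefs": list(map(float, model.temporal_coefs[t][m])),
                "spatial_parents": [int(p) for p in
                                    model.spatial_parents[t][m]],
                "spatial_coefs": list(map(float, model.spatial_coefs[t][m])),
            } for m in range(model.M)}
            for t in range(model.T)],
    }


def _model_from_dict(d: dict) -> MtvdbnModel:
    model = MtvdbnModel(direction=int(d["direction"]), T=int(d["T"]),
                        M=int(d["M"]), lam=float(d["lambda"]))
    for sl in d["slices"]:
        tp, tc, sp, sc = {}, {}, {}, {}
        for m_str, node in sl.items():
            m = int(m_str)
            tp[m] = list(node["temporal_parents"])
            tc[m] = np.asarray(node["temporal_coefs"], dtype=float)
            sp[m] = list(node["spatial_parents"])
            sc[m] = np.asarray(node["spatial_coefs"], dtype=float)
        model.temporal_parents.append(tp)
        model.temporal_coefs.append(tc)
        model.spatial_parents.append(sp)
        model.spatial_coefs.append(sc)
    return model


def save_direction_models(path, clf: MtvdbnDirectionClassifier) -> None:
    payload = {
        "classes": [int(c) for c in clf.classes_],
        "lambda": float(clf.lam_),
        "T": int(clf.T),
        "scaler_mean": np.asarray(clf.mean_).tolist(),
        "scaler_std": np.asarray(clf.std_).tolist(),
        "models": [_model_to_dict(m) for m in clf.models_],
    }
    Path(path).write_text(json.dumps(payload))


def load_direction_models(path) -> MtvdbnDirectionClassifier:
    payload = json.loads(Path(path).read_text())
    clf = MtvdbnDirectionClassifier(lam=payload["lambda"], T=payload["T"])
    clf.classes_ = np.asarray(payload["classes"])
    clf.lam_ = float(payload["lambda"])
    clf.mean_ = np.asarray(payload["scaler_mean"], dtype=float)
    clf.std_ = np.asarray(payload["scaler_std"], dtype=float)
    clf.models_ = [_model_from_dict(d) for d in payload["models"]]
    return clf
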