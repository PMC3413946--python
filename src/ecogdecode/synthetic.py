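"""Synthetic 8-target center-out ECoG session generator.

The generator realizes, by construction, the statistical structure the
decoders downstream assume:

* designated "motor" channels show a band-limited high-gamma amplitude
  increase and a mu/beta decrease starting at each trial's latent movement
  onset, plus a slow local-motor-potential (LMP) offset;
* in the second before onset, the latent band-features of all channels
  follow a direction-specific sparse linear-Gaussian transition/coupling
  model (one coefficient set per direction), so the time-varying dynamic
  Bayesian network's generative assumption holds at the feature level;
* the joystick's radial extension crosses one eighth of its maximum exactly
  at the latent onset and then extends fully toward the trial's target.

Raw signals are built as broadband pink noise plus per-band amplitude
modulated band-passed noise carriers, so the autoregressive spectral stage
has something real to estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .config import SimConfig, ConfigurationError

# paradigm timing (seconds)
TARGET_TO_CURSOR_S = 1.0   # cursor appears 1 s after the target
INTER_TRIAL_S = 1.0        # inter-trial interval
MOVE_RAMP_S = 0.8          # time from movement start to full extension
HOLD_S = 0.1               # dwell at full extension
RETURN_S = 0.3             # return of the joystick to rest
LATENCY_FLOOR_S = 0.2      # onset latency truncated 0.2 s after the cursor
ONSET_RESPONSE_S = 0.6     # duration of the movement-locked band response
STEP_S = 0.1               # latent envelope / feature step

N_BANDS = 4  # mu, beta, gamma, lmp
BAND_EDGES = {"mu": (8.0, 12.0), "beta": (18.0, 26.0), "gamma": (70.0, 170.0)}
BAND_BASE_AMP = {"mu": 1.0, "beta": 0.8, "gamma": 0.5}
ENVELOPE_GAIN = 0.5  # latent z -> fractional envelope modulation
LMP_SCALE = 1.0      # latent z -> LMP offset in signal units


@dataclass
class RawSession:
    """A multichannel synthetic recording with joystick and trial events."""

    signal: np.ndarray                 # (n_channels, n_samples)
    joystick_xy: np.ndarray            # (2, n_samples)
    trials: list[tuple[int, float, float]]  # (target_index, target_t, cursor_t)
    max_radial_extension: float
    sampling_rate: float = 1200.0
    n_directions: int = 8
    truth: dict | None = field(default=None, repr=False)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.sampling_rate

    def validate(self) -> None:
        dur = self.duration
        for k, (d, tt, ct) in enumerate(self.trials):
            if not (0 <= d < self.n_directions):
                raise ValueError(f"trial {k}: target_index {d} out of range")
            if not (0.0 <= tt < ct <= dur):
                raise ValueError(f"trial {k}: event times outside the signal")


def feature_index(channel: int, band: str) -> int:
    """Flat feature index for (channel, band); channel-major ordering."""
    order = ("mu", "beta", "gamma", "lmp")
    return N_BANDS * channel + order.index(band)


def motor_channels(config: SimConfig) -> np.ndarray:
    """Indices of the channels that carry movement-locked modulation."""
    return np.arange(max(1, config.n_channels // 2))


# ---------------------------------------------------------------------------
# Direction-specific coupling model (the feature-level generative core)
# ---------------------------------------------------------------------------

def direction_coupling_truth(config: SimConfig) -> dict:
    """Deterministically derive the per-direction coupling coefficients.

    For each direction ``d`` the latent band-features follow, over the ten
    100 ms steps before onset,

        x[t, m] = A_d[m] @ x[t-1] + S_d[m] @ x[t] + sigma_m * eps,

    with ``A_d`` a sparse temporal transition matrix and ``S_d`` a sparse
    within-step coupling matrix whose nonzeros respect a direction-specific
    topological node order (so each step's graph is acyclic by construction).
    Coefficients scale with ``direction_coupling_strength``; at strength 0
    the features are i.i.d. standard normal.

    Returns a dict with arrays ``temporal`` and ``spatial`` of shape
    (n_directions, M, M), the per-direction node ``orders`` and the residual
    scales ``noise_scale`` (n_directions, M).
    """
    M = N_BANDS * config.n_channels
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    c = config.direction_coupling_strength
    A = np.zeros((config.n_directions, M, M))
    S = np.zeros((config.n_directions, M, M))
    orders = np.empty((config.n_directions, M), dtype=int)
    sigma = np.ones((config.n_directions, M))
    for d in range(config.n_directions):
        order = rng.permutation(M)
        orders[d] = order
        rank = np.empty(M, dtype=int)
        rank[order] = np.arange(M)
        for m in range(M):
            tpar = rng.choice(M)
            A[d, m, tpar] = (c * rng.uniform(0.4, 0.7)
                             * rng.choice([-1.0, 1.0]))
            earlier = np.flatnonzero(rank < rank[m])
            if earlier.size and rng.random() < 0.5:
                sp = rng.choice(earlier)
                S[d, m, sp] = c * rng.uniform(0.4, 0.7) * rng.choice([-1.0, 1.0])
            load = np.sum(A[d, m] ** 2) + np.sum(S[d, m] ** 2)
            sigma[d, m] = np.sqrt(max(0.05, 1.0 - min(0.9, load)))
    return {"temporal": A, "spatial": S, "orders": orders,
            "noise_scale": sigma}


def _sample_window(truth: dict, d: int, T: int, rng: np.random.Generator,
                   noise_scale: float = 1.0) -> np.ndarray:
    """Draw one (T, M) latent feature window from direction d's model."""
    A, S = truth["temporal"][d], truth["spatial"][d]
    order, sig = truth["orders"][d], truth["noise_scale"][d]
    M = A.shape[0]
    x = np.zeros((T, M))
    eps = rng.standard_normal((T, M)) * sig * noise_scale
    for t in range(T):
        for m in order:  # topological order makes within-step terms available
            val = S[m] @ x[t] + eps[t, m]
            if t > 0:
                val += A[m] @ x[t - 1]
            x[t, m] = val
    return x


def sample_direction_windows(
    config: SimConfig,
    n_per_direction: int,
    T: int = 10,
    measurement_noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample exact pre-onset feature windows from the generative core.

    Returns ``(windows, directions)`` with windows of shape
    (n_directions * n_per_direction, T, M). These are the same latent windows
    :func:`generate_session` embeds into the raw signal, without the carrier
    synthesis / spectral re-estimation round trip. ``measurement_noise``
    adds i.i.d. Gaussian observation noise on top of the process (the
    process innovations themselves set its scale; a pure rescaling of the
    innovations would be absorbed by standardization downstream).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x51DE])
        )
    truth = direction_coupling_truth(config)
    windows, labels = [], []
    for d in range(config.n_directions):
        for _ in range(n_per_direction):
            w = _sample_window(truth, d, T, rng)
            if measurement_noise > 0:
                w = w + measurement_noise * rng.standard_normal(w.shape)
            windows.append(w)
            labels.append(d)
    return np.asarray(windows), np.asarray(labels)


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_carrier(n: int, lo: float, hi: float, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-passed white-noise carrier."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _trial_schedule(config: SimConfig, rng: np.random.Generator):
    """Event times per trial: (target_t, cursor_t, onset_t, hit_t)."""
    a = (LATENCY_FLOOR_S - config.onset_latency_mean) / max(
        config.onset_latency_sd, 1e-12)
    sched = []
    t = 1.0  # lead-in
    for _ in range(config.n_trials):
        target_t = t
        cursor_t = target_t + TARGET_TO_CURSOR_S
        if config.onset_latency_sd > 0:
            lat = stats.truncnorm.rvs(
                a, np.inf, loc=config.onset_latency_mean,
                scale=config.onset_latency_sd, random_state=rng)
        else:
            lat = max(config.onset_latency_mean, LATENCY_FLOOR_S)
        onset_t = cursor_t + lat
        hit_t = onset_t - MOVE_RAMP_S / 8 + MOVE_RAMP_S
        t = hit_t + HOLD_S + RETURN_S + INTER_TRIAL_S
        sched.append((target_t, cursor_t, onset_t, hit_t))
    return sched


def generate_session(config: SimConfig) -> RawSession:
    """Generate a complete synthetic center-out session.

    The returned session carries a ``truth`` dict with the latent per-trial
    onset times and directions, the embedded latent feature windows, the
    coupling coefficient truth, and the high-gamma envelope of the first
    motor channel (for envelope-tracking diagnostics).
    """
    fs = config.sampling_rate
    ss = np.random.SeedSequence([config.seed, 0x5E5510])
    rng_sched, rng_dir, rng_lat, rng_sig, rng_joy = (
        np.random.default_rng(s) for s in ss.spawn(5))

    directions = rng_dir.integers(0, config.n_directions, size=config.n_trials)
    sched = _trial_schedule(config, rng_sched)
    duration = sched[-1][3] + HOLD_S + RETURN_S + 1.0
    n_samples = int(np.ceil(duration * fs))
    n_steps = int(np.ceil(duration / STEP_S)) + 1
    M = N_BANDS * config.n_channels
    motor = motor_channels(config)

    # latent per-step feature deviations: baseline white, direction-coupled
    # windows spliced into the 10 steps before each onset
    z = rng_lat.standard_normal((n_steps, M))
    truth_coeffs = direction_coupling_truth(config)
    latent_windows = np.zeros((config.n_trials, 10, M))
    onset_steps = np.empty(config.n_trials, dtype=int)
    for k, (tt, ct, ot, ht) in enumerate(sched):
        o_step = int(round(ot / STEP_S))
        onset_steps[k] = o_step
        w = _sample_window(truth_coeffs, int(directions[k]), 10, rng_lat)
        latent_windows[k] = w
        z[o_step - 10:o_step, :] = w

    # movement-locked multiplicative / additive task response on motor chans
    gamma_mult = np.ones((config.n_channels, n_steps))
    mubeta_mult = np.ones((config.n_channels, n_steps))
    lmp_add = np.zeros((config.n_channels, n_steps))
    for (tt, ct, ot, ht) in sched:
        lo = int(round(ot / STEP_S))
        hi = min(n_steps, int(round((ot + ONSET_RESPONSE_S) / STEP_S)))
        gamma_mult[np.ix_(motor, range(lo, hi))] = 1.0 + config.gamma_gain
        mubeta_mult[np.ix_(motor, range(lo, hi))] = max(
            0.0, 1.0 - config.mu_beta_suppression)
        lmp_add[np.ix_(motor, range(lo, hi))] = config.lmp_shift

    def upsample(step_series: np.ndarray) -> np.ndarray:
        rep = np.repeat(step_series, int(round(STEP_S * fs)))
        return rep[:n_samples] if rep.size >= n_samples else np.pad(
            rep, (0, n_samples - rep.size), mode="edge")

    signal = np.empty((config.n_channels, n_samples))
    gamma_env_motor0 = None
    for c in range(config.n_channels):
        x = config.noise_sd * _pink_noise(n_samples, rng_sig)
        for band, (lo_f, hi_f) in BAND_EDGES.items():
            env = BAND_BASE_AMP[band] * np.maximum(
                0.05, 1.0 + ENVELOPE_GAIN * z[:, feature_index(c, band)])
            if band == "gamma":
                env = env * gamma_mult[c]
            else:
                env = env * mubeta_mult[c]
            if band == "gamma" and c == motor[0]:
                gamma_env_motor0 = env.copy()
            x += upsample(env) * _band_carrier(n_samples, lo_f, hi_f, fs,
                                               rng_sig)
        lmp_off = LMP_SCALE * z[:, feature_index(c, "lmp")] + lmp_add[c]
        x += upsample(lmp_off)
        signal[c] = x

    joystick = _synthesize_joystick(config, sched, directions, n_samples, fs,
                                    rng_joy)

    trials = [(int(directions[k]), float(sched[k][0]), float(sched[k][1]))
              for k in range(config.n_trials)]
    truth = {
        "onset_times": np.array([s[2] for s in sched]),
        "hit_times": np.array([s[3] for s in sched]),
        "directions": directions.copy(),
        "onset_steps": onset_steps,
        "latent_windows": latent_windows,
        "coupling": truth_coeffs,
        "gamma_env_motor0": gamma_env_motor0,
        "config": config,
    }
    session = RawSession(
        signal=signal, joystick_xy=joystick, trials=trials,
        max_radial_extension=config.target_radius, sampling_rate=fs,
        n_directions=config.n_directions, truth=truth)
    session.validate()
    return session


def _synthesize_joystick(config, sched, directions, n_samples, fs, rng):
    """Rest with small jitter, then a radial ramp crossing R/8 at onset."""
    R = config.target_radius
    t = np.arange(n_samples) / fs
    radial = np.zeros(n_samples)
    angle = np.zeros(n_samples)
    for k, (tt, ct, ot, ht) in enumerate(sched):
        theta = 2 * np.pi * directions[k] / config.n_directions
        start = ot - MOVE_RAMP_S / 8  # R/8 crossing lands exactly at onset
        seg = (t >= start) & (t < ht)
        radial[seg] = R * (t[seg] - start) / MOVE_RAMP_S
        hold = (t >= ht) & (t < ht + HOLD_S)
        radial[hold] = R
        ret = (t >= ht + HOLD_S) & (t < ht + HOLD_S + RETURN_S)
        radial[ret] = R * (1.0 - (t[ret] - ht - HOLD_S) / RETURN_S)
        moving = (t >= start) & (t < ht + HOLD_S + RETURN_S)
        angle[moving] = theta
    # sub-threshold rest jitter (never approaches R/8)
    jitter = sps.savgol_filter(
        rng.standard_normal((2, n_samples)) * R / 200.0,
        window_length=121, polyorder=2, axis=1)
    xy = np.vstack([radial * np.cos(angle), radial * np.sin(angle)])
    xy += jitter * (radial < R / 100.0)
    return xy


def latent_truth(session: RawSession) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (onset_times, directions) of a generated session."""
    if session.truth is None or "onset_times" not in session.truth:
        raise ValueError("session carries no ground-truth metadata")
    return (np.asarray(session.truth["onset_times"]),
            np.asarray(session.truth["directions"]))
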