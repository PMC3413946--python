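# Methods

This note documents the models, the synthetic data the package is tested
against, the numerical choices, and the known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Decoding problem and data model

An 8-target center-out session consists of multichannel ECoG-like signals
at 1200 Hz, synchronized joystick x/y traces, and per-trial events: target
presentation, cursor presentation 1 s later, and (latently) the moment the
subject starts to move. The decoding stack answers two questions from the
brain signal alone — *when* does a movement start (asynchronously, every
100 ms) and *toward which of the eight 45°-spaced targets* — and then asks
what those answers are worth in a simulated targeting task.

## Feature extraction

* **CAR.** The across-channel mean is subtracted per sample; channels
  listed in `exclude_channels` (e.g. occipital contacts, to avoid visual
  contamination) are dropped first.
* **Windows.** 300 ms, advanced by 100 ms (200 ms overlap), left-aligned
  and half-open, time-stamped with the window *end*. This makes each step
  depend only on past samples — the extraction is causal and could run
  online. A 1.2 s record yields exactly 10 steps.
* **Spectra.** Burg autoregressive estimation of order 25 per window and
  channel (Burg is stable on 360-sample windows where covariance methods
  can be fragile); amplitude is the square root of the AR power spectral
  density evaluated at integer frequencies 0–200 Hz. A zero-variance
  window has no AR representation and returns an all-zero amplitude vector
  rather than raising, so streaming extraction survives flat segments.
* **Band features.** Arithmetic means over inclusive integer bins:
  mu 8–12, beta 18–26, high gamma 70–170 Hz. The LMP is the plain
  time-domain mean of the same (CAR-filtered) window. Whether LMP should
  be computed before or after CAR is underdetermined; computing it after
  keeps a single filtered signal path and is stated here as the package's
  convention.
* **Rest normalization** (diagnostics only): spectral features divided by
  their mean over inter-trial rest steps, so 1 means no task modulation
  and 2 means a doubling. The classifiers consume raw band features,
  z-scored on training folds (the direction model's unit-variance noise
  assumption is enforced by standardization, not by this normalization).
* **Forward selection.** Greedy forward search adds, per iteration, the
  feature maximizing mean 5-fold cross-validated score; folds are
  trial-wise to prevent leakage across temporally overlapping windows, and
  ties break to the lower feature index so the order is reproducible. The
  default inner scorer is a fast class-weighted linear SVM on single-step
  features; scoring with the full downstream buffer classifier is
  supported via the `estimator` parameter but is quadratically more
  expensive and not the default. The default feature budget is 20.

## Onset detection

Each trial starts with an empty FIFO buffer; once 10 steps (1 s) have
accumulated, the detector predicts every 100 ms whether the *next* step is
the movement onset. Ground truth: the onset step is the first step at
which the moving-average radial joystick extension strictly exceeds one
eighth of its maximum; steps from the trial start up to the onset are
"not onset"; trials that never cross are excluded.

The classifier is an RBF-kernel SVM whose class penalties are weighted by
the inverse class-size ratio (onsets are one step per trial against
hundreds of rest steps). C and γ come from a small grid search on training
folds maximizing F1; probabilities are Platt-sigmoid calibrated on
training folds; the decision threshold is 0.3. Evaluation is per step:
a prediction at the exact onset step is a TP, a miss there an FN, any
other prediction an FP — with FPs more than 200 ms (2 steps) from every
true onset reported separately, since near misses are operationally far
less harmful. F1 = 2·TP/(2·TP + FP + FN) never sees the true negatives.

Per-feature confidence maps repeat the 5-fold cross-validation 20 times
with random trial-wise refolds, test the 20 F1 values against zero with a
one-sided t-test, and report −log(p) (natural log; p < 0.05 ⇔ index > 3).
A zero-variance all-positive F1 sample cannot be t-tested and is reported
as a flagged +∞ sentinel; an all-zero sample as index 0.

## Direction classification (MTVDBN)

Per direction d, per node m and slice t of the T = 10-step pre-onset
window:

    X^t_m = a^{t−1}_{d,m} · X^{t−1}_{π_m} + a^t_{d,m} · X^t_{π_m} + ε,
    ε ~ N(0, 1),

with parents selected by minimizing (1/N)·Σ residual² + λ·(‖a^{t−1}‖₁ +
‖a^t‖₁) on the LARS path (sklearn's `LassoLars` at α = λ/2 solves exactly
this objective). Design choices where the method is underdetermined:

* **Boundary slice.** t = 1 has no temporal parents (no slice 0 exists in
  the window); its likelihood term uses spatial parents only.
* **Candidates.** Temporal: all M features at t−1; spatial: all other
  M−1 features at t, screened jointly by the penalized problem.
* **Pruning.** ℓ1 screening keeps everything the path touches; a greedy
  add/delete pass per node re-scores candidates with the penalized
  *refit* objective, dropping weak edges whose coefficient pays more
  penalty than the residual it removes.
* **Acyclicity.** Within-slice spatial edges must form a DAG (temporal
  edges cannot create within-slice cycles and are unconstrained). A hill
  climber over edge additions, deletions, and reversals greedily minimizes
  the total penalized residual, rejecting cycle-closing moves; reversal
  moves, plus deterministic single-edge-reversal restarts, resolve the
  orientation conflicts that pure forward addition commits to too early.
  On small instances this reaches the exhaustive restricted-DAG optimum
  (verified in the test suite).
* **Refit.** Final coefficients are refit unpenalized on the surviving
  parent sets (relaxed-lasso practice).
* **Standardization.** Per node and slice on the pooled training trials —
  one scaler shared by all eight direction models, so their likelihoods
  are comparable at test time.
* **λ.** Chosen by trial-wise cross-validated classification accuracy on a
  logarithmic grid shared across directions. `select_lambda` offers a
  one-standard-error rule (favoring the sparsest competitive penalty; it
  drives pure-noise data to the sparse end of the grid), but the pipeline
  selects by plain maximum accuracy: with few folds on modest sessions the
  SE band is wide enough that the one-SE rule prunes genuine coupling.
  λ = 0.3 is the operating point used for structure-recovery experiments.
* **Feature set.** Whether the direction models consume all features or
  the forward-selected subset is configurable; the default is *all*
  features. The forward search selects for onset discriminability
  (movement-locked gamma/LMP on motor channels), which is largely
  orthogonal to the cross-channel coupling structure the direction models
  exploit; restricting the MTVDBN to the onset-selected subset measurably
  starves it.

Classification scores a standardized test window under all eight models
and returns the argmin of the total squared residual; ties break to the
lowest direction index. Angular error between targets i and j is
min(|45·(i−j)|, 360 − |45·(i−j)|).

Complexity (documented, not benchmarked): screening all nodes of one
slice is O(N·(2M−1)³) via LARS; scoring a window at test time is
O(d·T·M²) for d directions.

## Targeting simulation

On each trial the cursor is pre-placed at α·R along the predicted
direction (α ∈ [0, 1]); the remaining movement is simulated as a straight
line at the session's average speed (mean over trials of R / movement
duration). The law of cosines gives the assisted distance
d = R·√(1 + α² − 2α·cos θ) at angular error θ, hence:

* error < 60°: improvement for *every* α ∈ (0, 1];
* error > 60°: degradation exactly where α ≥ 2·cos θ — always at α = 1;
  for 60° < θ < 90° small α can still help, which is why the optimal α is
  a data-dependent quantity worth optimizing;
* error exactly 60° at α = 1 lands exactly at distance R and counts as no
  improvement.

The two-circle lens (radius R, centers R apart) covers
(2π/3 − √3/2)/π ≈ 39.1% of the circle; random repositioning therefore
lands farther from the target with probability ≈ 61%. Chance-level
angular statistics for 8 targets, computed exactly over the discrete error
distribution {0°, 45°, 90°, 135°, 180°} with weights {1,2,2,2,1}/8, are
mean 90.0° and sd √3037.5 ≈ 55.11°. (A continuous-uniform error would
give sd ≈ 51.96°; the package reports the exact discrete value.)

α is optimized on a 0–1 grid in steps of 0.05 (ties to the smaller α);
the α = 0 grid point reproduces the unassisted baseline exactly. In the
paired comparison, ties count as "degraded" (no improvement), and the
p-value is a one-sided paired t-test.

## Synthetic sessions: what they emulate, and what they do not

The generator realizes, by construction, the assumptions the decoders
make, so parameter recovery is a well-posed test:

* **Latent feature process.** Per direction, a sparse linear-Gaussian
  transition/coupling coefficient set (1 temporal parent per node,
  spatial parents on ~half the nodes along a direction-specific
  topological order, coefficients ±0.4–0.7 scaled by
  `direction_coupling_strength`) generates the 10-step pre-onset feature
  windows — exactly the MTVDBN's generative form. `sample_direction_windows`
  exposes this core directly; `generate_session` embeds the same windows
  into the raw signal.
* **Raw signal.** Per channel: broadband pink noise (`noise_sd`) plus
  band-passed noise carriers for mu/beta/gamma, amplitude-modulated by
  envelopes `base·(1 + 0.5·z)` of the latent features, plus a slow LMP
  offset. Motor channels (the first half) add a movement-locked response
  from onset for 600 ms: gamma × (1 + `gamma_gain`), mu/beta ×
  (1 − `mu_beta_suppression`), LMP + `lmp_shift`. Defaults (gain 1.0 =
  doubling, suppression 0.5, shift 1.0) are typical magnitudes for motor
  cortex during movement.
* **Behaviour.** Onset latency after cursor presentation is truncated
  normal (mean 0.5 s, sd 0.15 s, floor 0.2 s — a stand-in, since no
  latency distribution is specified for the paradigm); the joystick ramps
  to full extension over 0.8 s, timed so the raw radial extension crosses
  R/8 exactly at the latent onset; inter-trial interval 1 s.

**What passing tests do and do not show.** The raw round trip cannot
preserve the slice-wise linear model exactly: each 300 ms analysis window
averages three 100 ms envelope steps, so extracted features are a smoothed
mixture of adjacent latent slices, and the per-window AR amplitude of a
narrow band carries few degrees of freedom (mu: ~4 Hz × 0.3 s ≈ 1), so
mu/beta envelopes track latent features only loosely while gamma (~30
degrees of freedom) and LMP track well. Structure recovery is therefore
evaluated on the generator's feature-level output, and the raw path is
held to the weaker — and practically relevant — standards of envelope
tracking and above-chance end-to-end decoding. None of this says anything
about volume conduction, electrode geometry, artifacts, line noise, or
non-stationarities of real recordings, which the generator does not model.

## Problem sizes and defaults

The packaged experiments use deliberately modest sizes chosen to exercise
every stage: sessions of 24–120 trials on 3–6 channels for end-to-end
runs, 200 windows per direction for structure recovery, and a λ grid of
3–7 points. Real sessions in this paradigm are larger (hundreds of trials,
60–120 channels); all sizes are configuration, not code.

## Known limitations

* Per-step onset scoring counts near misses (±100–200 ms) as errors;
  F1 values are therefore conservative relative to event-tolerant scoring.
* The hill climber is greedy; optimality is verified only on small
  instances, and large slices may end in good local optima.
* The targeting simulation models straight-line motion at constant speed
  and ignores the user's reaction to cursor jumps.
* λ selected once on the evaluation set's training portion is shared
  across folds in the pipeline report (a small optimism; per-fold
  selection is available through the estimator API).
* The empty-model fallback for directions with fewer than two training
  trials keeps cross-validation defined but predicts those directions
  poorly; supply enough trials per direction for serious use.
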