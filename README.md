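# ecogdecode

Decoding *when* and *where* a person intends to move from
electrocorticographic (ECoG) signals, and simulating what that buys in a
targeting task.

The package implements the full offline decoding stack for an 8-target
center-out joystick task, driven end-to-end by a synthetic session
generator so that every stage is testable without patient data:

1. **Feature extraction** — common average reference (CAR), then for every
   300 ms window advanced by 100 ms per channel: a Burg autoregressive
   (order 25) amplitude spectrum on a 0–200 Hz / 1 Hz grid, averaged into
   mu (8–12 Hz), beta (18–26 Hz) and high-gamma (70–170 Hz) band features,
   plus the local motor potential (LMP, the raw time-domain window mean) —
   four features per channel per 100 ms step.
2. **Movement-onset detection** — a FIFO buffer of 1 s (10 steps) of
   features feeds a class-weighted RBF-kernel SVM (penalty ratio = inverse
   class-size ratio, Platt-calibrated probabilities); steps with
   probability above 0.3 are predicted onsets, scored per step with the
   F1 score, F1 = 2·TP / (2·TP + FP + FN), which ignores the overwhelming
   true-negative count.
3. **Direction classification** — one *modified time-varying dynamic
   Bayesian network* (MTVDBN) per direction on the 1 s pre-onset window
   (T = 10 slices, M features): per node m and slice t a linear-Gaussian
   model X^t_m = a^{t−1}_m·X^{t−1}_{π_m} + a^t_m·X^t_{π_m} + ε with
   temporal *and* within-slice (spatial) parents, selected by ℓ1-penalized
   least squares, min (1/N)Σ r² + λ(‖a^{t−1}‖₁ + ‖a^t‖₁), solved on the
   LARS path; a hill-climbing pass repairs within-slice acyclicity. A test
   window is assigned the direction d* = argmin_d Σ_t Σ_m residual², i.e.
   maximum likelihood over the eight networks.
4. **Targeting simulation** — on each decoded trial the cursor is
   pre-placed at a fraction α of the target radius R along the predicted
   direction; movement time to the target is simulated at the session's
   average speed and α is optimized on a grid. The analytic geometry of
   the two radius-R circles (centers R apart) gives a 39% improvement
   lens, a 61% chance that random repositioning hurts, and a ±60°
   angular error margin within which repositioning always helps.

## Worked example

```python
from ecogdecode import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(
    sim=SimConfig(n_channels=6, n_trials=120, seed=1),
    n_selected_features=12,
    lambda_grid=(0.1, 0.3, 1.0),
    seed=1,
)
report = run_pipeline(config)
stages = report["stages"]
print("onset F1:          ", round(stages["onset"]["f1"], 3))
print("direction accuracy:", round(stages["direction"]["accuracy"], 3),
      "(chance 0.125)")
print("mean angular error:",
      round(stages["direction"]["angular_error_mean"], 1),
      "deg (chance 90.0)")
print("optimal alpha:     ", stages["targeting"]["alpha_star"])
print("% trials improved: ", round(stages["targeting"]["pct_improved"], 1))
```

prints (seed 1):

```
onset F1:           0.59
direction accuracy: 0.267 (chance 0.125)
mean angular error: 69.8 deg (chance 90.0)
optimal alpha:      0.5
% trials improved:  52.5
```

The onset F1 of ~0.6 is per-step scoring at the exact 100 ms onset step —
near misses count as false positives (FPs within 200 ms of a true onset
are reported separately). Direction accuracy of ~27% against the 12.5%
chance level, and a mean angular error well below the 90° chance mean,
shows the pre-movement windows carry direction information through the
full raw-signal round trip; repositioning the cursor at the optimal
α = 0.5 then shortens simulated movement times in the majority of trials
(paired one-sided p ≈ 0.03 on this session).

A command-line interface mirrors the library
(`ecogdecode simulate / features / train-onset / detect-onset /
train-direction / classify-direction / simulate-targeting / run-all`).

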