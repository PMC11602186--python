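# Methods

This note documents the models, the tunable parameters, the synthetic-data
generator's scope, and the numerical choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task timing model

Stimuli of each modality form a renewal process with

    ISI = min(cap, Exp(exp_mean) + U(offset_lo, offset_hi)),

quantized to the nearest multiple of `bin`. Defaults: `exp_mean` 10 s,
offset 8–12 s, cap 55 s, bin 1 s, giving a nominal mean of 20 s (the cap
shaves ≈ 0.1 s: E[(X−55)⁺] ≈ 10·exp(−(55−offset)/10) averaged over the
offset). The two modality streams are drawn independently and may overlap;
only the conditioned modality is rewarded, at stimulus offset.

Numerical choices: quantization rounds to nearest (not floor) so the mean
is preserved; the cap is applied before quantization; the first event of a
stream sits one ISI after session start, which keeps the process stationary.
A `shaping` flag generates the trial-based variant (uniform 8–12 s gaps,
random modality per trial) used to model early training.

The hazard estimator is the discrete life-table form,
`h(t) = #ISIs∈[t,t+bin) / #ISIs≥t`, with flatness audited by an ordinary
linear fit over elapsed time 12–45 s (the analytic hazard of a shifted
exponential is constant beyond the offset's upper bound; the estimator's
variance grows with t as the at-risk count falls, which the unweighted fit
tolerates at the 10⁵-draw scale the tests use).

## Synthetic sessions: what is emulated

`generate_session` produces a schedule, behavior signals, and spike trains
that are *conditioned on the realized behavior* — the same causal direction
the movement regression assumes, which makes coefficient recovery
well-posed.

Per-cell rate model (spikes/s, rectified at zero, realized by Poisson
thinning on a 1-ms grid):

    r(t) = baseline
         + onset_amp   · 1[onset+lat ≤ t < onset+lat+0.1]      (per modality)
         + sustained_amp · 1[onset+lat ≤ t < onset+2]          (per modality)
         + offset_amp  · 1[offset ≤ t < offset+2]              (rewarded events)
         + β_whisk · whisk_amp(t) + β_pupil · (pupil(t) − setpoint)
         + β_lick · lick_rate(t)

Default parameter ranges (chosen once as plausible for awake secondary
thalamus, and fixed): baselines 6–18 (POm) / 3–12 (LP) spikes/s; each
modality responsive with probability 0.5; sustained kernels 4–12 spikes/s
(10% of responsive kernels are instead suppressions of 3–6 spikes/s); half
of the responsive cells also carry a 100-ms onset step of 18–30 spikes/s
with a true latency of 10–100 ms (1-ms grid); 40% of cells get an
offset/consumption kernel of 4–12 spikes/s; 70% of cells are
movement-coupled with β_whisk 0.1–0.4 /deg, β_pupil 0.1–0.5 /px, β_lick
0.2–0.8 /(licks/s).

Behavior signals:

* **Pupil** (60 fps, pixels): OU process, τ = 2 s, sd 2 px around a 20-px
  set point, plus a constriction kernel on every visual stimulus (the
  luminance reflex, −1.5 px, fast alpha) and a dilation kernel (arousal,
  +2.5 px, alpha peaking at 1.5 s) on the conditioned stimulus (+1 px on
  the air puff when it is the distractor — it stays salient).
* **Whisker angle** (125 fps, degrees): an 8-Hz carrier whose peak-to-trough
  envelope is a rectified OU process (mean 10, sd 5 deg, τ = 1 s) plus
  evoked increments (6 deg per air puff, 3 deg per conditioned grating).
  The envelope is the ground-truth whisking amplitude. Spontaneous
  variability deliberately dominates the evoked increments, the regime in
  which movement regression leaves direct stimulus responses largely
  intact (see *Limitations*).
* **Licks**: inhomogeneous point process — 0.3 licks/s baseline, a linear
  anticipatory ramp to 3.5 licks/s from 0.3 s after the conditioned onset
  to the offset, and a 7 licks/s consumption burst for 2 s after reward.
  The consumption rate is a free parameter (lick-bout microstructure is
  not otherwise constrained). The lick-rate signal cells couple to is
  defined as the piecewise-constant rate on 250-ms bins aligned to session
  start — exactly the quantity the regression stage reconstructs, so β_lick
  is an estimable parameter rather than the coefficient of an unobservable
  smoother.

Anatomy: positions are uniform in axis-aligned boxes per region sharing the
DV = 2800 µm boundary plane, so the 50-µm boundary-exclusion rule and the
selectivity-vs-ML-position model are exercisable. An `si_gradient` option
adds a linear ML dependence to the tactile kernel amplitude in visually
conditioned sessions.

Ground truth stores the config, seed, and all per-cell parameters;
regeneration is bit-exact. The stored true selectivity index includes the
movement-mediated pathway (β · expected event-triggered signal excursion
over the 1-s stimulus window, computed from the same kernel templates the
generator uses): a cell's true expected response is the sum of both
pathways, and sign-recovery is only well-posed against that total.

What the generator does **not** emulate: spike-sorting artifacts, bursting
and refractory structure (trains are inhomogeneous Poisson), slow
representational drift, lick-bout microstructure, video pixel data (only a
binary-mask generator exists, for the pupil-radius estimator), and any
correlation between cells beyond shared behavior. Passing recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated model, not robustness to real-data pathologies.

## Analysis-stage choices

* **Lick index**: the 50-ms onset exclusion applies to the stimulus-window
  count only (it exists to drop reaction-impossible licks). A 0/0 trial is
  undefined and excluded from means and tests, not set to zero. First-lick
  latency is measured from stimulus onset, taking the first lick after
  reward availability (stimulus offset).
* **Training criteria**: shaping requires the CS+ session mean LI
  significantly greater than zero (one-sided signed rank, realized as the
  halved two-sided p with a positive mean) and ≥ 3 sessions; the full-task
  criterion requires the distractor LI not significantly different from
  zero (two-sided) for ≥ 4 sessions. The one-sided/two-sided asymmetry is
  deliberate and matches the criteria as stated.
* **Pupil**: radius is √(a·b) from the mask's second-order moments
  (scikit-image `regionprops`, the same estimator family as the original
  MATLAB `regionprops`). Blink detection flags |raw − 3-s running median|
  > 5·MAD of that residual; because a running median tracks a smooth
  noise-free trace exactly (degenerate MAD), the scale is floored at 1% of
  the median radius — sub-percent deviations are never blinks. Repair is
  linear interpolation, then a 5-frame moving average.
* **Whisking amplitude**: zero-phase Butterworth band-pass (order 2 per
  pass, 4–30 Hz), Hilbert phase, envelopes from the *unfiltered* angle at
  the nearest sample to each phase-0 / ±π crossing, linearly interpolated
  between whisk cycles. Spans more than 0.5 s from any crossing are flagged
  and their amplitude decayed exponentially toward zero (no whisking ⇒ no
  amplitude), rather than held indefinitely.
* **Latency detector**: the baseline mean and SD are taken over the 2 s
  before onset in 10-ms bins (a 1-s variant is a config switch, since both
  windows appear in common practice); crossings count in both directions
  for both rules, and the reported latency is the left edge of the first
  crossing bin. A silent baseline (SD = 0) is floored at the Poisson
  sampling SD of the bin estimator, √(μ̂/(n_events·bin)), with μ̂ at least
  one expected spike over the whole baseline; the result is flagged.
* **Classification**: baselines from both modalities are pooled into one
  ANOVA group (three groups total); the overlap exclusion is symmetric
  (±6 s around a different-modality onset); Holm families are the region's
  cell set (conditioning is constant within a session); the post-hoc test
  is the paired Wilcoxon signed-rank on per-event (stimulus, baseline)
  counts — "paired" being the operative property — with zero-differences
  split. Cells with fewer than 5 usable events per modality are flagged
  insufficient rather than tested.
* **Movement regression**: fit over *all* session bins (spontaneous epochs
  are what identify the coupling; a per-trial fit would not), ordinary
  least-squares point estimates with HC1 heteroscedasticity-robust
  standard errors — binned count-derived rates have variance growing with
  the rate, which plain OLS SEs understate for the highly skewed lick
  predictor. The "baseline rate" predictor is the model intercept. The
  reward indicator spans 2 s from delivery, the same window as the offset
  period. Bin-size variants (50/100/500 ms) are config options.
* **Cross-correlation**: Pearson correlation of mean-subtracted series at
  integer-bin shifts; `r(ℓ) = corr(rate(t+ℓ), signal(t))`, so a peak at a
  negative lag means the rate precedes the signal.
* **Spontaneous rate**: maximal spans free of stimulus windows, licks, and
  2-s reward windows; the first 2 s of each span is dropped and the
  remainder must be ≥ 6 s. Spans are clipped to the session bounds.
* **SI ~ position model**: positions are fit in millimetres (coefficients
  O(1)); undefined SIs are dropped; with a single conditioning level the
  interaction terms are dropped with a warning.
* **I/O**: plain CSV + JSON, seconds as decimals, fixed formatting
  (microsecond precision in bundles, 6 significant digits in outputs), a
  config hash in every output header. All generated times are rounded to
  1 µs at generation so a write→read round trip is exact and a fixed seed
  yields byte-identical files.

## Problem sizes used by the test suite

Unit tests run on 400–2000-s sessions with 4–12 cells. The acceptance-level
recovery property uses 50 sessions of 2000 s and 30 cells (≈ 100
presentations per modality, the scale of a real recording); error
calibration uses 100 replicate 200-cell null families (simulated at the
per-event-count level through the same per-cell statistics and Holm
correction the pipeline applies — Poisson counts are the sufficient
statistics of a homogeneous null cell) plus two full 100-cell null sessions
for the regression tuning flags. Empirical error-rate checks are asserted
with binomial sampling slack (three standard errors of the replicate
count): a bound at the nominal α cannot be asserted exactly from finitely
many replicates.

## Known limitations

* Movement coefficients of cells with sharp stimulus transients are not an
  identified estimand of the regression: the three boxcar indicator
  columns do not span onset-transient structure, and the unabsorbed
  remainder anti-correlates with the within-trial rise of pupil and
  whisking, biasing those coefficients (≈ 1 SE at the default kernel
  sizes). This is a property of the movement-correction method itself, not
  of the simulator; recovery guarantees are therefore stated for cells the
  model nests.
* The selectivity-index sign is noise-limited for cells whose total
  absolute response is a few spikes/s: SI is a ratio and carries no
  magnitude information, so sign recovery is only guaranteed for cells
  with direct kernels (≥ 4 spikes/s here).
* The latency detector quantizes to 10-ms bins; a true latency just after
  a bin edge is reported at the next edge (≤ one bin of error), and the
  detector is only as good as the baseline-SD estimate for very low rates.
* Whisking amplitude is estimated once per whisk cycle; envelope dynamics
  faster than the ~8 Hz carrier are not resolvable.
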