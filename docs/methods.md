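# Methods

## Scope

`ebcscore` implements the trial-level scoring procedure for long-delay
eyeblink conditioning (long-dEBC) EMG — envelope standardization, CR
detection with threshold and duration gating, latency-window metrics —
plus session-level aggregation, the repeated-measures statistics, and a
synthetic cohort generator that emulates the four-group study design.
It does not model surgery, optogenetic light physics, spike or LFP
analysis, or histology.

## Trial design

Time is measured in ms from CS onset (t = 0) everywhere.  A paired trial
presents a 3350-ms tone CS and a 50-ms US starting at 3300 ms,
co-terminating with the CS (enforced as an invariant).  A daily session
is 12 blocks × 10 trials, 9 paired + 1 CS-alone per block; the CS-alone
position within each block is uniform-random (placement is not otherwise
constrained in standard practice, and randomizing avoids a positional
confound).  ITIs are continuous-uniform on [25, 40] s.  Block
composition is exact for every seed; schedules are bit-reproducible
given a seed.

## Preprocessing

Raw traces (default 10 kHz, spanning −300 to +3400 ms) are full-wave
rectified and integrated with a 1-ms time constant.  "Time constant" is
read as first-order leaky integration: `y[i] = a·y[i−1] + (1−a)·x[i]`,
`a = exp(−Δt/τ)`, unit DC gain, initialized at the first sample so no
artificial ramp enters the baseline window.  A 1-ms causal boxcar is
available as a config alternative (`integrator="boxcar"`).

Standardization z-scores the envelope against the trial's own baseline,
the half-open window [−300, 0) ms — the CS-onset sample itself is
excluded.  The sample SD uses the n−1 denominator.  Because the trial
threshold (baseline mean + 4 baseline SD of the standardized envelope)
is computed on the same window that defined the z-score, it equals the
multiplier, 4.0, exactly (asserted to 1e−9 relative tolerance).  A flat
baseline (zero SD) raises a degenerate-trial error; the pipeline marks
the trial invalid instead of crashing.

The chain is scale-invariant (scaling raw samples by any a > 0 leaves z
and all detections unchanged) and translation-equivariant in time.

## Detection and classification

Epochs are maximal runs of samples with z **strictly** above threshold
whose duration (run length × sample period) is **strictly** greater than
10 ms — at 10 kHz a run must span at least 101 samples, so a 10.0-ms run
never counts and a 10.1-ms run does.  Strictness in sample space avoids
float round-off at the boundary.

* Baseline epoch (onset in [−300, 0)) ⇒ hyperactivity trial: invalid,
  no CR evaluation, contributes to no downstream metric.
* CR epoch: onset in the valid period 121–3292 ms.  Window membership is
  decided by the **onset**; the printed integer bounds
  (121–1180 / 1181–2240 / 2241–3292) are evaluated half-open at internal
  boundaries (short [121, 1181), middle [1181, 2241), long [2241, 3292])
  so that every onset on the 0.1-ms sample grid belongs to exactly one
  window and the three windows tile the valid period.  A trial with
  epochs starting in several windows counts as a CR trial in each.

Per flagged window: start latency = onset of the earliest epoch in the
window; peak amplitude = maximum z over the union of that window's
epochs, never beyond 3292 ms; peak latency = time of that maximum, ties
broken to the earliest sample.  Restricting the peak to detected epochs
avoids crediting sub-threshold noise; taking the maximum over the whole
121–3292 ms span instead is available via `peak_scope="valid_period"`.
On paired trials nothing after 3292 ms is analyzed (the valid window
ends 8 ms before US onset), so UR artifacts need no blanking.

## Session metrics

CR%[w] = 100 × (valid trials with a CR in w) / (valid trials);
amplitude/latency means are over CR trials only.  The default scope
restricts denominators to paired trials (CS-alone trials are analyzed
separately); `all_trials` is available.  With zero valid trials the
summary is flagged undefined — CR% is missing, never 0 — and missing
conditional means are stored as absent rows in the long cohort table;
nothing is imputed.  Trial accounting is conserved:
total = valid + hyperactive + degenerate.

## Statistics

The mixed RM-ANOVA uses the classical decomposition for one
between-subjects factor (group) and one within-subjects factor
(session): the group effect is tested against subjects-within-groups,
session and group × session against the session × subjects residual.
With a single between factor the Type I/II/III hypotheses coincide, so
the weighted cell-means decomposition also covers the unbalanced group
sizes (13/10/12/16) of the emulated design.  Subjects missing any
session are dropped (complete-case) and their IDs logged.  No sphericity
correction is applied by default; a Greenhouse–Geisser adjustment of the
within-effect p values (pooled within-group covariance) is available via
`gg_correction=True`.  Zero-error degenerate cases are reported as
flagged rows (F = 0, p = 1 when the effect SS is also zero), not
exceptions.

LSD post hoc t tests use the omnibus error terms: group pairs use the
subjects-within-groups MS rescaled to the subject-mean scale with
df = N − G; session pairs use the within residual MS with its df.
Two-sided p, no multiplicity correction (that is what LSD means).
α defaults to 0.05.

## Synthetic cohort

The generator emulates what the analysis assumes about real data, not
blink biophysics:

* **Carrier noise** — Gaussian white noise band-passed to 100–1000 Hz
  (4th-order Butterworth, matching the acquisition band), scaled so the
  raw SD equals `sigma`.  The rectified-integrated envelope's baseline
  mean/SD at sigma = 1 are calibrated once by Monte Carlo (5 s of noise,
  fixed internal seed) and scale linearly with sigma.
* **Bursts** are injected at the envelope level: the burst waveform adds
  to the rectified carrier, which is then re-signed, so full-wave
  rectification recovers |carrier| + burst exactly.  Amplitudes are
  specified in baseline-envelope-SD units and therefore standardize to
  approximately the same number of z units.  The kernel is unimodal with
  a fast rise and slower decay (peak at 20% of the duration).
* **CRs** — at most one per trial.  Its latency window is drawn
  categorically from per-window logistic acquisition curves
  p(s) = p_max/(1 + exp(−k(s − s₀))) (so per-window asymptotes must sum
  to ≤ 1); given the window, the peak latency is Gaussian and the onset
  is clamped inside the window, 60 ms clear of its upper edge so the
  threshold crossing cannot leak into the next window.  Amplitude is
  lognormal, default log-mean ln 10, log-SD 0.25 (baseline SDs);
  duration 250 ms.  Ground truth records the onset, amplitude, peak
  time, and the predicted detection start — the first grid time at which
  the integrated burst waveform reaches 4 baseline SDs — which is what
  "start latency" estimates.
* **UR** — on paired trials, a 120-ms burst at 25 SD starting 8 ms after
  US onset; entirely outside the valid CR period.
* **Spontaneous blinks** — Poisson at 0.02 Hz with mostly small
  (sub-threshold) lognormal amplitudes (log-mean ln 2.5, log-SD 0.6);
  ~1 trial in 100 gains a detectable spurious in-window event, mirroring
  a preparation in which spontaneous-blink contamination is rare.
* **Hyperactive trials** (probability 0.02) — a brief (13 ms) square
  envelope burst at 100 baseline SDs placed inside the baseline window.
  The brevity is forced by the self-referential baseline z-scoring: a
  burst occupying fraction q of the 300-ms baseline inflates its own
  baseline SD and can reach at most z ≈ √((1−q)/q), so only bursts
  shorter than ~18 ms can cross the 4-SD threshold for more than 10 ms.
  The chosen 13 ms / 100 SD event crosses at z ≈ 4.7 for ≈ 11 ms,
  hyperactive by construction.

Default group parameter sets (saline, PCP, PCP-eNpHR, PCP-EYFP) are
**illustrative, not fitted**: no numeric learning curves are published
for this design, so the defaults encode only the qualitative orderings —
saline above PCP in every window, partial rescue of PCP-eNpHR over
PCP-EYFP, and earlier late-window peak latencies under PCP (3000 vs
2750 ms means).  Asymptotes (late window): 0.55 / 0.16 / 0.42 / 0.18.

A summary-level simulator (`simulate_summary_cohort`) draws
subject × session CR% directly from the learning curves (binomial over
108 paired trials plus a Gaussian subject offset, SD 0.05 on the
probability scale); it is used where trace-level simulation would be
wasteful (calibration and power studies).

What the generator does **not** emulate: motor-unit spike structure,
electrode drift, within-session fatigue or block-level learning, CR
topography changes with learning, and correlated multi-burst blinks.
Passing tests therefore show that the scoring rules are implemented
correctly and recover this generative structure — not that the defaults
quantitatively match any real cohort.

## Problem sizes and numerical choices

* Test-suite simulations use scaled-down cohorts (typically 1–6 subjects,
  1–6 sessions, full 120-trial sessions) and ≥ 500 trials per detection
  operating-characteristic condition; oracle-equivalence checks use
  1,000 random traces and seeded small ANOVA designs (1e−8 agreement).
* Type-I calibration of the group F test uses 1,000 null replicates of
  the study-sized design; power checks use 100 summary-level replicates.
* Time comparisons on the sample grid use a 1e−6 ms tolerance; the
  threshold identity is asserted at 1e−9; ANOVA sums of squares guard
  against tiny negative cancellation residues.
* Dataset files: JSON manifest + NumPy `.npz` traces, format-versioned;
  round trips are lossless and bit-identical for float samples.  All
  randomness in a run flows from one top-level seed recorded in the
  outputs together with a config hash.

## Known limitations

* The detector's sensitivity transitions steeply with burst amplitude
  (≈ 50% at 6 baseline SDs for raw-additive bursts vs ≥ 95% for
  envelope-level bursts of the same nominal amplitude); conclusions
  about marginal-amplitude CRs depend on the burst model.
* The weighted within-factor decomposition matches common statistical
  software for this one-between/one-within design but is not a general
  Type III engine for multiple between factors.
* CS-alone trials are scored with identical rules; the default CR%
  denominators follow the paired-trials convention.
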