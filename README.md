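# ebcscore

Trial-level EMG scoring and group statistics for **long-delay eyeblink
conditioning** (long-dEBC), with a synthetic cohort generator so the whole
analysis runs end-to-end without recorded data.

In long-dEBC a 3350-ms tone (CS) predicts a 50-ms periorbital shock (US)
that starts 3300 ms after tone onset and co-terminates with it.  Learning
is read out from orbicularis-oculi (O.O.) EMG: a conditioned response
(CR) is an anticipatory blink between tone onset and shock.  The package
is for behavioral neurophysiologists who need the standard trial scoring
rules as tested, reusable code: detecting CRs, excluding artifact trials,
splitting responses into latency windows, and running the
repeated-measures group statistics.

## The scoring procedure

For each trial the raw EMG (10 kHz) is full-wave rectified, integrated
with a 1-ms time constant, and standardized against the trial's own
0–300 ms pre-CS baseline:

    z(t) = (env(t) − μ_baseline) / σ_baseline

The **trial threshold** is μ + 4σ of the standardized baseline — exactly
4 z by construction.  An **epoch** is a maximal run of samples with
z strictly above threshold lasting strictly more than 10 ms.

* a baseline epoch ⇒ **hyperactivity trial**, excluded from everything;
* an epoch with onset in the **valid CR period 121–3292 ms** ⇒ CR, assigned
  to the short (121–1180 ms), middle (1181–2240 ms) or late (2241–3292 ms)
  latency window by its onset (onsets < 121 ms are reflexive alpha blinks
  and never count);
* per subject × session × window: **CR%** = 100 × CR trials / valid trials
  (paired trials only by default), plus CR peak amplitude (z), start
  latency and peak latency (ms) averaged over CR trials only.

Session-level measures feed a two-way mixed repeated-measures ANOVA
(group × session), one-way RM-ANOVAs, and LSD post hoc pairwise tests at
α = 0.05.

The synthetic cohort emulates the four-group study design (saline, PCP,
PCP-eNpHR, PCP-EYFP; 13/10/12/16 subjects × 7 daily sessions × 120 trials)
with logistic acquisition curves, band-limited carrier noise,
unconditioned responses, spontaneous blinks and hyperactive-baseline
trials — every injected event carries ground-truth labels.

## Worked example

```python
from ebcscore import run_pipeline
from ebcscore.config import default_config

cfg = default_config()
cfg["design"].update(n_sessions=3)
cfg["cohort"]["group_sizes"] = {"saline": 3, "PCP": 3}
bundle = run_pipeline(cfg, seed=42)

t = bundle["cohort_table"]
print(t[(t.measure == "cr_percent") & (t.window == "long")]
      .groupby(["group", "session"])["value"].mean().round(1))
```

```
group   session
PCP     1           0.6
        2           2.5
        3           4.5
saline  1           2.5
        2           9.7
        3          23.1
```

Late-window CR% grows across sessions in the saline group but barely
moves under PCP — the acquisition deficit the design encodes.  The
bundled ANOVA confirms it:

```
                effect  df       F      p
                 group   1 94.0230 0.0006
               session   2 56.3101 0.0000
       group_x_session   2 26.9504 0.0003

level_i level_j  mean_diff       t  df      p
    PCP  saline    -9.2382 -9.6965   4 0.0006
```

(group F tested against subjects-within-groups; session and interaction
against the within residual; the LSD row is the saline−PCP contrast on
subject means, here −9.2 percentage points of CR%.)

The same pipeline is scriptable from the shell:

```bash
ebcscore run --seed 42 --out results/ --subjects-per-group 3 --sessions 3
ebcscore simulate --seed 1 --out data/         # dataset: manifest + traces
ebcscore summarize --data data/ --out tables/  # score + aggregate
ebcscore stats --table tables/cohort_table.csv --out stats/
```

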