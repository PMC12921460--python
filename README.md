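# isopupil

Analysis pipeline for **iso-luminant VR pupillometry**: separating the
fast, luminance-driven **pupillary light reflex (PLR)** from the slow,
cognition-driven **task-evoked pupillary response (TEPR)** in eye-tracking
recordings from virtual-reality headsets.

Pupil diameter indexes cognitive load, but in VR the light reflex —
a brainstem loop that constricts the pupil within hundreds of
milliseconds of any luminance change — swamps the much smaller task-evoked
dilation mediated by the locus coeruleus–norepinephrine system. The
iso-luminant protocol removes the confound at the source: a 60 s
dark/bright alternation first characterizes each participant's reflex,
then luminance is clamped to a constant mid-gray while auditory tasks
alternate low and high working-memory load in an ABBA block design. Any
pupil change during the clamped phase cannot be reflex-driven.

The pipeline:

* builds and labels the three-phase protocol timeline;
* cleans ~90 Hz binocular traces — zero-value and ±10 mm/s velocity
  artifact rules, 50 ms mask dilation, linear interpolation, 15 %
  data-loss exclusion;
* filters through two pathways (zero-phase Butterworth: 4 Hz for the
  reflex, 0.5 Hz for the cognitive trend);
* extracts per-session metrics — PLR amplitude
  (dark mean − bright mean), constriction %, peak constriction velocity;
  cognitive difference (high mean − low mean), % change, peak dilation
  velocity — and the dissociation statistic

  ```
  velocity ratio = peak constriction velocity / peak dilation velocity
  ```

  which is well above 1 when constriction is reflex-fast and dilation is
  effort-slow;
* computes cohort statistics (one-sample t and Cohen's d for amplitude
  and difference vs 0; Wilcoxon signed-rank z for the ratio vs 1);
* and simulates ground-truthed synthetic sessions (first-order reflex
  dynamics, saturating task-evoked ramps, hippus, sensor noise, blinks)
  so every stage is testable without data collection.

See `docs/methods.md` for the model, parameter defaults and numerical
choices.

## Worked example

Simulate three sessions, analyze one, then summarize the cohort:

```sh
$ isopupil simulate --n 3 --seed 7 --out-dir demo
wrote 3 sessions to demo
$ isopupil analyze demo/sim_000.csv
wrote demo/sim_000.metrics.json
```

`sim_000.metrics.json` (abridged):

```json
{
  "plr": {
    "dark_mean_mm": 6.12, "bright_mean_mm": 4.63,
    "amplitude_mm": 1.496, "constriction_pct": 24.4,
    "peak_constriction_velocity_mm_s": 5.74
  },
  "cognitive": {
    "low_mean_mm": 5.37, "high_mean_mm": 5.90,
    "difference_mm": 0.526, "percent_change": 9.80,
    "peak_dilation_velocity_mm_s": 0.335
  },
  "velocity_ratio": 17.2,
  "data_loss_fraction": 0.040,
  "excluded": false
}
```

Reading: under bright light this simulated pupil constricted 1.50 mm from
a 6.12 mm dark baseline (24 %), at up to 5.7 mm/s; under high cognitive
load it dilated 0.53 mm (9.8 %) at only 0.33 mm/s. Constriction was ~17×
faster than dilation — the temporal dissociation the paradigm is designed
to expose. Four percent of samples were blink/velocity artifacts, below
the 15 % exclusion limit.

```sh
$ for f in demo/sim_00*.csv; do isopupil analyze $f; done
$ isopupil cohort demo --out demo/cohort.csv
                 metric       mean_sd       range test_statistic        p  effect_size_d
       plr_amplitude_mm   1.50 (0.23)   1.27-1.72     t(2)=11.36 0.007665       6.556622
cognitive_difference_mm   0.33 (0.18)   0.17-0.53      t(2)=3.14 0.088025       1.815067
         velocity_ratio 42.63 (40.45) 17.16-89.27         Z=1.60 0.054405            NaN
n=3 usable sessions (0 excluded); wrote demo/cohort.csv
```

The same workflow is available as library calls
(`simulate_cohort`, `analyze_session`, `cohort_summary`); `isopupil
timeline` prints and validates the protocol schedule.

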