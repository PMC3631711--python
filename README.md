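# sonoreach

Kinematic and performance analysis of hand-pointing movements toward
**virtual auditory targets**, for researchers studying auditory-motor
control with motion capture.

In the emulated paradigm, blindfolded subjects point on a table toward
spatialized sound sources at azimuths −35°, −20°, 0°, +20° and +35° (60 cm
away) under four feedback conditions: a short (250 ms) target sound (**A**),
a long (2000 ms) target sound (**B**), a short sound plus a continuous
*auditory avatar* of the hand (**C**), and the same avatar rendered 18.5° to
the **left** of the real hand — the *conflicting avatar* (**D**).  Hand
endpoint and head pose are sampled at 100 Hz.

The package provides:

* **Trial/session data model** with plain-text formats (CSV trials with
  `key=value` headers, JSON manifests).
* **Kinematics**: zero-phase Gaussian low-pass filtering (−3 dB at 5 Hz),
  tangential speed/acceleration/jerk norms (v3D, a3D, j3D) by central
  differences, two-stage movement segmentation — a coarse horizontal
  displacement window followed by onset/offset at **3% of peak speed**
  walking outward from the peak-velocity point (PVP) — and scalar features
  (duration, peak/mean speed, path length, acceleration peaks split at the
  PVP).
* **Heading analysis**: head yaw extracted from quaternions (0° forward,
  positive right), range of motion (ROM), final heading, and the relative
  position of the head's peak velocity inside the hand movement.
* **Pointing geometry**: protractor-convention azimuths
  (`atan2(x, y)`, degrees), signed error = pointed − target (negative =
  left of target), and the avatar/conflict transform.
* **Synthetic generator**: minimum-jerk reaches
  (`x(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)`, peak speed `1.875·D/T`) with
  overshoot gain and constant bias on the pointed azimuth, out-and-back
  corrective submovements concentrated in the deceleration phase, leading
  head-orienting yaw excursions, and Gaussian marker noise — calibrated so
  the pipeline reproduces study-level condition means.
* **Statistics**: subject-exclusion rules, subject × condition × target
  design tables, two-way repeated-measures ANOVA with Bonferroni post-hoc
  comparisons, tidy CSV/figure reports.

## Worked example

```python
import sonoreach as sr

sessions = sr.generate_cohort(6, seed=42)          # 6 subjects x 128 trials
results  = sr.analyze_cohort(sessions)             # tidy per-trial features
report, retained = sr.apply_exclusions(results)    # subject-level rules

valid = retained[retained["flag"] == ""]
print(valid.groupby("condition")[
    ["abs_error_deg", "head_rom", "n_acc_peaks_total", "path_length"]
].mean().round(2))
```

```
           abs_error_deg  head_rom  n_acc_peaks_total  path_length
condition
A                  26.26      5.30               4.17         0.45
B                  11.10     21.50               4.51         0.45
C                  24.61      7.48               4.14         0.45
D                  24.20      5.49               4.15         0.45
```

Condition B (target audible throughout the movement) shows the signature
pattern: much smaller absolute pointing error, a head that actually orients
toward the target (ROM ≈ 21.5° vs ≈ 5–7°), and slightly more corrective
acceleration peaks.  The repeated-measures ANOVA on the subject-level cell
means gives the factorial summary:

```python
table = sr.build_design_table(retained)
print(sr.rm_anova(table, "abs_error_deg").anova.round(3).to_string(index=False))
```

```
                        source       SS  df1  df2       F   p
                     condition 4284.366    3   15 112.181 0.0
            target_azimuth_deg 7966.161    4   20 113.442 0.0
condition * target_azimuth_deg 2226.541   12   60  10.701 0.0
```

A command-line interface wraps the same functions:

```bash
sonoreach generate --subjects 6 --seed 42 --out data/
sonoreach analyze --session data/S01 --session data/S02 --out results/ --exclusions on
sonoreach report --results results/trials.csv
```

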