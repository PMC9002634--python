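# tendonmetrics

A Python toolkit for assessing in-vivo Achilles tendon (AT) mechanical
properties from synchronized ultrasound and dynamometry, built around the
*time-efficient two-frame method*: instead of digitizing the gastrocnemius
medialis myotendinous junction (MTJ) on every ultrasound frame of a ramp
plantarflexion contraction, only two frames are digitized — one at rest and
one at maximal tendon force.

It is written for biomechanists and sports/clinical scientists who want to

* compute tendon force, rotation-corrected elongation, strain and the
  normalized stiffness index from multi-rate raw recordings,
* validate the two-frame shortcut against conventional frame-by-frame
  tracking, and
* quantify test–retest reliability (ICC, CV, RMS differences, minimum
  number of trials) and between-group sensitivity,

with a fully synthetic data generator providing ground truth for every step,
so the whole chain is testable without human-subject data.

## The measurement model

During an isometric ramp plantarflexion on a dynamometer:

* **Joint moment** from three foot-plate load cells:
  `M(t) = Σᵢ Fᵢ(t)·xᵢ`, with `xᵢ` the signed lever arm of load cell *i*
  about the ankle-axis projection (axis through the inferior tips of the
  malleoli).
* **Tendon force** `F_AT(t) = M(t) / d`, with `d` the AT moment arm
  (perpendicular distance from the ankle axis to the tendon's line of
  action).
* **Rotation correction.** The measured MTJ displacement `Δl_meas` mixes
  true tendon elongation with artefactual excursion from the inevitable
  small ankle rotation. The tendon-excursion method estimates the artefact
  as `d·Δθ` (moment arm × joint-angle change, from sagittal-plane LED
  markers), so `Δl = Δl_meas − d·Δθ`.
* **Strain** `ε = Δl / L₀` (resting length `L₀`: MTJ to calcaneal
  tuberosity), and the **normalized stiffness index**
  `k = (F_AT,max / 1000) / ε_max` in kN per unit strain, evaluated over the
  full 0–100% force range. Normalizing by strain rather than elongation
  removes the dependence on resting length and makes the index comparable
  across subjects and groups.

The three instruments run at different rates (load cells 100 Hz, marker
cameras 15 Hz, ultrasound 30 Hz) with a shared trigger; `tendonmetrics`
aligns them on the force time base before any mechanics is computed.

The statistics module implements the full reliability framework used to
qualify such a method: two-way repeated-measures ANOVA (trial × day),
ICC(A,1) (two-way model, absolute agreement, single measures), per-subject
CV, within/between-day RMS differences, the Spearman–Brown prophecy for the
minimum number of trials at 0.9 target reliability, Pearson + RMS method
agreement, one-way group ANOVA with Bonferroni post-hocs, and a Monte-Carlo
Lilliefors normality test.

## Worked example

```python
import numpy as np
import tendonmetrics as tm

cfg = tm.GeneratorConfig(          # noiseless single trial, known truth
    true_stiffness_index=75.0, max_force_n=4500.0, resting_length_mm=200.0,
    landmark_noise_sd_mm=0, force_noise_sd_n=0, marker_noise_sd_mm=0,
    force_within_subject_rel_sd=0, day_bias_mm_sd=0,
    stiffness_between_subject_sd=0, force_between_subject_sd=0,
    resting_length_between_subject_sd=0, moment_arm_between_subject_sd=0)
rng = np.random.default_rng(1)
subject = tm.draw_subject(cfg, "demo", rng)
record, truth = tm.simulate_trial(cfg, subject, rng)
constants = tm.AnatomicalConstants(subject.moment_arm_mm,
                                   subject.resting_length_mm,
                                   cfg.load_cell_positions_m)
aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
props = tm.two_frame_properties(aligned, constants)
print(props.f_max_n, props.dl_max_mm, props.strain_max_pct,
      props.stiffness_index_kn_per_strain)
```

prints

```
4500.0 12.0 6.0 75.0
```

i.e. a 4500 N maximal tendon force stretching a 200 mm tendon by 12.0 mm
(6.0% strain) gives a stiffness index of 75 kN/strain — the generator's
ground truth, recovered through the complete measurement chain (the ~2 mm
rotation artefact has been subtracted). The `examples/` directory contains
one narrative script per capability:

| script | what it shows |
| --- | --- |
| `examples/single_trial_analysis.py` | two-frame analysis of one trial vs ground truth |
| `examples/reliability_study.py` | ICC/CV/RMS/K tables for an 11 × 4 × 2 cohort |
| `examples/method_agreement.py` | two-frame vs frame-by-frame over 88 trials |
| `examples/group_comparison.py` | older vs young vs elite-athlete sensitivity |
| `examples/track_ultrasound_sequence.py` | NCC landmark tracking on speckle frames |

A thin CLI wraps the same functions:

```bash
tendonmetrics simulate --seed 1 --out session/
tendonmetrics analyze session/ --method both --out results/
tendonmetrics reliability results/results.csv --out reliability/
tendonmetrics compare-methods results/results.csv --out agreement/
```

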