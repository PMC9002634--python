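"""Analyze one synthetic ramp contraction with the two-frame method.

Simulates a single noiseless trial with a known tendon stiffness, runs the
full chain (synchronization -> joint moment -> tendon force -> rotation-
corrected elongation) and prints the recovered properties next to the
ground truth.
"""

import numpy as np

import tendonmetrics as tm

cfg = tm.GeneratorConfig(
    landmark_noise_sd_mm=0.0, force_noise_sd_n=0.0, marker_noise_sd_mm=0.0,
    force_within_subject_rel_sd=0.0, day_bias_mm_sd=0.0,
    stiffness_between_subject_sd=0.0, force_between_subject_sd=0.0,
    resting_length_between_subject_sd=0.0, moment_arm_between_subject_sd=0.0,
    true_stiffness_index=75.0, max_force_n=4500.0, resting_length_mm=200.0,
)
rng = np.random.default_rng(1)
subject = tm.draw_subject(cfg, "demo", rng)
record, truth = tm.simulate_trial(cfg, subject, rng)
constants = tm.AnatomicalConstants(
    subject.moment_arm_mm, subject.resting_length_mm, cfg.load_cell_positions_m
)

aligned = tm.synchronize(record, positions_m=cfg.load_cell_positions_m)
props = tm.two_frame_properties(aligned, constants)

print(f"maximal tendon force   {props.f_max_n:8.1f} N   (truth {truth.f_max_n:.1f})")
print(f"measured displacement  {props.dl_measured_mm:8.2f} mm")
print(f"rotation artefact      {props.dl_measured_mm - props.dl_max_mm:8.2f} mm "
      f"(moment arm x {np.degrees(props.delta_theta_rad):.2f} deg)")
print(f"corrected elongation   {props.dl_max_mm:8.2f} mm  (truth {truth.elongation_mm:.2f})")
print(f"maximal strain         {props.strain_max_pct:8.2f} %   (truth {100*truth.strain:.2f})")
print(f"stiffness index        {props.stiffness_index_kn_per_strain:8.2f} kN/strain "
      f"(truth {truth.stiffness_index:.2f})")
print()
print("The stiffness index is maximal force (kN) over maximal fractional")
print("strain; on a noiseless trial the two-frame estimate matches the")
print("generator's ground truth to numerical precision.")
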