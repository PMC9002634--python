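"""Track the myotendinous junction through a synthetic ultrasound sequence.

Renders a speckle frame stack whose dark wedge feature follows a known
landmark track, runs the NCC tracker with sub-pixel refinement and reports
the tracking error against the rendered ground truth.
"""

import numpy as np

import tendonmetrics as tm
from tendonmetrics.tracking import DEFAULT_SCORE_THRESHOLD

cfg = tm.GeneratorConfig(
    landmark_noise_sd_mm=0.0, force_noise_sd_n=0.0, marker_noise_sd_mm=0.0,
    force_within_subject_rel_sd=0.0, day_bias_mm_sd=0.0,
    stiffness_between_subject_sd=0.0, force_between_subject_sd=0.0,
    resting_length_between_subject_sd=0.0, moment_arm_between_subject_sd=0.0,
)
rng = np.random.default_rng(3)
subject = tm.draw_subject(cfg, "demo", rng)
record, _ = tm.simulate_trial(cfg, subject, rng)

params = tm.ImageParams()
frames, true_track = tm.simulate_ultrasound_sequence(
    record, params, rng=np.random.default_rng(5)
)
track = tm.track_sequence(frames, tuple(true_track[0]),
                          pixel_pitch_mm=params.pixel_pitch_mm)

err_px = np.linalg.norm(track.positions_px - true_track, axis=1)
excursion_mm = (true_track[-1, 0] - true_track[0, 0]) * params.pixel_pitch_mm
print(f"frames tracked        {frames.shape[0]}")
print(f"landmark excursion    {excursion_mm:.2f} mm "
      f"({excursion_mm / params.pixel_pitch_mm:.1f} px)")
print(f"RMS tracking error    {np.sqrt(np.mean(err_px**2)):.3f} px "
      f"({np.sqrt(np.mean(err_px**2)) * params.pixel_pitch_mm:.3f} mm)")
print(f"frames flagged        {int(track.flagged.sum())} "
      f"(NCC score < {DEFAULT_SCORE_THRESHOLD})")
print()
print("Sub-pixel tracking accuracy (well below the +-1 mm digitization")
print("error of manual operators) on a fully synthetic, reproducible scene.")
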