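"""Synthetic ramp-contraction trials with known ground truth.

The generator emulates the full measurement chain used for in-vivo Achilles
tendon testing: a subject with a true (unobservable) tendon stiffness
performs a ramp isometric plantarflexion; the joint moment is measured by
three foot-plate load cells at 100 Hz, ankle rotation by sagittal-plane LED
markers at 15 Hz, and MTJ displacement by ultrasound at 30 Hz.  Each stream
has its own clock offset and a shared trigger event, so downstream
synchronization is exercised for real.

The physical model is deliberately simple and fully transparent:

* force ramp: smoothstep ``F(t) = F_max * (3u^2 - 2u^3)`` over the ramp,
  preceded by a rest phase at zero force and followed by a short hold;
* tendon law: strain at force ``F`` is
  ``eps(F) = eps_max * (F/F_max)**(1/nonlinearity)`` with
  ``eps_max = (F_max/1000) / k_true`` so that the true stiffness index
  ``k_true`` (kN per unit strain) is recovered exactly at maximal force;
* ankle rotation: quasi-static compliance, ``dtheta(t) = c * M(t)``;
* observed MTJ displacement: true elongation plus the rotation artefact
  ``moment_arm * dtheta`` plus Gaussian digitization noise.

The frame-by-frame landmark series and the two-frame pair receive
*independent* noise realizations, mirroring the fact that in practice they
come from two independent digitizations of the same video.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .datamodel import (
    AnatomicalConstants,
    SessionDataset,
    SubjectInfo,
    TrialRecord,
    TwoFramePair,
)
from .errors import ConfigError

import pandas as pd


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a synthetic cohort.

    Stiffness is the normalized stiffness index in kN per unit (fractional)
    strain.  Between-subject SDs scatter the subject-level parameters;
    within-subject variation enters through trial-to-trial effort variation
    (``force_within_subject_rel_sd``), a per-day landmark re-application bias
    (``day_bias_mm_sd``, emulating probe repositioning between sessions) and
    the additive measurement noise of each stream.
    """

    # cohort design
    n_subjects: int = 11
    n_trials: int = 4
    n_days: int = 2
    group_label: str = "young_nonactive"
    # subject-level truth
    true_stiffness_index: float = 73.9        # kN / strain
    stiffness_between_subject_sd: float = 18.3
    max_force_n: float = 4436.0
    force_between_subject_sd: float = 898.0
    resting_length_mm: float = 200.0
    resting_length_between_subject_sd: float = 15.0
    moment_arm_mm: float = 50.0
    moment_arm_between_subject_sd: float = 3.0
    nonlinearity: float = 1.0                 # 1 = linear force-strain law
    # trial-level variation
    force_within_subject_rel_sd: float = 0.045
    day_bias_mm_sd: float = 0.3
    # contraction timing
    rest_duration_s: float = 1.0
    ramp_duration_s: float = 3.0
    hold_duration_s: float = 0.5
    # joint / plate model
    joint_compliance_rad_per_nm: float = 1.8e-4
    load_cell_positions_m: tuple[float, float, float] = (0.05, 0.15, 0.25)
    load_cell_weights: tuple[float, float, float] = (0.25, 0.5, 0.25)
    baseline_offsets_n: tuple[float, float, float] = (4.0, 6.0, 5.0)
    # measurement noise (additive, zero-mean Gaussian, independent samples)
    landmark_noise_sd_mm: float = 0.5   # 95% of digitization errors within +-1 mm
    force_noise_sd_n: float = 5.0
    marker_noise_sd_mm: float = 0.2
    # stream clocks
    sampling_rates_hz: dict = field(
        default_factory=lambda: {"force": 100.0, "markers": 15.0, "ultrasound": 30.0}
    )
    trigger_offsets_s: dict = field(
        default_factory=lambda: {"force": 0.0, "markers": 0.12, "ultrasound": 0.25}
    )
    seed: int = 0

    def validate(self) -> None:
        scalars = asdict(self)
        for name, value in scalars.items():
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise ConfigError(f"{name} is not finite")
        for name in (
            "stiffness_between_subject_sd", "force_between_subject_sd",
            "resting_length_between_subject_sd", "moment_arm_between_subject_sd",
            "force_within_subject_rel_sd", "day_bias_mm_sd",
            "landmark_noise_sd_mm", "force_noise_sd_n", "marker_noise_sd_mm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.true_stiffness_index <= 0:
            raise ConfigError("true_stiffness_index must be > 0")
        if self.nonlinearity <= 0:
            raise ConfigError("nonlinearity must be > 0")
        for stream, rate in self.sampling_rates_hz.items():
            if rate <= 0:
                raise ConfigError(f"sampling rate of {stream!r} must be > 0")
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_days < 1:
            raise ConfigError("cohort design counts must be >= 1")


@dataclass
class SubjectParams:
    """True subject-level parameters drawn from the cohort distributions."""

    subject_id: str
    true_stiffness_index: float
    max_force_n: float
    resting_length_mm: float
    moment_arm_mm: float
    day_bias_mm: dict[int, float] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Per-trial truth, internally consistent by construction:
    ``stiffness == (f_max/1000) / strain`` for fractional strain."""

    subject_id: str
    day: int
    trial: int
    f_max_n: float
    elongation_mm: float
    strain: float
    stiffness_index: float
    delta_theta_rad: float
    # dense truth on each stream's sample grid (global time), for testing
    time_s: Optional[np.ndarray] = None
    force_n: Optional[np.ndarray] = None
    elongation_series_mm: Optional[np.ndarray] = None
    theta_series_rad: Optional[np.ndarray] = None
    landmark_time_s: Optional[np.ndarray] = None
    landmark_true_mm: Optional[np.ndarray] = None


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# Neutral-position marker geometry (mm), sagittal plane, ankle axis at the
# origin, foot pointing toward +x, shank toward +y.  Plate markers sit on the
# (horizontal) foot plate, so the neutral shank-plate angle is pi/2.
_MARKER_REST_MM = np.array(
    [
        [0.0, 400.0],    # fibula_head
        [0.0, 0.0],      # lateral_malleolus
        [8.0, 6.0],      # medial_malleolus
        [-55.0, -25.0],  # calcaneus
        [-80.0, -40.0],  # plate_1
        [-20.0, -40.0],  # plate_2
        [120.0, -40.0],  # plate_3
        [180.0, -40.0],  # plate_4
    ]
)
_SHANK_ROWS = (0,)  # markers rigid with the shank; malleoli sit on the axis


def _force_profile(cfg: GeneratorConfig, t: np.ndarray, f_max: float) -> np.ndarray:
    u = (t - cfg.rest_duration_s) / cfg.ramp_duration_s
    return f_max * _smoothstep(u)


def simulate_trial(
    cfg: GeneratorConfig,
    subject: SubjectParams,
    rng: np.random.Generator,
    day: int = 1,
    trial: int = 1,
    leg: str = "right",
) -> tuple[TrialRecord, GroundTruth]:
    """Simulate one ramp contraction of ``subject`` and return the raw
    multi-rate trial plus its ground truth."""
    cfg.validate()
    k = subject.true_stiffness_index
    l0 = subject.resting_length_mm
    arm_mm = subject.moment_arm_mm
    arm_m = arm_mm / 1000.0

    f_max = subject.max_force_n * (
        1.0 + rng.normal(0.0, cfg.force_within_subject_rel_sd)
    )
    f_max = max(f_max, 0.1 * subject.max_force_n)
    strain_max = (f_max / 1000.0) / k
    day_bias = subject.day_bias_mm.get(day, 0.0)

    duration = cfg.rest_duration_s + cfg.ramp_duration_s + cfg.hold_duration_s

    def truth_at(t: np.ndarray):
        force = _force_profile(cfg, t, f_max)
        with np.errstate(divide="ignore"):
            rel = np.where(force > 0, force / f_max, 0.0)
        strain = strain_max * rel ** (1.0 / cfg.nonlinearity)
        elong = l0 * strain
        moment = force * arm_m
        theta = cfg.joint_compliance_rad_per_nm * moment
        return force, elong, theta, moment

    # --- force stream ------------------------------------------------------
    rate_f = cfg.sampling_rates_hz["force"]
    t_f = np.arange(0.0, duration + 0.5 / rate_f, 1.0 / rate_f)
    force_true, _, _, moment_true = truth_at(t_f)
    weights = np.asarray(cfg.load_cell_weights, dtype=float)
    positions = np.asarray(cfg.load_cell_positions_m, dtype=float)
    denom = float(weights @ positions)
    channels = np.outer(moment_true / denom, weights)
    channels += np.asarray(cfg.baseline_offsets_n)
    channels += rng.normal(0.0, cfg.force_noise_sd_n, channels.shape)

    # --- marker stream -----------------------------------------------------
    rate_m = cfg.sampling_rates_hz["markers"]
    t_m = np.arange(0.0, duration + 0.5 / rate_m, 1.0 / rate_m)
    _, _, theta_m, _ = truth_at(t_m)
    markers = np.repeat(_MARKER_REST_MM[None, :, :], t_m.size, axis=0)
    # plantarflexion: shank rotates toward the plate, shrinking the
    # shank-plate angle by dtheta
    cos_t, sin_t = np.cos(theta_m), np.sin(theta_m)
    for row in _SHANK_ROWS:
        x0, y0 = _MARKER_REST_MM[row]
        markers[:, row, 0] = cos_t * x0 + sin_t * y0
        markers[:, row, 1] = -sin_t * x0 + cos_t * y0
    markers += rng.normal(0.0, cfg.marker_noise_sd_mm, markers.shape)

    # --- ultrasound stream -------------------------------------------------
    rate_u = cfg.sampling_rates_hz["ultrasound"]
    t_u = np.arange(0.0, duration + 0.5 / rate_u, 1.0 / rate_u)
    force_u, elong_u, theta_u, _ = truth_at(t_u)
    p0 = 30.0  # arbitrary MTJ position in the image at rest (mm)
    landmark_true = p0 + elong_u + arm_mm * theta_u + day_bias
    landmark_obs = landmark_true + rng.normal(0.0, cfg.landmark_noise_sd_mm, t_u.shape)

    # Independent two-frame digitization of the rest and max-force frames.
    i_rest = 0
    i_max = int(np.argmax(force_u))
    two_frame = TwoFramePair(
        rest_time_s=t_u[i_rest] + cfg.trigger_offsets_s["ultrasound"],
        rest_mm=landmark_true[i_rest] + rng.normal(0.0, cfg.landmark_noise_sd_mm),
        max_time_s=t_u[i_max] + cfg.trigger_offsets_s["ultrasound"],
        max_mm=landmark_true[i_max] + rng.normal(0.0, cfg.landmark_noise_sd_mm),
    )

    record = TrialRecord(
        subject_id=subject.subject_id,
        day=day,
        trial=trial,
        leg=leg,
        force_time_s=t_f + cfg.trigger_offsets_s["force"],
        forces_n=channels,
        marker_time_s=t_m + cfg.trigger_offsets_s["markers"],
        markers_mm=markers,
        landmark_time_s=t_u + cfg.trigger_offsets_s["ultrasound"],
        landmark_mm=landmark_obs,
        two_frame=two_frame,
        triggers=dict(cfg.trigger_offsets_s),
        probe_displacement_ok=True,
    )
    truth = GroundTruth(
        subject_id=subject.subject_id,
        day=day,
        trial=trial,
        f_max_n=f_max,
        elongation_mm=l0 * strain_max,
        strain=strain_max,
        stiffness_index=k,
        delta_theta_rad=cfg.joint_compliance_rad_per_nm * f_max * arm_m,
        time_s=t_f,
        force_n=force_true,
        elongation_series_mm=elong_u,
        theta_series_rad=theta_u,
        landmark_time_s=t_u,
        landmark_true_mm=landmark_true,
    )
    return record, truth


def draw_subject(
    cfg: GeneratorConfig, subject_id: str, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject's true parameters from the cohort distributions."""

    def trunc_normal(mean, sd, lo):
        if sd == 0:
            return float(mean)
        for _ in range(100):
            v = rng.normal(mean, sd)
            if v > lo:
                return float(v)
        raise ConfigError("could not draw a positive subject parameter")

    day_bias = {
        d: rng.normal(0.0, cfg.day_bias_mm_sd) if cfg.day_bias_mm_sd > 0 else 0.0
        for d in range(1, cfg.n_days + 1)
    }
    return SubjectParams(
        subject_id=subject_id,
        true_stiffness_index=trunc_normal(
            cfg.true_stiffness_index, cfg.stiffness_between_subject_sd, 5.0
        ),
        max_force_n=trunc_normal(cfg.max_force_n, cfg.force_between_subject_sd, 300.0),
        resting_length_mm=trunc_normal(
            cfg.resting_length_mm, cfg.resting_length_between_subject_sd, 50.0
        ),
        moment_arm_mm=trunc_normal(
            cfg.moment_arm_mm, cfg.moment_arm_between_subject_sd, 10.0
        ),
        day_bias_mm=day_bias,
    )


def simulate_cohort(
    group_configs: dict[str, GeneratorConfig] | GeneratorConfig,
    seed: Optional[int] = None,
) -> tuple[SessionDataset, pd.DataFrame]:
    """Simulate one or more subject groups into a single session dataset.

    ``group_configs`` maps group label to its :class:`GeneratorConfig`
    (a single config is treated as a one-group cohort).  Returns the dataset
    plus a tidy ground-truth table with one row per trial.
    """
    if isinstance(group_configs, GeneratorConfig):
        group_configs = {group_configs.group_label: group_configs}
    if not group_configs:
        raise ConfigError("at least one group must be specified")
    dataset = SessionDataset()
    rows = []
    for group in sorted(group_configs):
        cfg = group_configs[group]
        cfg.validate()
        base = cfg.seed if seed is None else seed
        rng = np.random.default_rng(base + hash_group(group))
        for s in range(1, cfg.n_subjects + 1):
            sid = f"{group[:3]}{s:02d}"
            subject = draw_subject(cfg, sid, rng)
            info = SubjectInfo(
                id=sid,
                age_yr=float(rng.integers(20, 70)),
                height_cm=float(np.round(rng.normal(180, 5), 1)),
                mass_kg=float(np.round(rng.normal(76, 6), 1)),
            )
            constants = AnatomicalConstants(
                moment_arm_mm=subject.moment_arm_mm,
                resting_length_mm=subject.resting_length_mm,
                load_cell_positions_m=cfg.load_cell_positions_m,
            )
            dataset.subjects[sid] = (info, constants, group)
            for day in range(1, cfg.n_days + 1):
                for tr in range(1, cfg.n_trials + 1):
                    leg = "right"
                    if cfg.n_days == 1 and cfg.n_trials >= 8:
                        leg = "right" if tr <= cfg.n_trials // 2 else "left"
                    record, truth = simulate_trial(
                        cfg, subject, rng, day=day, trial=tr, leg=leg
                    )
                    dataset.add_trial(record)
                    rows.append(
                        {
                            "group": group,
                            "subject": sid,
                            "day": day,
                            "trial": tr,
                            "leg": leg,
                            "true_f_max_n": truth.f_max_n,
                            "true_elongation_mm": truth.elongation_mm,
                            "true_strain": truth.strain,
                            "true_stiffness_index": truth.stiffness_index,
                            "true_delta_theta_rad": truth.delta_theta_rad,
                        }
                    )
    dataset.validate()
    return dataset, pd.DataFrame(rows)


def hash_group(group: str) -> int:
    """Small deterministic per-group seed offset (stable across processes)."""
    return sum((i + 1) * ord(c) for i, c in enumerate(group)) % 10007


def default_group_configs(seed: int = 0) -> dict[str, GeneratorConfig]:
    """Three-group study design: older adults, young non-active, elite athletes.

    Group-level stiffness distributions follow typical published cohort
    values (older 49.4 +- 11.5, young 73.9 +- 18.3, athletes 96.3 +- 11.7
    kN/strain); maximal force is ordered athletes > young > older while
    maximal strain is similar across groups.
    """
    young = GeneratorConfig(seed=seed)
    older = GeneratorConfig(
        n_subjects=8, n_days=1, n_trials=8, group_label="older",
        true_stiffness_index=49.4, stiffness_between_subject_sd=11.5,
        max_force_n=3000.0, force_between_subject_sd=600.0, seed=seed,
    )
    athletes = GeneratorConfig(
        n_subjects=8, n_days=1, n_trials=8, group_label="elite_athlete",
        true_stiffness_index=96.3, stiffness_between_subject_sd=11.7,
        max_force_n=5500.0, force_between_subject_sd=800.0, seed=seed,
    )
    return {"older": older, "young_nonactive": young, "elite_athlete": athletes}


# ---------------------------------------------------------------------------
# Synthetic ultrasound imagery
# ---------------------------------------------------------------------------

@dataclass
class ImageParams:
    """Rendering parameters for synthetic B-mode-like frames.

    The frame is a multiplicative speckle background (tissue-attached, so it
    translates with the landmark) times a dark wedge feature centred on the
    landmark.  ``pixel_pitch_mm`` makes the mm <-> px conversion exact.
    """

    width_px: int = 192
    height_px: int = 128
    pixel_pitch_mm: float = 0.2
    speckle_contrast: float = 0.25
    speckle_scale_px: float = 1.5
    wedge_depth: float = 0.7
    wedge_sigma_y_px: float = 2.5
    wedge_sigma_x_px: float = 8.0
    wedge_slope: float = 0.5
    electronic_noise_sd: float = 0.02
    mean_level: float = 0.55
    landmark_y_px: float = 64.0
    landmark_x0_px: float = 60.0

    def validate(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ConfigError("frame smaller than the feature template")
        if self.pixel_pitch_mm <= 0:
            raise ConfigError("pixel_pitch_mm must be > 0")


def wedge_profile(dx: np.ndarray, dy: np.ndarray, p: ImageParams) -> np.ndarray:
    """Dark wedge multiplier, analytic so sub-pixel positions are exact."""
    ridge = dy - p.wedge_slope * np.abs(dx)
    return 1.0 - p.wedge_depth * np.exp(
        -0.5 * (ridge / p.wedge_sigma_y_px) ** 2
        - 0.5 * (dx / p.wedge_sigma_x_px) ** 2
    )


def simulate_ultrasound_sequence(
    trial: TrialRecord,
    image_params: Optional[ImageParams] = None,
    rng: Optional[np.random.Generator] = None,
    max_frames: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic ultrasound frame stack for a trial.

    Requires the full landmark series.  Returns ``(frames, track_px)`` where
    ``frames`` has shape ``(n, height, width)`` with values in [0, 1] and
    ``track_px`` has shape ``(n, 2)`` giving the true (x, y) landmark
    position in pixels for each frame.
    """
    if not trial.has_landmark_series():
        raise ConfigError("trial has no full landmark series to render")
    p = image_params or ImageParams()
    p.validate()
    rng = rng or np.random.default_rng(0)

    disp_mm = np.asarray(trial.landmark_mm) - float(trial.landmark_mm[0])
    if max_frames is not None:
        disp_mm = disp_mm[:max_frames]
    disp_px = disp_mm / p.pixel_pitch_mm

    # tissue-attached speckle canvas wide enough for the whole excursion
    margin = int(np.ceil(np.abs(disp_px).max())) + 8
    cw, ch = p.width_px + 2 * margin, p.height_px
    white = rng.normal(0.0, 1.0, (ch, cw))
    speckle = ndimage.gaussian_filter(white, p.speckle_scale_px)
    if speckle.std() > 0:
        speckle /= speckle.std()
    canvas = p.mean_level * (1.0 + p.speckle_contrast * speckle)

    ys, xs = np.mgrid[0 : p.height_px, 0 : p.width_px]
    frames = np.empty((disp_px.size, p.height_px, p.width_px))
    track = np.empty((disp_px.size, 2))
    for i, d in enumerate(disp_px):
        cx = p.landmark_x0_px + d
        # speckle moves rigidly with the tissue
        coords = np.array([ys.ravel(), (xs - d + margin).ravel()], dtype=float)
        bg = ndimage.map_coordinates(canvas, coords, order=3, mode="nearest")
        frame = bg.reshape(p.height_px, p.width_px) * wedge_profile(
            xs - cx, ys - p.landmark_y_px, p
        )
        if p.electronic_noise_sd > 0:
            frame = frame + rng.normal(0.0, p.electronic_noise_sd, frame.shape)
        frames[i] = np.clip(frame, 0.0, 1.0)
        track[i] = (cx, p.landmark_y_px)
    return frames, track
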