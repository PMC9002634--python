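"""Core tendon mechanics: force, rotation-corrected elongation, strain and
the normalized stiffness index.

The measured MTJ displacement during an isometric plantarflexion mixes two
effects: true tendon elongation under load and apparent displacement caused
by the inevitable small ankle rotation.  The rotation artefact is estimated
with the tendon-excursion method (moment arm times joint-angle change) and
subtracted.  The normalized stiffness index is the ratio of maximal tendon
force (kN) to maximal fractional strain, evaluated over the full 0-100%
force range; normalizing by strain rather than elongation removes the
dependence on resting length, so the index is comparable across subjects.

Two analysis routes are provided:

* :func:`two_frame_properties` - the time-efficient route using only the
  rest frame and the maximal-force frame;
* :func:`frame_by_frame_curve` - the conventional reference route that
  digitizes every ultrasound frame and returns the full force-elongation
  curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import AnatomicalConstants
from .errors import ValidationError
from .signals import ANGLE_SIGN, AlignedTrial

#: force threshold (fraction of maximal force) below which the tendon is
#: considered at rest when picking the rest frame
REST_FORCE_FRACTION = 0.02

#: sign of the rotation correction: plantarflexion (positive delta-theta)
#: produces artefactual MTJ excursion that is subtracted from the measured
#: displacement
ROTATION_CORRECTION_SIGN = -1.0


@dataclass
class TendonProperties:
    """Per-trial maximal tendon mechanical properties."""

    f_max_n: float
    dl_measured_mm: float
    dl_max_mm: float
    strain_max: float            # fractional; multiply by 100 for %
    measured_strain_max: float   # uncorrected (no rotation correction)
    stiffness_index_kn_per_strain: float
    delta_theta_rad: float
    method: str
    valid: bool = True
    notes: str = ""

    @property
    def strain_max_pct(self) -> float:
        return 100.0 * self.strain_max

    @property
    def measured_strain_max_pct(self) -> float:
        return 100.0 * self.measured_strain_max


@dataclass
class ForceElongationCurve:
    """Tendon force vs rotation-corrected elongation across a contraction."""

    force_n: np.ndarray
    elongation_mm: np.ndarray
    measured_elongation_mm: np.ndarray = field(default=None)  # uncorrected

    def __post_init__(self):
        if len(self.force_n) != len(self.elongation_mm):
            raise ValidationError("curve arrays must have equal length")


def tendon_force(moment_nm, moment_arm_mm: float):
    """Tendon force from joint moment: ``F = M / (moment_arm in m)``."""
    if not moment_arm_mm > 0:
        raise ValidationError("moment arm must be positive")
    return np.asarray(moment_nm, dtype=float) / (moment_arm_mm / 1000.0)


def moment_arm_from_points(axis_point_mm, line_p1_mm, line_p2_mm) -> float:
    """Perpendicular distance (mm) from the ankle axis point to the tendon
    line of action given two digitized points on the tendon."""
    a = np.asarray(axis_point_mm, dtype=float)
    p1 = np.asarray(line_p1_mm, dtype=float)
    p2 = np.asarray(line_p2_mm, dtype=float)
    d = p2 - p1
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValidationError("tendon line points coincide")
    v = a - p1
    return float(abs(d[0] * v[1] - d[1] * v[0]) / n)


def rotation_excursion(moment_arm_mm: float, delta_theta_rad: float) -> float:
    """Tendon excursion (mm) caused by joint rotation: moment arm x angle
    change; signed, plantarflexion positive."""
    return moment_arm_mm * delta_theta_rad


def _rest_index(aligned: AlignedTrial, force_n: np.ndarray) -> int:
    """First valid sample before force onset (force < 2% of maximum)."""
    f_max = force_n[aligned.max_force_index]
    at_rest = aligned.valid & (force_n < REST_FORCE_FRACTION * f_max)
    onset = at_rest & (np.arange(force_n.size) < aligned.max_force_index)
    if not onset.any():
        raise ValidationError("no valid rest sample before force onset")
    return int(np.argmax(onset))


def _delta_theta(aligned: AlignedTrial, i_rest: int, i_max: int) -> float:
    return ANGLE_SIGN * float(
        aligned.ankle_angle_rad[i_max] - aligned.ankle_angle_rad[i_rest]
    )


def _properties(
    f_max: float,
    dl_measured: float,
    delta_theta: float,
    constants: AnatomicalConstants,
    method: str,
) -> TendonProperties:
    excursion = rotation_excursion(constants.moment_arm_mm, delta_theta)
    dl_max = dl_measured + ROTATION_CORRECTION_SIGN * excursion
    strain = dl_max / constants.resting_length_mm
    valid = strain > 0
    stiffness = (f_max / 1000.0) / strain if valid else float("nan")
    return TendonProperties(
        f_max_n=float(f_max),
        dl_measured_mm=float(dl_measured),
        dl_max_mm=float(dl_max),
        strain_max=float(strain),
        measured_strain_max=float(dl_measured / constants.resting_length_mm),
        stiffness_index_kn_per_strain=float(stiffness),
        delta_theta_rad=float(delta_theta),
        method=method,
        valid=bool(valid),
        notes="" if valid else "non-positive strain after rotation correction",
    )


def two_frame_properties(
    aligned: AlignedTrial, constants: AnatomicalConstants
) -> TendonProperties:
    """Tendon properties from the rest frame and the maximal-force frame only.

    Prefers the trial's dedicated two-frame digitization; falls back to
    sampling the full landmark series at the rest and max-force samples.
    The angle change is evaluated between the same two frames as the
    landmark pair.
    """
    force = tendon_force(aligned.joint_moment_nm, constants.moment_arm_mm)
    i_max = aligned.max_force_index
    f_max = float(force[i_max])

    if aligned.two_frame is not None:
        pair = aligned.two_frame
        i_rest = int(np.argmin(np.abs(aligned.time_s - pair.rest_time_s)))
        i_pk = int(np.argmin(np.abs(aligned.time_s - pair.max_time_s)))
        dl_measured = pair.max_mm - pair.rest_mm
        delta_theta = _delta_theta(aligned, i_rest, i_pk)
    elif aligned.landmark_mm is not None:
        i_rest = _rest_index(aligned, force)
        dl_measured = float(aligned.landmark_mm[i_max] - aligned.landmark_mm[i_rest])
        delta_theta = _delta_theta(aligned, i_rest, i_max)
    else:
        raise ValidationError("no landmark information available")

    return _properties(f_max, dl_measured, delta_theta, constants, "two_frame")


def frame_by_frame_curve(
    aligned: AlignedTrial, constants: AnatomicalConstants
) -> tuple[ForceElongationCurve, TendonProperties]:
    """Conventional reference analysis digitizing every ultrasound frame.

    Returns the rotation-corrected force-elongation curve from rest to the
    maximal-force sample plus the trial's :class:`TendonProperties`
    (including the *measured*, uncorrected displacement used in
    method-agreement comparisons).
    """
    if aligned.landmark_mm is None:
        raise ValidationError("frame-by-frame analysis requires a landmark series")
    if int(aligned.meta.get("n_landmark_frames", 3)) < 3:
        raise ValidationError("fewer than 3 landmark frames")
    force = tendon_force(aligned.joint_moment_nm, constants.moment_arm_mm)
    i_max = aligned.max_force_index
    i_rest = _rest_index(aligned, force)
    if i_max - i_rest < 2:
        raise ValidationError("fewer than 3 frames between rest and maximal force")

    sel = slice(i_rest, i_max + 1)
    measured = aligned.landmark_mm[sel] - aligned.landmark_mm[i_rest]
    dtheta = ANGLE_SIGN * (
        aligned.ankle_angle_rad[sel] - aligned.ankle_angle_rad[i_rest]
    )
    corrected = measured + ROTATION_CORRECTION_SIGN * rotation_excursion(
        constants.moment_arm_mm, dtheta
    )
    curve = ForceElongationCurve(
        force_n=np.asarray(force[sel], dtype=float),
        elongation_mm=np.asarray(corrected, dtype=float),
        measured_elongation_mm=np.asarray(measured, dtype=float),
    )
    props = _properties(
        float(force[i_max]),
        float(measured[-1]),
        float(dtheta[-1]),
        constants,
        "frame_by_frame",
    )
    return curve, props
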