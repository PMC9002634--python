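"""Domain types for in-vivo tendon mechanics trials.

A *trial* is one ramp isometric plantarflexion contraction recorded with
three asynchronous instruments:

* a load-cell foot plate (three channels, nominally 100 Hz),
* a sagittal-plane marker camera system (8 LED markers, nominally 15 Hz),
* B-mode ultrasound of the gastrocnemius medialis myotendinous junction
  (MTJ), nominally 30 Hz.

Each stream carries its own clock plus a shared trigger event, which is how
the streams are later synchronized.  Positions are millimetres, forces
newtons, moments newton-metres and angles radians throughout the package;
lever arms of the load cells are metres because they multiply newtons into
newton-metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: Canonical marker order used by every marker array in the package:
#: four anatomical LEDs and four LEDs fixed to the dynamometer foot plate.
MARKER_NAMES: tuple[str, ...] = (
    "fibula_head",
    "lateral_malleolus",
    "medial_malleolus",
    "calcaneus",
    "plate_1",
    "plate_2",
    "plate_3",
    "plate_4",
)

STREAMS: tuple[str, ...] = ("force", "markers", "ultrasound")


@dataclass
class AnatomicalConstants:
    """Per-subject constants required to turn raw signals into tendon mechanics.

    Parameters
    ----------
    moment_arm_mm:
        Perpendicular distance from the ankle rotation axis (through the
        inferior tips of the malleoli) to the Achilles tendon line of action.
    resting_length_mm:
        Tendon resting length: MTJ to calcaneal tuberosity at neutral
        position.
    load_cell_positions_m:
        Signed lever arms (m) of the three foot-plate load cells measured
        along the plate from the projection of the ankle axis.
    ankle_axis_definition:
        Marker pair defining the ankle axis.
    """

    moment_arm_mm: float
    resting_length_mm: float
    load_cell_positions_m: tuple[float, float, float]
    ankle_axis_definition: str = "medial_malleolus/lateral_malleolus"

    def validate(self) -> None:
        if not self.moment_arm_mm > 0:
            raise ValidationError("moment_arm_mm must be > 0")
        if not self.resting_length_mm > 0:
            raise ValidationError("resting_length_mm must be > 0")
        pos = np.asarray(self.load_cell_positions_m, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValidationError("load_cell_positions_m must be three finite values")


@dataclass
class SubjectInfo:
    id: str
    age_yr: float
    height_cm: float
    mass_kg: float

    def validate(self) -> None:
        for name in ("age_yr", "height_cm", "mass_kg"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive for subject {self.id}")


@dataclass
class TwoFramePair:
    """MTJ position digitized on exactly two ultrasound frames.

    Times are in the ultrasound stream's own clock (seconds); they identify
    the rest frame (before force onset) and the frame at maximal tendon
    force.
    """

    rest_time_s: float
    rest_mm: float
    max_time_s: float
    max_mm: float


@dataclass
class TrialRecord:
    """Raw multi-rate streams of one contraction trial.

    ``landmark_time_s``/``landmark_mm`` hold the frame-by-frame MTJ
    digitization (position along the tendon axis).  ``two_frame`` holds the
    independent two-frame digitization.  At least one of the two must be
    present.  ``triggers`` maps each stream name to the stream-local
    timestamp of the shared trigger event.
    """

    subject_id: str
    day: int
    trial: int
    leg: str
    force_time_s: np.ndarray          # (n_f,)
    forces_n: np.ndarray              # (n_f, 3)
    marker_time_s: np.ndarray         # (n_m,)
    markers_mm: np.ndarray            # (n_m, 8, 2)
    triggers: dict[str, float]
    landmark_time_s: Optional[np.ndarray] = None   # (n_u,)
    landmark_mm: Optional[np.ndarray] = None       # (n_u,)
    two_frame: Optional[TwoFramePair] = None
    probe_displacement_ok: bool = True

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.day, self.trial)

    def has_landmark_series(self) -> bool:
        return self.landmark_time_s is not None and self.landmark_mm is not None


@dataclass
class SessionDataset:
    """A collection of trials plus per-subject metadata.

    ``subjects`` maps subject id to ``(SubjectInfo, AnatomicalConstants,
    group_label)``; trials are keyed by ``(subject_id, day, trial)``.
    """

    subjects: dict[str, tuple[SubjectInfo, AnatomicalConstants, str]] = field(
        default_factory=dict
    )
    trials: dict[tuple[str, int, int], TrialRecord] = field(default_factory=dict)

    def add_trial(self, trial: TrialRecord) -> None:
        if trial.subject_id not in self.subjects:
            raise ValidationError(
                f"trial references unknown subject {trial.subject_id!r}"
            )
        if trial.key in self.trials:
            raise ValidationError(f"duplicate trial key {trial.key}")
        self.trials[trial.key] = trial

    def validate(self) -> None:
        for sid, (info, constants, group) in self.subjects.items():
            info.validate()
            constants.validate()
            if not group:
                raise ValidationError(f"subject {sid} has empty group label")
        for key, trial in self.trials.items():
            if key != trial.key:
                raise ValidationError(f"trial stored under wrong key {key}")
            if trial.subject_id not in self.subjects:
                raise ValidationError(
                    f"trial {key} references unknown subject {trial.subject_id!r}"
                )
            findings = validate_trial(trial)
            errors = [f for f in findings if f[0] == "error"]
            if errors:
                raise ValidationError(f"trial {key}: {errors[0][1]}")


def _check_time(name: str, t: np.ndarray, findings: list) -> None:
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size == 0:
        findings.append(("error", f"{name} time vector empty or not 1-D"))
        return
    if not np.all(np.isfinite(t)):
        findings.append(("error", f"{name} time vector contains non-finite values"))
    if t.size > 1 and not np.all(np.diff(t) > 0):
        findings.append(("error", f"{name} time vector is not strictly increasing"))


def validate_trial(trial: TrialRecord) -> list[tuple[str, str]]:
    """Check a trial against its invariants.

    Returns a list of ``(level, message)`` findings; ``level`` is ``"error"``
    for invariant violations and ``"warning"`` for quality-control issues
    such as a failed probe-displacement tape check.  An empty list means the
    trial is fully valid.
    """
    findings: list[tuple[str, str]] = []
    _check_time("force", trial.force_time_s, findings)
    _check_time("markers", trial.marker_time_s, findings)

    forces = np.asarray(trial.forces_n, dtype=float)
    if forces.ndim != 2 or forces.shape[1] != 3:
        findings.append(("error", "forces_n must have shape (n, 3)"))
    elif forces.shape[0] != np.asarray(trial.force_time_s).shape[0]:
        findings.append(("error", "force time vector and channels disagree in length"))

    markers = np.asarray(trial.markers_mm, dtype=float)
    if markers.ndim != 3 or markers.shape[1:] != (len(MARKER_NAMES), 2):
        findings.append(("error", "markers_mm must have shape (n, 8, 2)"))
    elif markers.shape[0] != np.asarray(trial.marker_time_s).shape[0]:
        findings.append(("error", "marker time vector and positions disagree in length"))

    has_series = trial.has_landmark_series()
    if has_series:
        _check_time("ultrasound", trial.landmark_time_s, findings)
        lm = np.asarray(trial.landmark_mm, dtype=float)
        if lm.shape != np.asarray(trial.landmark_time_s).shape:
            findings.append(("error", "landmark series and time vector disagree"))
    if not has_series and trial.two_frame is None:
        findings.append(
            ("error", "trial has neither a landmark series nor a two-frame pair")
        )

    present = set(trial.triggers)
    needed = {"force", "markers"} | ({"ultrasound"} if has_series else set())
    for stream in sorted(needed - present):
        findings.append(("error", f"stream {stream!r} has no trigger event"))

    # Baseline-corrected force channels must not sit below zero; a small
    # allowance covers additive measurement noise around the rest baseline.
    if forces.ndim == 2 and forces.shape[1] == 3 and forces.size:
        rest = forces[: max(2, forces.shape[0] // 20)]
        corrected = forces - rest.mean(axis=0)
        noise = max(float(rest.std()), 1e-12)
        if corrected.min() < -6.0 * noise - 1e-9:
            findings.append(
                ("error", "force channel drops below zero after baseline correction")
            )

    if not trial.probe_displacement_ok:
        findings.append(
            ("warning", "probe displacement check failed (tape moved relative to skin)")
        )
    return findings
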