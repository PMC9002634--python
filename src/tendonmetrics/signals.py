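"""Multi-rate stream synchronization and raw-signal conversion.

All instruments share a trigger event; synchronization shifts every stream
so that its trigger sits at t = 0 and then interpolates the slower streams
linearly onto the force time base (the highest-rate stream).  Samples
outside a stream's recorded span are marked invalid rather than
extrapolated.

Conversions:

* joint moment from the three foot-plate load cells:
  ``M(t) = sum_i F_i(t) * x_i`` with ``x_i`` the signed lever arm (m) of
  load cell ``i`` about the projection of the ankle axis onto the plate;
* ankle angle as the sagittal-plane angle between the shank segment
  (fibula head -> lateral malleolus) and the foot-plate segment (line of
  the plate markers); approximately pi/2 in neutral position.  Sign
  convention: a *decreasing* shank-plate angle (plantarflexion) gives a
  *positive* rotation ``delta_theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt

from .datamodel import MARKER_NAMES, TrialRecord, TwoFramePair
from .errors import SynchronizationError, ValidationError

#: analysis configuration defaults, echoed into results for reproducibility
DEFAULT_LOWPASS_HZ = 10.0
DEFAULT_REST_WINDOW_S = 0.8
ANGLE_SIGN = -1.0  # decreasing shank-plate angle == positive delta-theta


@dataclass
class AlignedTrial:
    """All streams of one trial on the common (force) time base."""

    time_s: np.ndarray
    joint_moment_nm: np.ndarray
    ankle_angle_rad: np.ndarray
    valid: np.ndarray                       # samples covered by every stream
    landmark_mm: Optional[np.ndarray] = None
    two_frame: Optional[TwoFramePair] = None
    max_force_index: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def delta_theta_series_rad(self) -> np.ndarray:
        """Signed joint rotation relative to the first valid sample."""
        first = int(np.argmax(self.valid))
        return ANGLE_SIGN * (self.ankle_angle_rad - self.ankle_angle_rad[first])


def baseline_correct(
    forces_n: np.ndarray,
    time_s: np.ndarray,
    rest_window_s: float = DEFAULT_REST_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the per-channel rest offset from the load-cell channels.

    The rest window is the first ``rest_window_s`` seconds of the record and
    must precede contraction onset.  Returns ``(corrected, offsets)``; the
    mean of each channel over the window is zero afterwards.
    """
    time_s = np.asarray(time_s, dtype=float)
    forces_n = np.asarray(forces_n, dtype=float)
    mask = time_s <= time_s[0] + rest_window_s
    if rest_window_s <= 0 or not mask.any():
        raise ValidationError("rest window is empty")
    offsets = forces_n[mask].mean(axis=0)
    return forces_n - offsets, offsets


def joint_moment(forces_n: np.ndarray, positions_m) -> np.ndarray:
    """Plate moment about the ankle-axis projection: ``M = sum F_i x_i``."""
    forces_n = np.asarray(forces_n, dtype=float)
    positions_m = np.asarray(positions_m, dtype=float)
    if forces_n.ndim != 2 or forces_n.shape[1] != positions_m.shape[0]:
        raise ValidationError("force channels and load-cell positions mismatch")
    return forces_n @ positions_m


def ankle_angle(markers_mm: np.ndarray) -> float:
    """Sagittal shank-plate angle (rad) for one marker frame.

    ``markers_mm`` is the (8, 2) frame in :data:`MARKER_NAMES` order.  Uses
    the fibula-head -> lateral-malleolus segment against the plate-marker
    line (first to last plate marker); invariant to rigid motion of the
    whole marker set.
    """
    m = np.asarray(markers_mm, dtype=float)
    if m.shape != (len(MARKER_NAMES), 2):
        raise ValidationError("expected an (8, 2) marker frame")
    if not np.all(np.isfinite(m)):
        raise ValidationError("missing (non-finite) marker in frame")
    fib = m[MARKER_NAMES.index("fibula_head")]
    lat = m[MARKER_NAMES.index("lateral_malleolus")]
    p_first = m[MARKER_NAMES.index("plate_1")]
    p_last = m[MARKER_NAMES.index("plate_4")]
    shank = fib - lat
    plate = p_last - p_first
    ns, np_ = np.linalg.norm(shank), np.linalg.norm(plate)
    if ns < 1e-9 or np_ < 1e-9:
        raise ValidationError("degenerate segment: coincident markers")
    cosang = np.clip(shank @ plate / (ns * np_), -1.0, 1.0)
    return float(np.arccos(cosang))


def _interp_valid(
    t_out: np.ndarray, t_in: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    out = np.interp(t_out, t_in, y)
    valid = (t_out >= t_in[0]) & (t_out <= t_in[-1])
    return out, valid


def smoothed_argmax(
    moment_nm: np.ndarray, rate_hz: float, lowpass_hz: float = DEFAULT_LOWPASS_HZ
) -> int:
    """Index of maximal moment after zero-phase 2nd-order low-pass smoothing.

    The raw argmax is unstable under measurement noise; a 10 Hz cutoff keeps
    the slow ramp intact while suppressing sample-level jitter.
    """
    moment_nm = np.asarray(moment_nm, dtype=float)
    nyq = rate_hz / 2.0
    if lowpass_hz <= 0 or lowpass_hz >= nyq or moment_nm.size < 15:
        smooth = moment_nm
    else:
        b, a = butter(2, lowpass_hz / nyq)
        smooth = filtfilt(b, a, moment_nm)
    return int(np.argmax(smooth))


def synchronize(
    trial: TrialRecord,
    positions_m=None,
    rest_window_s: float = DEFAULT_REST_WINDOW_S,
    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
) -> AlignedTrial:
    """Place all streams of a trial on the force time base.

    Each stream is shifted so its trigger event is at t = 0; marker-derived
    ankle angle and the landmark series are then linearly interpolated onto
    the (shifted) force samples.  Load-cell channels are baseline-corrected
    and combined into the joint moment using ``positions_m`` (defaults to
    the values stored with the session's anatomical constants must be passed
    by the caller).
    """
    for stream in ("force", "markers") + (
        ("ultrasound",) if trial.has_landmark_series() else ()
    ):
        if stream not in trial.triggers:
            raise SynchronizationError(f"stream {stream!r} has no trigger event")
    if positions_m is None:
        raise SynchronizationError("load-cell positions are required")

    t_force = np.asarray(trial.force_time_s) - trial.triggers["force"]
    corrected, offsets = baseline_correct(trial.forces_n, t_force, rest_window_s)
    moment = joint_moment(corrected, positions_m)

    t_markers = np.asarray(trial.marker_time_s) - trial.triggers["markers"]
    angles = np.array([ankle_angle(f) for f in np.asarray(trial.markers_mm)])
    angle_i, valid_m = _interp_valid(t_force, t_markers, angles)

    valid = valid_m
    landmark_i = None
    n_landmark_frames = 0
    two_frame = trial.two_frame
    if trial.has_landmark_series():
        t_us = np.asarray(trial.landmark_time_s) - trial.triggers["ultrasound"]
        n_landmark_frames = int(np.asarray(trial.landmark_mm).size)
        landmark_i, valid_u = _interp_valid(
            t_force, t_us, np.asarray(trial.landmark_mm)
        )
        valid = valid & valid_u
    if two_frame is not None and "ultrasound" in trial.triggers:
        off = trial.triggers["ultrasound"]
        two_frame = TwoFramePair(
            rest_time_s=two_frame.rest_time_s - off,
            rest_mm=two_frame.rest_mm,
            max_time_s=two_frame.max_time_s - off,
            max_mm=two_frame.max_mm,
        )

    rate = 1.0 / float(np.median(np.diff(t_force)))
    masked = np.where(valid, moment, -np.inf)
    if not valid.any():
        raise SynchronizationError("no sample covered by all streams")
    i_max = smoothed_argmax(np.where(valid, moment, 0.0), rate, lowpass_hz)
    if not valid[i_max]:
        i_max = int(np.argmax(masked))

    return AlignedTrial(
        time_s=t_force,
        joint_moment_nm=moment,
        ankle_angle_rad=angle_i,
        valid=valid,
        landmark_mm=landmark_i,
        two_frame=two_frame,
        max_force_index=i_max,
        meta={
            "baseline_offsets_n": [float(v) for v in offsets],
            "rest_window_s": rest_window_s,
            "lowpass_hz": lowpass_hz,
            "angle_sign": ANGLE_SIGN,
            "n_landmark_frames": n_landmark_frames,
        },
    )
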