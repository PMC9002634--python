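"""Semi-automatic MTJ landmark localization in ultrasound frames.

Localization is normalized cross-correlation (NCC) template matching with
sub-pixel refinement by a parabolic fit around the correlation peak; frames
whose peak correlation falls below a threshold are flagged for manual
override, mirroring the operator-correction step of semi-automatic
digitization software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .errors import FlatImageError, TrackingLostError, ValidationError

#: NCC score below which a frame is flagged for manual override
DEFAULT_SCORE_THRESHOLD = 0.6
#: NCC score below which the feature is considered lost
LOST_SCORE = 0.2


@dataclass
class LandmarkTrack:
    """Frame-by-frame landmark positions with per-frame match quality."""

    positions_px: np.ndarray            # (n, 2) as (x, y)
    scores: np.ndarray                  # (n,)
    flagged: np.ndarray                 # (n,) bool - manual override advised
    pixel_pitch_mm: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def positions_mm(self) -> np.ndarray:
        return self.positions_px * self.pixel_pitch_mm

    def to_frame(self):
        """Tidy per-frame table (frame, x/y in px and mm, score, flag)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.positions_px.shape[0]),
                "x_px": self.positions_px[:, 0],
                "y_px": self.positions_px[:, 1],
                "x_mm": self.positions_mm[:, 0],
                "y_mm": self.positions_mm[:, 1],
                "score": self.scores,
                "manual_override": self.flagged,
            }
        )


def _parabolic_offset(cm1: float, c0: float, cp1: float) -> float:
    """Sub-pixel offset of a parabola through three equispaced samples,
    clamped to [-0.5, 0.5] (refinement never crosses to a neighbour)."""
    denom = cm1 - 2.0 * c0 + cp1
    if abs(denom) < 1e-15:
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def locate_landmark(
    frame: np.ndarray,
    template: np.ndarray,
    search_window: tuple[int, int, int, int] | None = None,
) -> tuple[tuple[float, float], float]:
    """Locate ``template`` inside ``frame`` by NCC.

    ``search_window`` is ``(x0, y0, x1, y1)`` (exclusive upper bounds)
    restricting the search; ``None`` searches the whole frame.  Returns the
    (x, y) position of the template *centre* refined to sub-pixel accuracy,
    and the peak NCC score in [-1, 1].
    """
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    if search_window is None:
        x0, y0, x1, y1 = 0, 0, frame.shape[1], frame.shape[0]
    else:
        x0, y0, x1, y1 = (int(v) for v in search_window)
        if x0 < 0 or y0 < 0 or x1 > frame.shape[1] or y1 > frame.shape[0]:
            raise ValidationError("search window outside frame")
    window = frame[y0:y1, x0:x1]
    th, tw = template.shape
    if th > window.shape[0] or tw > window.shape[1]:
        raise ValidationError("template larger than search window")
    if template.std() == 0:
        raise FlatImageError("template has zero variance")
    if window.std() == 0:
        raise FlatImageError("search window has zero variance")

    ncc = match_template(window, template)
    ncc = np.nan_to_num(ncc, nan=-1.0)
    iy, ix = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(ncc[iy, ix])

    dx = dy = 0.0
    if 0 < ix < ncc.shape[1] - 1:
        dx = _parabolic_offset(ncc[iy, ix - 1], ncc[iy, ix], ncc[iy, ix + 1])
    if 0 < iy < ncc.shape[0] - 1:
        dy = _parabolic_offset(ncc[iy - 1, ix], ncc[iy, ix], ncc[iy + 1, ix])

    cx = x0 + ix + dx + (tw - 1) / 2.0
    cy = y0 + iy + dy + (th - 1) / 2.0
    return (float(cx), float(cy)), score


def _extract_patch(
    frame: np.ndarray, cx: float, cy: float, size: int
) -> tuple[np.ndarray, float, float]:
    """Cut a ``size`` x ``size`` patch at the integer pixel nearest (cx, cy).

    Returns the patch plus the sub-pixel residual (cx - ix, cy - iy); the
    residual must be added back to subsequent match positions, otherwise the
    discarded fraction accumulates as drift when the template is refreshed
    every frame.
    """
    half = size // 2
    ix, iy = int(round(cx)), int(round(cy))
    ix = int(np.clip(ix, half, frame.shape[1] - 1 - half))
    iy = int(np.clip(iy, half, frame.shape[0] - 1 - half))
    patch = frame[iy - half : iy + half + 1, ix - half : ix + half + 1]
    return patch, cx - ix, cy - iy


def track_sequence(
    frames: np.ndarray,
    initial_position: tuple[float, float],
    template_size: int = 25,
    search_radius: int = 10,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    template_mode: str = "previous",
    pixel_pitch_mm: float = 1.0,
) -> LandmarkTrack:
    """Track the landmark through a frame stack.

    The template is cut from frame 0 around ``initial_position`` and, in the
    default ``"previous"`` mode, refreshed from each matched frame (adapts
    to slow appearance changes, but may drift); ``"anchor"`` keeps the
    frame-0 template throughout.  The template should be large enough to
    cover the landmark feature's full support - a template that clips the
    feature mid-gradient biases the sub-pixel peak fit.  Frames with a peak NCC below
    ``score_threshold`` are flagged for manual override; a score below a
    hard floor raises :class:`TrackingLostError` with the last good frame.
    With ``search_radius == 0`` no matching is done and the track stays at
    the initial position.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValidationError("frames must be a (n, h, w) stack")
    n, h, w = frames.shape
    cx, cy = float(initial_position[0]), float(initial_position[1])
    half = template_size // 2
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValidationError("initial position outside frame 0")
    if template_mode not in ("previous", "anchor"):
        raise ValidationError("template_mode must be 'previous' or 'anchor'")

    positions = np.empty((n, 2))
    scores = np.ones(n)
    flagged = np.zeros(n, dtype=bool)
    positions[0] = (cx, cy)

    if search_radius == 0:
        positions[:] = (cx, cy)
        return LandmarkTrack(positions, scores, flagged, pixel_pitch_mm,
                             meta={"template_mode": template_mode})

    template, offx, offy = _extract_patch(frames[0], cx, cy, template_size)
    for i in range(1, n):
        x0 = max(0, int(round(cx)) - half - search_radius)
        y0 = max(0, int(round(cy)) - half - search_radius)
        x1 = min(w, int(round(cx)) + half + search_radius + 1)
        y1 = min(h, int(round(cy)) + half + search_radius + 1)
        (px, py), score = locate_landmark(frames[i], template, (x0, y0, x1, y1))
        if score < LOST_SCORE:
            raise TrackingLostError(
                f"feature lost at frame {i} (score {score:.2f})", last_good_frame=i - 1
            )
        cx, cy = px + offx, py + offy
        positions[i] = (cx, cy)
        scores[i] = score
        flagged[i] = score < score_threshold
        if template_mode == "previous":
            template, offx, offy = _extract_patch(frames[i], cx, cy, template_size)

    return LandmarkTrack(
        positions, scores, flagged, pixel_pitch_mm,
        meta={"template_mode": template_mode, "template_size": template_size,
              "search_radius": search_radius, "score_threshold": score_threshold},
    )
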