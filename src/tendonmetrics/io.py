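"""On-disk session layout.

A session is a directory with one JSON manifest (``session.json``: subjects,
anatomical constants, group labels, per-trial metadata) plus one CSV per
stream per trial named ``sub<ID>_day<D>_trial<T>_<stream>.csv``.  Every CSV
has a leading ``time_s`` column.  Floats are written with 15 significant
digits, so write -> read round-trips are exact well below 1e-9 and two
writes of the same dataset are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MARKER_NAMES,
    AnatomicalConstants,
    SessionDataset,
    SubjectInfo,
    TrialRecord,
    TwoFramePair,
)
from .errors import LoadError, ValidationError

_FLOAT_FMT = "%.15g"
MANIFEST = "session.json"


def write_frame_stack(frames: np.ndarray, path, pixel_pitch_mm: float) -> None:
    """Write an ultrasound frame stack as a multi-page 16-bit TIFF with a
    JSON sidecar recording the pixel pitch (mm/px)."""
    import tifffile

    frames = np.clip(np.asarray(frames, dtype=float), 0.0, 1.0)
    path = Path(path)
    tifffile.imwrite(path, (frames * 65535).astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"pixel_pitch_mm": float(pixel_pitch_mm),
                   "n_frames": int(frames.shape[0])}, fh, sort_keys=True)
        fh.write("\n")


def read_frame_stack(path) -> tuple[np.ndarray, float]:
    """Read a frame stack written by :func:`write_frame_stack`.

    Returns ``(frames, pixel_pitch_mm)`` with frame values scaled back to
    [0, 1].
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise LoadError(f"no frame stack at {path}")
    frames = tifffile.imread(path).astype(float) / 65535.0
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise LoadError(f"frame stack {path} has no pixel-pitch sidecar")
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    return frames, float(meta["pixel_pitch_mm"])


def _trial_stem(trial: TrialRecord) -> str:
    return f"sub{trial.subject_id}_day{trial.day}_trial{trial.trial}"


def _marker_columns() -> list[str]:
    cols = []
    for name in MARKER_NAMES:
        cols += [f"{name}_x_mm", f"{name}_y_mm"]
    return cols


def write_session(dataset: SessionDataset, path) -> None:
    """Write a dataset to ``path`` (created if needed).

    The output is deterministic: identical datasets produce byte-identical
    files.
    """
    dataset.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    manifest = {"format": "tendonmetrics-session/1", "subjects": [], "trials": []}
    for sid in sorted(dataset.subjects):
        info, constants, group = dataset.subjects[sid]
        manifest["subjects"].append(
            {
                "id": sid,
                "age_yr": info.age_yr,
                "height_cm": info.height_cm,
                "mass_kg": info.mass_kg,
                "group": group,
                "constants": {
                    "moment_arm_mm": constants.moment_arm_mm,
                    "resting_length_mm": constants.resting_length_mm,
                    "load_cell_positions_m": list(constants.load_cell_positions_m),
                    "ankle_axis_definition": constants.ankle_axis_definition,
                },
            }
        )
    for key in sorted(dataset.trials):
        trial = dataset.trials[key]
        stem = _trial_stem(trial)
        entry = {
            "subject_id": trial.subject_id,
            "day": trial.day,
            "trial": trial.trial,
            "leg": trial.leg,
            "probe_displacement_ok": trial.probe_displacement_ok,
            "triggers": {k: trial.triggers[k] for k in sorted(trial.triggers)},
            "two_frame": None,
            "files": {"force": f"{stem}_force.csv", "markers": f"{stem}_markers.csv"},
        }
        if trial.two_frame is not None:
            tf = trial.two_frame
            entry["two_frame"] = {
                "rest_time_s": tf.rest_time_s,
                "rest_mm": tf.rest_mm,
                "max_time_s": tf.max_time_s,
                "max_mm": tf.max_mm,
            }

        force_df = pd.DataFrame(
            {
                "time_s": trial.force_time_s,
                "cell_1_n": trial.forces_n[:, 0],
                "cell_2_n": trial.forces_n[:, 1],
                "cell_3_n": trial.forces_n[:, 2],
            }
        )
        force_df.to_csv(root / entry["files"]["force"], index=False,
                        float_format=_FLOAT_FMT, lineterminator="\n")

        flat = np.asarray(trial.markers_mm).reshape(len(trial.marker_time_s), -1)
        marker_df = pd.DataFrame(flat, columns=_marker_columns())
        marker_df.insert(0, "time_s", trial.marker_time_s)
        marker_df.to_csv(root / entry["files"]["markers"], index=False,
                         float_format=_FLOAT_FMT, lineterminator="\n")

        if trial.has_landmark_series():
            entry["files"]["landmark"] = f"{stem}_landmark.csv"
            lm_df = pd.DataFrame(
                {"time_s": trial.landmark_time_s, "mtj_mm": trial.landmark_mm}
            )
            lm_df.to_csv(root / entry["files"]["landmark"], index=False,
                         float_format=_FLOAT_FMT, lineterminator="\n")
        manifest["trials"].append(entry)

    with open(root / MANIFEST, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_csv(root: Path, name: str, trial_desc: str, columns: list[str]) -> pd.DataFrame:
    fpath = root / name
    if not fpath.exists():
        raise LoadError(f"missing stream file {name!r} for trial {trial_desc}")
    df = pd.read_csv(fpath)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"trial {trial_desc}: file {name!r} lacks columns {missing}"
        )
    return df


def read_session(path) -> SessionDataset:
    """Read a session directory written by :func:`write_session`.

    Raises :class:`LoadError` for missing files and
    :class:`ValidationError` for schema or invariant violations (naming the
    offending trial and field).
    """
    root = Path(path)
    mpath = root / MANIFEST
    if not mpath.exists():
        raise LoadError(f"no {MANIFEST} in {root}")
    with open(mpath, encoding="utf-8") as fh:
        manifest = json.load(fh)

    dataset = SessionDataset()
    for s in manifest.get("subjects", []):
        try:
            info = SubjectInfo(
                id=s["id"], age_yr=s["age_yr"], height_cm=s["height_cm"],
                mass_kg=s["mass_kg"],
            )
            c = s["constants"]
            constants = AnatomicalConstants(
                moment_arm_mm=c["moment_arm_mm"],
                resting_length_mm=c["resting_length_mm"],
                load_cell_positions_m=tuple(c["load_cell_positions_m"]),
                ankle_axis_definition=c.get("ankle_axis_definition", ""),
            )
        except KeyError as exc:
            raise ValidationError(f"subject entry missing field {exc}") from exc
        dataset.subjects[s["id"]] = (info, constants, s.get("group", ""))

    for entry in manifest.get("trials", []):
        desc = "sub{subject_id}/day{day}/trial{trial}".format(**entry)
        files = entry["files"]
        force_df = _read_csv(root, files["force"], desc,
                             ["time_s", "cell_1_n", "cell_2_n", "cell_3_n"])
        marker_df = _read_csv(root, files["markers"], desc,
                              ["time_s"] + _marker_columns())
        landmark_time = landmark = None
        if "landmark" in files:
            lm_df = _read_csv(root, files["landmark"], desc, ["time_s", "mtj_mm"])
            landmark_time = lm_df["time_s"].to_numpy()
            landmark = lm_df["mtj_mm"].to_numpy()
        two_frame = None
        if entry.get("two_frame"):
            two_frame = TwoFramePair(**entry["two_frame"])
        trial = TrialRecord(
            subject_id=entry["subject_id"],
            day=int(entry["day"]),
            trial=int(entry["trial"]),
            leg=entry.get("leg", "right"),
            force_time_s=force_df["time_s"].to_numpy(),
            forces_n=force_df[["cell_1_n", "cell_2_n", "cell_3_n"]].to_numpy(),
            marker_time_s=marker_df["time_s"].to_numpy(),
            markers_mm=marker_df[_marker_columns()].to_numpy().reshape(
                -1, len(MARKER_NAMES), 2
            ),
            triggers={k: float(v) for k, v in entry["triggers"].items()},
            landmark_time_s=landmark_time,
            landmark_mm=landmark,
            two_frame=two_frame,
            probe_displacement_ok=bool(entry.get("probe_displacement_ok", True)),
        )
        dataset.add_trial(trial)
    dataset.validate()
    return dataset
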