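"""End-to-end analysis: raw session -> per-trial tendon properties ->
reliability / method-agreement / group-comparison reports."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datamodel import SessionDataset
from .errors import StatsError, TendonMetricsError, ValidationError
from .mechanics import frame_by_frame_curve, two_frame_properties
from .signals import synchronize
from .stats import (
    GroupComparison,
    MeasurementMatrix,
    ReliabilityReport,
    group_comparison,
    method_agreement,
    reliability_report,
)

#: tidy result columns, one row per (trial, method)
RESULT_COLUMNS = [
    "subject", "group", "day", "trial", "leg", "method",
    "f_max_n", "dl_measured_mm", "dl_max_mm", "strain_max_pct",
    "measured_strain_max_pct", "stiffness_index_kn_per_strain",
    "delta_theta_rad", "valid",
]

PARAMETERS = {
    "f_max_n": "N",
    "dl_max_mm": "mm",
    "strain_max_pct": "%",
    "stiffness_index_kn_per_strain": "kN/strain",
}


def analyze_session(
    dataset: SessionDataset, method: str = "two_frame"
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full per-trial analysis over a session.

    ``method`` is ``"two_frame"``, ``"frame_by_frame"`` or ``"both"``.
    Returns the tidy results table plus a list of per-trial failure
    messages (a failing trial is skipped, the run continues).
    """
    if method not in ("two_frame", "frame_by_frame", "both"):
        raise ValidationError(f"unknown method {method!r}")
    wanted = ("two_frame", "frame_by_frame") if method == "both" else (method,)
    rows, failures = [], []
    for key in sorted(dataset.trials):
        trial = dataset.trials[key]
        info, constants, group = dataset.subjects[trial.subject_id]
        try:
            aligned = synchronize(trial, positions_m=constants.load_cell_positions_m)
            for m in wanted:
                if m == "two_frame":
                    props = two_frame_properties(aligned, constants)
                else:
                    _, props = frame_by_frame_curve(aligned, constants)
                rows.append(
                    {
                        "subject": trial.subject_id,
                        "group": group,
                        "day": trial.day,
                        "trial": trial.trial,
                        "leg": trial.leg,
                        "method": m,
                        "f_max_n": props.f_max_n,
                        "dl_measured_mm": props.dl_measured_mm,
                        "dl_max_mm": props.dl_max_mm,
                        "strain_max_pct": props.strain_max_pct,
                        "measured_strain_max_pct": props.measured_strain_max_pct,
                        "stiffness_index_kn_per_strain":
                            props.stiffness_index_kn_per_strain,
                        "delta_theta_rad": props.delta_theta_rad,
                        "valid": props.valid,
                    }
                )
        except TendonMetricsError as exc:
            failures.append(f"trial {key}: {exc}")
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), failures


def results_matrix(
    results: pd.DataFrame, parameter: str, method: str = "two_frame"
) -> MeasurementMatrix:
    """Pivot tidy results into a subjects x trials grid for one parameter.

    Columns are ordered day-by-day, trial-by-trial (e.g. day-1 trials 1-4
    then day-2 trials 1-4); the column -> day mapping is preserved for the
    scope-aware statistics.
    """
    df = results[results["method"] == method]
    if df.empty:
        raise StatsError(f"no results for method {method!r}")
    pivot = df.pivot_table(
        index="subject", columns=["day", "trial"], values=parameter, sort=True
    )
    if pivot.isna().any().any():
        raise StatsError("incomplete subjects x trials grid")
    trial_days = tuple(int(day) for day, _ in pivot.columns)
    return MeasurementMatrix(
        values=pivot.to_numpy(),
        trial_days=trial_days,
        parameter=parameter,
        units=PARAMETERS.get(parameter, ""),
    )


def session_reliability(
    results: pd.DataFrame,
    method: str = "two_frame",
    parameters: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> ReliabilityReport:
    """Reliability report over all standard parameters of one method."""
    params = list(parameters) if parameters is not None else list(PARAMETERS)
    matrices = {p: results_matrix(results, p, method) for p in params}
    if any(m.values.shape[0] < 2 for m in matrices.values()):
        raise StatsError("reliability requires >= 2 subjects")
    return reliability_report(matrices, seed=seed)


def compare_methods(results: pd.DataFrame):
    """Method agreement on the *measured* (uncorrected) maximal strain,
    paired per trial, between the two-frame and frame-by-frame analyses."""
    a = results[results["method"] == "two_frame"]
    b = results[results["method"] == "frame_by_frame"]
    keys = ["subject", "day", "trial", "leg"]
    merged = a.merge(b, on=keys, suffixes=("_2f", "_fbf"))
    if merged.empty:
        raise StatsError("results contain no paired two-method trials")
    return method_agreement(
        merged["measured_strain_max_pct_2f"].to_numpy(),
        merged["measured_strain_max_pct_fbf"].to_numpy(),
    )


def select_group_values(
    results: pd.DataFrame, parameter: str = "stiffness_index_kn_per_strain"
) -> dict[str, np.ndarray]:
    """Per-subject summary values for the group comparison.

    Trial-selection rule (designed to be conservative): older adults
    contribute the mean of their four *strongest* trials (highest maximal
    force, either leg); elite athletes the mean of their four *weakest*
    trials; young non-active subjects the mean of all eight trials of the
    same leg.
    """
    out: dict[str, list[float]] = {}
    for (group, subject), df in results.groupby(["group", "subject"]):
        df = df[df["method"] == df["method"].iloc[0]]
        if group == "older":
            sel = df.nlargest(4, "f_max_n")
        elif group == "elite_athlete":
            sel = df.nsmallest(4, "f_max_n")
        else:
            leg = df["leg"].mode().iloc[0]
            sel = df[df["leg"] == leg]
        out.setdefault(group, []).append(float(sel[parameter].mean()))
    return {g: np.asarray(v) for g, v in out.items()}


def compare_groups(
    results: pd.DataFrame, parameter: str = "stiffness_index_kn_per_strain"
) -> tuple[GroupComparison, dict[str, np.ndarray]]:
    """Group-sensitivity analysis: trial selection, then one-way ANOVA with
    Bonferroni post-hocs."""
    values = select_group_values(results, parameter)
    return group_comparison(values), values
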