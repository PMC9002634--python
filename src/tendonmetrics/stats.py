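"""Test-retest reliability and agreement statistics.

Implements the statistical framework used to qualify a measurement method
in biomechanics: two-way repeated-measures ANOVA over trials and days,
intraclass correlation (two-way model, absolute agreement, single
measures - ICC(A,1)), within-subject coefficient of variation, RMS
differences, the Spearman-Brown prophecy for the minimum number of trials,
Pearson method agreement, one-way group ANOVA with Bonferroni post-hocs,
and a Monte-Carlo Lilliefors normality test.

Data enter as a :class:`MeasurementMatrix`: one parameter, subjects in rows
and trials in columns, with a column -> day mapping (e.g. trials 1-4 on day
one, trials 5-8 on day two).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError


@dataclass
class MeasurementMatrix:
    """Subjects x trials grid of one parameter."""

    values: np.ndarray                       # (n_subjects, n_trials)
    trial_days: tuple[int, ...]              # day of each column
    parameter: str = ""
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StatsError("values must be a 2-D subjects x trials grid")
        if len(self.trial_days) != self.values.shape[1]:
            raise StatsError("trial_days must map every column to a day")
        self.trial_days = tuple(int(d) for d in self.trial_days)

    def require_complete(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise StatsError(f"missing cells in matrix {self.parameter!r}")

    def scope_columns(self, scope: str) -> list[int]:
        days = sorted(set(self.trial_days))
        if scope == "overall":
            return list(range(len(self.trial_days)))
        if scope in ("day1", "day2"):
            want = days[int(scope[-1]) - 1]
            return [i for i, d in enumerate(self.trial_days) if d == want]
        raise StatsError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# ICC and Spearman-Brown
# ---------------------------------------------------------------------------

def _twoway_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way (subjects x trials) layout without
    replication: rows (subjects), columns (trials), residual."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return ms_rows, ms_cols, ms_err


def icc_a1(matrix: MeasurementMatrix | np.ndarray, columns=None) -> float:
    """Intraclass correlation, two-way model, absolute agreement, single
    measures:

    ``ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))``

    with ``MS_R`` the between-subject, ``MS_C`` the between-trial and
    ``MS_E`` the residual mean square of the two-way layout.
    """
    if isinstance(matrix, MeasurementMatrix):
        matrix.require_complete()
        x = matrix.values
    else:
        x = np.asarray(matrix, dtype=float)
        if not np.all(np.isfinite(x)):
            raise StatsError("missing cells in ICC input")
    if columns is not None:
        x = x[:, list(columns)]
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError("ICC requires >= 2 subjects and >= 2 trials")
    if np.allclose(x, x.flat[0]):
        raise StatsError("ICC undefined: zero total variance")
    ms_r, ms_c, ms_e = _twoway_mean_squares(x)
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise StatsError("ICC undefined: zero denominator")
    return float((ms_r - ms_e) / denom)


def icc_between_day(matrix: MeasurementMatrix) -> float:
    """Between-day ICC(A,1): day means per subject form a subjects x days
    grid that enters the single-measures formula."""
    matrix.require_complete()
    days = sorted(set(matrix.trial_days))
    if len(days) < 2:
        raise StatsError("between-day ICC requires >= 2 days")
    day_means = np.column_stack(
        [matrix.values[:, matrix.scope_columns(f"day{i+1}")].mean(axis=1)
         for i in range(len(days))]
    )
    return icc_a1(day_means)


@dataclass
class SpearmanBrown:
    k_exact: float
    floor: int
    ceil: int


def spearman_brown_trials(r: float, target: float = 0.9) -> SpearmanBrown:
    """Minimum number of averaged trials to reach ``target`` reliability
    given single-trial reliability ``r``:

    ``k = (target / (1 - target)) * ((1 - r) / r)``

    Returns the exact value plus its enclosing integer range (the practical
    "number of trials needed" bracket).
    """
    if not (0.0 < r < 1.0):
        raise StatsError("single-trial reliability must be in (0, 1)")
    if not (0.0 < target < 1.0):
        raise StatsError("target reliability must be in (0, 1)")
    k = (target / (1.0 - target)) * ((1.0 - r) / r)
    return SpearmanBrown(k_exact=float(k), floor=math.floor(k), ceil=math.ceil(k))


# ---------------------------------------------------------------------------
# CV and RMS differences
# ---------------------------------------------------------------------------

def cv_percent(matrix: MeasurementMatrix, scope: str = "overall") -> float:
    """Typical error as a percentage: per subject, 100 * SD / |mean| over the
    scope's trials (sample SD); the reported value is the mean across
    subjects."""
    matrix.require_complete()
    cols = matrix.scope_columns(scope)
    if len(cols) < 2:
        raise StatsError("CV requires >= 2 trials in scope")
    x = matrix.values[:, cols]
    means = x.mean(axis=1)
    if np.any(means == 0):
        raise StatsError("CV undefined: a subject mean is zero")
    cvs = 100.0 * x.std(axis=1, ddof=1) / np.abs(means)
    return float(cvs.mean())


def rms_difference(matrix: MeasurementMatrix, scope: str = "overall") -> float:
    """RMS difference in the parameter's own units.

    * ``day1``/``day2``: RMS over subjects and all within-day trial pairs;
    * ``within_day``: mean of the per-day values across days;
    * ``between_day``: RMS over subjects of (day-1 mean - day-2 mean);
    * ``overall``: RMS over subjects and *all* trial pairs pooled.
    """
    matrix.require_complete()
    x = matrix.values

    def pair_rms(cols: list[int]) -> float:
        diffs = [
            x[:, i] - x[:, j] for i, j in itertools.combinations(cols, 2)
        ]
        if not diffs:
            raise StatsError("scope has fewer than 2 trials")
        d = np.concatenate(diffs)
        return float(np.sqrt(np.mean(d**2)))

    if scope in ("day1", "day2", "overall"):
        return pair_rms(matrix.scope_columns(scope))
    if scope == "within_day":
        days = sorted(set(matrix.trial_days))
        return float(np.mean([pair_rms(matrix.scope_columns(f"day{i+1}"))
                              for i in range(len(days))]))
    if scope == "between_day":
        days = sorted(set(matrix.trial_days))
        if len(days) < 2:
            raise StatsError("between-day RMS requires 2 days")
        m1 = x[:, matrix.scope_columns("day1")].mean(axis=1)
        m2 = x[:, matrix.scope_columns("day2")].mean(axis=1)
        return float(np.sqrt(np.mean((m1 - m2) ** 2)))
    raise StatsError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (trial x day, subjects as random blocks)
# ---------------------------------------------------------------------------

def rm_anova_trial_day(matrix: MeasurementMatrix) -> pd.DataFrame:
    """Two-factor fully repeated-measures ANOVA with day and trial(within
    day) as within-subject factors.

    Each effect is tested against its interaction with subjects (the
    standard univariate repeated-measures error terms).  Returns a table
    with rows ``day``, ``trial`` and ``day x trial``.
    """
    matrix.require_complete()
    days = sorted(set(matrix.trial_days))
    a = len(days)
    per_day = [matrix.scope_columns(f"day{i+1}") for i in range(a)]
    b = len(per_day[0])
    if a < 2 or any(len(c) != b for c in per_day) or b < 2:
        raise StatsError("needs >= 2 days with equal numbers of trials (>= 2)")
    n = matrix.values.shape[0]
    if n < 2:
        raise StatsError("needs >= 2 subjects")
    # cube: subjects x days x trials-within-day
    y = np.stack([matrix.values[:, cols] for cols in per_day], axis=1)

    grand = y.mean()
    subj = y.mean(axis=(1, 2))
    day = y.mean(axis=(0, 2))
    tri = y.mean(axis=(0, 1))
    sd = y.mean(axis=2)          # subject x day
    st = y.mean(axis=1)          # subject x trial
    dt = y.mean(axis=0)          # day x trial

    ss_day = n * b * np.sum((day - grand) ** 2)
    ss_tri = n * a * np.sum((tri - grand) ** 2)
    ss_dt = n * np.sum((dt - day[:, None] - tri[None, :] + grand) ** 2)
    ss_sd = b * np.sum((sd - subj[:, None] - day[None, :] + grand) ** 2)
    ss_st = a * np.sum((st - subj[:, None] - tri[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_subj = a * b * np.sum((subj - grand) ** 2)
    ss_res = ss_tot - ss_subj - ss_day - ss_tri - ss_dt - ss_sd - ss_st

    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        ("day", ss_day, a - 1, ss_sd, (a - 1) * (n - 1)),
        ("trial", ss_tri, b - 1, ss_st, (b - 1) * (n - 1)),
        ("day x trial", ss_dt, (a - 1) * (b - 1), ss_res,
         (a - 1) * (b - 1) * (n - 1)),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            raise StatsError("degenerate model: zero residual variance")
        f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err))
        rows.append({"effect": name, "F": float(f), "df1": df_eff,
                     "df2": df_err, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparison, method agreement, normality
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame        # group_a, group_b, t, p_raw, p_bonferroni


def group_comparison(groups: dict[str, np.ndarray]) -> GroupComparison:
    """One-way ANOVA across subject groups with Bonferroni-corrected
    pairwise two-sample t-tests (raw p times the number of pairs, capped at
    1)."""
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise StatsError(f"group {g!r} has fewer than 2 values")
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        f_val, p_val = 0.0, 1.0
    else:
        f_val, p_val = sps.f_oneway(*arrays.values())
        f_val, p_val = float(f_val), float(p_val)
    names = sorted(arrays)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    for ga, gb in pairs:
        va, vb = arrays[ga], arrays[gb]
        if np.allclose(np.concatenate([va, vb]), va[0]):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(va, vb)
            t, p = float(t), float(p)
        rows.append({
            "group_a": ga, "group_b": gb, "t": t, "p_raw": p,
            "p_bonferroni": min(1.0, p * len(pairs)),
        })
    return GroupComparison(f_val, p_val, pd.DataFrame(rows))


@dataclass
class MethodAgreement:
    pearson_r: float
    pearson_p: float
    rms: float
    table: pd.DataFrame


def method_agreement(values_a, values_b) -> MethodAgreement:
    """Agreement between two methods measured on the same trials: Pearson r
    (strength of relationship) and RMS of the per-trial differences
    (absolute size of disagreement)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise StatsError("need paired 1-D samples of equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise StatsError("correlation undefined: zero variance")
    r, p = sps.pearsonr(a, b)
    rms = float(np.sqrt(np.mean((a - b) ** 2)))
    table = pd.DataFrame({"method_a": a, "method_b": b, "difference": a - b})
    return MethodAgreement(float(r), float(p), rms, table)


def lilliefors_normality(
    values, n_sims: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test for normality with estimated mean and SD
    (Lilliefors correction), p-value from a seeded Monte-Carlo null.

    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise StatsError("Lilliefors test requires n >= 4")
    if x.std(ddof=1) == 0:
        raise StatsError("normality test undefined: zero variance")

    def ks_stat(sample: np.ndarray) -> float:
        z = (np.sort(sample) - sample.mean()) / sample.std(ddof=1)
        cdf = sps.norm.cdf(z)
        n = sample.size
        upper = np.arange(1, n + 1) / n - cdf
        lower = cdf - np.arange(0, n) / n
        return float(max(upper.max(), lower.max()))

    d_obs = ks_stat(x)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_sims, x.size))
    # vectorized null distribution of the statistic
    z = np.sort(null, axis=1)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    n = x.size
    ranks_hi = np.arange(1, n + 1) / n
    ranks_lo = np.arange(0, n) / n
    d_null = np.maximum((ranks_hi - cdf).max(axis=1), (cdf - ranks_lo).max(axis=1))
    p = float((1 + np.sum(d_null >= d_obs)) / (1 + n_sims))
    return d_obs, p


# ---------------------------------------------------------------------------
# Full reliability report
# ---------------------------------------------------------------------------

SCOPES = ("day1", "day2", "between_day", "overall")


@dataclass
class ReliabilityReport:
    """Per-parameter reliability tables over a subjects x trials x days
    design, mirroring the usual descriptives / CV / RMS / ICC + K layout."""

    parameters: dict[str, dict] = field(default_factory=dict)
    sb_target: float = 0.9

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, d in self.parameters.items():
            row = {"parameter": name, "units": d.get("units", "")}
            row.update({f"icc_{s}": d["icc"].get(s) for s in SCOPES})
            row.update({f"cv_{s}_pct": d["cv"].get(s) for s in ("day1", "day2", "overall")})
            row.update({f"rms_{s}": d["rms"].get(s) for s in SCOPES})
            row["sb_k_exact"] = d["spearman_brown"].k_exact
            row["sb_k_floor"] = d["spearman_brown"].floor
            row["sb_k_ceil"] = d["spearman_brown"].ceil
            row["lilliefors_p"] = d["lilliefors_p"]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = []
        for name, d in self.parameters.items():
            sb = d["spearman_brown"]
            lines.append(f"{name} ({d.get('units', '')})")
            lines.append(
                "  ICC    day1 {day1:.2f}  day2 {day2:.2f}  between {between_day:.2f}"
                "  overall {overall:.2f}".format(**d["icc"])
            )
            lines.append(
                "  CV%    day1 {day1:.1f}  day2 {day2:.1f}  overall {overall:.1f}".format(
                    **d["cv"]
                )
            )
            lines.append(
                "  RMS    day1 {day1:.3g}  day2 {day2:.3g}  between {between_day:.3g}"
                "  overall {overall:.3g}".format(**d["rms"])
            )
            lines.append(
                f"  K      {sb.floor}-{sb.ceil} trials (k_exact {sb.k_exact:.2f}, "
                f"target {self.sb_target})"
            )
            anova = d["anova"]
            for _, r in anova.iterrows():
                lines.append(
                    f"  ANOVA  {r['effect']:<11} F({r['df1']},{r['df2']}) = "
                    f"{r['F']:.2f}, p = {r['p']:.3f}"
                )
        return "\n".join(lines)


def reliability_report(
    matrices: dict[str, MeasurementMatrix],
    sb_target: float = 0.9,
    seed: int = 0,
) -> ReliabilityReport:
    """Compute the full reliability table set for several parameters.

    The Spearman-Brown minimum-trials bracket is computed from the *overall*
    ICC (all trials pooled), which is the variant that reproduces the usual
    published K ranges.
    """
    report = ReliabilityReport(sb_target=sb_target)
    for name, m in matrices.items():
        m.require_complete()
        icc = {
            "day1": icc_a1(m, m.scope_columns("day1")),
            "day2": icc_a1(m, m.scope_columns("day2")),
            "between_day": icc_between_day(m),
            "overall": icc_a1(m),
        }
        cv = {s: cv_percent(m, s) for s in ("day1", "day2", "overall")}
        rms = {s: rms_difference(m, s) for s in SCOPES}
        if m.values.shape[0] >= 4:
            _, lillie_p = lilliefors_normality(m.values.mean(axis=1), seed=seed)
        else:
            lillie_p = float("nan")  # normality needs >= 4 subjects
        report.parameters[name] = {
            "units": m.units,
            "icc": icc,
            "cv": cv,
            "rms": rms,
            "spearman_brown": spearman_brown_trials(icc["overall"], sb_target),
            "anova": rm_anova_trial_day(m),
            "lilliefors_p": lillie_p,
        }
    return report
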