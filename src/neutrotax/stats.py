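"""Cohort statistics: group tests and C.I.–spirometry correlation.

Group comparisons use the pooled-variance two-sided Student's t-test (two
groups) or one-way ANOVA (three or more), both at α = 0.05 with no
multiple-testing correction.  The C.I.–spirometry relationship is ordinary
least squares of per-subject mean C.I. on FEV1/FVC, reported as slope sign
and r²; an exhaustive leave-one-out scan makes the small-cohort "n−1 of n
subjects correlate" observation reproducible and deterministic instead of a
by-inspection exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "StatResult",
    "RegressionResult",
    "load_table1",
    "records_from_frame",
    "two_sample_ttest",
    "one_way_anova",
    "regress_ci_on_spirometry",
    "leave_one_out_scan",
    "correlate_ci_speed",
]

log = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: demographics, spirometry, measured chemotaxis."""

    subject_id: str
    group: str  # COPD | control
    age: int
    sex: str
    fvc_l: float | None
    fev1_l: float | None
    fev1_fvc_pct: float | None
    ci_mean: float
    ci_sem: float
    speed_mean: float
    speed_sem: float

    def __post_init__(self) -> None:
        if self.group not in ("COPD", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if not -1.0 <= self.ci_mean <= 1.0:
            raise ValueError("ci_mean must be in [-1, 1]")
        if self.fvc_l is not None and self.fev1_l is not None:
            if not 0 < self.fev1_l <= self.fvc_l:
                raise ValueError("need 0 < FEV1 <= FVC")


@dataclass(frozen=True)
class StatResult:
    test_name: str
    statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    note: str = ""


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n: int
    subset_ids: tuple[str, ...] = ()
    excluded_id: str | None = None


def load_table1() -> list[SubjectRecord]:
    """Load the packaged per-subject clinical/chemotaxis table."""
    with resources.files("neutrotax.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Build subject records from a table with the packaged fixture's columns.

    Missing spirometry is encoded as "NA"/empty and maps to ``None``.
    """
    def opt(v):
        return None if pd.isna(v) else float(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                fvc_l=opt(row["FVC_L"]),
                fev1_l=opt(row["FEV1_L"]),
                fev1_fvc_pct=opt(row["FEV1_FVC_pct"]),
                ci_mean=float(row["ci_mean"]),
                ci_sem=float(row["ci_sem"]),
                speed_mean=float(row["speed_mean"]),
                speed_sem=float(row["speed_sem"]),
            )
        )
    return records


def two_sample_ttest(values_a, values_b, welch: bool = False) -> StatResult:
    """Two-sided Student's t-test; pooled variance unless ``welch``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        name = "welch_t"
    else:
        df = a.size + b.size - 2
        name = "student_t"
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return StatResult(name, float(t), float(df), float(p), bool(p < ALPHA))


def one_way_anova(groups) -> StatResult:
    """One-way ANOVA over three or more groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("ANOVA needs >= 3 groups; use the two-sample t-test for two")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    df1 = len(groups) - 1
    df2 = pooled.size - len(groups)
    if np.ptp(pooled) == 0:
        return StatResult("anova_f", float("nan"), df1, float("nan"), False,
                          note="zero variance in all groups")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    return StatResult("anova_f", float(f), float(df1), float(p), bool(p < ALPHA),
                      note=f"df=({df1},{df2})")


def _ols(x: np.ndarray, y: np.ndarray, subset_ids=(), excluded=None) -> RegressionResult:
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # zero-variance guard: no linear association measurable
        return RegressionResult(0.0, float(np.mean(y)), 0.0, 0.0, x.size,
                                tuple(subset_ids), excluded)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        subset_ids=tuple(subset_ids),
        excluded_id=excluded,
    )


def regress_ci_on_spirometry(
    records: list[SubjectRecord], subset: list[str] | None = None, excluded: str | None = None
) -> RegressionResult:
    """OLS of per-subject mean C.I. on FEV1/FVC (COPD subjects).

    Records without spirometry are excluded with a log entry.  ``subset``
    restricts to the named subject ids.
    """
    use = [r for r in records if subset is None or r.subject_id in subset]
    missing = [r.subject_id for r in use if r.fev1_fvc_pct is None]
    if missing:
        log.info("excluding subjects without spirometry: %s", ", ".join(missing))
    use = [r for r in use if r.fev1_fvc_pct is not None]
    if len(use) < 3:
        raise ValueError("need >= 3 records with spirometry")
    x = np.array([r.fev1_fvc_pct for r in use])
    y = np.array([r.ci_mean for r in use])
    return _ols(x, y, subset_ids=[r.subject_id for r in use], excluded=excluded)


def leave_one_out_scan(records: list[SubjectRecord]) -> list[RegressionResult]:
    """All n leave-one-out regressions, sorted by r² (desc), then excluded id.

    The first element identifies the maximizing subset — the reproducible
    counterpart of excluding one outlying subject by inspection.
    """
    with_spiro = [r for r in records if r.fev1_fvc_pct is not None]
    if len(with_spiro) < 4:
        raise ValueError("need >= 4 records with spirometry")
    results = []
    for r_out in with_spiro:
        keep = [r.subject_id for r in with_spiro if r.subject_id != r_out.subject_id]
        results.append(
            regress_ci_on_spirometry(with_spiro, subset=keep, excluded=r_out.subject_id)
        )
    results.sort(key=lambda r: (-r.r_squared, r.excluded_id))
    return results


def correlate_ci_speed(ci_values, speed_values) -> RegressionResult:
    """OLS of speed on C.I. (per track or per subject); near-zero r² means
    the two migration statistics carry independent information."""
    x = np.asarray(ci_values, dtype=float)
    y = np.asarray(speed_values, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired values")
    return _ols(x, y)
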