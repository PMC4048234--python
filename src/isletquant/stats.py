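"""Cohort-level statistics.

Per-patient aggregation uses the median of the per-islet values (even
counts: mean of the two middle values). Group contrasts use the classic
pooled-variance unpaired two-tailed t-test; association uses Pearson
correlation reported as r² with a two-tailed p from the t distribution
on n−2 degrees of freedom; regression-slope contrasts between the two
patient groups use ANCOVA fitted as one ordinary-least-squares model
with group, covariate and group×covariate terms, the interaction t-test
giving the slope-difference p. No multiple-testing correction is applied
anywhere; p < 0.05 is the significance convention throughout.

The estimators are implemented from the normal equations directly (with
scipy only supplying the t-distribution tail), so they can be checked
against independent library implementations in tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .errors import DegenerateDataError, ParameterError
from .types import IsletFeatures, PatientRecord, MARKERS


@dataclass(frozen=True)
class PatientAggregate:
    """Per-patient medians of the per-islet features for one marker."""

    patient_id: str
    group: str
    median_area_score: float
    n_islets: int
    median_islet_size: float | None = None
    median_beta_density: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: int


@dataclass(frozen=True)
class SlopeComparison:
    """Group-specific regression slopes and the interaction (difference) test."""

    groups: tuple[str, str]
    slopes: dict[str, float]
    interaction_t: float
    interaction_p: float

    def slope(self, group: str) -> float:
        return self.slopes[group]


@dataclass(frozen=True)
class CohortSummary:
    """Per-group clinical summary plus per-marker islet counts."""

    n_patients: dict[str, int]
    mean_age: dict[str, float]
    sd_age: dict[str, float]
    mean_bmi: dict[str, float]
    sd_bmi: dict[str, float]
    islet_totals: dict[str, int]            # per marker plus "overall"
    mean_islets_per_patient: dict[str, float]
    source_counts: dict[str, dict[str, int]]


def aggregate_patient(
    patient_id: str,
    group: str,
    features: list[IsletFeatures],
) -> PatientAggregate:
    """Collapse one patient's per-islet features to medians."""
    if not features:
        raise ParameterError(f"{patient_id}: no islet features to aggregate")
    scores = [f.area_score for f in features]
    sizes = [f.islet_size_px for f in features]
    dens = [f.beta_density for f in features]
    return PatientAggregate(
        patient_id=patient_id,
        group=group,
        median_area_score=float(np.median(scores)),
        median_islet_size=float(np.median(sizes)),
        median_beta_density=float(np.median(dens)),
        n_islets=len(features),
    )


def aggregate_scores(df: pd.DataFrame, value: str = "area_score") -> pd.DataFrame:
    """Per-patient median of ``value`` from a long per-islet table.

    Expects columns ``patient_id``, ``group`` and ``value`` (plus any
    others, ignored). Returns one row per patient.
    """
    for col in ("patient_id", "group", value):
        if col not in df.columns:
            raise ParameterError(f"missing column {col!r}")
    out = (
        df.groupby(["patient_id", "group"], sort=True)[value]
        .agg(["median", "size"])
        .reset_index()
        .rename(columns={"median": f"median_{value}", "size": "n_islets"})
    )
    return out


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with least-squares line and two-tailed p.

    p is derived from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and equally long")
    n = len(x)
    if n < 3:
        raise ParameterError(f"need at least 3 points, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateDataError("correlation undefined for constant input")
    sxy = float(dx @ dy)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r = sxy / np.sqrt(sxx * syy)
    r = min(1.0, max(-1.0, r))
    r2 = r * r
    if r2 >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r2))
        p = 2.0 * float(student_t.sf(abs(t), n - 2))
    return CorrelationResult(r2=float(r2), p_value=p, n=n, slope=float(slope),
                             intercept=intercept)


def ttest_unpaired(a, b, equal_var: bool = True) -> TTestResult:
    """Unpaired two-tailed t-test (pooled variance by default).

    ``equal_var=False`` switches to the Welch form with the
    Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ParameterError("each group needs at least 2 observations")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if equal_var:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 <= 0.0:
            raise DegenerateDataError("zero pooled variance; t-test undefined")
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se2 = va / na + vb / nb
        if se2 <= 0.0:
            raise DegenerateDataError("zero variance; t-test undefined")
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(student_t.sf(abs(t), df))
    return TTestResult(t=float(t), p_value=min(p, 1.0), df=df)


def ancova_slopes(x, y, group) -> SlopeComparison:
    """Compare regression slopes between two groups (ANCOVA interaction).

    Fits ``y ~ 1 + g + x + g·x`` by ordinary least squares, where ``g``
    indicates the second group. The per-group slope estimates equal the
    within-group least-squares slopes exactly, and ``interaction_p`` is
    the two-tailed p of the slope-difference (interaction) coefficient on
    n−4 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    group = np.asarray(group)
    if not (len(x) == len(y) == len(group)):
        raise ParameterError("x, y and group must be equally long")
    levels = list(dict.fromkeys(group.tolist()))  # order of first appearance
    if len(levels) != 2:
        raise ParameterError(f"need exactly two group levels, got {levels}")
    for lev in levels:
        sel = group == lev
        if sel.sum() < 3:
            raise ParameterError(f"group {lev!r} needs at least 3 points")
        if np.ptp(x[sel]) == 0:
            raise DegenerateDataError(f"group {lev!r} has constant covariate")
    g = (group == levels[1]).astype(np.float64)
    X = np.column_stack([np.ones_like(x), g, x, g * x])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise DegenerateDataError("design matrix is rank deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(y)
    dof = n - 4
    yscale = float(y @ y) / n + 1.0
    slopes = {levels[0]: float(beta[2]), levels[1]: float(beta[2] + beta[3])}
    if dof <= 0 or rss <= 1e-12 * yscale:
        # exact fit: the interaction is either exactly zero or exactly nonzero
        t_val = 0.0 if abs(beta[3]) <= 1e-12 * (abs(beta[2]) + 1.0) else np.inf
        p = 1.0 if t_val == 0.0 else 0.0
    else:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[3, 3]))
        t_val = float(beta[3] / se)
        p = 2.0 * float(student_t.sf(abs(t_val), dof))
    return SlopeComparison(
        groups=(str(levels[0]), str(levels[1])),
        slopes=slopes,
        interaction_t=float(t_val),
        interaction_p=min(p, 1.0),
    )


def summarize_cohort(records: list[PatientRecord]) -> CohortSummary:
    """Per-group clinical summary and per-marker islet totals."""
    if not records:
        raise ParameterError("no patient records to summarize")
    groups = sorted({r.group for r in records})
    n_patients, mean_age, sd_age, mean_bmi, sd_bmi = {}, {}, {}, {}, {}
    source_counts: dict[str, dict[str, int]] = {}
    for grp in groups:
        sub = [r for r in records if r.group == grp]
        ages = np.array([r.age for r in sub], dtype=float)
        bmis = np.array([r.bmi for r in sub], dtype=float)
        n_patients[grp] = len(sub)
        mean_age[grp] = float(ages.mean())
        sd_age[grp] = float(ages.std(ddof=1)) if len(sub) > 1 else 0.0
        mean_bmi[grp] = float(bmis.mean())
        sd_bmi[grp] = float(bmis.std(ddof=1)) if len(sub) > 1 else 0.0
        counts: dict[str, int] = {}
        for r in sub:
            counts[r.source] = counts.get(r.source, 0) + 1
        source_counts[grp] = counts
    totals = {
        marker: sum(getattr(r, f"n_islets_{marker}") for r in records)
        for marker in MARKERS
    }
    totals["overall"] = sum(totals[m] for m in MARKERS)
    n_all = len(records)
    per_patient = {m: totals[m] / n_all for m in MARKERS}
    return CohortSummary(
        n_patients=n_patients,
        mean_age=mean_age,
        sd_age=sd_age,
        mean_bmi=mean_bmi,
        sd_bmi=sd_bmi,
        islet_totals=totals,
        mean_islets_per_patient=per_patient,
        source_counts=source_counts,
    )
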