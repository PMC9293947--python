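"""Cohort-level statistics for hypomimia markers.

Covers the analysis pipeline applied to a marker table: normality-gated
group tests with Bonferroni correction over the 19 sided comparisons,
age-controlled Pearson partial correlations between side-averaged markers
and clinical covariates, and control-percentile abnormality cutoffs with
per-region affected-area counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .markers import (
    MARKER_CATALOGUE,
    REGION_MARKERS,
    REGIONS,
    MarkerDef,
    averaged_marker_names,
    sided_marker_names,
)

__all__ = [
    "GroupTestResult",
    "PartialCorrelationResult",
    "normality_check",
    "group_difference",
    "bonferroni_alpha",
    "comparison_count",
    "partial_correlation_age",
    "ControlPercentileCutoff",
    "control_cutoffs",
    "affected_areas",
    "group_difference_table",
    "correlation_table",
    "abnormality_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupTestResult:
    marker: str
    test: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    p_value: float
    significant_after_bonferroni: bool


@dataclass(frozen=True)
class PartialCorrelationResult:
    marker: str
    covariate: str
    r: float
    p_value: float
    n: int


def normality_check(values, alpha: float = 0.05, lilliefors: bool = False) -> bool:
    """One-sample Kolmogorov-Smirnov normality gate.

    The sample is standardised by its own mean and SD and compared with the
    standard normal; "normal" means p >= alpha.  Estimating the parameters
    from the sample makes the plain KS test anti-conservative (it accepts
    normality too readily); set ``lilliefors=True`` for the corrected
    small-sample critical values (Dallal-Wilkinson approximation).
    Zero-variance samples are non-normal by convention.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 4:
        raise ValueError("normality check needs at least 4 values")
    sd = values.std(ddof=1)
    if sd <= 0:
        return False
    z = (values - values.mean()) / sd
    d, p = sps.kstest(z, "norm")
    if lilliefors:
        p = _lilliefors_pvalue(d, values.size)
    return bool(p >= alpha)


def _lilliefors_pvalue(d: float, n: int) -> float:
    """Dallal-Wilkinson approximation to the Lilliefors p-value."""
    if n > 100:
        d = d * (n / 100.0) ** 0.49
        n = 100
    p = math.exp(-7.01256 * d * d * (n + 2.78019)
                 + 2.99587 * d * math.sqrt(n + 2.78019)
                 - 0.122119 + 0.974598 / math.sqrt(n) + 1.67997 / n)
    return min(1.0, max(0.0, p))


def group_difference(values, labels, adjusted_alpha: float = 0.05,
                     lilliefors: bool = False, marker: str = "") -> GroupTestResult:
    """PD-vs-HC difference test for one marker.

    One-way ANOVA when both groups pass the normality gate, Kruskal-Wallis
    otherwise (robust to outliers and skew).  A zero-variance group under
    ANOVA falls back to Kruskal-Wallis.  Two-sided p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    groups = [values[labels == g] for g in ("PD", "HC")]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 subjects per group")

    use_anova = all(
        len(g) >= 4 and normality_check(g, lilliefors=lilliefors) for g in groups
    )
    if use_anova and any(g.std(ddof=1) <= 0 for g in groups):
        logger.info("zero-variance group for %s; falling back to Kruskal-Wallis", marker)
        use_anova = False
    if use_anova:
        stat, p = sps.f_oneway(*groups)
        test = "ANOVA"
    else:
        stat, p = sps.kruskal(*groups)
        test = "Kruskal-Wallis"
    return GroupTestResult(marker=marker, test=test, statistic=float(stat),
                           p_value=float(p),
                           significant_after_bonferroni=bool(p < adjusted_alpha))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison significance level alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be at least 1")
    return alpha / m


def comparison_count(catalogue: list[MarkerDef] | None = None) -> int:
    """Number of group comparisons: one per midline marker, two per
    bilateral marker (19 for the full twelve-marker catalogue)."""
    if catalogue is None:
        catalogue = MARKER_CATALOGUE
    return sum(2 if m.bilateral else 1 for m in catalogue)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, x]."""
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_correlation_age(x, y, age, marker: str = "",
                            covariate: str = "") -> PartialCorrelationResult:
    """Pearson partial correlation of x and y controlling for age.

    Both variables are residualised on age by OLS (with intercept) and the
    Pearson correlation of the residuals is tested with
    t = r * sqrt((n-3) / (1-r^2)) on n-3 degrees of freedom (one df spent
    on the age control), two-sided.  Constant age reduces to the plain
    Pearson correlation on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(age))
    x, y, age = x[keep], y[keep], age[keep]
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs at least 4 complete cases")

    if age.std() <= 0:
        logger.info("constant age; falling back to plain Pearson correlation")
        rx, ry = x, y
        dof = n - 2
    else:
        rx = _residualize(x, age)
        ry = _residualize(y, age)
        dof = n - 3

    sx, sy = rx.std(), ry.std()
    if sx <= 0 or sy <= 0:
        return PartialCorrelationResult(marker, covariate, math.nan, math.nan, n)
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), dof)
    return PartialCorrelationResult(marker, covariate, r, float(p), n)


class ControlPercentileCutoff(BaseEstimator, TransformerMixin):
    """Normative abnormality cutoffs from the control group.

    Fit on the control subjects' marker table; for each marker the cutoff
    is the empirical percentile (linear interpolation) in the direction of
    impairment.  All hypomimia markers *decrease* with disease, so the
    operational 5% tail is the 5th percentile of controls with values
    below it abnormal (``direction='low'``); ``direction='high'`` gives
    the literal above-95th-percentile rule for markers that increase.

    Parameters
    ----------
    percentile : float
        Tail probability in percent (default 5.0).
    direction : {'low', 'high'}
        Side of the control distribution that counts as abnormal.
    min_controls : int
        Minimum control sample per marker (default 20).

    Attributes
    ----------
    cutoffs_ : pd.Series
        Per-marker cutoff values.
    """

    def __init__(self, percentile: float = 5.0, direction: str = "low",
                 min_controls: int = 20):
        self.percentile = percentile
        self.direction = direction
        self.min_controls = min_controls

    def fit(self, X: pd.DataFrame, y=None) -> "ControlPercentileCutoff":
        if self.direction not in ("low", "high"):
            raise ValueError("direction must be 'low' or 'high'")
        X = pd.DataFrame(X)
        cutoffs = {}
        for col in X.columns:
            vals = X[col].dropna().to_numpy(dtype=float)
            if vals.size < self.min_controls:
                raise ValueError(
                    f"marker {col!r}: {vals.size} controls < required {self.min_controls}")
            q = self.percentile if self.direction == "low" else 100.0 - self.percentile
            cutoffs[col] = float(np.percentile(vals, q))
        self.cutoffs_ = pd.Series(cutoffs)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean abnormality flags per subject and marker (NaN-safe:
        missing markers yield missing flags)."""
        check_is_fitted(self, "cutoffs_")
        X = pd.DataFrame(X)[list(self.cutoffs_.index)]
        if self.direction == "low":
            flags = X.lt(self.cutoffs_, axis=1)
        else:
            flags = X.gt(self.cutoffs_, axis=1)
        return flags.where(X.notna())

    def affected_regions(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-subject region flags and affected-area counts.

        A region is affected when ANY of its pooled markers is abnormal
        (the mouth region pools upper lip, lower lip and mouth corner; the
        eyebrow region pools its three markers).  Regions whose markers
        are all missing are excluded from the count.
        """
        flags = self.transform(X)
        out = {}
        for region in REGIONS:
            cols = [c for c in REGION_MARKERS[region] if c in flags.columns]
            if not cols:
                out[region] = pd.Series(np.nan, index=flags.index)
                continue
            sub = flags[cols]
            any_abn = sub.eq(True).any(axis=1)
            all_missing = sub.isna().all(axis=1)
            out[region] = any_abn.astype(float).where(~all_missing)
        regions = pd.DataFrame(out)
        regions["affected_region_count"] = regions[REGIONS].sum(axis=1, skipna=True).astype(int)
        return regions


def control_cutoffs(control_table: pd.DataFrame, percentile: float = 5.0,
                    direction: str = "low") -> pd.Series:
    """Per-marker normative cutoffs from a control marker table."""
    return ControlPercentileCutoff(percentile=percentile, direction=direction).fit(
        control_table).cutoffs_


def affected_areas(subject_markers: pd.Series | pd.DataFrame,
                   cutoffs: pd.Series, direction: str = "low") -> pd.DataFrame:
    """Region abnormality flags + affected-area count for subjects.

    Thin wrapper over ControlPercentileCutoff.affected_regions with
    precomputed cutoffs.
    """
    model = ControlPercentileCutoff(direction=direction)
    model.cutoffs_ = cutoffs
    model.feature_names_in_ = np.asarray(cutoffs.index, dtype=object)
    if isinstance(subject_markers, pd.Series):
        subject_markers = subject_markers.to_frame().T
    return model.affected_regions(subject_markers)


# ---------------------------------------------------------------------------
# table-level drivers

def group_difference_table(marker_table: pd.DataFrame, groups: pd.Series,
                           alpha: float = 0.05,
                           lilliefors: bool = False) -> pd.DataFrame:
    """Group tests for every sided marker with Bonferroni adjustment.

    The adjusted level is alpha divided by the number of comparisons
    actually made (19 for the full catalogue: twelve markers of which
    seven have left and right variants).
    """
    cols = [c for c in sided_marker_names()
            if c in marker_table.columns and marker_table[c].notna().sum() >= 4]
    adjusted = bonferroni_alpha(alpha, len(cols)) if cols else alpha
    rows = []
    for col in cols:
        res = group_difference(marker_table[col], groups, adjusted_alpha=adjusted,
                               lilliefors=lilliefors, marker=col)
        rows.append({
            "marker": col, "test": res.test, "statistic": res.statistic,
            "p_value": res.p_value, "adjusted_alpha": adjusted,
            "significant_after_bonferroni": res.significant_after_bonferroni,
        })
    return pd.DataFrame(rows)


def correlation_table(averaged_table: pd.DataFrame, covariates: pd.DataFrame,
                      age: pd.Series) -> pd.DataFrame:
    """Age-controlled partial correlations: averaged markers x covariates.

    Complete-case per pair; covariate columns with fewer than 4 complete
    cases are skipped.
    """
    rows = []
    for marker in averaged_marker_names():
        col = f"avg_{marker}" if f"avg_{marker}" in averaged_table.columns else marker
        if col not in averaged_table.columns:
            continue
        for cov in covariates.columns:
            x = averaged_table[col].to_numpy(dtype=float)
            y = covariates[cov].to_numpy(dtype=float)
            a = age.to_numpy(dtype=float)
            keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(a))
            if keep.sum() < 4:
                continue
            res = partial_correlation_age(x, y, a, marker=marker, covariate=cov)
            rows.append({"marker": marker, "covariate": cov, "r": res.r,
                         "p_value": res.p_value, "n": res.n})
    return pd.DataFrame(rows)


def abnormality_table(marker_table: pd.DataFrame, groups: pd.Series,
                      percentile: float = 5.0,
                      direction: str = "low") -> pd.DataFrame:
    """Fit cutoffs on controls and flag affected regions for all subjects.

    Markers absent from the table or never computed for any control (e.g.
    surface markers of a landmarks-only run) are excluded; their regions
    are then evaluated on the remaining markers.
    """
    avg_cols = [f"avg_{m}" for m in averaged_marker_names()
                if f"avg_{m}" in marker_table.columns]
    # cutoffs are defined on the side-averaged markers
    renamed = marker_table[avg_cols].rename(columns=lambda c: c.removeprefix("avg_"))
    controls = renamed[np.asarray(groups) == "HC"]
    computed = [c for c in renamed.columns if controls[c].notna().any()]
    model = ControlPercentileCutoff(percentile=percentile, direction=direction)
    model.fit(controls[computed])
    return model.affected_regions(renamed[computed])
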