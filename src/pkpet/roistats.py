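"""Composite-region aggregation and the group-comparison statistical battery.

Regions of interest are volume-weighted composites of anatomical subregions
(probability-map style delineation).  The statistics cover one-way ANOVA
(also reconstructible from printed group summaries), ANCOVA with age as
covariate, MANOVA (Wilks' lambda) across the five regional ROIs, Levene's
test, Pearson correlation, the 2x2 chi-square for gender, Bonferroni
correction, and the two-group normal-approximation sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import REGIONAL_ROIS, ROI_NAMES
from .kinetics import InputError, ValidationError

__all__ = [
    "RoiDefinition",
    "StatResult",
    "PowerSpec",
    "default_roi_definitions",
    "default_label_ids",
    "composite_roi_mean",
    "anova_oneway",
    "anova_from_summary",
    "ancova_group",
    "manova_rois",
    "levene_test",
    "pearson_corr",
    "chi2_2x2",
    "bonferroni_adjust",
    "sample_size_two_groups",
    "group_report",
]

# anatomical subregions making up each composite ROI
_ROI_SUBREGIONS = {
    "frontal": (
        "anterior_cingulate", "gyrus_rectus", "orbitofrontal", "precentral",
        "superior_frontal", "middle_frontal", "inferior_frontal",
    ),
    "temporal": (
        "hippocampus", "anterior_temporal", "posterior_temporal",
        "parahippocampal_ambient", "superior_temporal", "middle_temporal",
        "inferior_temporal", "fusiform",
    ),
    "parietal": (
        "posterior_cingulate", "postcentral", "superior_parietal",
        "inferolateral_parietal",
    ),
    "striatum": ("caudate_nucleus", "putamen"),
    "thalamus": ("thalamus",),
}
_ROI_SUBREGIONS["total_gray"] = tuple(
    s for roi in REGIONAL_ROIS for s in _ROI_SUBREGIONS[roi]
)


@dataclass(frozen=True)
class RoiDefinition:
    """A named composite region: volume-weighted average of subregions."""

    name: str
    subregions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValidationError(f"unknown ROI name {self.name!r}")
        if len(set(self.subregions)) != len(self.subregions) or not self.subregions:
            raise ValidationError("subregions must be non-empty and unique")


def default_roi_definitions() -> dict[str, RoiDefinition]:
    """The six composite ROIs and their subregion lists."""
    return {name: RoiDefinition(name, subs) for name, subs in _ROI_SUBREGIONS.items()}


def default_label_ids() -> dict[str, int]:
    """Stable integer label for every anatomical subregion (1-based)."""
    names = _ROI_SUBREGIONS["total_gray"]
    return {name: i + 1 for i, name in enumerate(names)}


def composite_roi_mean(
    map3d: np.ndarray,
    roi: RoiDefinition,
    labels: np.ndarray,
    label_ids: dict[str, int] | None = None,
    voxel_volume: float = 1.0,
) -> float:
    """Volume-weighted composite mean of a parametric map over one ROI.

    Each subregion contributes its mean over non-NaN voxels, weighted by its
    (non-NaN) voxel volume; NaN voxels drop out together with their volume
    share.  Missing or all-NaN subregions raise with the offending name.
    """
    map3d = np.asarray(map3d, dtype=float)
    labels = np.asarray(labels)
    if labels.shape != map3d.shape:
        raise InputError("labels volume must match the map shape")
    if label_ids is None:
        label_ids = default_label_ids()
    num = 0.0
    den = 0.0
    for sub in roi.subregions:
        if sub not in label_ids:
            raise InputError(f"no label id for subregion {sub!r}")
        sel = labels == label_ids[sub]
        if not np.any(sel):
            raise InputError(f"subregion {sub!r} absent from the label volume")
        vals = map3d[sel]
        ok = np.isfinite(vals)
        if not np.any(ok):
            raise InputError(f"subregion {sub!r} contains only missing values")
        vol = ok.sum() * voxel_volume
        num += vals[ok].mean() * vol
        den += vol
    return num / den


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    """One test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: tuple[float, ...]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError("p-value must lie in [0, 1]")


def _as_groups(values_by_group) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InputError("need at least two groups with n >= 2 each")
    return groups


def anova_oneway(values_by_group) -> StatResult:
    """Classical one-way fixed-effects F test."""
    groups = _as_groups(values_by_group)
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return StatResult(0.0, (df1, df2), 1.0, "anova_oneway")
        return StatResult(np.inf, (df1, df2), 0.0, "anova_oneway")
    f = (ssb / df1) / (ssw / df2)
    return StatResult(float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), "anova_oneway")


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """One-way F reconstructed from two groups' printed means, SDs and sizes.

    Identical to :func:`anova_oneway` on any dataset with exactly those
    moments.
    """
    if n1 < 2 or n2 < 2:
        raise InputError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InputError("SDs must be non-negative")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ssw = (n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2
    df1, df2 = 1, n - 2
    if ssw == 0.0:
        if ssb == 0.0:
            return StatResult(0.0, (df1, df2), 1.0, "anova_from_summary")
        return StatResult(np.inf, (df1, df2), 0.0, "anova_from_summary")
    f = ssb / (ssw / df2)
    return StatResult(float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), "anova_from_summary")


def _glm_group_f(y: np.ndarray, x: np.ndarray, n_params: int) -> tuple[float, float, int]:
    """F for dropping the group column (index 1) from a linear model."""
    n = y.size
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise InputError("design matrix is rank deficient (collinear group/age)")
    rss_full = float(((y - x @ beta) ** 2).sum())
    x0 = np.delete(x, 1, axis=1)
    beta0, _, _, _ = np.linalg.lstsq(x0, y, rcond=None)
    rss_red = float(((y - x0 @ beta0) ** 2).sum())
    df2 = n - n_params
    tiny = 1e-12 * max(float(y @ y), 1.0)
    if rss_full <= tiny:
        # perfect fit: the group term adds nothing unless it alone explains y
        f = 0.0 if rss_red - rss_full <= tiny else np.inf
    else:
        f = (rss_red - rss_full) / (rss_full / df2)
    return f, rss_full, df2


def ancova_group(values, group, age) -> StatResult:
    """Group effect F from the linear model ``value ~ group + age``.

    Single-df type-III group term (equivalently the extra-sum-of-squares F
    for dropping group), df = (1, n - 3).
    """
    y = np.asarray(values, dtype=float)
    g = _binary_group(group)
    a = np.asarray(age, dtype=float)
    if y.size < 4 or y.shape != g.shape or y.shape != a.shape:
        raise InputError("need n >= 4 matched values, groups and ages")
    if np.ptp(a) == 0:
        raise InputError("age does not vary")
    x = np.column_stack([np.ones_like(y), g, a])
    f, _, df2 = _glm_group_f(y, x, 3)
    return StatResult(float(f), (1, df2), float(sps.f.sf(f, 1, df2)), "ancova_group")


def _binary_group(group) -> np.ndarray:
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise InputError("group must have exactly two levels")
    return (g == levels[1]).astype(float)


def manova_rois(roi_matrix, group, age=None) -> StatResult:
    """Wilks' lambda for the group effect across ROI columns, age-adjusted.

    Multivariate linear model ``Y ~ 1 + group (+ age)``; the hypothesis SSCP
    for the single-df group contrast gives ``lambda = det(E)/det(E + H)``
    which, for one hypothesis df, converts exactly to
    ``F = (1 - lambda)/lambda * (ve - p + 1)/p`` on (p, ve - p + 1) df.
    """
    y = np.atleast_2d(np.asarray(roi_matrix, dtype=float))
    if y.ndim != 2:
        raise InputError("roi_matrix must be 2-D (subjects x ROIs)")
    n, p = y.shape
    if n <= 7:
        raise InputError("need more than 7 subjects")
    g = _binary_group(group)
    cols = [np.ones(n), g]
    if age is not None:
        a = np.asarray(age, dtype=float)
        if np.ptp(a) == 0:
            raise InputError("age does not vary")
        cols.append(a)
    x = np.column_stack(cols)
    if g.shape != (n,) or (age is not None and np.asarray(age).shape != (n,)):
        raise InputError("group/age length must match roi_matrix rows")
    r = x.shape[1]
    xtx = x.T @ x
    if np.linalg.matrix_rank(x) < r:
        raise InputError("design matrix is rank deficient")
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    e = resid.T @ resid
    c = np.zeros(r)
    c[1] = 1.0  # the group contrast
    cb = c @ beta                              # (p,)
    m = c @ np.linalg.solve(xtx, c)            # scalar: c (X'X)^-1 c'
    h = np.outer(cb, cb) / m
    ve = n - r
    if ve <= p or np.linalg.matrix_rank(e) < p:
        raise InputError(
            "within-group covariance is singular; more subjects (or fewer ROIs) needed"
        )
    lam = float(np.linalg.det(e) / np.linalg.det(e + h))
    df1 = p
    df2 = ve - p + 1
    f = (1.0 - lam) / lam * df2 / df1
    return StatResult(float(f), (df1, df2), float(sps.f.sf(f, df1, df2)), "manova_wilks")


def levene_test(values_by_group, center: str = "mean") -> StatResult:
    """Levene's test for equality of variances.

    Classical (mean-centered) Levene by default: a one-way ANOVA on absolute
    deviations from the group mean.  ``center='median'`` gives the
    Brown-Forsythe variant.
    """
    groups = _as_groups(values_by_group)
    if center == "mean":
        devs = [np.abs(g - g.mean()) for g in groups]
    elif center == "median":
        devs = [np.abs(g - np.median(g)) for g in groups]
    else:
        raise ValidationError("center must be 'mean' or 'median'")
    res = anova_oneway(devs)
    return StatResult(res.statistic, res.df, res.p_value, f"levene_{center}")


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise InputError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def chi2_2x2(table) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise InputError("expected a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InputError("all row and column margins must be positive")
    n = t.sum()
    a, b = t[0]
    c, d = t[1]
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return StatResult(float(chi2), (1,), float(sps.chi2.sf(chi2, 1)), "chi2_2x2")


def bonferroni_adjust(p_values, m: int) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, p * m)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m < 1:
        raise ValidationError("number of comparisons must be at least 1")
    if m < p.size:
        raise ValidationError("m must be at least the number of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


@dataclass(frozen=True)
class PowerSpec:
    """Two-group design for the sample-size calculation (BP_ND units)."""

    mu1: float = 0.07
    mu2: float = 0.18
    sigma1: float = 0.10
    sigma2: float = 0.08
    alpha: float = 0.01
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValidationError("sigmas must be positive")
        if self.mu1 == self.mu2:
            raise ValidationError("group means must differ (n would be infinite)")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")


def sample_size_two_groups(spec: PowerSpec) -> tuple[int, float]:
    """Per-group n for a two-sided two-sample comparison, normal approximation.

    ``n = ceil( (z_{1-alpha/2} + z_{power})^2 (sigma1^2 + sigma2^2) / (mu1 - mu2)^2 )``.
    Also returns the approximate achieved power at that n.
    """
    z_a = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sps.norm.ppf(spec.power)
    var = spec.sigma1 ** 2 + spec.sigma2 ** 2
    delta2 = (spec.mu1 - spec.mu2) ** 2
    n = math.ceil((z_a + z_b) ** 2 * var / delta2)
    achieved = float(sps.norm.cdf(math.sqrt(n * delta2 / var) - z_a))
    return n, achieved


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def group_report(
    subjects: pd.DataFrame,
    rois: tuple[str, ...] = ROI_NAMES,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Run the full between-group battery on a subject table.

    Per ROI: one-way ANOVA and age-adjusted ANCOVA, plus Levene's variance
    test; across the five regional ROIs: MANOVA (Wilks); gender chi-square;
    Bonferroni adjustment of the per-ROI ANCOVA p-values.  Returns a tidy
    rows table and a JSON-ready summary dict.
    """
    ctrl = subjects[subjects["group"] == "control"]
    pat = subjects[subjects["group"] == "patient"]
    rows = []
    ancova_ps = []
    for roi in rois:
        col = f"bpnd_{roi}"
        a = anova_oneway([ctrl[col].to_numpy(), pat[col].to_numpy()])
        rows.append({"test": "anova", "roi": roi, "statistic": a.statistic,
                     "df1": a.df[0], "df2": a.df[1], "p": a.p_value})
        anc = ancova_group(
            subjects[col].to_numpy(), subjects["group"].to_numpy(), subjects["age"].to_numpy()
        )
        ancova_ps.append(anc.p_value)
        rows.append({"test": "ancova_age", "roi": roi, "statistic": anc.statistic,
                     "df1": anc.df[0], "df2": anc.df[1], "p": anc.p_value})
        lev = levene_test([ctrl[col].to_numpy(), pat[col].to_numpy()])
        rows.append({"test": "levene", "roi": roi, "statistic": lev.statistic,
                     "df1": lev.df[0], "df2": lev.df[1], "p": lev.p_value})
    p_adj = bonferroni_adjust(ancova_ps, len(rois))
    report = pd.DataFrame(rows)
    report["p_bonferroni"] = np.nan
    for roi, padj in zip(rois, p_adj):
        report.loc[(report["test"] == "ancova_age") & (report["roi"] == roi),
                   "p_bonferroni"] = padj

    regional = [r for r in rois if r != "total_gray"]
    y = subjects[[f"bpnd_{r}" for r in regional]].to_numpy()
    man = manova_rois(y, subjects["group"].to_numpy(), subjects["age"].to_numpy())
    gender = pd.crosstab(subjects["group"], subjects["gender"])
    chi = chi2_2x2(gender.to_numpy())
    summary = {
        "n_control": int(len(ctrl)),
        "n_patient": int(len(pat)),
        "alpha": alpha,
        "manova_wilks_f": man.statistic,
        "manova_df": list(man.df),
        "manova_p": man.p_value,
        "gender_chi2": chi.statistic,
        "gender_chi2_p": chi.p_value,
        "any_roi_significant_bonferroni": bool(np.any(p_adj < alpha)),
    }
    return report, summary
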