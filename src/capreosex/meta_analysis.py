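"""Pooling of study-level sex-ratio effect sizes.

Implements inverse-variance fixed-effect pooling, random-effects pooling with
the DerSimonian-Laird moment estimator or REML for the between-study variance
tau^2, Cochran's Q and both flavours of the I^2 heterogeneity index, an
unweighted (optionally inverse-variance weighted) spatial meta-regression of
effect size on latitude/longitude with quadratic terms, and funnel-plot data
export with pseudo-confidence contours.

Effect sizes enter on the standardized log-odds (d) scale computed by
:mod:`capreosex.core_stats`; a negative pooled d indicates a male-biased sex
ratio across studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core_stats import SexRatioCount, effect_size_d

__all__ = [
    "StudyRecord",
    "MetaResult",
    "MetaRegressionResult",
    "FunnelPoint",
    "effect_table",
    "fixed_effect_pool",
    "random_effects_pool",
    "heterogeneity",
    "meta_regression",
    "spatial_regression",
    "funnel_data",
    "merge_by_reference",
]

Method = Literal["fixed", "DL", "REML"]


@dataclass(frozen=True)
class StudyRecord:
    """One data set in the meta-analysis.

    ``ratio_type`` is "P" for prenatal (fetal) sex ratios and "S" for
    secondary (at-birth) sex ratios; ``living_condition`` is "F"
    (free-ranging), "FI" (island/fenced/isolated) or "E" (enclosure).
    """

    id: str
    reference_id: str
    counts: SexRatioCount
    country: str = ""
    location: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    living_condition: str = ""
    ratio_type: str = ""
    max_offspring_age_days: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if self.ratio_type not in ("", "P", "S"):
            raise ValueError(f"ratio_type must be 'P' or 'S', got {self.ratio_type!r}")


@dataclass(frozen=True)
class MetaResult:
    pooled_d: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    df: int
    i2_q: float
    i2_tau: float
    method: str
    k: int


@dataclass(frozen=True)
class MetaRegressionResult:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    k: int
    weighted: bool

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])


@dataclass(frozen=True)
class FunnelPoint:
    id: str
    d: float
    se: float


def effect_table(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    """Per-study effect sizes and variances as a DataFrame (one row per study)."""
    rows = []
    for s in studies:
        es = effect_size_d(s.counts)
        rows.append(
            {
                "id": s.id,
                "d": es.d,
                "var_d": es.var_d,
                "se_d": es.se_d,
                "ci_low": es.ci_low,
                "ci_high": es.ci_high,
                "n": s.counts.n_total,
            }
        )
    return pd.DataFrame(rows)


def _d_v(studies: Sequence[StudyRecord]) -> tuple[np.ndarray, np.ndarray]:
    es = [effect_size_d(s.counts) for s in studies]
    return np.array([e.d for e in es]), np.array([e.var_d for e in es])


def _typical_within_variance(v: np.ndarray) -> float:
    # Higgins' "typical" within-study variance s^2 used in the tau2-based I2.
    w = 1.0 / v
    k = len(v)
    return float((k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum()))


def _pool(d: np.ndarray, v: np.ndarray, tau2: float, method: str) -> MetaResult:
    k = len(d)
    w_fixed = 1.0 / v
    pooled_fixed = float((w_fixed * d).sum() / w_fixed.sum())
    Q = float((w_fixed * (d - pooled_fixed) ** 2).sum())
    df = k - 1
    i2_q = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    if k > 1:
        s2 = _typical_within_variance(v)
        i2_tau = 100.0 * tau2 / (tau2 + s2)
    else:
        i2_tau = 0.0
    w = 1.0 / (v + tau2)
    pooled = float((w * d).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = stats.norm.ppf(0.975)
    return MetaResult(
        pooled_d=pooled,
        se=se,
        ci_low=pooled - z * se,
        ci_high=pooled + z * se,
        tau2=tau2,
        Q=Q,
        df=df,
        i2_q=i2_q,
        i2_tau=i2_tau,
        method=method,
        k=k,
    )


def fixed_effect_pool(studies: Sequence[StudyRecord]) -> MetaResult:
    """Inverse-variance fixed-effect pooled estimate.

    Weights are w_i = 1/var_i; the pooled standard error is (sum w_i)^(-1/2)
    and the 95% interval uses the normal multiplier.
    """
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    d, v = _d_v(studies)
    return _pool(d, v, tau2=0.0, method="fixed")


def _tau2_dl(d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    pooled = (w * d).sum() / w.sum()
    Q = (w * (d - pooled) ** 2).sum()
    df = len(d) - 1
    denom = w.sum() - (w**2).sum() / w.sum()
    return float(max(0.0, (Q - df) / denom))


def _reml_nll(tau2: float, d: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = (w * d).sum() / w.sum()
    return 0.5 * (
        np.log(v + tau2).sum() + np.log(w.sum()) + (w * (d - mu) ** 2).sum()
    )


def _tau2_reml(d: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> float:
    upper = max(10.0 * float(np.var(d)), 10.0 * float(v.max()), 1e-6)
    res = optimize.minimize_scalar(
        _reml_nll,
        args=(d, v),
        bounds=(0.0, upper),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(f"REML estimation of tau2 did not converge: {res}")
    tau2 = float(res.x)
    # the bounded minimizer cannot land exactly on the boundary; snap to 0
    # when the restricted likelihood is monotone increasing in tau2 there
    if _reml_nll(0.0, d, v) <= _reml_nll(tau2, d, v):
        return 0.0
    return tau2


def random_effects_pool(studies: Sequence[StudyRecord], method: Method = "DL") -> MetaResult:
    """Random-effects pooled estimate with DerSimonian-Laird or REML tau^2.

    DL: tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights.  REML: tau^2 maximizes the restricted likelihood.  Final weights
    are 1/(var_i + tau^2).  With tau^2 = 0 (e.g. whenever Q <= df under DL)
    the result coincides with the fixed-effect model.
    """
    if len(studies) < 2:
        raise ValueError("random-effects pooling requires at least 2 studies")
    d, v = _d_v(studies)
    if method == "DL":
        tau2 = _tau2_dl(d, v)
    elif method == "REML":
        tau2 = _tau2_reml(d, v)
    else:
        raise ValueError(f"unknown method {method!r}; use 'DL' or 'REML'")
    return _pool(d, v, tau2=tau2, method=method)


def heterogeneity(studies: Sequence[StudyRecord], method: Method = "REML") -> dict:
    """Heterogeneity statistics: Q, df, tau2 and the two I^2 flavours.

    ``i2_q`` is the Q-based index max(0, (Q - df)/Q) * 100; ``i2_tau`` is
    100 * tau2/(tau2 + s^2) with s^2 the typical within-study variance.  The
    two disagree when Q <= df (i2_q truncates to zero) while tau2 estimated
    by REML remains marginally positive.
    """
    if len(studies) < 2:
        raise ValueError("heterogeneity requires at least 2 studies")
    result = random_effects_pool(studies, method=method)
    return {
        "Q": result.Q,
        "df": result.df,
        "tau2": result.tau2,
        "i2_q": result.i2_q,
        "i2_tau": result.i2_tau,
    }


_TERMS = ("intercept", "latitude", "latitude2", "longitude", "longitude2")


def spatial_regression(
    d: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    var_d: Optional[np.ndarray] = None,
    weighted: bool = False,
) -> MetaRegressionResult:
    """Least squares of effect sizes on {lat, lat^2, lon, lon^2} plus intercept.

    Default is ordinary (unweighted) least squares, mirroring a plain GLM of
    d on the spatial terms; ``weighted=True`` uses inverse-variance weights
    (requires ``var_d``).  p-values are two-sided from the t distribution
    with k - 5 df.
    """
    d = np.asarray(d, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    k = len(d)
    if k <= len(_TERMS):
        raise ValueError(f"need more than {len(_TERMS)} studies, got {k}")
    X = np.column_stack([np.ones(k), lat, lat**2, lon, lon**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (e.g. all study sites identical)")
    if weighted:
        if var_d is None:
            raise ValueError("weighted regression requires var_d")
        model = sm.WLS(d, X, weights=1.0 / np.asarray(var_d, dtype=float))
    else:
        model = sm.OLS(d, X)
    fit = model.fit()
    return MetaRegressionResult(
        terms=_TERMS,
        coefficients=np.asarray(fit.params),
        standard_errors=np.asarray(fit.bse),
        p_values=np.asarray(fit.pvalues),
        residuals=np.asarray(fit.resid),
        k=k,
        weighted=weighted,
    )


def meta_regression(
    studies: Sequence[StudyRecord], weighted: bool = False
) -> MetaRegressionResult:
    """Spatial meta-regression of study effect sizes on site coordinates."""
    if any(s.latitude is None or s.longitude is None for s in studies):
        raise ValueError("all studies must carry coordinates for meta-regression")
    d, v = _d_v(studies)
    lat = np.array([s.latitude for s in studies], dtype=float)
    lon = np.array([s.longitude for s in studies], dtype=float)
    return spatial_regression(d, lat, lon, var_d=v, weighted=weighted)


def funnel_data(
    studies: Sequence[StudyRecord],
    levels: Sequence[float] = (0.90, 0.95, 0.99),
    n_contour: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Funnel-plot data: per-study (d, se) points and pseudo-CI contours.

    Contours fan out around the fixed-effect pooled estimate as
    pooled +- z(level) * se over a grid of standard errors from 0 to the
    largest observed se.  Rendering is the caller's job.
    """
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    tab = effect_table(studies)
    points = tab[["id", "d", "se_d"]].rename(columns={"se_d": "se"})
    center = fixed_effect_pool(studies).pooled_d
    se_grid = np.linspace(0.0, points["se"].max(), n_contour)
    rows = []
    for level in levels:
        z = stats.norm.ppf(0.5 + level / 2.0)
        for se in se_grid:
            rows.append(
                {
                    "level": level,
                    "se": se,
                    "lower": center - z * se,
                    "upper": center + z * se,
                }
            )
    return points, pd.DataFrame(rows)


def merge_by_reference(studies: Sequence[StudyRecord]) -> list[StudyRecord]:
    """Collapse data sets to one record per (reference, ratio type), summing counts.

    Used when pooling at the reference (publication) level rather than the
    data-set level.  Coordinates and labels are taken from the first row of
    each group; the merged id joins constituent ids with '+'.
    """
    groups: dict[tuple[str, str], list[StudyRecord]] = {}
    for s in studies:
        groups.setdefault((s.reference_id, s.ratio_type), []).append(s)
    merged = []
    for members in groups.values():
        first = members[0]
        if len(members) == 1:
            merged.append(first)
            continue
        counts = SexRatioCount(
            n_female=sum(m.counts.n_female for m in members),
            n_male=sum(m.counts.n_male for m in members),
        )
        merged.append(
            replace(first, id="+".join(m.id for m in members), counts=counts)
        )
    return merged
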