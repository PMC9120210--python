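"""Sliding climate-window sensitivity analysis for offspring sex.

The response is individual offspring sex (0 male, 1 female).  Candidate
covariates are means of monthly weather over every contiguous window on a
fixed nine-month axis running from June of the year before birth, ``Jun(t-1)``,
to February of the birth year, ``Feb(t)`` — the period spanning the rut,
gestation up to embryo implantation, and the winter preceding birth.  For
each window a binomial GLM with a quadratic polynomial in the (centered)
window covariate,

    logit P(female) = a0 + a1 * x + a2 * x^2,

is compared against an intercept-only null via AICc; Akaike weights are
normalized over the null plus all 45 windows.  Temperature covariates are
corrected to each individual's elevation with the standard environmental
lapse rate of 0.65 degC per 100 m, and the scan can be stratified over four
height classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "WINDOW_AXIS",
    "HEIGHT_CLASS_LABELS",
    "WindowSpec",
    "GlmFit",
    "WindowScanResult",
    "lapse_correct",
    "assign_height_class",
    "window_aggregate",
    "fit_binomial_glm",
    "muri_model",
    "scan_windows",
    "effect_curve",
]

#: Standard environmental lapse rate, degC per 100 m of elevation.
LAPSE_RATE_PER_100M = 0.65

#: The fixed month axis: (calendar month, year offset relative to birth year t).
#: Index 0 = June(t-1) ... index 8 = February(t).
WINDOW_AXIS: tuple[tuple[int, int], ...] = (
    (6, -1),
    (7, -1),
    (8, -1),
    (9, -1),
    (10, -1),
    (11, -1),
    (12, -1),
    (1, 0),
    (2, 0),
)

_MONTH_NAMES = {
    1: "Jan", 2: "Feb", 3: "Mar", 4: "Apr", 5: "May", 6: "Jun",
    7: "Jul", 8: "Aug", 9: "Sep", 10: "Oct", 11: "Nov", 12: "Dec",
}

#: Height classes (m a.s.l.), half-open [low, high) so that every elevation
#: maps to exactly one class.
HEIGHT_CLASS_BOUNDS: tuple[float, ...] = (0.0, 250.0, 500.0, 750.0, np.inf)
HEIGHT_CLASS_LABELS: tuple[str, ...] = ("<250", "250-500", "500-750", ">=750")

_WEATHER_COLUMN = {"temperature": "temperature_c", "precipitation": "precipitation_mm"}


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous window on the Jun(t-1)..Feb(t) axis, inclusive indices."""

    open_idx: int
    close_idx: int
    variable: str = "temperature"
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.open_idx <= self.close_idx <= len(WINDOW_AXIS) - 1:
            raise ValueError(
                f"window indices must satisfy 0 <= open <= close <= "
                f"{len(WINDOW_AXIS) - 1}, got ({self.open_idx}, {self.close_idx})"
            )
        if self.variable not in _WEATHER_COLUMN:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.statistic != "mean":
            raise ValueError("only the 'mean' statistic is supported")

    @property
    def months(self) -> tuple[tuple[int, int], ...]:
        return WINDOW_AXIS[self.open_idx : self.close_idx + 1]

    @property
    def width(self) -> int:
        return self.close_idx - self.open_idx + 1

    @property
    def label(self) -> str:
        def _name(idx: int) -> str:
            m, off = WINDOW_AXIS[idx]
            return f"{_MONTH_NAMES[m]}(t{off})" if off else f"{_MONTH_NAMES[m]}(t)"

        return f"{_name(self.open_idx)}-{_name(self.close_idx)}"

    def jaccard(self, other: "WindowSpec") -> float:
        a = set(range(self.open_idx, self.close_idx + 1))
        b = set(range(other.open_idx, other.close_idx + 1))
        return len(a & b) / len(a | b)


@dataclass(frozen=True)
class GlmFit:
    """A fitted binomial GLM: coefficients, Wald inference and information criteria."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    aic: float
    aicc: float
    n: int
    deviance: float
    cov_params: np.ndarray
    centering: tuple[float, ...] = ()


@dataclass(frozen=True)
class WindowScanResult:
    """Per-(height class, window) AICc table plus best and consensus windows.

    ``table`` has one row per model including the class null (open/close
    indices are -1 for the null); weights within a class sum to 1 over the
    null plus all windows.
    """

    table: pd.DataFrame
    best_window: dict[str, WindowSpec]
    consensus_window: Optional[WindowSpec]
    variable: str
    skipped_classes: tuple[str, ...] = ()


def lapse_correct(temperature_c, elevation_m):
    """Correct temperature to elevation: Tcor = T - 0.65 * (hasl / 100).

    Linear and strictly decreasing in elevation at fixed temperature.
    Accepts scalars or arrays.
    """
    return np.asarray(temperature_c) - LAPSE_RATE_PER_100M * np.asarray(elevation_m) / 100.0


def assign_height_class(elevation_m: float) -> str:
    """Map an elevation (m a.s.l.) to its height class label.

    Classes are half-open [low, high): 249.9 -> '<250', 250 -> '250-500'.
    """
    if elevation_m < 0:
        raise ValueError(f"elevation must be non-negative, got {elevation_m}")
    for low, high, label in zip(
        HEIGHT_CLASS_BOUNDS[:-1], HEIGHT_CLASS_BOUNDS[1:], HEIGHT_CLASS_LABELS
    ):
        if low <= elevation_m < high:
            return label
    raise AssertionError("unreachable: classes partition [0, inf)")


def _weather_lookup(weather: pd.DataFrame, variable: str) -> dict[tuple[int, int], float]:
    col = _WEATHER_COLUMN[variable]
    if col not in weather.columns:
        raise ValueError(f"weather table lacks column {col!r}")
    return {
        (int(y), int(m)): float(v)
        for y, m, v in zip(weather["year"], weather["month"], weather[col])
    }


def window_aggregate(
    weather: pd.DataFrame, window: WindowSpec, birth_year: int
) -> float:
    """Mean of the monthly values across the window for one birth year.

    Indices 0-6 map to Jun-Dec of the year before birth, 7-8 to Jan-Feb of
    the birth year.  A missing (year, month) is an error naming the gap.
    """
    lookup = _weather_lookup(weather, window.variable)
    vals = []
    for month, offset in window.months:
        key = (birth_year + offset, month)
        if key not in lookup:
            raise ValueError(
                f"weather series is missing year={key[0]}, month={key[1]} "
                f"needed for window {window.label}"
            )
        vals.append(lookup[key])
    return float(np.mean(vals))


def _window_series(
    lookup: dict[tuple[int, int], float], window: WindowSpec, years: np.ndarray
) -> dict[int, float]:
    out = {}
    for t in np.unique(years):
        t = int(t)
        vals = []
        for month, offset in window.months:
            key = (t + offset, month)
            if key not in lookup:
                raise ValueError(
                    f"weather series is missing year={key[0]}, month={key[1]} "
                    f"needed for window {window.label}"
                )
            vals.append(lookup[key])
        out[t] = float(np.mean(vals))
    return out


def _aicc(llf: float, p: int, n: int) -> float:
    if n <= p + 1:
        raise ValueError(f"AICc undefined for n={n} with p={p} parameters")
    return -2.0 * llf + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


def fit_binomial_glm(
    sex: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    quadratic: bool = False,
    center: bool = True,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> GlmFit:
    """Maximum-likelihood logistic fit of sex on the given covariates.

    ``covariates=None`` fits the intercept-only null.  With ``quadratic=True``
    each covariate contributes a linear and a squared term; covariates are
    mean-centered before squaring (reduces collinearity between x and x^2 and
    makes information-criterion differences invariant to additive covariate
    shifts).  Fitting is IRLS via statsmodels with the given tolerance and
    iteration cap; separation and single-sex data raise with a diagnostic.
    """
    y = np.asarray(sex, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("sex must be coded 0 (male) / 1 (female)")
    if y.min() == y.max():
        raise ValueError("single-sex data: logistic fit is degenerate")
    cols: list[np.ndarray] = [np.ones_like(y)]
    names: list[str] = ["intercept"]
    centering: list[float] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        n_per_param = len(y) / (1 + cov.shape[1] * (2 if quadratic else 1))
        if n_per_param < 10:
            raise ValueError("fewer than 10 records per parameter")
        for name in cov.columns:
            x = cov[name].to_numpy(dtype=float)
            mu = float(x.mean()) if center else 0.0
            xc = x - mu
            centering.append(mu)
            cols.append(xc)
            names.append(str(name))
            if quadratic:
                cols.append(xc**2)
                names.append(f"{name}^2")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix (constant or collinear covariates)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=tol, maxiter=maxiter)
    if not res.converged:
        raise RuntimeError(f"IRLS did not converge in {maxiter} iterations")
    if np.abs(res.params).max() > 30:
        raise RuntimeError(
            "fitted coefficients diverged (likely complete or quasi-separation)"
        )
    p = X.shape[1]
    n = len(y)
    return GlmFit(
        names=tuple(names),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        aic=-2.0 * float(res.llf) + 2.0 * p,
        aicc=_aicc(float(res.llf), p, n),
        n=n,
        deviance=float(res.deviance),
        cov_params=np.asarray(res.cov_params()),
        centering=tuple(centering),
    )


#: The twelve month-specific covariates of the classical Swiss tagging model:
#: temperature and precipitation for Jan/Feb/Mar of the birth year and
#: May/Jun/Dec of the previous year.
MURI_MONTHS: tuple[tuple[int, int], ...] = (
    (1, 0), (2, 0), (3, 0), (5, -1), (6, -1), (12, -1),
)


def muri_model(offspring: pd.DataFrame, weather: pd.DataFrame) -> GlmFit:
    """Linear logistic fit with the twelve fixed month covariates.

    sex ~ T_Jan(t) + T_Feb(t) + T_Mar(t) + T_May(t-1) + T_Jun(t-1) +
    T_Dec(t-1) + the same six months of precipitation.  No quadratic terms
    and no lapse-rate correction; covariates vary by birth year only.
    """
    years = offspring["year"].to_numpy(dtype=int)
    cov = {}
    for variable, prefix in (("temperature", "T"), ("precipitation", "P")):
        lookup = _weather_lookup(weather, variable)
        for month, offset in MURI_MONTHS:
            tag = f"{prefix}_{_MONTH_NAMES[month]}(t{offset})" if offset else f"{prefix}_{_MONTH_NAMES[month]}(t)"
            per_year = {}
            for t in np.unique(years):
                key = (int(t) + offset, month)
                if key not in lookup:
                    raise ValueError(
                        f"weather series is missing year={key[0]}, month={key[1]} "
                        f"needed for covariate {tag}"
                    )
                per_year[int(t)] = lookup[key]
            cov[tag] = np.array([per_year[int(t)] for t in years])
    return fit_binomial_glm(
        offspring["sex"].to_numpy(), pd.DataFrame(cov), quadratic=False
    )


def _fit_window(
    y: np.ndarray,
    years: np.ndarray,
    elevation: np.ndarray,
    lookup: dict[tuple[int, int], float],
    window: WindowSpec,
) -> GlmFit:
    per_year = _window_series(lookup, window, years)
    x = np.array([per_year[int(t)] for t in years])
    if window.variable == "temperature":
        x = lapse_correct(x, elevation)
    return fit_binomial_glm(y, pd.DataFrame({"x": x}), quadratic=True)


def scan_windows(
    offspring: pd.DataFrame,
    weather: pd.DataFrame,
    variable: str = "temperature",
    by_height_class: bool = True,
    use_aicc: bool = True,
    min_class_n: int = 200,
) -> WindowScanResult:
    """Enumerate all 45 contiguous windows and rank them by AICc weight.

    Per height class (or once, pooled), each window's quadratic logistic
    model is fit on the class subset and compared with the intercept-only
    null on the same subset.  Akaike weights w_i = exp(-dAICc_i/2) / sum_j
    exp(-dAICc_j/2) are normalized over {null + all windows}.  The best
    window per class minimizes AICc (ties broken toward the widest window,
    then the earliest opening); the consensus window minimizes the summed
    within-class AICc rank.  Classes with fewer than ``min_class_n`` records
    are skipped with a warning.
    """
    if variable not in _WEATHER_COLUMN:
        raise ValueError(f"unknown variable {variable!r}")
    if offspring["year"].nunique() < 2:
        raise ValueError("need at least 2 birth years of data")
    lookup = _weather_lookup(weather, variable)
    windows = [
        WindowSpec(lo, hi, variable=variable)
        for lo in range(len(WINDOW_AXIS))
        for hi in range(lo, len(WINDOW_AXIS))
    ]
    if by_height_class:
        labels = offspring["elevation_m"].map(assign_height_class)
        groups = [(label, offspring[labels == label]) for label in HEIGHT_CLASS_LABELS]
    else:
        groups = [("all", offspring)]

    rows = []
    best: dict[str, WindowSpec] = {}
    skipped: list[str] = []
    crit = "aicc" if use_aicc else "aic"
    for label, sub in groups:
        if len(sub) < min_class_n:
            warnings.warn(
                f"height class {label!r}: only {len(sub)} records (< {min_class_n}); skipped",
                stacklevel=2,
            )
            if len(sub) > 0 or by_height_class:
                skipped.append(label)
            continue
        y = sub["sex"].to_numpy(dtype=float)
        years = sub["year"].to_numpy(dtype=int)
        elev = sub["elevation_m"].to_numpy(dtype=float)
        null_fit = fit_binomial_glm(y)
        entries = [(-1, -1, 0, getattr(null_fit, crit))]
        for w in windows:
            fit = _fit_window(y, years, elev, lookup, w)
            entries.append((w.open_idx, w.close_idx, w.width, getattr(fit, crit)))
        crits = np.array([e[3] for e in entries])
        delta = crits - crits.min()
        weight = np.exp(-delta / 2.0)
        weight /= weight.sum()
        null_crit = entries[0][3]
        for (lo, hi, width, c), wt in zip(entries, weight):
            rows.append(
                {
                    "height_class": label,
                    "variable": variable,
                    "open_idx": lo,
                    "close_idx": hi,
                    "window": WindowSpec(lo, hi, variable=variable).label if lo >= 0 else "null",
                    "aicc": c,
                    "delta_aicc": c - null_crit,
                    "weight": wt,
                }
            )
        # best window: min criterion; ties -> widest, then earliest open
        candidates = sorted(
            entries[1:], key=lambda e: (round(e[3], 12), -e[2], e[0])
        )
        lo, hi, _, _ = candidates[0]
        best[label] = WindowSpec(lo, hi, variable=variable)

    if not rows:
        raise ValueError("no height class had enough records to scan")
    table = pd.DataFrame(rows)

    consensus: Optional[WindowSpec] = None
    scanned = [g for g, _ in groups if g not in skipped]
    window_rows = table[table["open_idx"] >= 0]
    ranks = (
        window_rows.groupby("height_class")["aicc"].rank(method="average")
    )
    window_rows = window_rows.assign(rank=ranks)
    total = window_rows.groupby(["open_idx", "close_idx"])["rank"].sum()
    # ties -> widest window, then earliest open
    ordered = sorted(
        total.items(), key=lambda kv: (kv[1], -(kv[0][1] - kv[0][0]), kv[0][0])
    )
    (lo, hi), _ = ordered[0]
    consensus = WindowSpec(int(lo), int(hi), variable=variable)

    return WindowScanResult(
        table=table,
        best_window=best,
        consensus_window=consensus,
        variable=variable,
        skipped_classes=tuple(skipped),
    )


def effect_curve(fit: GlmFit, x: np.ndarray, term: str = "x") -> pd.DataFrame:
    """Predicted proportion female over a covariate grid with a 95% Wald band.

    ``x`` is on the original (uncentered) covariate scale; the fit's stored
    centering is applied before evaluating the quadratic polynomial.  The
    band is computed on the link scale and transformed through the logistic
    function.
    """
    if term not in fit.names:
        raise ValueError(f"term {term!r} not in fit: {fit.names}")
    i = fit.names.index(term)
    mu = fit.centering[i - 1] if fit.centering else 0.0
    xc = np.asarray(x, dtype=float) - mu
    n_params = len(fit.params)
    X = np.zeros((len(xc), n_params))
    X[:, 0] = 1.0
    X[:, i] = xc
    quad = f"{term}^2"
    if quad in fit.names:
        X[:, fit.names.index(quad)] = xc**2
    eta = X @ fit.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params, X))
    expit = lambda v: 1.0 / (1.0 + np.exp(-v))
    return pd.DataFrame(
        {
            "x": np.asarray(x, dtype=float),
            "proportion_female": expit(eta),
            "ci_low": expit(eta - 1.96 * se),
            "ci_high": expit(eta + 1.96 * se),
        }
    )
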