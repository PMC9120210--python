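"""Effect-size and exact-binomial primitives for single-proportion sex-ratio data.

The unit of analysis throughout is a count of female vs. male offspring.  The
proportion of females ``pf`` is turned into a standardized effect size on the
log-odds scale,

    d = ln(pf / (1 - pf)) / (pi / sqrt(3)),

i.e. the log odds ratio rescaled by the standard deviation of the logistic
distribution (Chinn's conversion to the standardized-mean-difference scale).
``d < 0`` indicates a male-biased sex ratio.  Exact (Clopper-Pearson)
confidence intervals on the proportion scale complement the normal-theory
interval on the d scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "CHINN_SCALE",
    "SexRatioCount",
    "EffectSize",
    "BinomialCI",
    "odds_ratio",
    "effect_size_d",
    "clopper_pearson",
    "counts_from_proportion",
]

#: Standard deviation of the logistic distribution, pi/sqrt(3); divisor that
#: maps a log odds ratio onto the standardized-mean-difference scale.
CHINN_SCALE: float = math.pi / math.sqrt(3.0)


@dataclass(frozen=True)
class SexRatioCount:
    """Female/male offspring counts for one data set."""

    n_female: int
    n_male: int

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("counts must be non-negative")
        if self.n_total < 1:
            raise ValueError("at least one offspring is required")

    @property
    def n_total(self) -> int:
        return self.n_female + self.n_male

    @property
    def pf(self) -> float:
        """Proportion of female offspring."""
        return self.n_female / self.n_total


@dataclass(frozen=True)
class EffectSize:
    """Standardized log-odds effect size with its sampling variance.

    ``ci_low``/``ci_high`` are normal-approximation 95% bounds on the d scale.
    """

    d: float
    var_d: float
    se_d: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class BinomialCI:
    """Exact binomial confidence interval on the proportion scale."""

    level: float
    low: float
    high: float


def odds_ratio(pf: float) -> float:
    """Odds of a female offspring, ``pf / (1 - pf)``.

    Strictly increasing in ``pf``; defined only on the open interval (0, 1)
    (no continuity correction is applied at this level).
    """
    if not 0.0 < pf < 1.0:
        raise ValueError(f"pf must lie strictly between 0 and 1, got {pf}")
    return pf / (1.0 - pf)


def effect_size_d(counts: SexRatioCount, level: float = 0.95) -> EffectSize:
    """Standardized effect size d from female/male counts.

    d = ln(OR) / (pi/sqrt(3)) with OR = pf/(1-pf).  The sampling variance is
    the single-proportion logit variance 1/n_female + 1/n_male rescaled by
    3/pi^2 onto the d scale.  Zero cells are refused: with the screening rule
    N >= 50 and observed proportions well inside (0, 1) they do not occur in
    real tables, and a continuity correction would silently change d.
    """
    if counts.n_female == 0:
        raise ValueError("cannot compute effect size: n_female is zero")
    if counts.n_male == 0:
        raise ValueError("cannot compute effect size: n_male is zero")
    # log(nf) - log(nm) rather than log(nf/nm): makes swapping the sexes
    # negate d exactly in floating point
    d = (math.log(counts.n_female) - math.log(counts.n_male)) / CHINN_SCALE
    var_d = (1.0 / counts.n_female + 1.0 / counts.n_male) / CHINN_SCALE**2
    se = math.sqrt(var_d)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return EffectSize(d=d, var_d=var_d, se_d=se, ci_low=d - z * se, ci_high=d + z * se)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact (Clopper-Pearson) binomial confidence interval for k successes in n trials.

    Bounds are beta-distribution quantiles; the lower bound is 0 when k = 0
    and the upper bound is 1 when k = n.  Coverage is conservative
    (>= ``level``) by construction.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return BinomialCI(level=level, low=low, high=high)


def counts_from_proportion(pf: float, n: int) -> SexRatioCount:
    """Recover integer counts from a rounded proportion and a total.

    Published tables print the proportion of females to two decimals only;
    the female count is recovered as the nearest integer to ``pf * n`` (ties
    round half away from zero).  A warning is emitted when the recovered
    proportion differs from ``pf`` by more than 0.005, i.e. when ``pf``
    cannot have been the 2-dp rounding of any count out of ``n``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= pf <= 1.0:
        raise ValueError(f"pf must lie in [0, 1], got {pf}")
    n_female = int(math.floor(pf * n + 0.5))
    n_female = min(n_female, n)
    if abs(n_female / n - pf) > 0.005:
        warnings.warn(
            f"reconstructed proportion {n_female / n:.4f} differs from printed "
            f"pf={pf} by more than 0.005 (n={n})",
            stacklevel=2,
        )
    return SexRatioCount(n_female=n_female, n_male=n - n_female)
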