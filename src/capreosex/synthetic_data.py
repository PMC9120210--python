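"""Synthetic tagging, weather and study-table generators.

No individual-level tagging data or station weather series are shipped with
the package, so every pipeline stage is exercised on simulated inputs whose
generating process mirrors the models the pipeline fits:

* monthly weather follows a seasonal climatology (temperate central-European
  values) with independent Gaussian temperature noise and moment-matched
  Gamma precipitation;
* offspring sex is Bernoulli with log-odds a quadratic function of a planted
  climate-window covariate (the window mean temperature, lapse-corrected to
  the individual's elevation and centered);
* meta-analytic study tables draw true effects d_i ~ Normal(mu_d, tau2),
  convert them to proportions through the inverse of the Chinn scaling, and
  draw binomial female counts.

Everything is deterministic given ``SimulationConfig.seed``; each generator
uses an independent, purpose-keyed child stream of that seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .climate_window import (
    HEIGHT_CLASS_LABELS,
    WindowSpec,
    lapse_correct,
    _weather_lookup,
    _window_series,
)
from .core_stats import CHINN_SCALE, SexRatioCount
from .meta_analysis import StudyRecord

__all__ = [
    "DEFAULT_CLIMATOLOGY",
    "MetaConfig",
    "SimulationConfig",
    "simulate_weather",
    "simulate_offspring",
    "simulate_meta",
]

#: Per-month climatology: month -> (T mean degC, T sd, P mean mm, P sd).
#: Values are typical of low-elevation south-west Germany; the temperature
#: sd of ~1.5 degC is a realistic year-to-year spread of monthly means.
DEFAULT_CLIMATOLOGY: dict[int, tuple[float, float, float, float]] = {
    1: (0.5, 1.8, 55.0, 25.0),
    2: (1.5, 1.8, 50.0, 25.0),
    3: (5.5, 1.6, 55.0, 25.0),
    4: (9.5, 1.5, 60.0, 28.0),
    5: (14.0, 1.5, 85.0, 35.0),
    6: (17.0, 1.5, 90.0, 38.0),
    7: (19.0, 1.5, 85.0, 38.0),
    8: (18.5, 1.5, 80.0, 35.0),
    9: (14.5, 1.4, 65.0, 30.0),
    10: (9.5, 1.5, 60.0, 28.0),
    11: (4.5, 1.5, 60.0, 28.0),
    12: (1.5, 1.8, 65.0, 30.0),
}

#: Sampling bounds (m a.s.l.) for elevations drawn within each height class.
_CLASS_RANGES = {
    "<250": (50.0, 250.0),
    "250-500": (250.0, 500.0),
    "500-750": (500.0, 750.0),
    ">=750": (750.0, 1000.0),
}


@dataclass(frozen=True)
class MetaConfig:
    """Planted meta-analytic conditions: k studies with d_i ~ N(mu_d, tau2)."""

    k: int = 15
    mu_d: float = -0.045
    tau2: float = 0.0
    n_min: int = 100
    n_max: int = 5000
    #: European bounding box (lat_min, lat_max, lon_min, lon_max) for site draws.
    bbox: tuple[float, float, float, float] = (35.0, 72.0, -10.0, 32.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic tagging data.

    Defaults emulate the Baden-Wuerttemberg tagging programme: 48 birth-year
    cohorts, ~260 tagged fawns per year (~12,500 total, matching the real
    sample size), elevations spread over the four height classes with most
    animals below 500 m, a baseline proportion female of 0.48, and a planted
    quadratic effect of the Oct(t-1)-Feb(t) mean temperature.  The quadratic
    coefficient 0.08 makes the planted effect span roughly half a logit over
    the observed range of the centered window covariate (about +-2.5 degC of
    year-to-year plus within-class elevation variation).
    """

    seed: int = 0
    years: tuple[int, int] = (1972, 2019)  # inclusive birth-year range
    n_per_year: int = 260
    elevation_mix: tuple[float, float, float, float] = (0.35, 0.35, 0.20, 0.10)
    climatology: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATOLOGY)
    )
    planted_window: WindowSpec = WindowSpec(4, 8)  # Oct(t-1)..Feb(t)
    planted_coefficients: tuple[float, float, float] = (
        math.log(0.48 / 0.52),
        0.019,
        0.08,
    )
    meta: MetaConfig = MetaConfig()

    def __post_init__(self) -> None:
        if abs(sum(self.elevation_mix) - 1.0) > 1e-9:
            raise ValueError("elevation_mix proportions must sum to 1")
        if any(sd < 0 for _, sd, _, psd in self.climatology.values()) or any(
            psd < 0 for _, _, _, psd in self.climatology.values()
        ):
            raise ValueError("climatology standard deviations must be non-negative")
        if self.meta.n_min < 1:
            raise ValueError("meta n_min must be at least 1")

    def rng(self, purpose: int) -> np.random.Generator:
        """Independent stream keyed by (seed, purpose); deterministic."""
        return np.random.default_rng([int(self.seed), int(purpose)])


def simulate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Monthly weather covering the year before the first cohort through the last.

    T ~ Normal(month mean, month sd); P ~ Gamma moment-matched to the month
    mean/sd (non-negative and right-skewed, as monthly precipitation is);
    sd = 0 reproduces the climatology exactly.
    """
    rng = config.rng(1)
    y0, y1 = config.years
    rows = []
    for year in range(y0 - 1, y1 + 1):
        for month in range(1, 13):
            t_mean, t_sd, p_mean, p_sd = config.climatology[month]
            t = t_mean + (rng.normal(0.0, t_sd) if t_sd > 0 else 0.0)
            if p_sd > 0:
                shape = (p_mean / p_sd) ** 2
                scale = p_sd**2 / p_mean
                p = rng.gamma(shape, scale)
            else:
                p = p_mean
            rows.append(
                {
                    "year": year,
                    "month": month,
                    "temperature_c": t,
                    "precipitation_mm": p,
                }
            )
    return pd.DataFrame(rows)


def simulate_offspring(
    config: SimulationConfig, weather: pd.DataFrame
) -> pd.DataFrame:
    """Individual offspring records with a planted climate-window sex effect.

    Each record draws a birth year (uniform over cohorts, fixed per-year
    sample size), a height class from the elevation mix with a uniform
    elevation within the class, and an estimated tagging age (rounded
    Normal(8.4, 2.5), clipped to [0, 42] days).  Sex is Bernoulli with
    logit P(female) = a0 + a1*xc + a2*xc^2 where xc is the planted-window
    mean temperature, lapse-corrected to the record's elevation and centered
    over the generated data set.
    """
    rng = config.rng(2)
    y0, y1 = config.years
    years = np.repeat(np.arange(y0, y1 + 1), config.n_per_year)
    n = len(years)
    cls = rng.choice(len(HEIGHT_CLASS_LABELS), size=n, p=config.elevation_mix)
    lows = np.array([_CLASS_RANGES[HEIGHT_CLASS_LABELS[c]][0] for c in cls])
    highs = np.array([_CLASS_RANGES[HEIGHT_CLASS_LABELS[c]][1] for c in cls])
    elevation = rng.uniform(lows, highs)
    age = np.clip(np.round(rng.normal(8.4, 2.5, size=n)), 0, 42).astype(int)

    window = config.planted_window
    lookup = _weather_lookup(weather, window.variable)
    per_year = _window_series(lookup, window, years)
    x = np.array([per_year[int(t)] for t in years])
    if window.variable == "temperature":
        x = lapse_correct(x, elevation)
    xc = x - x.mean()
    a0, a1, a2 = config.planted_coefficients
    eta = a0 + a1 * xc + a2 * xc**2
    sex = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {
            "site_id": "SIM",
            "year": years,
            "sex": sex,
            "elevation_m": elevation,
            "est_age_days": age,
        }
    )


def simulate_meta(config: SimulationConfig) -> list[StudyRecord]:
    """Synthetic study table with planted mean effect and heterogeneity.

    d_i ~ Normal(mu_d, tau2); pf_i = logistic(d_i * pi/sqrt(3)) inverts the
    effect-size definition; n_i is uniform on [n_min, n_max] and the female
    count binomial.  Degenerate all-female/all-male draws are redrawn so
    every study admits an effect size.  Coordinates are uniform over a
    European bounding box.
    """
    mc = config.meta
    if mc.k < 2:
        raise ValueError("simulate_meta requires k >= 2 studies")
    rng = config.rng(3)
    d = rng.normal(mc.mu_d, math.sqrt(mc.tau2), size=mc.k) if mc.tau2 > 0 else np.full(
        mc.k, mc.mu_d
    )
    pf = 1.0 / (1.0 + np.exp(-d * CHINN_SCALE))
    n = rng.integers(mc.n_min, mc.n_max + 1, size=mc.k)
    lat = rng.uniform(mc.bbox[0], mc.bbox[1], size=mc.k)
    lon = rng.uniform(mc.bbox[2], mc.bbox[3], size=mc.k)
    studies = []
    for i in range(mc.k):
        nf = int(rng.binomial(int(n[i]), pf[i]))
        while nf == 0 or nf == n[i]:  # redraw degenerate cells (needs n >= 2)
            nf = int(rng.binomial(int(n[i]), pf[i]))
        studies.append(
            StudyRecord(
                id=f"sim{i + 1}",
                reference_id=f"simref{i + 1}",
                counts=SexRatioCount(n_female=nf, n_male=int(n[i]) - nf),
                country="synthetic",
                location="synthetic",
                latitude=float(lat[i]),
                longitude=float(lon[i]),
                living_condition="F",
                ratio_type="S",
            )
        )
    return studies
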