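"""Synthetic country-year-age panels with the statistical structure the pipeline assumes.

The generator emulates the qualitative regimes of the real global panels the
analysis is designed around, without calibrating to any real country's
magnitudes:

* populations grow log-linearly with country-specific rates, while the age
  structure ages (the open-ended elderly share drifts up, the under-5 share
  drifts down, the vector renormalized onto the simplex every year);
* the unimproved-sanitation share declines along a country-specific logistic
  with optional logit-scale noise, the remainder splitting between sewer and
  other improved facilities with the sewer fraction rising over time;
* log mortality rates follow an age-period-cohort surface with a U-shaped
  age profile (elevated under 5 and over 65), a linearly declining period
  effect, a small random-walk cohort effect and i.i.d. Gaussian noise;
* relative risks are fixed configuration, not claims.

Every generator is a pure function of (config, seed): per-country substreams
are derived with ``SeedSequence(seed, spawn_key=(stream, country))`` so that
adding a country never perturbs the panels of existing ones.  The ground
truth behind each surface (growth rates, APC effects, logistic parameters)
is returned alongside, for parameter-recovery tests that never peek at it
during fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .mortality_forecast import cohort_bin
from .panel_io import (
    MortalityPanel,
    PopulationPanel,
    RRRecord,
    SanitationShares,
    SHARE_PREFIX,
)
from .schema import AgeBand, DEFAULT_AGE_SCHEMA, validate_schema

logger = logging.getLogger(__name__)

_STREAM_POPULATION = 0
_STREAM_SANITATION = 1
_STREAM_MORTALITY = 2


@dataclass(frozen=True)
class SanitationTrendConfig:
    """Logistic-improvement parameters for the unimproved share."""

    midpoint_year_range: tuple[float, float] = (2005.0, 2020.0)
    slope_range: tuple[float, float] = (0.08, 0.20)  # per year, > 0 means decline
    start_unimproved_range: tuple[float, float] = (0.40, 0.80)
    sewer_fraction_start_range: tuple[float, float] = (0.10, 0.30)
    sewer_fraction_end_range: tuple[float, float] = (0.30, 0.60)
    logit_noise: float = 0.05


@dataclass(frozen=True)
class MortalityEffectsConfig:
    """Generative APC surface parameters (log scale, rates per 100,000)."""

    age_effects: tuple[float, ...] = (1.2, -0.3, -1.0, -0.4, 0.5)
    period_slope: float = -0.04  # log-rate change per year
    cohort_scale: float = 0.05  # random-walk innovation sd per cohort bin
    noise_scale: float = 0.05  # i.i.d. residual sd on log rate
    baseline_rate_range: tuple[float, float] = (20.0, 80.0)  # per 100,000
    bound_log_sd: float = 0.10  # 95% bounds = rate * exp(+-1.96 * sd)


@dataclass(frozen=True)
class WorldConfig:
    n_countries: int = 10
    year_start: int = 2000
    year_end: int = 2030
    age_schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA
    seed: int = 0
    growth_range: tuple[float, float] = (0.000, 0.020)  # annual log growth
    aging_drift: float = 0.0015  # absolute 65+ share increase per year
    base_age_shares: tuple[float, ...] = (0.12, 0.20, 0.45, 0.13, 0.10)
    age_share_floor: float = 0.01
    rural_share_range: tuple[float, float] = (0.30, 0.70)
    initial_population_range: tuple[float, float] = (1e6, 5e7)
    sanitation_trend: SanitationTrendConfig = field(default_factory=SanitationTrendConfig)
    mortality_effects: MortalityEffectsConfig = field(default_factory=MortalityEffectsConfig)
    cause: str = "diarrhea"
    rr_defaults: tuple[tuple[str, float, float, float], ...] = (
        ("unimproved", 2.5, 1.8, 3.2),
        ("improved", 1.3, 1.1, 1.6),
    )

    def __post_init__(self) -> None:
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        validate_schema(self.age_schema)
        if len(self.base_age_shares) != len(self.age_schema):
            raise ValueError("base_age_shares length must match age schema")
        if len(self.mortality_effects.age_effects) != len(self.age_schema):
            raise ValueError("age_effects length must match age schema")
        for rng in (self.growth_range, self.rural_share_range,
                    self.initial_population_range):
            if rng[1] < rng[0]:
                raise ValueError(f"ill-ordered range {rng}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def countries(self) -> list[str]:
        # synthetic ISO-alpha-3-style codes: SAA, SAB, ...
        out = []
        for i in range(self.n_countries):
            out.append("S" + chr(ord("A") + i // 26) + chr(ord("A") + i % 26))
        return out


def _rng(config: WorldConfig, stream: int, country_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream, country_index))
    )


def generate_population(config: WorldConfig) -> tuple[PopulationPanel, dict]:
    """Log-linear population growth with an aging age-share simplex."""
    years = config.years
    t = years - config.year_start
    n_bands = len(config.age_schema)
    rows, truth = [], {}
    for ci, country in enumerate(config.countries):
        rng = _rng(config, _STREAM_POPULATION, ci)
        pop0 = np.exp(rng.uniform(*np.log(config.initial_population_range)))
        growth = rng.uniform(*config.growth_range)
        rural = rng.uniform(*config.rural_share_range)
        base = np.asarray(config.base_age_shares, float)
        base = base + rng.normal(0.0, 0.005, n_bands)
        base = np.clip(base, config.age_share_floor, None)
        base /= base.sum()
        totals = pop0 * np.exp(growth * t)
        shares = np.tile(base, (len(years), 1))
        shares[:, -1] = base[-1] + config.aging_drift * t
        shares[:, 0] = base[0] - config.aging_drift * t
        if (shares < config.age_share_floor).any():
            logger.warning(
                "generate_population: %s age shares clipped at floor %.3g",
                country, config.age_share_floor,
            )
            shares = np.clip(shares, config.age_share_floor, None)
        shares /= shares.sum(axis=1, keepdims=True)
        block = pd.DataFrame({"country": country, "year": years,
                              "total_population": totals, "rural_share": rural})
        for b, band in enumerate(config.age_schema):
            block[SHARE_PREFIX + band.label] = shares[:, b]
        rows.append(block)
        truth[country] = {"initial_population": float(pop0), "growth_rate": float(growth),
                          "rural_share": float(rural), "base_age_shares": base.tolist()}
    panel = PopulationPanel(pd.concat(rows, ignore_index=True), config.age_schema)
    return panel, truth


def generate_sanitation(config: WorldConfig) -> tuple[SanitationShares, dict]:
    """Declining-logistic unimproved share; remainder split sewer vs improved."""
    years = config.years
    frac = (years - config.year_start) / max(len(years) - 1, 1)
    tc = config.sanitation_trend
    rows, truth = [], {}
    for ci, country in enumerate(config.countries):
        rng = _rng(config, _STREAM_SANITATION, ci)
        mid = rng.uniform(*tc.midpoint_year_range)
        slope = rng.uniform(*tc.slope_range)
        amp = rng.uniform(*tc.start_unimproved_range)
        f0 = rng.uniform(*tc.sewer_fraction_start_range)
        f1 = rng.uniform(*tc.sewer_fraction_end_range)
        u = amp * expit(-slope * (years - mid))
        if tc.logit_noise > 0:
            u = expit(logit(np.clip(u, 1e-9, 1 - 1e-9))
                      + rng.normal(0.0, tc.logit_noise, len(years)))
        f = f0 + (max(f1, f0) - f0) * frac
        sewer = (1.0 - u) * f
        improved = (1.0 - u) * (1.0 - f)
        rows.append(pd.DataFrame({"country": country, "year": years, "sewer": sewer,
                                  "improved": improved, "unimproved": u}))
        truth[country] = {"logistic_midpoint": float(mid), "logistic_slope": float(slope),
                          "start_unimproved": float(amp),
                          "sewer_fraction_start": float(f0),
                          "sewer_fraction_end": float(max(f1, f0))}
    return SanitationShares(pd.concat(rows, ignore_index=True)), truth


def generate_mortality(config: WorldConfig) -> tuple[MortalityPanel, dict]:
    """Log-linear APC mortality surface; stored truth supports recovery tests.

    The returned truth holds, per country, the identifiable version of the
    generative effects (age and cohort effects centered, cohort detrended,
    the surface's full temporal drift carried by the period effect), so that
    estimates fitted under the package's identifiability constraints are
    directly comparable.
    """
    years = config.years
    me = config.mortality_effects
    schema = config.age_schema
    mids = np.array([b.midpoint for b in schema])
    # global cohort-bin range shared across countries
    bins = np.arange(cohort_bin(years[0], mids.max()), cohort_bin(years[-1], mids.min()) + 1)
    rows, truth = [], {}
    A = np.asarray(me.age_effects, float)
    A = A - A.mean()
    for ci, country in enumerate(config.countries):
        rng = _rng(config, _STREAM_MORTALITY, ci)
        alpha = np.log(rng.uniform(*me.baseline_rate_range))
        P = me.period_slope * (years - years.mean())
        C = np.cumsum(rng.normal(0.0, me.cohort_scale, len(bins)))
        # project cohort effects onto the identified space: centered, zero slope
        k = bins - bins.mean()
        C = C - C.mean()
        C = C - (C @ k) / (k @ k) * k
        noise = rng.normal(0.0, me.noise_scale, (len(schema), len(years)))
        for ai, band in enumerate(schema):
            kidx = np.array([cohort_bin(y, mids[ai]) for y in years]) - bins[0]
            log_rate = alpha + A[ai] + P + C[kidx] + noise[ai]
            rate = np.exp(log_rate)
            rows.append(pd.DataFrame({
                "country": country, "year": years, "age_band": band.label,
                "cause": config.cause, "rate": rate,
                "rate_lo": rate * np.exp(-1.96 * me.bound_log_sd),
                "rate_hi": rate * np.exp(1.96 * me.bound_log_sd),
            }))
        truth[country] = {
            "alpha": float(alpha), "age_effects": A.tolist(),
            "period_slope": float(me.period_slope),
            "period_effects": P.tolist(), "period_years": years.tolist(),
            "cohort_effects": C.tolist(), "cohort_bins": bins.tolist(),
            "noise_scale": float(me.noise_scale),
        }
    return MortalityPanel(pd.concat(rows, ignore_index=True)), truth


def generate_rr(config: WorldConfig) -> list[RRRecord]:
    """Fixed relative-risk records per non-referent ladder category."""
    return [
        RRRecord(cat, config.cause, rr, lo, hi)
        for cat, rr, lo, hi in config.rr_defaults
    ]


@dataclass
class World:
    """A complete synthetic study world plus its generative ground truth."""

    config: WorldConfig
    population: PopulationPanel
    sanitation: SanitationShares
    mortality: MortalityPanel
    rr: list[RRRecord]
    truth: dict

    def write(self, out_dir) -> None:
        from pathlib import Path
        import json

        from . import panel_io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        panel_io.write_population_panel(self.population, out / "population.csv")
        panel_io.write_sanitation_shares(self.sanitation, out / "sanitation.csv")
        panel_io.write_mortality_panel(self.mortality, out / "mortality.csv")
        panel_io.write_rr_records(self.rr, out / "rr.csv")
        meta = {"seed": self.config.seed, "truth": self.truth}
        (out / "truth.json").write_text(json.dumps(meta, indent=2))


def generate_world(config: WorldConfig) -> World:
    population, pop_truth = generate_population(config)
    sanitation, san_truth = generate_sanitation(config)
    mortality, mort_truth = generate_mortality(config)
    rr = generate_rr(config)
    truth = {"seed": config.seed, "population": pop_truth,
             "sanitation": san_truth, "mortality": mort_truth}
    return World(config, population, sanitation, mortality, rr, truth)
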