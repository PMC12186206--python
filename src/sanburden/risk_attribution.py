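"""Comparative risk assessment: PAFs, attributable deaths, age-standardized rates.

For a dichotomous exposure with prevalence ``p`` and relative risk ``RR``,
the population-average relative risk is ``RRbar = p (RR - 1) + 1`` and the
population attributable fraction is ``PAF = (RRbar - 1) / RRbar``.  PAFs
for independent risk factors combine multiplicatively on the survival
scale, ``PAF = 1 - prod_A (1 - PAF_A)``.  Attributable deaths in a
country-year are

    deaths = POP * rural_share * AgeP_a * (Rate_a / 100000) * PAF_a

summed over age bands; the rural population is assumed to share the age
structure of the total population (an explicit, logged modelling
assumption).  Age-standardized rates weight the age-specific attributable
death rates of the rural population by a fixed standard population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    REFERENT_CATEGORY,
    MortalityPanel,
    PopulationPanel,
    RRRecord,
    SanitationShares,
)
from .schema import StandardPopulation

logger = logging.getLogger(__name__)

AGE_STRUCTURE_ASSUMPTION = (
    "rural age structure assumed congruent with the total population's"
)


def mean_relative_risk(p: float, rr: float) -> float:
    """Population-average relative risk ``p (rr - 1) + 1`` for binary exposure."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"exposed fraction p={p} outside [0, 1]")
    if rr < 0:
        raise ValueError("relative risk must be >= 0")
    return p * (rr - 1.0) + 1.0


def paf_single(p: float, rr: float, clamp_protective: bool = False) -> float:
    """PAF of one factor: ``(RRbar - 1) / RRbar``; lies in [0, 1) for rr >= 1.

    ``rr < 1`` (a protective exposure) is rejected by default — the
    attribution model covers harmful exposure only; with
    ``clamp_protective=True`` the PAF is clamped at 0 instead.
    """
    if rr < 0:
        raise ValueError("relative risk must be >= 0")
    if rr < 1.0:
        if clamp_protective:
            return 0.0
        raise ValueError(
            f"rr={rr} < 1: protective exposures are rejected under the default policy"
        )
    rr_bar = mean_relative_risk(p, rr)
    return (rr_bar - 1.0) / rr_bar


def paf_combined(pafs: Iterable[float]) -> float:
    """Multiplicative combination ``1 - prod(1 - PAF_A)`` of independent factors."""
    out = 1.0
    for paf in pafs:
        if not 0.0 <= paf < 1.0:
            raise ValueError(f"PAF {paf} outside [0, 1)")
        out *= 1.0 - paf
    return 1.0 - out


@dataclass
class PAFTable:
    """Combined PAF per (country, year, age_band?, cause); fractions in [0, 1)."""

    data: pd.DataFrame  # columns: country, year, age_band (may be "*"), cause, paf

    def __post_init__(self) -> None:
        if ((self.data["paf"] < 0) | (self.data["paf"] >= 1)).any():
            raise ValueError("PAF outside [0, 1)")


def compute_paf_table(shares: SanitationShares, rr: Sequence[RRRecord],
                      clamp_protective: bool = False) -> PAFTable:
    """Per country-year combined PAF from ladder shares and RR records.

    Each non-referent exposure category with an RR record contributes a
    single-factor PAF evaluated at that category's own share; the factors
    combine multiplicatively.  Records with an ``age_band`` produce
    age-specific rows; records without apply to all ages (band ``"*"``).
    """
    for rec in rr:
        if rec.exposure_category not in shares.data.columns:
            raise ValueError(
                f"RR record references category {rec.exposure_category!r} "
                "absent from the shares panel"
            )
        if rec.exposure_category == REFERENT_CATEGORY:
            raise ValueError("RR record for the referent category")

    rows = []
    by_key: dict[tuple[str, str], list[RRRecord]] = {}
    for rec in rr:
        by_key.setdefault((rec.cause, rec.age_band or "*"), []).append(rec)
    share_df = shares.data
    for (cause, band), recs in sorted(by_key.items()):
        paf_parts = []
        for rec in recs:
            p = share_df[rec.exposure_category].to_numpy(float)
            if rec.rr < 1.0 and not clamp_protective:
                raise ValueError(f"rr < 1 for {rec.exposure_category}: rejected")
            rr_eff = max(rec.rr, 1.0) if clamp_protective else rec.rr
            rr_bar = p * (rr_eff - 1.0) + 1.0
            paf_parts.append((rr_bar - 1.0) / rr_bar)
        combined = 1.0 - np.prod([1.0 - np.asarray(x) for x in paf_parts], axis=0)
        block = pd.DataFrame(
            {
                "country": share_df["country"].to_numpy(),
                "year": share_df["year"].to_numpy(),
                "age_band": band,
                "cause": cause,
                "paf": combined,
            }
        )
        rows.append(block)
    return PAFTable(pd.concat(rows, ignore_index=True))


@dataclass
class BurdenPanel:
    """Attributable deaths per (country, year, age_band, cause) with 95% bounds."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("deaths", "deaths_lo", "deaths_hi"):
            if col in df.columns and (df[col] < 0).any():
                raise ValueError(f"negative {col}")
        if {"deaths_lo", "deaths_hi"} <= set(df.columns):
            if ((df["deaths_lo"] > df["deaths"] + 1e-9)
                    | (df["deaths"] > df["deaths_hi"] + 1e-9)).any():
                raise ValueError("death bounds not ordered")


def _expand_paf_to_bands(paf: PAFTable, bands: Sequence[str]) -> pd.DataFrame:
    """Broadcast all-age ('*') PAF rows onto explicit age bands."""
    df = paf.data
    star = df[df["age_band"] == "*"]
    explicit = df[df["age_band"] != "*"]
    blocks = [explicit]
    for band in bands:
        b = star.copy()
        b["age_band"] = band
        blocks.append(b)
    return pd.concat(blocks, ignore_index=True)


def attributable_deaths(pop: PopulationPanel, mortality: MortalityPanel,
                        paf: PAFTable, rural: bool = True) -> BurdenPanel:
    """Attributable death counts per cell (Eq. deaths = POP*AgeP*Rate*PAF).

    With ``rural=True`` (the default and the pipeline's mode) the population
    at risk is ``total_population * rural_share``, with the age structure of
    the total population applied to the rural subpopulation.
    """
    if rural:
        logger.info("attributable_deaths: %s", AGE_STRUCTURE_ASSUMPTION)
    bands = list(mortality.data["age_band"].unique())
    paf_df = _expand_paf_to_bands(paf, bands)

    pop_long = pop.data.melt(
        id_vars=["country", "year", "total_population", "rural_share"],
        value_vars=pop.share_columns, var_name="age_band", value_name="age_share",
    )
    pop_long["age_band"] = pop_long["age_band"].str.removeprefix("share_")

    merged = mortality.data.merge(pop_long, on=["country", "year", "age_band"], how="left")
    if merged["age_share"].isna().any():
        bad = merged.loc[merged["age_share"].isna(),
                         ["country", "year", "age_band"]].to_dict("records")[:5]
        raise KeyError(f"population cells missing for mortality cells {bad}")
    merged = merged.merge(paf_df, on=["country", "year", "age_band", "cause"], how="left")
    if merged["paf"].isna().any():
        bad = merged.loc[merged["paf"].isna(),
                         ["country", "year", "age_band", "cause"]].to_dict("records")[:5]
        raise KeyError(f"PAF cells missing for mortality cells {bad}")

    at_risk = merged["total_population"] * (merged["rural_share"] if rural else 1.0)
    base = at_risk * merged["age_share"] / 1e5
    out = merged[["country", "year", "age_band", "cause"]].copy()
    out["deaths"] = base * merged["rate"] * merged["paf"]
    out["at_risk_population"] = at_risk * merged["age_share"]
    return BurdenPanel(out)


def age_standardized_rate(burden: BurdenPanel, pop: PopulationPanel,
                          std: StandardPopulation,
                          value_col: str = "deaths") -> pd.DataFrame:
    """Directly standardized attributable death rate per 100,000, per country-year.

    ``ASR = sum_a w_a * (deaths_a / rural_pop_a) * 100000``; invariant to a
    common scaling of all age-band populations.
    """
    weights = std.as_series()
    df = burden.data.groupby(["country", "year", "age_band"], as_index=False).agg(
        deaths=(value_col, "sum"), at_risk=("at_risk_population", "first")
    )
    if ((df["at_risk"] <= 0) & (df["deaths"] > 0)).any():
        bad = df.loc[(df["at_risk"] <= 0) & (df["deaths"] > 0),
                     ["country", "year", "age_band"]].to_dict("records")[:5]
        raise ValueError(f"zero population with nonzero deaths at {bad}")
    df["crude_rate"] = np.where(df["at_risk"] > 0, df["deaths"] / df["at_risk"] * 1e5, 0.0)
    df["w"] = df["age_band"].map(weights)
    if df["w"].isna().any():
        raise KeyError("burden age band missing from the standard population")
    out = (
        df.assign(wr=df["w"] * df["crude_rate"])
        .groupby(["country", "year"], as_index=False)
        .agg(asr=("wr", "sum"))
    )
    return out
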