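"""Tabular panel containers, CSV readers/writers, and world-level validation.

All panels are tidy (long-format) UTF-8 CSV files with one header row, one
row per key combination, mirroring the export style of the public mortality
and sanitation-coverage databases the pipeline is designed around.  Units
are fixed package-wide: populations in persons, mortality rates per 100,000
person-years, coverage shares as fractions in [0, 1] (never percent —
readers reject share-like columns above 1.5 to catch percent inputs).

File dialects
-------------
``population.csv``  country, year, total_population, rural_share, share_<band>...
``sanitation.csv``  counts: country, year, nonmissing_respondents,
                    sewer_respondents, improved_respondents_among_nonsewer
                    shares: country, year, sewer, improved, unimproved
``mortality.csv``   country, year, age_band, cause, rate, rate_lo, rate_hi
``rr.csv``          exposure_category, cause, rr, rr_lo, rr_hi[, age_band]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import AgeBand, DEFAULT_AGE_SCHEMA, validate_schema

SHARE_PREFIX = "share_"
EXPOSURE_CATEGORIES = ("sewer", "improved", "unimproved")
REFERENT_CATEGORY = "sewer"


class PanelSchemaError(ValueError):
    """A file is missing required columns or uses an unknown layout."""


class PanelValidationError(ValueError):
    """Rows violate a panel invariant (simplex, ordering, duplicates...)."""


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{what}: missing column(s) {missing}")


def _check_no_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        rows = df.loc[dup, keys].head(5).to_dict("records")
        raise PanelValidationError(f"{what}: duplicate keys {rows}")


def _check_contiguous_years(df: pd.DataFrame, what: str) -> None:
    for country, grp in df.groupby("country"):
        years = np.sort(grp["year"].unique())
        if len(years) and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise PanelValidationError(
                f"{what}: years not contiguous for {country}: {years.tolist()}"
            )


@dataclass
class PopulationPanel:
    """Country-year totals, rural share, and an age-share simplex vector."""

    data: pd.DataFrame
    schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA

    def __post_init__(self) -> None:
        self.schema = validate_schema(self.schema)
        df = self.data
        share_cols = self.share_columns
        _require_columns(
            df, ["country", "year", "total_population", "rural_share", *share_cols],
            "population panel",
        )
        _check_no_duplicates(df, ["country", "year"], "population panel")
        _check_contiguous_years(df, "population panel")
        if (df["total_population"] <= 0).any():
            raise PanelValidationError("population panel: total_population must be > 0")
        if ((df["rural_share"] < 0) | (df["rural_share"] > 1)).any():
            raise PanelValidationError("population panel: rural_share outside [0,1]")
        shares = df[share_cols].to_numpy(float)
        if (shares > 1.5).any():
            raise PanelValidationError(
                "population panel: age share > 1.5 — shares must be fractions, not percent"
            )
        sums = shares.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            rows = df.loc[bad, ["country", "year"]].to_dict("records")[:5]
            raise PanelValidationError(
                f"population panel: age_shares sum {sums[bad][0]:.6g} != 1 at {rows}"
            )

    @property
    def share_columns(self) -> list[str]:
        return [SHARE_PREFIX + b.label for b in self.schema]

    def age_shares(self, country: str, year: int) -> np.ndarray:
        row = self.data[(self.data.country == country) & (self.data.year == year)]
        if row.empty:
            raise KeyError(f"no population row for ({country}, {year})")
        return row[self.share_columns].to_numpy(float)[0]

    def countries(self) -> list[str]:
        return sorted(self.data["country"].unique())


@dataclass
class SanitationRawPanel:
    """Raw survey respondent counts feeding the sanitation-ladder normalization."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(
            df,
            ["country", "year", "nonmissing_respondents", "sewer_respondents",
             "improved_respondents_among_nonsewer"],
            "sanitation raw panel",
        )
        _check_no_duplicates(df, ["country", "year"], "sanitation raw panel")
        for col in ("nonmissing_respondents", "sewer_respondents",
                    "improved_respondents_among_nonsewer"):
            if (df[col] < 0).any():
                raise PanelValidationError(f"sanitation raw panel: negative {col}")
        if (df["sewer_respondents"] > df["nonmissing_respondents"]).any():
            raise PanelValidationError(
                "sanitation raw panel: sewer_respondents > nonmissing_respondents"
            )
        rem = df["nonmissing_respondents"] - df["sewer_respondents"]
        if (df["improved_respondents_among_nonsewer"] > rem).any():
            raise PanelValidationError(
                "sanitation raw panel: improved respondents exceed non-sewer respondents"
            )


@dataclass
class SanitationShares:
    """Per country-year exposure distribution over the three-rung sanitation ladder.

    Columns ``sewer, improved, unimproved`` are fractions on the simplex;
    optional ``*_lo``/``*_hi`` columns carry 95% bounds for projected years.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(df, ["country", "year", *EXPOSURE_CATEGORIES], "sanitation shares")
        _check_no_duplicates(df, ["country", "year"], "sanitation shares")
        vals = df[list(EXPOSURE_CATEGORIES)].to_numpy(float)
        if (vals > 1.5).any():
            raise PanelValidationError(
                "sanitation shares: value > 1.5 — shares must be fractions, not percent"
            )
        if ((vals < 0) | (vals > 1)).any():
            raise PanelValidationError("sanitation shares: share outside [0,1]")
        sums = vals.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            rows = df.loc[bad, ["country", "year"]].to_dict("records")[:5]
            raise PanelValidationError(f"sanitation shares off simplex at {rows}")


@dataclass
class MortalityPanel:
    """Cause-specific death rates per 100,000 by country, year, age band."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _require_columns(
            df, ["country", "year", "age_band", "cause", "rate", "rate_lo", "rate_hi"],
            "mortality panel",
        )
        _check_no_duplicates(df, ["country", "year", "age_band", "cause"], "mortality panel")
        for col in ("rate", "rate_lo", "rate_hi"):
            if (df[col] < 0).any():
                raise PanelValidationError(f"mortality panel: negative {col}")
        if ((df["rate_lo"] > df["rate"]) | (df["rate"] > df["rate_hi"])).any():
            raise PanelValidationError("mortality panel: bounds not ordered rate_lo <= rate <= rate_hi")


@dataclass(frozen=True)
class RRRecord:
    """Relative risk of a cause for one exposure category vs the sewer referent."""

    exposure_category: str
    cause: str
    rr: float
    rr_lo: float
    rr_hi: float
    age_band: str | None = None

    def __post_init__(self) -> None:
        if self.exposure_category == REFERENT_CATEGORY:
            raise PanelValidationError("RR record for the referent category is meaningless")
        if self.exposure_category not in EXPOSURE_CATEGORIES:
            raise PanelValidationError(
                f"unknown exposure category {self.exposure_category!r}"
            )
        if self.rr < 0:
            raise PanelValidationError("relative risk must be >= 0")
        if not (self.rr_lo <= self.rr <= self.rr_hi):
            raise PanelValidationError("RR bounds not ordered rr_lo <= rr <= rr_hi")


# ---------------------------------------------------------------------------
# readers / writers


def read_population_panel(path: str | Path,
                          schema: Sequence[AgeBand] = DEFAULT_AGE_SCHEMA) -> PopulationPanel:
    df = pd.read_csv(path)
    return PopulationPanel(df, tuple(schema))


def write_population_panel(panel: PopulationPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def read_mortality_panel(path: str | Path) -> MortalityPanel:
    return MortalityPanel(pd.read_csv(path))


def write_mortality_panel(panel: MortalityPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def read_sanitation_panel(path: str | Path, raw_counts: bool = False):
    """Read sanitation coverage, either normalized shares or raw counts.

    ``raw_counts=True`` selects the respondent-count layout; the default
    expects pre-normalized fraction shares.
    """
    df = pd.read_csv(path)
    if raw_counts:
        return SanitationRawPanel(df)
    return SanitationShares(df)


def write_sanitation_shares(panel: SanitationShares, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def write_sanitation_raw(panel: SanitationRawPanel, path: str | Path) -> None:
    panel.data.to_csv(path, index=False)


def read_rr_records(path: str | Path) -> list[RRRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["exposure_category", "cause", "rr", "rr_lo", "rr_hi"], "rr table")
    records = []
    for row in df.to_dict("records"):
        band = row.get("age_band")
        if band is not None and (pd.isna(band) or band == ""):
            band = None
        records.append(
            RRRecord(row["exposure_category"], row["cause"], float(row["rr"]),
                     float(row["rr_lo"]), float(row["rr_hi"]), band)
        )
    return records


def write_rr_records(records: Sequence[RRRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"exposure_category": r.exposure_category, "cause": r.cause,
             "rr": r.rr, "rr_lo": r.rr_lo, "rr_hi": r.rr_hi, "age_band": r.age_band}
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# world-level validation


@dataclass
class WorldValidationReport:
    """Which countries are usable over the configured year range.

    Countries with any missing (country, year) cell in any panel are flagged
    for hard exclusion; the pipeline never imputes.
    """

    year_range: tuple[int, int]
    excluded: dict[str, list[str]] = field(default_factory=dict)

    @property
    def excluded_countries(self) -> list[str]:
        return sorted(self.excluded)

    def included(self, countries: Iterable[str]) -> list[str]:
        return sorted(set(countries) - set(self.excluded))


def validate_world(population: PopulationPanel,
                   sanitation: SanitationShares | SanitationRawPanel,
                   mortality: MortalityPanel,
                   rr: Sequence[RRRecord],
                   year_range: tuple[int, int] | None = None) -> WorldValidationReport:
    """Flag countries with any missing cell across the panels (report-only).

    The report is order-independent in the input rows.  An empty world
    yields an all-excluded (empty-universe) report rather than an error.
    """
    panels = {
        "population": population.data,
        "sanitation": sanitation.data,
        "mortality": mortality.data,
    }
    all_countries = sorted(
        set().union(*(set(df["country"].unique()) for df in panels.values()))
    )
    if year_range is None:
        years = pd.concat([df["year"] for df in panels.values()])
        if years.empty:
            return WorldValidationReport((0, -1))
        year_range = (int(years.min()), int(years.max()))
    lo, hi = year_range
    expected_years = set(range(lo, hi + 1))

    n_bands = {len(mortality.data["age_band"].unique())} if len(mortality.data) else set()
    excluded: dict[str, list[str]] = {}
    for country in all_countries:
        reasons = []
        for name, df in panels.items():
            have = set(df.loc[df["country"] == country, "year"].astype(int))
            missing = sorted(expected_years - have)
            if missing:
                reasons.append(f"{name}: missing years {missing}")
        mort_c = mortality.data[mortality.data["country"] == country]
        if not mort_c.empty and n_bands:
            per_year = mort_c.groupby("year")["age_band"].nunique()
            short = per_year[per_year < max(n_bands)]
            if not short.empty:
                reasons.append(f"mortality: incomplete age bands in years {short.index.tolist()}")
        if reasons:
            excluded[country] = reasons
    if not rr:
        # no relative risks at all: attribution is impossible for everyone
        for country in all_countries:
            excluded.setdefault(country, []).append("rr: no relative-risk records")
    return WorldValidationReport(year_range, excluded)
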