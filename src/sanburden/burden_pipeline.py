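"""End-to-end orchestration: normalize, forecast, attribute, standardize, decompose.

``run_pipeline`` drives the full analysis on validated panels:

1. world validation (countries with any missing cell are excluded outright);
2. per-country Bayesian APC fit on the observed mortality surface and
   projection over the configured horizon;
3. per-country compositional ARIMA forecast of the sanitation ladder;
4. PAF and attributable-death computation for every year, observed and
   projected, with 95% bounds propagated by endpoint substitution: the
   lower death bound evaluates the attribution formulas at the lower
   limits of the exposed shares, mortality rates and (optionally) relative
   risks, the upper bound at the upper limits — valid because attributable
   deaths are monotone increasing in each of those inputs;
5. age-standardized attributable death rates per country-year;
6. Shapley driver decomposition at the configured breakpoint years.

The pipeline is a pure function of (inputs, config, seed).  Rural
populations are ``total_population * rural_share`` with the total
population's age structure applied to the rural subpopulation — an
explicit, logged assumption.  A Monte Carlo bounds mode (sampling shares,
rates and RRs within their intervals) is provided as an optional
cross-check of the endpoint-substitution scheme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, fields as _dc_fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .driver_decomposition import DEFAULT_FACTORS, decompose_timeline
from .exposure_forecast import ArimaOrder, forecast_composition
from .mortality_forecast import APCConfig, APCMortalityModel
from .panel_io import (
    MortalityPanel,
    PopulationPanel,
    RRRecord,
    SanitationShares,
    read_mortality_panel,
    read_population_panel,
    read_rr_records,
    read_sanitation_panel,
    validate_world,
)
from .risk_attribution import AGE_STRUCTURE_ASSUMPTION, BurdenPanel
from .schema import AgeBand, DEFAULT_AGE_SCHEMA, StandardPopulation, validate_schema

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    history_start: int = 2000
    history_end: int = 2020
    horizon: int = 10
    age_schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA
    seed: int = 0
    # attribution
    include_rr_bounds: bool = True
    clamp_protective: bool = False
    # forecasting
    apc_chains: int = 2
    apc_draws: int = 600
    apc_warmup: int = 300
    arima_max_orders: ArimaOrder = ArimaOrder(2, 2, 2)
    composition_mode: str = "alr"
    # reporting
    breakpoints: tuple[int, ...] = (2000, 2010, 2020, 2030)
    factors: tuple[str, ...] = DEFAULT_FACTORS
    grouping: dict[str, str] | None = None
    # optional file inputs (in-memory panels may be passed to run_pipeline instead)
    population_path: str | None = None
    sanitation_path: str | None = None
    sanitation_raw_counts: bool = False
    mortality_path: str | None = None
    rr_path: str | None = None

    def __post_init__(self) -> None:
        if self.history_end <= self.history_start:
            raise ValueError("history_end must exceed history_start")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        self.age_schema = validate_schema(self.age_schema)
        bad = [b for b in self.breakpoints
               if not self.history_start <= b <= self.history_end + self.horizon]
        if bad:
            raise ValueError(f"breakpoints {bad} outside the analysis span")

    @property
    def projection_end(self) -> int:
        return self.history_end + self.horizon

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML file mirroring the dataclass field-for-field.

        ``age_schema`` is given as a list of ``{label, lower, upper}`` tables
        (omit ``upper`` for the open-ended band); ``arima_max_orders`` as a
        three-integer list; everything else as scalars / lists of scalars.
        """
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kwargs: dict = dict(raw)
        if "age_schema" in kwargs:
            kwargs["age_schema"] = tuple(
                AgeBand(b["label"], int(b["lower"]),
                        int(b["upper"]) if "upper" in b else None)
                for b in kwargs["age_schema"]
            )
        if "arima_max_orders" in kwargs:
            kwargs["arima_max_orders"] = ArimaOrder(*kwargs["arima_max_orders"])
        for key in ("breakpoints", "factors"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in _dc_fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RunReport:
    config: PipelineConfig
    seed: int
    burden: pd.DataFrame  # per country-year-age-cause with bounds
    dausr: pd.DataFrame  # per country-year totals with bounds
    global_dausr: pd.DataFrame
    asr: pd.DataFrame  # per country-year with bounds
    global_asr: pd.DataFrame
    decomposition: pd.DataFrame
    shares: pd.DataFrame  # observed + projected sanitation shares
    mortality: pd.DataFrame  # observed + projected rates
    excluded: dict[str, list[str]]
    version: str = _pkg_version

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.burden.to_csv(out / "burden.csv", index=False)
        self.dausr.to_csv(out / "dausr.csv", index=False)
        self.asr.to_csv(out / "asr.csv", index=False)
        self.decomposition.to_csv(out / "decomposition.csv", index=False)
        self.shares.to_csv(out / "shares.csv", index=False)
        self.mortality.to_csv(out / "mortality_full.csv", index=False)
        pd.DataFrame(
            [{"country": c, "reasons": "; ".join(r)} for c, r in self.excluded.items()]
        ).to_csv(out / "exclusions.csv", index=False)
        cfg = asdict(self.config)
        cfg["age_schema"] = [b.label for b in self.config.age_schema]
        cfg["arima_max_orders"] = list(self.config.arima_max_orders)
        (out / "run_report.json").write_text(json.dumps(
            {"version": self.version, "seed": self.seed, "config": cfg,
             "excluded": self.excluded}, indent=2, default=str))


# ---------------------------------------------------------------------------
# bound propagation


def _paf_with_bounds(shares: pd.DataFrame, rr: Sequence[RRRecord],
                     include_rr_bounds: bool, clamp_protective: bool) -> pd.DataFrame:
    """Combined PAF point/lo/hi per row of a shares frame (with *_lo/_hi cols)."""
    def single(p: np.ndarray, r: float) -> np.ndarray:
        if r < 1.0:
            if not clamp_protective:
                raise ValueError(f"rr {r} < 1 rejected under the default policy")
            r = 1.0
        rr_bar = p * (r - 1.0) + 1.0
        return (rr_bar - 1.0) / rr_bar

    surv = {"paf": 1.0, "paf_lo": 1.0, "paf_hi": 1.0}
    for rec in rr:
        cat = rec.exposure_category
        p = shares[cat].to_numpy(float)
        p_lo = shares.get(cat + "_lo", shares[cat]).to_numpy(float)
        p_hi = shares.get(cat + "_hi", shares[cat]).to_numpy(float)
        # observed years carry no share bounds: degenerate intervals
        p_lo = np.where(np.isnan(p_lo), p, p_lo)
        p_hi = np.where(np.isnan(p_hi), p, p_hi)
        if ((p_lo > p + 1e-12) | (p > p_hi + 1e-12)).any():
            raise ValueError(f"crossed share bounds for category {cat!r}")
        r_lo, r_hi = (rec.rr_lo, rec.rr_hi) if include_rr_bounds else (rec.rr, rec.rr)
        surv["paf"] = surv["paf"] * (1.0 - single(p, rec.rr))
        surv["paf_lo"] = surv["paf_lo"] * (1.0 - single(p_lo, r_lo))
        surv["paf_hi"] = surv["paf_hi"] * (1.0 - single(p_hi, r_hi))
    out = shares[["country", "year"]].copy()
    for k, v in surv.items():
        out[k] = 1.0 - v
    return out


def propagate_bounds(population: PopulationPanel, mortality: MortalityPanel,
                     shares: SanitationShares, rr: Sequence[RRRecord],
                     include_rr_bounds: bool = True,
                     clamp_protective: bool = False) -> BurdenPanel:
    """Attributable deaths with 95% bounds by endpoint substitution.

    ``deaths_lo`` evaluates the attribution at the lower limits of the
    exposed shares, rates and (optionally) RRs; ``deaths_hi`` at the upper
    limits.  Monotonicity of the formulas in those inputs guarantees
    ``deaths_lo <= deaths <= deaths_hi``.
    """
    mort = mortality.data
    if ((mort["rate_lo"] > mort["rate"]) | (mort["rate"] > mort["rate_hi"])).any():
        raise ValueError("crossed mortality rate bounds")
    paf = _paf_with_bounds(shares.data, rr, include_rr_bounds, clamp_protective)

    pop_long = population.data.melt(
        id_vars=["country", "year", "total_population", "rural_share"],
        value_vars=population.share_columns, var_name="age_band", value_name="age_share",
    )
    pop_long["age_band"] = pop_long["age_band"].str.removeprefix("share_")
    merged = mort.merge(pop_long, on=["country", "year", "age_band"], how="left")
    if merged["age_share"].isna().any():
        bad = merged.loc[merged["age_share"].isna(),
                         ["country", "year", "age_band"]].to_dict("records")[:5]
        raise KeyError(f"population cells missing: {bad}")
    merged = merged.merge(paf, on=["country", "year"], how="left")
    if merged["paf"].isna().any():
        bad = merged.loc[merged["paf"].isna(), ["country", "year"]].to_dict("records")[:5]
        raise KeyError(f"sanitation shares missing: {bad}")
    base = merged["total_population"] * merged["rural_share"] * merged["age_share"] / 1e5
    out = merged[["country", "year", "age_band", "cause"]].copy()
    out["deaths"] = base * merged["rate"] * merged["paf"]
    out["deaths_lo"] = base * merged["rate_lo"] * merged["paf_lo"]
    out["deaths_hi"] = base * merged["rate_hi"] * merged["paf_hi"]
    out["at_risk_population"] = merged["total_population"] * merged["rural_share"] \
        * merged["age_share"]
    return BurdenPanel(out)


def monte_carlo_bounds(population: PopulationPanel, mortality: MortalityPanel,
                       shares: SanitationShares, rr: Sequence[RRRecord],
                       n_draws: int = 200, seed: int = 0) -> pd.DataFrame:
    """Optional cross-check: country-year death intervals by sampling inputs.

    Rates and RRs are sampled log-normally within their 95% intervals,
    exposed shares uniformly within theirs.  Returns per country-year
    2.5/97.5 percentiles of total attributable deaths.  This is an
    extension for sanity-checking the endpoint-substitution scheme, not
    the reported uncertainty method.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(31,)))
    mort = mortality.data
    sh = shares.data
    totals = []
    for _ in range(n_draws):
        z = rng.standard_normal(len(mort))
        sd = np.log(np.maximum(mort["rate_hi"], 1e-300) /
                    np.maximum(mort["rate_lo"], 1e-300)) / (2 * 1.96)
        rate = mort["rate"].to_numpy() * np.exp(z * sd.to_numpy())
        m = mort.assign(rate=rate, rate_lo=rate, rate_hi=rate)
        s = sh.copy()
        for rec in rr:
            cat = rec.exposure_category
            lo = s.get(cat + "_lo", s[cat]).to_numpy(float)
            hi = s.get(cat + "_hi", s[cat]).to_numpy(float)
            s[cat] = rng.uniform(lo, hi)
            s.drop(columns=[c for c in (cat + "_lo", cat + "_hi") if c in s],
                   inplace=True, errors="ignore")
        rr_draw = []
        for rec in rr:
            sd_r = np.log(max(rec.rr_hi, 1e-12) / max(rec.rr_lo, 1e-12)) / (2 * 1.96)
            r = rec.rr * float(np.exp(rng.standard_normal() * sd_r))
            rr_draw.append(RRRecord(rec.exposure_category, rec.cause, max(r, 1.0),
                                    max(r, 1.0), max(r, 1.0), rec.age_band))
        paf = _paf_with_bounds(s, rr_draw, include_rr_bounds=False,
                               clamp_protective=True)
        pop_long = population.data.melt(
            id_vars=["country", "year", "total_population", "rural_share"],
            value_vars=population.share_columns, var_name="age_band",
            value_name="age_share")
        pop_long["age_band"] = pop_long["age_band"].str.removeprefix("share_")
        merged = m.merge(pop_long, on=["country", "year", "age_band"]) \
                  .merge(paf[["country", "year", "paf"]], on=["country", "year"])
        merged["deaths"] = merged["total_population"] * merged["rural_share"] \
            * merged["age_share"] * merged["rate"] / 1e5 * merged["paf"]
        totals.append(merged.groupby(["country", "year"])["deaths"].sum())
    stack = pd.concat(totals, axis=1)
    out = stack.quantile([0.025, 0.975], axis=1).T.reset_index()
    out.columns = ["country", "year", "deaths_lo_mc", "deaths_hi_mc"]
    return out


# ---------------------------------------------------------------------------
# aggregation


def aggregate(burden: BurdenPanel, grouping: dict[str, str],
              std: StandardPopulation) -> pd.DataFrame:
    """Group-level death totals and pooled-population ASR per year.

    Group ASR is recomputed from pooled age-specific deaths and populations,
    never averaged over member-country ASRs.
    """
    df = burden.data.copy()
    unmapped = sorted(set(df["country"].unique()) - set(grouping))
    if unmapped:
        raise KeyError(f"countries missing from the grouping map: {unmapped}")
    df["group"] = df["country"].map(grouping)
    cell = df.groupby(["group", "year", "age_band"], as_index=False).agg(
        deaths=("deaths", "sum"),
        deaths_lo=("deaths_lo", "sum") if "deaths_lo" in df else ("deaths", "sum"),
        deaths_hi=("deaths_hi", "sum") if "deaths_hi" in df else ("deaths", "sum"),
        at_risk=("at_risk_population", "sum"),
    )
    weights = std.as_series()
    cell["w"] = cell["age_band"].map(weights)
    with np.errstate(divide="ignore", invalid="ignore"):
        for col, out_col in (("deaths", "asr"), ("deaths_lo", "asr_lo"),
                             ("deaths_hi", "asr_hi")):
            cell[out_col] = np.where(cell["at_risk"] > 0,
                                     cell[col] / cell["at_risk"] * 1e5, 0.0) * cell["w"]
    out = cell.groupby(["group", "year"], as_index=False).agg(
        deaths=("deaths", "sum"), deaths_lo=("deaths_lo", "sum"),
        deaths_hi=("deaths_hi", "sum"), asr=("asr", "sum"),
        asr_lo=("asr_lo", "sum"), asr_hi=("asr_hi", "sum"),
    )
    return out


# ---------------------------------------------------------------------------
# the pipeline


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, err: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _load_inputs(config: PipelineConfig):
    population = read_population_panel(config.population_path, config.age_schema)
    sanitation = read_sanitation_panel(config.sanitation_path,
                                       raw_counts=config.sanitation_raw_counts)
    if config.sanitation_raw_counts:
        from .exposure_ladder import normalize_panel

        sanitation = normalize_panel(sanitation)
    mortality = read_mortality_panel(config.mortality_path)
    rr = read_rr_records(config.rr_path)
    return population, sanitation, mortality, rr


def run_pipeline(config: PipelineConfig,
                 population: PopulationPanel | None = None,
                 sanitation: SanitationShares | None = None,
                 mortality: MortalityPanel | None = None,
                 rr: Sequence[RRRecord] | None = None) -> RunReport:
    """Execute the full analysis; fully reproducible from (inputs, config, seed)."""
    if population is None:
        population, sanitation, mortality, rr = _load_inputs(config)
    logger.info("run_pipeline: %s", AGE_STRUCTURE_ASSUMPTION)

    hist_years = (config.history_start, config.history_end)
    mort_hist = MortalityPanel(
        mortality.data[mortality.data.year.between(*hist_years)].reset_index(drop=True))
    san_hist = SanitationShares(
        sanitation.data[sanitation.data.year.between(*hist_years)].reset_index(drop=True))

    report = validate_world(population, san_hist, mort_hist, rr, year_range=hist_years)
    pop_future_ok = set(
        population.data[population.data.year.between(config.history_end + 1,
                                                     config.projection_end)]
        .groupby("country")["year"].nunique()
        .loc[lambda s: s == config.horizon].index
    )
    countries = [c for c in report.included(population.countries())
                 if c in pop_future_ok]
    excluded = dict(report.excluded)
    for c in sorted(set(population.countries()) - set(countries) - set(excluded)):
        excluded[c] = ["population: missing projection years"]
    if not countries:
        raise PipelineStageError("validation", ValueError("no usable countries"))
    logger.info("run_pipeline: %d countries included, %d excluded",
                len(countries), len(excluded))

    # -- stage: mortality projection per country
    mort_blocks = [mort_hist.data.assign(source="observed")]
    for idx, country in enumerate(countries):
        try:
            sub = MortalityPanel(
                mort_hist.data[mort_hist.data.country == country].reset_index(drop=True))
            seed = int(np.random.SeedSequence(
                config.seed, spawn_key=(101, idx)).generate_state(1)[0] % (2 ** 31))
            apc_cfg = APCConfig(age_schema=config.age_schema, horizon=config.horizon,
                                chains=config.apc_chains, draws=config.apc_draws,
                                warmup=config.apc_warmup, seed=seed)
            model = APCMortalityModel(apc_cfg).fit(sub)
            proj = model.project(config.horizon, force=True)
            proj["cause"] = sub.data["cause"].iloc[0]
            proj["source"] = "projected"
            mort_blocks.append(proj)
        except Exception as err:
            raise PipelineStageError("mortality_forecast", err) from err
    mort_full = MortalityPanel(pd.concat(mort_blocks, ignore_index=True))

    # -- stage: sanitation projection per country
    san_blocks = [san_hist.data.assign(source="observed")]
    for country in countries:
        try:
            sub = SanitationShares(
                san_hist.data[san_hist.data.country == country].reset_index(drop=True))
            proj = forecast_composition(sub, config.horizon,
                                        mode=config.composition_mode,
                                        max_orders=config.arima_max_orders)
            san_blocks.append(proj.data.drop(columns=["mode"]).assign(source="projected"))
        except Exception as err:
            raise PipelineStageError("exposure_forecast", err) from err
    san_full = SanitationShares(pd.concat(san_blocks, ignore_index=True))

    # -- stage: attribution with bound propagation
    try:
        pop_used = PopulationPanel(
            population.data[population.data.country.isin(countries)
                            & population.data.year.between(config.history_start,
                                                           config.projection_end)]
            .reset_index(drop=True), config.age_schema)
        burden = propagate_bounds(pop_used, mort_full, san_full, rr,
                                  include_rr_bounds=config.include_rr_bounds,
                                  clamp_protective=config.clamp_protective)
    except Exception as err:
        raise PipelineStageError("risk_attribution", err) from err

    # -- stage: totals, ASR, aggregation
    dausr = burden.data.groupby(["country", "year"], as_index=False).agg(
        deaths=("deaths", "sum"), deaths_lo=("deaths_lo", "sum"),
        deaths_hi=("deaths_hi", "sum"))
    std = StandardPopulation.who_world(config.age_schema)
    per_country = aggregate(burden, {c: c for c in countries}, std).rename(
        columns={"group": "country"})
    asr = per_country[["country", "year", "asr", "asr_lo", "asr_hi"]]
    global_rows = aggregate(burden, {c: "GLOBAL" for c in countries}, std)
    global_dausr = global_rows[["year", "deaths", "deaths_lo", "deaths_hi"]]
    global_asr = global_rows[["year", "asr", "asr_lo", "asr_hi"]]

    # -- stage: driver decomposition
    try:
        breaks = [b for b in config.breakpoints
                  if config.history_start <= b <= config.projection_end]
        decomposition = decompose_timeline(pop_used, san_full, mort_full, rr,
                                           breaks, config.factors, config.age_schema,
                                           countries=countries)
    except Exception as err:
        raise PipelineStageError("driver_decomposition", err) from err

    return RunReport(config=config, seed=config.seed, burden=burden.data,
                     dausr=dausr, global_dausr=global_dausr, asr=asr,
                     global_asr=global_asr, decomposition=decomposition,
                     shares=san_full.data, mortality=mort_full.data,
                     excluded=excluded)
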