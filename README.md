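# sanburden

Estimation of **deaths attributable to unsafe sanitation in rural areas
(DAUSRs)**: a tested, reusable pipeline for epidemiologists and global-health
analysts working with country-year panels of population structure, rural
sanitation coverage and cause-specific (diarrheal) mortality.

The pipeline covers the full comparative-risk-assessment workflow:

1. **Exposure normalization** — survey counts to the three-rung sanitation
   ladder (sewer/septic referent, improved, unimproved), kept on the unit
   simplex.
2. **Risk attribution** — population attributable fractions
   `PAF = (RRbar - 1)/RRbar` with `RRbar = p(RR - 1) + 1`, combined
   multiplicatively across independent factors, and attributable deaths

       DAUSR_t = Σ_{a,d} POP_t · AgeP_{a,t} · Rate_{a,d,t}/10⁵ · PAF_{a,d,t}

   plus directly age-standardized rates (WHO World Standard weights by
   default).
3. **Mortality projection** — a Bayesian age-period-cohort model
   `log μ_ijk = α + A_i + P_j + C_k + ε` with RW2 smoothing priors, fit by a
   blocked Gibbs sampler, projected with credible intervals.
4. **Exposure forecasting** — per-country ARIMA(p, d, q) with automatic AICc
   order selection, applied in additive-log-ratio coordinates so forecast
   share triples stay exactly on the simplex.
5. **Uncertainty propagation** — death bounds by endpoint substitution of the
   share, rate and relative-risk interval limits.
6. **Driver decomposition** — the change in DAUSRs split into contributions
   of population size, 65+ share, under-5 share, sanitation, and mortality
   by averaging marginal effects over *all* orderings of factor introduction
   (a Shapley value); contributions sum to the total change exactly.

A synthetic-world generator produces panels with the statistical structure
the analysis assumes (growing-then-aging populations, logistic sanitation
improvement, U-shaped age-mortality profiles with declining period effects),
with stored ground truth for parameter-recovery testing — no external data
download is needed anywhere. See `docs/methods.md` for models, priors,
identifiability constraints and limitations.

## Worked example

```python
import sanburden as sb

world = sb.generate_world(sb.WorldConfig(n_countries=4, year_start=2000,
                                         year_end=2030, seed=7))
config = sb.PipelineConfig(history_start=2000, history_end=2020, horizon=10,
                           seed=7, apc_draws=400, apc_warmup=200)
report = sb.run_pipeline(config, world.population, world.sanitation,
                         world.mortality, world.rr)

g = report.global_dausr.set_index("year")
for year in (2000, 2010, 2020, 2030):
    row = g.loc[year]
    print(f"{year}: {row.deaths:8.0f} deaths  (95% UI {row.deaths_lo:.0f}-{row.deaths_hi:.0f})")
```

prints

```
2000:    16805 deaths  (95% UI 8833-25732)
2010:    10413 deaths  (95% UI 5020-16849)
2020:     5263 deaths  (95% UI 2166-9423)
2030:     2400 deaths  (95% UI 111-27349)
```

— the attributable burden of this 4-country synthetic world falls as
sanitation improves and mortality declines; years past 2020 are projected
(hence the much wider 2030 interval, which carries the ARIMA share
intervals, the APC forecast uncertainty and the relative-risk bounds). The
age-standardized rate falls from 37.4 to 4.2 per 100,000 over the same
span, and the factor decomposition

```python
d = report.decomposition.query("group == 'GLOBAL'")
print(d.groupby("factor")["contribution_deaths"].sum())
```

attributes the net change to each driver in deaths (here: mortality decline
−10447, sanitation improvement −6009, fewer young children −1175, versus
population growth +2746 and aging +480); the five contributions sum to the
total 2000→2030 change exactly.

## Command line

```sh
sanburden synth --n-countries 10 --year-end 2030 --seed 1 --out-dir fixtures/
sanburden run --population fixtures/population.csv \
    --sanitation fixtures/sanitation.csv --mortality fixtures/mortality.csv \
    --rr fixtures/rr.csv --seed 1 --out-dir results/
sanburden forecast-sanitation --in fixtures/sanitation.csv --horizon 10 --out shares.csv
sanburden forecast-mortality  --in fixtures/mortality.csv  --horizon 10 --out rates.csv
sanburden decompose --population fixtures/population.csv --sanitation fixtures/sanitation.csv \
    --mortality fixtures/mortality.csv --rr fixtures/rr.csv --breakpoints 2000,2010,2020 --out d.csv
```

`run` also accepts `--config run.toml` (a TOML file mirroring
`PipelineConfig` field-for-field) in place of the individual options. It
writes a report bundle (`burden.csv`, `dausr.csv`, `asr.csv`,
`decomposition.csv`, `exclusions.csv`, `run_report.json` with the config
echo, seed and package version). All CSV dialects are documented in
`sanburden.panel_io`; shares are always fractions, rates per 100,000,
populations in persons.

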