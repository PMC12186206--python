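"""Decomposition of DAUSR changes into demographic, sanitation and mortality drivers.

The change in attributable deaths between two snapshots is attributed to a
set of swappable factors — by default the five of the reported analysis:
total rural population, the 65+ age share, the under-5 age share, the
sanitation-ladder shares, and age-specific cause mortality rates (relative
risks held fixed).  A factor's contribution is its marginal effect on the
attributable-death total, averaged over *all* orderings in which factors
can be switched from their first-period to their second-period values —
i.e. the Shapley value of the coalitional function "attributable deaths
with factor subset S at its later value".  By construction the
contributions sum exactly to the total change, and a factor identical in
both snapshots contributes exactly 0.

Age-share swap semantics: the 65+ and under-5 shares are separate factors,
so swapping one holds the other fixed and rescales only the interior bands
proportionally to keep the vector on the simplex.  That keeps the factor
components disjoint (swapping one never alters another), at the price of
assuming the interior age profile shifts proportionally — the minimal
assumption given that partial age-structure counterfactuals are otherwise
undefined.

The default implementation memoizes the 2^n subset values (32 evaluations
for 5 factors) and applies the Shapley weighting; the naive enumeration of
all n! orderings is retained (``decompose_naive``) as an exact oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Sequence

from .panel_io import RRRecord
from .schema import AgeBand, DEFAULT_AGE_SCHEMA, validate_schema

DEFAULT_FACTORS = ("population", "share_65plus", "share_under5",
                   "sanitation", "mortality")
FOUR_FACTOR_SET = ("population", "age_structure", "sanitation", "mortality")


@dataclass(frozen=True)
class FactorState:
    """One time point's snapshot of everything the death total depends on."""

    rural_population: float  # persons at risk
    age_shares: tuple[float, ...]  # over the age schema, on the simplex
    sanitation: tuple[float, float, float]  # (sewer, improved, unimproved)
    mortality_rates: tuple[float, ...]  # per 100,000, one per age band
    rr: tuple[RRRecord, ...]
    schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA

    def __post_init__(self) -> None:
        schema = validate_schema(self.schema)
        if self.rural_population < 0:
            raise ValueError("rural_population must be >= 0")
        if len(self.age_shares) != len(schema) or len(self.mortality_rates) != len(schema):
            raise ValueError("age_shares/mortality_rates length must match the schema")
        if abs(sum(self.age_shares) - 1.0) > 1e-9:
            raise ValueError(f"age_shares sum {sum(self.age_shares)} != 1")
        if abs(sum(self.sanitation) - 1.0) > 1e-9:
            raise ValueError("sanitation shares off the simplex")
        if any(r < 0 for r in self.mortality_rates):
            raise ValueError("negative mortality rate")


def evaluate_deaths(state: FactorState) -> float:
    """Attributable deaths of a snapshot: POP * sum_a AgeP_a * Rate_a/1e5 * PAF."""
    sewer, improved, unimproved = state.sanitation
    shares = {"sewer": sewer, "improved": improved, "unimproved": unimproved}
    surv = 1.0
    for rec in state.rr:
        p = shares[rec.exposure_category]
        rr_bar = p * (rec.rr - 1.0) + 1.0
        surv *= 1.0 - (rr_bar - 1.0) / rr_bar
    paf = 1.0 - surv
    total = 0.0
    for a, rate in zip(state.age_shares, state.mortality_rates):
        total += state.rural_population * a * rate / 1e5 * paf
    return total


def _swap_edge_share(age_shares: tuple[float, ...], idx: int, new_value: float,
                     fixed_idx: int) -> tuple[float, ...]:
    """Set band ``idx`` to ``new_value``; rescale interior bands; keep ``fixed_idx``."""
    if new_value == age_shares[idx]:  # no-op swap must be exact for dummy factors
        return age_shares
    shares = list(age_shares)
    interior = [i for i in range(len(shares)) if i not in (idx, fixed_idx)]
    remainder_new = 1.0 - new_value - shares[fixed_idx]
    remainder_old = sum(shares[i] for i in interior)
    if remainder_new < -1e-12:
        raise ValueError("edge age shares exceed 1 after swap")
    scale = remainder_new / remainder_old if remainder_old > 0 else 0.0
    for i in interior:
        shares[i] *= scale
    shares[idx] = new_value
    total = sum(shares)
    return tuple(s / total for s in shares)


def _apply_factor(state: FactorState, other: FactorState, factor: str) -> FactorState:
    """Return ``state`` with ``factor`` taken from ``other``."""
    kw = dict(rural_population=state.rural_population, age_shares=state.age_shares,
              sanitation=state.sanitation, mortality_rates=state.mortality_rates,
              rr=state.rr, schema=state.schema)
    n = len(state.schema)
    if factor == "population":
        kw["rural_population"] = other.rural_population
    elif factor == "share_65plus":
        kw["age_shares"] = _swap_edge_share(state.age_shares, n - 1,
                                            other.age_shares[n - 1], 0)
    elif factor == "share_under5":
        kw["age_shares"] = _swap_edge_share(state.age_shares, 0,
                                            other.age_shares[0], n - 1)
    elif factor == "age_structure":
        kw["age_shares"] = other.age_shares
    elif factor == "sanitation":
        kw["sanitation"] = other.sanitation
    elif factor == "mortality":
        kw["mortality_rates"] = other.mortality_rates
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return FactorState(**kw)


@dataclass
class DecompositionResult:
    contributions: dict[str, float]  # signed deaths per factor
    total_change: float
    orderings: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gap = abs(sum(self.contributions.values()) - self.total_change)
        scale = max(abs(self.total_change), 1.0)
        if gap > 1e-9 * scale:
            raise ValueError(
                f"decomposition not efficient: contributions sum off by {gap:g}"
            )


def _state_at(state_t0: FactorState, state_t1: FactorState,
              subset: frozenset[str]) -> FactorState:
    s = state_t0
    for f in sorted(subset):
        s = _apply_factor(s, state_t1, f)
    return s


def marginal_contribution(ordering: Sequence[str], state_t0: FactorState,
                          state_t1: FactorState,
                          value: Callable[[FactorState], float] = evaluate_deaths,
                          ) -> dict[str, float]:
    """Per-factor deltas along one ordering; they telescope to the total change."""
    factors = set(ordering)
    if len(factors) != len(ordering):
        raise ValueError("ordering repeats a factor")
    current = state_t0
    prev_val = value(current)
    deltas = {}
    for f in ordering:
        current = _apply_factor(current, state_t1, f)
        new_val = value(current)
        deltas[f] = new_val - prev_val
        prev_val = new_val
    return deltas


def decompose_naive(state_t0: FactorState, state_t1: FactorState,
                    factors: Sequence[str] = DEFAULT_FACTORS,
                    value: Callable[[FactorState], float] = evaluate_deaths,
                    ) -> DecompositionResult:
    """Average marginal deltas over the explicit enumeration of all orderings."""
    factors = tuple(factors)
    if len(factors) > 8:
        raise ValueError("more than 8 factors: exhaustive enumeration refused")
    sums = {f: 0.0 for f in factors}
    count = 0
    for ordering in permutations(factors):
        for f, d in marginal_contribution(ordering, state_t0, state_t1, value).items():
            sums[f] += d
        count += 1
    contributions = {f: s / count for f, s in sums.items()}
    total = value(_state_at(state_t0, state_t1, frozenset(factors))) - value(state_t0)
    return DecompositionResult(contributions, total, count)


def decompose(state_t0: FactorState, state_t1: FactorState,
              factors: Sequence[str] = DEFAULT_FACTORS,
              value: Callable[[FactorState], float] = evaluate_deaths,
              ) -> DecompositionResult:
    """Shapley contributions via memoized subset values (2^n evaluations).

    Exactly equal to :func:`decompose_naive`; factor order in the result
    follows the input order, contributions are order-invariant.
    """
    factors = tuple(factors)
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factors")
    nf = len(factors)
    if nf > 8:
        raise ValueError(
            "more than 8 factors: exhaustive Shapley refused (a sampling "
            "approximation is not implemented)"
        )
    subset_value: dict[frozenset[str], float] = {}

    def v(subset: frozenset[str]) -> float:
        if subset not in subset_value:
            subset_value[subset] = value(_state_at(state_t0, state_t1, subset))
        return subset_value[subset]

    fact = math.factorial
    contributions = {f: 0.0 for f in factors}
    all_factors = frozenset(factors)
    others = {f: [g for g in factors if g != f] for f in factors}
    for f in factors:
        rest = others[f]
        for mask in range(1 << len(rest)):
            S = frozenset(g for i, g in enumerate(rest) if mask >> i & 1)
            w = fact(len(S)) * fact(nf - len(S) - 1) / fact(nf)
            contributions[f] += w * (v(S | {f}) - v(S))
    total = v(all_factors) - v(frozenset())
    return DecompositionResult(contributions, total, fact(nf),
                               meta={"evaluations": len(subset_value)})


# ---------------------------------------------------------------------------
# building states from pipeline panels


def state_from_panels(country: str, year: int, population, sanitation, mortality,
                      rr: Sequence[RRRecord],
                      schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA) -> FactorState:
    """Assemble a :class:`FactorState` snapshot from the pipeline's panels."""
    schema = validate_schema(schema)
    pop_row = population.data[(population.data.country == country)
                              & (population.data.year == year)]
    san_row = sanitation.data[(sanitation.data.country == country)
                              & (sanitation.data.year == year)]
    mort = mortality.data[(mortality.data.country == country)
                          & (mortality.data.year == year)]
    for name, df in (("population", pop_row), ("sanitation", san_row), ("mortality", mort)):
        if df.empty:
            raise KeyError(f"{name} panel has no data for ({country}, {year})")
    pop_row = pop_row.iloc[0]
    san_row = san_row.iloc[0]
    rates = []
    for band in schema:
        cell = mort[mort.age_band == band.label]
        if cell.empty:
            raise KeyError(f"mortality missing band {band.label} for ({country}, {year})")
        rates.append(float(cell["rate"].iloc[0]))
    shares = tuple(float(pop_row["share_" + b.label]) for b in schema)
    total = sum(shares)
    return FactorState(
        rural_population=float(pop_row.total_population * pop_row.rural_share),
        age_shares=tuple(s / total for s in shares),
        sanitation=(float(san_row.sewer), float(san_row.improved),
                    float(san_row.unimproved)),
        mortality_rates=tuple(rates),
        rr=tuple(rr),
        schema=schema,
    )


def decompose_timeline(population, sanitation, mortality, rr: Sequence[RRRecord],
                       breakpoints: Sequence[int],
                       factors: Sequence[str] = DEFAULT_FACTORS,
                       schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA,
                       countries: Sequence[str] | None = None):
    """Per-country and aggregated decomposition over consecutive breakpoint pairs.

    The aggregate ("GLOBAL") contribution of a factor in an interval is the
    sum of the per-country contributions, so aggregate efficiency (sum of
    contributions = change in global DAUSRs) is inherited from the
    per-country decompositions.
    """
    import pandas as pd

    breakpoints = sorted(breakpoints)
    if len(breakpoints) < 2:
        raise ValueError("need at least two breakpoint years")
    if countries is None:
        countries = sorted(population.data["country"].unique())
    rows = []
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        agg = {f: 0.0 for f in factors}
        agg_total = 0.0
        for country in countries:
            s0 = state_from_panels(country, t0, population, sanitation, mortality, rr, schema)
            s1 = state_from_panels(country, t1, population, sanitation, mortality, rr, schema)
            res = decompose(s0, s1, factors)
            for f, c in res.contributions.items():
                rows.append({"group": country, "interval": f"{t0}-{t1}", "factor": f,
                             "contribution_deaths": c,
                             "total_change_deaths": res.total_change})
                agg[f] += c
            agg_total += res.total_change
        for f, c in agg.items():
            rows.append({"group": "GLOBAL", "interval": f"{t0}-{t1}", "factor": f,
                         "contribution_deaths": c, "total_change_deaths": agg_total})
    return pd.DataFrame(rows)
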