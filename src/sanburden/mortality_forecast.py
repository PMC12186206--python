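"""Bayesian age-period-cohort (APC) mortality model and projection.

Model
-----
For a single country the observed log death rate of age band ``i`` in
calendar year ``j`` (cohort bin ``k``) is decomposed additively:

    log(mu_ijk) = alpha + A_i + P_j + C_k + eps_ijk,   eps ~ N(0, sigma^2)

with second-order random-walk (RW2) smoothing priors on the age, period and
cohort effect vectors and weakly-informative Gamma hyperpriors on their
precisions — the standard Bayesian APC construction.  The likelihood is
Gaussian on observed log rates (inputs are rates, not death counts).

Identifiability.  The APC design has a rank deficiency of 4: one level per
effect vector plus the exact linear dependence cohort = period - age.  The
model is identified by sum-to-zero constraints on A, P and C plus a
zero-slope constraint on C, so the surface's entire temporal drift is
attributed to the period effect (the classical drift-to-period convention).
The constraints are enforced exactly on every posterior draw by
conditioning-by-kriging and recorded in the posterior's constraint record.

Cohort bins.  Because age bands have unequal widths there is no natural
integer cohort index; cohorts are binned as
``floor((year - band midpoint) / 5)`` (5-year birth cohorts).

Sampling.  All full conditionals are available in closed form (the effect
block is Gaussian given the variances; the variances are inverse-gamma /
gamma given the effects), so the posterior is explored with a blocked Gibbs
sampler — no external probabilistic-programming dependency.  Split-chain
R-hat (via ``arviz``) on all reported parameters must be <= 1.05 for the
fit to count as converged; projection from an unconverged fit is refused
unless forced.

Projection extends the period (and, where needed, cohort) effects under
their RW2 dynamics per posterior draw, exponentiates the per-draw log-rate
trajectories and summarizes them, so credible intervals widen with horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .panel_io import MortalityPanel
from .schema import AgeBand, DEFAULT_AGE_SCHEMA, validate_schema

logger = logging.getLogger(__name__)

COHORT_BIN_WIDTH = 5.0


def cohort_bin(year: float, age_midpoint: float, width: float = COHORT_BIN_WIDTH) -> int:
    """Discrete birth-cohort index: floor((year - midpoint) / width)."""
    return int(math.floor((year - age_midpoint) / width))


def _rw2_structure(n: int) -> np.ndarray:
    """RW2 structure matrix D'D with D the (n-2) x n second-difference operator."""
    if n < 3:
        return np.eye(n) * 0.0
    D = np.zeros((n - 2, n))
    for r in range(n - 2):
        D[r, r: r + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


@dataclass(frozen=True)
class APCConfig:
    age_schema: tuple[AgeBand, ...] = DEFAULT_AGE_SCHEMA
    horizon: int = 10
    chains: int = 2
    draws: int = 1000
    warmup: int = 500
    seed: int = 0
    # Gamma(shape, rate) hyperpriors on the RW2 precisions; the rates are
    # small so the smoothness variances are weakly identified by the data.
    tau_prior_shape: float = 1.0
    tau_prior_rate: float = 0.01
    # Inverse-gamma prior on the residual variance of eps.
    sigma2_prior_shape: float = 1.0
    sigma2_prior_rate: float = 1e-4
    alpha_prior_sd: float = 100.0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("projection horizon must be >= 1")
        if self.draws < 100:
            raise ValueError("at least 100 draws are required for reported intervals")
        if self.chains < 1 or self.warmup < 0:
            raise ValueError("invalid sampler settings")
        validate_schema(self.age_schema)


@dataclass
class APCPosterior:
    """Posterior draws and summaries of a fitted APC surface."""

    country: str
    age_labels: list[str]
    years: np.ndarray
    cohort_bins: np.ndarray
    # draw arrays, each (chains, draws, dim)
    alpha: np.ndarray
    age_effects: np.ndarray
    period_effects: np.ndarray
    cohort_effects: np.ndarray
    tau: dict[str, np.ndarray]  # RW2 precisions per effect
    sigma2: np.ndarray
    constraint_record: dict
    rhat: dict[str, float]
    config: APCConfig
    cell_index: tuple[np.ndarray, np.ndarray, np.ndarray] = None  # (age, year, cohort) idx

    @property
    def converged(self) -> bool:
        return all(np.isfinite(v) and v <= self.config.rhat_threshold
                   for v in self.rhat.values())

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, arr.shape[-1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr, labels in (
            ("alpha", self.alpha, ["alpha"]),
            ("age", self.age_effects, self.age_labels),
            ("period", self.period_effects, [str(y) for y in self.years]),
            ("cohort", self.cohort_effects, [str(k) for k in self.cohort_bins]),
        ):
            flat = self._flat(arr)
            mean = flat.mean(axis=0)
            lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
            for idx, label in enumerate(labels):
                rows.append({"effect": name, "label": label, "mean": mean[idx],
                             "lo": lo[idx], "hi": hi[idx]})
        flat = self.sigma2.reshape(-1)
        rows.append({"effect": "sigma", "label": "sigma",
                     "mean": float(np.sqrt(flat).mean()),
                     "lo": float(np.percentile(np.sqrt(flat), 2.5)),
                     "hi": float(np.percentile(np.sqrt(flat), 97.5))})
        return pd.DataFrame(rows)

    def effect_means(self, which: str) -> np.ndarray:
        arr = {"age": self.age_effects, "period": self.period_effects,
               "cohort": self.cohort_effects}[which]
        return self._flat(arr).mean(axis=0)

    def cell_log_rate_draws(self) -> np.ndarray:
        """Per-draw fitted log rates for every observed cell, shape (ndraws, ncells)."""
        ai, yi, ki = self.cell_index
        a = self._flat(self.age_effects)
        p = self._flat(self.period_effects)
        c = self._flat(self.cohort_effects)
        al = self.alpha.reshape(-1, 1)
        return al + a[:, ai] + p[:, yi] + c[:, ki]

    def fitted_rates(self) -> pd.DataFrame:
        """Posterior mean and 95% interval of the rate surface at observed cells."""
        draws = np.exp(self.cell_log_rate_draws())
        mean = draws.mean(axis=0)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        ai, yi, _ = self.cell_index
        return pd.DataFrame({
            "age_band": [self.age_labels[i] for i in ai],
            "year": self.years[yi],
            "rate": mean, "rate_lo": lo, "rate_hi": hi,
        })


class APCMortalityModel:
    """Fit/project interface around the Gibbs-sampled APC model.

    ``fit`` consumes a one-country :class:`MortalityPanel`; fitted state
    lives in ``posterior_``.  ``project`` extends the surface ``horizon``
    years past the fitted period range.
    """

    def __init__(self, config: APCConfig | None = None) -> None:
        self.config = config or APCConfig()

    # -- data preparation ---------------------------------------------------

    def _build_surface(self, panel: MortalityPanel):
        df = panel.data
        countries = df["country"].unique()
        if len(countries) != 1:
            raise ValueError("fit expects a single-country mortality panel")
        schema = self.config.age_schema
        labels = [b.label for b in schema]
        if set(df["age_band"].unique()) - set(labels):
            raise ValueError("panel contains age bands outside the configured schema")
        years = np.sort(df["year"].unique())
        if len(years) < 5:
            raise ValueError("at least 5 periods are required to fit the APC model")
        n_bands = df["age_band"].nunique()
        if n_bands < 3:
            raise ValueError("at least 3 age bands are required")
        used = [b for b in schema if b.label in set(df["age_band"])]
        pivot = df.pivot_table(index="age_band", columns="year", values="rate")
        pivot = pivot.reindex(index=[b.label for b in used], columns=years)
        rates = pivot.to_numpy(float)
        if np.isnan(rates).any():
            raise ValueError("mortality surface has missing (age, year) cells")
        if (rates == 0).any():
            floor = rates[rates > 0].min() / 2.0
            logger.warning(
                "APC fit %s: %d zero rates replaced by %.3g (half the smallest "
                "positive rate) before logging", countries[0], int((rates == 0).sum()),
                floor,
            )
            rates = np.where(rates == 0, floor, rates)
        mids = np.array([b.midpoint for b in used])
        return str(countries[0]), used, years, rates, mids

    # -- Gibbs sampler ------------------------------------------------------

    def fit(self, panel: MortalityPanel) -> "APCMortalityModel":
        cfg = self.config
        country, bands, years, rates, mids = self._build_surface(panel)
        I, J = rates.shape
        y = np.log(rates).ravel()  # row-major: age blocks of J years

        kmat = np.array([[cohort_bin(yr, m) for yr in years] for m in mids])
        kmin, kmax = int(kmat.min()), int(kmat.max())
        bins = np.arange(kmin, kmax + 1)
        K = len(bins)

        age_idx = np.repeat(np.arange(I), J)
        year_idx = np.tile(np.arange(J), I)
        coh_idx = (kmat - kmin).ravel()
        n = y.size
        m = 1 + I + J + K
        sA, sP, sC = 1, 1 + I, 1 + I + J  # block offsets

        X = np.zeros((n, m))
        X[:, 0] = 1.0
        X[np.arange(n), sA + age_idx] = 1.0
        X[np.arange(n), sP + year_idx] = 1.0
        X[np.arange(n), sC + coh_idx] = 1.0
        XtX = X.T @ X
        Xty = X.T @ y

        R = {"age": _rw2_structure(I), "period": _rw2_structure(J),
             "cohort": _rw2_structure(K)}
        rank = {"age": max(I - 2, 1), "period": max(J - 2, 1), "cohort": max(K - 2, 1)}

        # constraints: sum-to-zero on A, P, C; zero slope on C
        kc = bins - bins.mean()
        Acon = np.zeros((4, m))
        Acon[0, sA:sA + I] = 1.0
        Acon[1, sP:sP + J] = 1.0
        Acon[2, sC:sC + K] = 1.0
        Acon[3, sC:sC + K] = kc

        def embed(tauA, tauP, tauC):
            Q = np.zeros((m, m))
            Q[0, 0] = 1.0 / cfg.alpha_prior_sd ** 2
            Q[sA:sA + I, sA:sA + I] = tauA * R["age"]
            Q[sP:sP + J, sP:sP + J] = tauP * R["period"]
            Q[sC:sC + K, sC:sC + K] = tauC * R["cohort"]
            # tiny jitter keeps the intrinsic (improper) RW2 blocks factorizable
            Q[np.arange(m), np.arange(m)] += 1e-8
            return Q

        chains_out = {"alpha": [], "age": [], "period": [], "cohort": [],
                      "tau_age": [], "tau_period": [], "tau_cohort": [], "sigma2": []}
        total_iter = cfg.warmup + cfg.draws
        for chain in range(cfg.chains):
            rng = np.random.default_rng(
                np.random.SeedSequence(cfg.seed, spawn_key=(chain,))
            )
            tau = {"age": 10.0, "period": 10.0, "cohort": 10.0}
            sigma2 = max(float(np.var(y)), 1e-6)
            store = {k: [] for k in chains_out}
            for it in range(total_iter):
                Q = XtX / sigma2 + embed(tau["age"], tau["period"], tau["cohort"])
                cf = cho_factor(Q, lower=True)
                mu = cho_solve(cf, Xty / sigma2)
                z = mu + solve_triangular(cf[0], rng.standard_normal(m),
                                          lower=True, trans="T")
                V = cho_solve(cf, Acon.T)
                W = Acon @ V
                z = z - V @ np.linalg.solve(W, Acon @ z)

                beta = z
                A = beta[sA:sA + I]
                P = beta[sP:sP + J]
                C = beta[sC:sC + K]
                for name, vec in (("age", A), ("period", P), ("cohort", C)):
                    quad = float(vec @ R[name] @ vec)
                    tau[name] = rng.gamma(cfg.tau_prior_shape + rank[name] / 2.0,
                                          1.0 / (cfg.tau_prior_rate + quad / 2.0))
                resid = y - X @ beta
                sigma2 = 1.0 / rng.gamma(
                    cfg.sigma2_prior_shape + n / 2.0,
                    1.0 / (cfg.sigma2_prior_rate + float(resid @ resid) / 2.0),
                )
                if it >= cfg.warmup:
                    store["alpha"].append(beta[0:1].copy())
                    store["age"].append(A.copy())
                    store["period"].append(P.copy())
                    store["cohort"].append(C.copy())
                    store["tau_age"].append([tau["age"]])
                    store["tau_period"].append([tau["period"]])
                    store["tau_cohort"].append([tau["cohort"]])
                    store["sigma2"].append([sigma2])
            for k, v in store.items():
                chains_out[k].append(np.asarray(v))

        draws = {k: np.stack(v) for k, v in chains_out.items()}  # (chains, draws, dim)
        rhat = self._rhat_diagnostics(draws)
        constraint_record = {
            "sum_to_zero": ["age", "period", "cohort"],
            "zero_slope": ["cohort"],
            "drift_attributed_to": "period",
            "cohort_bin_width_years": COHORT_BIN_WIDTH,
        }
        self.posterior_ = APCPosterior(
            country=country,
            age_labels=[b.label for b in bands],
            years=years,
            cohort_bins=bins,
            alpha=draws["alpha"][..., 0],
            age_effects=draws["age"],
            period_effects=draws["period"],
            cohort_effects=draws["cohort"],
            tau={k: draws[f"tau_{k}"][..., 0] for k in ("age", "period", "cohort")},
            sigma2=draws["sigma2"][..., 0],
            constraint_record=constraint_record,
            rhat=rhat,
            config=cfg,
            cell_index=(age_idx, year_idx, coh_idx),
        )
        if not self.posterior_.converged:
            worst = max(rhat, key=rhat.get)
            logger.warning("APC fit %s flagged unconverged: max R-hat %.3f (%s)",
                           country, rhat[worst], worst)
        return self

    @staticmethod
    def _rhat_diagnostics(draws: dict[str, np.ndarray]) -> dict[str, float]:
        import arviz as az

        out = {}
        for name in ("alpha", "age", "period", "cohort", "sigma2"):
            arr = draws[name]  # (chains, draws, dim)
            r = az.rhat(az.convert_to_dataset(arr))["x"].values
            out[name] = float(np.nanmax(r))
        return out

    # -- projection ---------------------------------------------------------

    def project(self, horizon: int | None = None, force: bool = False) -> pd.DataFrame:
        """Project age-specific rates ``horizon`` years ahead with 95% intervals."""
        post = self._require_fitted()
        horizon = horizon if horizon is not None else self.config.horizon
        if horizon < 1:
            raise ValueError("projection horizon must be >= 1")
        if not post.converged and not force:
            raise RuntimeError(
                f"APC fit for {post.country} did not converge "
                f"(R-hat {post.rhat}); pass force=True to project anyway"
            )
        cfg = self.config
        alpha = post.alpha.reshape(-1)
        A = post._flat(post.age_effects)
        P = post._flat(post.period_effects)
        C = post._flat(post.cohort_effects)
        ndraw = alpha.size
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(997,)))

        sd_P = 1.0 / np.sqrt(post._flat(post.tau["period"][..., None])[:, 0])
        sd_C = 1.0 / np.sqrt(post._flat(post.tau["cohort"][..., None])[:, 0])

        # extend period effects by RW2 per draw
        P_ext = np.empty((ndraw, horizon))
        prev2, prev1 = P[:, -2], P[:, -1]
        for h in range(horizon):
            step = 2.0 * prev1 - prev2 + rng.standard_normal(ndraw) * sd_P
            P_ext[:, h] = step
            prev2, prev1 = prev1, step

        # extend cohort effects far enough for the youngest band's newest cohort
        mids = {b.label: b.midpoint for b in cfg.age_schema}
        band_mids = [mids[lbl] for lbl in post.age_labels]
        last_year = int(post.years[-1])
        k_needed = max(cohort_bin(last_year + horizon, min(band_mids)),
                       int(post.cohort_bins[-1]))
        n_new = k_needed - int(post.cohort_bins[-1])
        if n_new > 0:
            C_ext = np.empty((ndraw, n_new))
            prev2, prev1 = C[:, -2], C[:, -1]
            for h in range(n_new):
                step = 2.0 * prev1 - prev2 + rng.standard_normal(ndraw) * sd_C
                C_ext[:, h] = step
                prev2, prev1 = prev1, step
            C_all = np.concatenate([C, C_ext], axis=1)
        else:
            C_all = C
        kmin = int(post.cohort_bins[0])

        rows = []
        for ai, label in enumerate(post.age_labels):
            for h in range(horizon):
                year = last_year + 1 + h
                k = cohort_bin(year, band_mids[ai]) - kmin
                log_rate = alpha + A[:, ai] + P_ext[:, h] + C_all[:, k]
                rate = np.exp(log_rate)
                # median as the point summary: on a log-scale model the mean of
                # exp() inflates with forecast variance at long horizons
                lo, mid, hi = np.percentile(rate, [2.5, 50.0, 97.5])
                rows.append({"country": post.country, "age_band": label, "year": year,
                             "rate": float(mid), "rate_lo": float(lo),
                             "rate_hi": float(hi)})
        out = pd.DataFrame(rows)
        if not np.isfinite(out[["rate", "rate_lo", "rate_hi"]].to_numpy()).all():
            raise FloatingPointError("non-finite projected rates")
        return out

    def _require_fitted(self) -> APCPosterior:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("model is not fitted; call fit() first")
        return self.posterior_


def fit_apc(panel: MortalityPanel, config: APCConfig | None = None) -> APCPosterior:
    """Fit the APC model to a one-country mortality surface; returns the posterior."""
    model = APCMortalityModel(config)
    model.fit(panel)
    model.posterior_._model = model  # keep the fitted model reachable for projection
    return model.posterior_


def project_rates(posterior: APCPosterior, horizon: int, force: bool = False) -> pd.DataFrame:
    """Project rates from a posterior produced by :func:`fit_apc`."""
    model: APCMortalityModel = getattr(posterior, "_model", None)
    if model is None:
        model = APCMortalityModel(posterior.config)
        model.posterior_ = posterior
    return model.project(horizon, force=force)
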