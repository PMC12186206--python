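"""ARIMA forecasting of sanitation shares under a simplex constraint.

Each country's sanitation ladder history is a short annual series of
simplex-valued triples (sewer, improved, unimproved).  Shares are bounded,
so the default forecasting mode maps each triple to two additive-log-ratio
(ALR) coordinates with sewer as the reference,

    u1 = log(improved / sewer),   u2 = log(unimproved / sewer),

forecasts each coordinate with a univariate ARIMA(p, d, q) selected by an
AICc grid search (differencing degree seeded by an augmented Dickey-Fuller
test), and back-transforms, so point forecasts lie exactly on the simplex.
A clip-and-renormalize mode that forecasts the three shares independently
is provided as a fidelity alternative and flagged in its output.

Maximum-likelihood ARIMA estimation, forecasting and Gaussian prediction
intervals are delegated to ``statsmodels``; order selection is implemented
here (AICc with ties broken toward the smallest p + d + q, then smallest p
— parsimony matters for ~20-point country series).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA as _SMARIMA
from statsmodels.tsa.stattools import adfuller

from .panel_io import SanitationShares

logger = logging.getLogger(__name__)

MIN_SERIES_LENGTH = 10
ALR_REFERENCE = "sewer"
_ALR_COORDS = ("improved", "unimproved")


class ArimaOrder(NamedTuple):
    p: int
    d: int
    q: int


@dataclass
class ArimaFit:
    """A fitted ARIMA model with its coefficients and selection metadata."""

    order: ArimaOrder
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    const: float
    sigma2: float
    aicc: float
    series_id: str
    _result: object = None  # statsmodels results, used for forecasting

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("innovation variance must be >= 0")
        if len(self.ar_coefs):
            # stationarity: roots of phi(L) outside the unit circle, i.e. the
            # characteristic roots of z^p - phi_1 z^(p-1) - ... strictly inside
            roots = np.roots(np.r_[1.0, -np.asarray(self.ar_coefs)])
            if (np.abs(roots) >= 1 - 1e-8).any():
                raise ValueError("non-stationary AR coefficients")


def _aicc(aic: float, n_obs: int, k_params: int) -> float:
    denom = n_obs - k_params - 1
    if denom <= 0:
        return np.inf
    return aic + 2.0 * k_params * (k_params + 1) / denom


def _is_constant(series: np.ndarray, tol: float = 1e-12) -> bool:
    return float(np.ptp(series)) <= tol * max(1.0, float(np.abs(series).max()))


def _fit_sm(series: np.ndarray, order: ArimaOrder):
    trend = "c" if order.d == 0 else "n"
    model = _SMARIMA(series, order=tuple(order), trend=trend,
                     enforce_stationarity=True, enforce_invertibility=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(method_kwargs={"maxiter": 200, "disp": 0})


def _adf_differencing(series: np.ndarray, max_d: int, alpha: float = 0.05) -> int:
    """Smallest d for which the ADF test rejects a unit root (capped at max_d)."""
    x = series.astype(float)
    for d in range(max_d + 1):
        if _is_constant(x):
            return d
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pval = adfuller(x, autolag="AIC")[1]
        except Exception:  # short/degenerate series: keep differencing
            pval = 1.0
        if pval < alpha:
            return d
        x = np.diff(x)
    return max_d


def select_order(series: np.ndarray | pd.Series,
                 max_orders: ArimaOrder = ArimaOrder(3, 2, 3)) -> ArimaOrder:
    """AICc grid search; d seeded by a unit-root test then refined in the grid.

    Ties (AICc within 1e-9) break toward the smallest ``p + d + q`` and then
    the smallest ``p``.  A constant series maps to (0, 0, 0) with intercept.
    """
    x = np.asarray(series, float)
    if x.size < MIN_SERIES_LENGTH:
        raise ValueError(
            f"series of length {x.size} < {MIN_SERIES_LENGTH}: too short for order selection"
        )
    if _is_constant(x):
        return ArimaOrder(0, 0, 0)
    d0 = _adf_differencing(x, max_orders.d)
    d_grid = sorted({d0, min(d0 + 1, max_orders.d)})
    best: tuple[float, int, int, ArimaOrder] | None = None
    for d in d_grid:
        for p in range(max_orders.p + 1):
            for q in range(max_orders.q + 1):
                if p + q == 0 and d == 0:
                    order = ArimaOrder(0, 0, 0)
                else:
                    order = ArimaOrder(p, d, q)
                try:
                    res = _fit_sm(x, order)
                except Exception:
                    continue
                k = res.df_model + 1  # + innovation variance
                crit = _aicc(res.aic, x.size - d, int(k))
                key = (crit, p + d + q, p, order)
                if best is None or (crit < best[0] - 1e-9) or (
                    abs(crit - best[0]) <= 1e-9 and key[1:3] < best[1:3]
                ):
                    best = key
    if best is None:
        raise RuntimeError("no ARIMA order could be fitted to the series")
    return best[3]


def fit_arima(series: np.ndarray | pd.Series, order: ArimaOrder,
              series_id: str = "") -> ArimaFit:
    """Maximum-likelihood fit with stationarity/invertibility enforced."""
    x = np.asarray(series, float)
    order = ArimaOrder(*order)
    if any(v < 0 for v in order):
        raise ValueError("ARIMA orders must be non-negative")
    if x.size <= order.p + order.q + order.d + 1:
        raise ValueError("series too short for the requested order")
    last_err: Exception | None = None
    for attempt in range(3):
        try:
            xa = x if attempt == 0 else x + np.random.default_rng(attempt).normal(
                0.0, 1e-10 * max(1.0, np.abs(x).max()), x.size
            )
            res = _fit_sm(xa, order)
            break
        except Exception as err:  # retry from a perturbed series
            last_err = err
    else:
        raise RuntimeError(f"ARIMA fit failed for order {order}: {last_err}")
    params = np.asarray(res.params, float)
    names = list(res.param_names)
    ar = np.array([params[i] for i, nm in enumerate(names) if nm.startswith("ar.")])
    ma = np.array([params[i] for i, nm in enumerate(names) if nm.startswith("ma.")])
    const = next((params[i] for i, nm in enumerate(names) if nm in ("const", "intercept")), 0.0)
    sigma2 = float(next((params[i] for i, nm in enumerate(names) if nm == "sigma2"), 0.0))
    k = int(res.df_model + 1)
    return ArimaFit(order, ar, ma, float(const), sigma2,
                    _aicc(res.aic, x.size - order.d, k), series_id, res)


def forecast_series(fit: ArimaFit, horizon: int) -> pd.DataFrame:
    """h-step point forecasts with Gaussian 95% prediction intervals."""
    if horizon < 1:
        raise ValueError("forecast horizon must be >= 1")
    if fit._result is None:
        raise ValueError("fit carries no underlying model state")
    fc = fit._result.get_forecast(steps=horizon)
    mean = np.asarray(fc.predicted_mean, float)
    ci = np.asarray(fc.conf_int(alpha=0.05), float)
    return pd.DataFrame({"step": np.arange(1, horizon + 1), "mean": mean,
                         "lo": ci[:, 0], "hi": ci[:, 1]})


# ---------------------------------------------------------------------------
# compositional forecasting


def _forecast_coord(series: np.ndarray, horizon: int, max_orders: ArimaOrder,
                    series_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Select, fit and forecast one coordinate; constant series short-circuit.

    A constant history is its own exact forecast (zero innovation variance),
    so it bypasses maximum-likelihood fitting entirely.
    """
    if _is_constant(series):
        flat = np.full(horizon, series[-1])
        return flat, flat.copy(), flat.copy()
    order = select_order(series, max_orders)
    fit = fit_arima(series, order, series_id=series_id)
    fc = forecast_series(fit, horizon)
    return (fc["mean"].to_numpy(), fc["lo"].to_numpy(), fc["hi"].to_numpy())


def _alr(shares: np.ndarray, eps: float) -> np.ndarray:
    """(n, 3) simplex rows -> (n, 2) ALR coordinates, flooring zeros at eps."""
    s = np.clip(shares, eps, None)
    s = s / s.sum(axis=1, keepdims=True)
    ref = s[:, 0]
    return np.log(s[:, 1:] / ref[:, None])


def _alr_inverse(u: np.ndarray) -> np.ndarray:
    """(n, 2) ALR coordinates -> (n, 3) simplex rows (exact sum of 1)."""
    e = np.exp(u)
    denom = 1.0 + e.sum(axis=1)
    out = np.empty((u.shape[0], 3))
    out[:, 0] = 1.0 / denom
    out[:, 1:] = e / denom[:, None]
    return out


def forecast_composition(history: SanitationShares, horizon: int,
                         mode: str = "alr",
                         max_orders: ArimaOrder = ArimaOrder(2, 2, 2),
                         zero_floor: float = 1e-6) -> SanitationShares:
    """Forecast one country's share triples ``horizon`` years ahead.

    ``mode='alr'`` (default) forecasts the two ALR coordinates and
    back-transforms, so point forecasts sum to 1 exactly; per-component 95%
    bounds back-transform each coordinate's interval endpoint with the other
    coordinate held at its point forecast (a componentwise, not joint,
    interval).  ``mode='independent'`` forecasts each share separately,
    clips to [0, 1] and renormalizes; its rows are flagged
    ``mode='independent'``.
    """
    if mode not in ("alr", "independent"):
        raise ValueError(f"unknown mode {mode!r}")
    df = history.data.sort_values("year")
    countries = df["country"].unique()
    if len(countries) != 1:
        raise ValueError("forecast_composition expects a single-country panel")
    country = countries[0]
    if len(df) < MIN_SERIES_LENGTH:
        raise ValueError(f"need >= {MIN_SERIES_LENGTH} years of history")
    years_future = np.arange(df["year"].max() + 1, df["year"].max() + 1 + horizon)
    order_cols = ["sewer", "improved", "unimproved"]  # ALR reference first
    shares = df[order_cols].to_numpy(float)

    if mode == "alr":
        if (shares <= 0).any():
            logger.warning("forecast_composition %s: zero shares floored at %g",
                           country, zero_floor)
        u = _alr(shares, zero_floor)
        fcs = [_forecast_coord(u[:, j], horizon, max_orders, f"{country}:{coord}")
               for j, coord in enumerate(_ALR_COORDS)]
        u_mean = np.column_stack([fc[0] for fc in fcs])
        point = _alr_inverse(u_mean)
        lo = np.empty_like(point)
        hi = np.empty_like(point)
        for j in range(2):
            u_lo, u_hi = u_mean.copy(), u_mean.copy()
            u_lo[:, j] = fcs[j][1]
            u_hi[:, j] = fcs[j][2]
            lo[:, j + 1] = _alr_inverse(u_lo)[:, j + 1]
            hi[:, j + 1] = _alr_inverse(u_hi)[:, j + 1]
        u_all_lo = np.column_stack([fc[1] for fc in fcs])
        u_all_hi = np.column_stack([fc[2] for fc in fcs])
        lo[:, 0] = _alr_inverse(u_all_hi)[:, 0]  # sewer decreasing in both coords
        hi[:, 0] = _alr_inverse(u_all_lo)[:, 0]
    else:
        cols_point, cols_lo, cols_hi = [], [], []
        for coord in order_cols:
            mean, flo, fhi = _forecast_coord(df[coord].to_numpy(float), horizon,
                                             max_orders, f"{country}:{coord}")
            cols_point.append(mean)
            cols_lo.append(flo)
            cols_hi.append(fhi)
        point = np.clip(np.column_stack(cols_point), 0.0, 1.0)
        point = point / point.sum(axis=1, keepdims=True)
        lo = np.clip(np.column_stack(cols_lo), 0.0, 1.0)
        hi = np.clip(np.column_stack(cols_hi), 0.0, 1.0)

    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    out = pd.DataFrame({"country": country, "year": years_future})
    for j, coord in enumerate(order_cols):
        out[coord] = point[:, j]
        out[coord + "_lo"] = lo[:, j]
        out[coord + "_hi"] = hi[:, j]
    out["mode"] = mode
    return SanitationShares(out)


def forecast_all_compositions(history: SanitationShares, horizon: int,
                              mode: str = "alr",
                              max_orders: ArimaOrder = ArimaOrder(2, 2, 2)) -> SanitationShares:
    """Per-country :func:`forecast_composition` over a multi-country panel."""
    blocks = []
    for country in sorted(history.data["country"].unique()):
        sub = SanitationShares(history.data[history.data["country"] == country].copy())
        blocks.append(forecast_composition(sub, horizon, mode, max_orders).data)
    return SanitationShares(pd.concat(blocks, ignore_index=True))
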