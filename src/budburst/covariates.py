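"""Environmental covariates for bud-phenology models.

Every predictor used by the transition models is built here from daily
weather series: growing degree-day sums (base 0 °C from January 1, from
mean or maximum temperature), the binary frost indicator and the fitted
frost-probability curve, astronomical day length, regression gap-filling
of logger series against a reference, and z-standardization with stored
parameters so fitted coefficients can be applied to new covariate paths.

A weather series is a :class:`pandas.DataFrame` with columns
``site, year, doy, tmin, tmean, tmax`` (DOY is 1-based, Jan 1 = 1; leap
years keep the natural DOY).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "WEATHER_COLUMNS",
    "FrostModel",
    "GapFillModel",
    "StandardizationParams",
    "Standardizer",
    "gdd_accumulate",
    "frost_indicator",
    "fit_frost_curve",
    "day_length",
    "gap_fill",
    "standardize",
    "build_covariate_table",
]

WEATHER_COLUMNS = ["site", "year", "doy", "tmin", "tmean", "tmax"]


# ---------------------------------------------------------------------------
# Growing degree-days
# ---------------------------------------------------------------------------

def _check_contiguous(doy: np.ndarray, start_doy: int) -> None:
    expected = np.arange(start_doy, start_doy + len(doy))
    if len(doy) == 0:
        raise ValueError(f"weather series empty from start_doy={start_doy}")
    if doy[0] != start_doy or not np.array_equal(doy, expected):
        missing = sorted(set(range(start_doy, int(doy.max()) + 1)) - set(int(d) for d in doy))
        raise ValueError(
            f"weather series has gaps (fill them first); missing DOYs: {missing[:20]}"
            + ("..." if len(missing) > 20 else "")
        )


def gdd_accumulate(
    weather: pd.DataFrame,
    base: float = 0.0,
    start_doy: int = 1,
    which: str = "mean",
) -> pd.DataFrame:
    """Cumulative growing degree-days above ``base`` from ``start_doy``.

    Truncation is applied at the daily level (``max(T - base, 0)`` summed),
    the standard degree-day convention.  ``which`` selects the temperature
    input: ``"mean"`` uses ``tmean``, ``"max"`` uses ``tmax``.

    Returns one row per (site, year, doy) with a ``gdd_mean`` or
    ``gdd_max`` column.  Raises if any (site, year) series has gaps.
    """
    if which not in ("mean", "max"):
        raise ValueError(f"which must be 'mean' or 'max', got {which!r}")
    col = "tmean" if which == "mean" else "tmax"
    out_col = f"gdd_{which}"
    pieces = []
    for (site, year), grp in weather.groupby(["site", "year"], sort=True):
        grp = grp.sort_values("doy")
        sub = grp[grp["doy"] >= start_doy]
        doy = sub["doy"].to_numpy()
        _check_contiguous(doy, start_doy)
        daily = np.maximum(sub[col].to_numpy(dtype=float) - base, 0.0)
        pieces.append(
            pd.DataFrame(
                {"site": site, "year": year, "doy": doy, out_col: np.cumsum(daily)}
            )
        )
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Frost indicator and frost-probability curve
# ---------------------------------------------------------------------------

def frost_indicator(weather: pd.DataFrame) -> pd.Series:
    """Binary frost coding: 1 iff tmin < 0 °C (strictly), else 0.

    A day with tmin exactly 0.0 is coded 0 — "below 0 °C" is read strictly.
    """
    return (weather["tmin"].astype(float) < 0.0).astype(int)


@dataclass
class FrostModel:
    """Logistic regression of daily frost occurrence on day-of-year.

    ``predict(doy)`` returns the fitted daily frost probability.  When the
    input is degenerate (a single outcome class, or complete separation)
    the model is flagged and predictions are clamped near 0/1.
    """

    beta0: float
    beta1: float
    se0: float
    se1: float
    converged: bool
    degenerate: bool
    n: int = 0
    site: str | None = None

    def predict(self, doy) -> np.ndarray:
        doy = np.asarray(doy, dtype=float)
        if self.degenerate:
            warnings.warn(
                "frost model is degenerate; predictions clamped", stacklevel=2
            )
        eta = np.clip(self.beta0 + self.beta1 * doy, -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_frost_curve(indicators, doy, site: str | None = None) -> FrostModel:
    """Maximum-likelihood logistic fit of the frost indicator on DOY.

    All-same-outcome inputs yield a degenerate, clamped model with a
    warning rather than an error.  Perfect separation is flagged.
    """
    y = np.asarray(indicators, dtype=float)
    d = np.asarray(doy, dtype=float)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct DOYs to fit a frost curve")
    if y.min() == y.max():
        warnings.warn(
            f"all frost indicators identical ({int(y[0])}); degenerate frost model",
            stacklevel=2,
        )
        b0 = 30.0 if y[0] == 1 else -30.0
        return FrostModel(b0, 0.0, np.nan, np.nan, False, True, len(y), site)
    X = sm.add_constant(d)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
        except Exception:
            return FrostModel(0.0, 0.0, np.nan, np.nan, False, True, len(y), site)
    p = np.asarray(res.fittedvalues)
    separated = bool(np.all((p > 0.999) == (y == 1)) and np.all((p < 0.001) == (y == 0)))
    return FrostModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        se0=float(res.bse[0]),
        se1=float(res.bse[1]),
        converged=bool(res.converged) and not separated,
        degenerate=separated,
        n=len(y),
        site=site,
    )


def fit_frost_curves(
    weather: pd.DataFrame, pool_years: bool = True, start_doy: int = 90
) -> dict:
    """Fit frost curves per site (default: pooling years) or per (site, year).

    ``start_doy`` restricts the fit to the spring record (loggers are
    typically deployed at snowmelt; the mid-winter plateau of daily frost
    probability ≈ 1 would otherwise distort the logistic's spring slope).
    Returns a dict keyed by site (or ``(site, year)``) of :class:`FrostModel`.
    """
    out = {}
    keys = ["site"] if pool_years else ["site", "year"]
    sub = weather[weather["doy"] >= start_doy]
    for key, grp in sub.groupby(keys, sort=True):
        key = key[0] if len(keys) == 1 else key
        ind = frost_indicator(grp)
        out[key] = fit_frost_curve(ind, grp["doy"], site=str(key))
    return out


# ---------------------------------------------------------------------------
# Day length
# ---------------------------------------------------------------------------

_SUN_ALTITUDE_DEG = -0.833  # refraction + half solar disc at rise/set
_EPOCH_YEAR = 2017           # nominal year anchoring the solar ephemeris


def _solar_declination(doy) -> np.ndarray:
    """Apparent solar declination (radians), NOAA solar-calculator algorithm.

    Geometric mean longitude and anomaly, equation of center, apparent
    longitude with the nutation correction, and corrected obliquity, all
    evaluated for a nominal fixed year — day length is treated as a
    function of DOY alone, the photoperiod convention of phenology work.
    """
    n = np.asarray(doy, dtype=float) + (_EPOCH_YEAR - 2000) * 365.25
    t = n / 36525.0  # Julian centuries since J2000.0
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = np.deg2rad(357.52911 + t * (35999.05029 - 0.0001537 * t))
    c = (
        np.sin(m) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * m) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m) * 0.000289
    )
    true_long = l0 + c
    omega = np.deg2rad(125.04 - 1934.136 * t)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))
    return np.arcsin(np.sin(eps) * np.sin(app_long))


def day_length(latitude: float, doy) -> np.ndarray | float:
    """Hours of daylight from the sunrise equation.

    Sun altitude at rise/set is −0.833° (atmospheric refraction plus the
    solar half-disc).  Polar latitudes (|lat| > 66°) are rejected because
    polar day/night handling is out of scope.
    """
    if abs(latitude) > 66.0:
        raise ValueError(f"polar latitude {latitude} unsupported (|lat| must be <= 66)")
    doy_arr = np.asarray(doy, dtype=float)
    if np.any(doy_arr < 1) or np.any(doy_arr > 366):
        raise ValueError("doy must be within 1..366")
    phi = np.deg2rad(latitude)
    delta = _solar_declination(doy_arr)
    h0 = np.deg2rad(_SUN_ALTITUDE_DEG)
    cos_omega = (np.sin(h0) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    cos_omega = np.clip(cos_omega, -1.0, 1.0)
    hours = 2.0 * np.rad2deg(np.arccos(cos_omega)) / 15.0
    return float(hours) if np.isscalar(doy) else hours


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

@dataclass
class GapFillModel:
    """OLS calibration of one logger's variable against the reference series."""

    logger_id: str
    variable: str
    slope: float
    intercept: float
    adj_r2: float
    p_value: float
    n_overlap: int
    used: bool = True


def gap_fill(
    observed: pd.DataFrame,
    reference: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[GapFillModel]]:
    """Fill gaps in logger weather via per-logger regression on a reference.

    ``observed`` has columns ``site, year, doy, logger, tmin, tmean, tmax``
    (rows only for days a logger recorded); ``reference`` is a complete
    series ``site, year, doy, tmin, tmean, tmax`` covering the target span.
    Per logger and variable an OLS fit ``observed ~ reference`` on the
    overlapping days predicts the missing days; predictions are then
    averaged across loggers and spliced into the site series.  Observed
    days are the across-logger means and are never altered by filling.

    Regressions with p >= ``alpha`` (or fewer than 3 overlap days) are
    excluded from averaging with a warning.
    """
    models: list[GapFillModel] = []
    out_pieces = []
    for (site, year), ref in reference.groupby(["site", "year"], sort=True):
        ref = ref.sort_values("doy").set_index("doy")
        obs = observed[(observed["site"] == site) & (observed["year"] == year)]
        obs_days = np.sort(obs["doy"].unique())
        missing = ref.index.difference(obs_days)
        filled = pd.DataFrame(index=ref.index.copy())
        for var in ("tmin", "tmean", "tmax"):
            # observed days: mean across loggers
            site_obs = obs.groupby("doy")[var].mean()
            if len(site_obs.index.difference(ref.index)) and len(missing):
                pass  # observed days outside reference span are kept as-is below
            preds = []
            for logger, lg in obs.groupby("logger"):
                lg = lg.set_index("doy")
                overlap = lg.index.intersection(ref.index)
                if len(overlap) < 3:
                    warnings.warn(
                        f"logger {logger} ({var}): only {len(overlap)} overlap days; excluded",
                        stacklevel=2,
                    )
                    models.append(
                        GapFillModel(str(logger), var, np.nan, np.nan, np.nan, np.nan,
                                     len(overlap), used=False)
                    )
                    continue
                x = ref.loc[overlap, var].to_numpy(dtype=float)
                yv = lg.loc[overlap, var].to_numpy(dtype=float)
                X = sm.add_constant(x)
                res = sm.OLS(yv, X).fit()
                pval = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
                m = GapFillModel(
                    str(logger), var, float(res.params[1]), float(res.params[0]),
                    float(res.rsquared_adj), pval, len(overlap),
                    used=pval < alpha,
                )
                models.append(m)
                if not m.used:
                    warnings.warn(
                        f"logger {logger} ({var}): regression p={pval:.3g} >= {alpha}; "
                        "excluded from gap filling",
                        stacklevel=2,
                    )
                    continue
                if len(missing):
                    xm = ref.loc[missing, var].to_numpy(dtype=float)
                    preds.append(m.intercept + m.slope * xm)
            col = pd.Series(index=ref.index, dtype=float)
            col.loc[site_obs.index.intersection(ref.index)] = site_obs
            if len(missing):
                if not preds:
                    raise ValueError(
                        f"no usable gap-fill regression for {var} at site {site}, year {year}"
                    )
                col.loc[missing] = np.mean(np.vstack(preds), axis=0)
            filled[var] = col
        filled = filled.reset_index()
        filled.insert(0, "year", year)
        filled.insert(0, "site", site)
        out_pieces.append(filled)
    completed = pd.concat(out_pieces, ignore_index=True)
    if completed[["tmin", "tmean", "tmax"]].isna().any().any():
        raise ValueError("reference series does not cover all gap days")
    return completed, models


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    variable: str
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"zero-variance variable {self.variable!r}: sd must be > 0")


def standardize(values, params: StandardizationParams | None = None,
                name: str = "x") -> tuple[np.ndarray, StandardizationParams]:
    """z-score ``values``; fit (mean, sd) when ``params`` is None.

    The returned params can be reused to standardize prediction-time
    covariate paths on the training scale.
    """
    x = np.asarray(values, dtype=float)
    if params is None:
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if not sd > 0:
            raise ValueError(f"zero-variance variable {name!r} cannot be standardized")
        params = StandardizationParams(name, float(np.mean(x)), sd)
    return (x - params.mean) / params.sd, params


class Standardizer:
    """Per-variable standardization parameters fitted on a covariate table."""

    def __init__(self) -> None:
        self.params: dict[str, StandardizationParams] = {}

    def fit(self, table: pd.DataFrame, variables: list[str]) -> "Standardizer":
        for v in variables:
            _, p = standardize(table[v].to_numpy(dtype=float), name=v)
            self.params[v] = p
        return self

    def transform(self, values, variable: str) -> np.ndarray:
        z, _ = standardize(values, self.params[variable])
        return z

    def inverse_transform(self, z, variable: str) -> np.ndarray:
        p = self.params[variable]
        return np.asarray(z, dtype=float) * p.sd + p.mean

    def to_dict(self) -> dict:
        return {v: {"mean": p.mean, "sd": p.sd} for v, p in self.params.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        for v, mp in d.items():
            s.params[v] = StandardizationParams(v, float(mp["mean"]), float(mp["sd"]))
        return s


# ---------------------------------------------------------------------------
# Assembled covariate table
# ---------------------------------------------------------------------------

def build_covariate_table(
    weather: pd.DataFrame,
    latitudes: dict,
    pool_years: bool = True,
    frost_start_doy: int = 90,
) -> tuple[pd.DataFrame, dict]:
    """All candidate predictors on a daily grid per (site, year).

    Columns: site, year, doy, tmin, tmean, tmax, gdd_mean, gdd_max,
    frost_prob, day_length.  The frost curve is by default one logistic
    fit per site pooling years.  Returns the table and the frost models.
    """
    gm = gdd_accumulate(weather, which="mean")
    gx = gdd_accumulate(weather, which="max")
    table = weather.merge(gm, on=["site", "year", "doy"]).merge(
        gx, on=["site", "year", "doy"]
    )
    frost_models = fit_frost_curves(weather, pool_years=pool_years,
                                    start_doy=frost_start_doy)
    fp = np.empty(len(table))
    for site, grp in table.groupby("site"):
        if pool_years:
            model = frost_models[site]
            fp[grp.index] = model.predict(grp["doy"].to_numpy())
        else:
            for year, g2 in grp.groupby("year"):
                fp[g2.index] = frost_models[(site, year)].predict(g2["doy"].to_numpy())
    table["frost_prob"] = fp
    dl = np.empty(len(table))
    for site, grp in table.groupby("site"):
        if site not in latitudes:
            raise ValueError(f"no latitude provided for site {site!r}")
        dl[grp.index] = day_length(float(latitudes[site]), grp["doy"].to_numpy())
    table["day_length"] = dl
    return table.sort_values(["site", "year", "doy"]).reset_index(drop=True), frost_models
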