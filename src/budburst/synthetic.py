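"""Synthetic weather and bud-development trajectories with known drivers.

The generator emulates the study design the analysis targets: two
plantation sites on either side of a boreal–temperate ecotone (the
boreal site colder, with a later decline in spring frost probability),
two years, several species/seed-source groups, a few buds per tree, and
weekly censuses of an ordinal bud-stage trajectory.

Weather is a sinusoidal annual cycle plus AR(1) noise; daily minimum and
maximum temperatures sit half a diurnal range below/above the mean with
independent noise.  Bud development is a daily discrete-time hazard
process: a bud at stage k advances (at most one stage per day) with
probability logistic(β₀ + β₁·x(d) + σ_tree·z_tree + σ_year·z_year),
where x(d) is the transition's standardized driver (frost probability,
GDD, photoperiod, or DOY) evaluated on the simulated weather.  All
randomness flows from one master seed split deterministically into
weather / random-effect / hazard streams.

The ground truth records the realized random intercepts and, per
(site, year, group, transition), the DOY at which the noiseless hazard
crosses the prediction threshold — both the daily hazard itself and the
census-interval-aggregated transition probability (what a binomial model
fitted to weekly censuses actually estimates).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import Standardizer, build_covariate_table
from .transitions import STAGES, TRANSITIONS

THRESHOLD = 0.51

DRIVERS = ("frost_prob", "gdd_mean", "gdd_max", "photoperiod", "doy")
_DRIVER_COLUMN = {
    "frost_prob": "frost_prob",
    "gdd_mean": "gdd_mean",
    "gdd_max": "gdd_max",
    "photoperiod": "day_length",
    "doy": "doy",
}


@dataclass
class SiteClimateParams:
    """Sinusoid + AR(1) daily climate for one site."""

    site_id: str
    latitude: float
    mean_annual_temp: float      # °C
    seasonal_amplitude: float    # °C, half peak-to-trough
    phase_doy: float             # DOY of the temperature peak
    diurnal_range: float         # °C between tmin and tmax
    ar1_rho: float = 0.6
    noise_sd: float = 3.0        # °C innovation SD

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude must be in [-90, 90]")


@dataclass
class TransitionHazardParams:
    """Daily-hazard parameters for one transition within one group."""

    transition_id: str
    driver: str
    beta0: float                 # logit intercept
    beta1: float                 # per standardized driver unit
    sigma_tree: float = 0.0
    sigma_year: float = 0.0

    def __post_init__(self):
        if self.transition_id not in TRANSITIONS:
            raise ValueError(f"transition_id must be one of {TRANSITIONS}")
        if self.driver not in DRIVERS:
            raise ValueError(f"driver must be one of {DRIVERS}")
        if self.sigma_tree < 0 or self.sigma_year < 0:
            raise ValueError("random-effect SDs must be >= 0")


@dataclass
class StudyDesign:
    """Factorial layout of the simulated study."""

    sites: list
    years: list
    groups: list                         # dicts with species, seed_source
    latitudes: dict
    trees_per_group: int = 50            # per site
    buds_per_tree: int = 4
    schedule: np.ndarray = field(
        default_factory=lambda: np.arange(130, 186, 7)
    )

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=int)
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("observation schedule must be strictly increasing")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    hazards: dict                        # (species, seed_source) -> {transition: params}
    tree_effects: dict                   # tree label -> z
    year_effects: dict                   # (site, year) -> z
    crossings: pd.DataFrame              # noiseless threshold crossings
    standardizer: Standardizer


def _site_rng(seed: int, site_id: str, year: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed, year, zlib.crc32(site_id.encode()), zlib.crc32(stream.encode())]
    )


def simulate_weather(
    params: SiteClimateParams, year: int, seed: int, n_days: int = 243
) -> pd.DataFrame:
    """One site-year of daily weather (DOY 1..n_days).

    tmean follows the annual sinusoid plus AR(1) noise; tmin/tmax are
    offset by half the diurnal range with independent noise, clamped so
    that tmin <= tmean <= tmax.  Identical arguments give byte-identical
    output.
    """
    if n_days < 243:
        raise ValueError("season must cover at least DOY 1-243")
    rng = _site_rng(seed, params.site_id, year, "weather")
    doy = np.arange(1, n_days + 1)
    base = params.mean_annual_temp + params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - params.phase_doy) / 365.25
    )
    e = np.zeros(n_days)
    if params.noise_sd > 0:
        innov = rng.normal(scale=params.noise_sd, size=n_days)
        stat_sd = params.noise_sd / np.sqrt(1.0 - params.ar1_rho**2)
        e[0] = innov[0] * stat_sd / params.noise_sd
        for d in range(1, n_days):
            e[d] = params.ar1_rho * e[d - 1] + innov[d]
    else:
        rng.normal(size=n_days)  # keep stream alignment across noise settings
    tmean = base + e
    lo_noise = rng.normal(scale=params.noise_sd, size=n_days) if params.noise_sd > 0 else 0.0
    hi_noise = rng.normal(scale=params.noise_sd, size=n_days) if params.noise_sd > 0 else 0.0
    tmin = tmean - params.diurnal_range / 2.0 + lo_noise
    tmax = tmean + params.diurnal_range / 2.0 + hi_noise
    tmin = np.minimum(tmin, tmean)
    tmax = np.maximum(tmax, tmean)
    return pd.DataFrame(
        {"site": params.site_id, "year": year, "doy": doy,
         "tmin": tmin, "tmean": tmean, "tmax": tmax}
    )


def _driver_paths(covariates: pd.DataFrame, standardizer: Standardizer) -> dict:
    """(site, year) -> {driver column: standardized values indexed by doy}."""
    paths = {}
    for (site, year), grp in covariates.groupby(["site", "year"]):
        grp = grp.sort_values("doy")
        path = {"doy_index": grp["doy"].to_numpy()}
        for var in ("tmin", "tmean", "tmax", "gdd_mean", "gdd_max",
                    "frost_prob", "day_length", "doy"):
            path[var] = standardizer.transform(grp[var].to_numpy(dtype=float), var)
        paths[(site, year)] = path
    return paths


def make_standardizer(covariates: pd.DataFrame) -> Standardizer:
    """Season-wide standardization over the pooled covariate table.

    The same scope is used by the generator and by the analysis, so fitted
    coefficients are directly comparable to the generating β₁.
    """
    cov = covariates.copy()
    return Standardizer().fit(
        cov, ["tmin", "tmean", "tmax", "gdd_mean", "gdd_max",
              "frost_prob", "day_length", "doy"]
    )


def _noiseless_crossings(
    hazards: dict, paths: dict, schedule: np.ndarray
) -> pd.DataFrame:
    interval = int(np.min(np.diff(schedule))) if len(schedule) > 1 else 7
    rows = []
    for (site, year), path in paths.items():
        doy = path["doy_index"]
        for gkey, hz in hazards.items():
            species, seed_source = gkey
            for tid in TRANSITIONS:
                p = hz[tid]
                x = path[_DRIVER_COLUMN[p.driver]]
                eta = np.clip(p.beta0 + p.beta1 * x, -700, 700)
                h = 1.0 / (1.0 + np.exp(-eta))
                # census-interval transition probability (sliding window)
                log_surv = np.log1p(-np.minimum(h, 1 - 1e-12))
                cum = np.concatenate([[0.0], np.cumsum(log_surv)])
                idx = np.arange(1, len(h) + 1)
                lower = np.maximum(idx - interval, 0)
                pw = 1.0 - np.exp(cum[idx] - cum[lower])
                rows.append({
                    "site": site, "year": year, "species": species,
                    "seed_source": seed_source, "transition": tid,
                    "daily_crossing": _first_crossing(doy, h),
                    "interval_crossing": _first_crossing(doy, pw),
                })
    return pd.DataFrame(rows)


def _first_crossing(doy: np.ndarray, prob: np.ndarray,
                    threshold: float = THRESHOLD) -> float | None:
    if prob[0] >= threshold:
        return float(doy[0])
    idx = np.nonzero(prob >= threshold)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    frac = (threshold - prob[i - 1]) / (prob[i] - prob[i - 1])
    return float(doy[i - 1] + frac * (doy[i] - doy[i - 1]))


def simulate_buds(
    design: StudyDesign,
    hazards: dict,
    weather: pd.DataFrame,
    seed: int,
    covariates: pd.DataFrame | None = None,
    standardizer: Standardizer | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate bud-stage trajectories under known transition hazards.

    ``hazards`` maps (species, seed_source) to a complete per-transition
    dict of :class:`TransitionHazardParams`.  Buds advance by daily
    Bernoulli draws (at most one stage per day, never backwards); the
    returned observation table holds the stage at each scheduled census
    (one record per bud and census DOY).
    """
    schedule = design.schedule
    for (site, year) in [(s, y) for s in design.sites for y in design.years]:
        wdoys = weather[(weather["site"] == site) & (weather["year"] == year)]["doy"]
        if len(wdoys) == 0 or schedule.max() > wdoys.max() or schedule.min() < wdoys.min():
            raise ValueError(
                f"schedule {schedule.min()}..{schedule.max()} outside weather "
                f"coverage for ({site}, {year})"
            )
    for gkey, hz in hazards.items():
        missing = [t for t in TRANSITIONS if t not in hz]
        if missing:
            raise ValueError(f"group {gkey}: missing hazards for {missing}")

    if covariates is None:
        covariates, _ = build_covariate_table(weather, design.latitudes)
    if standardizer is None:
        standardizer = make_standardizer(covariates)
    paths = _driver_paths(covariates, standardizer)

    # --- enumerate buds -----------------------------------------------------
    site_year = [(s, y) for s in design.sites for y in design.years]
    sy_index = {sy: i for i, sy in enumerate(site_year)}
    gkeys = [(g["species"], g["seed_source"]) for g in design.groups]

    rng_re = np.random.default_rng([seed, zlib.crc32(b"random-effects")])
    tree_labels = []
    for site in design.sites:
        for gi, gkey in enumerate(gkeys):
            for t in range(design.trees_per_group):
                tree_labels.append((site, gkey, f"g{gi}t{t:03d}"))
    z_tree = {lbl: float(z) for lbl, z in
              zip([t[2] + "@" + t[0] for t in tree_labels],
                  rng_re.normal(size=len(tree_labels)))}
    z_year = {sy: float(z) for sy, z in
              zip(site_year, rng_re.normal(size=len(site_year)))}

    buds = []
    for (site, gkey, tree) in tree_labels:
        for year in design.years:
            for b in range(design.buds_per_tree):
                buds.append((site, year, gkey[0], gkey[1], tree, f"b{b}"))
    n = len(buds)
    site_arr = np.array([b[0] for b in buds])
    sy_arr = np.array([sy_index[(b[0], b[1])] for b in buds])
    g_arr = np.array([gkeys.index((b[2], b[3])) for b in buds])
    zt = np.array([z_tree[b[4] + "@" + b[0]] for b in buds])
    zy = np.array([z_year[(b[0], b[1])] for b in buds])

    # per (group, transition) parameter lookups
    n_g, n_t = len(gkeys), len(TRANSITIONS)
    B0 = np.zeros((n_g, n_t)); B1 = np.zeros((n_g, n_t))
    ST = np.zeros((n_g, n_t)); SY = np.zeros((n_g, n_t))
    DRV = np.empty((n_g, n_t), dtype=object)
    for gi, gkey in enumerate(gkeys):
        for ti, tid in enumerate(TRANSITIONS):
            p = hazards[gkey][tid]
            B0[gi, ti], B1[gi, ti] = p.beta0, p.beta1
            ST[gi, ti], SY[gi, ti] = p.sigma_tree, p.sigma_year
            DRV[gi, ti] = _DRIVER_COLUMN[p.driver]

    # driver value lookup: matrix per column, rows = site-year index
    doy0 = int(covariates["doy"].min())
    n_days_cov = int(covariates["doy"].max()) - doy0 + 1
    driver_mat = {}
    for col in set(DRV.ravel()):
        M = np.empty((len(site_year), n_days_cov))
        for sy, i in sy_index.items():
            M[i] = paths[sy][col]
        driver_mat[col] = M

    rng_h = np.random.default_rng([seed, zlib.crc32(b"hazard")])
    rank = np.zeros(n, dtype=int)                  # index into STAGES
    records = []
    last_day = int(schedule.max())
    sched_set = set(int(d) for d in schedule)
    for d in range(doy0, last_day + 1):
        di = d - doy0
        for ti in range(n_t):
            for gi in range(n_g):
                mask = (rank == ti) & (g_arr == gi)
                if not mask.any():
                    continue
                x = driver_mat[DRV[gi, ti]][sy_arr[mask], di]
                eta = (B0[gi, ti] + B1[gi, ti] * x
                       + ST[gi, ti] * zt[mask] + SY[gi, ti] * zy[mask])
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
                adv = rng_h.random(mask.sum()) < p
                idx = np.nonzero(mask)[0][adv]
                rank[idx] += 1
        if d in sched_set:
            stage_now = np.array(STAGES)[rank]
            for i, b in enumerate(buds):
                records.append((*b, d, int(stage_now[i])))

    obs = pd.DataFrame(
        records,
        columns=["site", "year", "species", "seed_source", "tree", "bud",
                 "doy", "stage"],
    )
    truth = GroundTruth(
        hazards=hazards,
        tree_effects=z_tree,
        year_effects=z_year,
        crossings=_noiseless_crossings(hazards, paths, schedule),
        standardizer=standardizer,
    )
    return obs, truth


# ---------------------------------------------------------------------------
# Calibration and the default scenario
# ---------------------------------------------------------------------------

def calibrate_hazards(
    covariates: pd.DataFrame,
    standardizer: Standardizer,
    targets: dict,
    drivers: dict,
    reference: tuple,
    slope_per_day: float = 1.2,
    sigma_tree: float = 0.5,
    sigma_year: float = 0.3,
) -> dict:
    """Hazard parameters hitting target crossing DOYs at a reference site-year.

    ``targets`` maps (species, seed_source) -> {transition: target DOY};
    ``drivers`` maps transition -> driver name.  β₁ is set so the daily
    hazard's logit rises by ``slope_per_day`` per day at the target (sign
    follows the driver's local trend) and β₀ so the noiseless hazard
    crosses the prediction threshold exactly at the target DOY of the
    reference site-year.
    """
    site, year = reference
    grp = covariates[(covariates["site"] == site) & (covariates["year"] == year)]
    grp = grp.sort_values("doy")
    doy = grp["doy"].to_numpy()
    out = {}
    for gkey, tmap in targets.items():
        out[gkey] = {}
        for tid, target in tmap.items():
            driver = drivers[tid]
            col = _DRIVER_COLUMN[driver]
            x = standardizer.transform(grp[col].to_numpy(dtype=float), col)
            xt = float(np.interp(target, doy, x))
            lo, hi = target - 4, target + 4
            dxdd = (np.interp(hi, doy, x) - np.interp(lo, doy, x)) / (hi - lo)
            if abs(dxdd) < 1e-9:
                raise ValueError(f"driver {driver} flat near DOY {target}")
            beta1 = slope_per_day / dxdd
            beta0 = float(np.log(THRESHOLD / (1 - THRESHOLD)) - beta1 * xt)
            out[gkey][tid] = TransitionHazardParams(
                tid, driver, beta0, float(beta1), sigma_tree, sigma_year
            )
    return out


DEFAULT_SITES = {
    "temperate": SiteClimateParams(
        "temperate", latitude=47.29, mean_annual_temp=3.1,
        seasonal_amplitude=16.9, phase_doy=201.0, diurnal_range=18.0,
    ),
    "boreal": SiteClimateParams(
        "boreal", latitude=48.29, mean_annual_temp=1.0,
        seasonal_amplitude=17.3, phase_doy=201.0, diurnal_range=18.0,
    ),
}

#: transition -> generating driver: frost probability gates the early
#: stages, thermal time the later ones.
DEFAULT_DRIVERS = {
    "0->12": "frost_prob",
    "12->3": "frost_prob",
    "3->4": "gdd_mean",
    "4->5": "gdd_mean",
    "5->6": "gdd_mean",
}

#: target crossing DOYs at the temperate reference site-year; the white
#: spruce analogue leads the black spruce analogue by ~5 days.
DEFAULT_TARGETS = {
    ("white_spruce", "local"): dict(zip(TRANSITIONS, (140, 146, 151, 156, 161))),
    ("black_spruce", "local"): dict(zip(TRANSITIONS, (145, 150, 155, 160, 165))),
}


@dataclass
class Scenario:
    """A fully realized synthetic study."""

    design: StudyDesign
    weather: pd.DataFrame
    covariates: pd.DataFrame
    frost_models: dict
    standardizer: Standardizer
    hazards: dict
    observations: pd.DataFrame
    truth: GroundTruth


def default_scenario(
    seed: int,
    trees_per_group: int = 50,
    buds_per_tree: int = 4,
    sigma_tree: float = 0.5,
    sigma_year: float = 0.3,
    slope_per_day: float = 1.2,
) -> Scenario:
    """The standard two-site, two-year synthetic study.

    Frost probability drives the two early transitions, mean-temperature
    GDD the three later ones; the boreal site's colder spring shifts all
    crossings later through the drivers alone.
    """
    years = [2016, 2017]
    design = StudyDesign(
        sites=list(DEFAULT_SITES),
        years=years,
        groups=[{"species": s, "seed_source": ss} for s, ss in DEFAULT_TARGETS],
        latitudes={k: v.latitude for k, v in DEFAULT_SITES.items()},
        trees_per_group=trees_per_group,
        buds_per_tree=buds_per_tree,
    )
    weather = pd.concat(
        [simulate_weather(DEFAULT_SITES[s], y, seed)
         for s in design.sites for y in years],
        ignore_index=True,
    )
    covariates, frost_models = build_covariate_table(weather, design.latitudes)
    standardizer = make_standardizer(covariates)
    hazards = calibrate_hazards(
        covariates, standardizer, DEFAULT_TARGETS, DEFAULT_DRIVERS,
        reference=("temperate", years[0]), slope_per_day=slope_per_day,
        sigma_tree=sigma_tree, sigma_year=sigma_year,
    )
    obs, truth = simulate_buds(design, hazards, weather, seed,
                               covariates=covariates, standardizer=standardizer)
    return Scenario(design, weather, covariates, frost_models, standardizer,
                    hazards, obs, truth)
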