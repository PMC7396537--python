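"""Candidate models, AICc selection, multimodel averaging and diagnostics.

The candidate set mirrors the collinearity-avoiding design of the
analysis: each model carries a single climate variable V (or day-of-year
for the null model) in one of five fixed-effect structures —

    {V}, {V + site}, {V + group}, {V + site + group},
    {V + site + group + V:site + V:group + site:group}

— always with crossed random intercepts for year and tree.  Six
temperature variables (tmin, tmean, tmax, gdd_mean, gdd_max, frost_prob)
give 30 models plus the DOY null = 31; the single photoperiod variable
(day_length) gives 5 plus the null = 6.

Selection is by small-sample AICc; Akaike weights rank the candidates and
models with weight > 0.05 form the plausible set.  When several models
are plausible their coefficients are combined by natural (conditional)
model averaging with Burnham–Anderson unconditional standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import Standardizer
from .glmm import FitResult, fit_logistic_glm, fit_logistic_glmm, nakagawa_r2

logger = logging.getLogger(__name__)

TEMPERATURE_POOL = ["tmin", "tmean", "tmax", "gdd_mean", "gdd_max", "frost_prob"]
PHOTOPERIOD_POOL = ["day_length"]

#: the five fixed-effect structures applied to each climate variable
STRUCTURES = ("v", "v+site", "v+group", "v+site+group", "v*site*group")

PLAUSIBLE_WEIGHT = 0.05


# ---------------------------------------------------------------------------
# Model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: a single climate variable in a fixed structure.

    ``variable is None`` denotes the null model (day-of-year only).
    ``group_factor`` chooses the biological grouping (species or
    seed_source) used by group terms.
    """

    variable: str | None
    structure: str = "v"
    group_factor: str = "species"
    random: tuple = ("year", "tree")

    @property
    def model_id(self) -> str:
        if self.variable is None:
            return "null(doy)"
        return f"{self.variable}[{self.structure.replace('group', self.group_factor)}]"

    @property
    def effective_variable(self) -> str:
        return self.variable if self.variable is not None else "doy"


def enumerate_candidates(
    variable_pool: list[str],
    group_factor: str = "species",
    include_null: bool = True,
    random: tuple = ("year", "tree"),
) -> list[ModelSpec]:
    """All single-climate-variable candidates plus the optional DOY null.

    len == 5 * len(pool) + include_null; six temperature variables yield
    the 31-model set, one photoperiod variable the 6-model set.
    """
    if not variable_pool and not include_null:
        raise ValueError("empty variable pool without a null model")
    specs = [
        ModelSpec(v, s, group_factor, random)
        for v in variable_pool
        for s in STRUCTURES
    ]
    if include_null:
        specs.append(ModelSpec(None, "v", group_factor, random))
    return specs


def _dummies(values: pd.Series, levels: list) -> pd.DataFrame:
    """Treatment-coded indicators against the first (sorted) level."""
    out = {}
    for lev in levels[1:]:
        out[f"{values.name}[{lev}]"] = (values == lev).astype(float)
    return pd.DataFrame(out, index=values.index)


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    standardizer: Standardizer,
    levels: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix for a candidate model on encoded transition records.

    The climate variable is z-scored with the (training) standardizer.
    Factor levels are taken from the data unless ``levels`` is supplied
    (prediction-time paths must reuse the training levels).  Returns the
    design and the level map actually used.
    """
    var = spec.effective_variable
    z = standardizer.transform(records[var].to_numpy(dtype=float), var)
    X = pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    X[var] = z
    s = spec.structure
    needs_factors = spec.variable is not None and s != "v"
    if levels is None:
        levels = {}
        if needs_factors:
            for fct in ("site", spec.group_factor):
                levels[fct] = sorted(records[fct].unique().tolist())
    if needs_factors:
        site_d = _dummies(records["site"].rename("site"), levels["site"])
        grp_d = _dummies(records[spec.group_factor].rename(spec.group_factor),
                         levels[spec.group_factor])
        if "site" in s:
            X = pd.concat([X, site_d], axis=1)
        if "group" in s:
            X = pd.concat([X, grp_d], axis=1)
        if s == "v*site*group":
            for c in site_d.columns:
                X[f"{var}:{c}"] = z * site_d[c]
            for c in grp_d.columns:
                X[f"{var}:{c}"] = z * grp_d[c]
            for cs in site_d.columns:
                for cg in grp_d.columns:
                    X[f"{cs}:{cg}"] = site_d[cs] * grp_d[cg]
    return X, levels


# ---------------------------------------------------------------------------
# Information criteria and ranking
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2ℓ + 2k + 2k(k+1)/(n − k − 1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """ΔAICc and normalized evidence weights exp(−Δ/2)/Σexp(−Δ/2)."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def rank_models(fits: list[FitResult]) -> pd.DataFrame:
    """Selection table over converged fits, sorted by AICc.

    Non-converged candidates are excluded (and logged); an empty converged
    set is an error.  Columns: model_id, k, n, loglik, aicc, delta,
    weight, plausible, r2_marginal, r2_conditional.
    """
    ok = [f for f in fits if f.converged]
    bad = [f.model_id for f in fits if not f.converged]
    if bad:
        logger.warning("excluded %d non-converged candidates: %s", len(bad), bad)
    if not ok:
        raise ValueError("no converged candidate model to rank")
    for f in ok:
        if np.isnan(f.aicc):
            f.aicc = aicc(f.loglik, f.k, f.n)
    delta, w = akaike_weights([f.aicc for f in ok])
    table = pd.DataFrame(
        {
            "model_id": [f.model_id for f in ok],
            "k": [f.k for f in ok],
            "n": [f.n for f in ok],
            "loglik": [f.loglik for f in ok],
            "aicc": [f.aicc for f in ok],
            "delta": delta,
            "weight": w,
            "plausible": w > PLAUSIBLE_WEIGHT,
            "r2_marginal": [f.r2_marginal for f in ok],
            "r2_conditional": [f.r2_conditional for f in ok],
        }
    )
    return table.sort_values("aicc", kind="mergesort").reset_index(drop=True)


def model_average(fits: list[FitResult], weights: dict | pd.Series) -> pd.DataFrame:
    """Natural (conditional) model averaging with unconditional SEs.

    Each coefficient is averaged over the models containing it, with
    weights renormalized over that subset; the unconditional standard
    error follows Burnham & Anderson:
    sqrt(Σ w̃ᵢ [se²ᵢ + (βᵢ − β̄)²]).
    """
    if not fits:
        raise ValueError("empty model set for averaging")
    wmap = dict(weights)
    terms: dict[str, list] = {}
    for f in fits:
        for term in f.params.index:
            terms.setdefault(term, []).append(f)
    rows = []
    for term, models in terms.items():
        w = np.array([wmap[m.model_id] for m in models], dtype=float)
        w = w / w.sum()
        b = np.array([m.params[term] for m in models])
        se = np.array([m.bse[term] for m in models])
        bbar = float(w @ b)
        use = float(np.sqrt(w @ (se**2 + (b - bbar) ** 2)))
        rows.append({"term": term, "estimate": bbar, "se": use,
                     "n_models": len(models)})
    return pd.DataFrame(rows).set_index("term")


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1 − R²ⱼ) per predictor column.

    Exactly collinear columns are reported as ``inf`` (the >10 screening
    flags them).  An intercept column named 'const' is ignored.
    """
    cols = [c for c in X.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    Xm = X[cols].to_numpy(dtype=float)
    out = {}
    for j, c in enumerate(cols):
        others = np.column_stack(
            [np.ones(len(Xm))] + [Xm[:, i] for i in range(len(cols)) if i != j]
        )
        yj = Xm[:, j]
        coef, res_ss, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tot_ss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tot_ss if tot_ss > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def coef_significant(estimate: float, se: float, multiplier: float = 1.96) -> bool:
    """True when the ±multiplier·SE error interval excludes zero."""
    if not se > 0:
        raise ValueError(f"standard error must be positive, got {se}")
    return abs(estimate) > multiplier * se


# ---------------------------------------------------------------------------
# Fitting candidates and the two-phase selection
# ---------------------------------------------------------------------------

#: loosened outer tolerances for large candidate sweeps ("fast" Laplace)
SWEEP_OPTIONS = {"method": "fast", "outer_xatol": 0.05, "outer_fatol": 0.005,
                 "max_restarts": 1}


def fit_candidate(
    records: pd.DataFrame,
    spec: ModelSpec,
    standardizer: Standardizer,
    **fit_options,
) -> FitResult:
    """Fit one candidate model (GLMM when random terms remain) on records."""
    X, levels = build_design(records, spec, standardizer)
    y = records["outcome"].to_numpy(dtype=float)
    groups = {}
    for fct in spec.random:
        col = "tree" if fct == "tree" else fct
        if fct == "tree":
            # tree identity nested labels -> unique across sites/groups
            vals = (records["site"].astype(str) + "/" + records["tree"].astype(str))
        else:
            vals = records[col]
        groups[fct] = np.asarray(vals)
    try:
        if groups:
            fit = fit_logistic_glmm(y, X, groups, model_id=spec.model_id, **fit_options)
        else:
            fit = fit_logistic_glm(y, X, model_id=spec.model_id)
    except ValueError as exc:
        fit = FitResult(
            params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
            loglik=np.nan, k=X.shape[1], n=len(records), vc={}, converged=False,
            message=str(exc), model_id=spec.model_id,
        )
    fit.spec = replace(spec)
    if fit.converged:
        fit.aicc = aicc(fit.loglik, fit.k, fit.n)
        fit.r2_marginal, fit.r2_conditional = nakagawa_r2(fit)
    # reuse levels for prediction
    fit.levels = levels  # type: ignore[attr-defined]
    return fit


def fit_candidates(
    records: pd.DataFrame,
    specs: list[ModelSpec],
    standardizer: Standardizer,
    sweep: bool = True,
    **fit_options,
) -> list[FitResult]:
    """Fit a list of candidates, warm-starting variance components.

    With ``sweep=True`` the loosened SWEEP_OPTIONS are applied (candidates
    on a shared dataset have near-identical variance components, so each
    fit starts from the previous one's estimate).
    """
    options = dict(SWEEP_OPTIONS) if sweep else {}
    options.update(fit_options)
    fits = []
    start = None
    for spec in specs:
        f = fit_candidate(records, spec, standardizer,
                          start_logsigma=start, **options)
        fits.append(f)
        if f.converged and f.vc:
            start = np.log(np.sqrt(np.maximum(list(f.vc.values()), 1e-4)))
    return fits


@dataclass
class PhaseResult:
    """Selection outcome for one candidate phase (temperature or photoperiod)."""

    table: pd.DataFrame
    fits: list[FitResult]
    best: FitResult
    averaged: pd.DataFrame | None
    climate_coef: float
    climate_coef_se: float
    null_beats_all: bool

    @property
    def best_variable(self) -> str:
        return self.best.spec.effective_variable


def _run_phase(records, specs, standardizer, refit_best: bool = True,
               **fit_options) -> PhaseResult:
    fits = fit_candidates(records, specs, standardizer, **fit_options)
    table = rank_models(fits)
    by_id = {f.model_id: f for f in fits}
    best = by_id[table.loc[0, "model_id"]]
    if refit_best and best.vc:
        # tighten the winner with the full Laplace scheme
        refit = fit_candidate(records, best.spec, standardizer, method="full",
                              start_logsigma=np.log(np.sqrt(
                                  np.maximum(list(best.vc.values()), 1e-4))))
        if refit.converged:
            best = refit
            by_id[best.model_id] = best
    plaus = table[table["plausible"]]
    averaged = None
    var = best.spec.effective_variable
    if len(plaus) >= 2:
        averaged = model_average(
            [by_id[m] for m in plaus["model_id"]],
            dict(zip(plaus["model_id"], plaus["weight"])),
        )
        if var in averaged.index:
            coef = float(averaged.loc[var, "estimate"])
            se = float(averaged.loc[var, "se"])
        else:
            coef, se = float(best.params[var]), float(best.bse[var])
    else:
        coef, se = float(best.params[var]), float(best.bse[var])
    return PhaseResult(
        table=table,
        fits=fits,
        best=best,
        averaged=averaged,
        climate_coef=coef,
        climate_coef_se=se,
        null_beats_all=best.spec.variable is None,
    )


@dataclass
class TwoPhaseReport:
    """Per-transition comparison of the temperature and photoperiod phases."""

    transition: str
    temperature: PhaseResult
    photoperiod: PhaseResult

    @property
    def stronger_phase(self) -> str:
        return ("temperature"
                if abs(self.temperature.climate_coef) >= abs(self.photoperiod.climate_coef)
                else "photoperiod")

    def summary_row(self) -> dict:
        return {
            "transition": self.transition,
            "best_temperature_model": self.temperature.best.model_id,
            "best_photoperiod_model": self.photoperiod.best.model_id,
            "temp_coef": self.temperature.climate_coef,
            "temp_coef_se": self.temperature.climate_coef_se,
            "photo_coef": self.photoperiod.climate_coef,
            "photo_coef_se": self.photoperiod.climate_coef_se,
            "stronger_phase": self.stronger_phase,
            "temp_null_beats_all": self.temperature.null_beats_all,
            "photo_null_beats_all": self.photoperiod.null_beats_all,
        }


def two_phase_selection(
    records: pd.DataFrame,
    standardizer: Standardizer,
    transition: str = "",
    temperature_pool: list[str] | None = None,
    photoperiod_pool: list[str] | None = None,
    group_factor: str = "species",
    random: tuple = ("year", "tree"),
    refit_best: bool = True,
    **fit_options,
) -> TwoPhaseReport:
    """Temperature-phase then photoperiod-phase AICc selection on one transition.

    Each phase ranks its own candidate set (including a DOY null); the
    report compares the standardized climate coefficients of the two
    winners, the analysis's criterion for which cue dominates.
    ``refit_best=False`` skips the full-Laplace refit of each winner
    (threshold crossings, being ratios of coefficients, are nearly
    unaffected by the fast stage's proportional attenuation).
    """
    tpool = TEMPERATURE_POOL if temperature_pool is None else temperature_pool
    ppool = PHOTOPERIOD_POOL if photoperiod_pool is None else photoperiod_pool
    tspecs = enumerate_candidates(tpool, group_factor, True, random)
    pspecs = enumerate_candidates(ppool, group_factor, True, random)
    temp = _run_phase(records, tspecs, standardizer, refit_best=refit_best,
                      **fit_options)
    photo = _run_phase(records, pspecs, standardizer, refit_best=refit_best,
                       **fit_options)
    return TwoPhaseReport(transition=transition, temperature=temp, photoperiod=photo)
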