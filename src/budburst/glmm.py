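"""Binomial logistic models with and without crossed random intercepts.

``fit_logistic_glm`` is a thin wrapper over statsmodels' IRLS GLM and
serves as the fixed-effects fallback (and as the σ² → 0 oracle for the
mixed fitter).  ``fit_logistic_glmm`` is the package's own Laplace fitter
for logit models with crossed random intercepts (here: year and tree):

    logit P(y=1) = x'β + Σ_f σ_f u_f[level],   u_f ~ N(0, I)

The marginal likelihood is approximated by a Laplace expansion around the
mode of the spherical random effects,

    ℓ(β, σ) ≈ ℓ_cond(β, û) − ½ û'û − ½ log|Z̃'WZ̃ + I|,

fitted in two stages mirroring lme4: a fast stage profiles (β, u) jointly
out of the inner penalized IRLS and optimizes log σ alone (the nAGQ = 0
scheme); the default full stage then optimizes (β, log σ) together in a
bounded derivative-free outer loop with the inner solve over u only, the
standard Laplace scheme of glmer.  Three candidate starting points are
screened and perturbed restarts follow a failed outer optimization.
Standard errors for β come from the fixed-effect block of the inverse
joint penalized Hessian, which propagates uncertainty in u.

Because every random term is an intercept, each factor's own Hessian
block is diagonal; the inner Newton systems are solved by eliminating
the largest factor and forming a Schur complement on the small remainder
(fixed effects plus the other factors), so the per-iteration cost is
linear in the number of records and levels.

Variance-component estimates on the boundary (σ² ≈ 0) are legitimate and
reported with ``boundary=True``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

_PI2_3 = np.pi**2 / 3.0  # logit-link residual variance


@dataclass
class FitResult:
    """One fitted candidate model on one transition dataset."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    vc: dict[str, float]                 # variance components sigma^2 per factor
    converged: bool
    boundary: bool = False
    message: str = ""
    aicc: float = np.nan
    r2_marginal: float = np.nan
    r2_conditional: float = np.nan
    model_id: str = ""
    spec: object = None
    dropped_factors: tuple = ()
    fixed_var: float = np.nan            # variance of fixed-effect linear predictor

    @property
    def sigma2_total(self) -> float:
        return float(sum(self.vc.values()))


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _check_rank(Xm: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(Xm)
    if r < Xm.shape[1]:
        # name the aliased columns by inspecting QR pivots
        _, R = np.linalg.qr(Xm)
        diag = np.abs(np.diag(R))
        aliased = [names[j] for j in range(len(names))
                   if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix rank deficient; aliased columns: {aliased or names}")


def fit_logistic_glm(y, X, model_id: str = "") -> FitResult:
    """Fixed-effects logistic regression by IRLS maximum likelihood.

    Separation is flagged as non-converged rather than raised; rank
    deficiency is an error naming aliased columns.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    _check_rank(Xm, names)
    if yv.min() == yv.max():
        raise ValueError("both outcome classes must be present")
    converged = True
    message = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(yv, Xm, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    p = np.asarray(res.fittedvalues)
    if np.all((p > 1 - 1e-6) == (yv == 1)):
        converged = False
        message = "complete separation"
    if not res.converged:
        converged = False
        message = message or "IRLS did not converge"
    params = pd.Series(np.asarray(res.params), index=names)
    eta = Xm @ params.to_numpy()
    return FitResult(
        params=params,
        bse=pd.Series(np.asarray(res.bse), index=names),
        loglik=float(res.llf),
        k=Xm.shape[1],
        n=len(yv),
        vc={},
        converged=converged,
        message=message,
        model_id=model_id,
        fixed_var=float(np.var(eta)),
    )


# ---------------------------------------------------------------------------
# Laplace GLMM internals
# ---------------------------------------------------------------------------

class _Kernel:
    """Cross-product kernels for a design with crossed intercept factors.

    The factor with the most levels is eliminated analytically (its own
    Hessian block is diagonal); everything else — the other factors and,
    for the joint solve, the fixed effects — lives in a small dense tail.
    """

    def __init__(self, Xm: np.ndarray, groups: dict):
        self.Xm = Xm
        self.p = Xm.shape[1]
        self.names: list[str] = []
        self.codes: list[np.ndarray] = []
        self.q: list[int] = []
        for name, levels in groups.items():
            codes, uniq = pd.factorize(np.asarray(levels), sort=True)
            self.names.append(name)
            self.codes.append(codes.astype(np.int64))
            self.q.append(len(uniq))
        self.nf = len(self.names)
        self.big = int(np.argmax(self.q))
        self.rest = [f for f in range(self.nf) if f != self.big]
        self.q_total = int(sum(self.q))
        self.offsets = np.concatenate([[0], np.cumsum(self.q)])[:-1]

    # -- linear-predictor helpers -------------------------------------------
    def eta_random(self, sigmas, u):
        eta = 0.0
        for f, c in enumerate(self.codes):
            uf = u[self.offsets[f]: self.offsets[f] + self.q[f]]
            eta = eta + sigmas[f] * uf[c]
        return eta

    def zt_dot(self, sigmas, v):
        out = np.empty(self.q_total)
        for f, c in enumerate(self.codes):
            out[self.offsets[f]: self.offsets[f] + self.q[f]] = (
                sigmas[f] * np.bincount(c, weights=v, minlength=self.q[f])
            )
        return out

    def _u_slice(self, f):
        return slice(self.offsets[f], self.offsets[f] + self.q[f])

    # -- Hessian pieces ------------------------------------------------------
    def pieces(self, sigmas, w, with_beta: bool):
        """Diagonal of the big factor, cross block B and dense tail T.

        Tail order: [β (if with_beta), u_f for f in rest].
        All blocks include the +I spherical penalty where applicable.
        """
        b = self.big
        cb = self.codes[b]
        qb = self.q[b]
        D = sigmas[b] ** 2 * np.bincount(cb, weights=w, minlength=qb) + 1.0
        cols = []
        m = (self.p if with_beta else 0) + sum(self.q[f] for f in self.rest)
        B = np.empty((qb, m))
        T = np.zeros((m, m))
        pos = 0
        if with_beta:
            Xw = self.Xm * w[:, None]
            T[: self.p, : self.p] = Xw.T @ self.Xm
            for j in range(self.p):
                B[:, j] = sigmas[b] * np.bincount(cb, weights=Xw[:, j], minlength=qb)
            pos = self.p
        tail_slices = {}
        for f in self.rest:
            tail_slices[f] = slice(pos, pos + self.q[f])
            pos += self.q[f]
        for f in self.rest:
            qf = self.q[f]
            sl = tail_slices[f]
            M = np.zeros((qb, qf))
            np.add.at(M, (cb, self.codes[f]), w)
            B[:, sl] = sigmas[b] * sigmas[f] * M
            T[sl, sl] = np.diag(
                sigmas[f] ** 2 * np.bincount(self.codes[f], weights=w, minlength=qf)
                + 1.0
            )
            if with_beta:
                for j in range(self.p):
                    T[j, sl] = sigmas[f] * np.bincount(
                        self.codes[f], weights=Xw[:, j], minlength=qf
                    )
                    T[sl, j] = T[j, sl]
            for g in self.rest:
                if g <= f:
                    continue
                Mfg = np.zeros((qf, self.q[g]))
                np.add.at(Mfg, (self.codes[f], self.codes[g]), w)
                T[sl, tail_slices[g]] = sigmas[f] * sigmas[g] * Mfg
                T[tail_slices[g], sl] = sigmas[f] * sigmas[g] * Mfg.T
        return D, B, T

    @staticmethod
    def solve_partitioned(D, B, T, g_big, g_tail):
        """Solve [[diag(D), B], [B', T]] z = [g_big, g_tail]."""
        Binv = B / D[:, None]
        S = T - B.T @ Binv
        z_tail = np.linalg.solve(S, g_tail - Binv.T @ g_big)
        z_big = (g_big - B @ z_tail) / D
        return z_big, z_tail, S

    def logdet_uu(self, sigmas, w):
        """log|Z̃'WZ̃ + I| via elimination of the big factor."""
        D, B, T = self.pieces(sigmas, w, with_beta=False)
        out = float(np.sum(np.log(D)))
        if T.shape[0]:
            S = T - (B / D[:, None]).T @ B
            sign, ld = np.linalg.slogdet(S)
            if sign <= 0:
                return None
            out += float(ld)
        return out


def _pirls(yv, kern: _Kernel, sigmas, state, beta=None, max_iter=60, tol=1e-10):
    """Penalized IRLS at fixed σ.

    With ``beta=None`` the fixed effects are solved jointly with the
    random effects (profiled stage); otherwise only the random-effect
    mode is found.  Returns (beta, u, pen_ll, logdet_uu, ok).
    """
    p = kern.p
    profile_beta = beta is None
    b = state["beta"].copy() if profile_beta else np.asarray(beta, dtype=float)
    u = state["u"].copy()
    big_sl = kern._u_slice(kern.big)
    rest_sls = [kern._u_slice(f) for f in kern.rest]

    def pen_ll_of(b, u):
        eta = np.clip(kern.Xm @ b + kern.eta_random(sigmas, u), -500, 500)
        ll = float(np.sum(yv * eta - np.log1p(np.exp(eta))))
        return ll - 0.5 * float(u @ u), eta

    obj, eta = pen_ll_of(b, u)
    ok = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        r = yv - mu
        gu = kern.zt_dot(sigmas, r) - u
        g_big = gu[big_sl]
        tail_parts = []
        if profile_beta:
            tail_parts.append(kern.Xm.T @ r)
        tail_parts.extend(gu[sl] for sl in rest_sls)
        g_tail = np.concatenate(tail_parts) if tail_parts else np.empty(0)
        D, B, T = kern.pieces(sigmas, w, with_beta=profile_beta)
        try:
            z_big, z_tail, _ = kern.solve_partitioned(D, B, T, g_big, g_tail)
        except np.linalg.LinAlgError:
            return b, u, obj, None, False
        db = z_tail[:p] if profile_beta else np.zeros(p)
        du = np.zeros_like(u)
        du[big_sl] = z_big
        pos = p if profile_beta else 0
        for f, sl in zip(kern.rest, rest_sls):
            du[sl] = z_tail[pos: pos + kern.q[f]]
            pos += kern.q[f]
        step = 1.0
        for _half in range(30):
            nb, nu = b + step * db, u + step * du
            new_obj, new_eta = pen_ll_of(nb, nu)
            if new_obj >= obj - 1e-12:
                break
            step *= 0.5
        else:
            break
        b, u, obj, eta = nb, nu, new_obj, new_eta
        if max(np.max(np.abs(step * du)), np.max(np.abs(step * db), initial=0.0)) < tol:
            ok = True
            break
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    logdet = kern.logdet_uu(sigmas, w)
    return b, u, obj, logdet, ok


def fit_logistic_glmm(
    y,
    X,
    groups: dict,
    model_id: str = "",
    method: str = "full",
    outer_xatol: float = 5e-3,
    outer_fatol: float = 1e-6,
    max_restarts: int = 2,
    start_logsigma: np.ndarray | None = None,
    outer_maxfev: int | None = None,
) -> FitResult:
    """Laplace fit of a logit model with crossed random intercepts.

    ``groups`` maps factor name -> level labels per record.  Factors with a
    single observed level are dropped with a warning; with no factors left
    the fit delegates to :func:`fit_logistic_glm`.

    ``method="full"`` (default) optimizes (β, log σ) jointly in the outer
    loop (glmer's Laplace); ``method="fast"`` stops after the profiled
    stage (glmer's nAGQ = 0), trading a small attenuation of β for a
    several-fold speedup — adequate for large model-selection sweeps.
    Non-convergence after perturbed restarts is flagged, never silently
    returned as converged.
    """
    if method not in ("full", "fast"):
        raise ValueError(f"unknown method {method!r}")
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    _check_rank(Xm, names)

    kept, dropped = {}, []
    for name, levels in groups.items():
        if len(pd.unique(np.asarray(levels))) < 2:
            dropped.append(name)
        else:
            kept[name] = levels
    if dropped:
        warnings.warn(f"random factor(s) with a single level dropped: {dropped}",
                      stacklevel=2)
    if not kept:
        res = fit_logistic_glm(yv, X, model_id=model_id)
        res.dropped_factors = tuple(dropped)
        return res

    kern = _Kernel(Xm, kept)
    p, nf = kern.p, kern.nf
    lo, hi = -6.0, 3.0

    # ---- stage 1: profile (β, u), optimize log σ ---------------------------
    state = {"beta": np.zeros(p), "u": np.zeros(kern.q_total)}

    def neg_laplace_profiled(log_sigma):
        sigmas = np.exp(log_sigma)
        b, u, pen_ll, logdet, ok = _pirls(yv, kern, sigmas, state)
        if ok:
            state["beta"], state["u"] = b, u
        if logdet is None:
            return 1e10
        return -(pen_ll - 0.5 * logdet)

    if start_logsigma is not None:
        x0 = np.clip(np.asarray(start_logsigma, dtype=float)[:nf], lo, hi)
    else:
        starts = [np.full(nf, np.log(s)) for s in (0.5, 0.15, 1.5)]
        start_vals = [neg_laplace_profiled(s) for s in starts]
        x0 = starts[int(np.argmin(start_vals))]
    opt1 = minimize(
        neg_laplace_profiled, x0, method="Nelder-Mead", bounds=[(lo, hi)] * nf,
        options={"xatol": outer_xatol, "fatol": outer_fatol,
                 "maxfev": outer_maxfev or 200 * nf},
    )
    beta1, u1, _, _, _ = _pirls(yv, kern, np.exp(opt1.x), state, max_iter=100)

    if method == "fast":
        opt, beta, log_sigma = opt1, beta1, opt1.x
        ustate = {"beta": beta1, "u": u1}
    else:
        # ---- stage 2: outer over (β, log σ), inner over u only ------------
        ustate = {"beta": beta1, "u": u1.copy()}

        def neg_laplace_joint(z):
            b, log_sigma = z[:p], z[p:]
            sigmas = np.exp(log_sigma)
            _, u, pen_ll, logdet, ok = _pirls(yv, kern, sigmas, ustate, beta=b)
            if ok:
                ustate["u"] = u
            if logdet is None:
                return 1e10
            return -(pen_ll - 0.5 * logdet)

        z0 = np.concatenate([beta1, opt1.x])
        zbounds = [(-50.0, 50.0)] * p + [(lo, hi)] * nf
        rng = np.random.default_rng(0)
        best = None
        for _attempt in range(1 + max_restarts):
            if p + nf <= 4:
                opt = minimize(
                    neg_laplace_joint, z0, method="Nelder-Mead", bounds=zbounds,
                    options={"xatol": 1e-4, "fatol": 1e-8,
                             "maxfev": 500 * (p + nf)},
                )
            else:
                # high-dimensional outer: quasi-Newton with numeric gradient
                opt = minimize(
                    neg_laplace_joint, z0, method="L-BFGS-B", bounds=zbounds,
                    options={"maxiter": 100, "ftol": 1e-11, "gtol": 1e-6,
                             "eps": 1e-6},
                )
            if best is None or opt.fun < best.fun:
                best = opt
            if opt.success:
                break
            z0 = best.x + rng.normal(scale=0.2, size=p + nf)
            z0[p:] = np.clip(z0[p:], lo, hi)
        opt = best
        beta, log_sigma = opt.x[:p], opt.x[p:]

    sigmas = np.exp(log_sigma)
    _, u, pen_ll, logdet, inner_ok = _pirls(
        yv, kern, sigmas, ustate, beta=beta, max_iter=100
    )
    det_ok = logdet is not None
    loglik = pen_ll - 0.5 * logdet if det_ok else -np.inf

    # standard errors from the joint penalized Hessian at the optimum
    eta = np.clip(Xm @ beta + kern.eta_random(sigmas, u), -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    try:
        D, B, T = kern.pieces(sigmas, w, with_beta=True)
        S = T - (B / D[:, None]).T @ B   # Schur complement onto [β, u_rest]
        cov_tail = np.linalg.inv(S)
        bse = np.sqrt(np.maximum(np.diag(cov_tail)[:p], 0.0))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
        inner_ok = False

    boundary = bool(np.any(log_sigma <= lo + 1e-6))
    converged = bool(opt.success and inner_ok and det_ok)
    vc = {name: float(sigmas[f] ** 2) for f, name in enumerate(kern.names)}
    res = FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        loglik=float(loglik),
        k=p + nf,
        n=len(yv),
        vc=vc,
        converged=converged,
        boundary=boundary,
        message="" if converged else f"outer: {opt.message}; inner ok: {inner_ok}",
        model_id=model_id,
        dropped_factors=tuple(dropped),
        fixed_var=float(np.var(Xm @ beta)),
    )
    if not converged:
        logger.warning("GLMM %s did not converge: %s", model_id or "<unnamed>", res.message)
    return res


def laplace_loglik(y, X, groups: dict, beta, sigmas) -> float:
    """Laplace marginal log-likelihood at fixed (β, σ).

    Evaluates the approximation at the random-effect mode for the given
    parameters; at σ = 0 it reduces exactly to the fixed-effects binomial
    log-likelihood.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    kern = _Kernel(Xm, groups)
    state = {"beta": np.asarray(beta, dtype=float), "u": np.zeros(kern.q_total)}
    _, _, pen_ll, logdet, _ = _pirls(
        yv, kern, np.asarray(sigmas, dtype=float), state, beta=beta, max_iter=100
    )
    if logdet is None:
        raise ValueError("random-effect Hessian not positive definite")
    return float(pen_ll - 0.5 * logdet)


def nakagawa_r2(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional pseudo-R² on the latent logit scale.

    R²m = σ²_f / (σ²_f + Σσ²_re + π²/3);  R²c adds the random-effect
    variances to the numerator.  σ²_f is the variance of the fixed-effect
    linear predictor over the fitted records.
    """
    s2f = fit.fixed_var
    s2r = fit.sigma2_total
    denom = s2f + s2r + _PI2_3
    return s2f / denom, (s2f + s2r) / denom
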