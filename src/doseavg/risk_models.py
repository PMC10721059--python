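"""Linear excess-risk likelihoods and constrained maximum-likelihood fitting.

Two model families are supported, both with a *linear* dose term:

- ``poisson_err``: per-stratum counts ``Y_i ~ Poisson(PY_i * exp(a'W_i) *
  (1 + beta*D_i*exp(eta'M_i)))`` — the linear excess-relative-risk (ERR)
  Poisson model with a person-years offset;
- ``logistic_eor``: binary outcomes with odds ``exp(a'W_i) *
  (1 + beta*D_i*exp(eta'M_i))`` — the linear excess-odds-ratio (EOR) model.

The linear dose term makes the likelihood domain-restricted: the excess
factor ``1 + beta*D_i*exp(eta'M_i)`` must stay positive, so ``beta`` is
box-constrained to ``(-1/max_i(D_i*exp(eta'M_i)) + 1e-8, +inf)`` inside the
optimizer.  Log-likelihoods retain their constants (``log Y_i!``) so AIC
values are absolute and comparable across software.

Model averaging over K dose realizations requires K fits that differ only in
the dose column; :func:`fit_realizations` fits them jointly with a vectorized
Newton-Raphson over a (K, p) parameter array.  Columns are frozen as soon as
they individually converge, so each column's result is independent of which
other columns it was batched with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import gammaln

from doseavg.suma import Cohort

__all__ = [
    "DomainError",
    "ModelSpec",
    "FitResult",
    "build_design",
    "logistic_eor_loglik",
    "poisson_err_loglik",
    "fit_model",
    "fit_realizations",
    "null_alpha_fit",
]

#: relative log-likelihood change below which a fit is declared converged
LOGLIK_RTOL = 1e-9
#: gradient max-norm threshold at convergence
GRAD_TOL = 1e-4
#: margin keeping beta strictly inside the positivity boundary
BETA_MARGIN = 1e-8


class DomainError(ValueError):
    """The linear excess term is non-positive at the requested parameters."""


_COVARIATES = {
    "gender": lambda c: c.gender,
    "age": lambda c: c.age,
    "log_age40": lambda c: np.log(c.age / 40.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which likelihood family to use and which cohort columns enter it.

    ``confounders`` enter the baseline log-linear term (after an intercept);
    ``modifiers`` enter the dose-effect factor ``exp(eta'M)``.  An empty
    modifier tuple removes ``eta`` from the parameter vector.  Parameter
    layout is ``theta = (alpha_0, alpha_confounders..., beta, eta...)``.
    """

    family: str
    confounders: tuple[str, ...] = ("gender", "log_age40")
    modifiers: tuple[str, ...] = ()
    offset_person_years: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("poisson_err", "logistic_eor"):
            raise ValueError(f"unknown family {self.family!r}")
        for name in (*self.confounders, *self.modifiers):
            if name not in _COVARIATES:
                raise ValueError(
                    f"unknown covariate {name!r}; available: {sorted(_COVARIATES)}"
                )

    @property
    def n_alpha(self) -> int:
        return 1 + len(self.confounders)

    @property
    def n_params(self) -> int:
        return self.n_alpha + 1 + len(self.modifiers)

    @property
    def beta_index(self) -> int:
        return self.n_alpha


#: model used throughout the simulation study
DEFAULT_POISSON = ModelSpec(family="poisson_err")


@dataclass
class FitResult:
    """MLE of one dose-realization model.

    ``theta_hat`` follows the ModelSpec layout; ``cov`` is the inverse
    observed information (None when the fit failed); ``var_beta`` is its
    beta-diagonal entry, ``+inf`` when beta is unidentified (e.g. an all-zero
    dose column).  ``aic = 2*n_params - 2*loglik`` exactly.
    """

    theta_hat: np.ndarray
    beta_hat: float
    var_beta: float
    loglik: float
    aic: float
    converged: bool
    n_params: int
    cov: np.ndarray | None = None
    message: str = ""


def build_design(cohort: Cohort, names: tuple[str, ...], intercept: bool = True) -> np.ndarray:
    cols = []
    if intercept:
        cols.append(np.ones(len(cohort)))
    cols.extend(_COVARIATES[name](cohort) for name in names)
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def _split_theta(theta: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, float, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != spec.n_params:
        raise ValueError(f"theta has {theta.shape[-1]} entries, expected {spec.n_params}")
    q = spec.n_alpha
    return theta[:q], float(theta[q]), theta[q + 1 :]


def _excess_factor(beta: float, dose: np.ndarray, eta: np.ndarray, Mmat: np.ndarray) -> np.ndarray:
    mod = np.exp(Mmat @ eta) if eta.size else 1.0
    return 1.0 + beta * dose * mod


def poisson_err_loglik(
    theta: np.ndarray, dose_vector: np.ndarray, cohort: Cohort, spec: ModelSpec
) -> float:
    """Exact linear-ERR Poisson log-likelihood, including the log Y! constant."""
    if cohort.outcome is None:
        raise ValueError("cohort has no outcome vector")
    alpha, beta, eta = _split_theta(theta, spec)
    W = build_design(cohort, spec.confounders)
    Mmat = build_design(cohort, spec.modifiers, intercept=False)
    dose = np.asarray(dose_vector, dtype=float)
    r = _excess_factor(beta, dose, eta, Mmat)
    if np.any(r <= 0):
        raise DomainError("1 + beta*D*exp(eta'M) must be positive for every stratum")
    Y = cohort.outcome
    logpy = np.log(cohort.person_years) if spec.offset_person_years else np.zeros(len(cohort))
    lin = W @ alpha
    return float(
        np.sum(Y * (logpy + lin + np.log(r)))
        - np.sum(np.exp(logpy + lin) * r)
        - np.sum(gammaln(Y + 1.0))
    )


def logistic_eor_loglik(
    theta: np.ndarray, dose_vector: np.ndarray, cohort: Cohort, spec: ModelSpec
) -> float:
    """Bernoulli log-likelihood of the linear-EOR logistic model."""
    if cohort.outcome is None:
        raise ValueError("cohort has no outcome vector")
    alpha, beta, eta = _split_theta(theta, spec)
    W = build_design(cohort, spec.confounders)
    Mmat = build_design(cohort, spec.modifiers, intercept=False)
    dose = np.asarray(dose_vector, dtype=float)
    r = _excess_factor(beta, dose, eta, Mmat)
    if np.any(r <= 0):
        raise DomainError("odds must be positive: 1 + beta*D*exp(eta'M) <= 0")
    log_odds = W @ alpha + np.log(r)
    Y = cohort.outcome
    # sum y*log(odds) - log(1+odds), written stably via logaddexp
    return float(np.sum(Y * log_odds - np.logaddexp(0.0, log_odds)))


def family_loglik(
    theta: np.ndarray, dose_vector: np.ndarray, cohort: Cohort, spec: ModelSpec
) -> float:
    if spec.family == "poisson_err":
        return poisson_err_loglik(theta, dose_vector, cohort, spec)
    return logistic_eor_loglik(theta, dose_vector, cohort, spec)


def null_alpha_fit(cohort: Cohort, spec: ModelSpec):
    """Baseline (beta = 0) fit via a standard GLM; returns (alpha_hat, loglik)."""
    W = build_design(cohort, spec.confounders)
    if spec.family == "poisson_err":
        offset = np.log(cohort.person_years) if spec.offset_person_years else None
        model = sm.GLM(cohort.outcome, W, family=sm.families.Poisson(), offset=offset)
    else:
        model = sm.GLM(cohort.outcome, W, family=sm.families.Binomial())
    res = model.fit()
    return np.asarray(res.params), float(res.llf)


def _beta_lower_bound(dose: np.ndarray, eta: np.ndarray, Mmat: np.ndarray) -> float:
    mod = np.exp(Mmat @ eta) if eta.size else 1.0
    m = np.max(dose * mod)
    if m <= 0:
        return -np.inf
    return -1.0 / m + BETA_MARGIN


# ---------------------------------------------------------------------------
# Vectorized Newton-Raphson for the ERR Poisson family (no effect modifiers)


def _batched_loglik(
    alpha: np.ndarray, beta: np.ndarray, Y: np.ndarray, W: np.ndarray,
    logpy: np.ndarray, D: np.ndarray, const: float,
) -> np.ndarray:
    """Log-likelihood for each column k of D at (alpha[k], beta[k]).

    Returns -inf for columns violating the positivity constraint.
    """
    r = 1.0 + beta[None, :] * D
    eta_lin = W @ alpha.T + logpy[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        term = Y[:, None] * (eta_lin + np.log(r)) - np.exp(eta_lin) * r
        ll = term.sum(axis=0) - const
    ll[np.any(r <= 0, axis=0)] = -np.inf
    return ll


def _pair_index(q: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(q) for j in range(i, q)]


def _assemble_info(
    mu: np.ndarray, s: np.ndarray, Y: np.ndarray, W: np.ndarray,
    Wpair: np.ndarray, pairs: list[tuple[int, int]],
) -> np.ndarray:
    """Observed information matrices, (k, p, p), via BLAS-shaped products."""
    k = mu.shape[1]
    q = W.shape[1]
    p = q + 1
    info = np.empty((k, p, p))
    aa = mu.T @ Wpair  # (k, n_pairs)
    for idx_pair, (i, j) in enumerate(pairs):
        info[:, i, j] = aa[:, idx_pair]
        info[:, j, i] = aa[:, idx_pair]
    cross = (mu * s).T @ W  # (k, q)
    info[:, :q, q] = cross
    info[:, q, :q] = cross
    info[:, q, q] = (s * s).T @ Y
    return info


def _fit_poisson_err_batched(
    Y: np.ndarray,
    W: np.ndarray,
    logpy: np.ndarray,
    D: np.ndarray,
    alpha_init: np.ndarray,
    null_loglik: float,
    max_iter: int = 200,
) -> list[FitResult]:
    """Jointly maximize the ERR Poisson likelihood for every dose column of D."""
    N, q = W.shape
    K = D.shape[1]
    p = q + 1
    const = float(np.sum(gammaln(Y + 1.0)))
    pairs = _pair_index(q)
    Wpair = np.column_stack([W[:, i] * W[:, j] for i, j in pairs])

    max_D = D.max(axis=0)
    degenerate = max_D <= 0
    with np.errstate(divide="ignore"):
        beta_lb = np.where(max_D > 0, -1.0 / np.where(max_D > 0, max_D, 1.0) + BETA_MARGIN, -np.inf)

    alpha = np.tile(alpha_init, (K, 1))
    beta = np.zeros(K)
    ll = _batched_loglik(alpha, beta, Y, W, logpy, D, const)
    last_dll = np.full(K, np.inf)
    converged = degenerate.copy()
    failed = np.zeros(K, dtype=bool)

    for _ in range(max_iter):
        act = ~converged & ~failed
        if not act.any():
            break
        idx = np.flatnonzero(act)
        A, B, Dk = alpha[idx], beta[idx], D[:, idx]
        r = 1.0 + B[None, :] * Dk
        mu = np.exp(A @ W.T + logpy[None, :]).T * r
        resid = Y[:, None] - mu
        s = Dk / r
        grad = np.empty((idx.size, p))
        grad[:, :q] = resid.T @ W
        grad[:, q] = np.sum(resid * s, axis=0)

        gmax = np.max(np.abs(grad), axis=1)
        done = (gmax < GRAD_TOL) & (last_dll[idx] < LOGLIK_RTOL * (1.0 + np.abs(ll[idx])))
        if done.any():
            converged[idx[done]] = True
            keep = ~done
            if not keep.any():
                continue
            idx = idx[keep]
            A, B, Dk, r, mu, s, grad = A[keep], B[keep], Dk[:, keep], r[:, keep], mu[:, keep], s[:, keep], grad[keep]

        info = _assemble_info(mu, s, Y, W, Wpair, pairs)

        try:
            step = np.linalg.solve(info, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.empty((idx.size, p))
            for j in range(idx.size):
                try:
                    step[j] = np.linalg.solve(info[j], grad[j])
                except np.linalg.LinAlgError:
                    step[j] = np.linalg.lstsq(info[j], grad[j], rcond=None)[0]

        # backtracking line search, per column
        t = np.ones(idx.size)
        ll_old = ll[idx]
        best_ll = ll_old.copy()
        best_alpha, best_beta = A.copy(), B.copy()
        improved = np.zeros(idx.size, dtype=bool)
        for _h in range(50):
            cand_a = A + t[:, None] * step[:, :q]
            cand_b = B + t * step[:, q]
            ok_dom = cand_b > beta_lb[idx]
            ll_new = np.full(idx.size, -np.inf)
            if ok_dom.any():
                sub = np.flatnonzero(ok_dom)
                ll_new[sub] = _batched_loglik(
                    cand_a[sub], cand_b[sub], Y, W, logpy, D[:, idx[sub]], const
                )
            better = ll_new > best_ll
            if better.any():
                best_ll[better] = ll_new[better]
                best_alpha[better] = cand_a[better]
                best_beta[better] = cand_b[better]
                improved |= better
            if improved.all():
                break
            t = np.where(improved, 0.0, t * 0.5)

        # a column that cannot improve: converged if gradient already small, else failed
        stuck = ~improved
        if stuck.any():
            g_small = np.max(np.abs(grad[stuck]), axis=1) < GRAD_TOL
            converged[idx[stuck][g_small]] = True
            failed[idx[stuck][~g_small]] = True
        upd = improved
        if upd.any():
            cols = idx[upd]
            alpha[cols] = best_alpha[upd]
            beta[cols] = best_beta[upd]
            last_dll[cols] = best_ll[upd] - ll_old[upd]
            ll[cols] = best_ll[upd]
    else:
        failed |= ~converged

    # covariance at the optimum (observed information inverse), all columns at once
    r = 1.0 + beta[None, :] * D
    mu = np.exp(alpha @ W.T + logpy[None, :]).T * r
    s_all = np.where(r > 0, D / np.where(r > 0, r, 1.0), 0.0)
    info_all = _assemble_info(mu, s_all, Y, W, Wpair, pairs)
    covs = np.full((K, p, p), np.nan)
    solvable = ~degenerate & np.all(np.isfinite(info_all), axis=(1, 2))
    if solvable.any():
        sub = np.flatnonzero(solvable)
        try:
            covs[sub] = np.linalg.inv(info_all[sub])
        except np.linalg.LinAlgError:
            for k in sub:
                c = _safe_inv(info_all[k])
                if c is not None:
                    covs[k] = c

    results: list[FitResult] = []
    for k in range(K):
        theta = np.concatenate([alpha[k], [beta[k]]])
        if degenerate[k]:
            results.append(
                FitResult(theta, 0.0, np.inf, null_loglik, 2 * p - 2 * null_loglik,
                          True, p, None, "dose identically zero; beta unidentified")
            )
            continue
        cov = covs[k]
        cov_ok = bool(np.all(np.isfinite(cov))) and cov[q, q] >= 0
        ok = bool(converged[k]) and not failed[k] and cov_ok
        var_beta = float(cov[q, q]) if cov_ok else np.inf
        results.append(
            FitResult(theta, float(beta[k]), var_beta, float(ll[k]),
                      2 * p - 2 * float(ll[k]), ok, p, cov if cov_ok else None,
                      "" if ok else "Newton iteration did not converge")
        )
    return results


def _safe_inv(mat: np.ndarray) -> np.ndarray | None:
    try:
        cond = np.linalg.cond(mat)
        if not np.isfinite(cond) or cond > 1e12:
            return None
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# Generic (scalar) fit with an initialization ladder


def _moment_beta_init(
    Y: np.ndarray, py: np.ndarray, W: np.ndarray, alpha: np.ndarray, dose: np.ndarray
) -> float:
    """Crude moment slope: regress the observed excess ratio on dose."""
    with np.errstate(divide="ignore", invalid="ignore"):
        excess = Y / (py * np.exp(W @ alpha)) - 1.0
    excess = np.where(np.isfinite(excess), excess, 0.0)
    dd = dose - dose.mean()
    denom = float(dd @ dd)
    if denom <= 0:
        return 0.0
    return float(dd @ excess / denom)


def fit_model(
    spec: ModelSpec,
    dose_vector: np.ndarray,
    cohort: Cohort,
    init: np.ndarray | None = None,
) -> FitResult:
    """Constrained MLE of one model (one dose vector).

    The positivity constraint on the linear excess term is enforced as a box
    constraint on beta.  Initialization ladder: (1) null-model alphas with
    beta = 0, (2) a moment-based beta, (3) three deterministic jitters.  On
    total failure the best point found is returned with ``converged=False``.
    """
    dose = np.asarray(dose_vector, dtype=float)
    if cohort.outcome is None:
        raise ValueError("cohort has no outcome vector")
    if dose.shape[0] != len(cohort):
        raise ValueError("dose vector length must match the cohort size")

    if spec.family == "poisson_err" and not spec.modifiers and init is None:
        W = build_design(cohort, spec.confounders)
        logpy = np.log(cohort.person_years) if spec.offset_person_years else np.zeros(len(cohort))
        alpha0, null_ll = null_alpha_fit(cohort, spec)
        res = _fit_poisson_err_batched(
            cohort.outcome, W, logpy, dose[:, None], alpha0, null_ll
        )[0]
        if res.converged:
            return res
        # fall through to the scipy ladder from the best point found
        init = res.theta_hat

    return _fit_generic(spec, dose, cohort, init)


def _fit_generic(
    spec: ModelSpec, dose: np.ndarray, cohort: Cohort, init: np.ndarray | None
) -> FitResult:
    p = spec.n_params
    q = spec.n_alpha
    Mmat = build_design(cohort, spec.modifiers, intercept=False)

    def negll(theta: np.ndarray) -> float:
        try:
            return -family_loglik(theta, dose, cohort, spec)
        except DomainError:
            return np.inf

    inits: list[np.ndarray] = []
    if init is not None:
        inits.append(np.asarray(init, dtype=float))
    try:
        alpha0, _ = null_alpha_fit(cohort, spec)
    except Exception:
        alpha0 = np.zeros(q)
    base = np.zeros(p)
    base[:q] = alpha0
    inits.append(base)
    if spec.family == "poisson_err":
        W = build_design(cohort, spec.confounders)
        b_m = _moment_beta_init(cohort.outcome, cohort.person_years, W, alpha0, dose)
        mb = base.copy()
        mb[q] = b_m
        inits.append(mb)
    jrng = np.random.default_rng(170258)
    for _ in range(3):
        jit = base + jrng.normal(0.0, 0.25, size=p)
        jit[q] = 0.0
        inits.append(jit)

    lb = _beta_lower_bound(dose, np.zeros(len(spec.modifiers)), Mmat)
    bounds = [(None, None)] * q + [(lb if np.isfinite(lb) else None, None)]
    bounds += [(None, None)] * len(spec.modifiers)

    best = None
    for theta0 in inits:
        if not np.isfinite(negll(theta0)):
            continue
        sol = minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7})
        if best is None or sol.fun < best.fun:
            best = sol
        if sol.success and np.isfinite(sol.fun):
            break
    if best is None:
        nanv = np.full(p, np.nan)
        return FitResult(nanv, np.nan, np.inf, -np.inf, np.inf, False, p, None,
                         "likelihood non-finite at every initialization")

    theta_hat = np.asarray(best.x, dtype=float)
    ll = -float(best.fun)
    cov = _numerical_covariance(spec, theta_hat, dose, cohort)
    var_beta = float(cov[q, q]) if cov is not None else np.inf
    ok = bool(best.success) and cov is not None and var_beta >= 0
    return FitResult(theta_hat, float(theta_hat[q]), var_beta if ok else np.inf,
                     ll, 2 * p - 2 * ll, ok, p, cov,
                     "" if ok else str(best.message))


def _numerical_covariance(
    spec: ModelSpec, theta: np.ndarray, dose: np.ndarray, cohort: Cohort,
    h: float = 1e-5,
) -> np.ndarray | None:
    """Inverse of the numerically differentiated observed information."""
    p = theta.size

    def f(t: np.ndarray) -> float:
        try:
            return family_loglik(t, dose, cohort, spec)
        except DomainError:
            return -np.inf

    H = np.empty((p, p))
    scale = np.maximum(np.abs(theta), 1.0) * h
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = scale[i]
            ej = np.zeros(p); ej[j] = scale[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                return None
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * scale[i] * scale[j])
    return _safe_inv(-H)


# ---------------------------------------------------------------------------
# Batch interface used by the model-averaging engines


def fit_realizations(
    spec: ModelSpec,
    doses: np.ndarray,
    cohort: Cohort,
    workers: int = 1,
) -> list[FitResult]:
    """Fit the specified model to every dose column of ``doses`` (N x K).

    Results are independent of ``workers`` and of column batching up to
    floating-point lane effects (about one ulp): each column is frozen as
    soon as it converges, so no column's trajectory depends on the others.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 2:
        raise ValueError("doses must be a 2-D (N, K) matrix")
    if doses.shape[0] != len(cohort):
        raise ValueError("dose matrix rows must match the cohort size")
    K = doses.shape[1]

    if spec.family == "poisson_err" and not spec.modifiers:
        W = build_design(cohort, spec.confounders)
        logpy = np.log(cohort.person_years) if spec.offset_person_years else np.zeros(len(cohort))
        alpha0, null_ll = null_alpha_fit(cohort, spec)

        def run(cols: np.ndarray) -> list[FitResult]:
            return _fit_poisson_err_batched(
                cohort.outcome, W, logpy, doses[:, cols], alpha0, null_ll
            )

        if workers > 1 and K > 1:
            from joblib import Parallel, delayed

            chunks = np.array_split(np.arange(K), min(workers, K))
            parts = Parallel(n_jobs=workers)(delayed(run)(c) for c in chunks)
            results = [r for part in parts for r in part]
        else:
            results = run(np.arange(K))
        # retry any stragglers on the scalar ladder
        for k, r in enumerate(results):
            if not r.converged and np.isfinite(r.loglik):
                results[k] = _fit_generic(spec, doses[:, k], cohort, r.theta_hat)
        return results

    return [fit_model(spec, doses[:, k], cohort) for k in range(K)]
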