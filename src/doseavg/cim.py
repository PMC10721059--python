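"""Corrected-information-matrix (CIM) intervals for the mean-dose ERR fit.

CIM fits the linear-ERR Poisson model once, on the per-individual *mean*
dose ``Z`` (the average of each individual's dose across all retained
realizations), and then widens the Wald interval to account for the spread
of the realizations around ``Z``:

    Var(theta_hat) = I_Z^{-1} + beta^2 I_Z^{-1} M Cov(X|Z) M' I_Z^{-1}

where ``I_Z`` is the observed information of the mean-dose fit,
``Cov(X|Z)`` the empirical N x N covariance of the dose realizations around
their row means, and ``M = Q G`` with

    Q_i = (1, C_i, Z_i / (1 + beta*Z_i))',
    G   = diag(PY_i * exp(a0 + a1'C_i)).

``M`` is minus the sensitivity of the score to the dose vector: a Taylor
expansion of the Poisson ERR score around the true dose gives
``dS/dX_i = -beta * PY_i * exp(a'W_i) * q_i``, so the person-years factor
belongs in ``G`` for the correction to be consistent with the person-years
offset in the likelihood (with PY = 1 the familiar diag(exp(a'W)) form is
recovered).  The correction term is a positive-semidefinite quadratic form,
so the corrected variance can never fall below the naive one, and it
vanishes when ``beta = 0`` or when all realizations coincide.

The method applies to the Poisson ERR family only; it has no published form
for binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from doseavg.risk_models import (
    DEFAULT_POISSON,
    DomainError,
    FitResult,
    ModelSpec,
    build_design,
    fit_model,
)
from doseavg.suma import Cohort, DoseRealizations

__all__ = ["CIMResult", "dose_covariance", "cim_build_M", "cim_interval", "cim_fit"]


class UnsupportedFamilyError(ValueError):
    """CIM is defined for the Poisson ERR family only."""


@dataclass
class CIMResult:
    """Mean-dose slope estimate with naive and corrected Wald intervals."""

    beta_hat: float
    naive_var: float
    corrected_var: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    fit: FitResult | None = None

    @property
    def interval_length(self) -> float:
        return self.ci_high - self.ci_low


def dose_covariance(realizations: DoseRealizations | np.ndarray) -> np.ndarray:
    """Empirical N x N covariance of dose realizations around their row means.

    Entry (i, j) = sum_k (X_ik - Zbar_i)(X_jk - Zbar_j) / (K - 1) over the
    analysis columns.  Symmetric positive semidefinite; requires K >= 2.
    """
    X = (
        realizations.analysis_doses()
        if isinstance(realizations, DoseRealizations)
        else np.asarray(realizations, dtype=float)
    )
    if X.ndim != 2:
        raise ValueError("realizations must be a 2-D (N, K) matrix")
    K = X.shape[1]
    if K < 2:
        raise ValueError(f"need at least 2 realizations for a covariance, got {K}")
    Xc = X - X.mean(axis=1, keepdims=True)
    return (Xc @ Xc.T) / (K - 1)


def cim_build_M(fit: FitResult, cohort: Cohort, Z: np.ndarray,
                spec: ModelSpec = DEFAULT_POISSON) -> np.ndarray:
    """The p x N score-sensitivity matrix M = Q G of the mean-dose fit."""
    if spec.family != "poisson_err":
        raise UnsupportedFamilyError("CIM supports the poisson_err family only")
    Z = np.asarray(Z, dtype=float)
    q = spec.n_alpha
    alpha = fit.theta_hat[:q]
    beta = fit.beta_hat
    r = 1.0 + beta * Z
    if np.any(r <= 0):
        raise DomainError("1 + beta*Z must be positive for every individual")
    W = build_design(cohort, spec.confounders)  # (N, q), intercept first
    Q = np.vstack([W.T, (Z / r)[None, :]])  # (p, N)
    g = np.exp(W @ alpha)
    if spec.offset_person_years:
        g = g * cohort.person_years
    return Q * g[None, :]


def cim_interval(
    fit: FitResult,
    covXZ: np.ndarray,
    cohort: Cohort,
    Z: np.ndarray,
    level: float = 0.95,
    spec: ModelSpec = DEFAULT_POISSON,
) -> CIMResult:
    """Corrected Wald interval for beta from the mean-dose fit.

    corrected_var = [I_Z^{-1}]_bb + beta^2 [I_Z^{-1} M covXZ M' I_Z^{-1}]_bb,
    with the p x p product computed as (p x N)(N x N)(N x p).
    """
    if spec.family != "poisson_err":
        raise UnsupportedFamilyError("CIM supports the poisson_err family only")
    if fit.cov is None or not fit.converged:
        cond = "non-converged fit" if not fit.converged else "singular information matrix"
        raise ValueError(f"cannot build a CIM interval from a {cond}")
    p = fit.n_params
    b = spec.beta_index
    inv_I = fit.cov  # inverse observed information of the mean-dose fit
    M = cim_build_M(fit, cohort, Z, spec)
    MCM = (M @ covXZ) @ M.T  # (p, p) without any intermediate bigger than p x N
    correction = fit.beta_hat**2 * (inv_I @ MCM @ inv_I)
    naive_var = float(inv_I[b, b])
    corrected_var = naive_var + float(correction[b, b])
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(corrected_var)
    return CIMResult(
        beta_hat=fit.beta_hat,
        naive_var=naive_var,
        corrected_var=corrected_var,
        ci_low=fit.beta_hat - half,
        ci_high=fit.beta_hat + half,
        level=level,
        fit=fit,
    )


def cim_fit(
    realizations: DoseRealizations | np.ndarray,
    cohort: Cohort,
    level: float = 0.95,
    spec: ModelSpec = DEFAULT_POISSON,
) -> CIMResult:
    """Convenience wrapper: mean-dose fit + dose covariance + corrected interval."""
    X = (
        realizations.analysis_doses()
        if isinstance(realizations, DoseRealizations)
        else np.asarray(realizations, dtype=float)
    )
    Z = X.mean(axis=1)
    fit = fit_model(spec, Z, cohort)
    covXZ = dose_covariance(X)
    return cim_interval(fit, covXZ, cohort, Z, level=level, spec=spec)
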