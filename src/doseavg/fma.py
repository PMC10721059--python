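"""Frequentist model averaging over dose realizations.

Two-stage procedure.  Stage 1: the same risk model is fit separately to each
of the K dose realizations, giving per-realization estimates
``(beta_k, var_k)`` and AIC values.  Stage 2: each realization receives an
Akaike weight

    FW_k = exp(-0.5 * (AIC_k - min AIC)) / sum_m exp(-0.5 * (AIC_m - min AIC)),

``n_k = FW_k * M`` draws (largest-remainder rounding) are simulated from
``N(beta_k, var_k)``, and the pooled M draws yield the averaged point
estimate (their mean) and a 95% interval (their 2.5th/97.5th empirical
percentiles).  Because draws are allocated proportionally to the weights,
the plain mean of the pooled sample already is the weight-proportional
estimator.

Realizations whose fit did not converge, or whose slope is unidentified
(infinite variance), receive weight zero rather than aborting the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from doseavg.risk_models import FitResult, ModelSpec, fit_realizations
from doseavg.suma import Cohort, DoseRealizations

__all__ = ["FMAResult", "akaike_weights", "allocate_draws", "fma_combine", "fma_fit"]

#: weights below this threshold do not count as "effective" models
EFFECTIVE_WEIGHT = 1e-3


@dataclass
class FMAResult:
    """Averaged slope estimate with its percentile interval and weights."""

    beta_fma: float
    ci_low: float
    ci_high: float
    weights: np.ndarray
    draws_per_model: np.ndarray
    M: int
    effective_models: int
    n_failed_fits: int = 0
    aics: np.ndarray | None = None

    @property
    def interval_length(self) -> float:
        return self.ci_high - self.ci_low


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-0.5*dAIC), normalized; +inf AIC maps to weight 0.

    Shift-invariant and overflow-safe via the min-AIC shift.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.ndim != 1 or aics.size == 0:
        raise ValueError("aics must be a non-empty 1-D vector")
    if np.any(np.isnan(aics)) or np.any(aics == -np.inf):
        raise ValueError("AIC values must be finite or +inf")
    finite = np.isfinite(aics)
    if not finite.any():
        raise ValueError("all AIC values are infinite; no model to weight")
    w = np.zeros_like(aics)
    shifted = aics[finite] - aics[finite].min()
    w[finite] = np.exp(-0.5 * shifted)
    return w / w.sum()


def allocate_draws(weights: np.ndarray, M: int) -> np.ndarray:
    """Largest-remainder rounding of ``weights * M`` to integers summing to M."""
    weights = np.asarray(weights, dtype=float)
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    exact = weights * M
    base = np.floor(exact).astype(int)
    short = M - int(base.sum())
    if short > 0:
        remainder = exact - base
        # ties broken by lower index for determinism
        order = np.lexsort((np.arange(weights.size), -remainder))
        base[order[:short]] += 1
    return base


def fma_combine(fits: list[FitResult], M: int, rng: np.random.Generator) -> FMAResult:
    """Stage 2: pool M normal draws across realizations, weighted by AIC.

    Fits that did not converge or have non-finite slope variance get weight
    zero.  Raises if no realization is informative.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    usable = np.array(
        [f.converged and np.isfinite(f.var_beta) and np.isfinite(f.aic) for f in fits]
    )
    n_failed = int((~usable).sum())
    if not usable.any():
        raise ValueError("no informative realizations: every fit failed or is unidentified")
    aics = np.array([f.aic if u else np.inf for f, u in zip(fits, usable)])
    weights = akaike_weights(aics)
    n_k = allocate_draws(weights, M)

    draws = np.empty(M)
    pos = 0
    for f, n in zip(fits, n_k):
        if n == 0:
            continue
        sd = np.sqrt(f.var_beta)
        draws[pos : pos + n] = rng.normal(f.beta_hat, sd, size=n) if sd > 0 else f.beta_hat
        pos += n
    assert pos == M

    lo, hi = np.percentile(draws, [2.5, 97.5])
    return FMAResult(
        beta_fma=float(draws.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        weights=weights,
        draws_per_model=n_k,
        M=M,
        effective_models=int(np.sum(weights > EFFECTIVE_WEIGHT)),
        n_failed_fits=n_failed,
        aics=aics,
    )


def fma_fit(
    spec: ModelSpec,
    realizations: DoseRealizations | np.ndarray,
    cohort: Cohort,
    M: int = 100_000,
    rng: np.random.Generator | None = None,
    workers: int = 1,
) -> FMAResult:
    """End-to-end FMA: fit every analysis dose column, weight, and combine.

    ``realizations`` may be a DoseRealizations (its designated true column,
    if any, is excluded) or a plain N x K matrix.  The result is independent
    of the execution order of the per-column fits and of ``workers``.
    """
    if rng is None:
        rng = np.random.default_rng()
    doses = (
        realizations.analysis_doses()
        if isinstance(realizations, DoseRealizations)
        else np.asarray(realizations, dtype=float)
    )
    if doses.ndim != 2 or doses.shape[1] < 1:
        raise ValueError("need at least one analysis dose column")
    fits = fit_realizations(spec, doses, cohort, workers=workers)
    return fma_combine(fits, M, rng)
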