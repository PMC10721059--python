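"""Bayesian model averaging with a sampled dose-index parameter.

The dose realization used in the likelihood is itself a parameter: a
categorical index ``gamma`` in {1..K} selects the column of the dose matrix,
and the joint posterior

    p(alpha, beta, gamma | Y, X, C) ∝ L(alpha, beta | Y, X_gamma, C)
                                      p(alpha) p(beta) p(gamma)

is explored with a blocked Metropolis-Hastings sampler: random-walk
proposals for each regression parameter and an independent uniform proposal
over {1..K} for ``gamma``.  A Dirichlet(1,..,1) hyperprior on the
realization probabilities marginalizes analytically to a uniform
``p(gamma) = 1/K``, so the simplex is never sampled.  The uniform global
``gamma`` proposal lets the chain jump between well-separated posterior
modes that a local move would get trapped in.

Priors are weakly informative: N(0, 1000) for the baseline parameters and,
for the slope, either a truncated-at-zero N(0, 1000) (the default — it
encodes the non-negativity constraint of the linear excess term) or an
exponential.  Under either choice every posterior slope draw is >= 0.

Outputs: pooled post-burn-in slope draws, posterior mean, the 95% highest
posterior density (HPD) interval, and per-realization Bayesian weights
``BW_k`` — the relative selection frequency of each dose column in the
chain, a goodness-of-fit measure directly comparable to the FMA weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from doseavg.risk_models import ModelSpec, build_design, null_alpha_fit
from doseavg.suma import Cohort, DoseRealizations

__all__ = [
    "BmaConfig",
    "BMAResult",
    "log_posterior",
    "mh_sample",
    "bayesian_weights",
    "hpd_interval",
]


@dataclass(frozen=True)
class BmaConfig:
    """Sampler settings: chain lengths, priors and proposal scales."""

    n_iter: int = 50_000
    burn_in: int = 20_000
    thin: int = 5
    n_chains: int = 4
    prior_alpha_sd: float = math.sqrt(1000.0)
    beta_prior: str = "truncated_normal"  # or "exponential"
    beta_prior_sd: float = math.sqrt(1000.0)
    beta_prior_rate: float = 1.0
    proposal_sds: tuple[float, ...] | None = None
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.beta_prior not in ("truncated_normal", "exponential"):
            raise ValueError(f"unknown beta_prior {self.beta_prior!r}")
        if self.proposal_sds is not None and any(s <= 0 for s in self.proposal_sds):
            raise ValueError("proposal scales must be positive")


@dataclass
class BMAResult:
    """Pooled posterior draws, HPD interval and realization weights."""

    beta_samples: np.ndarray
    beta_hat: float
    hpd_low: float
    hpd_high: float
    bw: np.ndarray
    acceptance_rates: dict[str, float]
    gamma_trace: np.ndarray
    theta_samples: np.ndarray | None = None


def _log_prior(theta: np.ndarray, spec: ModelSpec, config: BmaConfig) -> float:
    q = spec.n_alpha
    beta = theta[q]
    others = np.concatenate([theta[:q], theta[q + 1 :]])
    lp = float(
        np.sum(-0.5 * (others / config.prior_alpha_sd) ** 2)
        - others.size * math.log(config.prior_alpha_sd * math.sqrt(2 * math.pi))
    )
    if config.beta_prior == "truncated_normal":
        if beta < 0:
            return -np.inf
        lp += (
            -0.5 * (beta / config.beta_prior_sd) ** 2
            - math.log(config.beta_prior_sd * math.sqrt(2 * math.pi))
            + math.log(2.0)  # truncation at zero
        )
    else:
        if beta < 0:
            return -np.inf
        lp += math.log(config.beta_prior_rate) - config.beta_prior_rate * beta
    return lp


def _make_loglik(spec: ModelSpec, doses: np.ndarray, cohort: Cohort):
    """Closure evaluating the family log-likelihood at (theta, dose column k).

    Design matrices and outcome constants are precomputed once; gamma moves
    revisit columns of the shared dose matrix by index.
    """
    W = build_design(cohort, spec.confounders)
    Mmat = build_design(cohort, spec.modifiers, intercept=False)
    Y = cohort.outcome
    q = spec.n_alpha
    if spec.family == "poisson_err":
        logpy = np.log(cohort.person_years) if spec.offset_person_years else np.zeros(len(cohort))
        const = float(np.sum(gammaln(Y + 1.0)))

        def ll(theta: np.ndarray, k: int) -> float:
            alpha, beta, eta = theta[:q], theta[q], theta[q + 1 :]
            mod = np.exp(Mmat @ eta) if eta.size else 1.0
            r = 1.0 + beta * doses[:, k] * mod
            if np.any(r <= 0):
                return -np.inf
            lin = logpy + W @ alpha
            return float(np.sum(Y * (lin + np.log(r))) - np.sum(np.exp(lin) * r) - const)

    else:

        def ll(theta: np.ndarray, k: int) -> float:
            alpha, beta, eta = theta[:q], theta[q], theta[q + 1 :]
            mod = np.exp(Mmat @ eta) if eta.size else 1.0
            r = 1.0 + beta * doses[:, k] * mod
            if np.any(r <= 0):
                return -np.inf
            log_odds = W @ alpha + np.log(r)
            return float(np.sum(Y * log_odds - np.logaddexp(0.0, log_odds)))

    return ll


def log_posterior(
    theta: np.ndarray,
    gamma_index: int,
    realizations: DoseRealizations | np.ndarray,
    cohort: Cohort,
    spec: ModelSpec,
    config: BmaConfig,
) -> float:
    """Unnormalized log posterior at (theta, gamma); -inf outside the support."""
    doses = (
        realizations.analysis_doses()
        if isinstance(realizations, DoseRealizations)
        else np.asarray(realizations, dtype=float)
    )
    K = doses.shape[1]
    if not 0 <= gamma_index < K:
        raise ValueError(f"gamma_index {gamma_index} out of range for K={K}")
    theta = np.asarray(theta, dtype=float)
    lp = _log_prior(theta, spec, config)
    if not np.isfinite(lp):
        return -np.inf
    ll = _make_loglik(spec, doses, cohort)(theta, gamma_index)
    return lp + ll - math.log(K)  # uniform p(gamma) = 1/K


def _run_chain(
    ll, spec: ModelSpec, config: BmaConfig, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    p = spec.n_params
    q = spec.n_alpha
    theta = np.zeros(p)
    theta[q] = 0.01  # strictly inside the slope prior support
    gamma = int(rng.integers(K))
    scales = np.array(config.proposal_sds) if config.proposal_sds else np.full(p, 0.1)
    scales = scales.astype(float).copy()
    lp = _log_prior(theta, spec, config) + ll(theta, gamma)

    n_keep = (config.n_iter - config.burn_in + config.thin - 1) // config.thin
    thetas = np.empty((n_keep, p))
    gammas = np.empty(n_keep, dtype=int)
    acc = np.zeros(p + 1)
    tot = np.zeros(p + 1)
    acc_win = np.zeros(p)
    tot_win = np.zeros(p)
    kept = 0

    for it in range(config.n_iter):
        for j in range(p):
            prop = theta.copy()
            prop[j] += rng.normal(0.0, scales[j])
            lp_prop = _log_prior(prop, spec, config)
            if np.isfinite(lp_prop):
                lp_prop += ll(prop, gamma)
            tot[j] += 1
            tot_win[j] += 1
            if np.isfinite(lp_prop) and math.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                acc[j] += 1
                acc_win[j] += 1
        # independent uniform proposal for the dose index (symmetric)
        gnew = int(rng.integers(K))
        tot[p] += 1
        if gnew != gamma:
            lp_new = _log_prior(theta, spec, config) + ll(theta, gnew)
            if np.isfinite(lp_new) and math.log(rng.random()) < lp_new - lp:
                gamma, lp = gnew, lp_new
                acc[p] += 1
        else:
            acc[p] += 1

        if config.adapt and it < config.burn_in and (it + 1) % 200 == 0:
            rate = np.divide(acc_win, np.maximum(tot_win, 1))
            scales[rate > 0.45] *= 1.25
            scales[rate < 0.20] /= 1.25
            acc_win[:] = 0
            tot_win[:] = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            thetas[kept] = theta
            gammas[kept] = gamma
            kept += 1

    return thetas[:kept], gammas[:kept], acc, tot


def mh_sample(
    realizations: DoseRealizations | np.ndarray,
    cohort: Cohort,
    spec: ModelSpec,
    config: BmaConfig,
    rng: np.random.Generator,
) -> BMAResult:
    """Blocked Metropolis-Hastings over (theta, gamma); pooled multi-chain draws."""
    doses = (
        realizations.analysis_doses()
        if isinstance(realizations, DoseRealizations)
        else np.asarray(realizations, dtype=float)
    )
    if doses.ndim != 2 or doses.shape[1] < 1:
        raise ValueError("need at least one analysis dose column")
    K = doses.shape[1]
    ll = _make_loglik(spec, doses, cohort)

    seeds = rng.spawn(config.n_chains)
    all_theta, all_gamma = [], []
    acc_total = np.zeros(spec.n_params + 1)
    tot_total = np.zeros(spec.n_params + 1)
    for chain_rng in seeds:
        thetas, gammas, acc, tot = _run_chain(ll, spec, config, K, chain_rng)
        all_theta.append(thetas)
        all_gamma.append(gammas)
        acc_total += acc
        tot_total += tot

    thetas = np.vstack(all_theta)
    gammas = np.concatenate(all_gamma)
    q = spec.n_alpha
    beta_samples = thetas[:, q]

    rates = acc_total / np.maximum(tot_total, 1)
    names = [f"alpha{i}" for i in range(q)] + ["beta"] + [
        f"eta{i}" for i in range(len(spec.modifiers))
    ] + ["gamma"]
    acceptance = dict(zip(names, rates))
    low_blocks = [n for n, r in acceptance.items() if n != "gamma" and r < 0.01]
    if low_blocks:
        warnings.warn(
            f"near-zero MH acceptance for block(s) {low_blocks}; "
            "reduce the corresponding proposal scales (BmaConfig.proposal_sds)",
            RuntimeWarning,
            stacklevel=2,
        )

    lo, hi = hpd_interval(beta_samples) if beta_samples.size >= 100 else (
        float(beta_samples.min()), float(beta_samples.max())
    )
    return BMAResult(
        beta_samples=beta_samples,
        beta_hat=float(beta_samples.mean()),
        hpd_low=lo,
        hpd_high=hi,
        bw=bayesian_weights(gammas, K),
        acceptance_rates=acceptance,
        gamma_trace=gammas,
        theta_samples=thetas,
    )


def bayesian_weights(gamma_trace: np.ndarray, K: int) -> np.ndarray:
    """BW_k: relative selection frequency of each dose column in the chain."""
    gamma_trace = np.asarray(gamma_trace)
    if gamma_trace.size == 0:
        raise ValueError("empty gamma trace")
    counts = np.bincount(gamma_trace.astype(int), minlength=K)
    return counts / counts.sum()


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(level * n) sorted samples."""
    samples = np.sort(np.asarray(samples, dtype=float))
    n = samples.size
    if n < 100:
        raise ValueError(f"need at least 100 samples for an HPD interval, got {n}")
    m = int(math.ceil(level * n))
    widths = samples[m - 1 :] - samples[: n - m + 1]
    i = int(np.argmin(widths))
    return float(samples[i]), float(samples[i + m - 1])
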