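"""SUMA dose-uncertainty simulator and cohort/outcome generators.

The SUMA model ("Shared and Unshared, Multiplicative and Additive") is a
deliberately simple stand-in for a full Monte Carlo dosimetry system.  Given
a baseline vector of per-individual mean doses ``Z`` (Gy), each realization
``k`` of the cohort dose vector is

    X[i, k] = eps_SM[k] * eps_UM[i, k] * Z[i] + eps_SA[k] + eps_UA[i, k]

where the multiplicative errors are lognormal with mean exactly 1 (so the
ensemble of realizations is centered on ``Z`` — a Berkson-type structure)
and the additive errors are normal with mean 0.  "Shared" errors take a
single value per realization, common to every cohort member; "unshared"
errors are drawn independently per individual.  Shared errors model the
systematic, lack-of-knowledge component of dose reconstruction that
dominates uncertainty in fallout and occupational dosimetry.

Scenario presets 1-4 carry the log-scale variances used in the comparison
study; their geometric standard deviations are exp(sqrt(var)):

====  ========  ========  =======  =======
name  shared    unshared  GSD(SM)  GSD(UM)
====  ========  ========  =======  =======
1     0.318     0.223     1.8      1.6
2     0.632     0.223     2.2      1.6
3     0.632     0.446     2.2      2.0
4     0.954     0.223     2.7      1.6
====  ========  ========  =======  =======

The variances are interpreted as variances of ``ln(eps)`` — this is the only
reading under which the tabulated GSDs are reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SumaScenario",
    "DoseRealizations",
    "Cohort",
    "SCENARIOS",
    "lognormal_unit_mean_params",
    "sample_mean_doses",
    "generate_realizations",
    "generate_cohort",
    "generate_poisson_outcomes",
    "generate_binary_outcomes",
    "read_cohort",
    "write_cohort",
    "read_realizations",
    "write_realizations",
]


@dataclass(frozen=True)
class SumaScenario:
    """Error variances for one SUMA configuration.

    Multiplicative variances are on the log scale (variance of ``ln eps``);
    additive variances are in Gy^2.  All must be non-negative.
    """

    var_shared_mult: float
    var_unshared_mult: float
    var_shared_add: float = 0.0
    var_unshared_add: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "var_shared_mult",
            "var_unshared_mult",
            "var_shared_add",
            "var_unshared_add",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative number, got {v!r}")

    @property
    def gsd_shared(self) -> float:
        """Geometric standard deviation of the shared multiplicative error."""
        return float(np.exp(np.sqrt(self.var_shared_mult)))

    @property
    def gsd_unshared(self) -> float:
        """Geometric standard deviation of the unshared multiplicative error."""
        return float(np.exp(np.sqrt(self.var_unshared_mult)))


#: Preset scenarios, ordered by increasing shared-to-unshared variance ratio.
SCENARIOS: dict[str, SumaScenario] = {
    "scenario1": SumaScenario(0.318, 0.223),
    "scenario2": SumaScenario(0.632, 0.223),
    "scenario3": SumaScenario(0.632, 0.446),
    "scenario4": SumaScenario(0.954, 0.223),
}


def resolve_scenario(scenario: SumaScenario | str) -> SumaScenario:
    """Accept either a preset name (``'scenario1'``..``'scenario4'``) or a scenario."""
    if isinstance(scenario, SumaScenario):
        return scenario
    try:
        return SCENARIOS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; presets are {sorted(SCENARIOS)}"
        ) from None


@dataclass
class DoseRealizations:
    """N x K matrix of reconstructed cohort dose vectors (Gy).

    ``true_index`` (0-based column) optionally marks the realization used to
    generate outcomes; :meth:`analysis_doses` drops it, leaving the K-1
    columns an analyst would actually see.
    """

    doses: np.ndarray
    true_index: int | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.ndim != 2:
            raise ValueError("doses must be a 2-D (N, K) array")
        if self.true_index is not None and not (0 <= self.true_index < self.n_realizations):
            raise ValueError(
                f"true_index {self.true_index} out of range for K={self.n_realizations}"
            )

    @property
    def n_individuals(self) -> int:
        return self.doses.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.doses.shape[1]

    @property
    def mean_dose(self) -> np.ndarray:
        """Per-individual arithmetic mean dose across all K realizations."""
        return self.doses.mean(axis=1)

    def true_dose(self) -> np.ndarray:
        if self.true_index is None:
            raise ValueError("no realization is designated as true")
        return self.doses[:, self.true_index]

    def analysis_doses(self) -> np.ndarray:
        """Dose columns available for analysis (true column excluded, copied)."""
        if self.true_index is None:
            return self.doses.copy()
        keep = np.ones(self.n_realizations, dtype=bool)
        keep[self.true_index] = False
        return self.doses[:, keep].copy()

    def with_true_index(self, index: int) -> "DoseRealizations":
        return replace(self, true_index=int(index))


@dataclass
class Cohort:
    """Per-individual covariates, follow-up and (optionally) outcomes.

    One row is one individual, treated as its own stratum in the Poisson
    model.  ``gender`` is coded 0/1; ``age`` in years; ``person_years`` > 0.
    """

    age: np.ndarray
    gender: np.ndarray
    person_years: np.ndarray
    outcome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        n = self.age.shape[0]
        if self.gender.shape[0] != n or self.person_years.shape[0] != n:
            raise ValueError("age, gender and person_years must have equal length")
        if np.any(self.person_years <= 0):
            raise ValueError("person_years must be strictly positive")
        if self.outcome is not None:
            self.outcome = np.asarray(self.outcome, dtype=float)
            if self.outcome.shape[0] != n:
                raise ValueError("outcome length must match the cohort size")

    def __len__(self) -> int:
        return self.age.shape[0]

    def with_outcome(self, outcome: np.ndarray) -> "Cohort":
        return Cohort(self.age, self.gender, self.person_years, np.asarray(outcome))

    def to_frame(self) -> pd.DataFrame:
        data = {
            "id": np.arange(1, len(self) + 1),
            "age": self.age,
            "gender": self.gender.astype(int),
            "person_years": self.person_years,
        }
        if self.outcome is not None:
            data["outcome"] = self.outcome
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        outcome = df["outcome"].to_numpy() if "outcome" in df.columns else None
        return cls(
            age=df["age"].to_numpy(),
            gender=df["gender"].to_numpy(),
            person_years=df["person_years"].to_numpy(),
            outcome=outcome,
        )


def lognormal_unit_mean_params(var_log: float) -> tuple[float, float]:
    """Parameters (mu, sigma) of a lognormal with mean 1 and log-variance ``var_log``.

    sigma = sqrt(var_log) and mu = -var_log/2, so that
    E[exp(mu + sigma*N(0,1))] = exp(mu + sigma^2/2) = 1 exactly.  The
    geometric standard deviation is exp(sigma).
    """
    if not np.isfinite(var_log) or var_log < 0:
        raise ValueError(f"var_log must be a finite non-negative number, got {var_log!r}")
    sigma = float(np.sqrt(var_log))
    return -var_log / 2.0, sigma


def sample_mean_doses(
    n: int, median: float, gsd: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a baseline mean-dose vector Z from a lognormal (median, GSD).

    This is package plumbing: it supplies the per-individual mean doses the
    SUMA error model perturbs.  ``gsd = 1`` collapses to a constant dose.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not median > 0:
        raise ValueError(f"median must be positive, got {median!r}")
    if gsd < 1:
        raise ValueError(f"gsd must be >= 1, got {gsd!r}")
    return rng.lognormal(mean=np.log(median), sigma=np.log(gsd), size=n)


def generate_realizations(
    Z: np.ndarray,
    scenario: SumaScenario | str,
    K: int,
    rng: np.random.Generator,
) -> DoseRealizations:
    """Generate K SUMA realizations of the cohort dose vector.

    Per realization k, one shared multiplicative draw eps_SM[k] (and, when the
    additive variances are positive, one shared additive draw) applies to the
    whole column, while unshared draws are independent per individual.
    """
    scenario = resolve_scenario(scenario)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 1 or Z.size == 0:
        raise ValueError("Z must be a non-empty 1-D dose vector")
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    n = Z.size

    mu_sm, sd_sm = lognormal_unit_mean_params(scenario.var_shared_mult)
    mu_um, sd_um = lognormal_unit_mean_params(scenario.var_unshared_mult)
    eps_sm = rng.lognormal(mu_sm, sd_sm, size=K) if sd_sm > 0 else np.ones(K)
    eps_um = rng.lognormal(mu_um, sd_um, size=(n, K)) if sd_um > 0 else np.ones((n, K))

    doses = eps_sm[None, :] * eps_um * Z[:, None]
    if scenario.var_shared_add > 0:
        doses = doses + rng.normal(0.0, np.sqrt(scenario.var_shared_add), size=K)[None, :]
    if scenario.var_unshared_add > 0:
        doses = doses + rng.normal(0.0, np.sqrt(scenario.var_unshared_add), size=(n, K))
    return DoseRealizations(doses=doses)


def generate_cohort(n: int, rng: np.random.Generator) -> Cohort:
    """Simulate cohort covariates: age ~ U(20, 50), gender ~ Bern(0.5), PY ~ Exp(rate 0.5)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    age = rng.uniform(20.0, 50.0, size=n)
    gender = rng.integers(0, 2, size=n).astype(float)
    person_years = rng.exponential(scale=2.0, size=n)  # rate 0.5 -> scale 2
    # an exactly-zero exponential draw would violate PY > 0; nudge it
    person_years = np.maximum(person_years, np.finfo(float).tiny)
    return Cohort(age=age, gender=gender, person_years=person_years)


def poisson_rates(cohort: Cohort, dose: np.ndarray, beta: float) -> np.ndarray:
    """Per-stratum incidence rate lambda_i of the simulation's generating model.

    lambda_i = exp(1 + 1.5*gender_i + 2*log(age_i/40)) * (1 + beta*dose_i).
    """
    dose = np.asarray(dose, dtype=float)
    err = 1.0 + beta * dose
    if np.any(err <= 0):
        raise ValueError("1 + beta*dose must be positive for every individual")
    baseline = np.exp(1.0 + 1.5 * cohort.gender + 2.0 * np.log(cohort.age / 40.0))
    return baseline * err


def generate_poisson_outcomes(
    cohort: Cohort, true_dose: np.ndarray, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-stratum counts y_i ~ Poisson(lambda_i * PY_i) at the true dose."""
    lam = poisson_rates(cohort, true_dose, beta)
    return rng.poisson(lam * cohort.person_years).astype(float)


def generate_binary_outcomes(
    cohort: Cohort,
    true_dose: np.ndarray,
    theta: tuple[float, float, float, float],
    rng: np.random.Generator,
    confounder: np.ndarray | None = None,
    modifier: np.ndarray | None = None,
) -> np.ndarray:
    """Draw binary outcomes from the linear EOR logistic model.

    odds_i = exp(a0 + a1*C_i) * (1 + beta*D_i*exp(eta*M_i)), Y_i ~ Bern(p_i)
    with p_i = odds_i / (1 + odds_i).  The confounder defaults to gender and
    the effect modifier to zero.
    """
    a0, a1, beta, eta = theta
    dose = np.asarray(true_dose, dtype=float)
    C = cohort.gender if confounder is None else np.asarray(confounder, dtype=float)
    M = np.zeros(len(cohort)) if modifier is None else np.asarray(modifier, dtype=float)
    excess = 1.0 + beta * dose * np.exp(eta * M)
    if np.any(excess <= 0):
        raise ValueError("odds must be positive: 1 + beta*D*exp(eta*M) <= 0 for some i")
    odds = np.exp(a0 + a1 * C) * excess
    p = odds / (1.0 + odds)
    return (rng.random(len(cohort)) < p).astype(float)


# ---------------------------------------------------------------------------
# Delimited-text interchange


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    return Cohort.from_frame(pd.read_csv(path))


def write_realizations(realizations: DoseRealizations, path, sep: str = "\t") -> None:
    """Write the dose matrix as delimited text: id column + r0001..rK columns."""
    K = realizations.n_realizations
    width = max(4, len(str(K)))
    cols = [f"r{k + 1:0{width}d}" for k in range(K)]
    df = pd.DataFrame(realizations.doses, columns=cols)
    df.insert(0, "id", np.arange(1, realizations.n_individuals + 1))
    df.to_csv(path, sep=sep, index=False)


def read_realizations(path, sep: str = "\t") -> DoseRealizations:
    df = pd.read_csv(path, sep=sep)
    if "id" in df.columns:
        df = df.drop(columns=["id"])
    return DoseRealizations(doses=df.to_numpy(dtype=float))
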