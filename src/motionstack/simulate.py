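"""Synthetic cohort generator with a single-latent-factor shared-variance structure.

The generator emulates the statistical skeleton of a naturalistic psychiatric
cohort study of head motion: n subjects, a right-skewed motion outcome
modelled on the log scale, 15 physical (anthropometric/demographic) and 105
psychological (self-report) predictors with sparse MCAR missingness, and a
latent structure in which psychological predictors relate to motion *only*
through their correlation with the physical block.

Mechanism (one latent factor ``L ~ N(0,1)`` per subject):

- continuous physical variables:  ``X_j = a_j * L + N(0,1)`` with loadings
  ``a_j`` drawn once per cohort; two *dominant* variables (weight/BMI-like)
  draw from a high range and the remainder from a lower one, reproducing
  the clear importance hierarchy of real anthropometric batteries (a pair
  of strong correlates standing out from weaker demographics);
- one binary sex-like physical variable: Bernoulli with logit linear in L,
  to exercise mixed-type handling;
- "drug-like" psychological variables: a shared substance-use factor
  ``D = rho*L + sqrt(1-rho^2)*eps`` with per-variable loading ``b``
  (``X = b*D + sqrt(1-b^2)*noise``, unit variance), so drug-like variables
  are mutually correlated (pairwise ``b^2``, as real nicotine/alcohol
  instruments are) and each correlates ``psi = b*rho`` with L;
- remaining psychological variables: independent N(0,1) noise;
- outcome (log-motion scale): ``y = mu + c*L + N(0, noise_sd^2)``.

The outcome loading ``c`` is calibrated **analytically** so that the
population R² of the best linear function of the physical block equals the
requested ``r2_physical``:  with ``g = Cov(X_phys, L)`` and
``Sigma = Cov(X_phys)``, the latent projection variance is
``rho² = gᵀ Sigma⁻¹ g`` and ``R² = c² rho² / (c² + noise_sd²)``, hence
``c² = R² noise_sd² / (rho² − R²)``.  The Bernoulli variable's moments enter
``g`` and ``Sigma`` through Gauss–Hermite quadrature, so the calibration is
exact (no simulation).  Because the psychological signal rides on the same
latent factor, residualizing psychological variables on the physical block
removes (in population) all of their predictive value — the generator's
ground-truth version of the shared-variance phenomenon.

MCAR missingness is injected per predictor with *exact* counts
``floor(rate_j * n)``, ``rate_j ~ U(0, missing_rate_max)``, so the observed
missing fraction never exceeds the cap (at the defaults, at most
``floor(0.0625 * 464) = 29`` missing values per predictor).

A companion drift-plus-spike model produces realistic six-parameter motion
time series: each parameter is a random walk with Gaussian increments plus
sparse transient Laplace spikes arriving at a Poisson rate.  For a pure
random walk with increment SD sigma in each of the six parameters, the
expected per-TR ENORM is ``sigma * E[chi_6]`` with
``E[chi_6] = sqrt(2) * Gamma(7/2) / Gamma(3) ≈ 2.3500``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from .motion import MotionParams
from .preprocess import FeatureTable

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "ConfigurationError",
    "E_CHI6",
    "generate_cohort",
    "generate_motion_series",
    "generate_motion_cohort",
]

#: E[chi_6]: mean L2 norm of a standard 6-d Gaussian vector.
E_CHI6 = float(math.sqrt(2.0) * math.exp(gammaln(3.5) - gammaln(3.0)))


class ConfigurationError(ValueError):
    """Raised when a cohort specification cannot be calibrated."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the emulated study: 464 subjects, 15 physical and 105
    psychological predictors, physical-block population R² of 0.11, at most
    6.25% missingness per predictor.  ``psych_loading`` is the correlation
    of each drug-like psychological variable with the physical latent
    factor and ``drug_cohesion`` the loading of those variables on their
    shared substance-use factor; the defaults (0.46, 0.7) imply a
    psychological-block population R² of ≈ 0.05.
    """

    n_subjects: int = 464
    n_physical: int = 15
    n_psych: int = 105
    r2_physical: float = 0.11
    psych_loading: float = 0.46
    drug_cohesion: float = 0.7
    n_drug_like: int = 20
    missing_rate_max: float = 0.0625
    noise_sd: float = 0.5
    outcome_mean: float = -2.5
    loading_range: tuple[float, float] = (0.3, 0.95)
    dominant_range: tuple[float, float] = (1.25, 1.45)
    n_dominant: int = 2
    sex_slope: float = 0.3
    sex_prevalence: float = 0.375
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.n_physical < 1 or self.n_psych < 1:
            raise ConfigurationError("need at least one variable per block")
        if not 0.0 <= self.r2_physical < 1.0:
            raise ConfigurationError("r2_physical must lie in [0, 1)")
        if not 0.0 <= self.psych_loading < 1.0:
            raise ConfigurationError("psych_loading must lie in [0, 1)")
        if not 0.0 < self.drug_cohesion < 1.0:
            raise ConfigurationError("drug_cohesion must lie in (0, 1)")
        if self.psych_loading > self.drug_cohesion:
            raise ConfigurationError(
                "psych_loading cannot exceed drug_cohesion (the implied "
                "drug-factor correlation with the latent factor would exceed 1)"
            )
        if not 0 <= self.n_drug_like <= self.n_psych:
            raise ConfigurationError("n_drug_like must not exceed n_psych")
        if not 0.0 <= self.missing_rate_max <= 1.0:
            raise ConfigurationError("missing_rate_max must lie in [0, 1]")
        if self.n_dominant < 0:
            raise ConfigurationError("n_dominant must be non-negative")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass(frozen=True)
class CohortTruth:
    """Generating parameters recorded for recovery tests."""

    loadings: np.ndarray  # continuous physical loadings a_j
    variable_loadings: dict  # name -> latent loading (incl. binary effective)
    outcome_loading: float  # c
    rho2_physical: float  # Var of the linear projection of L on X_phys
    rho2_psych: float
    r2_physical: float  # population R², physical block
    r2_psych: float  # population R², psychological block
    r2_combined: float  # population R², physical + psychological
    r2_residualized_psych: float  # r2_combined − r2_physical (≈ 0)
    outcome_sd: float


@dataclass
class SyntheticCohort:
    features: FeatureTable
    outcome: np.ndarray  # log-motion scale, length n_subjects
    truth: CohortTruth
    spec: CohortSpec
    motion: list[MotionParams] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.outcome)


# ---------------------------------------------------------------------------
# analytic calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def _gauss_expect(fn) -> float:
    """E[fn(Z)] for Z ~ N(0,1) via Gauss–Hermite quadrature."""
    z = math.sqrt(2.0) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * fn(z)) / math.sqrt(math.pi))


def _physical_projection_variance(
    loadings: np.ndarray, sex_slope: float, sex_intercept: float
) -> float:
    """rho² = Var of the best linear predictor of L from the physical block.

    Continuous block: X_j = a_j L + N(0,1).  Binary variable S with
    P(S=1|L) = expit(sex_slope*L + sex_intercept).  Returns gᵀ Sigma⁻¹ g for
    g = Cov(X, L), Sigma = Cov(X), with the binary moments obtained by
    Gauss–Hermite quadrature.
    """
    a = np.asarray(loadings, dtype=float)
    p_fn = lambda z: expit(sex_slope * z + sex_intercept)
    m1 = _gauss_expect(p_fn)  # E[S]
    mL = _gauss_expect(lambda z: z * p_fn(z))  # Cov(S, L)
    k = a.size
    g = np.concatenate([a, [mL]])
    sigma = np.empty((k + 1, k + 1))
    sigma[:k, :k] = np.outer(a, a) + np.eye(k)
    sigma[:k, k] = sigma[k, :k] = a * mL
    sigma[k, k] = m1 - m1 * m1
    rho2 = float(g @ np.linalg.solve(sigma, g))
    return rho2


def _psych_projection_variance(psi: float, b: float, n_drug: int) -> float:
    # equicorrelated drug block: pairwise correlation b², each variable
    # correlating psi with L ⇒ rho² = n psi² / (1 − b² + n b²)
    if n_drug == 0 or psi == 0.0:
        return 0.0
    return n_drug * psi**2 / (1.0 - b * b + n_drug * b * b)


def _combined_projection_variance(
    loadings: np.ndarray,
    sex_slope: float,
    sex_intercept: float,
    psi: float,
    b: float,
    n_drug: int,
) -> float:
    """rho² of the linear projection of L on physical + drug-like variables."""
    a = np.asarray(loadings, dtype=float)
    p_fn = lambda z: expit(sex_slope * z + sex_intercept)
    m1 = _gauss_expect(p_fn)
    mL = _gauss_expect(lambda z: z * p_fn(z))
    k = a.size
    dim = k + 1 + n_drug
    g = np.concatenate([a, [mL], np.full(n_drug, psi)])
    sigma = np.empty((dim, dim))
    sigma[:k, :k] = np.outer(a, a) + np.eye(k)
    sigma[:k, k] = sigma[k, :k] = a * mL
    sigma[k, k] = m1 - m1 * m1
    sigma[:k, k + 1 :] = np.outer(a, np.full(n_drug, psi))
    sigma[k + 1 :, :k] = sigma[:k, k + 1 :].T
    sigma[k, k + 1 :] = sigma[k + 1 :, k] = psi * mL
    sigma[k + 1 :, k + 1 :] = (1.0 - b * b) * np.eye(n_drug) + b * b
    return float(g @ np.linalg.solve(sigma, g))


def _calibrate_outcome_loading(r2: float, rho2: float, noise_sd: float) -> float:
    if r2 == 0.0:
        return 0.0
    if rho2 <= r2:
        raise ConfigurationError(
            f"requested r2_physical={r2} is not attainable: the physical block "
            f"carries at most rho2={rho2:.4f} of latent variance"
        )
    return math.sqrt(r2 * noise_sd**2 / (rho2 - r2))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _variable_names(spec: CohortSpec) -> tuple[list[str], list[str], list[str]]:
    phys = ["sex"] + [f"phys_{i:02d}" for i in range(1, spec.n_physical)]
    drug = [f"psy_drug_{i:02d}" for i in range(1, spec.n_drug_like + 1)]
    nondrug = [
        f"psy_gen_{i:02d}" for i in range(1, spec.n_psych - spec.n_drug_like + 1)
    ]
    return phys, drug, nondrug


def generate_cohort(spec: CohortSpec, with_motion: bool = False) -> SyntheticCohort:
    """Draw one synthetic cohort under ``spec``; fully deterministic under its seed.

    With ``with_motion=True`` a drift-plus-spike motion series is attached per
    subject, scaled so its expected mean ENORM is exp(outcome) — approximate,
    because spikes perturb the random-walk calibration slightly; the exact
    modelling outcome remains ``cohort.outcome``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    phys_names, drug_names, nondrug_names = _variable_names(spec)
    n_cont = spec.n_physical - 1  # one slot is the binary sex-like variable

    n_dom = min(spec.n_dominant, n_cont)
    loadings = np.concatenate([
        rng.uniform(*spec.dominant_range, size=n_dom),
        rng.uniform(*spec.loading_range, size=n_cont - n_dom),
    ])
    sex_intercept = float(np.log(spec.sex_prevalence / (1.0 - spec.sex_prevalence)))

    psi, b = spec.psych_loading, spec.drug_cohesion
    rho2_phys = _physical_projection_variance(
        loadings, spec.sex_slope, sex_intercept
    )
    rho2_psych = _psych_projection_variance(psi, b, spec.n_drug_like)
    rho2_comb = _combined_projection_variance(
        loadings, spec.sex_slope, sex_intercept, psi, b, spec.n_drug_like
    )
    c = _calibrate_outcome_loading(spec.r2_physical, rho2_phys, spec.noise_sd)
    var_y = c * c + spec.noise_sd**2
    r2_psych = c * c * rho2_psych / var_y if var_y > 0 else 0.0
    r2_comb = c * c * rho2_comb / var_y if var_y > 0 else 0.0

    # Exact-moment draws for the outcome equation: the latent factor is
    # standardized to sample mean 0 / variance 1 and the outcome noise is
    # orthogonalized against it, so each cohort's realized signal matches
    # the calibrated population R² rather than fluctuating around it
    # (fixed-score simulation; see the methods note).
    latent = rng.standard_normal(n)
    latent = (latent - latent.mean()) / latent.std()
    sex = (rng.uniform(size=n) < expit(spec.sex_slope * latent + sex_intercept))
    x_cont = latent[:, None] * loadings[None, :] + rng.standard_normal((n, n_cont))
    rho = psi / b  # drug-factor correlation with the latent factor
    drug_factor = rho * latent + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    x_drug = b * drug_factor[:, None] + math.sqrt(1.0 - b * b) * rng.standard_normal(
        (n, spec.n_drug_like)
    )
    x_nondrug = rng.standard_normal((n, len(nondrug_names)))
    noise = rng.standard_normal(n)
    noise = noise - latent * (noise @ latent) / n  # exact orthogonality
    noise = (noise - noise.mean()) / noise.std()
    outcome = spec.outcome_mean + c * latent + spec.noise_sd * noise

    import pandas as pd

    subjects = [f"sub-{i:04d}" for i in range(1, n + 1)]
    values = pd.DataFrame(
        np.column_stack([sex.astype(float), x_cont, x_drug, x_nondrug]),
        index=subjects,
        columns=phys_names + drug_names + nondrug_names,
    )

    # MCAR missingness: exact counts, never exceeding the cap.
    for col in values.columns:
        rate = rng.uniform(0.0, spec.missing_rate_max)
        n_miss = int(math.floor(rate * n))
        if n_miss > 0:
            idx = rng.choice(n, size=n_miss, replace=False)
            values.iloc[idx, values.columns.get_loc(col)] = np.nan

    block = {v: "physical" for v in phys_names}
    block.update({v: "psychological" for v in drug_names + nondrug_names})
    subblock = {v: "drug" for v in drug_names}
    subblock.update({v: "nondrug" for v in nondrug_names})
    features = FeatureTable(
        values=values,
        block=block,
        subblock=subblock,
        max_missing_fraction=max(spec.missing_rate_max, 0.0625),
    )

    var_loadings = {"sex": float("nan")}  # binary: no linear loading recorded
    var_loadings.update(dict(zip(phys_names[1:], loadings)))
    var_loadings.update({v: psi for v in drug_names})
    var_loadings.update({v: 0.0 for v in nondrug_names})

    truth = CohortTruth(
        loadings=loadings,
        variable_loadings=var_loadings,
        outcome_loading=c,
        rho2_physical=rho2_phys,
        rho2_psych=rho2_psych,
        r2_physical=spec.r2_physical,
        r2_psych=r2_psych,
        r2_combined=r2_comb,
        r2_residualized_psych=r2_comb - spec.r2_physical,
        outcome_sd=math.sqrt(var_y),
    )

    motion = None
    if with_motion:
        motion = []
        child_seeds = rng.integers(0, 2**31 - 1, size=n)
        for i in range(n):
            target_enorm = math.exp(outcome[i])
            drift = target_enorm / E_CHI6
            motion.append(
                generate_motion_series(
                    n_trs=240,
                    drift_sd=drift,
                    spike_rate=0.02,
                    spike_scale=6.0 * drift,
                    seed=int(child_seeds[i]),
                    subject_id=subjects[i],
                )
            )

    return SyntheticCohort(
        features=features, outcome=outcome, truth=truth, spec=spec, motion=motion
    )


# ---------------------------------------------------------------------------
# motion time-series model
# ---------------------------------------------------------------------------


def generate_motion_series(
    n_trs: int = 240,
    drift_sd: float = 0.02,
    spike_rate: float = 0.02,
    spike_scale: float = 0.15,
    seed: int = 0,
    tr_seconds: float = 2.0,
    subject_id: str = "",
) -> MotionParams:
    """Drift-plus-spike model for one subject's six-parameter series.

    Each parameter is a random walk with N(0, drift_sd²) increments.  Spikes
    arrive as a Poisson process with ``spike_rate`` expected events per TR;
    each spike adds a Laplace(0, spike_scale) displacement to one randomly
    chosen parameter at one TR and removes it at the next (a transient
    excursion, the typical signature of a brief head jerk).
    """
    if n_trs < 2:
        raise ValueError("n_trs must be at least 2")
    if drift_sd < 0 or spike_rate < 0 or spike_scale < 0:
        raise ValueError("rates and scales must be non-negative")
    rng = np.random.default_rng(seed)
    increments = drift_sd * rng.standard_normal((n_trs - 1, 6))
    positions = np.zeros((n_trs, 6))
    positions[1:] = np.cumsum(increments, axis=0)
    n_spikes = rng.poisson(spike_rate * n_trs)
    if n_spikes > 0 and spike_scale > 0:
        times = rng.integers(1, n_trs, size=n_spikes)
        params = rng.integers(0, 6, size=n_spikes)
        amps = rng.laplace(0.0, spike_scale, size=n_spikes)
        for t, j, a in zip(times, params, amps):
            positions[t, j] += a  # single-TR excursion
    return MotionParams(
        values=positions, tr_seconds=tr_seconds, subject_id=subject_id
    )


def generate_motion_cohort(
    n_subjects: int = 464,
    n_trs: int = 240,
    seed: int = 0,
    log_amp_mean: float = math.log(0.02),
    log_amp_sd: float = 0.5,
    spike_rate: float = 0.02,
    spike_scale_ratio: float = 6.0,
) -> list[MotionParams]:
    """A cohort of drift-plus-spike series with lognormal between-subject amplitude.

    Per-subject random-walk increment SDs are lognormal (median
    ``exp(log_amp_mean)`` mm), producing the right-skewed distribution of
    scan-average motion seen across real subjects; spike magnitude scales
    with each subject's drift amplitude.
    """
    rng = np.random.default_rng(seed)
    drift_sds = np.exp(rng.normal(log_amp_mean, log_amp_sd, size=n_subjects))
    child_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        generate_motion_series(
            n_trs=n_trs,
            drift_sd=float(drift_sds[i]),
            spike_rate=spike_rate,
            spike_scale=spike_scale_ratio * float(drift_sds[i]),
            seed=int(child_seeds[i]),
            subject_id=f"sub-{i + 1:04d}",
        )
        for i in range(n_subjects)
    ]
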