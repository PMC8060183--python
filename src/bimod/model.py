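"""Structural/statistical parameter layer of the bounded integer model.

Maps population parameters, subject-level random effects and covariates to
individual latent-scale parameters, and assembles per-subject log-likelihoods
and the joint (likelihood x random-effect prior) log-density that Laplace and
SAEM estimation integrate over.

The structural model is linear on the latent scale, f(t) = beta + alpha * t
(time in months), with constant latent SD g = sigma.  Between-subject
variability: beta and alpha are normal; sigma is either fixed or log-normal
(eta_sigma acts on log sigma so sigma > 0 by construction).  The covariate
model on the slope is

    alpha = theta_alpha * (age/75)^theta_age * theta_apoe^apoe
            * theta_sex^sex + eta_alpha

with the age-centering constant 75 part of the printed model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .kernels import LatentGrid, loglik_improved, loglik_naive

__all__ = [
    "PopulationParams",
    "SubjectEffects",
    "CovariateSet",
    "IndividualParams",
    "Observation",
    "individual_params",
    "latent_mean",
    "subject_loglik",
    "joint_logdensity",
]

AGE_REFERENCE = 75.0  # years; hard-coded centering constant of the slope model


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects and random-effect variances of the population model."""

    theta_beta: float
    theta_alpha: float
    theta_sigma: float
    omega2_beta: float
    omega2_alpha: float
    omega2_sigma: Optional[float] = None
    theta_age: Optional[float] = None
    theta_apoe: Optional[float] = None
    theta_sex: Optional[float] = None

    def __post_init__(self):
        if self.theta_sigma <= 0:
            raise ValueError("theta_sigma must be > 0")
        for name in ("omega2_beta", "omega2_alpha", "omega2_sigma"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def has_sigma_iiv(self) -> bool:
        return self.omega2_sigma is not None

    @property
    def has_covariates(self) -> bool:
        return any(v is not None for v in (self.theta_age, self.theta_apoe, self.theta_sex))

    def replace(self, **kw) -> "PopulationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SubjectEffects:
    eta_beta: float = 0.0
    eta_alpha: float = 0.0
    eta_sigma: Optional[float] = None


@dataclass(frozen=True)
class CovariateSet:
    age: Optional[float] = None
    apoe: Optional[int] = None
    sex: Optional[int] = None

    def __post_init__(self):
        if self.age is not None and self.age <= 0:
            raise ValueError("age must be > 0")


@dataclass(frozen=True)
class IndividualParams:
    beta: float
    alpha: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class Observation:
    time: float
    score: int


def individual_params(pop: PopulationParams, eff: SubjectEffects,
                      cov: Optional[CovariateSet] = None) -> IndividualParams:
    """Individual latent-scale parameters from population params + effects.

    The random effect on the slope enters additively after the covariate
    multiplier; the random effect on sigma acts on the log scale.
    """
    if pop.has_sigma_iiv != (eff.eta_sigma is not None):
        raise ValueError("eta_sigma must be present iff omega2_sigma is present")
    beta = pop.theta_beta + eff.eta_beta
    if pop.has_covariates:
        if cov is None:
            raise ValueError("covariate effects present but no covariates supplied")
        mult = 1.0
        if pop.theta_age is not None:
            if cov.age is None:
                raise ValueError("theta_age present but age covariate missing")
            mult *= (cov.age / AGE_REFERENCE) ** pop.theta_age
        if pop.theta_apoe is not None:
            if cov.apoe is None:
                raise ValueError("theta_apoe present but apoe covariate missing")
            mult *= pop.theta_apoe ** cov.apoe
        if pop.theta_sex is not None:
            if cov.sex is None:
                raise ValueError("theta_sex present but sex covariate missing")
            mult *= pop.theta_sex ** cov.sex
        alpha = pop.theta_alpha * mult + eff.eta_alpha
    else:
        alpha = pop.theta_alpha + eff.eta_alpha
    if pop.has_sigma_iiv:
        sigma = float(np.exp(np.log(pop.theta_sigma) + eff.eta_sigma))
    else:
        sigma = pop.theta_sigma
    return IndividualParams(beta=beta, alpha=alpha, sigma=sigma)


def latent_mean(ind: IndividualParams, time) -> float:
    """Latent-scale mean ``beta + alpha * t`` (t in months)."""
    return ind.beta + ind.alpha * np.asarray(time, dtype=float)


_KERNELS = {"naive": loglik_naive, "improved": loglik_improved}


def subject_loglik(obs: Sequence[Observation], ind: IndividualParams,
                   grid: LatentGrid, impl: str = "improved") -> float:
    """Sum of per-visit BI log-likelihood terms for one subject.

    Any non-finite term makes the sum non-finite (no masking).
    """
    if impl not in _KERNELS:
        raise ValueError(f"impl must be one of {sorted(_KERNELS)}, got {impl!r}")
    if len(obs) == 0:
        return 0.0
    times = np.array([o.time for o in obs], dtype=float)
    scores = np.array([o.score for o in obs], dtype=int)
    f = ind.beta + ind.alpha * times
    terms = _KERNELS[impl](scores, grid, f, ind.sigma)
    return float(np.sum(terms))


def _normal_logpdf(x, var):
    return -0.5 * (np.log(2 * np.pi * var) + x * x / var)


def joint_logdensity(obs: Sequence[Observation], pop: PopulationParams,
                     eff: SubjectEffects, cov: Optional[CovariateSet],
                     grid: LatentGrid, impl: str = "improved") -> float:
    """Subject log-likelihood plus log-prior of the random effects.

    A zero variance contributes 0 when the matching effect is 0 and ``-inf``
    otherwise (returned, not raised): a degenerate prior concentrates all
    mass at zero.
    """
    ind = individual_params(pop, eff, cov)
    total = subject_loglik(obs, ind, grid, impl)
    pairs = [(eff.eta_beta, pop.omega2_beta), (eff.eta_alpha, pop.omega2_alpha)]
    if pop.has_sigma_iiv:
        pairs.append((eff.eta_sigma, pop.omega2_sigma))
    for eta, om2 in pairs:
        if om2 == 0.0:
            if eta != 0.0:
                return -np.inf
        else:
            total += _normal_logpdf(eta, om2)
    return float(total)
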