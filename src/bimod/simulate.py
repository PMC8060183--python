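"""Synthetic longitudinal bounded-score data.

Emulates the structure of composite-score trials: ``N`` subjects, a common
visit schedule in months, a 0..S score generated from the BI model with a
linear latent trend, normal between-subject variability on baseline and
slope, and either fixed or log-normal within-subject latent SD.

The three built-in scenarios share design (S = 70, 600 subjects, visits at
0, 3, 6, 9, 12 months) and trend parameters (theta_beta = -0.3,
theta_alpha = 0.1 per month, omega2_beta = 1, omega2_alpha = 0.000625) and
differ only in the latent SD: S1 sigma = 1 fixed, S2 sigma = 0.1 fixed,
S3 log sigma ~ N(log 0.1, 0.1).  S2/S3 are the regimes where the naive
log-likelihood kernel breaks down.

Sampling is by latent binning: draw L = f + sigma * eps and emit the score
whose cut-point interval contains L (lower-open, upper-closed, matching the
Phi(z_{s+1}) - Phi(z_s) definition).  This is equivalent in law to sampling
the categorical distribution directly; the equivalence is tested.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .model import PopulationParams
from .kernels import make_grid

__all__ = [
    "ScenarioSpec",
    "builtin_scenarios",
    "simulate_dataset",
    "replicate_seeds",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class CovariateGenerator:
    """Covariate sampling for exercising the slope covariate model.

    Placeholder distributions (the real study's covariate distribution is
    not public): age ~ uniform integers on [age_low, age_high], apoe and sex
    ~ Bernoulli(1/2).
    """

    age_low: int = 60
    age_high: int = 90
    p_apoe: float = 0.5
    p_sex: float = 0.5

    def draw(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        return pd.DataFrame({
            "AGE": rng.integers(self.age_low, self.age_high + 1, size=n),
            "APOE": (rng.random(n) < self.p_apoe).astype(int),
            "SEX": (rng.random(n) < self.p_sex).astype(int),
        })


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation truth: design plus population parameters."""

    name: str
    max_score: int
    n_subjects: int
    visit_times: tuple
    pop: PopulationParams
    covariate_generator: Optional[CovariateGenerator] = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if len(self.visit_times) == 0:
            raise ValueError("visit_times must be nonempty")
        if np.any(np.diff(self.visit_times) < 0):
            raise ValueError("visit_times must be nondecreasing")

    def with_overrides(self, **kw) -> "ScenarioSpec":
        from dataclasses import replace
        return replace(self, **kw)


_DESIGN = dict(max_score=70, n_subjects=600, visit_times=(0.0, 3.0, 6.0, 9.0, 12.0))


def builtin_scenarios() -> Dict[str, ScenarioSpec]:
    """The three standard simulation scenarios (S1, S2, S3)."""
    common = dict(theta_beta=-0.3, theta_alpha=0.1, omega2_beta=1.0,
                  omega2_alpha=0.000625)
    return {
        "S1": ScenarioSpec(name="S1", pop=PopulationParams(theta_sigma=1.0, **common), **_DESIGN),
        "S2": ScenarioSpec(name="S2", pop=PopulationParams(theta_sigma=0.1, **common), **_DESIGN),
        "S3": ScenarioSpec(name="S3", pop=PopulationParams(theta_sigma=0.1, omega2_sigma=0.1, **common), **_DESIGN),
    }


def simulate_dataset(spec: ScenarioSpec, seed: int) -> pd.DataFrame:
    """Simulate one dataset; deterministic given (spec, seed).

    One pseudo-random stream per dataset; covariates (if any), then random
    effects, then residuals are drawn, each block in subject order, so the
    realization is reproducible regardless of machine parallelism.

    Returns a DataFrame with columns ID, TIME, DV (+ AGE/APOE/SEX when a
    covariate generator is configured); provenance (scenario name, seed) is
    kept in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    pop = spec.pop
    N = spec.n_subjects
    times = np.asarray(spec.visit_times, dtype=float)
    M = times.size
    grid = make_grid(spec.max_score)

    cov_df = None
    if spec.covariate_generator is not None:
        cov_df = spec.covariate_generator.draw(rng, N)

    eta_beta = rng.normal(0.0, np.sqrt(pop.omega2_beta), N)
    eta_alpha = rng.normal(0.0, np.sqrt(pop.omega2_alpha), N)
    beta = pop.theta_beta + eta_beta
    if pop.has_covariates and cov_df is not None:
        mult = np.ones(N)
        if pop.theta_age is not None:
            mult *= (cov_df["AGE"].to_numpy() / 75.0) ** pop.theta_age
        if pop.theta_apoe is not None:
            mult *= pop.theta_apoe ** cov_df["APOE"].to_numpy()
        if pop.theta_sex is not None:
            mult *= pop.theta_sex ** cov_df["SEX"].to_numpy()
        alpha = pop.theta_alpha * mult + eta_alpha
    else:
        alpha = pop.theta_alpha + eta_alpha
    if pop.has_sigma_iiv:
        eta_sigma = rng.normal(0.0, np.sqrt(pop.omega2_sigma), N)
        sigma = np.exp(np.log(pop.theta_sigma) + eta_sigma)
    else:
        sigma = np.full(N, pop.theta_sigma)

    eps = rng.standard_normal((N, M))
    latent = beta[:, None] + alpha[:, None] * times[None, :] + sigma[:, None] * eps
    interior = grid.cutpoints[1:-1]
    # q_s < L <= q_{s+1}: first interior cut-point >= L indexes the category
    scores = np.searchsorted(interior, latent.ravel(), side="left").reshape(N, M)

    df = pd.DataFrame({
        "ID": np.repeat(np.arange(1, N + 1), M),
        "TIME": np.tile(times, N),
        "DV": scores.ravel(),
    })
    if cov_df is not None:
        for c in ("AGE", "APOE", "SEX"):
            df[c] = np.repeat(cov_df[c].to_numpy(), M)
    df.attrs["scenario"] = spec.name
    df.attrs["seed"] = int(seed)
    df.attrs["max_score"] = spec.max_score
    return df


def replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic, collision-free (w.h.p.) derived seeds for replicates.

    Derived through numpy's SeedSequence so different base seeds give
    disjoint streams; values fit in 31 bits.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset as delimited text (header ID,TIME,DV[,AGE,APOE,SEX])."""
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset written by :func:`write_dataset` (round-trip fidelity)."""
    df = pd.read_csv(path)
    required = {"ID", "TIME", "DV"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset must have columns {sorted(required)}")
    df["ID"] = df["ID"].astype(int)
    df["DV"] = df["DV"].astype(int)
    return df
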