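"""Stochastic Approximation EM for the bounded integer model.

SAEM alternates (i) a few Metropolis random-walk sweeps per subject that
sample the random effects from their conditional distribution given the data
and current population parameters, and (ii) stochastic-approximation updates
of the population parameters from the sampled effects.  Because no
per-subject mode search is involved, the algorithm is insensitive to
log-likelihood kernel breakdowns: a region of effect space where the kernel
returns ``-inf`` is simply never accepted by the chain.

Parameters with a matching random effect (population mean and variance of
beta, alpha and - in the log-normal sigma model - log sigma) have closed-form
updates from smoothed first and second moments of the sampled individual
parameters.  A fixed-effect sigma (no variability) is not exponential-family;
its update smooths the complete-data log-likelihood surface itself on a fixed
log-sigma grid and maximizes the smoothed surface (parabolic refinement
around the grid argmax).

The step-size schedule is 1 during burn-in and ``(k - B)^(-a)`` afterwards.
All schedule settings are explicit package choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import LatentGrid, loglik_improved, loglik_naive, make_grid
from .laplace import (FitOptions, FitResult, _Batch, _ParamStructure,
                      _SubjectObjective, _laplace_terms, _typical_alpha)
from .model import CovariateSet, Observation, PopulationParams, SubjectEffects

__all__ = ["SaemSchedule", "mcmc_kernel", "fit_saem"]


@dataclass
class SaemSchedule:
    """Iteration and proposal settings of the SAEM run."""

    n_burnin_iter: int = 300
    n_sa_iter: int = 300
    exponent_a: float = 1.0
    mcmc_steps_per_iter: int = 2
    proposal_scale: float = 1.0
    sigma_grid_halfwidth: float = 2.0   # log-sigma units around the initial value
    sigma_grid_points: int = 81

    def __post_init__(self):
        if min(self.n_burnin_iter, self.n_sa_iter, self.mcmc_steps_per_iter) < 1:
            raise ValueError("iteration counts must be positive")
        if not (0.5 < self.exponent_a <= 1.0):
            raise ValueError("exponent_a must lie in (0.5, 1]")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be > 0")


def _mh_sweep(loglik_fn, b: np.ndarray, cur_ll: np.ndarray, prior_mean,
              prior_var, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random-walk Metropolis sweep: one update per coordinate, run for
    all chains (rows of ``b``) at once.

    ``loglik_fn`` maps the state matrix to per-chain data log-likelihoods;
    the normal prior with ``prior_mean``/``prior_var`` per coordinate closes
    the target density.  Proposals with a non-finite likelihood are always
    rejected.  ``b`` and ``cur_ll`` are updated in place; returns the
    per-chain, per-coordinate acceptance indicators.
    """
    N, k = b.shape
    pm = np.broadcast_to(np.asarray(prior_mean, dtype=float), (k,))
    pv = np.broadcast_to(np.asarray(prior_var, dtype=float), (k,))
    accepted = np.zeros((N, k), dtype=bool)
    for c in range(k):
        prop = b.copy()
        prop[:, c] = b[:, c] + scale[:, c] * rng.standard_normal(N)
        new_ll = loglik_fn(prop)
        dprior = (-0.5 * (prop[:, c] - pm[c]) ** 2 / pv[c]
                  + 0.5 * (b[:, c] - pm[c]) ** 2 / pv[c])
        with np.errstate(invalid="ignore"):
            log_ratio = new_ll - cur_ll + dprior
            accept = np.isfinite(new_ll) & (np.log(rng.random(N)) < log_ratio)
        b[accept, c] = prop[accept, c]
        cur_ll[accept] = new_ll[accept]
        accepted[:, c] = accept
    return accepted


def mcmc_kernel(obs: Sequence[Observation], pop: PopulationParams,
                cov: Optional[CovariateSet], grid: LatentGrid, impl: str,
                current_eff: SubjectEffects, proposal_scale,
                rng: np.random.Generator) -> SubjectEffects:
    """One Metropolis sweep (one update per effect coordinate) for a subject.

    Targets the conditional density ``exp(joint_logdensity)``; proposals with
    a non-finite target are always rejected, which is what makes the sampler
    robust to kernel breakdowns.
    """
    from .laplace import _single_batch

    obj = _SubjectObjective(_single_batch(obs, grid, cov), pop, impl)
    k = obj.k
    eta = np.zeros((1, k))
    eta[0, 0] = current_eff.eta_beta
    eta[0, 1] = current_eff.eta_alpha
    if k == 3:
        if current_eff.eta_sigma is None:
            raise ValueError("eta_sigma required when omega2_sigma is present")
        eta[0, 2] = current_eff.eta_sigma
    scale = np.broadcast_to(np.asarray(proposal_scale, dtype=float), (1, k)).copy()

    def data_only_ll(e):
        # obj.value includes the prior; subtract it so _mh_sweep's prior
        # bookkeeping is the single source of the prior term
        val = obj.value(e)
        pr = obj._log_prior_const - 0.5 * np.sum(e * e / obj.omega2, axis=1)
        return val - pr

    cur = data_only_ll(eta)
    _mh_sweep(data_only_ll, eta, cur, np.zeros(k), obj.omega2, scale, rng)
    return SubjectEffects(eta_beta=eta[0, 0], eta_alpha=eta[0, 1],
                          eta_sigma=eta[0, 2] if k == 3 else None)


def _batch_loglik(batch: _Batch, beta, alpha, sigma, impl: str) -> np.ndarray:
    """Per-subject data log-likelihood for individual parameter arrays."""
    kern = loglik_naive if impl == "naive" else loglik_improved
    f = beta[:, None] + alpha[:, None] * batch.times
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        terms = kern(batch.scores, batch.grid, f, np.asarray(sigma)[:, None]
                     if np.ndim(sigma) else np.full((batch.n, 1), sigma))
    return np.where(batch.mask, terms, 0.0).sum(axis=1)


def fit_saem(data: pd.DataFrame, init: PopulationParams,
             schedule: Optional[SaemSchedule] = None,
             grid: Optional[LatentGrid] = None, impl: str = "improved",
             seed: int = 0) -> FitResult:
    """Fit the population model by SAEM; deterministic given ``seed``.

    ``success`` requires every parameter trajectory's relative change over
    the final 20% of SA iterations to stay below 1e-2.  The reported ``ofv``
    is a Laplace-approximate -2 log-likelihood evaluated once at the final
    estimates with the improved kernel (a reporting diagnostic, not part of
    the SAEM iteration).
    """
    if init.has_covariates:
        raise NotImplementedError("SAEM supports the no-covariate parameter models")
    schedule = schedule or SaemSchedule()
    if grid is None:
        S = data.attrs.get("max_score", int(data["DV"].max()))
        grid = make_grid(int(S))
    batch = _Batch(data, grid)
    rng = np.random.default_rng(seed)
    struct = _ParamStructure(init)
    sigma_iiv = init.has_sigma_iiv
    k = 3 if sigma_iiv else 2
    N = batch.n

    theta = dict(beta=init.theta_beta, alpha=init.theta_alpha,
                 log_sigma=float(np.log(init.theta_sigma)))
    omega2 = np.array([init.omega2_beta, init.omega2_alpha]
                      + ([init.omega2_sigma] if sigma_iiv else []), float)
    if np.any(omega2 <= 0):
        raise ValueError("present-effect variances must be > 0")

    # chain state: absolute individual parameters [beta_i, alpha_i, (log sigma_i)]
    b = np.empty((N, k))
    b[:, 0] = theta["beta"]
    b[:, 1] = theta["alpha"]
    if sigma_iiv:
        b[:, 2] = theta["log_sigma"]

    def prior_mean():
        m = np.array([theta["beta"], theta["alpha"]]
                     + ([theta["log_sigma"]] if sigma_iiv else []))
        return m

    def data_ll(bb):
        sigma = np.exp(bb[:, 2]) if sigma_iiv else np.full(N, np.exp(theta["log_sigma"]))
        return _batch_loglik(batch, bb[:, 0], bb[:, 1], sigma, impl)

    cur_ll = data_ll(b)
    # subjects with a non-finite likelihood at the typical values: nudge with
    # prior draws until finite (the chain cannot start at -inf)
    bad = ~np.isfinite(cur_ll)
    for _ in range(100):
        if not bad.any():
            break
        b[bad] = prior_mean() + rng.standard_normal((bad.sum(), k)) * np.sqrt(omega2)
        cur_ll[bad] = data_ll(b)[bad]
        bad = ~np.isfinite(cur_ll)

    scale = np.broadcast_to(schedule.proposal_scale * np.sqrt(omega2), (N, k)).copy()
    acc_avg = np.full((N, k), 0.4)

    # fixed grid for the non-closed-form sigma update (S1/S2-type models)
    if not sigma_iiv:
        g_grid = theta["log_sigma"] + np.linspace(-schedule.sigma_grid_halfwidth,
                                                  schedule.sigma_grid_halfwidth,
                                                  schedule.sigma_grid_points)
        Q_sigma = None

    s1 = None
    s2 = None
    n_total = schedule.n_burnin_iter + schedule.n_sa_iter
    history = np.empty((n_total, len(struct.names)))

    for it in range(n_total):
        burnin = it < schedule.n_burnin_iter
        gamma = 1.0 if burnin else (it - schedule.n_burnin_iter + 1.0) ** (-schedule.exponent_a)

        pm = prior_mean()
        for _ in range(schedule.mcmc_steps_per_iter):
            accepted = _mh_sweep(data_ll, b, cur_ll, pm, omega2, scale, rng)
            acc_avg = 0.9 * acc_avg + 0.1 * accepted
        if burnin:
            # steer per-subject, per-coordinate acceptance into the 30-50% band
            scale *= np.exp(0.1 * (acc_avg - 0.4))

        # --- M-step -------------------------------------------------------
        stat1 = b.mean(axis=0)
        stat2 = (b * b).mean(axis=0)
        s1 = stat1 if s1 is None else s1 + gamma * (stat1 - s1)
        s2 = stat2 if s2 is None else s2 + gamma * (stat2 - s2)
        theta["beta"] = s1[0]
        theta["alpha"] = s1[1]
        omega2 = np.maximum(s2 - s1 * s1, 1e-12)
        if sigma_iiv:
            theta["log_sigma"] = s1[2]
        else:
            # smooth the complete-data log-likelihood over the sigma grid
            sig = np.exp(g_grid)
            f = b[:, 0][:, None] + b[:, 1][:, None] * batch.times
            with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
                kern = loglik_naive if impl == "naive" else loglik_improved
                terms = kern(batch.scores[None], batch.grid, f[None],
                             sig[:, None, None])
            L = np.where(batch.mask[None], terms, 0.0).sum(axis=(1, 2))
            # a kernel breakdown at a grid point must neither poison the
            # smoothing with NaN nor attract the argmax: floor it far below
            # any attainable finite value
            L = np.where(np.isfinite(L), L, -1e12)
            Q_sigma = L if Q_sigma is None else Q_sigma + gamma * (L - Q_sigma)
            j = int(np.argmax(Q_sigma))
            if 0 < j < g_grid.size - 1 and np.isfinite(Q_sigma[[j - 1, j + 1]]).all():
                y0, y1, y2 = Q_sigma[j - 1:j + 2]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
                shift = np.clip(shift, -1.0, 1.0)
            else:
                shift = 0.0
            theta["log_sigma"] = g_grid[j] + shift * (g_grid[1] - g_grid[0])
            cur_ll = data_ll(b)  # sigma changed: cached likelihoods are stale

        pop_now = _assemble(theta, omega2, sigma_iiv)
        history[it] = struct.pack(pop_now)

    estimates = _assemble(theta, omega2, sigma_iiv)

    # convergence: relative span of each packed parameter over the last 20%
    tail = history[n_total - max(1, int(0.2 * schedule.n_sa_iter)):]
    span = tail.max(axis=0) - tail.min(axis=0)
    rel = span / np.maximum(np.abs(tail[-1]), 1e-3)
    success = bool(np.all(np.isfinite(tail)) and np.all(rel < 1e-2))
    messages = []
    if not success:
        worst = struct.names[int(np.argmax(rel))]
        messages.append(f"trajectory not settled (max relative span {rel.max():.3g} on {worst})")

    # reporting OFV: one Laplace evaluation at the final estimates
    try:
        obj = _SubjectObjective(batch, estimates, "improved")
        marg, _, _, bad_m = _laplace_terms(obj, np.zeros((N, k)), FitOptions())
        ofv = float(-2.0 * marg[~bad_m].sum()) if (~bad_m).any() else np.inf
    except ValueError:
        ofv = np.inf
    if not np.isfinite(ofv):
        success = False
        messages.append("reporting OFV non-finite")

    eta_modes = b - prior_mean()
    return FitResult(estimates=estimates, ofv=ofv, success=success,
                     n_outer_iter=n_total, method="saem", implementation=impl,
                     eta_modes=eta_modes, messages=messages,
                     param_names=struct.names, x=struct.pack(estimates))


def _assemble(theta, omega2, sigma_iiv) -> PopulationParams:
    return PopulationParams(
        theta_beta=float(theta["beta"]), theta_alpha=float(theta["alpha"]),
        theta_sigma=float(np.exp(theta["log_sigma"])),
        omega2_beta=float(omega2[0]), omega2_alpha=float(omega2[1]),
        omega2_sigma=float(omega2[2]) if sigma_iiv else None)
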