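"""Laplace-approximation marginal likelihood and population fitting.

For each subject the random effects are integrated out by a second-order
expansion of the joint log-density at the empirical-Bayes mode:

    log p(y_i) ~= log p(y_i, eta_hat_i) + (k/2) log(2 pi)
                  - (1/2) log det(-H_i),

with ``H_i`` the Hessian of the joint log-density at the mode.  Population
parameters are found by quasi-Newton minimization of
``OFV = -2 * sum_i log p(y_i)`` with variance-type parameters on the log
scale.  The "minimization successful" analog is transparent and documented:
finite OFV, a scaled-gradient criterion, and a positive-definite
finite-difference OFV Hessian.

Mode search is a safeguarded (damped, backtracked) Newton from eta = 0 with
an analytic gradient and finite-difference Hessian, run vectorized across
all subjects.  Subjects whose joint density is non-finite at the start (a
naive-kernel failure mode) are recorded as failed and contribute a large
penalty to the objective rather than aborting the outer step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .kernels import LatentGrid, loglik_grad, loglik_improved, loglik_naive, make_grid
from .model import (AGE_REFERENCE, CovariateSet, Observation, PopulationParams,
                    SubjectEffects)

__all__ = ["FitOptions", "FitResult", "eta_mode", "laplace_subject_marginal",
           "fit_laplace"]

FAILED_SUBJECT_PENALTY = -1.0e7  # log-likelihood contribution of a failed subject


@dataclass
class FitOptions:
    """Tuning knobs of the Laplace fit; defaults are the package's analog of
    a production NLME configuration (the reference software's criteria are
    proprietary, so every knob is explicit)."""

    max_outer_iter: int = 500
    outer_gradient_tol: float = 1e-3   # relative, scaled by parameter magnitude
    inner_newton_tol: float = 1e-8     # gradient inf-norm at the mode
    inner_max_iter: int = 50
    finite_difference_step: float = 1e-5
    implementation: str = "improved"
    bfgs_gtol: float = 1e-2
    compute_standard_errors: bool = False

    def __post_init__(self):
        for name in ("outer_gradient_tol", "inner_newton_tol", "finite_difference_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.implementation not in ("naive", "improved"):
            raise ValueError("implementation must be 'naive' or 'improved'")


@dataclass
class FitResult:
    """Estimates and diagnostics of one population fit (results object).

    ``ofv`` is -2 times the total log marginal likelihood.  ``success`` is
    the package's "minimization successful" analog.
    """

    estimates: PopulationParams
    ofv: float
    success: bool
    n_outer_iter: int
    method: str = "laplace"
    implementation: str = "improved"
    eta_modes: Optional[np.ndarray] = None
    standard_errors: Optional[pd.Series] = None
    messages: List[str] = field(default_factory=list)
    param_names: Optional[List[str]] = None
    x: Optional[np.ndarray] = None
    gradient: Optional[np.ndarray] = None
    n_failed_subjects: int = 0

    @property
    def params(self) -> pd.Series:
        """Estimates as a named Series (natural scale)."""
        est = self.estimates
        vals = {"theta_beta": est.theta_beta, "theta_alpha": est.theta_alpha,
                "theta_sigma": est.theta_sigma, "omega2_beta": est.omega2_beta,
                "omega2_alpha": est.omega2_alpha}
        if est.omega2_sigma is not None:
            vals["omega2_sigma"] = est.omega2_sigma
        for n in ("theta_age", "theta_apoe", "theta_sex"):
            v = getattr(est, n)
            if v is not None:
                vals[n] = v
        return pd.Series(vals)

    def summary(self) -> str:
        """Plain-text fit report."""
        lines = [
            "Bounded integer model fit",
            "=" * 42,
            f"method:          {self.method} ({self.implementation} kernel)",
            f"OFV (-2 log L):  {self.ofv:.4f}",
            f"success:         {self.success}",
            f"outer iters:     {self.n_outer_iter}",
            f"failed subjects: {self.n_failed_subjects}",
            "-" * 42,
        ]
        se = self.standard_errors
        for name, val in self.params.items():
            if se is not None and name in se.index and np.isfinite(se[name]):
                lines.append(f"{name:>14s}  {val: .6g}  (SE {se[name]:.3g})")
            else:
                lines.append(f"{name:>14s}  {val: .6g}")
        for m in self.messages:
            lines.append(f"note: {m}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable results table."""
        df = pd.DataFrame({"estimate": self.params})
        if self.standard_errors is not None:
            df["se"] = self.standard_errors
        return df


# ---------------------------------------------------------------------------
# batched data and parameter packing

class _Batch:
    """Per-subject arrays padded to a rectangular (N, M) layout."""

    def __init__(self, data: pd.DataFrame, grid: LatentGrid):
        ids = data["ID"].to_numpy()
        order = np.unique(ids)
        self.subject_ids = order
        self.n = order.size
        groups = [data[ids == i] for i in order]
        M = max(len(g) for g in groups)
        self.times = np.zeros((self.n, M))
        self.scores = np.zeros((self.n, M), dtype=int)
        self.mask = np.zeros((self.n, M), dtype=bool)
        for r, g in enumerate(groups):
            m = len(g)
            self.times[r, :m] = g["TIME"].to_numpy()
            self.scores[r, :m] = g["DV"].to_numpy()
            self.mask[r, :m] = True
        if self.scores.max() > grid.max_score or self.scores.min() < 0:
            raise ValueError("scores outside 0..max_score")
        self.grid = grid
        self.has_cov = {"AGE", "APOE", "SEX"}.issubset(data.columns)
        if self.has_cov:
            first = data.groupby("ID", sort=True).first()
            self.age = first["AGE"].to_numpy(dtype=float)
            self.apoe = first["APOE"].to_numpy(dtype=float)
            self.sex = first["SEX"].to_numpy(dtype=float)


class _ParamStructure:
    """Packs a PopulationParams into an unconstrained vector and back.

    Variance-type parameters (theta_sigma, omega2_*) travel on the log scale
    so positivity is automatic.
    """

    def __init__(self, template: PopulationParams):
        self.sigma_iiv = template.has_sigma_iiv
        self.covariates = template.has_covariates
        self.names = ["theta_beta", "theta_alpha", "theta_sigma",
                      "omega2_beta", "omega2_alpha"]
        self.log_scale = [False, False, True, True, True]
        if self.sigma_iiv:
            self.names.append("omega2_sigma")
            self.log_scale.append(True)
        if self.covariates:
            for n in ("theta_age", "theta_apoe", "theta_sex"):
                if getattr(template, n) is not None:
                    self.names.append(n)
                    self.log_scale.append(False)
        self.n_effects = 3 if self.sigma_iiv else 2

    def pack(self, pop: PopulationParams) -> np.ndarray:
        vals = [getattr(pop, n) for n in self.names]
        return np.array([np.log(v) if lg else v
                         for v, lg in zip(vals, self.log_scale)])

    def unpack(self, x: np.ndarray) -> PopulationParams:
        kw = {}
        with np.errstate(over="ignore"):
            for n, lg, v in zip(self.names, self.log_scale, x):
                kw[n] = float(np.exp(v)) if lg else float(v)
                if not np.isfinite(kw[n]):
                    raise ValueError(f"{n} over/underflowed during optimization")
        return PopulationParams(**kw)


def _typical_alpha(pop: PopulationParams, batch: _Batch) -> np.ndarray:
    """Per-subject typical slope including the covariate multiplier."""
    alpha = np.full(batch.n, pop.theta_alpha)
    if pop.has_covariates:
        if not batch.has_cov:
            raise ValueError("covariate effects present but dataset has no covariates")
        mult = np.ones(batch.n)
        if pop.theta_age is not None:
            mult = mult * (batch.age / AGE_REFERENCE) ** pop.theta_age
        if pop.theta_apoe is not None:
            mult = mult * pop.theta_apoe ** batch.apoe
        if pop.theta_sex is not None:
            mult = mult * pop.theta_sex ** batch.sex
        alpha = pop.theta_alpha * mult
    return alpha


class _SubjectObjective:
    """Joint log-density (likelihood x effect prior) and its eta-gradient,
    evaluated for all subjects simultaneously.  Effect layout: columns
    [eta_beta, eta_alpha, (eta_sigma)]."""

    def __init__(self, batch: _Batch, pop: PopulationParams, impl: str):
        self.batch = batch
        self.pop = pop
        self.impl = impl
        self.alpha_typ = _typical_alpha(pop, batch)
        self.k = 3 if pop.has_sigma_iiv else 2
        om = [pop.omega2_beta, pop.omega2_alpha]
        if pop.has_sigma_iiv:
            om.append(pop.omega2_sigma)
        self.omega2 = np.asarray(om, dtype=float)
        if np.any(self.omega2 <= 0):
            raise ValueError("present-effect variances must be > 0")
        self._log_prior_const = -0.5 * np.sum(np.log(2 * np.pi * self.omega2))

    def _individual(self, eta: np.ndarray):
        pop = self.pop
        beta = pop.theta_beta + eta[:, 0]
        alpha = self.alpha_typ + eta[:, 1]
        if self.k == 3:
            with np.errstate(over="ignore"):
                sigma = np.exp(np.log(pop.theta_sigma) + eta[:, 2])
        else:
            sigma = np.full(self.batch.n, pop.theta_sigma)
        return beta, alpha, sigma

    @staticmethod
    def _guard_sigma(sigma):
        """exp(log sigma + eta) can under/overflow for extreme proposals;
        such rows are invalid (objective -inf), not errors."""
        bad = ~np.isfinite(sigma) | (sigma <= 0.0)
        return np.where(bad, 1.0, sigma), bad

    def value(self, eta: np.ndarray) -> np.ndarray:
        b = self.batch
        beta, alpha, sigma = self._individual(eta)
        sigma, bad_sig = self._guard_sigma(sigma)
        f = beta[:, None] + alpha[:, None] * b.times
        kern = loglik_naive if self.impl == "naive" else loglik_improved
        with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
            terms = kern(b.scores, b.grid, f, sigma[:, None])
            ll = np.where(b.mask, terms, 0.0).sum(axis=1)
            prior = self._log_prior_const - 0.5 * np.sum(eta * eta / self.omega2, axis=1)
            out = ll + prior
        out[bad_sig] = -np.inf
        return out

    def grad(self, eta: np.ndarray) -> np.ndarray:
        b = self.batch
        beta, alpha, sigma = self._individual(eta)
        sigma, bad_sig = self._guard_sigma(sigma)
        f = beta[:, None] + alpha[:, None] * b.times
        with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
            d_f, d_sig = loglik_grad(b.scores, b.grid, f, sigma[:, None], self.impl)
            d_f = np.where(b.mask, d_f, 0.0)
            g = np.empty((b.n, self.k))
            g[:, 0] = d_f.sum(axis=1)
            g[:, 1] = (d_f * b.times).sum(axis=1)
            if self.k == 3:
                d_sig = np.where(b.mask, d_sig, 0.0)
                g[:, 2] = d_sig.sum(axis=1) * sigma
            g -= eta / self.omega2
        g[bad_sig] = 0.0
        return g

    def neg_hessian(self, eta: np.ndarray, h: float) -> np.ndarray:
        """-(Hessian of the joint log-density), central FD of the gradient."""
        n, k = eta.shape
        H = np.empty((n, k, k))
        with np.errstate(invalid="ignore"):
            for c in range(k):
                ep = eta.copy(); ep[:, c] += h
                em = eta.copy(); em[:, c] -= h
                H[:, :, c] = -(self.grad(ep) - self.grad(em)) / (2 * h)
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def _find_modes(obj: _SubjectObjective, eta0: np.ndarray, opts: FitOptions):
    """Safeguarded Newton ascent for all subjects at once.

    Returns (eta, J, start_failed) where start_failed marks subjects whose
    joint density was non-finite at their starting point.
    """
    eta = eta0.copy()
    J = obj.value(eta)
    start_failed = ~np.isfinite(J)
    # failed-at-start subjects are frozen; everything they produce is ignored
    eta[start_failed] = 0.0
    J[start_failed] = -np.inf
    active = ~start_failed
    h = opts.finite_difference_step
    for _ in range(opts.inner_max_iter):
        if not active.any():
            break
        g = obj.grad(eta)
        g[~np.isfinite(g)] = 0.0
        gnorm = np.abs(g).max(axis=1)
        active &= gnorm > opts.inner_newton_tol
        if not active.any():
            break
        negH = obj.neg_hessian(eta, h)
        step = np.zeros_like(eta)
        idx = np.flatnonzero(active)
        for i in idx:
            Hi = negH[i]
            gi = g[i]
            if not np.isfinite(Hi).all():
                step[i] = gi  # curvature unusable here; plain ascent step
                continue
            lam = 0.0
            for _ in range(8):
                try:
                    np.linalg.cholesky(Hi + lam * np.eye(obj.k))  # PD check
                    step[i] = np.linalg.solve(Hi + lam * np.eye(obj.k), gi)
                    break
                except np.linalg.LinAlgError:
                    lam = max(2.0 * lam, 1e-4 * (1.0 + np.abs(np.diag(Hi)).max()))
            else:
                step[i] = gi  # gradient fallback
        # backtracking line search, vectorized over subjects
        t = np.where(active, 1.0, 0.0)
        improved = np.zeros_like(active)
        for _ in range(25):
            trial = eta + t[:, None] * step
            Jt = obj.value(trial)
            ok = active & ~improved & np.isfinite(Jt) & (Jt >= J - 1e-12)
            eta[ok] = trial[ok]
            J[ok] = Jt[ok]
            improved |= ok
            t = np.where(active & ~improved, t * 0.5, t)
            if (improved | ~active).all():
                break
        active &= improved  # subjects with no improving step have stalled
    return eta, J, start_failed


def _laplace_terms(obj: _SubjectObjective, eta0: np.ndarray, opts: FitOptions):
    """Per-subject log marginal likelihoods, modes and failure mask."""
    eta, J, start_failed = _find_modes(obj, eta0, opts)
    negH = obj.neg_hessian(eta, opts.finite_difference_step)
    bad = start_failed | ~np.isfinite(J)
    negH_ok = np.where(np.isfinite(negH).all(axis=(1, 2))[:, None, None], negH,
                       np.eye(obj.k)[None])
    eigs = np.linalg.eigvalsh(negH_ok)
    pd_ok = (eigs > 0).all(axis=1) & np.isfinite(negH).all(axis=(1, 2))
    bad |= ~pd_ok
    sign, logdet = np.linalg.slogdet(negH_ok)
    marg = J + 0.5 * obj.k * np.log(2 * np.pi) - 0.5 * logdet
    marg[bad] = -np.inf
    return marg, eta, negH, bad


# ---------------------------------------------------------------------------
# public per-subject operations

def _single_batch(obs: Sequence[Observation], grid: LatentGrid,
                  cov: Optional[CovariateSet]) -> _Batch:
    rows = {"ID": [1] * max(len(obs), 1),
            "TIME": [o.time for o in obs] or [0.0],
            "DV": [o.score for o in obs] or [0]}
    df = pd.DataFrame(rows)
    if cov is not None and cov.age is not None:
        df["AGE"], df["APOE"], df["SEX"] = cov.age, cov.apoe or 0, cov.sex or 0
    b = _Batch(df, grid)
    if len(obs) == 0:
        b.mask[:] = False
    return b


def eta_mode(obs: Sequence[Observation], pop: PopulationParams,
             cov: Optional[CovariateSet], grid: LatentGrid,
             impl: str = "improved",
             opts: Optional[FitOptions] = None) -> Tuple[SubjectEffects, np.ndarray]:
    """Empirical-Bayes mode and negative joint-density Hessian for a subject.

    Raises no exception on a naive-kernel failure; the mode is flagged via a
    non-finite Hessian (and the population fit records it as a failed
    subject).
    """
    opts = opts or FitOptions(implementation=impl)
    obj = _SubjectObjective(_single_batch(obs, grid, cov), pop, impl)
    eta, J, start_failed = _find_modes(obj, np.zeros((1, obj.k)), opts)
    negH = obj.neg_hessian(eta, opts.finite_difference_step)[0]
    if start_failed[0]:
        negH = np.full((obj.k, obj.k), np.nan)
    eff = SubjectEffects(eta_beta=eta[0, 0], eta_alpha=eta[0, 1],
                         eta_sigma=eta[0, 2] if obj.k == 3 else None)
    return eff, negH


def laplace_subject_marginal(obs: Sequence[Observation], pop: PopulationParams,
                             cov: Optional[CovariateSet], grid: LatentGrid,
                             impl: str = "improved",
                             opts: Optional[FitOptions] = None) -> float:
    """Laplace-approximate log marginal likelihood of one subject."""
    opts = opts or FitOptions(implementation=impl)
    obj = _SubjectObjective(_single_batch(obs, grid, cov), pop, impl)
    marg, _, _, _ = _laplace_terms(obj, np.zeros((1, obj.k)), opts)
    return float(marg[0])


# ---------------------------------------------------------------------------
# population fit

def _fd_gradient(fun, x, rel_step=1e-4):
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1.0)
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2 * h)
    return g


def _fd_hessian(fun, x, rel_step=1e-3):
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
        for j in range(i + 1, n):
            xpp = x.copy(); xpp[[i, j]] += [h[i], h[j]]
            xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x.copy(); xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)) / (4 * h[i] * h[j])
    return H


def fit_laplace(data: pd.DataFrame, init: PopulationParams,
                grid: Optional[LatentGrid] = None,
                opts: Optional[FitOptions] = None) -> FitResult:
    """Fit the population model by Laplace-approximate maximum likelihood.

    Parameters present in ``init`` define what is estimated (an
    ``omega2_sigma`` in ``init`` turns on the log-normal sigma model,
    covariate thetas turn on the slope covariate model).  Initial estimates
    are ``init`` itself.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    opts = opts or FitOptions()
    if grid is None:
        S = data.attrs.get("max_score", int(data["DV"].max()))
        grid = make_grid(int(S))
    batch = _Batch(data, grid)
    struct = _ParamStructure(init)
    x0 = struct.pack(init)
    impl = opts.implementation
    messages: List[str] = []

    warm = {"eta": np.zeros((batch.n, struct.n_effects))}
    state = {"n_failed": 0, "eta": warm["eta"]}

    def ofv(x):
        try:
            pop = struct.unpack(x)
            obj = _SubjectObjective(batch, pop, impl)
        except (ValueError, OverflowError):
            return np.inf
        marg, eta, _, bad = _laplace_terms(obj, warm["eta"], opts)
        good = ~bad
        warm["eta"] = np.where(good[:, None], eta, warm["eta"])
        state["n_failed"] = int(bad.sum())
        state["eta"] = eta
        data_part = marg[good].sum()
        state["ofv_data"] = -2.0 * data_part  # penalty-free, for the success scaling
        total = data_part + FAILED_SUBJECT_PENALTY * bad.sum()
        return -2.0 * total if np.isfinite(total) else np.inf

    f0 = ofv(x0)
    if not np.isfinite(f0):
        messages.append("objective non-finite at initial estimates")
        return FitResult(estimates=init, ofv=np.inf, success=False,
                         n_outer_iter=0, method="laplace", implementation=impl,
                         eta_modes=state["eta"], messages=messages,
                         param_names=struct.names, x=x0,
                         n_failed_subjects=state["n_failed"])

    if opts.max_outer_iter > 0:
        # central-difference gradient with a parameter-scaled step: the
        # objective carries ~1e-8 inner-optimization noise, far too large
        # for an absolute sqrt(eps) forward-difference step
        jac = lambda x: _fd_gradient(ofv, x, rel_step=1e-4)
        res = optimize.minimize(ofv, x0, jac=jac, method="BFGS",
                                options=dict(maxiter=opts.max_outer_iter,
                                             gtol=opts.bfgs_gtol))
        x_hat, n_iter = res.x, int(res.nit)
        if not res.success:
            messages.append(f"outer optimizer: {res.message}")
    else:
        x_hat, n_iter = x0, 0
        messages.append("outer iteration limit is 0; returning initial estimates")

    f_hat = ofv(x_hat)
    eta_final = state["eta"].copy()
    n_failed = state["n_failed"]
    if n_failed:
        messages.append(f"{n_failed} subject(s) failed inner optimization at the solution")

    # --- "minimization successful" analog -----------------------------------
    # a subject whose inner optimization failed means the evaluated OFV is
    # not the model's marginal likelihood: the failure propagates to the flag
    success = bool(np.isfinite(f_hat)) and n_failed == 0
    if np.isfinite(f_hat) and n_failed > 0:
        messages.append("failed subjects at the solution veto success")
    g = np.full(x_hat.size, np.nan)
    f_scale = state.get("ofv_data", f_hat)  # penalty-free OFV sets the scale
    if success:
        g = _fd_gradient(ofv, x_hat)
        scaled = np.abs(g) * np.maximum(np.abs(x_hat), 1.0)
        grad_ok = bool(np.all(np.isfinite(g))
                       and scaled.max() < opts.outer_gradient_tol * max(1.0, abs(f_scale)))
        if not grad_ok:
            messages.append(f"gradient criterion unmet (max scaled grad {np.nanmax(scaled):.3g})")
        hess_ok = False
        H = None
        if grad_ok:
            H = _fd_hessian(ofv, x_hat)
            try:
                np.linalg.cholesky(0.5 * (H + H.T))
                hess_ok = True
            except np.linalg.LinAlgError:
                messages.append("OFV Hessian not positive definite")
        success = grad_ok and hess_ok
    elif not np.isfinite(f_hat):
        messages.append("final OFV non-finite")

    se = None
    if opts.compute_standard_errors and success:
        try:
            cov = 2.0 * np.linalg.inv(0.5 * (H + H.T))
            se_x = np.sqrt(np.maximum(np.diag(cov), 0.0))
            # delta method back to the natural scale for log-parameterized params
            nat = struct.pack(struct.unpack(x_hat))
            se_vals = [s * (np.exp(v) if lg else 1.0)
                       for s, v, lg in zip(se_x, x_hat, struct.log_scale)]
            se = pd.Series(se_vals, index=struct.names)
        except np.linalg.LinAlgError:
            messages.append("standard errors unavailable (singular Hessian)")

    return FitResult(estimates=struct.unpack(x_hat), ofv=float(f_hat),
                     success=success, n_outer_iter=n_iter, method="laplace",
                     implementation=impl, eta_modes=eta_final,
                     standard_errors=se, messages=messages,
                     param_names=struct.names, x=x_hat, gradient=g,
                     n_failed_subjects=n_failed)
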