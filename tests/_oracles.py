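"""Independent numerical oracles used by the test-suite only.

These deliberately avoid the package's Laplace/Newton code paths: the
marginal-likelihood oracle integrates by adaptive Gauss-Hermite quadrature
(mode/curvature located by dense grid search plus numerical refinement), and
the mode oracle is a dense grid search.
"""

import numpy as np

from bimod.model import SubjectEffects, joint_logdensity


def joint_on_grid(obs, pop, cov, grid, eta_axes, impl="improved"):
    """Evaluate the joint log-density on a dense tensor grid of effects."""
    mesh = np.meshgrid(*eta_axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    out = np.empty(flat[0].size)
    has_sig = pop.has_sigma_iiv
    for i in range(flat[0].size):
        eff = SubjectEffects(eta_beta=flat[0][i],
                             eta_alpha=flat[1][i] if len(flat) > 1 else 0.0,
                             eta_sigma=(flat[2][i] if len(flat) > 2 else 0.0) if has_sig else None)
        out[i] = joint_logdensity(obs, pop, eff, cov, grid, impl)
    return out.reshape(mesh[0].shape)


def grid_mode_1d(obs, pop, cov, grid, lo=-5.0, hi=5.0, step=1e-3, impl="improved"):
    """Dense 1-D grid argmax over eta_beta (other effects at 0)."""
    axis = np.arange(lo, hi + step / 2, step)
    vals = joint_on_grid(obs, pop, cov, grid, [axis], impl)
    return axis[int(np.nanargmax(vals))]


def gh_marginal(obs, pop, cov, grid, n_nodes=64, impl="improved"):
    """Adaptive Gauss-Hermite log marginal likelihood over the free effects.

    Centers and scales the rule at the integrand's mode/curvature found by a
    coarse grid search plus local quadratic refinement; tensorizes over two
    effects when omega2_alpha is not degenerate.
    """
    two_dim = pop.omega2_alpha > 1e-10
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)

    def f1(e):
        return joint_on_grid(obs, pop, cov, grid, [np.atleast_1d(e)], impl)[0]

    # locate mode of eta_beta (coarse) for centering
    ax = np.linspace(-6, 6, 241)
    if two_dim:
        v1 = joint_on_grid(obs, pop, cov, grid, [ax, np.array([0.0])], impl)[:, 0]
        c1 = ax[int(np.nanargmax(v1))]
        w2 = 5 * np.sqrt(pop.omega2_alpha)
        axb = np.linspace(c1 - 1.0, c1 + 1.0, 41)
        ax2 = np.linspace(-w2, w2, 41)
        vals = joint_on_grid(obs, pop, cov, grid, [axb, ax2], impl)
        i, j = np.unravel_index(np.nanargmax(vals), vals.shape)
        m1, m2 = axb[i], ax2[j]
        h1, h2 = 1e-3, 1e-4

        def f2(a, b):
            return joint_on_grid(obs, pop, cov, grid,
                                 [np.atleast_1d(a), np.atleast_1d(b)], impl)[0, 0]

        c11 = -(f2(m1 + h1, m2) - 2 * f2(m1, m2) + f2(m1 - h1, m2)) / h1**2
        c22 = -(f2(m1, m2 + h2) - 2 * f2(m1, m2) + f2(m1, m2 - h2)) / h2**2
        s1, s2 = 1 / np.sqrt(max(c11, 1e-12)), 1 / np.sqrt(max(c22, 1e-12))
        x1 = m1 + np.sqrt(2) * s1 * nodes
        x2 = m2 + np.sqrt(2) * s2 * nodes
        vals = joint_on_grid(obs, pop, cov, grid, [x1, x2], impl)
        lw = (vals + nodes[:, None]**2 + nodes[None, :]**2
              + np.log(weights[:, None]) + np.log(weights[None, :]))
        m = np.nanmax(lw)
        total = np.exp(lw[np.isfinite(lw)] - m).sum()
        return m + np.log(total) + np.log(2 * s1 * s2)  # sqrt(2)^2 * s1 * s2
    vals = joint_on_grid(obs, pop, cov, grid, [ax], impl)
    m1 = ax[int(np.nanargmax(vals))]
    h = 1e-3
    c = -(f1(m1 + h) - 2 * f1(m1) + f1(m1 - h)) / h**2
    s = 1 / np.sqrt(max(c, 1e-12))
    x = m1 + np.sqrt(2) * s * nodes
    vals = joint_on_grid(obs, pop, cov, grid, [x], impl)
    lw = vals + nodes**2 + np.log(weights)
    m = np.nanmax(lw)
    out = m + np.log(np.exp(lw[np.isfinite(lw)] - m).sum()) + np.log(np.sqrt(2) * s)
    # the pinned eta_alpha coordinate integrates analytically: the grid above
    # holds it at its prior mode, so add back int N(a; 0, w2) da / N(0; 0, w2)
    out += 0.5 * np.log(2 * np.pi * pop.omega2_alpha)
    return out
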