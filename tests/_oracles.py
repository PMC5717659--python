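"""Independent oracles used by the test suite.

These deliberately avoid the package's grid code: closed forms and
generic numerical integration only, so they can arbitrate its results.
"""

import numpy as np
from scipy import integrate, stats


def conjugate_bf(mean, se, grid):
    """Closed-form Savage-Dickey BF for the symmetric N(0,1) prior, with
    prior and posterior truncated-renormalized to the grid range."""
    s2 = se**2
    post_mean = mean / (1 + s2)
    post_sd = np.sqrt(s2 / (1 + s2))
    z_prior = stats.norm.cdf(grid.hi) - stats.norm.cdf(grid.lo)
    z_post = stats.norm.cdf(grid.hi, post_mean, post_sd) - stats.norm.cdf(
        grid.lo, post_mean, post_sd
    )
    return (stats.norm.pdf(0) / z_prior) / (
        stats.norm.pdf(0, post_mean, post_sd) / z_post
    )


def integration_bf(mean, se, direction, grid):
    """Marginal-likelihood route: BF = int L(x) prior(x) dx / L(0), prior
    truncated to the grid range.  Mathematically identical to the
    Savage-Dickey density ratio for a point null."""
    if direction == "none":
        lo, hi, scale = grid.lo, grid.hi, 1.0
    elif direction == "high":
        lo, hi, scale = 0.0, grid.hi, 2.0
    else:
        lo, hi, scale = grid.lo, 0.0, 2.0
    z = scale * (stats.norm.cdf(hi) - stats.norm.cdf(lo))

    def integrand(x):
        return stats.norm.pdf(x, mean, se) * scale * stats.norm.pdf(x) / z

    num, _ = integrate.quad(integrand, lo, hi, limit=200)
    return num / stats.norm.pdf(0, mean, se)


def grid_marginal_bf(prior, mean, se, grid):
    """Marginal-likelihood identity on the prior's own discrete measure:
    BF = sum_i prior_i L(x_i) step / L(0), with likelihood values taken
    straight from scipy (independent of the package's likelihood,
    posterior and density-ratio code paths)."""
    lik = stats.norm.pdf(grid.nodes, mean, se)
    return float((prior.density * lik).sum() * grid.step / stats.norm.pdf(0, mean, se))


def exhaustive_narrowest_window(post, level=0.95):
    """Brute-force scan over every contiguous node window."""
    masses = post.density * post.grid.step
    cum = np.concatenate([[0.0], np.cumsum(masses)])
    n = len(masses)
    best = None
    for i in range(n):
        for j in range(i, n):
            if cum[j + 1] - cum[i] >= level:
                # minimal width, then maximal coverage, then leftmost
                cand = (j - i, -(cum[j + 1] - cum[i]), i)
                if best is None or cand < best:
                    best = cand
                break
    width, _, i = best
    return post.grid.nodes[i], post.grid.nodes[i + width]


def max_congruence(true_loadings, estimated_loadings):
    """Per-true-factor best Tucker congruence against estimated factors."""
    A = np.asarray(true_loadings, float)
    B = np.asarray(estimated_loadings, float)
    C = np.abs(A.T @ B) / (
        np.linalg.norm(A, axis=0)[:, None] * np.linalg.norm(B, axis=0)[None, :]
    )
    return C.max(axis=1)
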