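"""Independent brute-force oracles used to validate the estimators."""

import numpy as np
from scipy.stats import norm


def grid_search_loglik(x, n_mu=28, n_sigma=14, n_lam=9):
    """Best two-component-mixture log-likelihood over a dense parameter grid.

    Exhaustive search over (mu1 <= mu2, sigma1, sigma2, lambda); independent
    of the EM implementation it is used to check. The unequal-variance
    mixture likelihood is unbounded as sigma -> 0 (a one-point spike beats
    any interior solution), so the search is restricted to the
    non-degenerate region sigma >= std/4 — the interior optimum that EM-type
    estimators target.
    """
    x = np.asarray(x, float)
    mus = np.linspace(x.min() - 0.25, x.max() + 0.25, n_mu)
    sigmas = np.geomspace(x.std() / 4, 2.5 * x.std() + 0.05, n_sigma)
    lams = np.linspace(0.1, 0.9, n_lam)
    best = -np.inf
    for i, m1 in enumerate(mus):
        for m2 in mus[i:]:
            d1 = norm.pdf(x, m1, sigmas[:, None])  # (s1, n)
            d2 = norm.pdf(x, m2, sigmas[:, None])  # (s2, n)
            mix = (
                lams[:, None, None, None] * d1[None, :, None, :]
                + (1 - lams[:, None, None, None]) * d2[None, None, :, :]
            )
            ll = np.log(mix).sum(axis=-1).max()
            best = max(best, float(ll))
    return best
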