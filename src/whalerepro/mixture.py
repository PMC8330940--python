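"""Two-component normal mixture on log progesterone and pregnancy probability.

The model: log-transformed blubber progesterone of non-calf females is a
mixture of two normal components, a low cluster (non-pregnant: immature,
lactating, resting) and a high cluster (pregnant). With component means
``mu_k``, standard deviations ``sigma_k`` and mixing weights ``lambda_k``
(``k`` in {low, high}), the probability a whale with concentration ``x`` ng/g
is pregnant is the posterior probability of the high-mean component,

    p(x) = lambda_h * phi(ln x; mu_h, sigma_h) /
           [lambda_l * phi(ln x; mu_l, sigma_l) + lambda_h * phi(ln x; mu_h, sigma_h)]

The maximum-likelihood fit is by expectation-maximisation (EM) with a
deterministic median-split initialisation, so repeated fits of the same data
are identical. Components are always relabelled so the higher-mean component
is the pregnant one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "MixtureFit",
    "FitError",
    "fit_mixture",
    "pregnancy_probability",
    "threshold_at",
    "overlap_coefficient",
    "categorize",
    "summarize_fit",
]

_LOG_2PI = math.log(2.0 * math.pi)


class FitError(RuntimeError):
    """EM failed: degenerate collapse persisted across restarts."""


@dataclass
class MixtureFit:
    """Converged (or flagged) two-component univariate normal mixture.

    Parameters are on the natural-log concentration scale; ``mu_low <
    mu_high`` by construction and the high component is read as the
    pregnant cluster.
    """

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    lambda_low: float
    lambda_high: float
    loglik_trace: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def _params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.array([self.mu_low, self.mu_high]),
            np.array([self.sigma_low, self.sigma_high]),
            np.array([self.lambda_low, self.lambda_high]),
        )


def _log_norm_pdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (x[..., None] - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def _em(
    x: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    lam: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Run EM from the given start; returns params, trace, iterations, flag."""
    trace = []
    ll_old = -np.inf
    converged = False
    n = len(x)
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for stability at extreme observations
        log_dens = _log_norm_pdf(x, mu, sigma) + np.log(lam)
        m = log_dens.max(axis=1, keepdims=True)
        log_tot = m[:, 0] + np.log(np.exp(log_dens - m).sum(axis=1))
        ll = float(log_tot.sum())
        trace.append(ll)
        gamma = np.exp(log_dens - log_tot[:, None])
        # M-step
        nk = gamma.sum(axis=0)
        if np.any(nk < 1e-10):
            break  # a component lost all responsibility -> degenerate
        lam = nk / n
        mu = gamma.T @ x / nk
        var = (gamma * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(var)
        if np.any(sigma < 1e-8):
            break
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return mu, sigma, lam, np.asarray(trace), it, converged


def _split_init(x: np.ndarray, thr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moment-match the two halves of a threshold split."""
    lo, hi = x[x <= thr], x[x > thr]
    if len(lo) == 0 or len(hi) == 0:
        thr = float(np.median(x))
        lo, hi = x[x <= thr], x[x > thr]
    mu = np.array([lo.mean(), hi.mean()])
    sigma = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    lam = np.array([len(lo) / len(x), len(hi) / len(x)])
    return mu, sigma, lam


def _initial_params(x: np.ndarray, init: str):
    """Deterministic starting points; ``best`` yields several candidates."""
    median = _split_init(x, float(np.median(x)))
    if init == "median_split":
        return [median]
    q1, q3 = np.quantile(x, [0.25, 0.75])
    s = max(x.std() / 2, 1e-3)
    quartile = (np.array([q1, q3]), np.array([s, s]), np.array([0.5, 0.5]))
    if init == "quartile":
        return [quartile]
    if init == "best":
        # Lloyd-style 1-D 2-means threshold as a third deterministic start
        thr = float(x.mean())
        for _ in range(50):
            lo, hi = x[x <= thr], x[x > thr]
            if len(lo) == 0 or len(hi) == 0:
                break
            new = 0.5 * (lo.mean() + hi.mean())
            if abs(new - thr) < 1e-12:
                break
            thr = new
        starts = [median, quartile, _split_init(x, thr)]
        if len(x) <= 30:
            # small samples are cheap: seed EM from every ordered split so the
            # local optimiser cannot miss the dominant basin
            xs = np.sort(x)
            for k in range(2, len(xs) - 1):
                starts.append(_split_init(x, float(0.5 * (xs[k - 1] + xs[k]))))
        return starts
    raise ValueError(f"unknown init strategy {init!r}")


def fit_mixture(
    log_values: np.ndarray,
    init: str = "best",
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 5,
    restart_seed: int = 0,
) -> MixtureFit:
    """Fit the two-component normal mixture by EM.

    Parameters
    ----------
    log_values
        Log-transformed concentrations (natural log of ng/g); n >= 6.
    init
        ``"best"`` (default) runs EM from three deterministic starts —
        median split, outer-quartile moment match, and a 1-D 2-means
        threshold split — and keeps the highest log-likelihood; the
        individual strategies are selectable by name. All are
        deterministic, so repeated fits are identical.
    tol
        Absolute log-likelihood change declaring convergence.
    n_restarts
        Perturbed re-initialisations attempted if every start collapses
        onto a single point (sigma -> 0); exhausting them raises
        :class:`FitError`.
    """
    x = np.asarray(log_values, dtype=float)
    if x.ndim != 1 or len(x) < 6:
        raise ValueError("need a 1-D sample of at least 6 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("log values must be finite")

    starts = _initial_params(x, init)
    n_deterministic = len(starts)
    rng = np.random.default_rng(restart_seed)
    mu0, sigma0, lam0 = starts[0]
    for _ in range(n_restarts):
        starts.append(
            (
                mu0 + rng.normal(0, x.std() / 4, size=2),
                sigma0 * rng.uniform(0.5, 2.0, size=2),
                lam0,
            )
        )

    best: MixtureFit | None = None
    for attempt, (mu, sigma, lam) in enumerate(starts):
        mu_f, sigma_f, lam_f, trace, n_iter, converged = _em(
            x, mu, sigma, lam, tol, max_iter
        )
        if not (np.all(sigma_f > 1e-8) and np.all(lam_f > 0)):
            continue  # degenerate collapse from this start
        order = np.argsort(mu_f)
        fit = MixtureFit(
            mu_low=float(mu_f[order[0]]),
            mu_high=float(mu_f[order[1]]),
            sigma_low=float(sigma_f[order[0]]),
            sigma_high=float(sigma_f[order[1]]),
            lambda_low=float(lam_f[order[0]]),
            lambda_high=float(lam_f[order[1]]),
            loglik_trace=trace,
            n_iter=n_iter,
            converged=converged,
        )
        if best is None or (fit.converged and not best.converged) or (
            fit.converged == best.converged and fit.loglik > best.loglik
        ):
            best = fit
        if best is not None and best.converged and attempt >= n_deterministic - 1:
            break  # deterministic starts exhausted with a usable optimum
    if best is None:
        raise FitError(
            f"EM collapsed to a degenerate solution from all {len(starts)} starts "
            f"(n={len(x)}, sd={x.std():.3g})"
        )
    return best


def pregnancy_probability(
    x, fit: MixtureFit, weighted: bool = True, require_converged: bool = True
):
    """Posterior probability of the high (pregnant) component at ``x`` ng/g.

    ``weighted=True`` (default) uses the mixing-weighted component densities
    ``lambda_k * phi_k``; ``weighted=False`` drops the weights (sensitivity
    variant). Accepts scalars or arrays; invariant to the logarithm base used
    for the transform since the Jacobian cancels in the density ratio.
    """
    if require_converged and not fit.converged:
        raise FitError("mixture fit did not converge; refusing probability")
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("concentrations must be positive")
    z = np.log(xa)
    mu, sigma, lam = fit._params()
    log_dens = _log_norm_pdf(z, mu, sigma)
    if weighted:
        log_dens = log_dens + np.log(lam)
    # p = exp(lh) / (exp(ll) + exp(lh)), computed stably in log space
    diff = log_dens[..., 0] - log_dens[..., 1]
    p = np.exp(-np.logaddexp(0.0, diff))
    return p if xa.ndim else float(p)


def threshold_at(
    fit: MixtureFit,
    p_target: float = 0.5,
    search_range: tuple[float, float] = (0.05, 500.0),
    weighted: bool = True,
) -> float:
    """Concentration (ng/g) at which p(x) crosses ``p_target``.

    Solved by bracketed root-finding on the log scale. The curve must cross
    the target exactly once on the search range; zero or multiple crossings
    raise with the crossings listed.
    """
    lo, hi = np.log(search_range[0]), np.log(search_range[1])

    def f(z: float) -> float:
        return pregnancy_probability(math.exp(z), fit, weighted=weighted) - p_target

    grid = np.linspace(lo, hi, 2048)
    vals = np.array([f(z) for z in grid])
    sign_flips = np.nonzero(np.diff(np.signbit(vals)))[0]
    if len(sign_flips) != 1:
        crossings = [float(np.exp(grid[i])) for i in sign_flips]
        raise ValueError(
            f"p(x) - {p_target} has {len(sign_flips)} crossings on "
            f"{search_range}: {crossings}"
        )
    i = sign_flips[0]
    z_root = brentq(f, grid[i], grid[i + 1], xtol=1e-12)
    return float(math.exp(z_root))


def overlap_coefficient(fit: MixtureFit) -> float:
    """Area under the pointwise minimum of the two weighted component curves.

    Integrates ``min(lambda_l phi_l, lambda_h phi_h)`` over the
    log-concentration line by adaptive quadrature — the overlap of the two
    cluster curves as drawn on a mixture density plot.
    """
    mu, sigma, lam = fit._params()
    lo = float(min(mu - 12 * sigma))
    hi = float(max(mu + 12 * sigma))

    def f(z: float) -> float:
        d = lam * norm.pdf(z, mu, sigma)
        return float(min(d[0], d[1]))

    # split at the crossing points of the weighted densities to help quad
    grid = np.linspace(lo, hi, 1024)
    d = lam * norm.pdf(grid[:, None], mu, sigma)
    s = np.signbit(d[:, 0] - d[:, 1])
    breaks = [float(grid[i]) for i in np.nonzero(np.diff(s))[0]]
    pts = [lo, *breaks, hi]
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += quad(f, a, b, limit=200)[0]
    return total


def categorize(probability: float, hi: float = 0.95, lo: float = 0.05) -> str:
    """Strictly above ``hi`` -> likely_pregnant, strictly below ``lo`` ->
    likely_non_pregnant, otherwise indeterminate (boundaries included)."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability out of [0,1]: {probability}")
    if probability > hi:
        return "likely_pregnant"
    if probability < lo:
        return "likely_non_pregnant"
    return "indeterminate"


def summarize_fit(fit: MixtureFit, coverage_z: float = 1.96) -> dict:
    """Fit summary on log and concentration scales.

    Back-transformed component means are geometric means; the component
    "95% interval" is the back-transformed mu +/- 1.96 sigma coverage
    interval of each normal component.
    """
    return {
        "log_scale": {
            "mu_low": fit.mu_low,
            "mu_high": fit.mu_high,
            "sigma_low": fit.sigma_low,
            "sigma_high": fit.sigma_high,
        },
        "lambda_low": fit.lambda_low,
        "lambda_high": fit.lambda_high,
        "geometric_mean_low_ng_g": math.exp(fit.mu_low),
        "geometric_mean_high_ng_g": math.exp(fit.mu_high),
        "coverage_low_ng_g": [
            math.exp(fit.mu_low - coverage_z * fit.sigma_low),
            math.exp(fit.mu_low + coverage_z * fit.sigma_low),
        ],
        "coverage_high_ng_g": [
            math.exp(fit.mu_high - coverage_z * fit.sigma_high),
            math.exp(fit.mu_high + coverage_z * fit.sigma_high),
        ],
        "loglik": fit.loglik,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
    }
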