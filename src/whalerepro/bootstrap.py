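"""Constrained percentile bootstrap for the pregnancy-probability curve.

Each replicate resamples the non-calf-female progesterone values with
replacement, refits the mixture, and evaluates the probability curve. Two
constraints stabilise the procedure on a sample with only four confirmed
pregnancies:

* the confirmed-pregnant whales are forced into every replicate (the random
  part of the resample has size n - n_forced, keeping the total at n);
* replicates whose fitted curve does not approach 1 at high progesterone
  (label-flipped or degenerate fits) are discarded. By default a replicate
  is retained when its probability curve is monotone increasing over the
  observed concentration range *and* reaches at least
  ``retention_min_probability`` at the reference concentration (defaulting
  to the highest observed value). ``require_monotone=False`` relaxes this
  to the end-point check alone; the strict limit form (p -> 1 iff
  sigma_high > sigma_low) is exposed as :func:`asymptotic_retention`.

The band is the pointwise 2.5th/97.5th percentile of the retained curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixture import FitError, MixtureFit, fit_mixture, pregnancy_probability

__all__ = ["BootstrapConfig", "BootstrapBand", "bootstrap_band", "attach_cis"]


@dataclass
class BootstrapConfig:
    n_replicates: int = 10_000
    seed: int = 0
    retention_ref_concentration: float | None = None  # None -> max observed
    retention_min_probability: float = 0.99
    require_monotone: bool = True
    forced_ids: tuple[str, ...] = ()
    grid_size: int = 200
    percentiles: tuple[float, float] = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class BootstrapBand:
    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    retained_fraction: float
    per_whale_ci: dict[str, tuple[float, float]]
    rejection_causes: dict[str, int] = field(default_factory=dict)
    n_replicates: int = 0


def bootstrap_band(
    ids,
    concentrations,
    cfg: BootstrapConfig,
    resample: bool = True,
) -> BootstrapBand:
    """Bootstrap the probability curve; see module docstring for the scheme.

    ``resample=False`` is the degenerate diagnostic mode: every replicate is
    the original sample, so the band collapses onto the point estimate.
    """
    ids = [str(i) for i in ids]
    x = np.asarray(concentrations, dtype=float)
    if len(ids) != len(x):
        raise ValueError("ids and concentrations differ in length")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if len(x) < 20:
        raise ValueError("need at least 20 values to bootstrap the curve")
    forced_idx = []
    for fid in cfg.forced_ids:
        if fid not in ids:
            raise ValueError(f"forced id {fid!r} not in dataset")
        forced_idx.append(ids.index(fid))
    forced_vals = x[forced_idx]

    ref = cfg.retention_ref_concentration or float(x.max())
    grid = np.exp(np.linspace(np.log(x.min()), np.log(x.max()), cfg.grid_size))
    eval_points = np.concatenate([grid, x])

    rng = np.random.default_rng(cfg.seed)
    n = len(x)
    n_random = n - len(forced_vals)
    curves = []
    causes = {
        "not_converged": 0,
        "retention_filter": 0,
        "not_monotone": 0,
        "degenerate": 0,
    }
    for _ in range(cfg.n_replicates):
        if resample:
            draw = rng.choice(x, size=n_random, replace=True)
            sample = np.concatenate([draw, forced_vals])
        else:
            sample = x
        try:
            fit = fit_mixture(np.log(sample))
        except FitError:
            causes["degenerate"] += 1
            continue
        if not fit.converged:
            causes["not_converged"] += 1
            continue
        curve = pregnancy_probability(eval_points, fit)
        if pregnancy_probability(ref, fit) < cfg.retention_min_probability:
            causes["retention_filter"] += 1
            continue
        if cfg.require_monotone and np.any(
            np.diff(curve[: cfg.grid_size]) < -1e-12
        ):
            causes["not_monotone"] += 1
            continue
        curves.append(curve)

    if not curves:
        raise RuntimeError(f"all {cfg.n_replicates} replicates rejected: {causes}")
    curve_mat = np.vstack(curves)
    lo_q, hi_q = cfg.percentiles
    lower = np.percentile(curve_mat, lo_q, axis=0, method="linear")
    upper = np.percentile(curve_mat, hi_q, axis=0, method="linear")
    per_whale = {
        wid: (float(lower[cfg.grid_size + j]), float(upper[cfg.grid_size + j]))
        for j, wid in enumerate(ids)
    }
    return BootstrapBand(
        grid=grid,
        lower=lower[: cfg.grid_size],
        upper=upper[: cfg.grid_size],
        retained_fraction=len(curves) / cfg.n_replicates,
        per_whale_ci=per_whale,
        rejection_causes=causes,
        n_replicates=cfg.n_replicates,
    )


def asymptotic_retention(fit: MixtureFit) -> bool:
    """Literal limit form of the retention rule: p(x) -> 1 as x -> infinity
    iff the high component has the heavier upper tail (sigma_high >
    sigma_low, or equal sigmas with mu_high > mu_low)."""
    if fit.sigma_high != fit.sigma_low:
        return fit.sigma_high > fit.sigma_low
    return fit.mu_high > fit.mu_low


def attach_cis(calls, band: BootstrapBand):
    """Populate ci_low/ci_high on each :class:`~whalerepro.pipeline.PregnancyCall`
    from the per-whale percentile intervals; probabilities are untouched."""
    out = []
    for call in calls:
        if call.whale_id not in band.per_whale_ci:
            raise KeyError(f"no bootstrap CI for whale {call.whale_id!r}")
        lo, hi = band.per_whale_ci[call.whale_id]
        out.append(call.with_ci(lo, hi))
    return out
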