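"""EIA plate processing: standard curves, validation tests and unit conversion.

Competitive enzyme immunoassays read out a binding fraction (signal relative
to the zero-standard B0 well) that falls with analyte dose along a
four-parameter logistic (4PL):

    y = d + (a - d) / (1 + (x / c)^b)

with asymptotes ``a`` (zero dose) and ``d`` (infinite dose), inflection
``c`` (the EC50, where binding is midway between the asymptotes) and hill
slope ``b``. Validation of an assay for a new matrix requires parallelism
(serially diluted pooled extract displaces binding with the same slope as
the standards) and accuracy (recovered vs added mass is linear with slope
near 1); per-sample QC gates on the duplicate-well coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SampleWell",
    "PlateData",
    "FourPLFit",
    "ParallelismResult",
    "four_pl",
    "fit_4pl",
    "parallelism_test",
    "accuracy_test",
    "duplicate_cv",
    "to_ng_per_g",
    "process_plate",
]

#: Standard-series design ranges (pg/ml) of the two assay kits.
STANDARD_RANGES = {"testosterone": (40.96, 10_000.0), "progesterone": (50.0, 3_200.0)}

#: Intra-assay duplicate CV threshold (percent) above which a sample is re-assayed.
CV_THRESHOLD_PERCENT = 10.0


class AssayError(ValueError):
    pass


@dataclass
class SampleWell:
    """Duplicate-well measurement of one extract on a plate."""

    sample_id: str
    duplicate_readings: tuple[float, float]  # raw assay concentrations, pg/ml
    dilution_factor: float = 1.0
    extract_volume_ml: float = 1.0
    blubber_mass_g: float = 0.1

    def __post_init__(self) -> None:
        if len(self.duplicate_readings) != 2:
            raise AssayError(f"{self.sample_id}: exactly two duplicates required")
        if self.blubber_mass_g <= 0:
            raise AssayError(f"{self.sample_id}: blubber mass must be positive")
        if self.dilution_factor <= 0 or self.extract_volume_ml <= 0:
            raise AssayError(f"{self.sample_id}: factors must be positive")


@dataclass
class PlateData:
    hormone: str
    standards: list[tuple[float, float]]  # (concentration pg/ml, mean binding fraction)
    samples: list[SampleWell]
    b0: float = 1.0

    def __post_init__(self) -> None:
        if self.hormone not in STANDARD_RANGES:
            raise AssayError(f"unknown hormone {self.hormone!r}")
        if len(self.standards) < 7:
            raise AssayError("standard series needs at least 7 points")
        for conc, y in self.standards:
            if not 0.0 <= y <= 1.0:
                raise AssayError(f"binding fraction out of [0,1] at {conc} pg/ml")


@dataclass
class FourPLFit:
    lower_asymptote: float
    upper_asymptote: float
    ec50: float
    slope: float
    rss: float
    slope_se: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return four_pl(
            np.asarray(x, float),
            self.upper_asymptote,
            self.lower_asymptote,
            self.ec50,
            self.slope,
        )

    def invert(self, y: float) -> float:
        """Dose at binding ``y`` (between the asymptotes)."""
        a, d, c, b = self.upper_asymptote, self.lower_asymptote, self.ec50, self.slope
        if not min(a, d) < y < max(a, d):
            raise AssayError(f"binding {y} outside asymptotes ({d}, {a})")
        return c * ((a - d) / (y - d) - 1.0) ** (1.0 / b)


@dataclass
class ParallelismResult:
    slope_standard: float
    slope_pool: float
    t_statistic: float
    p_value: float
    parallel: bool
    method: str
    df: int


def four_pl(x, a, d, c, b):
    """4PL response: ``a`` at zero dose, ``d`` at infinite dose."""
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(standards) -> FourPLFit:
    """Least-squares 4PL fit of (concentration, binding) points.

    At the fitted EC50 the predicted binding is midway between the
    asymptotes, by construction of the functional form.
    """
    pts = np.asarray(standards, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 4:
        raise AssayError("need at least 4 distinct concentrations")
    a0, d0 = float(y.max()), float(y.min())
    c0 = float(np.exp(np.mean(np.log(x[x > 0]))))
    try:
        popt, pcov = optimize.curve_fit(
            four_pl,
            x,
            y,
            p0=[a0, d0, c0, 1.0],
            bounds=([-np.inf, -np.inf, 1e-12, 1e-6], [np.inf, np.inf, np.inf, 50.0]),
            maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise AssayError(
            f"4PL fit failed to converge on {len(x)} points "
            f"(range {x.min():g}-{x.max():g} pg/ml): {exc}"
        ) from exc
    a, d, c, b = popt
    resid = y - four_pl(x, *popt)
    slope_se = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else np.nan
    return FourPLFit(
        lower_asymptote=float(min(a, d)),
        upper_asymptote=float(max(a, d)),
        ec50=float(c),
        slope=float(b),
        rss=float(resid @ resid),
        slope_se=slope_se,
        n_points=len(x),
    )


def _linear_slope_80_20(points) -> tuple[float, float, int]:
    """OLS slope of logit(binding) on log dose, restricted to the 20–80 %
    binding window (the linear region of a competitive EIA)."""
    pts = np.asarray(points, dtype=float)
    mask = (pts[:, 1] >= 0.2) & (pts[:, 1] <= 0.8) & (pts[:, 0] > 0)
    if mask.sum() < 3:
        raise AssayError(
            f"only {int(mask.sum())} points inside the 80-20% binding window; need >= 3"
        )
    x = np.log(pts[mask, 0])
    y = np.log(pts[mask, 1] / (1.0 - pts[mask, 1]))
    res = stats.linregress(x, y)
    n = int(mask.sum())
    return float(res.slope), float(res.stderr), n


def parallelism_test(
    standard_points, pool_points, method: str = "linear_80_20", alpha: float = 0.05
) -> ParallelismResult:
    """Student's t-test for equality of displacement slopes.

    ``linear_80_20``: slopes of the logit-log linearisation inside the
    80-20 % binding window, pooled-variance t with df = n1 + n2 - 4.
    ``fourpl_slope``: hill slopes of separate 4PL fits, t from the two
    slope standard errors with df = n1 + n2 - 8.
    A non-significant difference (p > alpha) is evidence of parallelism.
    """
    if method == "linear_80_20":
        b1, se1, n1 = _linear_slope_80_20(standard_points)
        b2, se2, n2 = _linear_slope_80_20(pool_points)
        df = n1 + n2 - 4
    elif method == "fourpl_slope":
        f1, f2 = fit_4pl(standard_points), fit_4pl(pool_points)
        b1, se1, n1 = f1.slope, f1.slope_se, f1.n_points
        b2, se2, n2 = f2.slope, f2.slope_se, f2.n_points
        df = n1 + n2 - 8
    else:
        raise ValueError(f"unknown parallelism method {method!r}")
    if df < 1:
        raise AssayError("not enough points for the slope comparison")
    t = (b1 - b2) / math.hypot(se1, se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return ParallelismResult(
        slope_standard=b1,
        slope_pool=b2,
        t_statistic=float(t),
        p_value=float(p),
        parallel=bool(p > alpha),
        method=method,
        df=df,
    )


def accuracy_test(spiked) -> tuple[float, float, float]:
    """OLS of recovered vs added hormone mass: (slope, intercept, R^2)."""
    pts = np.asarray(spiked, dtype=float)
    if len(pts) < 3:
        raise AssayError("need at least 3 spiked standards")
    if np.ptp(pts[:, 0]) == 0:
        raise AssayError("added masses have zero variance")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def duplicate_cv(well: SampleWell) -> tuple[float, bool]:
    """Percent CV of the two duplicate readings; pass iff CV <= 10 %."""
    r = np.asarray(well.duplicate_readings, dtype=float)
    if np.any(r <= 0):
        raise AssayError(f"{well.sample_id}: nonpositive duplicate reading")
    cv = float(r.std(ddof=1) / r.mean() * 100.0)
    return cv, cv <= CV_THRESHOLD_PERCENT


def to_ng_per_g(well: SampleWell, assay_conc_pg_ml: float) -> float:
    """Blubber concentration in ng/g from the raw assay reading.

    ng/g = pg/ml * extract volume (ml) * dilution factor / (mass (g) * 1000);
    the 1000 converts pg to ng.
    """
    if assay_conc_pg_ml < 0:
        raise AssayError("assay concentration must be nonnegative")
    return (
        assay_conc_pg_ml
        * well.extract_volume_ml
        * well.dilution_factor
        / (well.blubber_mass_g * 1000.0)
    )


def process_plate(plate: PlateData):
    """Fit the standard curve and convert every sample to ng/g with QC flags.

    Returns (FourPLFit, rows) where each row carries the mean duplicate
    reading, CV, pass flag and final blubber concentration.
    """
    curve = fit_4pl(plate.standards)
    rows = []
    for well in plate.samples:
        cv, ok = duplicate_cv(well)
        mean_pg_ml = float(np.mean(well.duplicate_readings))
        rows.append(
            {
                "sample_id": well.sample_id,
                "mean_pg_ml": mean_pg_ml,
                "cv_percent": cv,
                "cv_pass": ok,
                "reassay": not ok,
                "concentration_ng_g": to_ng_per_g(well, mean_pg_ml),
            }
        )
    return curve, rows
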