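"""Synthetic gray-whale cohorts and EIA plates with the structure the
analysis assumes.

The generator emulates the features the pipeline exploits: log progesterone
in non-calf females follows a two-component normal mixture (low non-pregnant
cluster, high pregnant cluster) with defaults pinned to the fitted field
data (geometric means ~2.0 and ~16.9 ng/g); calves of both sexes carry
maternally transferred progesterone; adult males show a fall testosterone
elevation; sighting metadata is generated consistently with each class, so
the life-history rules recover the classes that generated the hormones.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np

from .assay_qc import PlateData, SampleWell, STANDARD_RANGES, four_pl
from .records import Area, FeedingGroup, Sex, WhaleRecord

__all__ = ["SyntheticConfig", "generate_cohort", "generate_plate"]

#: Female class mix of the field dataset (n = 66).
_DEFAULT_FEMALE_PROPORTIONS = {
    "calf": 4 / 66,
    "immature": 6 / 66,
    "lactating": 6 / 66,
    "pregnant": 4 / 66,
    "adult_unknown": 26 / 66,
    "unknown": 20 / 66,
}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the field-data structure."""

    n_females: int = 66
    n_males: int = 40
    class_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_FEMALE_PROPORTIONS)
    )
    # log-scale progesterone mixture (natural log of ng/g)
    prog_mu_low: float = math.log(2.0)
    prog_sigma_low: float = 0.61
    prog_mu_high: float = math.log(16.9)
    prog_sigma_high: float = 0.64
    lambda_high: float = 0.31
    # testosterone structure (log ng/g): adult-male seasonal means, immature level
    testo_mu_adult_summer: float = math.log(0.7)
    testo_mu_adult_fall: float = math.log(3.9)
    testo_mu_immature: float = math.log(0.4)
    testo_sigma: float = 0.8
    calf_maternal_elevation: float = 2.3  # multiplier on the low-cluster draw
    assay_cv: float = 0.05  # duplicate-well relative noise
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        for name in ("prog_sigma_low", "prog_sigma_high", "testo_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.lambda_high <= 1.0:
            raise ValueError("lambda_high must be in [0, 1]")


def _sampling_date(rng: np.random.Generator) -> dt.date:
    """Uniform date over the field season (mid-June to mid-November)."""
    start = dt.date(2015, 6, 15)
    return start + dt.timedelta(days=int(rng.integers(0, 154)))


def _noisy(value: float, cv: float, rng: np.random.Generator) -> float:
    if cv <= 0:
        return value
    return float(value * rng.lognormal(-0.5 * cv**2, cv))


def generate_cohort(cfg: SyntheticConfig, return_truth: bool = False):
    """Draw a cohort of whale records (and optionally the latent truth).

    Pregnant females (and the latent-pregnant fraction of unknown-status
    females, drawn Bernoulli(lambda_high)) take log progesterone from the
    high component; other non-calf females from the low component; calves
    from the low component times the maternal-transfer multiplier.
    ``return_truth`` additionally returns a list of dicts with each whale's
    class and latent pregnancy state.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[c] for c in classes])
    records: list[WhaleRecord] = []
    truth: list[dict] = []

    draws = rng.choice(len(classes), size=cfg.n_females, p=probs)
    for i, ci in enumerate(draws):
        cls = classes[ci]
        date = _sampling_date(rng)
        if cls == "pregnant":
            pregnant = True
        elif cls in ("calf", "immature", "lactating"):
            pregnant = False
        else:  # unknown-status whales come from the weighted mixture
            pregnant = bool(rng.random() < cfg.lambda_high)
        if cls == "calf":
            z = rng.normal(cfg.prog_mu_low, cfg.prog_sigma_low) + math.log(
                cfg.calf_maternal_elevation
            )
        elif pregnant:
            z = rng.normal(cfg.prog_mu_high, cfg.prog_sigma_high)
        else:
            z = rng.normal(cfg.prog_mu_low, cfg.prog_sigma_low)
        prog = _noisy(math.exp(z), cfg.assay_cv, rng)

        kw: dict = {
            "whale_id": f"F{i:04d}",
            "sex": Sex.female,
            "feeding_group": FeedingGroup.PCFG,
            "area": Area.WA,
            "sampling_date": date,
            "progesterone_ng_g": prog,
        }
        if cls == "calf":
            kw.update(sampled_as_calf=True, first_seen_as_calf=True, known_age_years=0)
        elif cls == "immature":
            kw.update(
                first_seen_as_calf=True,
                known_age_years=int(rng.integers(1, 8)),
            )
            kw["lsh_years"] = kw["known_age_years"]
        elif cls == "lactating":
            kw.update(lsh_years=int(rng.integers(8, 26)), with_calf_sampling_year=True)
        elif cls == "pregnant":
            kw.update(
                lsh_years=int(rng.integers(8, 26)),
                with_calf_next_year=True,
                resight_year=date.year + 1,
            )
        elif cls == "adult_unknown":
            kw.update(lsh_years=int(rng.integers(8, 26)))
        else:
            kw.update(lsh_years=int(rng.integers(0, 8)))
        records.append(WhaleRecord(**kw))
        truth.append({"whale_id": kw["whale_id"], "class": cls, "pregnant": pregnant})

    male_classes = ["calf", "immature", "adult", "unknown"]
    male_probs = np.array([4, 6, 16, 14]) / 40.0
    mdraws = rng.choice(4, size=cfg.n_males, p=male_probs)
    for i, ci in enumerate(mdraws):
        cls = male_classes[ci]
        date = _sampling_date(rng)
        from .life_history import assign_season  # local import avoids a cycle

        season = assign_season(date)
        if cls == "adult":
            mu_t = (
                cfg.testo_mu_adult_fall
                if season.value == "fall"
                else cfg.testo_mu_adult_summer
            )
        else:
            mu_t = cfg.testo_mu_immature
        testo = _noisy(
            math.exp(rng.normal(mu_t, cfg.testo_sigma)), cfg.assay_cv, rng
        )
        kw = {
            "whale_id": f"M{i:04d}",
            "sex": Sex.male,
            "sampling_date": date,
            "testosterone_ng_g": testo,
        }
        if cls == "calf":
            kw.update(sampled_as_calf=True, first_seen_as_calf=True, known_age_years=0)
            z = rng.normal(cfg.prog_mu_low, cfg.prog_sigma_low) + math.log(
                cfg.calf_maternal_elevation
            )
            kw["progesterone_ng_g"] = _noisy(math.exp(z), cfg.assay_cv, rng)
        elif cls == "immature":
            kw.update(first_seen_as_calf=True, known_age_years=int(rng.integers(1, 8)))
            kw["lsh_years"] = kw["known_age_years"]
        elif cls == "adult":
            kw.update(lsh_years=int(rng.integers(8, 23)))
        else:
            kw.update(lsh_years=int(rng.integers(0, 8)))
        records.append(WhaleRecord(**kw))
        truth.append({"whale_id": kw["whale_id"], "class": cls, "pregnant": False})

    if return_truth:
        return records, truth
    return records


def generate_plate(
    cfg: SyntheticConfig,
    true_concentrations_ng_g,
    hormone: str = "progesterone",
    blubber_mass_g: float = 0.10,
    dilution_factor: float = 1.0,
    standard_noise_sd: float = 0.003,
) -> PlateData:
    """Simulate an EIA plate measuring the given true blubber concentrations.

    Standards follow a reference 4PL over the kit's design range with small
    additive read noise; each sample appears as duplicate raw readings
    (pg/ml) whose relative spread is ``cfg.assay_cv``. Round-tripping the
    plate through the QC module recovers the true values to within that
    noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = STANDARD_RANGES[hormone]
    concs = np.exp(np.linspace(np.log(lo), np.log(hi), 7))
    ec50 = float(np.exp(0.5 * (np.log(lo) + np.log(hi))))
    curve = lambda x: four_pl(x, 0.95, 0.03, ec50, 1.1)  # noqa: E731
    standards = [
        (float(c), float(np.clip(curve(c) + rng.normal(0, standard_noise_sd), 0, 1)))
        for c in concs
    ]
    samples = []
    for j, true_ng_g in enumerate(np.asarray(true_concentrations_ng_g, float)):
        if true_ng_g <= 0:
            raise ValueError("true concentrations must be positive")
        true_pg_ml = true_ng_g * blubber_mass_g * 1000.0 / (1.0 * dilution_factor)
        dup = tuple(
            float(true_pg_ml * rng.lognormal(-0.5 * cfg.assay_cv**2, cfg.assay_cv))
            for _ in range(2)
        ) if cfg.assay_cv > 0 else (float(true_pg_ml), float(true_pg_ml))
        samples.append(
            SampleWell(
                sample_id=f"S{j:03d}",
                duplicate_readings=dup,
                dilution_factor=dilution_factor,
                extract_volume_ml=1.0,
                blubber_mass_g=blubber_mass_g,
            )
        )
    return PlateData(hormone=hormone, standards=standards, samples=samples, b0=1.0)
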