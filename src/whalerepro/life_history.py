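"""Age-class, reproductive-state and season assignment from sighting history.

Gray whales cannot be aged directly from a biopsy, so age class is inferred
from photo-identification records: whales first documented as calves have a
known age; for the rest, the length of sighting history (LSH, years since
first identification) is a lower bound on age. The mean age of sexual
maturity in this species is 8 years, which sets the adult/immature cutoff.

Reproductive state for adult females comes from calf associations: a female
sighted with a calf the year *after* sampling was pregnant when biopsied; one
accompanied by a calf in the sampling year was lactating. Calves, immatures
and lactating females are known non-pregnant.
"""

from __future__ import annotations

import datetime as dt
import warnings
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    AgeClass,
    ClassificationError,
    ReproState,
    Season,
    Sex,
    WhaleRecord,
)

#: Age (years) at which gray whales are classified adult.
ADULT_AGE_YEARS = 8

# Season windows (month, day), both ends inclusive.
_SUMMER = ((6, 15), (9, 21))
_FALL = ((9, 22), (11, 15))


def classify_age_class(record: WhaleRecord) -> AgeClass:
    """Assign calf / immature / adult / unknown from sighting metadata.

    Known age (available only for whales first seen as calves) takes
    precedence over LSH; a known-age juvenile with adult-length LSH is
    contradictory and rejected.
    """
    if record.sampled_as_calf:
        return AgeClass.calf
    if record.known_age_years is not None:
        if record.known_age_years < ADULT_AGE_YEARS:
            if record.lsh_years >= ADULT_AGE_YEARS:
                raise ClassificationError(
                    f"{record.whale_id}: known age {record.known_age_years} < "
                    f"{ADULT_AGE_YEARS} but LSH {record.lsh_years} years"
                )
            return AgeClass.immature
        return AgeClass.adult
    if record.lsh_years >= ADULT_AGE_YEARS:
        return AgeClass.adult
    return AgeClass.unknown


def classify_repro_state(record: WhaleRecord, age: AgeClass | None = None) -> ReproState:
    """Assign reproductive state for a female; males mirror their age class.

    Calf associations decide the state of adults: next-year calf means
    pregnant at sampling, same-year calf means lactating. The two flags are
    mutually exclusive by construction of the sighting data.
    """
    if age is None:
        age = classify_age_class(record)
    if record.with_calf_next_year and record.with_calf_sampling_year:
        raise ClassificationError(
            f"{record.whale_id}: with_calf_next_year and with_calf_sampling_year both set"
        )
    if record.sex is Sex.male:
        return ReproState(age.value) if age in (AgeClass.calf, AgeClass.immature) else (
            ReproState.adult_unknown if age is AgeClass.adult else ReproState.unknown
        )
    if age is AgeClass.calf:
        return ReproState.calf
    if age is AgeClass.immature:
        return ReproState.immature
    if record.with_calf_next_year:
        return ReproState.pregnant
    if record.with_calf_sampling_year:
        return ReproState.lactating
    if age is AgeClass.adult:
        return ReproState.adult_unknown
    return ReproState.unknown


def assign_season(date: dt.date) -> Season:
    """Summer = Jun 15 – Sep 21, fall = Sep 22 – Nov 15 (inclusive)."""
    md = (date.month, date.day)
    if _SUMMER[0] <= md <= _SUMMER[1]:
        return Season.summer
    if _FALL[0] <= md <= _FALL[1]:
        return Season.fall
    return Season.other


NON_PREGNANT_STATES = frozenset(
    {ReproState.calf, ReproState.immature, ReproState.lactating}
)


def classify_records(records: Iterable[WhaleRecord]) -> pd.DataFrame:
    """Classify every record; returns a frame with age_class / repro_state /
    season columns appended to the key fields."""
    rows = []
    for r in records:
        age = classify_age_class(r)
        state = classify_repro_state(r, age)
        season = assign_season(r.sampling_date) if r.sampling_date else None
        rows.append(
            {
                "whale_id": r.whale_id,
                "feeding_group": r.feeding_group.value,
                "sex": r.sex.value,
                "age_class": age.value,
                "repro_state": state.value,
                "season": season.value if season else None,
                "sampling_date": r.sampling_date.isoformat() if r.sampling_date else None,
                "area": r.area.value,
                "progesterone_ng_g": r.progesterone_ng_g,
                "testosterone_ng_g": r.testosterone_ng_g,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    records: Sequence[WhaleRecord], hormone: str = "progesterone"
) -> pd.DataFrame:
    """Per (age class, reproductive state) arithmetic mean and range in ng/g.

    Groups with no measured value for the hormone are omitted with a warning.
    """
    col = f"{hormone}_ng_g"
    if col not in ("progesterone_ng_g", "testosterone_ng_g"):
        raise ValueError(f"unknown hormone {hormone!r}")
    classified = classify_records(records)
    classified = classified.dropna(subset=[col])
    all_groups = {
        (classify_age_class(r).value, classify_repro_state(r).value) for r in records
    }
    out = []
    for (age, state), grp in classified.groupby(["age_class", "repro_state"]):
        vals = grp[col]
        out.append(
            {
                "age_class": age,
                "repro_state": state,
                "n": len(vals),
                "mean": vals.mean(),
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    present = {(r["age_class"], r["repro_state"]) for r in out}
    for missing in sorted(all_groups - present):
        warnings.warn(f"group {missing} has no {hormone} values; omitted", stacklevel=2)
    return pd.DataFrame(out).sort_values(["age_class", "repro_state"]).reset_index(drop=True)


def deduplicate(records: Sequence[WhaleRecord]) -> tuple[list[WhaleRecord], list[WhaleRecord]]:
    """One record per individual for the main analyses.

    Keeps the biopsy whose age class or reproductive state is determined;
    among equally-informative biopsies, the earliest. Returns (kept, repeats)
    so repeated samples can be analysed separately.
    """
    by_id: dict[str, list[WhaleRecord]] = defaultdict(list)
    for r in records:
        by_id[r.whale_id].append(r)

    def informative(r: WhaleRecord) -> bool:
        age = classify_age_class(r)
        state = classify_repro_state(r, age)
        return age is not AgeClass.unknown or state is not ReproState.unknown

    kept, repeats = [], []
    for rid, group in by_id.items():
        group = sorted(group, key=lambda r: r.sampling_date or dt.date.min)
        known = [r for r in group if informative(r)]
        chosen = known[0] if known else group[0]
        kept.append(chosen)
        if len(group) > 1:
            repeats.extend(group)
    return kept, repeats
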