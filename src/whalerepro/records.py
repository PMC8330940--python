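"""Core record types and CSV round-trip for the gray-whale biopsy dataset.

Each biopsy is one :class:`WhaleRecord`. Sighting-history metadata (length of
sighting history, calf associations, known age) carries the information needed
to place a whale in an age class and reproductive state; hormone concentrations
are blubber values in ng/g.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class FeedingGroup(str, enum.Enum):
    """Population subgroup the whale is assigned to by photo-ID/genetics."""

    PCFG = "PCFG"
    NPS = "NPS"
    ENP = "ENP"
    PCFG_NPS = "PCFG-NPS"


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Area(str, enum.Enum):
    CA = "CA"
    OR = "OR"
    WA = "WA"
    BC = "BC"
    AK = "AK"


class AgeClass(str, enum.Enum):
    calf = "calf"
    immature = "immature"
    adult = "adult"
    unknown = "unknown"


class ReproState(str, enum.Enum):
    calf = "calf"
    immature = "immature"
    lactating = "lactating"
    pregnant = "pregnant"
    adult_unknown = "adult_unknown"
    unknown = "unknown"


class Season(str, enum.Enum):
    summer = "summer"
    fall = "fall"
    other = "other"


class ClassificationError(ValueError):
    """A record is missing or contradicts the fields classification needs."""


@dataclass
class WhaleRecord:
    """One biopsied individual with sighting history and hormone values.

    ``lsh_years`` (length of sighting history) is a lower bound on age;
    ``known_age_years`` is only available for whales first seen as calves.
    Hormone concentrations are strictly positive when present, ``None`` when
    the assay was not run or did not detect the hormone.
    """

    whale_id: str
    feeding_group: FeedingGroup = FeedingGroup.PCFG
    sex: Sex = Sex.female
    first_seen_as_calf: bool = False
    known_age_years: int | None = None
    lsh_years: int = 0
    sampled_as_calf: bool = False
    with_calf_sampling_year: bool = False
    with_calf_next_year: bool = False
    resight_year: int | None = None
    sampling_date: dt.date | None = None
    area: Area = Area.WA
    progesterone_ng_g: float | None = None
    testosterone_ng_g: float | None = None

    def __post_init__(self) -> None:
        if self.known_age_years is not None and not self.first_seen_as_calf:
            raise ClassificationError(
                f"{self.whale_id}: known_age_years requires first_seen_as_calf"
            )
        for name in ("progesterone_ng_g", "testosterone_ng_g"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ClassificationError(f"{self.whale_id}: {name} must be > 0, got {v}")


_BOOL_COLS = (
    "first_seen_as_calf",
    "sampled_as_calf",
    "with_calf_sampling_year",
    "with_calf_next_year",
)
_OPT_INT = ("known_age_years", "resight_year")
_OPT_FLOAT = ("progesterone_ng_g", "testosterone_ng_g")


def records_to_frame(records: Iterable[WhaleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {}
        for f in fields(r):
            v = getattr(r, f.name)
            if isinstance(v, enum.Enum):
                v = v.value
            elif isinstance(v, dt.date):
                v = v.isoformat()
            row[f.name] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[WhaleRecord]:
    records = []
    for _, row in df.iterrows():
        kw: dict = {"whale_id": str(row["whale_id"])}
        kw["feeding_group"] = FeedingGroup(row.get("feeding_group", "PCFG"))
        kw["sex"] = Sex(row.get("sex", "female"))
        kw["area"] = Area(row.get("area", "WA"))
        for name in _BOOL_COLS:
            if name in row and not pd.isna(row[name]):
                v = row[name]
                kw[name] = v if isinstance(v, bool) else str(v).lower() in ("true", "1")
        if "lsh_years" in row and not pd.isna(row["lsh_years"]):
            kw["lsh_years"] = int(row["lsh_years"])
        for name in _OPT_INT:
            if name in row and not pd.isna(row[name]):
                kw[name] = int(row[name])
        for name in _OPT_FLOAT:
            if name in row and not pd.isna(row[name]):
                kw[name] = float(row[name])
        if "sampling_date" in row and not pd.isna(row["sampling_date"]):
            kw["sampling_date"] = dt.date.fromisoformat(str(row["sampling_date"]))
        records.append(WhaleRecord(**kw))
    return records


def read_records(path: str | Path) -> list[WhaleRecord]:
    """Read a one-row-per-biopsy CSV (ISO-8601 dates) into records."""
    df = pd.read_csv(path, dtype={"whale_id": str}, float_precision="round_trip")
    return frame_to_records(df)


def write_records(records: Sequence[WhaleRecord], path: str | Path) -> None:
    # %.17g guarantees float64 round-trip through the CSV
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")
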