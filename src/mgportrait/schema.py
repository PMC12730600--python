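"""Instrument definitions and long-format score tables for MG outcome measures.

The four instruments handled here are the ones routinely collected in
myasthenia gravis trials:

* **MG-ADL** — 8-item patient-reported activities-of-daily-living scale,
  each item scored 0 (normal) to 3 (severe);
* **QMG** — 13-item examiner-performed quantitative muscle assessment,
  each item 0..3;
* **MG-CE** — 8-item core examination adapted to telemedicine, 0..3;
* **MG-QOL15** — 15-item patient-reported quality-of-life scale, 0..4.

Items that probe the same anatomical function are tagged with a muscle
group (1 = ocular, 2 = arm/grip, 3 = respiratory, 4 = legs / sit-to-stand,
5 = sustained speech, 6 = bulbar/facial); items without a clear anatomical
assignment carry ``muscle_group=None``.

Score data live in a long-format table: one row per
(patient, visit month, instrument, item, optional rater) with an integer
value, or an empty cell for a missing score.  Missing values are *never*
encoded as sentinel numbers because 0 is a valid score.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Item",
    "Instrument",
    "ScoreTable",
    "SchemaError",
    "ValidationError",
    "builtin_instruments",
    "get_instrument",
    "read_scores",
    "write_scores",
    "total_score",
    "snap_visit_months",
    "QMG_LR_PAIRS",
    "COLUMNS",
]

COLUMNS = ["patient_id", "visit_month", "instrument", "item_id", "rater_id", "value"]

#: left/right QMG item pairs that assess the same muscle group bilaterally
QMG_LR_PAIRS = (
    ("left_leg", "right_leg"),
    ("left_arm", "right_arm"),
    ("left_grip", "right_grip"),
)


class SchemaError(ValueError):
    """Unknown instrument or item, or an ill-formed instrument definition."""


class ValidationError(ValueError):
    """A score table violates a domain or uniqueness invariant."""


@dataclass(frozen=True)
class Item:
    """One scored test within an instrument.

    Parameters
    ----------
    item_id:
        Short key, unique within the instrument.
    label:
        Human-readable name.
    lo, hi:
        Inclusive bounds of the contiguous integer score domain.
    muscle_group:
        Anatomical group 1..6 shared across instruments, or ``None``.
    """

    item_id: str
    label: str
    lo: int = 0
    hi: int = 3
    muscle_group: int | None = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise SchemaError(f"item {self.item_id!r}: need lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def n_levels(self) -> int:
        return self.hi - self.lo + 1

    @property
    def domain(self) -> range:
        return range(self.lo, self.hi + 1)

    def contains(self, value: float) -> bool:
        return float(value).is_integer() and self.lo <= value <= self.hi


@dataclass(frozen=True)
class Instrument:
    name: str
    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SchemaError(f"instrument {self.name!r}: duplicate item ids")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def total_max(self) -> int:
        return sum(it.hi for it in self.items)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise SchemaError(f"instrument {self.name!r} has no item {item_id!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "total_max": self.total_max,
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "lo": it.lo,
                    "hi": it.hi,
                    "muscle_group": it.muscle_group,
                }
                for it in self.items
            ],
        }


def _adl(hi: int = 3) -> Instrument:
    mk = lambda i, label, g: Item(i, label, 0, hi, g)  # noqa: E731
    return Instrument(
        "MG-ADL",
        (
            mk("talking", "Talking", 6),
            mk("chewing", "Chewing", 6),
            mk("swallowing", "Swallowing", 6),
            mk("breathing", "Breathing", 3),
            mk("brush_teeth", "Brush teeth / comb hair", 2),
            mk("sit_to_stand", "Sit to stand", 4),
            mk("double_vision", "Double vision", 1),
            mk("eyelid_drop", "Eyelid drop", 1),
        ),
    )


def _qmg(hi: int = 3) -> Instrument:
    mk = lambda i, label, g: Item(i, label, 0, hi, g)  # noqa: E731
    return Instrument(
        "QMG",
        (
            mk("left_leg", "Left leg outstretched", 4),
            mk("right_leg", "Right leg outstretched", 4),
            mk("head", "Head lift", None),
            mk("left_grip", "Left hand grip", 2),
            mk("right_grip", "Right hand grip", 2),
            mk("vital", "Vital capacity", 3),
            mk("left_arm", "Left arm outstretched", 2),
            mk("right_arm", "Right arm outstretched", 2),
            mk("speech", "Speech (dysarthria)", 5),
            mk("swallow", "Swallowing", 6),
            mk("facial", "Facial muscles", 6),
            mk("ptosis", "Ptosis (upward gaze)", 1),
            mk("vision", "Double vision (lateral gaze)", 1),
        ),
    )


def _mgce(hi: int = 3) -> Instrument:
    mk = lambda i, label, g: Item(i, label, 0, hi, g)  # noqa: E731
    return Instrument(
        "MG-CE",
        (
            mk("ptosis", "Ptosis", 1),
            mk("diplopia", "Diplopia", 1),
            mk("cheek_puff", "Cheek puff", None),
            mk("tongue_to_cheek", "Tongue to cheek", 6),
            mk("count_to_50", "Count to 50", 5),
            mk("arm_fatigue", "Arm fatigue", 2),
            mk("single_breath", "Single breath count", 3),
            mk("sit_to_stand", "Sit to stand", 4),
        ),
    )


_QOL_ITEMS = (
    ("frustration", "Frustrated by my MG"),
    ("eyes", "Trouble with my eyes"),
    ("eating", "Trouble eating"),
    ("social_activity", "Limited social activity"),
    ("hobbies", "Limited hobbies / fun activities"),
    ("family_duties", "Trouble meeting family needs"),
    ("making_plans", "Have to make plans around my MG"),
    ("work_ability", "Occupational skills / job status affected"),
    ("speaking", "Difficulty speaking"),
    ("autonomy", "Trouble driving / loss of autonomy"),
    ("depression", "Depressed about my MG"),
    ("walking", "Trouble walking"),
    ("moving_around", "Trouble getting around public places"),
    ("overwhelmed", "Overwhelmed by my MG"),
    ("grooming", "Trouble performing personal grooming"),
)


def _qol(hi: int = 4) -> Instrument:
    return Instrument(
        "MG-QOL15",
        tuple(Item(i, label, 0, hi, None) for i, label in _QOL_ITEMS),
    )


def builtin_instruments() -> list[Instrument]:
    """The four MG instruments with their item inventories and muscle groups.

    Item score domains default to 0..3 for MG-ADL, QMG and MG-CE and 0..4
    for MG-QOL15; pass custom :class:`Instrument` objects downstream if a
    study uses different granularity.
    """
    return [_adl(), _qmg(), _mgce(), _qol()]


_BUILTIN: dict[str, Instrument] = {ins.name: ins for ins in builtin_instruments()}


def get_instrument(name: str, instruments: Iterable[Instrument] | None = None) -> Instrument:
    if instruments is not None:
        for ins in instruments:
            if ins.name == name:
                return ins
        raise SchemaError(f"unknown instrument {name!r}")
    try:
        return _BUILTIN[name]
    except KeyError:
        raise SchemaError(f"unknown instrument {name!r}") from None


def export_instruments_json(path: str | Path, instruments: Iterable[Instrument] | None = None) -> None:
    """Write instrument definitions as JSON for audit."""
    instruments = list(instruments) if instruments is not None else builtin_instruments()
    Path(path).write_text(
        json.dumps([ins.to_dict() for ins in instruments], indent=2, sort_keys=True) + "\n"
    )


def snap_visit_months(
    months: Sequence[float], schedule: Sequence[float], window: float = 1.0
) -> np.ndarray:
    """Snap real-valued visit months to the nearest scheduled visit.

    Real visits rarely land exactly on protocol months; a month within
    ``window`` of a scheduled visit is snapped to it, otherwise the raw
    month is kept so no record is discarded.
    """
    sched = np.asarray(sorted(schedule), dtype=float)
    m = np.asarray(months, dtype=float)
    idx = np.clip(np.searchsorted(sched, m), 0, len(sched) - 1)
    idx_lo = np.clip(idx - 1, 0, len(sched) - 1)
    pick = np.where(np.abs(sched[idx] - m) <= np.abs(sched[idx_lo] - m), idx, idx_lo)
    snapped = sched[pick]
    return np.where(np.abs(snapped - m) <= window, snapped, m)


class ScoreTable:
    """Long-format table of ordinal item scores.

    One row per (patient, visit month, instrument, item, optional rater).
    All invariants are validated at construction: values lie in their
    item's domain, keys are unique, and visit months are non-negative.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        instruments: Sequence[Instrument] | None = None,
        validate: bool = True,
    ) -> None:
        df = df.copy()
        missing_cols = [c for c in COLUMNS if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"score table missing columns: {missing_cols}")
        df = df[COLUMNS].reset_index(drop=True)
        df["patient_id"] = df["patient_id"].astype(str)
        df["visit_month"] = df["visit_month"].astype(float)
        df["instrument"] = df["instrument"].astype(str)
        df["item_id"] = df["item_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(object).where(df["rater_id"].notna(), None)
        df["rater_id"] = df["rater_id"].map(lambda r: None if r in (None, "", float("nan")) else str(r))
        df["value"] = pd.to_numeric(df["value"], errors="coerce").astype(float)
        self.df = df
        self.instruments = tuple(instruments) if instruments is not None else tuple(builtin_instruments())
        self._by_name = {ins.name: ins for ins in self.instruments}
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], instruments: Sequence[Instrument] | None = None
    ) -> "ScoreTable":
        """Build from (patient_id, visit_month, instrument, item_id, rater_id, value) tuples."""
        df = pd.DataFrame(list(records), columns=COLUMNS)
        return cls(df, instruments=instruments)

    def _validate(self) -> None:
        df = self.df
        if (df["visit_month"] < 0).any():
            bad = df.index[df["visit_month"] < 0].tolist()
            raise ValidationError(f"negative visit_month at rows {bad[:10]}")
        for name, sub in df.groupby("instrument", sort=False):
            if name not in self._by_name:
                raise SchemaError(
                    f"unknown instrument {name!r} at row {int(sub.index[0])}"
                )
            ins = self._by_name[name]
            known = set(ins.item_ids)
            bad_items = sub.loc[~sub["item_id"].isin(known)]
            if len(bad_items):
                row = bad_items.iloc[0]
                raise SchemaError(
                    f"unknown item {row['item_id']!r} for instrument {name!r}"
                    f" at row {int(bad_items.index[0])}"
                )
            for item_id, isub in sub.groupby("item_id", sort=False):
                it = ins.item(item_id)
                vals = isub["value"]
                obs = vals.notna()
                bad = obs & (
                    (vals < it.lo) | (vals > it.hi) | (vals != np.floor(vals))
                )
                if bad.any():
                    rows = isub.index[bad].tolist()
                    raise ValidationError(
                        f"value out of domain [{it.lo}..{it.hi}] for {name}/{item_id}"
                        f" at rows {rows[:10]}"
                    )
        key = df[["patient_id", "visit_month", "instrument", "item_id"]].copy()
        key["rater_id"] = df["rater_id"].fillna("")
        dup = key.duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate (patient, visit, instrument, item, rater) keys at rows "
                f"{df.index[dup].tolist()[:10]}"
            )

    # -- basic accessors -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        a = self.df.fillna({"rater_id": ""}).copy()
        b = other.df.fillna({"rater_id": ""}).copy()
        order = ["patient_id", "visit_month", "instrument", "item_id", "rater_id"]
        a = a.sort_values(order).reset_index(drop=True)
        b = b.sort_values(order).reset_index(drop=True)
        return a.equals(b)

    def instrument(self, name: str) -> Instrument:
        if name not in self._by_name:
            raise SchemaError(f"unknown instrument {name!r}")
        return self._by_name[name]

    def observed(self) -> pd.DataFrame:
        return self.df[self.df["value"].notna()]

    def wide(self, instrument: str, dropna: bool = False) -> pd.DataFrame:
        """Pivot one instrument to a (patient, visit, rater) x item matrix."""
        ins = self.instrument(instrument)
        sub = self.df[self.df["instrument"] == instrument].copy()
        if sub.empty:
            raise SchemaError(f"instrument {instrument!r} absent from table")
        sub["rater_id"] = sub["rater_id"].fillna("")
        wide = sub.pivot_table(
            index=["patient_id", "visit_month", "rater_id"],
            columns="item_id",
            values="value",
            aggfunc="first",
        )
        wide = wide.reindex(columns=ins.item_ids)
        if dropna:
            wide = wide.dropna()
        return wide

    def totals(self, instrument: str, missing_policy: str = "require_complete") -> pd.Series:
        """Instrument totals per (patient, visit); raters averaged per item first."""
        _check_policy(missing_policy)
        ins = self.instrument(instrument)
        wide = self.wide(instrument)
        # average replicate rater scores per item before summing
        per_visit = wide.groupby(level=["patient_id", "visit_month"]).mean()
        if missing_policy == "require_complete":
            tot = per_visit.sum(axis=1, min_count=len(ins.items))
        else:
            tot = per_visit.sum(axis=1, min_count=1)
        return tot


def _check_policy(policy: str) -> None:
    if policy not in ("require_complete", "sum_available"):
        raise ValueError(f"unknown missing_policy {policy!r}")


def total_score(
    table: ScoreTable,
    patient_id: str,
    visit_month: float,
    instrument: str,
    missing_policy: str = "require_complete",
) -> float | None:
    """Sum of item values for one patient visit, or ``None`` when missing.

    Under ``require_complete`` any missing item makes the total missing;
    under ``sum_available`` observed items are summed (>= 1 required).
    """
    _check_policy(missing_policy)
    ins = table.instrument(instrument)
    sub = table.df[
        (table.df["patient_id"] == str(patient_id))
        & (table.df["visit_month"] == float(visit_month))
        & (table.df["instrument"] == instrument)
    ]
    if sub.empty:
        raise KeyError(
            f"no records for patient {patient_id!r} at month {visit_month} on {instrument}"
        )
    per_item = sub.groupby("item_id")["value"].mean()
    per_item = per_item.reindex(ins.item_ids)
    if missing_policy == "require_complete":
        if per_item.isna().any():
            return None
        return float(per_item.sum())
    if per_item.notna().sum() == 0:
        return None
    return float(per_item.sum(skipna=True))


def read_scores(
    path: str | Path,
    instruments: Sequence[Instrument] | None = None,
    schedule: Sequence[float] | None = None,
    snap_window: float = 1.0,
) -> ScoreTable:
    """Read a long-format score CSV and validate it.

    When ``schedule`` is given, real-valued visit months within
    ``snap_window`` of a scheduled visit are snapped to it.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "rater_id": str}, keep_default_na=True)
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    if schedule is not None:
        df["visit_month"] = snap_visit_months(df["visit_month"].to_numpy(float), schedule, snap_window)
    return ScoreTable(df, instruments=instruments)


def write_scores(table: ScoreTable, path: str | Path) -> None:
    """Write the table in canonical column order; round-trips with :func:`read_scores`."""
    df = table.df.copy()

    def fmt_num(v: float) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return ""
        return f"{v:g}"

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "visit_month": df["visit_month"].map(fmt_num),
            "instrument": df["instrument"],
            "item_id": df["item_id"],
            "rater_id": df["rater_id"].map(lambda r: "" if r is None else str(r)),
            "value": df["value"].map(fmt_num),
        }
    )
    out.to_csv(path, index=False)
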