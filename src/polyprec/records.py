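"""Experimental records: domain types, validated dataset container, CSV I/O.

The experimental unit is a vial of four males and four females observed over
four daily sessions. One male per vial (the *focal*) is wild-type; rival males
and all females carry the recessive *sparkling poliert* (``spa``) eye marker,
so wild-type offspring are unambiguously sired by the focal male.

Three delimited tables describe a dataset:

``roster.csv``
    one row per fly: ``id, vial, sex, size_class, marker, role``
``events.csv``
    one row per copulation: ``vial, day, seq, male_id, female_id`` where
    ``seq`` is the temporal rank of the mating within its vial-day
``offspring.csv``
    one row per female per laying interval: ``vial, female_id, lay_day,
    count_wildtype, count_spa`` (eggs laid in the 20 h after that day's
    session)

An optional fourth table ``design.csv`` (``vial, experiment, social,
focal_size``) carries treatment labels, which are not always derivable from
the roster alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    DayRangeError,
    DuplicateEventError,
    MissingColumnError,
    NoDataError,
    RosterError,
    UnknownIdError,
    ValidationError,
)

logger = logging.getLogger("polyprec")

N_DAYS = 4

SEXES = {"male", "female"}
SIZE_CLASSES = {"large", "small"}
MARKERS = {"wildtype", "spa"}
ROLES = {"focal_male", "rival_male", "female"}

ROSTER_COLUMNS = ["id", "vial", "sex", "size_class", "marker", "role"]
EVENT_COLUMNS = ["vial", "day", "seq", "male_id", "female_id"]
OFFSPRING_COLUMNS = ["vial", "female_id", "lay_day", "count_wildtype", "count_spa"]
DESIGN_COLUMNS = ["vial", "experiment", "social", "focal_size"]


@dataclass(frozen=True, slots=True)
class Individual:
    """One fly on the roster."""

    id: str
    vial: str
    sex: str
    size_class: str
    marker: str
    role: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RosterError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.size_class not in SIZE_CLASSES:
            raise RosterError(f"unknown size_class {self.size_class!r} for {self.id!r}")
        if self.marker not in MARKERS:
            raise RosterError(f"unknown marker {self.marker!r} for {self.id!r}")
        if self.role not in ROLES:
            raise RosterError(f"unknown role {self.role!r} for {self.id!r}")
        if self.role == "focal_male" and self.marker != "wildtype":
            raise RosterError(f"focal male {self.id!r} must be wildtype")
        if self.role in ("rival_male", "female") and self.marker != "spa":
            raise RosterError(f"{self.role} {self.id!r} must carry the spa marker")
        if self.role == "female" and self.sex != "female":
            raise RosterError(f"{self.id!r}: role female requires sex female")
        if self.role in ("focal_male", "rival_male") and self.sex != "male":
            raise RosterError(f"{self.id!r}: role {self.role} requires sex male")


@dataclass(frozen=True, slots=True)
class MatingEvent:
    """A single copulation, ordered within its vial-day by ``seq``."""

    vial: str
    day: int
    seq: int
    male_id: str
    female_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.day <= N_DAYS:
            raise DayRangeError(f"day {self.day} outside 1..{N_DAYS}")
        if self.seq < 1:
            raise ValidationError(f"seq {self.seq} must be >= 1")


@dataclass(frozen=True, slots=True)
class OffspringBatch:
    """Marker-split offspring counts for one female on one laying day."""

    vial: str
    female_id: str
    lay_day: int
    count_wildtype: int
    count_spa: int

    def __post_init__(self) -> None:
        if not 1 <= self.lay_day <= N_DAYS:
            raise DayRangeError(f"lay_day {self.lay_day} outside 1..{N_DAYS}")
        if self.count_wildtype < 0 or self.count_spa < 0:
            raise ValidationError("offspring counts must be non-negative")


@dataclass(frozen=True)
class VialDesign:
    """Composition of one experimental vial (4 males, 4 females, one focal)."""

    vial: str
    experiment: str  # F | M | FM
    social: str  # Hom | Het
    focal_size: str  # large | small
    members: tuple[Individual, ...] = field(default_factory=tuple)
    treatment: str = ""  # e.g. "LM:HetF"; free-form composition label

    def __post_init__(self) -> None:
        if self.experiment not in {"F", "M", "FM"}:
            raise RosterError(f"unknown experiment code {self.experiment!r}")
        if self.social not in {"Hom", "Het"}:
            raise RosterError(f"unknown social label {self.social!r}")
        if self.focal_size not in SIZE_CLASSES:
            raise RosterError(f"unknown focal size {self.focal_size!r}")
        males = [m for m in self.members if m.sex == "male"]
        females = [m for m in self.members if m.sex == "female"]
        if self.members and (len(males) != 4 or len(females) != 4):
            raise RosterError(
                f"vial {self.vial!r}: expected 4 males and 4 females, "
                f"got {len(males)}M/{len(females)}F"
            )
        focals = [m for m in males if m.role == "focal_male"]
        if self.members and len(focals) != 1:
            raise RosterError(f"vial {self.vial!r}: expected exactly one focal male")
        if focals and focals[0].size_class != self.focal_size:
            raise RosterError(f"vial {self.vial!r}: focal size label mismatch")
        if self.members:
            manipulated = {"F": [females], "M": [males], "FM": [males, females]}
            for group in manipulated[self.experiment]:
                sizes = {m.size_class for m in group}
                if self.social == "Het" and len(sizes) != 2:
                    raise RosterError(
                        f"vial {self.vial!r}: Het requires both size classes "
                        "in the manipulated sex"
                    )
                if self.social == "Hom" and len(sizes) != 1:
                    raise RosterError(
                        f"vial {self.vial!r}: Hom requires a single size class "
                        "in the manipulated sex"
                    )

    @property
    def focal(self) -> Individual:
        return next(m for m in self.members if m.role == "focal_male")

    def roster_rows(self) -> list[dict]:
        return [
            {
                "id": m.id,
                "vial": m.vial,
                "sex": m.sex,
                "size_class": m.size_class,
                "marker": m.marker,
                "role": m.role,
            }
            for m in self.members
        ]


def _require_columns(df: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{table}: missing column(s) {missing}")


def _canonical_roster(df: pd.DataFrame) -> pd.DataFrame:
    out = df[ROSTER_COLUMNS].copy()
    for c in ROSTER_COLUMNS:
        out[c] = out[c].astype(str)
    return out.sort_values(["vial", "id"], kind="mergesort").reset_index(drop=True)


def _canonical_events(df: pd.DataFrame) -> pd.DataFrame:
    out = df[EVENT_COLUMNS].copy()
    for c in ("vial", "male_id", "female_id"):
        out[c] = out[c].astype(str)
    for c in ("day", "seq"):
        out[c] = out[c].astype(int)
    return out.sort_values(["vial", "day", "seq"], kind="mergesort").reset_index(drop=True)


def _canonical_offspring(df: pd.DataFrame) -> pd.DataFrame:
    out = df[OFFSPRING_COLUMNS].copy()
    for c in ("vial", "female_id"):
        out[c] = out[c].astype(str)
    for c in ("lay_day", "count_wildtype", "count_spa"):
        out[c] = out[c].astype(int)
    return out.sort_values(["vial", "female_id", "lay_day"], kind="mergesort").reset_index(
        drop=True
    )


def _canonical_design(df: pd.DataFrame) -> pd.DataFrame:
    cols = DESIGN_COLUMNS + (["treatment"] if "treatment" in df.columns else [])
    out = df[cols].copy()
    for c in cols:
        out[c] = out[c].astype(str)
    return out.sort_values(["vial"], kind="mergesort").reset_index(drop=True)


@dataclass
class Dataset:
    """A validated, cross-linked set of roster / events / offspring tables."""

    roster: pd.DataFrame
    events: pd.DataFrame
    offspring: pd.DataFrame
    design: pd.DataFrame | None = None

    @classmethod
    def from_frames(
        cls,
        roster: pd.DataFrame,
        events: pd.DataFrame,
        offspring: pd.DataFrame,
        design: pd.DataFrame | None = None,
    ) -> "Dataset":
        _require_columns(roster, ROSTER_COLUMNS, "roster")
        _require_columns(events, EVENT_COLUMNS, "events")
        _require_columns(offspring, OFFSPRING_COLUMNS, "offspring")
        if design is not None:
            _require_columns(design, DESIGN_COLUMNS, "design")
        ds = cls(
            roster=_canonical_roster(roster),
            events=_canonical_events(events),
            offspring=_canonical_offspring(offspring),
            design=None if design is None else _canonical_design(design),
        )
        ds.validate()
        return ds

    # -- validation ---------------------------------------------------------

    def validate(self) -> "Dataset":
        self._validate_roster()
        self._validate_events()
        self._validate_offspring()
        logger.info(
            "dataset validated: %d flies, %d vials, %d matings, %d offspring batches",
            len(self.roster),
            self.roster["vial"].nunique(),
            len(self.events),
            len(self.offspring),
        )
        if self.events.empty:
            logger.warning("events table is empty: dataset contains zero matings")
        return self

    def _validate_roster(self) -> None:
        r = self.roster
        if r.empty:
            logger.warning("roster is empty: dataset contains zero vials")
            return
        if r["id"].duplicated().any():
            dup = r.loc[r["id"].duplicated(), "id"].iloc[0]
            raise RosterError(f"duplicate fly id {dup!r} in roster")
        for row in r.itertuples(index=False):
            Individual(**row._asdict())  # field-level invariants
        focal_counts = (
            r[r["role"] == "focal_male"].groupby("vial").size().reindex(
                r["vial"].unique(), fill_value=0
            )
        )
        bad = focal_counts[focal_counts != 1]
        if not bad.empty:
            raise RosterError(
                f"vial(s) {list(bad.index)} have {list(bad.values)} focal males; "
                "expected exactly one each"
            )
        comp = r.groupby("vial")["sex"].value_counts().unstack(fill_value=0)
        off_design = comp[(comp.get("male", 0) != 4) | (comp.get("female", 0) != 4)]
        if not off_design.empty:
            logger.warning(
                "vial(s) %s deviate from the 4M:4F design", list(off_design.index)
            )
        if self.design is not None:
            unknown = set(self.design["vial"]) - set(r["vial"])
            if unknown:
                raise UnknownIdError(f"design table references unknown vial(s) {sorted(unknown)}")

    def _validate_events(self) -> None:
        e = self.events
        if e.empty:
            return
        bad_day = e[(e["day"] < 1) | (e["day"] > N_DAYS)]
        if not bad_day.empty:
            raise DayRangeError(
                f"event day(s) {sorted(bad_day['day'].unique())} outside 1..{N_DAYS}"
            )
        if (e["seq"] < 1).any():
            raise ValidationError("event seq values must be >= 1")
        dup = e.duplicated(subset=["vial", "day", "seq"])
        if dup.any():
            row = e[dup].iloc[0]
            raise DuplicateEventError(
                f"duplicate (vial, day, seq) = ({row['vial']}, {row['day']}, {row['seq']})"
            )
        males = self.roster[self.roster["sex"] == "male"].set_index("id")["vial"]
        females = self.roster[self.roster["sex"] == "female"].set_index("id")["vial"]
        for row in e.itertuples(index=False):
            if males.get(row.male_id) != row.vial:
                raise UnknownIdError(
                    f"event references male {row.male_id!r} not on vial {row.vial!r} roster"
                )
            if females.get(row.female_id) != row.vial:
                raise UnknownIdError(
                    f"event references female {row.female_id!r} not on vial {row.vial!r} roster"
                )

    def _validate_offspring(self) -> None:
        o = self.offspring
        if o.empty:
            return
        bad_day = o[(o["lay_day"] < 1) | (o["lay_day"] > N_DAYS)]
        if not bad_day.empty:
            raise DayRangeError(
                f"lay_day(s) {sorted(bad_day['lay_day'].unique())} outside 1..{N_DAYS}"
            )
        if (o[["count_wildtype", "count_spa"]] < 0).any().any():
            raise ValidationError("offspring counts must be non-negative")
        females = self.roster[self.roster["sex"] == "female"].set_index("id")["vial"]
        for row in o.itertuples(index=False):
            if females.get(row.female_id) != row.vial:
                raise UnknownIdError(
                    f"offspring row references female {row.female_id!r} "
                    f"not on vial {row.vial!r} roster"
                )
        if o.duplicated(subset=["vial", "female_id", "lay_day"]).any():
            raise DuplicateEventError("duplicate (vial, female_id, lay_day) offspring row")

    # -- conveniences -------------------------------------------------------

    @property
    def vials(self) -> list[str]:
        return sorted(self.roster["vial"].unique())

    def focal_of(self, vial: str) -> str:
        sub = self.roster[(self.roster["vial"] == vial) & (self.roster["role"] == "focal_male")]
        if sub.empty:
            raise NoDataError(f"vial {vial!r} not in dataset")
        return sub["id"].iloc[0]

    def equals(self, other: "Dataset") -> bool:
        same = (
            self.roster.equals(other.roster)
            and self.events.equals(other.events)
            and self.offspring.equals(other.offspring)
        )
        if self.design is None or other.design is None:
            return same and (self.design is None) == (other.design is None)
        return same and self.design.equals(other.design)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - thin alias
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.equals(other)


# -- file I/O ---------------------------------------------------------------

_FILE_NAMES = {
    "roster": "roster.csv",
    "events": "events.csv",
    "offspring": "offspring.csv",
    "design": "design.csv",
}


def _resolve_paths(where: str | Path | Mapping[str, str | Path]) -> dict[str, Path]:
    if isinstance(where, (str, Path)):
        base = Path(where)
        return {k: base / v for k, v in _FILE_NAMES.items()}
    return {k: Path(v) for k, v in where.items()}


def read_dataset(where: str | Path | Mapping[str, str | Path]) -> Dataset:
    """Read and validate a dataset.

    ``where`` is either a directory containing ``roster.csv``, ``events.csv``,
    ``offspring.csv`` (and optionally ``design.csv``) or a mapping from those
    keys to explicit paths.
    """
    paths = _resolve_paths(where)
    for key in ("roster", "events", "offspring"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"required input table {key!r} not found: {paths.get(key)}")
    roster = pd.read_csv(paths["roster"], dtype=str)
    events = pd.read_csv(paths["events"], dtype=str)
    offspring = pd.read_csv(paths["offspring"], dtype=str)
    _require_columns(roster, ROSTER_COLUMNS, "roster")
    _require_columns(events, EVENT_COLUMNS, "events")
    _require_columns(offspring, OFFSPRING_COLUMNS, "offspring")
    try:
        if not events.empty:
            events["day"] = events["day"].astype(int)
            events["seq"] = events["seq"].astype(int)
        else:
            events = events.assign(day=pd.Series(dtype=int), seq=pd.Series(dtype=int))
        if not offspring.empty:
            for c in ("lay_day", "count_wildtype", "count_spa"):
                offspring[c] = offspring[c].astype(int)
        else:
            offspring = offspring.assign(
                lay_day=pd.Series(dtype=int),
                count_wildtype=pd.Series(dtype=int),
                count_spa=pd.Series(dtype=int),
            )
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer value in integer column: {exc}") from exc
    design = None
    if "design" in paths and Path(paths["design"]).exists():
        design = pd.read_csv(paths["design"], dtype=str)
    return Dataset.from_frames(roster, events, offspring, design)


def read_dataset_mapped(
    where: Mapping[str, str | Path],
    column_maps: Mapping[str, Mapping[str, str]],
    value_maps: Mapping[str, Mapping[str, Mapping[str, str]]] | None = None,
) -> Dataset:
    """Ingestion adapter for externally deposited tables with foreign layouts.

    ``column_maps[table]`` maps source column names to the documented schema
    (e.g. ``{"Vial_ID": "vial", ...}``); ``value_maps[table][column]`` optionally
    recodes cell values (e.g. ``{"role": {"Focal": "focal_male"}}``). The mapping
    is user-supplied because deposited layouts vary.
    """
    frames: dict[str, pd.DataFrame] = {}
    for table in ("roster", "events", "offspring"):
        df = pd.read_csv(where[table], dtype=str)
        df = df.rename(columns=dict(column_maps.get(table, {})))
        if value_maps and table in value_maps:
            for col, mapping in value_maps[table].items():
                if col in df.columns:
                    df[col] = df[col].replace(dict(mapping))
        frames[table] = df
    for c in ("day", "seq"):
        if c in frames["events"].columns and not frames["events"].empty:
            frames["events"][c] = frames["events"][c].astype(int)
    for c in ("lay_day", "count_wildtype", "count_spa"):
        if c in frames["offspring"].columns and not frames["offspring"].empty:
            frames["offspring"][c] = frames["offspring"][c].astype(int)
    design = None
    if "design" in where:
        design = pd.read_csv(where["design"], dtype=str)
        design = design.rename(columns=dict(column_maps.get("design", {})))
    return Dataset.from_frames(frames["roster"], frames["events"], frames["offspring"], design)


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to ``out_dir`` with deterministic row and column order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / _FILE_NAMES["roster"],
        "events": out / _FILE_NAMES["events"],
        "offspring": out / _FILE_NAMES["offspring"],
    }
    _canonical_roster(ds.roster).to_csv(paths["roster"], index=False, lineterminator="\n")
    _canonical_events(ds.events).to_csv(paths["events"], index=False, lineterminator="\n")
    _canonical_offspring(ds.offspring).to_csv(
        paths["offspring"], index=False, lineterminator="\n"
    )
    if ds.design is not None:
        paths["design"] = out / _FILE_NAMES["design"]
        _canonical_design(ds.design).to_csv(paths["design"], index=False, lineterminator="\n")
    return paths
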