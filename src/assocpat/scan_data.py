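"""Data model and I/O for focal-follow scan samples.

A *scan* is an instantaneous record of which group members were in visual
contact with a focal individual.  Datasets are one season (October-September)
of such scans over a fixed roster.  Internally a dataset is held as a boolean
presence matrix (scans x roster members), which every downstream statistic
(permutation nulls, entropy, association indices) operates on directly.

Two CSV dialects are supported:

* **wide** (canonical): one row per scan with columns
  ``scan_id,timestamp,focal`` followed by one 0/1 column per roster member.
* **long**: one row per (scan, present member) pair with columns
  ``scan_id,timestamp,focal,member``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: age (in years at season start) above which an individual is included
MIN_AGE = 3
#: adulthood thresholds: females above 5 years, males above 7 years
ADULT_AGE = {"female": 5, "male": 7}

_WIDE_FIXED = ("scan_id", "timestamp", "focal")


@dataclass(frozen=True)
class Individual:
    """One group member with the attributes the dyadic models need.

    ``birth_year`` or an explicit ``age_class`` must be given; an explicit
    class takes precedence when both are present.  ``infant_years`` is the
    set of season labels in which the individual had a newborn infant.
    """

    id: str
    sex: str
    birth_year: int | None = None
    age_class: str | None = None
    mother_id: str | None = None
    infant_years: frozenset = frozenset()

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"individual {self.id!r}: sex must be 'female' or 'male', got {self.sex!r}")
        if self.birth_year is None and self.age_class is None:
            raise ValueError(f"individual {self.id!r}: need birth_year or age_class")
        if self.age_class is not None and self.age_class not in ("adult", "subadult"):
            raise ValueError(f"individual {self.id!r}: age_class must be 'adult' or 'subadult'")
        object.__setattr__(self, "infant_years", frozenset(self.infant_years))


@dataclass(frozen=True)
class SeasonRoster:
    """All individuals eligible for one season.

    Eligibility follows the study design: members must be above ``MIN_AGE``
    years at season start and present the whole season (presence is the
    caller's responsibility; age is validated here when birth years are
    known).  ``start_year`` is the calendar year of the season's October
    start, so ages at season start are ``start_year - birth_year``.
    """

    season: str
    members: tuple
    start_year: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate roster ids: {dupes}")
        known = {m.id for m in self.members}
        for m in self.members:
            a = self.age(m)
            if a is not None and a <= MIN_AGE:
                raise ValueError(
                    f"individual {m.id!r} is {a} years old at season start; roster requires age > {MIN_AGE}"
                )
            if m.mother_id is not None and m.mother_id not in known:
                # dam may be dead/absent; keep but note it
                log.debug("roster %s: %s's mother %s not on roster", self.season, m.id, m.mother_id)

    @property
    def ids(self) -> tuple:
        return tuple(m.id for m in self.members)

    @property
    def index(self) -> dict:
        return {m.id: i for i, m in enumerate(self.members)}

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, id_: str) -> Individual:
        for m in self.members:
            if m.id == id_:
                return m
        raise KeyError(id_)

    def __contains__(self, id_: str) -> bool:
        return any(m.id == id_ for m in self.members)

    def age(self, member: Individual) -> int | None:
        if member.birth_year is None or self.start_year is None:
            return None
        return self.start_year - member.birth_year

    def age_class_of(self, id_: str) -> str:
        """Adult/subadult at season start (explicit class wins over age)."""
        m = self[id_] if isinstance(id_, str) else id_
        if m.age_class is not None:
            return m.age_class
        a = self.age(m)
        if a is None:
            raise ValueError(f"individual {m.id!r}: no age information for season {self.season}")
        return "adult" if a > ADULT_AGE[m.sex] else "subadult"

    def has_infant(self, id_: str) -> bool:
        return self.season in self[id_].infant_years


@dataclass(frozen=True)
class ScanRecord:
    """One scan: the focal and the set of members in visual contact."""

    scan_id: int
    timestamp: np.datetime64
    focal_id: str
    present: frozenset

    def __post_init__(self):
        object.__setattr__(self, "present", frozenset(self.present))
        if self.focal_id not in self.present:
            raise ValueError(f"scan {self.scan_id}: focal {self.focal_id!r} not in present set")
        if len(self.present) < 1:
            raise ValueError(f"scan {self.scan_id}: empty present set")


class ScanDataset:
    """Ordered scans over a fixed roster, stored as a presence matrix."""

    def __init__(self, roster: SeasonRoster, scan_ids, timestamps, focal_idx, presence):
        self.roster = roster
        self.scan_ids = np.asarray(scan_ids, dtype=np.int64)
        self.timestamps = np.asarray(timestamps, dtype="datetime64[s]")
        self.focal_idx = np.asarray(focal_idx, dtype=np.intp)
        self.presence = np.ascontiguousarray(presence, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        s, n = self.presence.shape
        if not (len(self.scan_ids) == len(self.timestamps) == len(self.focal_idx) == s):
            raise ValueError("scan_ids, timestamps, focal_idx and presence rows must align")
        if n != len(self.roster):
            raise ValueError("presence columns must match roster size")
        if s:
            if np.any(self.timestamps[1:] < self.timestamps[:-1]):
                raise ValueError("scans must be sorted by timestamp")
            if self.focal_idx.min() < 0 or self.focal_idx.max() >= n:
                raise ValueError("focal index out of roster range")
            if not self.presence[np.arange(s), self.focal_idx].all():
                bad = int(np.flatnonzero(~self.presence[np.arange(s), self.focal_idx])[0])
                raise ValueError(f"scan {self.scan_ids[bad]}: focal not in present set")
            if not self.presence.any(axis=1).all():
                raise ValueError("every scan must contain at least one member")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, roster: SeasonRoster, records: Iterable[ScanRecord]) -> "ScanDataset":
        records = sorted(records, key=lambda r: (r.timestamp, r.scan_id))
        idx = roster.index
        s, n = len(records), len(roster)
        presence = np.zeros((s, n), dtype=bool)
        focal = np.empty(s, dtype=np.intp)
        ts = np.empty(s, dtype="datetime64[s]")
        sid = np.empty(s, dtype=np.int64)
        for i, r in enumerate(records):
            unknown = [m for m in r.present if m not in idx]
            if unknown:
                raise KeyError(f"scan {r.scan_id}: ids not on roster: {sorted(unknown)}")
            for m in r.present:
                presence[i, idx[m]] = True
            focal[i] = idx[r.focal_id]
            ts[i] = np.datetime64(r.timestamp, "s")
            sid[i] = r.scan_id
        return cls(roster, sid, ts, focal, presence)

    # -- accessors ---------------------------------------------------------

    @property
    def ids(self) -> tuple:
        return self.roster.ids

    @property
    def n_scans(self) -> int:
        return self.presence.shape[0]

    def subgroup_sizes(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def records(self) -> Iterator[ScanRecord]:
        ids = self.ids
        for i in range(self.n_scans):
            yield ScanRecord(
                scan_id=int(self.scan_ids[i]),
                timestamp=self.timestamps[i],
                focal_id=ids[self.focal_idx[i]],
                present=frozenset(ids[j] for j in np.flatnonzero(self.presence[i])),
            )

    def __len__(self) -> int:
        return self.n_scans

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScanDataset):
            return NotImplemented
        return (
            self.ids == other.ids
            and np.array_equal(self.scan_ids, other.scan_ids)
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.focal_idx, other.focal_idx)
            and np.array_equal(self.presence, other.presence)
        )

    def replace_presence(self, presence: np.ndarray) -> "ScanDataset":
        """Same scans/focals/timestamps with a new presence matrix."""
        return ScanDataset(self.roster, self.scan_ids, self.timestamps, self.focal_idx, presence)


# -- CSV I/O ----------------------------------------------------------------


def _detect_dialect(columns: Sequence[str]) -> str:
    return "long" if "member" in columns else "wide"


def read_scans(path, roster: SeasonRoster, dialect: str | None = None, drop_unknown: bool = False) -> ScanDataset:
    """Read a scan CSV (wide or long dialect) against a season roster.

    Rows whose focal is not marked present are repaired (the focal is added)
    with a logged warning: the subgroup is by definition centred on the
    focal.  Unknown member ids are a hard error unless ``drop_unknown``.
    """
    df = pd.read_csv(path)
    if dialect is None:
        dialect = _detect_dialect(df.columns)
    if dialect not in ("wide", "long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in _WIDE_FIXED:
        if col not in df.columns:
            raise ValueError(f"scan file {path}: missing required column {col!r}")

    idx = roster.index
    n = len(roster)

    unknown_focal = set(df["focal"]) - set(idx)
    if unknown_focal:
        raise KeyError(f"scan file {path}: focal ids not on roster: {sorted(unknown_focal)}")

    if dialect == "wide":
        member_cols = [c for c in df.columns if c not in _WIDE_FIXED]
        unknown = [c for c in member_cols if c not in idx]
        if unknown and not drop_unknown:
            raise KeyError(f"scan file {path}: member columns not on roster: {sorted(unknown)}")
        if unknown:
            log.warning("dropping %d unknown member columns: %s", len(unknown), sorted(unknown))
            member_cols = [c for c in member_cols if c in idx]
        vals = df[member_cols].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = member_cols[int(np.argwhere(~np.isin(vals, (0, 1)))[0][1])]
            raise ValueError(f"scan file {path}: non-0/1 presence value in column {bad!r}")
        presence = np.zeros((len(df), n), dtype=bool)
        for c in member_cols:
            presence[:, idx[c]] = df[c].to_numpy().astype(bool)
    else:
        keep = df
        unknown = set(df["member"]) - set(idx)
        if unknown and not drop_unknown:
            raise KeyError(f"scan file {path}: member ids not on roster: {sorted(unknown)}")
        if unknown:
            log.warning("dropping %d rows with unknown member ids", int(df["member"].isin(unknown).sum()))
            keep = df[~df["member"].isin(unknown)]
        meta = df.drop_duplicates("scan_id")[list(_WIDE_FIXED)]
        presence = np.zeros((len(meta), n), dtype=bool)
        pos = {s: i for i, s in enumerate(meta["scan_id"])}
        for s_id, member in zip(keep["scan_id"], keep["member"]):
            presence[pos[s_id], idx[member]] = True
        df = meta

    focal = np.array([idx[f] for f in df["focal"]], dtype=np.intp)
    rows = np.arange(len(df))
    missing_focal = ~presence[rows, focal]
    if missing_focal.any():
        log.warning("%d scans had focal absent from present set; repaired", int(missing_focal.sum()))
        presence[rows[missing_focal], focal[missing_focal]] = True

    ts = pd.to_datetime(df["timestamp"]).to_numpy().astype("datetime64[s]")
    order = np.argsort(ts, kind="stable")
    return ScanDataset(roster, df["scan_id"].to_numpy()[order], ts[order], focal[order], presence[order])


def write_scans(ds: ScanDataset, path, dialect: str = "wide") -> None:
    """Write a dataset to CSV; ``read_scans(write_scans(ds)) == ds``."""
    ids = ds.ids
    ts = pd.to_datetime(ds.timestamps).strftime("%Y-%m-%dT%H:%M:%S")
    if dialect == "wide":
        out = pd.DataFrame({"scan_id": ds.scan_ids, "timestamp": ts, "focal": [ids[i] for i in ds.focal_idx]})
        for j, name in enumerate(ids):
            out[name] = ds.presence[:, j].astype(int)
        out.to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for i in range(ds.n_scans):
            for j in np.flatnonzero(ds.presence[i]):
                rows.append((ds.scan_ids[i], ts[i], ids[ds.focal_idx[i]], ids[j]))
        pd.DataFrame(rows, columns=["scan_id", "timestamp", "focal", "member"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# -- filtering and summaries --------------------------------------------------


def filter_season(ds: ScanDataset, roster: SeasonRoster) -> ScanDataset:
    """Restrict a dataset to a season-eligible roster.

    Present sets are intersected with the new roster; scans whose present
    set becomes empty, or whose focal is not eligible, are dropped (counts
    logged).  Idempotent.
    """
    old_ids = ds.ids
    keep_cols = [j for j, i in enumerate(old_ids) if i in roster]
    colmap = {old_ids[j]: k for k, j in enumerate(keep_cols)}
    presence = ds.presence[:, keep_cols]

    focal_ok = np.array([old_ids[f] in roster for f in ds.focal_idx])
    nonempty = presence.any(axis=1)
    keep = focal_ok & nonempty
    dropped_focal = int((~focal_ok).sum())
    dropped_empty = int((focal_ok & ~nonempty).sum())
    if dropped_focal or dropped_empty:
        log.info("filter_season: dropped %d focal-ineligible and %d emptied scans", dropped_focal, dropped_empty)

    new_idx = roster.index
    # reorder columns to the new roster's order
    ordered = np.zeros((int(keep.sum()), len(roster)), dtype=bool)
    for i in roster.ids:
        if i in colmap:
            ordered[:, new_idx[i]] = presence[keep][:, colmap[i]]
    focal = np.array([new_idx[old_ids[f]] for f in ds.focal_idx[keep]], dtype=np.intp)
    return ScanDataset(roster, ds.scan_ids[keep], ds.timestamps[keep], focal, ordered)


def occurrence_frequency(ds: ScanDataset) -> dict:
    """Per-member proportion of scans in which the member appears."""
    if ds.n_scans == 0:
        raise ValueError("occurrence_frequency: empty dataset")
    freq = ds.presence.mean(axis=0)
    return dict(zip(ds.ids, freq.tolist()))


def summarize_dataset(ds: ScanDataset) -> dict:
    """Season-level descriptives of the subgroup compositions."""
    sizes = ds.subgroup_sizes()
    sex = np.array([m.sex for m in ds.roster.members])
    male = ds.presence[:, sex == "male"]
    female = ds.presence[:, sex == "female"]
    uniq = len(np.unique(_pack_rows(ds.presence)))
    return {
        "season": ds.roster.season,
        "n_scans": int(ds.n_scans),
        "n_individuals": len(ds.roster),
        "mean_subgroup_size": float(sizes.mean()),
        "max_subgroup_size": int(sizes.max()),
        "pct_with_male": float(male.any(axis=1).mean()),
        "pct_with_female": float(female.any(axis=1).mean()),
        "mean_males": float(male.sum(axis=1).mean()),
        "mean_females": float(female.sum(axis=1).mean()),
        "unique_compositions": int(uniq),
        "pct_unique": float(uniq / ds.n_scans),
    }


def _pack_rows(presence: np.ndarray) -> np.ndarray:
    """Encode boolean composition rows as hashable scalars (roster <= 64)."""
    n = presence.shape[1]
    if n <= 64:
        packed = np.packbits(presence, axis=1)
        out = np.zeros((presence.shape[0], 8), dtype=np.uint8)
        out[:, : packed.shape[1]] = packed
        return out.view("<u8").ravel()
    packed = np.packbits(presence, axis=1)
    return packed.view([("", packed.dtype)] * packed.shape[1]).ravel()


# -- attribute file -----------------------------------------------------------


def read_individuals(path) -> tuple:
    """Read the individual-attribute CSV.

    Columns: ``id,sex`` required; ``birth_year``, ``age_class``,
    ``mother_id`` optional; ``infant_years`` is a semicolon-separated list
    of season labels.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "sex"):
        if col not in df.columns:
            raise ValueError(f"attribute file {path}: missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        by = row.get("birth_year")
        infants = row.get("infant_years")
        out.append(
            Individual(
                id=row["id"],
                sex=row["sex"],
                birth_year=int(by) if isinstance(by, str) and by else None,
                age_class=row.get("age_class") if isinstance(row.get("age_class"), str) else None,
                mother_id=row.get("mother_id") if isinstance(row.get("mother_id"), str) else None,
                infant_years=frozenset(infants.split(";")) if isinstance(infants, str) and infants else frozenset(),
            )
        )
    return tuple(out)
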