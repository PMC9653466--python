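"""Flock data model: animal registrations, trait records, events, snapshots.

The flock ledger is event-sourced: animal registrations plus dated trait,
reproduction, health and disposal events.  Every report and genetic
evaluation is a pure function of this ledger, so farm state can be
reconstructed as of any calendar date, current or past.

Files are plain CSV with ISO-8601 dates.  Unknown parents may be written as
an empty cell or a literal ``"0"`` on input (matching common on-farm
ledgers); output always uses the empty cell.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Sex",
    "DisposalReason",
    "ReproOutcome",
    "HealthKind",
    "AnimalRecord",
    "TraitRecord",
    "ReproductionEvent",
    "HealthEvent",
    "FlockDataset",
    "Finding",
    "FarmSnapshot",
    "SnapshotAnimal",
    "FlockFormatError",
    "read_flock",
    "write_flock",
    "validate_flock",
    "snapshot",
    "effective_sex",
]

CANONICAL_TRAITS = ("BWT", "WWT", "W6M", "W9M", "W12M", "GFY", "FD", "SL")


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    WETHER = "WETHER"


class DisposalReason(str, Enum):
    DEATH = "DEATH"
    SALE = "SALE"
    TRANSFER = "TRANSFER"
    CULL = "CULL"


class ReproOutcome(str, Enum):
    LAMBING = "LAMBING"
    ABORTION = "ABORTION"
    NONE = "NONE"


class HealthKind(str, Enum):
    VACCINATION = "VACCINATION"
    DEWORMING = "DEWORMING"
    TREATMENT = "TREATMENT"
    CASTRATION = "CASTRATION"


class FlockFormatError(ValueError):
    """Raised for malformed input files; carries file, line and column."""


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: Sex
    breed: str
    birth_date: dt.date
    farm_id: str
    entry_date: dt.date
    disposal_date: Optional[dt.date] = None
    disposal_reason: Optional[DisposalReason] = None


@dataclass(frozen=True)
class TraitRecord:
    animal_id: str
    trait_code: str
    value: float
    record_date: dt.date


@dataclass(frozen=True)
class ReproductionEvent:
    ewe_id: str
    ram_id: str
    mating_date: dt.date
    outcome: ReproOutcome
    outcome_date: Optional[dt.date]
    lamb_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class HealthEvent:
    animal_id: str
    date: dt.date
    kind: HealthKind
    detail: str = ""
    drug: Optional[str] = None


@dataclass
class FlockDataset:
    animals: list[AnimalRecord] = field(default_factory=list)
    traits: list[TraitRecord] = field(default_factory=list)
    repro: list[ReproductionEvent] = field(default_factory=list)
    health: list[HealthEvent] = field(default_factory=list)

    def animal_index(self) -> dict[str, AnimalRecord]:
        return {a.animal_id: a for a in self.animals}


@dataclass(frozen=True)
class Finding:
    code: str
    severity: str  # "ERROR" or "WARNING"
    message: str
    subject: str = ""


@dataclass(frozen=True)
class SnapshotAnimal:
    record: AnimalRecord
    age_days: int
    age_class: str  # LAMB / HOGGET / ADULT
    sex: Sex  # effective sex as of the snapshot date (castration applied)


@dataclass
class FarmSnapshot:
    as_of: dt.date
    animals: list[SnapshotAnimal]

    def __len__(self) -> int:
        return len(self.animals)

    def ids(self) -> set[str]:
        return {a.record.animal_id for a in self.animals}


# ---------------------------------------------------------------------------
# parsing helpers

_ANIMAL_COLS = [
    "animal_id", "sire_id", "dam_id", "sex", "breed", "birth_date",
    "farm_id", "entry_date", "disposal_date", "disposal_reason",
]
_TRAIT_COLS = ["animal_id", "trait_code", "value", "record_date"]
_REPRO_COLS = ["ewe_id", "ram_id", "mating_date", "outcome", "outcome_date", "lamb_ids"]
_HEALTH_COLS = ["animal_id", "date", "kind", "detail", "drug"]


def _parse_date(raw: str, path: str, line: int, col: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw.strip())
    except ValueError as exc:
        raise FlockFormatError(
            f"{path}:{line}: column '{col}': bad date {raw!r} (expected YYYY-MM-DD)"
        ) from exc


def _parse_opt_date(raw: str, path: str, line: int, col: str) -> Optional[dt.date]:
    raw = raw.strip()
    if not raw:
        return None
    return _parse_date(raw, path, line, col)


def _parse_enum(cls, raw: str, path: str, line: int, col: str):
    try:
        return cls(raw.strip().upper())
    except ValueError as exc:
        allowed = ", ".join(m.value for m in cls)
        raise FlockFormatError(
            f"{path}:{line}: column '{col}': {raw!r} not one of {{{allowed}}}"
        ) from exc


def _parse_float(raw: str, path: str, line: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError as exc:
        raise FlockFormatError(
            f"{path}:{line}: column '{col}': {raw!r} is not a number"
        ) from exc


def _parent(raw: str) -> Optional[str]:
    raw = raw.strip()
    if raw in ("", "0"):
        return None
    return raw


def _read_rows(path: str | Path, expected: Sequence[str], optional: Sequence[str] = ()):
    path = Path(path)
    if not path.exists():
        raise FlockFormatError(f"{path}: file not found")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FlockFormatError(f"{path}: empty file (missing header)")
        header = [h.strip() for h in header]
        required = [c for c in expected if c not in optional]
        missing = [c for c in required if c not in header]
        if missing:
            raise FlockFormatError(
                f"{path}:1: header missing column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in expected if c in header}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < len(header):
                raise FlockFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, {c: (row[i] if i < len(row) else "") for c, i in idx.items()}


def read_flock(
    animals: str | Path,
    traits: str | Path | None = None,
    repro: str | Path | None = None,
    health: str | Path | None = None,
) -> FlockDataset:
    """Read a flock dataset from per-table CSV files.

    Only the animals table is mandatory.  ``entry_date`` defaults to
    ``birth_date`` when missing; empty or ``"0"`` parent cells become absent
    parents.  Duplicate animal ids and malformed rows raise
    :class:`FlockFormatError` naming the file, line and column.
    """
    ds = FlockDataset()
    seen: dict[str, int] = {}
    dupes: list[str] = []
    for lineno, row in _read_rows(
        animals, _ANIMAL_COLS, optional=("entry_date", "disposal_date", "disposal_reason")
    ):
        aid = row["animal_id"].strip()
        if not aid:
            raise FlockFormatError(f"{animals}:{lineno}: column 'animal_id': empty id")
        if aid in seen:
            if aid not in dupes:
                dupes.append(aid)
            continue
        seen[aid] = lineno
        birth = _parse_date(row["birth_date"], str(animals), lineno, "birth_date")
        entry_raw = row.get("entry_date", "").strip()
        entry = (
            _parse_date(entry_raw, str(animals), lineno, "entry_date")
            if entry_raw
            else birth
        )
        reason_raw = row.get("disposal_reason", "").strip()
        ds.animals.append(
            AnimalRecord(
                animal_id=aid,
                sire_id=_parent(row["sire_id"]),
                dam_id=_parent(row["dam_id"]),
                sex=_parse_enum(Sex, row["sex"], str(animals), lineno, "sex"),
                breed=row["breed"].strip(),
                birth_date=birth,
                farm_id=row["farm_id"].strip(),
                entry_date=entry,
                disposal_date=_parse_opt_date(
                    row.get("disposal_date", ""), str(animals), lineno, "disposal_date"
                ),
                disposal_reason=(
                    _parse_enum(DisposalReason, reason_raw, str(animals), lineno, "disposal_reason")
                    if reason_raw
                    else None
                ),
            )
        )
    if dupes:
        raise FlockFormatError(
            f"{animals}: duplicate animal_id(s): {', '.join(sorted(dupes))}"
        )

    if traits is not None:
        for lineno, row in _read_rows(traits, _TRAIT_COLS):
            ds.traits.append(
                TraitRecord(
                    animal_id=row["animal_id"].strip(),
                    trait_code=row["trait_code"].strip().upper(),
                    value=_parse_float(row["value"], str(traits), lineno, "value"),
                    record_date=_parse_date(row["record_date"], str(traits), lineno, "record_date"),
                )
            )
    if repro is not None:
        for lineno, row in _read_rows(repro, _REPRO_COLS):
            lambs = tuple(x.strip() for x in row["lamb_ids"].split(";") if x.strip())
            ds.repro.append(
                ReproductionEvent(
                    ewe_id=row["ewe_id"].strip(),
                    ram_id=row["ram_id"].strip(),
                    mating_date=_parse_date(row["mating_date"], str(repro), lineno, "mating_date"),
                    outcome=_parse_enum(ReproOutcome, row["outcome"], str(repro), lineno, "outcome"),
                    outcome_date=_parse_opt_date(row["outcome_date"], str(repro), lineno, "outcome_date"),
                    lamb_ids=lambs,
                )
            )
    if health is not None:
        for lineno, row in _read_rows(health, _HEALTH_COLS, optional=("drug",)):
            drug = row.get("drug", "").strip() or None
            ds.health.append(
                HealthEvent(
                    animal_id=row["animal_id"].strip(),
                    date=_parse_date(row["date"], str(health), lineno, "date"),
                    kind=_parse_enum(HealthKind, row["kind"], str(health), lineno, "kind"),
                    detail=row["detail"].strip(),
                    drug=drug,
                )
            )
    return ds


def write_flock(ds: FlockDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the four canonical CSV tables under ``outdir``.

    Output is canonical: absent parents are empty cells, dates ISO-8601,
    so ``write(read(x))`` is byte-stable for canonical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "animals": outdir / "animals.csv",
        "traits": outdir / "traits.csv",
        "repro": outdir / "repro.csv",
        "health": outdir / "health.csv",
    }
    with open(paths["animals"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ANIMAL_COLS)
        for a in ds.animals:
            w.writerow([
                a.animal_id, a.sire_id or "", a.dam_id or "", a.sex.value, a.breed,
                a.birth_date.isoformat(), a.farm_id, a.entry_date.isoformat(),
                a.disposal_date.isoformat() if a.disposal_date else "",
                a.disposal_reason.value if a.disposal_reason else "",
            ])
    with open(paths["traits"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_TRAIT_COLS)
        for t in ds.traits:
            w.writerow([t.animal_id, t.trait_code, repr(t.value), t.record_date.isoformat()])
    with open(paths["repro"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_REPRO_COLS)
        for r in ds.repro:
            w.writerow([
                r.ewe_id, r.ram_id, r.mating_date.isoformat(), r.outcome.value,
                r.outcome_date.isoformat() if r.outcome_date else "",
                ";".join(r.lamb_ids),
            ])
    with open(paths["health"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_HEALTH_COLS)
        for h in ds.health:
            w.writerow([h.animal_id, h.date.isoformat(), h.kind.value, h.detail, h.drug or ""])
    return paths


# ---------------------------------------------------------------------------
# validation

def validate_flock(
    ds: FlockDataset,
    trait_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> list[Finding]:
    """Referential-integrity and range checks; findings are data, not errors.

    Returns one finding per violation: dangling references, sires that are
    not MALE / dams not FEMALE, self-parenting, out-of-order dates, trait
    values outside configured bounds, events dated before birth.  An empty
    list means the dataset is clean.
    """
    findings: list[Finding] = []
    index = ds.animal_index()

    for a in ds.animals:
        if a.sire_id == a.animal_id or a.dam_id == a.animal_id:
            findings.append(Finding("SELF_PARENT", "ERROR",
                                    f"animal {a.animal_id} is its own parent", a.animal_id))
        for pid, role, want in ((a.sire_id, "sire", Sex.MALE), (a.dam_id, "dam", Sex.FEMALE)):
            if pid is None:
                continue
            parent = index.get(pid)
            if parent is None:
                findings.append(Finding("DANGLING_PARENT", "WARNING",
                                        f"{role} {pid} of {a.animal_id} not registered", a.animal_id))
            elif role == "sire" and parent.sex != want:
                findings.append(Finding("SIRE_SEX", "ERROR",
                                        f"sire {pid} of {a.animal_id} has sex {parent.sex.value}", a.animal_id))
            elif role == "dam" and parent.sex != want:
                findings.append(Finding("DAM_SEX", "ERROR",
                                        f"dam {pid} of {a.animal_id} has sex {parent.sex.value}", a.animal_id))
        if a.entry_date < a.birth_date:
            findings.append(Finding("ENTRY_BEFORE_BIRTH", "ERROR",
                                    f"{a.animal_id}: entry {a.entry_date} precedes birth {a.birth_date}",
                                    a.animal_id))
        if a.disposal_date is not None and a.disposal_date < a.entry_date:
            findings.append(Finding("DISPOSAL_BEFORE_ENTRY", "ERROR",
                                    f"{a.animal_id}: disposal {a.disposal_date} precedes entry {a.entry_date}",
                                    a.animal_id))
        if (a.disposal_date is None) != (a.disposal_reason is None):
            findings.append(Finding("DISPOSAL_INCOMPLETE", "ERROR",
                                    f"{a.animal_id}: disposal date and reason must appear together",
                                    a.animal_id))

    for t in ds.traits:
        animal = index.get(t.animal_id)
        if animal is None:
            findings.append(Finding("DANGLING_ANIMAL", "WARNING",
                                    f"trait record for unregistered animal {t.animal_id}", t.animal_id))
            continue
        if t.record_date < animal.birth_date:
            findings.append(Finding("RECORD_BEFORE_BIRTH", "ERROR",
                                    f"{t.animal_id}: {t.trait_code} on {t.record_date} precedes birth",
                                    t.animal_id))
        if not math.isfinite(t.value):
            findings.append(Finding("VALUE_NOT_FINITE", "ERROR",
                                    f"{t.animal_id}: {t.trait_code} value not finite", t.animal_id))
        elif trait_bounds and t.trait_code in trait_bounds:
            lo, hi = trait_bounds[t.trait_code]
            if not (lo <= t.value <= hi):
                findings.append(Finding("VALUE_RANGE", "ERROR",
                                        f"{t.animal_id}: {t.trait_code}={t.value} outside [{lo}, {hi}]",
                                        t.animal_id))

    for r in ds.repro:
        for rid, role in ((r.ewe_id, "ewe"), (r.ram_id, "ram")):
            if rid not in index:
                findings.append(Finding("DANGLING_ANIMAL", "WARNING",
                                        f"reproduction event references unregistered {role} {rid}", rid))
        if r.outcome_date is not None and r.outcome_date < r.mating_date:
            findings.append(Finding("OUTCOME_BEFORE_MATING", "ERROR",
                                    f"ewe {r.ewe_id}: outcome {r.outcome_date} precedes mating", r.ewe_id))
        if (r.outcome == ReproOutcome.LAMBING) != bool(r.lamb_ids):
            findings.append(Finding("LAMBS_OUTCOME_MISMATCH", "ERROR",
                                    f"ewe {r.ewe_id}: lamb list inconsistent with outcome {r.outcome.value}",
                                    r.ewe_id))
        for lid in r.lamb_ids:
            if lid not in index:
                findings.append(Finding("DANGLING_ANIMAL", "WARNING",
                                        f"lamb {lid} of ewe {r.ewe_id} not registered", lid))

    for h in ds.health:
        animal = index.get(h.animal_id)
        if animal is None:
            findings.append(Finding("DANGLING_ANIMAL", "WARNING",
                                    f"health event for unregistered animal {h.animal_id}", h.animal_id))
        elif h.date < animal.birth_date:
            findings.append(Finding("EVENT_BEFORE_BIRTH", "ERROR",
                                    f"{h.animal_id}: {h.kind.value} on {h.date} precedes birth", h.animal_id))

    return findings


# ---------------------------------------------------------------------------
# snapshots

def effective_sex(ds: FlockDataset, animal: AnimalRecord, as_of: dt.date) -> Sex:
    """Registered sex, flipped to WETHER once a CASTRATION event has occurred."""
    if animal.sex == Sex.MALE:
        for h in ds.health:
            if (h.animal_id == animal.animal_id and h.kind == HealthKind.CASTRATION
                    and h.date <= as_of):
                return Sex.WETHER
    return animal.sex


def _age_class(age_days: int) -> str:
    if age_days < 365:
        return "LAMB"
    if age_days < 548:  # ~18 months
        return "HOGGET"
    return "ADULT"


def snapshot(ds: FlockDataset, as_of: dt.date) -> FarmSnapshot:
    """Live animals on a given date, with derived age.

    An animal is present iff ``entry_date <= as_of`` and it has no disposal
    dated on or before ``as_of``; i.e. a disposal on day *d* removes the
    animal from snapshots with ``as_of >= d`` (present through the day
    before disposal).
    """
    live: list[SnapshotAnimal] = []
    for a in ds.animals:
        if a.entry_date > as_of:
            continue
        if a.disposal_date is not None and a.disposal_date <= as_of:
            continue
        age = (as_of - a.birth_date).days
        live.append(SnapshotAnimal(
            record=a,
            age_days=age,
            age_class=_age_class(age),
            sex=effective_sex(ds, a, as_of),
        ))
    return FarmSnapshot(as_of=as_of, animals=live)
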