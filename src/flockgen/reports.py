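"""Date-indexed farm reports: inventories, reproduction, production, wool,
health, disposal and yearly trends.

Every report is a pure function of (dataset, request, config), so repeated
runs on the same inputs are byte-identical; run timestamps live only in
metadata.  Reports compose the snapshot primitive — farm state as of any
calendar date, current or past — with simple aggregations, and each table
has a documented deterministic sort key.

Conventions (configurable): a lamb is under 12 months; a breedable ewe or
ram is at least 18 months old (wethers are never breedable); the lambing
rate for a calendar year divides lambing events in the year by breedable
ewes present at the year's start; mortality divides deaths in the year by
the year-start snapshot size.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .config import FlockConfig
from .records import (
    DisposalReason,
    FlockDataset,
    HealthKind,
    ReproOutcome,
    Sex,
    snapshot,
)

__all__ = [
    "ReportError",
    "ReportRequest",
    "ReportTable",
    "inventory_report",
    "reproduction_report",
    "production_report",
    "wool_report",
    "health_report",
    "disposal_report",
    "trend_report",
]

UNDEFINED = "NA"  # marker for rates with an empty denominator


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class ReportRequest:
    as_of: dt.date
    breed: Optional[str] = None
    farm: Optional[str] = None


@dataclass
class ReportTable:
    name: str
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_csv(self) -> str:
        return self.table.to_csv(index=False)


def _filtered_snapshot(ds: FlockDataset, req: ReportRequest, cfg: FlockConfig):
    snap = snapshot(ds, req.as_of)
    animals = snap.animals
    if req.breed is not None:
        known = {a.breed for a in ds.animals}
        if req.breed not in known:
            raise ReportError(f"unknown breed filter {req.breed!r}")
        animals = [a for a in animals if a.record.breed == req.breed]
    if req.farm is not None:
        animals = [a for a in animals if a.record.farm_id == req.farm]
    return animals


def _classify(a, cfg: FlockConfig) -> str:
    if a.age_days < cfg.lamb_age_days:
        return "LAMB"
    if a.sex == Sex.WETHER:
        return "WETHER"
    if a.age_days >= cfg.breedable_age_days:
        return "EWE" if a.sex == Sex.FEMALE else "RAM"
    return "HOGGET"


def inventory_report(ds: FlockDataset, req: ReportRequest,
                     cfg: FlockConfig | None = None) -> ReportTable:
    """Breed-wise counts of total sheep, breedable ewes and rams, wethers
    and lambs on the snapshot date.  Rows sorted by breed; a TOTAL row
    closes the table."""
    cfg = cfg or FlockConfig()
    animals = _filtered_snapshot(ds, req, cfg)
    by_breed: dict[str, dict[str, int]] = {}
    for a in animals:
        row = by_breed.setdefault(a.record.breed, {
            "TOTAL": 0, "EWES": 0, "RAMS": 0, "WETHERS": 0, "LAMBS": 0, "HOGGETS": 0,
        })
        row["TOTAL"] += 1
        cls = _classify(a, cfg)
        key = {"EWE": "EWES", "RAM": "RAMS", "WETHER": "WETHERS",
               "LAMB": "LAMBS", "HOGGET": "HOGGETS"}[cls]
        row[key] += 1
    rows = [{"breed": b, **counts} for b, counts in sorted(by_breed.items())]
    total = {"breed": "TOTAL"}
    for col in ("TOTAL", "EWES", "RAMS", "WETHERS", "LAMBS", "HOGGETS"):
        total[col] = sum(r[col] for r in rows)
    rows.append(total)
    return ReportTable(
        name="inventory",
        table=pd.DataFrame(rows, columns=["breed", "TOTAL", "EWES", "RAMS",
                                          "WETHERS", "LAMBS", "HOGGETS"]),
        metadata={"as_of": req.as_of.isoformat(), "breed": req.breed, "farm": req.farm},
    )


def reproduction_report(ds: FlockDataset, req: ReportRequest,
                        cfg: FlockConfig | None = None) -> ReportTable:
    """Lambing/abortion inventory for the calendar year of the request.

    Per-ewe rows (outcome, lamb count, parity through as_of) sorted by
    ewe id; the lambing rate divides the year's lambing events by
    breedable ewes present at the year start (NA when none)."""
    cfg = cfg or FlockConfig()
    year = req.as_of.year
    start = dt.date(year, 1, 1)

    def in_year(d: Optional[dt.date]) -> bool:
        return d is not None and d.year == year and d <= req.as_of

    events = [r for r in ds.repro if in_year(r.outcome_date)]
    if req.farm is not None:
        farm_of = {a.animal_id: a.farm_id for a in ds.animals}
        events = [r for r in events if farm_of.get(r.ewe_id) == req.farm]

    parity: dict[str, int] = {}
    for r in ds.repro:
        if (r.outcome == ReproOutcome.LAMBING and r.outcome_date is not None
                and r.outcome_date <= req.as_of):
            parity[r.ewe_id] = parity.get(r.ewe_id, 0) + 1

    rows = []
    for r in sorted(events, key=lambda r: (r.ewe_id, r.outcome_date or req.as_of)):
        rows.append({
            "ewe_id": r.ewe_id, "ram_id": r.ram_id,
            "outcome": r.outcome.value,
            "outcome_date": r.outcome_date.isoformat() if r.outcome_date else "",
            "n_lambs": len(r.lamb_ids),
            "parity": parity.get(r.ewe_id, 0),
        })

    start_snap = _filtered_snapshot(ds, ReportRequest(start, req.breed, req.farm), cfg)
    breedable_ewes = sum(1 for a in start_snap if _classify(a, cfg) == "EWE")
    n_lambings = sum(1 for r in events if r.outcome == ReproOutcome.LAMBING)
    n_abortions = sum(1 for r in events if r.outcome == ReproOutcome.ABORTION)
    rate = n_lambings / breedable_ewes if breedable_ewes > 0 else None
    return ReportTable(
        name="reproduction",
        table=pd.DataFrame(rows, columns=["ewe_id", "ram_id", "outcome",
                                          "outcome_date", "n_lambs", "parity"]),
        metadata={
            "as_of": req.as_of.isoformat(), "year": year,
            "n_lambings": n_lambings, "n_abortions": n_abortions,
            "breedable_ewes_at_start": breedable_ewes,
            "lambing_rate": rate if rate is not None else UNDEFINED,
        },
    )


def production_report(ds: FlockDataset, req: ReportRequest,
                      cfg: FlockConfig | None = None) -> ReportTable:
    """Body weights at the standard ages (0/90/180/270/365 d).

    Each animal gets, per age point, the weight record nearest that age
    within +/-15% of it (minimum +/-7 d so the birth column can fill);
    records outside every window are left blank.  Breed means close the
    table.  Rows sorted by animal id."""
    cfg = cfg or FlockConfig()
    animals = _filtered_snapshot(ds, req, cfg)
    birth = {a.record.animal_id: a.record.birth_date for a in animals}
    breed_of = {a.record.animal_id: a.record.breed for a in animals}
    weight_codes = {"BWT", "WWT", "W6M", "W9M", "W12M"}

    per_animal: dict[str, dict[int, tuple[int, float]]] = {aid: {} for aid in birth}
    for t in ds.traits:
        if t.trait_code not in weight_codes or t.animal_id not in birth:
            continue
        if t.record_date > req.as_of:
            continue
        age = (t.record_date - birth[t.animal_id]).days
        for std in cfg.standard_ages_days:
            window = max(std * cfg.age_window_fraction, 7)
            if abs(age - std) <= window:
                cur = per_animal[t.animal_id].get(std)
                if cur is None or abs(age - std) < abs(cur[0] - std):
                    per_animal[t.animal_id][std] = (age, t.value)

    cols = [f"d{std}" for std in cfg.standard_ages_days]
    rows = []
    for aid in sorted(birth):
        row: dict = {"animal_id": aid, "breed": breed_of[aid]}
        for std, col in zip(cfg.standard_ages_days, cols):
            hit = per_animal[aid].get(std)
            row[col] = hit[1] if hit else None
        rows.append(row)
    df = pd.DataFrame(rows, columns=["animal_id", "breed"] + cols)
    means = df.groupby("breed")[cols].mean().reset_index()
    means.insert(0, "animal_id", "MEAN:" + means["breed"])
    df = pd.concat([df, means], ignore_index=True)
    return ReportTable(
        name="production", table=df,
        metadata={"as_of": req.as_of.isoformat(), "windows_pct": cfg.age_window_fraction},
    )


def wool_report(ds: FlockDataset, req: ReportRequest,
                cfg: FlockConfig | None = None) -> ReportTable:
    """Per-animal wool summary: clip count, total and mean greasy fleece
    yield, latest fibre diameter and staple length.  Animals without wool
    records keep a zero-clip row.  Sorted by animal id."""
    cfg = cfg or FlockConfig()
    animals = _filtered_snapshot(ds, req, cfg)
    ids = sorted(a.record.animal_id for a in animals)
    idset = set(ids)
    gfy: dict[str, list[float]] = {aid: [] for aid in ids}
    latest: dict[str, dict[str, tuple[dt.date, float]]] = {aid: {} for aid in ids}
    for t in ds.traits:
        if t.animal_id not in idset or t.record_date > req.as_of:
            continue
        if t.trait_code == "GFY":
            gfy[t.animal_id].append(t.value)
        elif t.trait_code in ("FD", "SL"):
            cur = latest[t.animal_id].get(t.trait_code)
            if cur is None or t.record_date >= cur[0]:
                latest[t.animal_id][t.trait_code] = (t.record_date, t.value)
    rows = []
    for aid in ids:
        clips = gfy[aid]
        rows.append({
            "animal_id": aid,
            "clips": len(clips),
            "total_gfy": sum(clips),
            "mean_gfy": sum(clips) / len(clips) if clips else None,
            "latest_fd": latest[aid].get("FD", (None, None))[1],
            "latest_sl": latest[aid].get("SL", (None, None))[1],
        })
    return ReportTable(
        name="wool",
        table=pd.DataFrame(rows, columns=["animal_id", "clips", "total_gfy",
                                          "mean_gfy", "latest_fd", "latest_sl"]),
        metadata={"as_of": req.as_of.isoformat()},
    )


def health_report(ds: FlockDataset, req: ReportRequest,
                  cfg: FlockConfig | None = None) -> ReportTable:
    """Health events in the calendar year of the request, sorted by date
    then animal id, with per-kind counts in the metadata."""
    cfg = cfg or FlockConfig()
    year = req.as_of.year
    farm_of = {a.animal_id: a.farm_id for a in ds.animals}
    events = [h for h in ds.health
              if h.date.year == year and h.date <= req.as_of]
    if req.farm is not None:
        events = [h for h in events if farm_of.get(h.animal_id) == req.farm]
    events.sort(key=lambda h: (h.date, h.animal_id, h.kind.value))
    rows = [{
        "date": h.date.isoformat(), "animal_id": h.animal_id,
        "kind": h.kind.value, "detail": h.detail, "drug": h.drug or "",
    } for h in events]
    by_kind = {k.value: sum(1 for h in events if h.kind == k) for k in HealthKind}
    return ReportTable(
        name="health",
        table=pd.DataFrame(rows, columns=["date", "animal_id", "kind", "detail", "drug"]),
        metadata={"as_of": req.as_of.isoformat(), "year": year, "counts": by_kind},
    )


def disposal_report(ds: FlockDataset, req: ReportRequest,
                    cfg: FlockConfig | None = None) -> ReportTable:
    """Disposals in the calendar year: one row per disposal (sorted by
    date then id), breed-wise death counts and the mortality rate
    deaths / year-start snapshot size in the metadata."""
    cfg = cfg or FlockConfig()
    year = req.as_of.year
    start = dt.date(year, 1, 1)
    disposed = [a for a in ds.animals
                if a.disposal_date is not None
                and a.disposal_date.year == year and a.disposal_date <= req.as_of]
    if req.farm is not None:
        disposed = [a for a in disposed if a.farm_id == req.farm]
    if req.breed is not None:
        disposed = [a for a in disposed if a.breed == req.breed]
    disposed.sort(key=lambda a: (a.disposal_date, a.animal_id))
    rows = [{
        "animal_id": a.animal_id, "breed": a.breed, "farm_id": a.farm_id,
        "disposal_date": a.disposal_date.isoformat(),
        "reason": a.disposal_reason.value,
    } for a in disposed]
    deaths_by_breed: dict[str, int] = {}
    for a in disposed:
        if a.disposal_reason == DisposalReason.DEATH:
            deaths_by_breed[a.breed] = deaths_by_breed.get(a.breed, 0) + 1
    by_reason = {r.value: sum(1 for a in disposed if a.disposal_reason == r)
                 for r in DisposalReason}
    start_size = len(_filtered_snapshot(ds, ReportRequest(start, req.breed, req.farm), cfg))
    deaths = sum(deaths_by_breed.values())
    mortality = deaths / start_size if start_size > 0 else None
    return ReportTable(
        name="disposal",
        table=pd.DataFrame(rows, columns=["animal_id", "breed", "farm_id",
                                          "disposal_date", "reason"]),
        metadata={
            "as_of": req.as_of.isoformat(), "year": year,
            "by_reason": by_reason, "deaths_by_breed": deaths_by_breed,
            "snapshot_at_year_start": start_size,
            "mortality": mortality if mortality is not None else UNDEFINED,
        },
    )


class TrendMetric(str, Enum):
    TOTAL = "TOTAL"
    LAMBING_RATE = "LAMBING_RATE"
    MORTALITY = "MORTALITY"
    MEAN_W12M = "MEAN_W12M"


def trend_report(ds: FlockDataset, metric: TrendMetric | str,
                 years: list[int], cfg: FlockConfig | None = None,
                 farm: Optional[str] = None) -> ReportTable:
    """Yearly trend of a scalar metric, each year evaluated exactly as the
    corresponding single-year report; years with no defined value get an
    explicit NA, never interpolation."""
    cfg = cfg or FlockConfig()
    metric = TrendMetric(metric)
    if not years:
        raise ReportError("need at least one year")
    rows = []
    for year in sorted(years):
        eoy = dt.date(year, 12, 31)
        req = ReportRequest(as_of=eoy, farm=farm)
        value = None
        if metric == TrendMetric.TOTAL:
            value = len(_filtered_snapshot(ds, req, cfg))
        elif metric == TrendMetric.LAMBING_RATE:
            value = reproduction_report(ds, req, cfg).metadata["lambing_rate"]
            value = None if value == UNDEFINED else value
        elif metric == TrendMetric.MORTALITY:
            value = disposal_report(ds, req, cfg).metadata["mortality"]
            value = None if value == UNDEFINED else value
        else:  # MEAN_W12M
            animals = {a.record.animal_id for a in _filtered_snapshot(ds, req, cfg)}
            vals = [t.value for t in ds.traits
                    if t.trait_code == "W12M" and t.record_date.year == year
                    and t.animal_id in animals]
            value = sum(vals) / len(vals) if vals else None
        rows.append({"year": year, "value": value if value is not None else UNDEFINED})
    return ReportTable(
        name=f"trend:{metric.value}",
        table=pd.DataFrame(rows, columns=["year", "value"]),
        metadata={"metric": metric.value, "farm": farm},
    )
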