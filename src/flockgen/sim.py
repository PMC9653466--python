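"""Synthetic multi-generation, multi-farm flocks with known genetics.

The generator follows the standard additive infinitesimal model so that
every estimator in the package has a surface with retained ground truth:

* founders draw breeding values a ~ N(0, sigma2_A) with
  sigma2_A = h2 * sigma2_p;
* an offspring inherits a = (a_s + a_d)/2 + m, with the Mendelian-sampling
  term m ~ N(0, sigma2_A/2 * (1 - (F_s + F_d)/2)) — the parental-inbreeding
  correction makes consistency with the relationship matrix a testable
  theorem rather than an assumption;
* phenotypes add fixed sex and year-of-birth effects and residual noise
  e ~ N(0, (1 - h2) * sigma2_p).

Mating is random within generation with sires reused across dams;
parent-offspring matings are avoided unless explicitly allowed.  Animals
die before 12 months with probability 1 - survival_to_12m (disposal
records, reason DEATH) and then contribute a birth weight but no
12-month record.  Farms are assigned round-robin.  All randomness flows
from one seed, so seeded runs regenerate identical datasets.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .pedigree import build_pedigree, inbreeding
from .records import (
    AnimalRecord,
    DisposalReason,
    FlockDataset,
    ReproductionEvent,
    ReproOutcome,
    Sex,
    TraitRecord,
)
from .selection import WoolPriceObservation
from .varcomp import SibDesign

__all__ = [
    "SimParams",
    "SimTruth",
    "SimError",
    "simulate_flock",
    "simulate_sib_design",
    "simulate_wool_market",
]

BASE_YEAR = 2010


class SimError(ValueError):
    pass


@dataclass
class SimParams:
    n_founder_sires: int = 10
    n_founder_dams: int = 50
    n_generations: int = 3
    progeny_per_dam: int = 2
    h2_true: float = 0.3
    sigma2_p: float = 16.0      # kg^2 for a 12-month weight
    mu: float = 30.0            # kg, 12-month weight mean
    sex_effect: float = 3.0     # additive shift for MALE, kg
    year_effects: tuple[float, ...] = ()  # per-generation shifts, kg
    n_farms: int = 1
    survival_to_12m: float = 0.9
    allow_close_mating: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_founder_sires, self.n_founder_dams,
               self.n_generations, self.progeny_per_dam, self.n_farms) < 1:
            raise SimError("counts must be positive")
        if not (0.0 < self.h2_true < 1.0):
            raise SimError("h2_true must lie in (0, 1)")
        if self.sigma2_p <= 0:
            raise SimError("sigma2_p must be positive")
        if not (0.0 < self.survival_to_12m <= 1.0):
            raise SimError("survival_to_12m must lie in (0, 1]")


@dataclass
class SimTruth:
    true_bv: dict[str, float]
    F: dict[str, float]
    residual: dict[str, float]


def _year_effect(p: SimParams, gen: int) -> float:
    if gen < len(p.year_effects):
        return float(p.year_effects[gen])
    return 0.0


def simulate_flock(p: SimParams) -> tuple[FlockDataset, SimTruth]:
    """Generate a pedigreed flock with retained true breeding values.

    Generations are birth-year cohorts starting at 2010; generation g
    animals are born on 2010+g-01-01 and weighed at birth (BWT) and, if
    they survive, at 12 months (W12M).  Birth weight is generated from the
    same breeding value at one tenth of the genetic and environmental
    scale of the 12-month weight.
    """
    rng = np.random.default_rng(p.seed)
    s2a = p.h2_true * p.sigma2_p
    s2e = (1.0 - p.h2_true) * p.sigma2_p

    ds = FlockDataset()
    truth = SimTruth(true_bv={}, F={}, residual={})
    parent_of: dict[str, tuple[str | None, str | None]] = {}
    bv: dict[str, float] = {}
    alive_males: list[str] = []
    alive_females: list[str] = []
    counter = 0

    def register(sex: Sex, gen: int, sire: str | None, dam: str | None) -> str:
        nonlocal counter
        counter += 1
        aid = f"A{counter:05d}"
        birth = dt.date(BASE_YEAR + gen, 1, 1)
        farm = f"F{(counter - 1) % p.n_farms + 1}"
        if sire is None:
            a = rng.normal(0.0, np.sqrt(s2a))
        else:
            fs = truth.F[sire]
            fd = truth.F[dam]
            msv = 0.5 * s2a * (1.0 - 0.5 * (fs + fd))
            a = 0.5 * (bv[sire] + bv[dam]) + rng.normal(0.0, np.sqrt(msv))
        bv[aid] = a
        parent_of[aid] = (sire, dam)
        # realized F from the pedigree built so far (recursive kinship)
        fsire = 0.0
        if sire is not None:
            fsire = _kinship(parent_of, sire, dam)
        truth.F[aid] = fsire
        truth.true_bv[aid] = a

        dead = rng.random() > p.survival_to_12m
        disp_date = birth + dt.timedelta(days=int(rng.integers(10, 330))) if dead else None
        ds.animals.append(AnimalRecord(
            animal_id=aid, sire_id=sire, dam_id=dam, sex=sex, breed="SYN",
            birth_date=birth, farm_id=farm, entry_date=birth,
            disposal_date=disp_date,
            disposal_reason=DisposalReason.DEATH if dead else None,
        ))
        year_eff = _year_effect(p, gen)
        sex_eff = p.sex_effect if sex == Sex.MALE else 0.0
        e_bwt = rng.normal(0.0, np.sqrt(s2e) / 10.0)
        ds.traits.append(TraitRecord(aid, "BWT", max(
            0.5, p.mu / 10.0 + sex_eff / 10.0 + a / 10.0 + e_bwt), birth))
        if not dead:
            e12 = rng.normal(0.0, np.sqrt(s2e))
            truth.residual[aid] = e12
            y12 = p.mu + sex_eff + year_eff + a + e12
            # record on the first birthday so year cohorts stay distinct
            ds.traits.append(TraitRecord(
                aid, "W12M", max(1.0, y12),
                dt.date(birth.year + 1, birth.month, birth.day)))
            if sex == Sex.MALE:
                alive_males.append(aid)
            else:
                alive_females.append(aid)
        return aid

    # founders, generation 0
    for _ in range(p.n_founder_sires):
        register(Sex.MALE, 0, None, None)
    for _ in range(p.n_founder_dams):
        register(Sex.FEMALE, 0, None, None)

    for gen in range(1, p.n_generations):
        sires = list(alive_males)
        dams = list(alive_females)
        if not sires or not dams:
            raise SimError(f"no surviving parents for generation {gen}")
        alive_males.clear()
        alive_females.clear()
        for dam in dams:
            candidates = sires
            if not p.allow_close_mating:
                sd, dd = parent_of[dam]
                candidates = [s for s in sires
                              if s not in (sd, dd) and dam not in parent_of[s][:2]]
                if not candidates:
                    candidates = sires
            sire = candidates[int(rng.integers(len(candidates)))]
            n_lambs = p.progeny_per_dam
            lamb_ids = []
            for _ in range(n_lambs):
                sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
                lamb_ids.append(register(sex, gen, sire, dam))
            mating = dt.date(BASE_YEAR + gen - 1, 8, 1)
            ds.repro.append(ReproductionEvent(
                ewe_id=dam, ram_id=sire, mating_date=mating,
                outcome=ReproOutcome.LAMBING,
                outcome_date=dt.date(BASE_YEAR + gen, 1, 1),
                lamb_ids=tuple(lamb_ids),
            ))
        # older generation can breed again only if still alive; keep cohorts
        # discrete by carrying survivors of the new generation forward only
        if not alive_males:
            alive_males.extend(sires)  # fall back so the next round is feasible
        if not alive_females:
            alive_females.extend(dams)

    return ds, truth


def _kinship(parent_of: dict, i: str | None, j: str | None,
             _memo: dict | None = None) -> float:
    if _memo is None:
        _memo = {}
    if i is None or j is None:
        return 0.0
    key = (i, j) if i <= j else (j, i)
    if key in _memo:
        return _memo[key]
    if i == j:
        s, d = parent_of[i]
        v = 0.5 * (1.0 + _kinship(parent_of, s, d, _memo))
    else:
        # recurse through the animal registered later (its parents precede it)
        a, b = (i, j) if i > j else (j, i)
        s, d = parent_of[a]
        v = 0.5 * (_kinship(parent_of, s, b, _memo) + _kinship(parent_of, d, b, _memo))
    _memo[key] = v
    return v


def simulate_sib_design(
    s: int, d: int, n: int, h2: float, sigma2_p: float = 1.0,
    mu: float = 0.0, seed: int = 0,
) -> tuple[SibDesign, dict]:
    """Balanced nested sib design: s sires x d dams x n progeny.

    y_ijk = mu + s_i + d_ij + e_ijk with sigma2_s = sigma2_d =
    h2*sigma2_p/4 (no maternal or dominance inflation) and sigma2_w the
    remainder.  Returns the design and the true component values.
    """
    if s < 2 or d < 1 or n < 2:
        raise SimError("need s >= 2 sires, d >= 1 dams, n >= 2 progeny")
    if not (0.0 <= h2 < 1.0):
        raise SimError("h2 must lie in [0, 1)")
    s2s = s2d = h2 * sigma2_p / 4.0
    s2w = sigma2_p - s2s - s2d
    if s2w <= 0:
        raise SimError("impossible partition: within variance non-positive")
    rng = np.random.default_rng(seed)
    groups: dict[str, dict[str, list[float]]] = {}
    for i in range(s):
        si = rng.normal(0.0, np.sqrt(s2s)) if s2s > 0 else 0.0
        dams: dict[str, list[float]] = {}
        for j in range(d):
            dij = rng.normal(0.0, np.sqrt(s2d)) if s2d > 0 else 0.0
            vals = mu + si + dij + rng.normal(0.0, np.sqrt(s2w), size=n)
            dams[f"S{i+1}D{j+1}"] = [float(v) for v in vals]
        groups[f"S{i+1}"] = dams
    truth = {"sigma2_s": s2s, "sigma2_d": s2d, "sigma2_w": s2w, "h2": h2}
    return SibDesign(groups=groups), truth


def simulate_wool_market(
    slope_fd: float, slope_sl: float, intercept: float,
    noise_sd: float, n: int, seed: int = 0,
) -> list[WoolPriceObservation]:
    """Market price table: price = intercept + slope_fd*FD + slope_sl*SL + e.

    Fibre diameter is uniform on 18-36 um and staple length on 5-12 cm —
    realistic apparel-to-carpet wool ranges.  Prices are floored just
    above zero so observations remain valid.
    """
    if n < 3:
        raise SimError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    fd = rng.uniform(18.0, 36.0, size=n)
    sl = rng.uniform(5.0, 12.0, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    price = intercept + slope_fd * fd + slope_sl * sl + noise
    price = np.maximum(price, 0.01)
    return [WoolPriceObservation(float(p), float(f), float(s))
            for p, f, s in zip(price, fd, sl)]
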