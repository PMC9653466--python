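import datetime as dt

import numpy as np
import pytest

from flockgen.records import (
    AnimalRecord, DisposalReason, FlockDataset, HealthEvent, HealthKind,
    ReproductionEvent, ReproOutcome, Sex, TraitRecord,
)


def kinship_oracle(trios):
    """Brute-force recursive kinship on (id, sire, dam) trios.

    Independent of the package's pedigree code: plain dict recursion with
    no ordering assumptions beyond parents being listed somewhere.
    """
    parents = {aid: (s, d) for aid, s, d in trios}
    order = {aid: i for i, (aid, _, _) in enumerate(trios)}

    def phi(i, j, depth=0):
        if i is None or j is None:
            return 0.0
        assert depth < 200
        if i == j:
            s, d = parents[i]
            return 0.5 * (1.0 + phi(s, d, depth + 1))
        # recurse through whichever animal has the larger listing index;
        # founders-first generation keeps this terminating
        a, b = (i, j) if order[i] >= order[j] else (j, i)
        s, d = parents[a]
        if s is None and d is None:
            a, b = b, a
            s, d = parents[a]
            if s is None and d is None:
                return 0.0
        return 0.5 * (phi(s, b, depth + 1) + phi(d, b, depth + 1))

    return phi, parents


def random_trios(rng, n, founder_frac=0.35):
    """Random valid pedigree as (id, sire, dam) trios, parents precede."""
    trios = []
    ids = [f"P{i}" for i in range(n)]
    for i, aid in enumerate(ids):
        if i < 2 or rng.random() < founder_frac:
            trios.append((aid, None, None))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            trios.append((aid, ids[s], ids[d]))
    return trios


def _animal(aid, sire, dam, sex, breed="AWASSI", birth="2014-03-01", farm="F1",
            entry=None, dd=None, dr=None):
    return AnimalRecord(
        animal_id=aid, sire_id=sire, dam_id=dam, sex=Sex(sex), breed=breed,
        birth_date=dt.date.fromisoformat(birth), farm_id=farm,
        entry_date=dt.date.fromisoformat(entry or birth),
        disposal_date=dt.date.fromisoformat(dd) if dd else None,
        disposal_reason=DisposalReason(dr) if dr else None,
    )


@pytest.fixture
def small_flock() -> FlockDataset:
    """Hand-built two-breed flock: 2 founder rams, 3 ewes, 4 lambs, one
    wether, one disposal, wool and weight records, a castration."""
    animals = [
        _animal("R1", None, None, "MALE", birth="2012-01-10"),
        _animal("R2", None, None, "MALE", "MERINO", birth="2012-02-15", farm="F2"),
        _animal("E1", None, None, "FEMALE", birth="2012-03-01"),
        _animal("E2", None, None, "FEMALE", birth="2012-03-20"),
        _animal("E3", None, None, "FEMALE", "MERINO", birth="2012-04-05", farm="F2"),
        _animal("L1", "R1", "E1", "MALE", birth="2015-01-15"),
        _animal("L2", "R1", "E1", "FEMALE", birth="2015-01-15"),
        _animal("L3", "R1", "E2", "MALE", birth="2015-02-01",
                dd="2015-11-20", dr="DEATH"),
        _animal("L4", "R2", "E3", "MALE", "MERINO", birth="2015-02-10", farm="F2"),
        _animal("W1", None, None, "WETHER", birth="2013-06-01"),
    ]
    d = dt.date.fromisoformat
    traits = [
        TraitRecord("L1", "BWT", 4.1, d("2015-01-15")),
        TraitRecord("L2", "BWT", 3.8, d("2015-01-15")),
        TraitRecord("L3", "BWT", 3.5, d("2015-02-01")),
        TraitRecord("L4", "BWT", 4.4, d("2015-02-10")),
        TraitRecord("L1", "WWT", 18.0, d("2015-04-16")),  # 91 d old
        TraitRecord("L1", "W12M", 34.0, d("2016-01-15")),
        TraitRecord("L2", "W12M", 30.5, d("2016-01-15")),
        TraitRecord("L4", "W12M", 36.0, d("2016-02-10")),
        TraitRecord("E1", "GFY", 1.2, d("2014-10-01")),
        TraitRecord("E1", "GFY", 1.4, d("2015-10-01")),
        TraitRecord("E1", "FD", 24.0, d("2015-10-01")),
        TraitRecord("E1", "SL", 8.5, d("2015-10-01")),
    ]
    repro = [
        ReproductionEvent("E1", "R1", d("2014-08-20"), ReproOutcome.LAMBING,
                          d("2015-01-15"), ("L1", "L2")),
        ReproductionEvent("E2", "R1", d("2014-09-01"), ReproOutcome.LAMBING,
                          d("2015-02-01"), ("L3",)),
        ReproductionEvent("E3", "R2", d("2014-09-10"), ReproOutcome.LAMBING,
                          d("2015-02-10"), ("L4",)),
        ReproductionEvent("E2", "R1", d("2015-08-15"), ReproOutcome.ABORTION,
                          d("2015-11-01"), ()),
    ]
    health = [
        HealthEvent("L1", d("2015-03-01"), HealthKind.VACCINATION, "FMD", "vaccine-A"),
        HealthEvent("L3", d("2015-06-01"), HealthKind.DEWORMING, "routine", "albendazole"),
        HealthEvent("L4", d("2015-09-01"), HealthKind.CASTRATION, "", None),
    ]
    return FlockDataset(animals=animals, traits=traits, repro=repro, health=health)


@pytest.fixture(scope="session")
def sim_flock():
    from flockgen.sim import SimParams, simulate_flock
    return simulate_flock(SimParams(
        n_founder_sires=8, n_founder_dams=40, n_generations=3,
        progeny_per_dam=2, h2_true=0.3, n_farms=2, seed=11,
    ))
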