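"""Pedigree algebra: relationship matrix A, its sparse inverse, inbreeding.

The numerator relationship matrix A holds additive genetic relationships
a_ij between all pedigree members; its diagonal is 1 + F_i where F_i is the
inbreeding coefficient.  A is built by the tabular method on a
topologically sorted pedigree; A^-1 is assembled directly from pedigree
structure by Henderson's per-animal rules with Meuwissen–Luo style
inbreeding adjustment, without ever inverting A.

Two independent routes to F are provided: the recursive-kinship route used
in production, and Wright's path-counting formula

    F_X = sum over paths (1/2)^(n+1) * (1 + F_A)

where n counts segregations (edges) on a path running sire -> common
ancestor A -> dam without repeating animals.  Path enumeration is
exponential and is guarded; it exists as a cross-check oracle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .records import AnimalRecord, FlockDataset, Sex

__all__ = [
    "Pedigree",
    "PedigreeError",
    "build_pedigree",
    "amatrix",
    "inbreeding",
    "inbreeding_wright",
    "ainverse",
    "pedigree_sheet",
    "history_sheet",
]

DENSE_A_GUARD = 5000
WRIGHT_ANCESTOR_GUARD = 25


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents precede offspring.

    ``sire_idx[i]``/``dam_idx[i]`` index into ``ids`` and are always < i,
    or -1 for an unknown parent.
    """

    ids: list[str]
    sire_idx: np.ndarray  # int array, -1 for unknown
    dam_idx: np.ndarray
    sex: list[Optional[Sex]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        try:
            return self._pos[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown animal id {animal_id!r}")

    def parents(self, i: int) -> tuple[int, int]:
        return int(self.sire_idx[i]), int(self.dam_idx[i])


def build_pedigree(animals: Sequence[AnimalRecord | tuple]) -> Pedigree:
    """Build a topologically sorted pedigree from animal records.

    Also accepts bare ``(animal_id, sire_id, dam_id)`` triples (parent ids
    ``None`` for founders).  Parents referenced but not registered become
    founders.  A parentage cycle raises :class:`PedigreeError` naming the
    animals on one cycle.
    """
    trios: list[tuple[str, Optional[str], Optional[str], Optional[Sex]]] = []
    for a in animals:
        if isinstance(a, AnimalRecord):
            trios.append((a.animal_id, a.sire_id, a.dam_id, a.sex))
        else:
            aid, sid, did = a
            trios.append((aid, sid, did, None))

    known = {t[0] for t in trios}
    if len(known) != len(trios):
        seen: set[str] = set()
        dup = sorted({t[0] for t in trios if t[0] in seen or seen.add(t[0])})
        raise PedigreeError(f"duplicate animal id(s): {', '.join(dup)}")

    # dangling parents become founders, listed first
    extra = []
    for aid, sid, did, _ in trios:
        for pid in (sid, did):
            if pid is not None and pid not in known:
                known.add(pid)
                extra.append((pid, None, None, None))
    trios = extra + trios

    g = nx.DiGraph()
    g.add_nodes_from(t[0] for t in trios)
    for aid, sid, did, _ in trios:
        for pid in (sid, did):
            if pid is not None:
                if pid == aid:
                    raise PedigreeError(f"animal {aid} is its own parent")
                g.add_edge(pid, aid)
    try:
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise PedigreeError(f"pedigree cycle involving: {', '.join(sorted(cycle))}")

    info = {t[0]: t for t in trios}
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire_idx = np.full(n, -1, dtype=np.int64)
    dam_idx = np.full(n, -1, dtype=np.int64)
    sexes: list[Optional[Sex]] = []
    for i, aid in enumerate(order):
        _, sid, did, sx = info[aid]
        if sid is not None:
            sire_idx[i] = pos[sid]
        if did is not None:
            dam_idx[i] = pos[did]
        sexes.append(sx)
    return Pedigree(ids=order, sire_idx=sire_idx, dam_idx=dam_idx, sex=sexes)


def amatrix(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method.

    Recurrences on the sorted pedigree, missing parents contributing 0:
        a_ij = (a_{j,s(i)} + a_{j,d(i)}) / 2     for j < i
        a_ii = 1 + a_{s(i),d(i)} / 2
    """
    n = len(ped)
    if n > DENSE_A_GUARD:
        raise PedigreeError(
            f"refusing dense A for {n} animals (guard {DENSE_A_GUARD}); "
            "use ainverse()/inbreeding() instead"
        )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.parents(i)
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F via recursive kinship.

    F_i is the kinship between the animal's parents (0 when either parent
    is unknown); kinship is computed by memoised recursion on the sorted
    pedigree, so full A is never materialised.
    """
    sire, dam = ped.sire_idx, ped.dam_idx
    memo: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        v = memo.get(key)
        if v is not None:
            return v
        if i == j:
            v = 0.5 * (1.0 + kin(int(sire[i]), int(dam[i])))
        else:
            # i is later in the order, so recurse through i's parents
            v = 0.5 * (kin(int(sire[i]), j) + kin(int(dam[i]), j))
        memo[key] = v
        return v

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped) + 1000))
    try:
        F = np.array([kin(int(sire[i]), int(dam[i])) for i in range(len(ped))])
    finally:
        sys.setrecursionlimit(old)
    return F


def _ascending_paths(ped: Pedigree, start: int, guard: int) -> list[list[int]]:
    """All parent-link paths from ``start`` upward, as node lists
    [start, ..., ancestor]; includes the trivial path [start]."""
    ancestors: set[int] = set()
    out: list[list[int]] = []

    def walk(path: list[int]) -> None:
        out.append(list(path))
        node = path[-1]
        ancestors.add(node)
        if len(ancestors) > guard:
            raise PedigreeError(
                f"path enumeration exceeds {guard} ancestors; use the recursive method"
            )
        for p in ped.parents(node):
            if p >= 0 and p not in path:
                path.append(p)
                walk(path)
                path.pop()

    walk([start])
    return out


def inbreeding_wright(ped: Pedigree, x: str, guard: int = WRIGHT_ANCESTOR_GUARD) -> float:
    """Wright's path-counting inbreeding coefficient for a single animal.

    Sums (1/2)^(n+1) * (1 + F_A) over all sire-to-dam paths through each
    common ancestor A that repeat no animal, n being the number of
    segregations on the path.  Exponential in pedigree depth; guarded, and
    intended as an independent cross-check of :func:`inbreeding`.
    """
    i = ped.index_of(x)
    s, d = ped.parents(i)
    if s < 0 or d < 0:
        return 0.0
    sp_paths = _ascending_paths(ped, s, guard)
    dp_paths = _ascending_paths(ped, d, guard)
    by_anc: dict[int, list[list[int]]] = {}
    for p in dp_paths:
        by_anc.setdefault(p[-1], []).append(p)

    @lru_cache(maxsize=None)
    def f_of(idx: int) -> float:
        return inbreeding_wright(ped, ped.ids[idx], guard)

    total = 0.0
    for p1 in sp_paths:
        anc = p1[-1]
        for p2 in by_anc.get(anc, ()):
            if len(set(p1) & set(p2)) != 1:  # may share only the ancestor
                continue
            n_seg = (len(p1) - 1) + (len(p2) - 1)
            total += 0.5 ** (n_seg + 1) * (1.0 + f_of(anc))
    return total


def ainverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding correction.

    For each animal i with parents s, d, the Mendelian-sampling variance is
    d_i = 1/2 - (F_s + F_d)/4, with an unknown parent's term replaced by
    the founder value (d_i = 3/4 with one parent known, 1 with none).  The
    contributions alpha_i = 1/d_i are scattered over (i, s, d) with
    coefficients (1, -1/2, -1/2) outer-squared.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        s, d = ped.parents(i)
        var = 0.5
        if s < 0:
            var += 0.25
        else:
            var -= 0.25 * F[s]
        if d < 0:
            var += 0.25
        else:
            var -= 0.25 * F[d]
        alpha = 1.0 / var
        members = [(i, 1.0)]
        if s >= 0:
            members.append((s, -0.5))
        if d >= 0:
            members.append((d, -0.5))
        for a, ca in members:
            for b, cb in members:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ca * cb)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# sheets

def pedigree_sheet(ped: Pedigree, x: str, generations: int,
                   F: np.ndarray | None = None) -> dict:
    """Ancestor tree for one animal, as nested dicts.

    Each node carries id, sex, inbreeding F and (down to the requested
    depth) ``sire``/``dam`` subtrees; unknown parents appear as explicit
    ``{"id": "UNKNOWN"}`` leaves.
    """
    if generations < 1:
        raise PedigreeError("generations must be >= 1")
    if F is None:
        F = inbreeding(ped)

    def node(idx: int, depth: int) -> dict:
        out: dict = {
            "id": ped.ids[idx],
            "sex": ped.sex[idx].value if ped.sex[idx] else None,
            "F": float(F[idx]),
        }
        if depth > 0:
            s, d = ped.parents(idx)
            out["sire"] = node(s, depth - 1) if s >= 0 else {"id": "UNKNOWN"}
            out["dam"] = node(d, depth - 1) if d >= 0 else {"id": "UNKNOWN"}
        return out

    return node(ped.index_of(x), generations)


def history_sheet(ds: FlockDataset, x: str) -> dict:
    """Comprehensive per-animal sheet: identity, traits, reproduction,
    progeny (with trait summaries), health and disposal, all date-sorted."""
    index = ds.animal_index()
    if x not in index:
        raise PedigreeError(f"unknown animal id {x!r}")
    a = index[x]

    traits = sorted((t for t in ds.traits if t.animal_id == x),
                    key=lambda t: (t.record_date, t.trait_code))
    repro = sorted((r for r in ds.repro if x in (r.ewe_id, r.ram_id)),
                   key=lambda r: r.mating_date)
    health = sorted((h for h in ds.health if h.animal_id == x), key=lambda h: h.date)
    progeny = sorted((c for c in ds.animals if x in (c.sire_id, c.dam_id)),
                     key=lambda c: (c.birth_date, c.animal_id))

    prog_ids = {c.animal_id for c in progeny}
    prog_traits: dict[str, list[float]] = {}
    for t in ds.traits:
        if t.animal_id in prog_ids:
            prog_traits.setdefault(t.trait_code, []).append(t.value)
    prog_summary = {
        code: {"n": len(vals), "mean": float(np.mean(vals))}
        for code, vals in sorted(prog_traits.items())
    }

    return {
        "identity": {
            "animal_id": a.animal_id, "sire_id": a.sire_id, "dam_id": a.dam_id,
            "sex": a.sex.value, "breed": a.breed, "farm_id": a.farm_id,
            "birth_date": a.birth_date.isoformat(),
        },
        "traits": [
            {"trait_code": t.trait_code, "value": t.value,
             "record_date": t.record_date.isoformat()} for t in traits
        ],
        "reproduction": [
            {"role": "ewe" if r.ewe_id == x else "ram",
             "mate": r.ram_id if r.ewe_id == x else r.ewe_id,
             "mating_date": r.mating_date.isoformat(),
             "outcome": r.outcome.value, "lambs": list(r.lamb_ids)} for r in repro
        ],
        "progeny": [c.animal_id for c in progeny],
        "progeny_trait_summary": prog_summary,
        "health": [
            {"date": h.date.isoformat(), "kind": h.kind.value,
             "detail": h.detail, "drug": h.drug} for h in health
        ],
        "disposal": (
            {"date": a.disposal_date.isoformat(), "reason": a.disposal_reason.value}
            if a.disposal_date else None
        ),
    }
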