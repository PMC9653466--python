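"""BLUP breeding values via Henderson's mixed-model equations, plus the
simple individual-selection predictor.

The mixed model is y = Xb + Zu + e with u the vector of breeding values
(animal model) or sire transmitting abilities (sire model).  The
coefficient matrix

    [ X'X      X'Z          ] [b]   [X'y]
    [ Z'X   Z'Z + lambda*A^-1 ] [u] = [Z'y]

uses the variance ratio lambda = sigma2_e/sigma2_u expressed through
heritability: (1 - h2)/h2 for the animal model, (4 - h2)/h2 for the sire
model.  X is made full rank by reference-level dropping, so the system is
nonsingular whenever lambda > 0 and solutions are unique and reproducible.

The individual-selection predictor is the phenotype regressed toward the
population mean: EBV = P_m + h2 (P_i - P_m), a value on the trait scale
(unlike BLUP u-hat, which is a deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree, ainverse, build_pedigree, inbreeding
from .records import FlockDataset
from .varcomp import HeritabilityEstimate, RandomUnit, VarcompError, build_design_matrices

__all__ = [
    "BlupError",
    "MixedModelSpec",
    "MMESystem",
    "EBVTable",
    "lambda_from_h2",
    "assemble_mme",
    "solve_mme",
    "individual_ebv",
    "blup_ebv",
    "rank_animals",
]


class BlupError(ValueError):
    pass


@dataclass
class MixedModelSpec:
    trait: str
    fixed: tuple[str, ...] = ("sex", "year")
    random_unit: RandomUnit = RandomUnit.ANIMAL
    h2: float = 0.3

    @property
    def lam(self) -> float:
        return lambda_from_h2(self.h2, self.random_unit)


@dataclass
class MMESystem:
    """Assembled mixed-model equations (sparse symmetric coefficient matrix)."""

    coeff: sp.csr_matrix
    rhs: np.ndarray
    n_fixed: int
    fixed_labels: list[str]
    unit_ids: list[str]
    lam: float


@dataclass
class EBVRow:
    animal_id: str
    farm_id: str
    trait: str
    method: str  # "BLUP" or "INDIVIDUAL"
    ebv: float


@dataclass
class EBVTable:
    trait: str
    method: str
    rows: list[EBVRow] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {r.animal_id: r.ebv for r in self.rows}


def lambda_from_h2(h2: float, random_unit: RandomUnit | str = RandomUnit.ANIMAL) -> float:
    """Variance ratio for the MME: (1-h2)/h2 (animal), (4-h2)/h2 (sire)."""
    if not (0.0 < h2 < 1.0):
        raise BlupError(f"h2 must lie in (0, 1), got {h2}")
    random_unit = RandomUnit(random_unit)
    if random_unit == RandomUnit.SIRE:
        return (4.0 - h2) / h2
    return (1.0 - h2) / h2


def assemble_mme(y, X, Z, Ainv, lam: float) -> MMESystem:
    """Assemble Henderson's equations; no centering or scaling of y.

    Units absent from the data enter only through lambda*A^-1 (zero Z'Z
    diagonal and zero right-hand side), which is how unrecorded ancestors
    receive evaluations.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = sp.csr_matrix(Z)
    Ainv = sp.csr_matrix(Ainv)
    n, p = X.shape
    q = Z.shape[1]
    if Z.shape[0] != n:
        raise BlupError(f"Z has {Z.shape[0]} rows but X has {n}")
    if y.size != n:
        raise BlupError(f"y has {y.size} entries but X has {n} rows")
    if Ainv.shape != (q, q):
        raise BlupError(f"Ainv is {Ainv.shape} but Z has {q} units")
    if lam <= 0:
        raise BlupError("lambda must be positive")

    XtX = sp.csr_matrix(X.T @ X)
    XtZ = sp.csr_matrix(X.T @ Z)
    ZtZ = (Z.T @ Z).tocsr()
    coeff = sp.bmat(
        [[XtX, XtZ], [XtZ.T, ZtZ + lam * Ainv]], format="csr"
    )
    rhs = np.concatenate([X.T @ y, np.asarray(Z.T @ y).ravel()])
    return MMESystem(coeff=coeff, rhs=rhs, n_fixed=p,
                     fixed_labels=[f"b{i}" for i in range(p)],
                     unit_ids=[f"u{i}" for i in range(q)], lam=lam)


def solve_mme(system: MMESystem) -> tuple[np.ndarray, np.ndarray]:
    """Solve the assembled equations by direct sparse factorisation.

    X is assumed full rank (reference-level dropping upstream), so with
    lambda > 0 the coefficient matrix is nonsingular; u-hat is invariant
    to the fixed-effect parameterisation.
    """
    coeff = system.coeff.tocsc()
    sol = spla.spsolve(coeff, system.rhs)
    if not np.all(np.isfinite(sol)):
        raise BlupError("singular mixed-model equations after constraints")
    p = system.n_fixed
    return sol[:p], sol[p:]


def individual_ebv(
    phenotypes: Mapping[str, float],
    h2: float,
    trait: str = "",
    farm_ids: Mapping[str, str] | None = None,
) -> EBVTable:
    """Individual-selection breeding values EBV_i = P_m + h2 (P_i - P_m).

    P_m is the mean of all supplied phenotypes; the result is on the trait
    scale (h2 = 0 returns the mean for everyone, h2 = 1 the phenotype).
    """
    if not phenotypes:
        raise BlupError("no phenotypes supplied")
    if not (0.0 <= h2 <= 1.0):
        raise BlupError(f"h2 must lie in [0, 1], got {h2}")
    pm = float(np.mean(list(phenotypes.values())))
    table = EBVTable(trait=trait, method="INDIVIDUAL")
    for aid in sorted(phenotypes):
        ebv = pm + h2 * (phenotypes[aid] - pm)
        table.rows.append(EBVRow(
            animal_id=aid,
            farm_id=(farm_ids or {}).get(aid, ""),
            trait=trait, method="INDIVIDUAL", ebv=ebv,
        ))
    return table


def blup_ebv(
    ds: FlockDataset,
    spec: MixedModelSpec,
    h2_source: HeritabilityEstimate | float | None = None,
) -> EBVTable:
    """End-to-end BLUP: design matrices -> A^-1 -> lambda -> assemble -> solve.

    ``h2_source`` (an estimate object or a plain float) overrides
    ``spec.h2`` so a heritability fitted on the same data can feed the
    evaluation.  Every pedigree member receives an EBV, including
    unrecorded ancestors.
    """
    h2 = spec.h2
    if h2_source is not None:
        h2 = h2_source.h2_clamped if isinstance(h2_source, HeritabilityEstimate) else float(h2_source)
    lam = lambda_from_h2(h2, spec.random_unit)

    ped = build_pedigree(ds.animals)
    if spec.random_unit == RandomUnit.ANIMAL:
        unit_ids = ped.ids
    else:
        unit_ids = None  # distinct sires, chosen by build_design_matrices
    y, X, Z, units, _ = build_design_matrices(
        ds, spec.trait, spec.fixed, spec.random_unit, unit_ids=unit_ids
    )
    if spec.random_unit == RandomUnit.ANIMAL:
        Ainv = ainverse(ped)
    else:
        sire_ped = build_pedigree([(u, None, None) for u in units])
        Ainv = ainverse(sire_ped)

    system = assemble_mme(y, X, Z, Ainv, lam)
    _, u_hat = solve_mme(system)

    index = ds.animal_index()
    table = EBVTable(trait=spec.trait, method="BLUP")
    for uid, val in zip(units, u_hat):
        rec = index.get(uid)
        table.rows.append(EBVRow(
            animal_id=uid,
            farm_id=rec.farm_id if rec else "",
            trait=spec.trait, method="BLUP", ebv=float(val),
        ))
    return table


def rank_animals(tables: Sequence[EBVTable], values: Mapping[str, float] | None = None):
    """Merge EBV tables across farms and rank by value.

    Descending by EBV (or by supplied index ``values``), ties broken by
    ascending animal_id; ranks are 1-based and dense (equal values share a
    rank).  Tables must agree on trait and method.
    """
    if not tables:
        raise BlupError("no tables to rank")
    trait = tables[0].trait
    method = tables[0].method
    for t in tables[1:]:
        if t.trait != trait or t.method != method:
            raise BlupError("tables mix traits or methods")
    rows = [r for t in tables for r in t.rows]
    if values is not None:
        rows = [r for r in rows if r.animal_id in values]
        keyval = {r.animal_id: values[r.animal_id] for r in rows}
    else:
        keyval = {r.animal_id: r.ebv for r in rows}
    rows.sort(key=lambda r: (-keyval[r.animal_id], r.animal_id))
    ranked = []
    rank = 0
    prev = None
    for r in rows:
        v = keyval[r.animal_id]
        if prev is None or v != prev:
            rank += 1
            prev = v
        ranked.append({
            "rank": rank, "animal_id": r.animal_id, "farm_id": r.farm_id,
            "trait": trait, "method": method, "value": v,
        })
    return ranked
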