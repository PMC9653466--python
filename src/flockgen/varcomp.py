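"""Variance components and heritability: nested-ANOVA sib analysis and
animal-model EM-REML.

Two estimators of h² = σ²A/σ²P are provided.  The sib analysis treats full
sibs nested within paternal half-sib groups and solves the unbalanced
expected-mean-square equations for the sire, dam-within-sire and
within-dam components; h² is then 4σ²s/σ²p (sire), 4σ²d/σ²p (dam) or
2(σ²s+σ²d)/σ²p (combined).  The animal model fits sex/year (and farm, when
more than one farm is present) as fixed effects and either each animal's
breeding value or the sire's transmitting ability as the random effect,
with variance components estimated by EM-REML on the mixed-model
equations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .records import FlockDataset, Sex

__all__ = [
    "SibDesign",
    "AnovaTable",
    "HeritabilityEstimate",
    "H2Method",
    "VarcompError",
    "nested_anova",
    "h2_from_anova",
    "build_design_matrices",
    "reml_animal",
    "reml_loglik",
]


class VarcompError(ValueError):
    pass


class H2Method(str, Enum):
    SIRE = "SIRE"
    DAM = "DAM"
    SIRE_DAM = "SIRE_DAM"
    ANIMAL_MODEL = "ANIMAL_MODEL"


@dataclass
class SibDesign:
    """Phenotypes grouped sire -> dam -> progeny values (full sibs nested
    within half-sib groups)."""

    groups: dict[str, dict[str, list[float]]]

    def __post_init__(self) -> None:
        dams = [d for sire in self.groups.values() for d in sire]
        if len(dams) != len(set(dams)):
            raise VarcompError("each dam must appear under exactly one sire")
        if len(self.groups) < 2:
            raise VarcompError("need at least 2 sires")
        for sire in self.groups.values():
            for vals in sire.values():
                if not all(np.isfinite(vals)):
                    raise VarcompError("phenotypes must be finite")

    @property
    def n_obs(self) -> int:
        return sum(len(v) for s in self.groups.values() for v in s.values())


@dataclass
class AnovaTable:
    df_s: int
    df_d: int
    df_w: int
    ms_s: float
    ms_d: float
    ms_w: float
    k1: float
    k2: float
    k3: float
    sigma2_s: float
    sigma2_d: float
    sigma2_w: float
    truncated: dict[str, bool] = field(default_factory=dict)

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_s + self.sigma2_d + self.sigma2_w


@dataclass
class HeritabilityEstimate:
    method: H2Method
    h2_raw: float
    h2_clamped: float
    components: dict[str, float]
    converged: bool = True
    iterations: int = 0


def nested_anova(design: SibDesign) -> AnovaTable:
    """Nested ANOVA for a sire/dam/progeny hierarchy, unbalanced allowed.

    Sums of squares follow the definitional between-sire /
    dams-within-sire / within-dam partition; variance components solve the
    unbalanced expected-mean-square equations with coefficients

        k1 = (N - Σ_ij n_ij²/n_i.) / (D - S)
        k2 = (Σ_ij n_ij²/n_i. - Σ_ij n_ij²/N) / (S - 1)
        k3 = (N - Σ_i n_i.²/N) / (S - 1)

    so that E[ms_w] = σ²w, E[ms_d] = σ²w + k1 σ²d and
    E[ms_s] = σ²w + k2 σ²d + k3 σ²s.  Negative component solutions are
    truncated to zero and flagged.
    """
    sires = sorted(design.groups)
    all_vals = np.concatenate([
        np.asarray(v, dtype=float)
        for s in sires for v in design.groups[s].values()
    ])
    N = all_vals.size
    S = len(sires)
    D = sum(len(design.groups[s]) for s in sires)
    grand = all_vals.mean()
    if np.allclose(all_vals, grand):
        raise VarcompError("TOTAL_VARIANCE_ZERO: all phenotypes are equal")

    ss_s = ss_d = ss_w = 0.0
    sum_nij2_over_ni = 0.0
    sum_nij2 = 0.0
    sum_ni2 = 0.0
    for s in sires:
        dams = design.groups[s]
        sire_vals = np.concatenate([np.asarray(v, dtype=float) for v in dams.values()])
        ni = sire_vals.size
        smean = sire_vals.mean()
        ss_s += ni * (smean - grand) ** 2
        sum_ni2 += ni ** 2
        for v in dams.values():
            arr = np.asarray(v, dtype=float)
            nij = arr.size
            dmean = arr.mean()
            ss_d += nij * (dmean - smean) ** 2
            ss_w += float(((arr - dmean) ** 2).sum())
            sum_nij2_over_ni += nij ** 2 / ni
            sum_nij2 += nij ** 2

    df_s = S - 1
    df_d = D - S
    df_w = N - D
    if df_w <= 0:
        raise VarcompError("no dam has 2+ progeny: within-dam df is zero")
    if df_d <= 0:
        raise VarcompError("no sire has 2+ dams: dam-within-sire df is zero")

    ms_s = ss_s / df_s
    ms_d = ss_d / df_d
    ms_w = ss_w / df_w

    k1 = (N - sum_nij2_over_ni) / df_d
    k2 = (sum_nij2_over_ni - sum_nij2 / N) / df_s
    k3 = (N - sum_ni2 / N) / df_s
    if min(k1, k2, k3) <= 0:
        raise VarcompError("degenerate design: non-positive EMS coefficient")

    sigma2_w = ms_w
    sigma2_d = (ms_d - ms_w) / k1
    sigma2_s = (ms_s - ms_w - k2 * sigma2_d) / k3
    truncated = {"sigma2_s": sigma2_s < 0, "sigma2_d": sigma2_d < 0, "sigma2_w": False}
    sigma2_d = max(sigma2_d, 0.0)
    sigma2_s = max(sigma2_s, 0.0)

    return AnovaTable(
        df_s=df_s, df_d=df_d, df_w=df_w,
        ms_s=ms_s, ms_d=ms_d, ms_w=ms_w,
        k1=k1, k2=k2, k3=k3,
        sigma2_s=sigma2_s, sigma2_d=sigma2_d, sigma2_w=sigma2_w,
        truncated=truncated,
    )


def h2_from_anova(table: AnovaTable, component: H2Method | str) -> HeritabilityEstimate:
    """Heritability from sib-analysis components.

    SIRE: 4σ²s/σ²p; DAM: 4σ²d/σ²p; SIRE_DAM: 2(σ²s+σ²d)/σ²p, with
    σ²p = σ²s + σ²d + σ²w.  Both the raw value and its [0, 1] clamp are
    reported.
    """
    component = H2Method(component)
    s2p = table.sigma2_p
    if s2p <= 0:
        raise VarcompError("phenotypic variance is zero")
    if component == H2Method.SIRE:
        raw = 4.0 * table.sigma2_s / s2p
    elif component == H2Method.DAM:
        raw = 4.0 * table.sigma2_d / s2p
    elif component == H2Method.SIRE_DAM:
        raw = 2.0 * (table.sigma2_s + table.sigma2_d) / s2p
    else:
        raise VarcompError("component must be SIRE, DAM or SIRE_DAM")
    return HeritabilityEstimate(
        method=component,
        h2_raw=raw,
        h2_clamped=min(max(raw, 0.0), 1.0),
        components={
            "sigma2_s": table.sigma2_s, "sigma2_d": table.sigma2_d,
            "sigma2_w": table.sigma2_w, "sigma2_p": s2p,
        },
    )


# ---------------------------------------------------------------------------
# animal model

class RandomUnit(str, Enum):
    ANIMAL = "ANIMAL"
    SIRE = "SIRE"


def build_design_matrices(
    ds: FlockDataset,
    trait: str,
    fixed: Sequence[str] = ("sex", "year"),
    random_unit: RandomUnit | str = RandomUnit.ANIMAL,
    unit_ids: Sequence[str] | None = None,
):
    """Response vector and incidence matrices for a single-trait mixed model.

    Fixed factors are encoded as a global mean column plus dummy contrasts
    dropping the alphabetically first level of each factor; single-level
    factors are dropped.  A farm factor is auto-included whenever records
    span more than one farm.  Z maps records to evaluation units — every
    pedigree member for the animal model (so unrecorded ancestors get
    equations), or the distinct sires of recorded animals for the sire
    model.  ``unit_ids`` overrides the unit list (it must cover every
    record's unit).

    Returns ``(y, X, Z, units, x_labels)`` with X dense and Z sparse CSR.
    """
    random_unit = RandomUnit(random_unit)
    index = ds.animal_index()
    recs = [t for t in ds.traits if t.trait_code == trait and t.animal_id in index]
    if not recs:
        raise VarcompError(f"no records for trait {trait!r}")
    recs.sort(key=lambda t: (t.animal_id, t.record_date))
    y = np.array([t.value for t in recs])
    n = len(recs)

    fixed = list(fixed)
    farms = {index[t.animal_id].farm_id for t in recs}
    if len(farms) > 1 and "farm" not in fixed:
        fixed.append("farm")

    def factor_levels(name: str) -> list[str]:
        if name == "sex":
            return [index[t.animal_id].sex.value for t in recs]
        if name == "year":
            return [str(t.record_date.year) for t in recs]
        if name == "farm":
            return [index[t.animal_id].farm_id for t in recs]
        if name == "breed":
            return [index[t.animal_id].breed for t in recs]
        raise VarcompError(f"unknown fixed factor {name!r}")

    cols = [np.ones(n)]
    labels = ["mu"]
    for name in fixed:
        vals = factor_levels(name)
        levels = sorted(set(vals))
        if len(levels) < 2:
            continue  # uninformative factor: silently dropped
        for lev in levels[1:]:
            cols.append(np.array([1.0 if v == lev else 0.0 for v in vals]))
            labels.append(f"{name}:{lev}")
    X = np.column_stack(cols)

    if unit_ids is not None:
        units = list(unit_ids)
    elif random_unit == RandomUnit.ANIMAL:
        units = [a.animal_id for a in ds.animals]
    else:
        units = sorted({
            index[t.animal_id].sire_id for t in recs
            if index[t.animal_id].sire_id is not None
        })
        if not units:
            raise VarcompError("sire model requires records with known sires")
    upos = {u: i for i, u in enumerate(units)}

    rows, cols_z = [], []
    for r, t in enumerate(recs):
        uid = t.animal_id if random_unit == RandomUnit.ANIMAL else index[t.animal_id].sire_id
        if uid is None or uid not in upos:
            raise VarcompError(f"record for {t.animal_id} maps to no evaluation unit")
        rows.append(r)
        cols_z.append(upos[uid])
    Z = sp.csr_matrix((np.ones(n), (rows, cols_z)), shape=(n, len(units)))
    return y, X, Z, units, labels


def _mme_solve(XtX, XtZ, ZtZ, Ainv, Xty, Zty, lam):
    p = XtX.shape[0]
    q = ZtZ.shape[0]
    top = np.hstack([XtX, XtZ])
    bottom = np.hstack([XtZ.T, ZtZ + lam * Ainv])
    M = np.vstack([top, bottom])
    rhs = np.concatenate([Xty, Zty])
    try:
        sol = scipy.linalg.solve(M, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise VarcompError("singular mixed-model equations") from exc
    return M, sol[:p], sol[p:]


def reml_animal(
    y: np.ndarray,
    X: np.ndarray,
    Z,
    Ainv,
    init: tuple[float, float] = (1.0, 1.0),
    tol: float = 1e-6,
    maxit: int = 200,
) -> HeritabilityEstimate:
    """EM-REML for (σ²u, σ²e) in y = Xb + Zu + e, u ~ N(0, A σ²u).

    Each iteration solves the mixed-model equations at the current
    components and updates

        σ²u <- (û' A⁻¹ û + σ²e tr(A⁻¹ C_uu)) / q
        σ²e <- (y - Xb̂ - Zû)' y / (n - rank X)

    with C_uu the u-block of the inverse MME coefficient matrix.  EM keeps
    both components non-negative by construction; convergence is declared
    when both relative changes fall below ``tol``.  Returns an estimate
    with h² = σ²u / (σ²u + σ²e) and a ``converged`` flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = sp.csr_matrix(Z)
    Ainv = np.asarray(Ainv.todense() if sp.issparse(Ainv) else Ainv, dtype=float)
    n = y.size
    q = Ainv.shape[0]
    p_rank = np.linalg.matrix_rank(X)
    if n - p_rank <= 0:
        raise VarcompError("no residual degrees of freedom")

    s2u, s2e = float(init[0]), float(init[1])
    if s2u <= 0 or s2e <= 0:
        raise VarcompError("initial components must be positive")

    XtX = X.T @ X
    XtZ = np.asarray(X.T @ Z.todense())
    ZtZ = np.asarray((Z.T @ Z).todense())
    Xty = X.T @ y
    Zty = np.asarray(Z.T @ y).ravel()
    p = XtX.shape[0]

    converged = False
    it = 0
    for it in range(1, maxit + 1):
        lam = s2e / s2u
        M, b_hat, u_hat = _mme_solve(XtX, XtZ, ZtZ, Ainv, Xty, Zty, lam)
        Minv = scipy.linalg.inv(M)
        Cuu = Minv[p:, p:]
        new_s2u = (u_hat @ Ainv @ u_hat + s2e * np.trace(Ainv @ Cuu)) / q
        resid = y - X @ b_hat - Z @ u_hat
        new_s2e = float(resid @ y) / (n - p_rank)
        if new_s2e <= 0:
            new_s2e = 1e-12
        du = abs(new_s2u - s2u) / max(s2u, 1e-12)
        de = abs(new_s2e - s2e) / max(s2e, 1e-12)
        s2u, s2e = new_s2u, new_s2e
        if du < tol and de < tol:
            converged = True
            break

    h2 = s2u / (s2u + s2e) if (s2u + s2e) > 0 else 0.0
    return HeritabilityEstimate(
        method=H2Method.ANIMAL_MODEL,
        h2_raw=h2,
        h2_clamped=min(max(h2, 0.0), 1.0),
        components={"sigma2_u": s2u, "sigma2_e": s2e},
        converged=converged,
        iterations=it,
    )


def reml_loglik(y, X, Z, A, s2u: float, s2e: float) -> float:
    """Restricted log-likelihood by direct dense V-matrix evaluation.

    -2 l_R = log|V| + log|X'V⁻¹X| + y'Py, with V = ZAZ'σ²u + Iσ²e and
    P = V⁻¹ - V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ (constants dropped).  Independent of
    the EM path; used to verify likelihood ascent.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Zd = np.asarray(Z.todense() if sp.issparse(Z) else Z, dtype=float)
    Ad = np.asarray(A.todense() if sp.issparse(A) else A, dtype=float)
    n = y.size
    V = Zd @ Ad @ Zd.T * s2u + np.eye(n) * s2e
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    sign, logdet_V = np.linalg.slogdet(V)
    sign2, logdet_XVX = np.linalg.slogdet(XtVinvX)
    b = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ b
    yPy = float(r @ Vinv @ y)
    return -0.5 * (logdet_V + logdet_XVX + yPy)
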