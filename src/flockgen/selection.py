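"""Selection indices and relative economic values for growth and wool traits.

The selection index is a weighted sum of BLUP breeding values,
I = v1*EBV1 + ... + vn*EBVn, with weights v_i normally taken as relative
economic values.  Economic values come from three sources:

* body weight at a given age: ((book value / trait mean) / days to attain)
  x survivability — the marginal return per kg per day, discounted by the
  chance the animal survives to that age;
* fleece weight: (book value / days to attain) x mean fleece weight;
* wool quality (fibre diameter, staple length): the slope of a simple
  regression of wool price per kg on the trait, taken from user-supplied
  market observations.  The slope keeps its sign (finer fibre usually
  commands a premium, so the diameter slope is typically negative).

Weights default to the computed economic values but may be overridden per
flock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SelectionError",
    "IndexSpec",
    "EconomicInputs",
    "WoolPriceObservation",
    "WoolTrait",
    "selection_index",
    "econ_value_weight",
    "econ_value_fleece",
    "ols_fit",
    "econ_value_wool_quality",
    "survivability_from_records",
]


class SelectionError(ValueError):
    pass


class WoolTrait(str, Enum):
    FIBRE_DIAMETER = "FIBRE_DIAMETER"
    STAPLE_LENGTH = "STAPLE_LENGTH"


@dataclass(frozen=True)
class IndexSpec:
    traits: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.weights):
            raise SelectionError("traits and weights must have equal length")
        if not self.traits:
            raise SelectionError("index needs at least one trait")
        if all(w == 0 for w in self.weights):
            raise SelectionError("at least one weight must be nonzero")


@dataclass(frozen=True)
class EconomicInputs:
    book_value: float
    trait_mean: float
    days_to_attain: float
    survivability: float = 1.0

    def __post_init__(self) -> None:
        if self.book_value <= 0 or self.trait_mean < 0:
            raise SelectionError("book value must be positive, trait mean non-negative")
        if self.days_to_attain <= 0:
            raise SelectionError("days to attain must be positive")
        if not (0.0 < self.survivability <= 1.0):
            raise SelectionError("survivability must lie in (0, 1]")


@dataclass(frozen=True)
class WoolPriceObservation:
    price: float
    fibre_diameter: float
    staple_length: float

    def __post_init__(self) -> None:
        if self.price <= 0 or self.fibre_diameter <= 0 or self.staple_length <= 0:
            raise SelectionError("price and predictors must be positive")


def selection_index(
    ebvs: Mapping[str, Mapping[str, float]],
    spec: IndexSpec,
) -> dict[str, float]:
    """Index values I = sum_i v_i * EBV_i per animal.

    ``ebvs`` maps animal_id -> {trait_code: EBV}.  Animals missing an EBV
    for any index trait are excluded (they cannot be scored on the full
    goal); the arithmetic is exact linear combination, no scaling.
    """
    out: dict[str, float] = {}
    for aid in sorted(ebvs):
        vec = ebvs[aid]
        if any(t not in vec for t in spec.traits):
            continue
        out[aid] = float(sum(v * vec[t] for t, v in zip(spec.traits, spec.weights)))
    return out


def econ_value_weight(inp: EconomicInputs) -> float:
    """Economic value of body weight at an age:
    ((book_value / trait_mean) / days_to_attain) x survivability."""
    if inp.trait_mean <= 0:
        raise SelectionError("trait mean must be positive for body weight")
    return (inp.book_value / inp.trait_mean) / inp.days_to_attain * inp.survivability


def econ_value_fleece(inp: EconomicInputs) -> float:
    """Economic value of fleece weight:
    (book_value / days_to_attain) x mean fleece weight."""
    return inp.book_value / inp.days_to_attain * inp.trait_mean


def ols_fit(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Simple least-squares line y = a x + b.

    a = S_xy / S_xx, b = y-bar - a x-bar, so the fitted line passes through
    (x-bar, y-bar).  Returns (slope, intercept, r-squared); r² is defined
    as 1 when y has zero variance (the line is exact).
    """
    if len(points) < 2:
        raise SelectionError("need at least 2 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0:
        raise SelectionError("degenerate predictor: all x equal")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    a = sxy / sxx
    b = ybar - a * xbar
    syy = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if syy == 0 else 1.0 - float(((y - (a * x + b)) ** 2).sum()) / syy
    return a, b, r2


def econ_value_wool_quality(
    obs: Sequence[WoolPriceObservation],
    trait: WoolTrait | str,
) -> float:
    """Relative economic value of a wool-quality trait: the slope of price
    per kg on the trait across market observations, sign preserved."""
    trait = WoolTrait(trait)
    if len(obs) < 3:
        raise SelectionError("need at least 3 market observations")
    attr = "fibre_diameter" if trait == WoolTrait.FIBRE_DIAMETER else "staple_length"
    pts = [(getattr(o, attr), o.price) for o in obs]
    slope, _, _ = ols_fit(pts)
    return slope


def survivability_from_records(n_born: int, n_alive_at_age: int) -> float:
    """Helper: survival proportion to a trait age from flock counts."""
    if n_born <= 0:
        raise SelectionError("need a positive number of births")
    if not (0 <= n_alive_at_age <= n_born):
        raise SelectionError("survivors must lie between 0 and births")
    return n_alive_at_age / n_born
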