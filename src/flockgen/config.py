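"""Runtime configuration: trait bounds, age windows, economic inputs.

A flat ``key = value`` text file; section-free, comments with ``#``.
Trait bounds use keys like ``bound.W12M = 5,80``; everything else is a
scalar.  Defaults cover common sheep values so the toolkit runs without a
config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["FlockConfig", "load_config", "DEFAULT_TRAIT_BOUNDS"]

DEFAULT_TRAIT_BOUNDS: dict[str, tuple[float, float]] = {
    "BWT": (0.5, 10.0),    # kg
    "WWT": (5.0, 40.0),    # kg
    "W6M": (8.0, 60.0),    # kg
    "W9M": (10.0, 70.0),   # kg
    "W12M": (12.0, 80.0),  # kg
    "GFY": (0.2, 8.0),     # kg greasy fleece
    "FD": (10.0, 50.0),    # micron
    "SL": (2.0, 25.0),     # cm
}


@dataclass
class FlockConfig:
    trait_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_BOUNDS))
    breedable_age_days: int = 548      # ~18 months
    lamb_age_days: int = 365           # < 12 months counts as lamb
    age_window_fraction: float = 0.15  # +/-15% around standard weigh ages
    standard_ages_days: tuple[int, ...] = (0, 90, 180, 270, 365)


def load_config(path: str | Path | None = None) -> FlockConfig:
    cfg = FlockConfig()
    if path is None:
        return cfg
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("bound."):
            trait = key[len("bound."):].upper()
            lo, hi = (float(x) for x in value.split(","))
            cfg.trait_bounds[trait] = (lo, hi)
        elif key == "breedable_age_days":
            cfg.breedable_age_days = int(value)
        elif key == "lamb_age_days":
            cfg.lamb_age_days = int(value)
        elif key == "age_window_fraction":
            cfg.age_window_fraction = float(value)
        elif key == "standard_ages_days":
            cfg.standard_ages_days = tuple(int(x) for x in value.split(","))
        else:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
    return cfg
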