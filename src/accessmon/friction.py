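"""Friction (cost) surfaces: per-cell traversal time from surface class.

The three surface classes carry assumed travel speeds — by default
35 km/h on tarmac (minibus along the main road, net of stops), 5 km/h on
tracks (bicycle taxi / occasional motorised lift), and 3.5 km/h everywhere
else (straight-line-equivalent walking speed). Friction is stored as
minutes per metre so the cost-distance engine stays unit-free:

    minutes_per_metre = 60 / (1000 * speed_kmh)

A sensitivity range sweeps each class speed over an interval (defaults:
walking 3–6, track 5–8, tarmac 30–45 km/h) on a Cartesian grid of levels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geodata import CLASS_CODES, ClassRaster, GridSpec


class FrictionError(ValueError):
    pass


@dataclass(frozen=True)
class SpeedSet:
    """Travel speeds (km/h) for the three surface classes."""

    tarmac_kmh: float = 35.0
    track_kmh: float = 5.0
    walk_kmh: float = 3.5

    def __post_init__(self) -> None:
        for name, v in (("tarmac_kmh", self.tarmac_kmh),
                        ("track_kmh", self.track_kmh),
                        ("walk_kmh", self.walk_kmh)):
            if v <= 0:
                raise FrictionError(f"{name} must be > 0, got {v}")
        if not (self.tarmac_kmh >= self.track_kmh >= self.walk_kmh):
            warnings.warn(
                "speed ordering tarmac >= track >= walk violated: "
                f"{self}", stacklevel=2,
            )

    def scaled(self, k: float) -> "SpeedSet":
        return SpeedSet(self.tarmac_kmh * k, self.track_kmh * k,
                        self.walk_kmh * k)

    def minutes_per_metre(self) -> dict[int, float]:
        """Map class code -> minutes to traverse one metre."""
        return {
            CLASS_CODES["other"]: 60.0 / (1000.0 * self.walk_kmh),
            CLASS_CODES["track"]: 60.0 / (1000.0 * self.track_kmh),
            CLASS_CODES["tarmac"]: 60.0 / (1000.0 * self.tarmac_kmh),
        }


@dataclass
class FrictionSurface:
    """Per-cell traversal cost in minutes per metre."""

    grid: GridSpec
    cell_time_per_m: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.cell_time_per_m = np.asarray(self.cell_time_per_m, dtype=float)
        if self.cell_time_per_m.shape != self.grid.shape:
            raise FrictionError("friction shape does not match grid")
        if not np.all(np.isfinite(self.cell_time_per_m)):
            raise FrictionError("friction values must be finite")
        if not np.all(self.cell_time_per_m > 0):
            raise FrictionError("friction values must be > 0")


@dataclass(frozen=True)
class SensitivityRange:
    """Per-class speed intervals (km/h) for the sensitivity sweep."""

    walk: tuple[float, float] = (3.0, 6.0)
    track: tuple[float, float] = (5.0, 8.0)
    tarmac: tuple[float, float] = (30.0, 45.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("walk", self.walk), ("track", self.track),
                               ("tarmac", self.tarmac)):
            if lo > hi:
                raise FrictionError(f"{name} range min > max: ({lo}, {hi})")


def build_friction(classes: ClassRaster, speeds: SpeedSet) -> FrictionSurface:
    """Convert a class raster to minutes-per-metre under a speed set."""
    lut = np.zeros(max(CLASS_CODES.values()) + 1, dtype=float)
    for code, mpm in speeds.minutes_per_metre().items():
        lut[code] = mpm
    return FrictionSurface(grid=classes.grid,
                           cell_time_per_m=lut[classes.codes])


def speed_grid(rng: SensitivityRange = SensitivityRange(),
               levels_per_axis: int = 2) -> list[SpeedSet]:
    """Cartesian grid of speed sets over the sensitivity range.

    ``levels_per_axis`` equally spaced levels per class, endpoints
    included; the default 2 levels give the 8-corner design.
    """
    if levels_per_axis < 2:
        raise FrictionError("levels_per_axis must be >= 2")
    axes = [np.linspace(lo, hi, levels_per_axis)
            for lo, hi in (rng.tarmac, rng.track, rng.walk)]
    return [SpeedSet(tarmac_kmh=t, track_kmh=k, walk_kmh=w)
            for t, k, w in itertools.product(*axes)]
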