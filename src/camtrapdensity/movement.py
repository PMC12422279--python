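"""Home-range-confined correlated-random-walk movement simulation.

Animal movement is modelled as a correlated random walk (CRW): each step
turns by a normal deviate relative to the previous heading and advances by
a normally distributed, zero-truncated step length. Movement is confined
to a circular home range of a given area centred on the individual's home
centre (reject-and-resample), and to the rectangular simulation arena.
Parameters are species-specific and expressed per calendar month of
activity (a fixed number of steps per month, evenly spaced in time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernels import crw_walk

__all__ = [
    "MovementParams",
    "Region",
    "Trajectory",
    "draw_home_centers",
    "simulate_trajectory",
    "simulate_population",
]

_MAX_SEED = 2**31 - 1


def subseed(base_seed: int, *key: int) -> int:
    """Stable sub-seed derivation: SeedSequence(base, spawn_key=key).

    numpy's SeedSequence hash is documented and stable across platforms,
    so any stage seeded this way is bit-reproducible from one user seed.
    """
    ss = np.random.SeedSequence(int(base_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % _MAX_SEED)


@dataclass(frozen=True)
class MovementParams:
    """Species-specific CRW parameters.

    mean_step_m / sd_step_m parameterise the zero-truncated normal step
    length (metres); sd_turn_deg is the SD of the angular deflection
    between consecutive steps (degrees); steps_per_month sets the monthly
    activity level; home_range_km2 is the area of the circular home range
    (km²; ``inf`` disables confinement).
    """

    species_label: str
    mean_step_m: float
    sd_step_m: float
    sd_turn_deg: float
    steps_per_month: int
    home_range_km2: float

    def __post_init__(self):
        for name in ("mean_step_m", "sd_step_m", "sd_turn_deg"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.steps_per_month < 1:
            raise ValueError("steps_per_month must be >= 1")
        if not self.home_range_km2 > 0:
            raise ValueError("home_range_km2 must be > 0")

    @property
    def home_range_radius_m(self) -> float:
        """Radius of the home-range disc in metres: sqrt(A·10⁶/π)."""
        if math.isinf(self.home_range_km2):
            return math.inf
        return math.sqrt(self.home_range_km2 * 1e6 / math.pi)


@dataclass(frozen=True)
class Region:
    """Rectangular simulation arena: a core rectangle plus a buffer strip.

    The buffered rectangle [x0-b, x0+w+b] × [y0-b, y0+h+b] is the area
    over which home centres are drawn and within which movement is kept;
    its area (in km²) is the effective sampling area used to convert
    abundance to density.
    """

    origin: tuple[float, float] = (0.0, 0.0)
    width_m: float = 4000.0
    height_m: float = 1000.0
    buffer_m: float = 0.0

    def __post_init__(self):
        if not (self.width_m > 0 and self.height_m > 0):
            raise ValueError("width_m and height_m must be > 0")
        if self.buffer_m < 0:
            raise ValueError("buffer_m must be >= 0")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xlo, ylo, xhi, yhi) of the buffered rectangle."""
        x0, y0 = self.origin
        return (x0 - self.buffer_m, y0 - self.buffer_m,
                x0 + self.width_m + self.buffer_m,
                y0 + self.height_m + self.buffer_m)

    @property
    def area_km2(self) -> float:
        xlo, ylo, xhi, yhi = self.bounds
        return (xhi - xlo) * (yhi - ylo) / 1e6


@dataclass
class Trajectory:
    """One individual's simulated track: step endpoints with timestamps."""

    individual_id: int
    species: str
    home_center: tuple[float, float]
    positions: np.ndarray  # (n_steps, 2) metres
    timestamps: np.ndarray = field(repr=False)  # datetime64[ns], same length

    def __post_init__(self):
        if len(self.positions) != len(self.timestamps):
            raise ValueError("positions and timestamps must have equal length")

    def __len__(self) -> int:
        return len(self.positions)


def step_timestamps(start, months: int, steps_per_month: int) -> np.ndarray:
    """Evenly spaced step times within each calendar month of the survey.

    Month k spans [start + k months, start + (k+1) months); its
    steps_per_month steps sit at the (i + 1/2)/steps_per_month quantiles of
    that span, so timestamps are strictly increasing across the survey.
    """
    start = pd.Timestamp(start)
    bounds = [start + pd.DateOffset(months=k) for k in range(months + 1)]
    out = []
    frac = (np.arange(steps_per_month) + 0.5) / steps_per_month
    for k in range(months):
        t0 = bounds[k].value
        t1 = bounds[k + 1].value
        out.append((t0 + frac * (t1 - t0)).astype("int64"))
    return np.concatenate(out).view("datetime64[ns]")


def draw_home_centers(n: int, region: Region, rng_seed: int) -> np.ndarray:
    """Draw n home centres uniformly over the buffered region."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(rng_seed)
    xlo, ylo, xhi, yhi = region.bounds
    xs = rng.uniform(xlo, xhi, size=n)
    ys = rng.uniform(ylo, yhi, size=n)
    return np.column_stack([xs, ys])


def simulate_trajectory(params: MovementParams, home_center, start,
                        months: int, rng_seed: int,
                        region: Region | None = None,
                        individual_id: int = 0) -> Trajectory:
    """Simulate one CRW trajectory of months × steps_per_month steps.

    The walk starts at ``home_center`` (not included in the output
    positions) and is confined to the home-range disc and, if ``region``
    is given, to its buffered rectangle.
    """
    if months < 1:
        raise ValueError("months must be >= 1")
    cx, cy = float(home_center[0]), float(home_center[1])
    if region is None:
        xlo = ylo = -math.inf
        xhi = yhi = math.inf
    else:
        xlo, ylo, xhi, yhi = region.bounds
    r = params.home_range_radius_m
    n_steps = months * params.steps_per_month
    xs, ys = crw_walk(
        int(rng_seed) % _MAX_SEED, n_steps,
        params.mean_step_m, params.sd_step_m,
        math.radians(params.sd_turn_deg),
        cx, cy, r * r, xlo, xhi, ylo, yhi,
    )
    ts = step_timestamps(start, months, params.steps_per_month)
    return Trajectory(individual_id=individual_id, species=params.species_label,
                      home_center=(cx, cy),
                      positions=np.column_stack([xs, ys]), timestamps=ts)


def simulate_population(n: int, params: MovementParams, region: Region,
                        start, months: int, rng_seed: int) -> list[Trajectory]:
    """Simulate n independent individuals with uniform home centres.

    Each individual gets a sub-seed derived from ``rng_seed`` and its
    index, so populations are reproducible and individuals independent.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    centers = draw_home_centers(n, region, subseed(rng_seed, 0))
    return [
        simulate_trajectory(params, centers[i], start, months,
                            subseed(rng_seed, 1, i), region=region,
                            individual_id=i)
        for i in range(n)
    ]
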