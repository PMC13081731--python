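"""Synthetic study generators.

These produce the four kinds of inputs the analysis consumes, with the
statistical structure the downstream models assume:

* irregular simply-connected tumor boundaries (random Fourier perturbation
  of a circle),
* marker-positive cell point patterns whose density varies monotonically
  with depth from the boundary — acceptance weight ∝ exp(β·u) with
  u = depth / max-depth, so β = 0 is uniform, β > 0 core-enriched and
  β < 0 periphery-shifted; an optional zone subset confines the pattern,
* caliper growth studies with exponential growth, group-specific daily
  log-growth rates, lognormal multiplicative noise, and baselines drawn
  from the 75–150 mm³ enrollment window (length/width back-derived so that
  (L·W²)/2 reproduces the simulated volume at a fixed aspect ratio),
* logistic-normal cell-population frequency tables.

Every generator is a pure function of its config: the same seed yields the
same output (numpy Generator/PCG64 streams, one per call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import DepthMap, Polygon2D, ZoneMap

__all__ = [
    "BoundaryGenConfig",
    "PatternConfig",
    "GrowthSimConfig",
    "FreqSimConfig",
    "simulate_boundary",
    "simulate_cells",
    "simulate_growth",
    "simulate_frequencies",
    "disk_boundary",
]

ENROLLMENT_WINDOW_MM3 = (75.0, 150.0)


@dataclass(frozen=True)
class BoundaryGenConfig:
    seed: int = 0
    r0: float = 2000.0  # mean radius, µm
    n_harmonics: int = 4
    amplitude: float = 0.15  # total radial perturbation as a fraction of r0
    n_vertices: int = 256

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class PatternConfig:
    seed: int = 0
    n_cells: int = 10_000
    beta: float = 0.0
    confine_to_zones: tuple[int, ...] | None = None
    marker: str = "CD8a"

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.confine_to_zones is not None and len(self.confine_to_zones) == 0:
            raise ValueError("confine_to_zones must be a non-empty zone subset")


@dataclass(frozen=True)
class GrowthSimConfig:
    """Exponential-growth caliper study.

    ``groups`` maps group label → daily log-growth rate (1/day); the
    untreated syngeneic models in this setting double roughly every 3 days,
    i.e. a control rate near ln(2)/3 ≈ 0.23/day, with treatment lowering
    the rate.  ``genotypes`` optionally maps group label → genotype label
    (default "wildtype").
    """

    seed: int = 0
    n_per_group: int = 10
    groups: dict = field(default_factory=lambda: {"control": 0.23, "treated": 0.10})
    genotypes: dict = field(default_factory=dict)
    baseline_range_mm3: tuple[float, float] = ENROLLMENT_WINDOW_MM3
    residual_sd: float = 0.10  # lognormal sd on the log scale
    days: tuple[int, ...] = (0, 3, 7, 10, 14, 17, 21)
    aspect_ratio: float = 1.3  # L / W, must be >= 1 so that L >= W

    def __post_init__(self):
        if self.baseline_range_mm3[0] <= 0 or self.baseline_range_mm3[1] < self.baseline_range_mm3[0]:
            raise ValueError("baseline range must be positive and ordered")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect ratio L/W must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass(frozen=True)
class FreqSimConfig:
    seed: int = 0
    n_per_group: int = 8
    group_means_logit: dict = field(default_factory=lambda: {"control": -2.0, "treated": -1.0})
    between_animal_sd: float = 0.5

    def __post_init__(self):
        if self.between_animal_sd < 0:
            raise ValueError("between_animal_sd must be non-negative")


def simulate_boundary(cfg: BoundaryGenConfig) -> Polygon2D:
    """Star-convex random boundary r(θ) = r0·(1 + Σ_k a_k cos(kθ + φ_k)).

    Harmonic amplitudes are drawn so their total equals ``cfg.amplitude``
    and clamped at 0.8 so every radius stays positive; harmonics start at
    k = 2 (k = 1 mostly translates the shape).  amplitude = 0 yields a
    regular n-gon approximating a circle of radius r0.
    """
    rng = np.random.default_rng(cfg.seed)
    theta = np.linspace(0.0, 2 * np.pi, cfg.n_vertices, endpoint=False)
    perturb = np.zeros_like(theta)
    if cfg.n_harmonics > 0 and cfg.amplitude > 0:
        raw = rng.random(cfg.n_harmonics)
        total = min(cfg.amplitude, 0.8)
        if total < cfg.amplitude:
            warnings.warn(
                f"amplitude {cfg.amplitude} clamped to 0.8 to keep radii positive",
                stacklevel=2,
            )
        a = raw / raw.sum() * total
        phases = rng.uniform(0, 2 * np.pi, cfg.n_harmonics)
        ks = np.arange(2, cfg.n_harmonics + 2)
        perturb = (a[:, None] * np.cos(ks[:, None] * theta[None, :] + phases[:, None])).sum(axis=0)
    r = cfg.r0 * (1.0 + perturb)
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Polygon2D(outer_ring=verts)


def disk_boundary(radius_um: float = 2000.0, n_vertices: int = 512) -> Polygon2D:
    """Regular polygon approximating a disk — the canonical test fixture."""
    return simulate_boundary(
        BoundaryGenConfig(seed=0, r0=radius_um, amplitude=0.0, n_vertices=n_vertices)
    )


def simulate_cells(zonemap: ZoneMap, depth: DepthMap, cfg: PatternConfig) -> pd.DataFrame:
    """Sample a depth-profiled point pattern inside the mask.

    Pixels are chosen with probability ∝ exp(β·u), u = depth/max-depth,
    restricted to ``confine_to_zones`` when set; each cell is then placed
    uniformly within its pixel.  Returns a CellTable-shaped DataFrame with
    columns x_um, y_um, marker.
    """
    if zonemap.zone.shape != depth.depth.shape:
        raise ValueError("zonemap and depth map have inconsistent grids")
    rng = np.random.default_rng(cfg.seed)
    admissible = zonemap.zone > 0
    if cfg.confine_to_zones is not None:
        admissible &= np.isin(zonemap.zone, np.asarray(cfg.confine_to_zones))
    iy, ix = np.nonzero(admissible)
    if len(iy) == 0:
        raise ValueError("no admissible pixels (confine_to_zones excludes everything)")
    u = depth.depth[iy, ix] / depth.max_depth
    logw = cfg.beta * u
    w = np.exp(logw - logw.max())
    p = w / w.sum()
    chosen = rng.choice(len(iy), size=cfg.n_cells, replace=True, p=p)
    ps = zonemap.mask.pixel_size
    x0, y0 = zonemap.mask.origin
    jitter = rng.uniform(-0.5, 0.5, size=(cfg.n_cells, 2)) * ps
    x = x0 + ix[chosen] * ps + jitter[:, 0]
    y = y0 + iy[chosen] * ps + jitter[:, 1]
    return pd.DataFrame({"x_um": x, "y_um": y, "marker": cfg.marker})


def simulate_growth(cfg: GrowthSimConfig) -> pd.DataFrame:
    """Simulate a caliper growth study in long format.

    Per animal: V₀ ~ Uniform(enrollment window); V(t) = V₀·e^{rate·t}·ε_t
    with ln ε_t ~ Normal(0, residual_sd).  Length and width are
    back-derived from V at the fixed aspect ratio a = L/W via
    W = (2V/a)^{1/3}, L = a·W, so (L·W²)/2 reproduces V exactly.

    Columns: animal, group, genotype, day, length_mm, width_mm, volume_mm3.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    days = np.asarray(cfg.days, dtype=float)
    for group, rate in cfg.groups.items():
        genotype = cfg.genotypes.get(group, "wildtype")
        for j in range(cfg.n_per_group):
            animal = f"{group}_{j + 1:02d}"
            v0 = rng.uniform(*cfg.baseline_range_mm3)
            noise = np.exp(rng.normal(0.0, cfg.residual_sd, size=len(days))) \
                if cfg.residual_sd > 0 else np.ones(len(days))
            v = v0 * np.exp(rate * days) * noise
            w = np.cbrt(2.0 * v / cfg.aspect_ratio)
            l = cfg.aspect_ratio * w
            for d, li, wi, vi in zip(cfg.days, l, w, v):
                rows.append((animal, group, genotype, int(d), li, wi, vi))
    return pd.DataFrame(
        rows,
        columns=["animal", "group", "genotype", "day", "length_mm", "width_mm", "volume_mm3"],
    )


def simulate_frequencies(cfg: FreqSimConfig) -> pd.DataFrame:
    """Logistic-normal cell-population frequencies, one row per animal.

    frequency = expit(Normal(mean_logit_group, between_animal_sd));
    columns animal, group, frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group, mu in cfg.group_means_logit.items():
        z = rng.normal(mu, cfg.between_animal_sd, size=cfg.n_per_group)
        for j, freq in enumerate(expit(z)):
            rows.append((f"{group}_{j + 1:02d}", group, float(freq)))
    return pd.DataFrame(rows, columns=["animal", "group", "frequency"])
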