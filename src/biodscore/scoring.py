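"""BioD scoring: zone counts, region densities, pairwise ratios, phenotype.

The BioD (biodistribution) score summarizes where marker-positive cells
(typically CD8α+ T cells) sit relative to the tumor boundary.  Cells are
counted in the K equal-area annular zones, the zones are binned into three
contiguous regions — periphery (outermost zones), intermediate, core
(innermost) — and the score is the set of pairwise ratios of the average
cell density (cells/mm²) between regions:

    ratio_CP = core / periphery
    ratio_CI = core / intermediate
    ratio_IP = intermediate / periphery

The phenotype label follows the core-to-periphery ratio: > 1 means the
marker is enriched toward the core ("core_enriched", a hot infiltrated
tumor), values in [0.5, 1.0] mean a homogeneous distribution, and < 0.5
means the marker is excluded from the core and piles up at the margin
("excluded", the immune-excluded phenotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Polygon2D, ZoneMap, Zonation, locate

__all__ = [
    "RegionScheme",
    "ZoneCounts",
    "BioDResult",
    "count_by_zone",
    "region_densities",
    "biod",
    "classify",
    "score_section",
    "LOWER_THRESHOLD",
    "UPPER_THRESHOLD",
]

LOWER_THRESHOLD = 0.5
UPPER_THRESHOLD = 1.0

REGIONS = ("periphery", "intermediate", "core")


@dataclass(frozen=True)
class RegionScheme:
    """Contiguous zone→region binning: periphery is a prefix of the zone
    order (shallowest), core a suffix (deepest), intermediate the rest.

    The default for K = 10 is 3/4/3: periphery = zones 1–3,
    intermediate = 4–7, core = 8–10.
    """

    n_periphery: int = 3
    n_intermediate: int = 4
    n_core: int = 3

    def __post_init__(self):
        if min(self.n_periphery, self.n_intermediate, self.n_core) < 1:
            raise ValueError("each region must contain at least one zone")

    @property
    def n_zones(self) -> int:
        return self.n_periphery + self.n_intermediate + self.n_core

    def validate_for(self, n_zones: int) -> None:
        if self.n_zones != n_zones:
            raise ValueError(
                f"region scheme covers {self.n_zones} zones but the zone map "
                f"has {n_zones}"
            )

    def region_of_zone(self, k: int) -> str:
        if not 1 <= k <= self.n_zones:
            raise ValueError(f"zone index {k} outside 1..{self.n_zones}")
        if k <= self.n_periphery:
            return "periphery"
        if k <= self.n_periphery + self.n_intermediate:
            return "intermediate"
        return "core"

    def zones_of(self, region: str) -> range:
        p, i = self.n_periphery, self.n_intermediate
        if region == "periphery":
            return range(1, p + 1)
        if region == "intermediate":
            return range(p + 1, p + i + 1)
        if region == "core":
            return range(p + i + 1, self.n_zones + 1)
        raise ValueError(f"unknown region {region!r}")

    @classmethod
    def from_string(cls, text: str) -> "RegionScheme":
        """Parse e.g. ``"3,4,3"`` (periphery, intermediate, core sizes)."""
        parts = [int(s) for s in text.split(",")]
        if len(parts) != 3:
            raise ValueError("region scheme must be three comma-separated sizes")
        return cls(*parts)


@dataclass(frozen=True)
class ZoneCounts:
    counts: np.ndarray  # (K,) ints, zone 1 first
    n_inside: int
    n_outside: int

    def __post_init__(self):
        if int(self.counts.sum()) != self.n_inside:
            raise ValueError("zone counts do not sum to n_inside")


@dataclass(frozen=True)
class BioDResult:
    region_density: dict  # cells/mm² for periphery, intermediate, core
    ratio_cp: float
    ratio_ci: float
    ratio_ip: float
    label: str  # core_enriched | homogeneous | excluded | undefined
    lower: float = LOWER_THRESHOLD
    upper: float = UPPER_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "region_density_per_mm2": dict(self.region_density),
            "ratio_CP": self.ratio_cp,
            "ratio_CI": self.ratio_ci,
            "ratio_IP": self.ratio_ip,
            "label": self.label,
            "thresholds": {"lower": self.lower, "upper": self.upper},
        }


def count_by_zone(zonemap: ZoneMap, cells: pd.DataFrame, marker: str | None = None) -> ZoneCounts:
    """Count cells per zone via pixel lookup.

    ``cells`` needs columns x_um, y_um and (if ``marker`` is given) marker.
    Cells landing outside the mask are tallied separately; a warning is
    issued when they exceed 5% of the input, which usually indicates a
    coordinate-frame mismatch between the boundary and the cell export.
    """
    if marker is not None and "marker" in cells.columns:
        cells = cells[cells["marker"] == marker]
    elif marker is not None and len(cells):
        raise ValueError("marker filter requested but cells table has no 'marker' column")
    n = len(cells)
    if n == 0:
        return ZoneCounts(np.zeros(zonemap.n_zones, dtype=int), 0, 0)
    zones = locate(zonemap, cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    counts = np.bincount(zones, minlength=zonemap.n_zones + 1)
    n_outside = int(counts[0])
    if n_outside > 0.05 * n:
        warnings.warn(
            f"{n_outside}/{n} cells fall outside the viable-tumor mask; "
            "check that boundary and cells share a coordinate frame",
            stacklevel=2,
        )
    return ZoneCounts(counts[1:].astype(int), n_inside=n - n_outside, n_outside=n_outside)


def region_densities(
    zc: ZoneCounts,
    zonemap: ZoneMap,
    scheme: RegionScheme | None = None,
    pooled: bool = True,
) -> dict:
    """Average cell density (cells/mm²) per region.

    Default is pooled: region density = (Σ zone counts) / (Σ zone areas),
    which equals the mean of zone densities when zone areas are exactly
    equal and is robust to pixel-granularity area jitter.  ``pooled=False``
    instead averages the per-zone densities.
    """
    scheme = scheme or _default_scheme(zonemap.n_zones)
    scheme.validate_for(zonemap.n_zones)
    out = {}
    for region in REGIONS:
        ks = np.array(list(scheme.zones_of(region))) - 1
        areas = zonemap.zone_areas_mm2[ks]
        counts = zc.counts[ks]
        if pooled:
            out[region] = float(counts.sum() / areas.sum())
        else:
            out[region] = float(np.mean(counts / areas))
    return out


def _default_scheme(n_zones: int) -> RegionScheme:
    if n_zones == 10:
        return RegionScheme(3, 4, 3)
    # split K as evenly as possible, giving the remainder to the middle
    p = c = n_zones // 3
    return RegionScheme(p, n_zones - p - c, c)


def _ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    return np.inf if num > 0 else np.nan


def biod(densities: dict, lower: float = LOWER_THRESHOLD,
         upper: float = UPPER_THRESHOLD) -> BioDResult:
    """Pairwise region-density ratios and the phenotype label.

    Zero-denominator ratios are reported as +inf (or NaN when 0/0), never
    silently regularized with a pseudocount.  The phenotype label follows
    the primary core:periphery axis, so it is ``undefined`` exactly when
    ratio_CP itself is undefined (empty periphery); an empty intermediate
    region leaves ratio_CI/ratio_IP flagged but still allows a label —
    a strictly periphery-confined pattern is ``excluded``, not undefined.
    """
    p, i, c = (densities[r] for r in REGIONS)
    if min(p, i, c) < 0:
        raise ValueError("densities must be non-negative")
    r_cp, r_ci, r_ip = _ratio(c, p), _ratio(c, i), _ratio(i, p)
    label = classify(r_cp, lower=lower, upper=upper)
    return BioDResult(
        region_density=dict(zip(REGIONS, (p, i, c))),
        ratio_cp=r_cp, ratio_ci=r_ci, ratio_ip=r_ip,
        label=label, lower=lower, upper=upper,
    )


def classify(ratio_cp: float, lower: float = LOWER_THRESHOLD,
             upper: float = UPPER_THRESHOLD) -> str:
    """Phenotype from the core:periphery ratio.

    > upper → core_enriched; < lower → excluded; in [lower, upper] →
    homogeneous (the band boundaries themselves count as homogeneous);
    non-finite ratio → undefined.
    """
    if not 0 < lower < upper:
        raise ValueError("need 0 < lower < upper")
    if not np.isfinite(ratio_cp):
        return "undefined"
    if ratio_cp > upper:
        return "core_enriched"
    if ratio_cp < lower:
        return "excluded"
    return "homogeneous"


def score_section(
    boundary: Polygon2D,
    cells: pd.DataFrame,
    marker: str | None = None,
    pixel_size: float = 4.0,
    n_zones: int = 10,
    scheme: RegionScheme | None = None,
) -> tuple[BioDResult, ZoneCounts, ZoneMap]:
    """End-to-end BioD score of one tumor section.

    Rasterizes the boundary, builds the equal-area zones, counts the
    marker-positive cells and returns (BioDResult, ZoneCounts, ZoneMap).
    """
    zn = Zonation(pixel_size=pixel_size, n_zones=n_zones).fit(boundary)
    zc = count_by_zone(zn.zones_, cells, marker=marker)
    dens = region_densities(zc, zn.zones_, scheme=scheme)
    return biod(dens), zc, zn.zones_
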