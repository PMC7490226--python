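"""Perimetric grids, Goldmann stimuli, and the two displacement methods.

Stimulus coordinates are planar visual degrees with the fovea at the
origin; angles match the retinal meridian convention of the density map in
use (the CLI converts between visual-field and retinal frames for a given
laterality).  Method 1 displaces only the stimulus center; Method 2
displaces each of 72 points on the stimulus edge independently along its
own meridian, producing the distorted, ovoidal shapes characteristic of
the parafovea, where the edge nearer the fovea is displaced farther than
the edge away from it.

Counts are mask integrals on a local pixel raster (pixel-center inclusion
test): expected RGC-RF counts integrate the RF surface over the
undisplaced stimulus in planar deg^2; RGC body counts integrate the body
density map over the displaced shape with each pixel weighted by its
retinal area (mm^2 per solid degree through the schematic eye).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .density_maps import RetinalDensityMap
from .displacement import DisplacementField
from .schematic_eye import SchematicEye, build_eye

__all__ = [
    "GOLDMANN_DIAMETER_DEG",
    "PerimetricStimulus",
    "DisplacedStimulus",
    "grid_10_2",
    "goldmann_diameter",
    "auto_resolution",
    "displace_method1",
    "displace_method2",
    "rasterize",
    "expected_rf_count",
    "gcb_count",
    "count_grid",
    "summarize",
]

# Goldmann sizes subtend areas of 1/4, 1, 4, 16, 64 mm^2 on the standard
# 300 mm perimeter bowl.  Size III (4 mm^2) anchors the angular scale
# (2*atan(sqrt(4/pi)/300) = 0.431 deg); each step doubles the diameter
# (quadruples the area) exactly.
_BOWL_MM = 300.0
_DIAM_III_DEG = 2.0 * math.degrees(math.atan(math.sqrt(4.0 / math.pi) / _BOWL_MM))
GOLDMANN_DIAMETER_DEG = {
    size: _DIAM_III_DEG * 2.0 ** (i - 2)
    for i, size in enumerate(["I", "II", "III", "IV", "V"])
}


def auto_resolution(size: str, base_deg: float = 0.008) -> float:
    """Mask resolution guaranteeing >= ~27 pixels across the stimulus radius.

    Binary pixel-center masks need enough pixels for stable counts; at the
    default 0.008 deg raster a size-I stimulus spans only ~7 pixels per
    radius, so small sizes are rasterized proportionally finer (III-V are
    unchanged at the default).
    """
    return min(base_deg, goldmann_diameter(size) / 54.0)


def goldmann_diameter(size: str) -> float:
    """Stimulus diameter in visual degrees for Goldmann size I-V."""
    try:
        return GOLDMANN_DIAMETER_DEG[size.upper()]
    except KeyError:
        raise ValueError(f"unknown Goldmann size {size!r} (expected I-V)") from None


def grid_10_2() -> np.ndarray:
    """The 68 stimulus centers of the 10-2 pattern (degrees).

    All points with odd integer coordinates within 10 degrees of fixation
    (eccentricity <= sqrt(82) ~ 9.06 deg), 2 deg spacing.
    """
    coords = [(x, y) for x in range(-9, 10, 2) for y in range(-9, 10, 2)
              if math.hypot(x, y) <= math.sqrt(82.0) + 1e-9]
    coords.sort(key=lambda p: (-p[1], p[0]))
    return np.array(coords, dtype=float)


@dataclass(frozen=True)
class PerimetricStimulus:
    """A circular perimetric test target."""

    center: tuple[float, float]     # visual degrees
    size: str = "III"

    @property
    def diameter_deg(self) -> float:
        return goldmann_diameter(self.size)

    @property
    def radius_deg(self) -> float:
        return self.diameter_deg / 2.0

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(*self.center)

    @property
    def area_deg2(self) -> float:
        return math.pi * self.radius_deg ** 2

    def edge_points(self, n: int = 72) -> np.ndarray:
        ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        return np.column_stack((
            self.center[0] + self.radius_deg * np.cos(ang),
            self.center[1] + self.radius_deg * np.sin(ang)))


@dataclass(frozen=True)
class DisplacedStimulus:
    """Closed polygon of a displaced stimulus (visual degrees)."""

    vertices: np.ndarray
    origin: PerimetricStimulus
    method: int

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("displaced stimulus needs at least 3 vertices")
        ring = shapely.LinearRing(self.vertices)
        if not ring.is_simple:
            raise ValueError("displaced stimulus polygon self-intersects "
                             "(displacement field is not monotone)")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


def _displace_points(points: np.ndarray, field: DisplacementField) -> np.ndarray:
    e = np.hypot(points[:, 0], points[:, 1])
    theta = np.degrees(np.arctan2(points[:, 1], points[:, 0]))
    ep = np.asarray(field.displace(theta, e))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(e > 0, ep / np.where(e > 0, e, 1.0), 1.0)
    return points * ratio[:, None]


def displace_method1(stim: PerimetricStimulus, field: DisplacementField,
                     n_edge: int = 72) -> DisplacedStimulus:
    """Displace only the stimulus center; the circular shape is unchanged."""
    center = _displace_points(np.array([stim.center], dtype=float), field)[0]
    moved = PerimetricStimulus(tuple(center), stim.size)
    return DisplacedStimulus(moved.edge_points(n_edge), stim, 1)


def displace_method2(stim: PerimetricStimulus, field: DisplacementField,
                     n_edge: int = 72) -> DisplacedStimulus:
    """Displace each of ``n_edge`` edge points independently along its meridian."""
    verts = _displace_points(stim.edge_points(n_edge), field)
    return DisplacedStimulus(verts, stim, 2)


# ---------------------------------------------------------------------------
# Rasterized count integration
# ---------------------------------------------------------------------------

def rasterize(polygon, resolution_deg: float):
    """Binary pixel-center mask of a polygon on a local raster.

    Returns ``(xs, ys, mask)``: pixel-center coordinate vectors and the
    boolean inclusion mask (shape ``(len(ys), len(xs))``).  Pixel centers
    sit on a lattice offset half a pixel from the polygon centroid, so
    lattice-aligned polygon edges fall between pixel centers; pixel solid
    area is ``resolution_deg**2`` on the planar chart.
    """
    if resolution_deg <= 0:
        raise ValueError("resolution must be positive")
    poly = polygon if isinstance(polygon, shapely.Polygon) else shapely.Polygon(polygon)
    cx, cy = poly.centroid.x, poly.centroid.y
    minx, miny, maxx, maxy = poly.bounds
    h = resolution_deg
    nlo_x = int(np.ceil((cx - minx) / h)) + 1
    nhi_x = int(np.ceil((maxx - cx) / h)) + 1
    nlo_y = int(np.ceil((cy - miny) / h)) + 1
    nhi_y = int(np.ceil((maxy - cy) / h)) + 1
    xs = cx + h * (np.arange(-nlo_x, nhi_x + 1) + 0.5)
    ys = cy + h * (np.arange(-nlo_y, nhi_y + 1) + 0.5)
    xx, yy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return xs, ys, mask


def _mask_points(polygon, resolution_deg):
    xs, ys, mask = rasterize(polygon, resolution_deg)
    xx, yy = np.meshgrid(xs, ys)
    return xx[mask], yy[mask]


def expected_rf_count(stim: PerimetricStimulus, field: DisplacementField,
                      resolution_deg: float = 0.008, n_edge: int = 72,
                      k=None) -> float:
    """Expected RGC-RF count within the (undisplaced) stimulus.

    Each pixel uses the RF surface of its own meridian (per-meridian E_2v)
    at its own eccentricity; pixel solid area is planar deg^2.
    """
    from .displacement import K_DEFAULT, RO, RV

    px, py = _mask_points(stim.edge_points(n_edge), resolution_deg)
    e = np.hypot(px, py)
    theta = np.degrees(np.arctan2(py, px))
    e2v = np.asarray(field.e2v_at(theta))
    if callable(k):
        kv = np.asarray(k(e), dtype=float)
    else:
        kv = K_DEFAULT if k is None else float(k)
    denom = RV * (1.0 + e / e2v) ** 2 - RO * (1.0 + e / 20.0) ** 2
    dens = kv * (1.12 + 0.0273 * e) ** 1.155 / denom
    return float(np.sum(dens) * resolution_deg ** 2)


def gcb_count(dstim: DisplacedStimulus, density_map: RetinalDensityMap,
              eye: SchematicEye | None = None,
              resolution_deg: float = 0.008) -> float:
    """RGC body count within a displaced stimulus on the structural map.

    Pixels are placed on the planar visual chart; each contributes body
    density (cells/mm^2) at its retinal position times its retinal area
    (resolution^2 times the mm^2-per-solid-degree Jacobian).
    """
    eye = eye or build_eye()
    px, py = _mask_points(dstim.vertices, resolution_deg)
    e = np.hypot(px, py)
    theta = np.degrees(np.arctan2(py, px))
    ecc_mm = np.asarray(eye.deg_to_mm(e))
    dens = np.asarray(density_map.density_at(theta, ecc_mm))
    jac = np.asarray(eye.solid_deg_to_mm2(e))
    return float(np.sum(dens * jac) * resolution_deg ** 2)


# ---------------------------------------------------------------------------
# Grid-level tables
# ---------------------------------------------------------------------------

def count_grid(density_map: RetinalDensityMap, field: DisplacementField,
               eye: SchematicEye | None = None, size: str = "IV",
               centers: np.ndarray | None = None,
               resolution_deg: float = 0.008, n_edge: int = 72,
               k=None) -> pd.DataFrame:
    """Per-location RF and body counts for a perimetric grid.

    Returns one row per stimulus location with expected RF count and the
    Method-1 / Method-2 body counts, plus densities per solid degree
    (count / undisplaced stimulus area) and dB values (10*log10 count).
    """
    eye = eye or build_eye()
    if centers is None:
        centers = grid_10_2()
    rows = []
    for cx, cy in np.asarray(centers, dtype=float):
        stim = PerimetricStimulus((float(cx), float(cy)), size)
        rf = expected_rf_count(stim, field, resolution_deg, n_edge, k)
        d1 = displace_method1(stim, field, n_edge)
        d2 = displace_method2(stim, field, n_edge)
        b1 = gcb_count(d1, density_map, eye, resolution_deg)
        b2 = gcb_count(d2, density_map, eye, resolution_deg)
        area = stim.area_deg2
        rows.append({
            "x_deg": cx, "y_deg": cy, "size": size,
            "eccentricity_deg": round(stim.eccentricity_deg, 2),
            "rf_count": rf, "gcb_count_m1": b1, "gcb_count_m2": b2,
            "rf_density": rf / area, "m1_density": b1 / area,
            "m2_density": b2 / area,
            "rf_db": 10.0 * np.log10(rf) if rf > 0 else -np.inf,
            "m1_db": 10.0 * np.log10(b1) if b1 > 0 else -np.inf,
            "m2_db": 10.0 * np.log10(b2) if b2 > 0 else -np.inf,
        })
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Eccentricity-grouped mean (SD) of the per-solid-degree densities.

    Locations are grouped by eccentricity rounded to 2 decimals; densities
    are count / stimulus solid area in deg^2.
    """
    g = table.groupby("eccentricity_deg")
    out = pd.DataFrame({
        "rf_density_mean": g["rf_density"].mean(),
        "rf_density_sd": g["rf_density"].std(ddof=1).fillna(0.0),
        "m1_density_mean": g["m1_density"].mean(),
        "m1_density_sd": g["m1_density"].std(ddof=1).fillna(0.0),
        "m2_density_mean": g["m2_density"].mean(),
        "m2_density_sd": g["m2_density"].std(ddof=1).fillna(0.0),
        "n_locations": g.size(),
    })
    return out.reset_index()
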