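"""Wide-angle schematic eye and the visual-degree -> retinal-mm mapping.

The eye is a rotationally symmetric sequence of spherical refracting
surfaces (cornea and lens) followed by a spherical retina.  A chief ray
entering at visual eccentricity ``e`` (degrees from the fixation axis) is
refracted through each surface with the exact (non-paraxial) Snell law in
the meridional plane, intersected with the retinal sphere, and converted to
great-circle arc length from the fovea (the posterior pole).  Because the
projection through the optics is non-linear, both the mm/degree and the
mm^2/solid-degree ratios vary with eccentricity.

Axial-length customization follows a global expansion model: the retinal
sphere radius ``r`` and its center distance from the corneal vertex ``c``
scale linearly with AL (``r = r0*AL/AL0``, ``c = c0*AL/AL0``) while the
anterior optics are left unchanged.  At the default axial length
AL0 = 23.84 mm the sphere matches the one used for the retinal histology
density map (r0 = 11.459 mm, c0 = 12.38 mm; the original wide-angle eye
used 11.06 mm and 11.95 mm, AL 23.01 mm).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

__all__ = [
    "R0",
    "C0",
    "AL0",
    "Surface",
    "SchematicEye",
    "AngularMapping",
    "GeometryError",
    "build_eye",
    "trace_to_retina",
    "deg_to_mm",
    "mm_to_deg",
    "solid_deg_to_mm2",
]

# Reference (histology-sphere) geometry, mm.  The original wide-angle eye
# used r=11.06, c=11.95 (AL 23.01); rescaling the sphere to the histology
# radius 11.459 scales c proportionally: c0 = 11.95*(11.459/11.06).  Kept at
# full precision so that AL = c + r holds exactly (c0 and AL0 print as 12.38
# and 23.84 at two decimals).
R0 = 11.459
C0 = 11.95 * (11.459 / 11.06)
AL0 = C0 + R0


class GeometryError(RuntimeError):
    """Raised when a ray cannot be propagated through the eye."""


@dataclass(frozen=True)
class Surface:
    name: str
    radius_mm: float       # center of curvature at vertex_z + radius
    vertex_z_mm: float
    n_after: float


def _load_surface_table() -> dict:
    with resources.files("drasdo.data").joinpath("drasdo_fowler_surfaces.json").open() as fh:
        return json.load(fh)


_TABLE = _load_surface_table()
SURFACES: tuple[Surface, ...] = tuple(
    Surface(s["name"], s["radius_mm"], s["vertex_z_mm"], s["n_after"])
    for s in _TABLE["surfaces"]
)
_N_OBJECT = float(_TABLE["n_object"])
_STOP_Z = float(_TABLE["stop_z_mm"])


# ---------------------------------------------------------------------------
# Exact meridional ray tracing
# ---------------------------------------------------------------------------

def _refract(d: np.ndarray, n: np.ndarray, n1: float, n2: float, name: str) -> np.ndarray:
    """Vector Snell refraction of unit direction ``d`` at unit normal ``n``.

    ``n`` must point against the incoming ray (``d . n < 0``).
    """
    cos_i = -float(np.dot(d, n))
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if k < 0.0:
        raise GeometryError(f"total internal reflection at surface '{name}'")
    return eta * d + (eta * cos_i - math.sqrt(k)) * n


def _intersect_sphere(p: np.ndarray, d: np.ndarray, center: np.ndarray,
                      radius: float, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of ray p + t*d with a sphere; returns (t roots sorted)."""
    oc = p - center
    b = float(np.dot(oc, d))
    c = float(np.dot(oc, oc)) - radius * radius
    disc = b * b - c
    if disc < 0.0:
        raise GeometryError(f"ray misses surface '{name}'")
    sq = math.sqrt(disc)
    return np.array([-b - sq, -b + sq])


def _hit_refracting_surface(p: np.ndarray, d: np.ndarray, surf: Surface) -> np.ndarray:
    """Point where the ray meets the vertex-side cap of a spherical surface."""
    center = np.array([0.0, surf.vertex_z_mm + surf.radius_mm])
    ts = _intersect_sphere(p, d, center, abs(surf.radius_mm), surf.name)
    for t in ts:
        if t <= 1e-9:
            continue
        pt = p + t * d
        # accept the intersection on the vertex-facing hemisphere
        if (pt[1] - center[1]) * surf.radius_mm < 0:
            return pt
    raise GeometryError(f"ray misses surface '{surf.name}'")


def _trace_through_optics(y0: float, angle_deg: float,
                          surfaces: Sequence[Surface] = SURFACES,
                          upto: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a ray entering the z=0 plane at height ``y0``.

    The incoming ray travels at ``angle_deg`` to the optical axis.  Returns
    position and unit direction after refraction at ``surfaces[:upto]``.
    """
    a = math.radians(angle_deg)
    d = np.array([math.sin(a), math.cos(a)])
    p = np.array([y0 - 2.0 * math.tan(a), -2.0])  # start 2 mm before the cornea
    n_before = _N_OBJECT
    for surf in surfaces[:upto]:
        pt = _hit_refracting_surface(p, d, surf)
        center = np.array([0.0, surf.vertex_z_mm + surf.radius_mm])
        normal = (pt - center) / abs(surf.radius_mm)
        if float(np.dot(normal, d)) > 0:
            normal = -normal
        d = _refract(d, normal, n_before, surf.n_after, surf.name)
        d = d / float(np.hypot(*d))
        p = pt
        n_before = surf.n_after
    return p, d


def _height_at_stop(y0: float, angle_deg: float) -> float:
    """Ray height at the aperture-stop plane after the corneal surfaces."""
    n_pre_stop = sum(1 for s in SURFACES if s.vertex_z_mm < _STOP_Z)
    p, d = _trace_through_optics(y0, angle_deg, upto=n_pre_stop)
    t = (_STOP_Z - p[1]) / d[1]
    return float(p[0] + t * d[0])


def _chief_entry_height(angle_deg: float) -> float:
    """Entry height such that the refracted ray crosses the stop center."""
    if angle_deg == 0.0:
        return 0.0
    # bracket the root of the (monotone) height-at-stop function
    grid = np.linspace(-7.0, 7.0, 29)
    vals = []
    for h in grid:
        try:
            vals.append(_height_at_stop(float(h), angle_deg))
        except GeometryError:
            vals.append(np.nan)
    vals = np.asarray(vals)
    ok = np.isfinite(vals)
    g, v = grid[ok], vals[ok]
    sign_change = np.nonzero(np.sign(v[:-1]) * np.sign(v[1:]) <= 0)[0]
    if len(sign_change) == 0:
        raise GeometryError(f"no chief ray found for angle {angle_deg} deg")
    i = sign_change[0]
    return brentq(_height_at_stop, g[i], g[i + 1], args=(angle_deg,), xtol=1e-10)


# ---------------------------------------------------------------------------
# Schematic eye and angular mapping
# ---------------------------------------------------------------------------

@dataclass
class AngularMapping:
    """Tabulated monotone visual-degree -> retinal-arc-mm map for one eye."""

    ecc_deg: np.ndarray
    arc_mm: np.ndarray
    radius_mm: float
    _fwd: PchipInterpolator = field(init=False, repr=False)
    _inv: PchipInterpolator = field(init=False, repr=False)
    _dfwd: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc_mm) <= 0):
            raise GeometryError("angular mapping is not strictly increasing")
        self._fwd = PchipInterpolator(self.ecc_deg, self.arc_mm)
        self._inv = PchipInterpolator(self.arc_mm, self.ecc_deg)
        self._dfwd = self._fwd.derivative()

    @property
    def max_deg(self) -> float:
        return float(self.ecc_deg[-1])

    def deg_to_mm(self, e):
        e = np.asarray(e, dtype=float)
        if np.any(e < 0) or np.any(e > self.max_deg + 1e-12):
            raise ValueError(f"eccentricity outside tabulated range 0-{self.max_deg} deg")
        return self._fwd(np.clip(e, 0.0, self.max_deg))[()]

    def mm_to_deg(self, d):
        d = np.asarray(d, dtype=float)
        if np.any(d < 0) or np.any(d > self.arc_mm[-1] + 1e-9):
            raise ValueError("arc length outside tabulated range")
        return self._inv(np.clip(d, 0.0, self.arc_mm[-1]))[()]

    def mm_per_deg(self, e):
        e = np.asarray(e, dtype=float)
        if np.any(e < 0) or np.any(e > self.max_deg + 1e-12):
            raise ValueError("eccentricity outside tabulated range")
        return self._dfwd(np.clip(e, 0.0, self.max_deg))[()]

    def areal_mm2_per_deg2(self, e):
        """mm^2 of retina per deg^2 of the planar visual chart at ecc ``e``.

        Radial factor d(arc)/de times the transverse metric r*sin(arc/r)/e
        on the retinal sphere; at the pole the ratio is isotropic and equals
        (d arc/de)^2.
        """
        e = np.atleast_1d(np.asarray(e, dtype=float))
        s = np.asarray(self.deg_to_mm(e), dtype=float)
        ds = np.asarray(self.mm_per_deg(e), dtype=float)
        out = np.empty_like(ds)
        small = e < 1e-6
        out[small] = ds[small] ** 2
        ns = ~small
        out[ns] = ds[ns] * self.radius_mm * np.sin(s[ns] / self.radius_mm) / e[ns]
        return out if out.size > 1 else float(out[0])


@dataclass
class SchematicEye:
    """A rescaled wide-angle schematic eye.

    ``r`` is the retinal-sphere radius, ``c`` the distance from the sphere
    center to the corneal vertex; AL = c + r.  The anterior optics are shared
    by all axial lengths.
    """

    r: float
    c: float
    surfaces: tuple[Surface, ...] = SURFACES
    _mapping: AngularMapping | None = field(default=None, repr=False)

    @property
    def AL(self) -> float:
        return self.c + self.r

    @property
    def scale(self) -> float:
        """Global expansion factor relative to the reference geometry."""
        return self.r / R0

    def trace_to_retina(self, angle_deg: float) -> float:
        """Arc length (mm) from the fovea for a chief ray at ``angle_deg``."""
        if not 0.0 <= angle_deg <= 60.0:
            raise ValueError("angle must be within 0-60 degrees")
        if angle_deg == 0.0:
            return 0.0
        y0 = _chief_entry_height(angle_deg)
        p, d = _trace_through_optics(y0, angle_deg)
        center = np.array([0.0, self.c])
        ts = _intersect_sphere(p, d, center, self.r, "retina")
        t = ts[1]  # posterior intersection
        if t <= 0:
            raise GeometryError("ray misses surface 'retina'")
        pt = p + t * d
        phi = math.atan2(abs(pt[0]), pt[1] - self.c)
        return self.r * phi

    @property
    def mapping(self) -> AngularMapping:
        """Cached angular mapping sampled every 0.25 deg out to 40 deg."""
        if self._mapping is None:
            ecc = np.arange(0.0, 40.0 + 1e-9, 0.25)
            arc = np.array([self.trace_to_retina(float(e)) for e in ecc])
            self._mapping = AngularMapping(ecc, arc, self.r)
        return self._mapping

    def deg_to_mm(self, e):
        return self.mapping.deg_to_mm(e)

    def mm_to_deg(self, d):
        return self.mapping.mm_to_deg(d)

    def solid_deg_to_mm2(self, e):
        return self.mapping.areal_mm2_per_deg2(e)


def build_eye(AL: float = AL0) -> SchematicEye:
    """Build a schematic eye for axial length ``AL`` (mm), global expansion.

    The retinal sphere and its center distance scale by AL/AL0; refracting
    surfaces are unchanged.
    """
    if not np.isfinite(AL) or AL <= 0:
        raise ValueError(f"axial length must be positive and finite, got {AL!r}")
    if not 18.0 <= AL <= 35.0:
        warnings.warn(f"axial length {AL} mm outside the typical 18-35 mm range",
                      stacklevel=2)
    s = AL / AL0
    return SchematicEye(r=R0 * s, c=C0 * s)


# Functional aliases matching the operation names.
def trace_to_retina(eye: SchematicEye, angle_deg: float) -> float:
    return eye.trace_to_retina(angle_deg)


def deg_to_mm(eye: SchematicEye, e):
    return eye.deg_to_mm(e)


def mm_to_deg(eye: SchematicEye, d):
    return eye.mm_to_deg(d)


def solid_deg_to_mm2(eye: SchematicEye, e):
    return eye.solid_deg_to_mm2(e)
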