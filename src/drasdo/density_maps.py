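"""Fovea-centered RGC body density maps on the retinal sphere.

A :class:`RetinalDensityMap` stores planar density (cells/mm^2) on a polar
grid of meridian angle (degrees, 0 = temporal retina, counter-clockwise for
a right eye) by eccentricity (mm of great-circle arc from the fovea), on a
sphere of stated radius.  Maps can be loaded from CSV (the documented
histology-map exchange format), rescaled for axial length under global
expansion, interpolated, integrated into per-meridian cumulative body
counts, and synthesized for testing.

Counts are accumulated on the sphere: a wedge of unit meridian angle
contributes ``\\int density(rho) * r * sin(rho/r) drho`` cells per radian,
which makes the cumulative count exactly invariant under the global
expansion rescaling (eccentricities times s, densities times 1/s^2).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import RegularGridInterpolator

from .schematic_eye import AL0, R0, SchematicEye, build_eye

__all__ = [
    "RetinalDensityMap",
    "SyntheticDensityParams",
    "load_density_map",
    "save_density_map",
    "scale_density_for_AL",
    "density_at",
    "cumulative_gcb",
    "synthetic_density",
]


@dataclass
class RetinalDensityMap:
    """RGC body density (cells/mm^2) on a polar grid over the retina.

    ``meridian_deg`` is sorted in [0, 360); ``ecc_mm`` is sorted and starts
    at 0; ``density`` has shape (n_meridians, n_ecc).
    """

    meridian_deg: np.ndarray
    ecc_mm: np.ndarray
    density: np.ndarray
    radius_mm: float
    provenance: str = "synthetic"
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.meridian_deg = np.asarray(self.meridian_deg, dtype=float)
        self.ecc_mm = np.asarray(self.ecc_mm, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        if self.density.shape != (self.meridian_deg.size, self.ecc_mm.size):
            raise ValueError("density grid shape mismatch")
        if np.any(np.diff(self.meridian_deg) <= 0) or np.any(self.meridian_deg < 0) \
                or np.any(self.meridian_deg >= 360):
            raise ValueError("meridians must be sorted within [0, 360)")
        if np.any(np.diff(self.ecc_mm) <= 0):
            raise ValueError("eccentricity axis must be strictly increasing")
        if np.any(~np.isfinite(self.density)) or np.any(self.density < 0):
            raise ValueError("densities must be finite and non-negative")

    @property
    def max_ecc_mm(self) -> float:
        return float(self.ecc_mm[-1])

    def _interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            # pad the angular axis for periodic interpolation across the seam
            ang = np.concatenate((
                [self.meridian_deg[-1] - 360.0], self.meridian_deg,
                [self.meridian_deg[0] + 360.0]))
            dens = np.vstack((self.density[-1], self.density, self.density[0]))
            self._interp = RegularGridInterpolator(
                (ang, self.ecc_mm), dens, method="linear", bounds_error=True)
        return self._interp

    def density_at(self, meridian_deg, ecc_mm):
        """Bilinear interpolation, periodic in angle; exact at grid nodes."""
        m = np.mod(np.asarray(meridian_deg, dtype=float), 360.0)
        e = np.asarray(ecc_mm, dtype=float)
        if np.any(e < self.ecc_mm[0] - 1e-12) or np.any(e > self.max_ecc_mm + 1e-12):
            raise ValueError("eccentricity outside the map grid (no extrapolation)")
        e = np.clip(e, self.ecc_mm[0], self.max_ecc_mm)
        mb, eb = np.broadcast_arrays(m, e)
        pts = np.stack((mb, eb), axis=-1).reshape(-1, 2)
        return self._interpolator()(pts).reshape(mb.shape)[()]

    def wedge_cumulative(self, meridian_deg: float, ecc_mm, step_mm: float = 0.01):
        """Cumulative body count per radian of wedge angle out to ``ecc_mm``.

        Spherical wedge integral ``\\int density * r * sin(rho/r) drho``
        along the meridian, trapezoidal at <= ``step_mm`` resolution.
        """
        e = np.atleast_1d(np.asarray(ecc_mm, dtype=float))
        emax = float(np.max(e, initial=0.0))
        if emax > self.max_ecc_mm + 1e-9:
            raise ValueError("requested eccentricity beyond map coverage")
        if emax == 0.0:
            out = np.zeros_like(e)
            return out if out.size > 1 else float(out[0])
        n = max(int(np.ceil(emax / step_mm)), 2) + 1
        rho = np.linspace(0.0, emax, n)
        dens = np.asarray(self.density_at(meridian_deg, rho), dtype=float)
        integrand = dens * self.radius_mm * np.sin(rho / self.radius_mm)
        cum = np.concatenate(([0.0], cumulative_trapezoid(integrand, rho)))
        out = np.interp(e, rho, cum)
        return out if out.size > 1 else float(out[0])

    def total_count(self, max_ecc_mm: float, n_rho: int = 600, n_theta: int = 360) -> float:
        """Total body count within ``max_ecc_mm`` (spherical area integral)."""
        rho = np.linspace(0.0, min(max_ecc_mm, self.max_ecc_mm), n_rho)
        theta = np.linspace(0.0, 360.0, n_theta, endpoint=False)
        tt, rr = np.meshgrid(theta, rho, indexing="ij")
        dens = np.asarray(self.density_at(tt, rr), dtype=float)
        integrand = dens * self.radius_mm * np.sin(rho / self.radius_mm)[None, :]
        per_wedge = np.trapezoid(integrand, rho, axis=1)
        return float(np.mean(per_wedge) * 2.0 * np.pi)


# ---------------------------------------------------------------------------
# CSV exchange format
# ---------------------------------------------------------------------------

def load_density_map(path, radius_mm: float,
                     provenance: str = "histology") -> RetinalDensityMap:
    """Load a density map from CSV.

    Format: '#' comment lines for provenance, then a header row whose first
    cell is a label and remaining cells are eccentricities in mm (strictly
    increasing); each following row starts with the meridian angle in
    degrees followed by densities in cells/mm^2.  Missing cells are filled
    by periodic angular interpolation at fixed eccentricity.
    """
    df = pd.read_csv(path, comment="#", index_col=0)
    try:
        ecc = df.columns.to_numpy(dtype=float)
        mer = df.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed density CSV: {exc}") from exc
    if np.any(np.diff(ecc) <= 0):
        raise ValueError("eccentricity header must be strictly increasing")
    order = np.argsort(mer)
    mer = mer[order]
    dens = df.to_numpy(dtype=float)[order]
    if np.any(np.isnan(dens)):
        dens = _fill_angular_gaps(mer, dens)
    if np.any(dens < 0):
        raise ValueError("negative density in CSV")
    return RetinalDensityMap(mer, ecc, dens, radius_mm, provenance)


def _fill_angular_gaps(mer: np.ndarray, dens: np.ndarray) -> np.ndarray:
    out = dens.copy()
    for j in range(dens.shape[1]):
        col = dens[:, j]
        bad = np.isnan(col)
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(f"eccentricity column {j} has no data")
        # periodic linear interpolation in meridian angle
        good_m = mer[~bad]
        good_v = col[~bad]
        ext_m = np.concatenate((good_m - 360.0, good_m, good_m + 360.0))
        ext_v = np.tile(good_v, 3)
        out[bad, j] = np.interp(mer[bad], ext_m, ext_v)
    return out


def save_density_map(m: RetinalDensityMap, path, header_comment: str = "") -> None:
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write(f"# radius_mm={m.radius_mm} provenance={m.provenance}\n")
    df = pd.DataFrame(m.density, index=m.meridian_deg, columns=m.ecc_mm)
    df.index.name = "meridian_deg"
    df.to_csv(buf)
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Axial-length scaling (global expansion)
# ---------------------------------------------------------------------------

def scale_density_for_AL(m: RetinalDensityMap, AL: float) -> RetinalDensityMap:
    """Rescale a map given at the reference AL for a different axial length.

    Global expansion: eccentricities scale with r/r0, planar densities with
    (r0/r)^2, so the count over any corresponding region is unchanged.
    """
    if not np.isfinite(AL) or AL <= 0:
        raise ValueError("axial length must be positive")
    s = AL / AL0
    return replace(m, ecc_mm=m.ecc_mm * s, density=m.density / s**2,
                   radius_mm=m.radius_mm * s, _interp=None)


# ---------------------------------------------------------------------------
# Synthetic fovea-peaked maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDensityParams:
    """Parameters of the synthetic fovea-peaked density profile.

    Radial profile is a gamma-type curve ``(rho/beta)^alpha * exp(-rho/beta)``
    with ``beta = ridge_ecc_mm/alpha``: zero at the fovea center (the
    RGC-free foveola), a single radial peak at ``ridge_ecc_mm``, and a
    smooth outward decay.  Meridional asymmetry is a multiplicative
    harmonic modulation ``1 + sum_k amp_k cos(k*(theta - phase_k))``.
    """

    peak_density: float = 30000.0       # cells/mm^2 at the ridge
    ridge_ecc_mm: float = 1.0
    alpha: float = 2.0
    asymmetry: tuple[tuple[int, float, float], ...] = ((1, 0.2, 180.0),)
    radius_mm: float = R0
    max_ecc_mm: float = 5.0
    ecc_step_mm: float = 0.025
    meridian_step_deg: float = 5.0

    @property
    def beta(self) -> float:
        return self.ridge_ecc_mm / self.alpha

    def radial_profile(self, rho):
        """Unit-peak radial profile (analytic; peak value 1 at the ridge)."""
        x = np.asarray(rho, dtype=float) / self.beta
        peak = self.alpha**self.alpha * np.exp(-self.alpha)
        return np.power(x, self.alpha) * np.exp(-x) / peak

    def wedge_integral_planar(self, max_ecc_mm: float) -> float:
        """Closed form of ``peak * \\int_0^R profile(rho) * rho drho``."""
        from scipy.special import gamma, gammainc
        a = self.alpha
        peak = a**a * np.exp(-a)
        return float(self.peak_density / peak * self.beta**2
                     * gamma(a + 2) * gammainc(a + 2, max_ecc_mm / self.beta))


def synthetic_density(params: SyntheticDensityParams | None = None,
                      **overrides) -> RetinalDensityMap:
    """Generate a smooth, fovea-peaked, meridionally asymmetric density map."""
    p = params or SyntheticDensityParams()
    if overrides:
        p = replace(p, **overrides)
    if p.ridge_ecc_mm <= 0 or p.alpha <= 0 or p.ecc_step_mm <= 0:
        raise ValueError("profile widths must be positive")
    amp_total = sum(abs(a) for _, a, _ in p.asymmetry)
    if amp_total >= 1.0:
        raise ValueError("asymmetry amplitudes must sum below 1 (non-negativity)")
    mer = np.arange(0.0, 360.0, p.meridian_step_deg)
    ecc = np.arange(0.0, p.max_ecc_mm + 1e-12, p.ecc_step_mm)
    radial = p.peak_density * p.radial_profile(ecc)
    mod = np.ones_like(mer)
    for k, amp, phase in p.asymmetry:
        mod = mod + amp * np.cos(np.radians(k * (mer - phase)))
    dens = np.outer(mod, radial)
    return RetinalDensityMap(mer, ecc, dens, p.radius_mm, "synthetic")


# ---------------------------------------------------------------------------
# Functional aliases
# ---------------------------------------------------------------------------

def density_at(m: RetinalDensityMap, meridian_deg, ecc_mm):
    return m.density_at(meridian_deg, ecc_mm)


def cumulative_gcb(m: RetinalDensityMap, eye: SchematicEye | None,
                   meridian_deg: float, e_deg, step_mm: float = 0.01):
    """Cumulative RGC body count per radian out to visual eccentricity ``e_deg``.

    ``C_gcb(e)`` integrates body density along the meridian to the retinal
    arc distance corresponding to ``e`` through the schematic eye.
    """
    eye = eye or build_eye()
    d = np.asarray(eye.deg_to_mm(e_deg), dtype=float)
    return m.wedge_cumulative(meridian_deg, d, step_mm=step_mm)
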