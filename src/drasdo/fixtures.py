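"""Deterministic synthetic data generators.

Every pipeline stage is testable without downloads: the generators here
produce (1) body-density maps that are exactly self-consistent with the
receptive-field surface under a prescribed displacement profile, so that
fitting recovers known parameters, and (2) cohorts of GCL thickness maps
whose parafoveal ridge scales geometrically with axial length.

The self-consistent construction inverts the displacement model: given a
per-meridian E_2v and a prescribed monotone displacement psi(e) that is
the identity at and beyond the zone edge, the body density is defined so
that the cumulative body count at psi(e) equals the cumulative RF count at
e.  By construction the zone-edge counts agree for the prescribed E_2v, so
the count-matching fit recovers it, and inverting the cumulative tables
recovers psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density_maps import RetinalDensityMap
from .displacement import cumulative_grf, zone_edge_deg
from .schematic_eye import AL0, SchematicEye, build_eye

__all__ = [
    "FixtureSpec",
    "prescribed_displacement",
    "make_selfconsistent_density",
    "make_thickness_cohort",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition parameters for the synthetic thickness cohort."""

    seed: int = 0
    n_eyes: int = 28
    al_range_mm: tuple[float, float] = (21.0, 27.0)
    axes0_mm: tuple[float, float] = (2.0, 1.6)   # semi-axes of the GCL ridge at AL0
    ridge_height_um: float = 40.0
    base_um: float = 10.0
    ridge_width: float = 0.18        # Gaussian width in elliptical-radius units
    pit_sigma_mm: float = 0.35
    noise_um: float = 1.0            # additive Gaussian thickness noise
    axis_jitter_mm: float = 0.0      # Gaussian jitter of the ridge semi-axes
    shape: tuple[int, int] = (192, 192)
    fov_deg: float = 30.0

    def __post_init__(self) -> None:
        if min(self.axes0_mm) <= 0 or self.ridge_width <= 0 or self.pit_sigma_mm <= 0:
            raise ValueError("scale parameters must be positive")


# ---------------------------------------------------------------------------
# Self-consistent density maps
# ---------------------------------------------------------------------------

def prescribed_displacement(e_deg, e_dz_deg: float, d0_deg: float = 2.0):
    """Smooth monotone displacement profile psi(e) used by the fixture.

    ``psi(e) = e + d0*(1 - (e/e_dz)^2)^2`` inside the zone, identity at and
    beyond the edge (value and slope continuous).  Monotone for
    ``d0 < e_dz/1.54``.
    """
    e = np.asarray(e_deg, dtype=float)
    delta = np.where(e < e_dz_deg,
                     d0_deg * (1.0 - (np.minimum(e, e_dz_deg) / e_dz_deg) ** 2) ** 2,
                     0.0)
    return (e + delta)[()]


def make_selfconsistent_density(e2v, eye: SchematicEye | None = None,
                                d0_deg: float = 2.0,
                                meridian_step_deg: float = 5.0,
                                max_ecc_mm: float = 5.0,
                                ecc_step_mm: float = 0.02,
                                k=None) -> RetinalDensityMap:
    """Body-density map exactly consistent with the RF surface.

    ``e2v`` is a scalar, a callable of meridian angle (degrees), or an
    array matching the meridian grid.  Fitting E_2v on the returned map
    recovers the inputs; the displacement model applied to it recovers the
    prescribed profile.
    """
    eye = eye or build_eye()
    if d0_deg < 0:
        raise ValueError("prescribed displacement must be non-negative")
    e_dz = zone_edge_deg(eye)
    mer = np.arange(0.0, 360.0, meridian_step_deg)
    if callable(e2v):
        e2v_arr = np.asarray([float(e2v(m)) for m in mer])
    else:
        e2v_arr = np.broadcast_to(np.asarray(e2v, dtype=float), mer.shape).copy()
    if np.any(e2v_arr <= 0):
        raise ValueError("E_2v must be positive")

    ecc_grid = np.arange(0.0, max_ecc_mm + 1e-12, ecc_step_mm)
    r = eye.r
    # RF-eccentricity grid fine enough for stable differentiation
    e_grid = np.linspace(0.0, float(eye.mm_to_deg(max_ecc_mm)), 3000)
    u_grid = np.asarray(prescribed_displacement(e_grid, e_dz, d0_deg), dtype=float)
    s_u = np.asarray(eye.deg_to_mm(u_grid), dtype=float)      # body arc position, mm
    dens = np.empty((mer.size, ecc_grid.size))
    for i in range(mer.size):
        cgrf = np.asarray(cumulative_grf(e_grid, float(e2v_arr[i]), k,
                                         step_deg=e_grid[1] - e_grid[0]))
        # body density from the derivative of the displaced cumulative:
        # dC/ds_u = density(s_u) * r * sin(s_u / r)
        dc_ds = np.gradient(cgrf, s_u)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_dens = dc_ds / (r * np.sin(np.clip(s_u, 1e-12, None) / r))
        rho_dens = np.clip(np.nan_to_num(rho_dens), 0.0, None)
        col = np.interp(ecc_grid, s_u, rho_dens, left=0.0, right=rho_dens[-1])
        col[ecc_grid < s_u[0]] = 0.0   # displaced foveola: no bodies inside
        dens[i] = col
    return RetinalDensityMap(mer, ecc_grid, dens, eye.r, "synthetic")


# ---------------------------------------------------------------------------
# Thickness cohorts under geometric scaling
# ---------------------------------------------------------------------------

def _thickness_surface(x_mm, y_mm, a_mm, b_mm, spec: FixtureSpec):
    rho_ell = np.hypot(x_mm / a_mm, y_mm / b_mm)
    ridge = spec.ridge_height_um * np.exp(-(rho_ell - 1.0) ** 2
                                          / (2.0 * spec.ridge_width ** 2))
    rho = np.hypot(x_mm, y_mm)
    pit = 1.0 - np.exp(-rho ** 2 / (2.0 * spec.pit_sigma_mm ** 2))
    return (spec.base_um + ridge) * pit


def make_thickness_cohort(spec: FixtureSpec | None = None):
    """Synthetic GCL thickness maps whose ridge scales with axial length.

    Each eye's ridge semi-axes are the AL0 axes times AL/AL0 (geometric
    scaling), optionally jittered; thickness is evaluated on the eye's own
    degree raster through its schematic eye (so magnification correction
    recovers the mm-space geometry), with seeded additive Gaussian noise.
    Returns a list of ThicknessMap.
    """
    from .oct import ThicknessMap

    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    als = rng.uniform(*spec.al_range_mm, size=spec.n_eyes)
    nrow, ncol = spec.shape
    pitch = spec.fov_deg / ncol
    maps = []
    for al in als:
        eye = build_eye(float(al))
        a = spec.axes0_mm[0] * al / AL0 + spec.axis_jitter_mm * rng.standard_normal()
        b = spec.axes0_mm[1] * al / AL0 + spec.axis_jitter_mm * rng.standard_normal()
        # pixel-centered raster with the fovea exactly on a pixel center
        xs = (np.arange(ncol) - ncol // 2) * pitch
        ys = (nrow // 2 - np.arange(nrow)) * pitch
        xx, yy = np.meshgrid(xs, ys)
        e = np.hypot(xx, yy)
        theta = np.arctan2(yy, xx)
        ecc_mm = np.asarray(eye.deg_to_mm(np.clip(e, 0.0, 39.0).ravel())).reshape(e.shape)
        t = _thickness_surface(ecc_mm * np.cos(theta), ecc_mm * np.sin(theta),
                               a, b, spec)
        if spec.noise_um > 0:
            t = t + spec.noise_um * rng.standard_normal(t.shape)
        t = np.clip(t, 0.0, None)
        maps.append(ThicknessMap(
            data_um=t, fov_deg=(spec.fov_deg, spec.fov_deg), al_mm=float(al),
            laterality="OD", fovea_px=(nrow // 2, ncol // 2),
            valid=np.ones(spec.shape, dtype=bool)))
    return maps
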