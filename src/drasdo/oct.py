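"""OCT thickness-map processing and conversion to RGC density.

Covers the structural arm of the analysis: building smooth raster
thickness maps from sparse B-scan segmentations, locating the fovea by
template matching, re-gridding degree rasters onto retinal millimetres
through the schematic eye (ocular magnification correction), the
point-by-point thickness-to-density conversion (histology density divided
by a cohort-mean thickness map to give a volumetric density, multiplied by
an individual thickness map to give that eye's planar density), and the
GCL-peak ellipse analysis used to test geometric scaling of retinal
structures with axial length.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator
from scipy.stats import linregress
from skimage.feature import match_template
from skimage.measure import EllipseModel

from .density_maps import RetinalDensityMap
from .schematic_eye import AL0, R0, SchematicEye, build_eye

__all__ = [
    "ThicknessMap",
    "MmRaster",
    "VolumetricDensityMap",
    "EllipseFit",
    "FoveaResult",
    "ScalingAnalysis",
    "build_thickness_map",
    "find_fovea",
    "magnification_correct",
    "raza_hood_volumetric",
    "subject_density",
    "gcl_peak_ellipse",
    "scaling_analysis",
]


@dataclass
class ThicknessMap:
    """Raster thickness map (um) on a visual-degree field of view.

    Row 0 is the top of the field; ``fovea_px`` is (row, col).  The pixel
    pitch is ``fov_deg / n_cols`` (0.0391 deg/px for the reference
    768 x 768, 30 x 30 deg geometry).
    """

    data_um: np.ndarray
    fov_deg: tuple[float, float]
    al_mm: float
    laterality: str = "OD"
    fovea_px: tuple[int, int] | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data_um = np.asarray(self.data_um, dtype=float)
        if np.any(self.data_um < 0):
            raise ValueError("thickness must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.data_um.shape, dtype=bool)
        if self.fovea_px is not None:
            r, c = self.fovea_px
            if not (0 <= r < self.data_um.shape[0] and 0 <= c < self.data_um.shape[1]):
                raise ValueError("fovea outside the raster")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @property
    def pitch_deg(self) -> float:
        return self.fov_deg[0] / self.data_um.shape[1]

    def save(self, path_csv, path_meta=None) -> None:
        np.savetxt(path_csv, self.data_um, delimiter=",", fmt="%.4f")
        meta = {"al_mm": self.al_mm, "eye": self.laterality,
                "fov_deg": list(self.fov_deg),
                "fovea_px": list(self.fovea_px) if self.fovea_px else None}
        p = Path(path_meta) if path_meta else Path(path_csv).with_suffix(".json")
        p.write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path_csv, path_meta=None) -> "ThicknessMap":
        data = np.loadtxt(path_csv, delimiter=",")
        p = Path(path_meta) if path_meta else Path(path_csv).with_suffix(".json")
        meta = json.loads(p.read_text())
        return cls(data_um=data, fov_deg=tuple(meta["fov_deg"]),
                   al_mm=float(meta["al_mm"]), laterality=meta.get("eye", "OD"),
                   fovea_px=tuple(meta["fovea_px"]) if meta.get("fovea_px") else None)


@dataclass
class MmRaster:
    """Square raster on retinal-mm coordinates centered at the fovea."""

    data: np.ndarray
    half_extent_mm: float
    al_mm: float
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.isfinite(self.data)

    @property
    def pitch_mm(self) -> float:
        return 2.0 * self.half_extent_mm / self.data.shape[1]

    def coords(self):
        n = self.data.shape[0]
        xs = (np.arange(n) - n // 2) * self.pitch_mm
        ys = (n // 2 - np.arange(n)) * self.pitch_mm
        return xs, ys


@dataclass
class VolumetricDensityMap:
    """RGC/mm^3 raster in the canonical fovea-centered mm frame."""

    data: np.ndarray
    half_extent_mm: float
    valid: np.ndarray
    provenance: str = "histology / cohort-mean thickness"

    @property
    def pitch_mm(self) -> float:
        return 2.0 * self.half_extent_mm / self.data.shape[1]


@dataclass(frozen=True)
class EllipseFit:
    center_mm: tuple[float, float]
    major_mm: float                 # semi-axis
    minor_mm: float                 # semi-axis
    orientation_rad: float
    peaks_mm: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not (self.major_mm >= self.minor_mm > 0):
            raise ValueError("expected major >= minor > 0")


@dataclass(frozen=True)
class FoveaResult:
    px: tuple[int, int]
    score: float
    confident: bool


# ---------------------------------------------------------------------------
# Thickness-map construction from sparse B-scan samples
# ---------------------------------------------------------------------------

def build_thickness_map(x_deg, y_deg, thickness_um, *, al_mm: float,
                        laterality: str = "OD", shape=(768, 768),
                        fov_deg: float = 30.0, anisotropy: float = 10.0,
                        smoothing: float = 1e-3, neighbors: int = 32) -> ThicknessMap:
    """Interpolate scattered B-scan thickness samples onto a raster.

    A thin-plate-spline radial-basis interpolant with mild smoothing is
    fitted to the samples; anisotropy > 1 stretches the kernel across the
    B-scan axis (y), making smoothing stronger across scans than along
    them.  Pixels outside the sampled bounding box are zero-padded and
    flagged invalid.
    """
    x = np.asarray(x_deg, dtype=float).ravel()
    y = np.asarray(y_deg, dtype=float).ravel()
    t = np.asarray(thickness_um, dtype=float).ravel()
    if np.unique(np.round(y, 6)).size < 3:
        raise ValueError("need at least 3 B-scan lines")
    if np.min(np.hypot(x, y)) > 1.0:
        raise ValueError("no samples within 1 degree of the fovea")
    nrow, ncol = shape
    pitch = fov_deg / ncol
    xs = (np.arange(ncol) - ncol // 2) * pitch
    ys = (nrow // 2 - np.arange(nrow)) * pitch
    xx, yy = np.meshgrid(xs, ys)
    inside = ((xx >= x.min()) & (xx <= x.max())
              & (yy >= y.min()) & (yy <= y.max()))
    pts = np.column_stack((x, y / anisotropy))
    rbf = RBFInterpolator(pts, t, kernel="thin_plate_spline",
                          smoothing=smoothing,
                          neighbors=min(neighbors, len(t)))
    out = np.zeros(shape, dtype=float)
    q = np.column_stack((xx[inside], yy[inside] / anisotropy))
    out[inside] = np.clip(rbf(q), 0.0, None)
    return ThicknessMap(out, (fov_deg, fov_deg), al_mm, laterality,
                        fovea_px=(nrow // 2, ncol // 2), valid=inside)


# ---------------------------------------------------------------------------
# Fovea detection
# ---------------------------------------------------------------------------

def find_fovea(tmap: ThicknessMap, sigma_deg: float = 1.0,
               threshold: float = 0.2) -> FoveaResult:
    """Locate the foveal pit by normalized cross-correlation.

    The template is a radially symmetric Gaussian pit (negative peak,
    ``sigma_deg`` wide).  NCC is invariant to adding a constant to the
    map; a maximum below ``threshold`` yields a low-confidence warning.
    """
    pitch = tmap.pitch_deg
    half = int(np.ceil(3.0 * sigma_deg / pitch))
    ax = np.arange(-half, half + 1) * pitch
    gx, gy = np.meshgrid(ax, ax)
    template = -np.exp(-(gx ** 2 + gy ** 2) / (2.0 * sigma_deg ** 2))
    resp = match_template(tmap.data_um, template, pad_input=True, mode="edge")
    idx = np.unravel_index(np.nanargmax(resp), resp.shape)
    score = float(resp[idx])
    confident = score >= threshold
    if not confident:
        warnings.warn(f"low-confidence fovea detection (NCC={score:.3f})",
                      stacklevel=2)
    return FoveaResult((int(idx[0]), int(idx[1])), score, confident)


# ---------------------------------------------------------------------------
# Ocular magnification correction
# ---------------------------------------------------------------------------

def magnification_correct(tmap: ThicknessMap, eye: SchematicEye | None = None,
                          shape: int | None = None) -> MmRaster:
    """Re-grid a degree raster onto retinal-mm coordinates (fovea-centered).

    Each mm-raster pixel is mapped to its visual direction through the
    subject's schematic eye (arc mm -> degrees along the same meridian)
    and sampled bilinearly from the degree raster.
    """
    if tmap.fovea_px is None:
        raise ValueError("fovea position required for magnification correction")
    eye = eye or build_eye(tmap.al_mm)
    n = shape or tmap.data_um.shape[0]
    half_deg = tmap.fov_deg[0] / 2.0
    half_mm = float(eye.deg_to_mm(half_deg))
    pitch_mm = 2.0 * half_mm / n
    xs = (np.arange(n) - n // 2) * pitch_mm
    ys = (n // 2 - np.arange(n)) * pitch_mm
    xx, yy = np.meshgrid(xs, ys)
    rr = np.hypot(xx, yy)
    e = np.asarray(eye.mm_to_deg(np.clip(rr, 0.0, float(eye.deg_to_mm(39.0)))))
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rr > 0, e / np.where(rr > 0, rr, 1.0), 0.0)
    x_deg = xx * scale
    y_deg = yy * scale
    fr, fc = tmap.fovea_px
    pitch_deg = tmap.pitch_deg
    rows = fr - y_deg / pitch_deg
    cols = fc + x_deg / pitch_deg
    data = ndimage.map_coordinates(tmap.data_um, [rows.ravel(), cols.ravel()],
                                   order=1, mode="constant", cval=0.0)
    vmask = ndimage.map_coordinates(tmap.valid.astype(float),
                                    [rows.ravel(), cols.ravel()],
                                    order=0, mode="constant", cval=0.0)
    return MmRaster(data.reshape(n, n), half_mm, tmap.al_mm,
                    valid=vmask.reshape(n, n) > 0.5)


# ---------------------------------------------------------------------------
# Thickness -> density conversion
# ---------------------------------------------------------------------------

def _density_map_to_raster(m: RetinalDensityMap, half_extent_mm: float,
                           n: int) -> np.ndarray:
    pitch = 2.0 * half_extent_mm / n
    xs = (np.arange(n) - n // 2) * pitch
    ys = (n // 2 - np.arange(n)) * pitch
    xx, yy = np.meshgrid(xs, ys)
    rr = np.clip(np.hypot(xx, yy), 0.0, m.max_ecc_mm)
    theta = np.degrees(np.arctan2(yy, xx))
    return np.asarray(m.density_at(theta, rr))


def raza_hood_volumetric(histology: RetinalDensityMap | np.ndarray,
                         mean_thickness: MmRaster,
                         min_thickness_um: float = 5.0) -> VolumetricDensityMap:
    """Volumetric density: histology density / cohort-mean GCL thickness.

    ``histology`` may be a polar density map (rasterized onto the cohort
    grid) or an aligned planar raster in cells/mm^2.  Pixels with mean
    thickness below ``min_thickness_um`` (foveal pit, padded regions) are
    masked.
    """
    n = mean_thickness.data.shape[0]
    if isinstance(histology, RetinalDensityMap):
        dens = _density_map_to_raster(histology, mean_thickness.half_extent_mm, n)
    else:
        dens = np.asarray(histology, dtype=float)
        if dens.shape != mean_thickness.data.shape:
            raise ValueError("misaligned frames: histology raster shape differs "
                             "from the cohort-mean thickness raster")
    ok = (mean_thickness.data >= min_thickness_um) & mean_thickness.valid
    out = np.full_like(dens, np.nan)
    out[ok] = dens[ok] / (mean_thickness.data[ok] * 1e-3)   # um -> mm
    return VolumetricDensityMap(out, mean_thickness.half_extent_mm, ok)


def subject_density(volumetric: VolumetricDensityMap, subject: MmRaster,
                    al_mm: float | None = None) -> MmRaster:
    """Planar RGC density (cells/mm^2) for an individual eye.

    The volumetric map (canonical AL0 frame) is sampled at the subject's
    retinal positions shrunk by r0/r and rescaled by (r0/r)^2 — the global
    expansion of the histology map — then multiplied point-by-point by the
    subject's GCL thickness.
    """
    al = al_mm if al_mm is not None else subject.al_mm
    s = (al / AL0)
    n = subject.data.shape[0]
    xs, ys = subject.coords()
    xx, yy = np.meshgrid(xs, ys)
    pitch_v = volumetric.pitch_mm
    nv = volumetric.data.shape[0]
    rows = nv // 2 - (yy / s) / pitch_v
    cols = nv // 2 + (xx / s) / pitch_v
    vol = ndimage.map_coordinates(np.nan_to_num(volumetric.data),
                                  [rows.ravel(), cols.ravel()],
                                  order=1, mode="constant", cval=np.nan)
    vmask = ndimage.map_coordinates(volumetric.valid.astype(float),
                                    [rows.ravel(), cols.ravel()],
                                    order=0, mode="constant", cval=0.0)
    dens = vol.reshape(n, n) / s ** 2 * (subject.data * 1e-3)
    ok = (vmask.reshape(n, n) > 0.5) & subject.valid
    dens[~ok] = np.nan
    return MmRaster(dens, subject.half_extent_mm, al, valid=ok)


def subject_density_polar(dens: MmRaster, n_meridians: int = 90,
                          ecc_step_mm: float = 0.05) -> RetinalDensityMap:
    """Resample a subject planar density raster onto the polar map format."""
    max_ecc = dens.half_extent_mm * 0.99
    mer = np.arange(0.0, 360.0, 360.0 / n_meridians)
    ecc = np.arange(0.0, max_ecc, ecc_step_mm)
    tt, rr = np.meshgrid(np.radians(mer), ecc, indexing="ij")
    xq = rr * np.cos(tt)
    yq = rr * np.sin(tt)
    n = dens.data.shape[0]
    rows = n // 2 - yq / dens.pitch_mm
    cols = n // 2 + xq / dens.pitch_mm
    vals = ndimage.map_coordinates(np.nan_to_num(dens.data),
                                   [rows.ravel(), cols.ravel()], order=1,
                                   mode="nearest").reshape(rr.shape)
    r_sphere = R0 * dens.al_mm / AL0
    return RetinalDensityMap(mer, ecc, np.clip(vals, 0.0, None), r_sphere,
                             "subject-OCT")


# ---------------------------------------------------------------------------
# GCL-peak ellipse and axial-length scaling analysis
# ---------------------------------------------------------------------------

def gcl_peak_ellipse(mm_map: MmRaster, n_meridians: int = 36,
                     r_min_mm: float = 0.3, r_max_mm: float = 3.0,
                     smooth_sigma_mm: float = 0.08) -> EllipseFit:
    """Fit an ellipse to the per-meridian GCL thickness peaks.

    For each meridian a 1-D radial profile from the fovea is extracted,
    lightly smoothed, and its maximum within [r_min, r_max] refined to
    sub-pixel precision by parabolic interpolation; an algebraic
    least-squares ellipse is fitted through the peak points.
    """
    step = mm_map.pitch_mm / 2.0
    radii = np.arange(r_min_mm, min(r_max_mm, mm_map.half_extent_mm * 0.98), step)
    if radii.size < 8:
        raise ValueError("map too small for peak-profile extraction")
    thetas = np.arange(0.0, 360.0, 360.0 / n_meridians)
    n = mm_map.data.shape[0]
    peaks = []
    for th in np.radians(thetas):
        xq = radii * np.cos(th)
        yq = radii * np.sin(th)
        rows = n // 2 - yq / mm_map.pitch_mm
        cols = n // 2 + xq / mm_map.pitch_mm
        prof = ndimage.map_coordinates(mm_map.data, [rows, cols], order=1,
                                       mode="nearest")
        prof = ndimage.gaussian_filter1d(prof, smooth_sigma_mm / step)
        i = int(np.argmax(prof))
        if i == 0 or i == len(prof) - 1:
            continue  # peak at the window edge: not a valid ridge crossing
        # parabolic sub-sample refinement
        y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
        denom = y0 - 2.0 * y1 + y2
        off = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        r_pk = radii[i] + off * step
        peaks.append((r_pk * np.cos(th), r_pk * np.sin(th)))
    if len(peaks) < 5:
        raise ValueError(f"only {len(peaks)} valid GCL peaks found (need >= 5)")
    pts = np.asarray(peaks)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("ellipse fit failed")
        xc, yc = model.center
        a, b = model.axis_lengths
        th = model.theta
    else:
        model = EllipseModel()
        if not model.estimate(pts):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, th = model.params
    major, minor = (a, b) if a >= b else (b, a)
    if a < b:
        th = th + np.pi / 2.0
    return EllipseFit((float(xc), float(yc)), float(major), float(minor),
                      float(np.mod(th, np.pi)), pts)


@dataclass(frozen=True)
class ScalingAnalysis:
    """Axis-length-on-AL regression vs the geometric-scaling prediction."""

    slope: tuple[float, float]
    intercept: tuple[float, float]
    p_value: tuple[float, float]
    mae_linear: tuple[float, float]
    mae_geometric: tuple[float, float]


def scaling_analysis(fits, als) -> ScalingAnalysis:
    """Compare linear regression and geometric scaling of ellipse axes on AL.

    The geometric model predicts each axis as its linear-regression value
    at AL0 multiplied by r(AL)/r0 = AL/AL0.  Goodness of fit is the mean
    absolute error of each model's residuals.
    """
    als = np.asarray(als, dtype=float)
    major = np.array([f.major_mm for f in fits])
    minor = np.array([f.minor_mm for f in fits])
    slopes, icepts, ps, mael, maeg = [], [], [], [], []
    for axis in (major, minor):
        res = linregress(als, axis)
        pred_lin = res.intercept + res.slope * als
        at_al0 = res.intercept + res.slope * AL0
        pred_geo = at_al0 * als / AL0
        slopes.append(float(res.slope))
        icepts.append(float(res.intercept))
        ps.append(float(res.pvalue))
        mael.append(float(np.mean(np.abs(axis - pred_lin))))
        maeg.append(float(np.mean(np.abs(axis - pred_geo))))
    return ScalingAnalysis(tuple(slopes), tuple(icepts), tuple(ps),
                           tuple(mael), tuple(maeg))
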