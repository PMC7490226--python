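# Methods

This note documents the model, its numerical choices, and what the
synthetic-data generators do and do not emulate.

## Schematic eye

The eye is a rotationally symmetric sequence of four spherical refracting
surfaces followed by a spherical retina; the surface table ships in
`src/drasdo/data/drasdo_fowler_surfaces.json`. The anterior segment is a
Le Grand-type reconstruction of the classic wide-angle schematic eye
(anterior/posterior cornea 7.80/6.50 mm at 0/0.55 mm, n = 1.3771/1.3374;
anterior/posterior lens 10.20/−6.00 mm at 3.60/7.60 mm, n = 1.4200/1.3360),
with the original retina (radius 11.06 mm centered 11.95 mm behind the
cornea, AL 23.01 mm) rescaled to the histology sphere: r₀ = 11.459 mm,
c₀ = 11.95·(11.459/11.06) = 12.381108 mm, AL₀ = 23.840108 mm. The exact
derived values are kept so that AL = c + r holds to machine precision;
they print as 12.38 and 23.84 at two decimals. The reconstruction is
validated behaviorally: the ray-traced foveal conversion at the original
geometry is 0.274 mm/deg against the published ≈0.268 mm/deg, and the
mapping's curvature matches the published nonlinear shape.

The mapping e → arc(e) is built by tracing the chief ray (the ray of each
field angle that crosses the aperture stop center at the anterior lens
vertex) with exact vector Snell refraction, intersecting the retinal
sphere, and converting to great-circle arc from the posterior pole.
Samples every 0.25° out to 40° feed a monotone PCHIP interpolant (cached
per eye); forward and inverse maps agree to <1e-4. The areal Jacobian is
J(e) = arc′(e) · r·sin(arc/r)/e mm²/deg² (planar-chart visual
coordinates, spherical transverse metric on the retina; J(0) = arc′(0)²).

Axial length enters by global expansion: r and c scale with AL/AL₀, the
optics do not. A measured consequence: the *shape* of the angular mapping
is invariant to <0.05%, but its overall millimetre scale grows slightly
faster than AL/AL₀ (≈ +1.7% per +10% AL) because the chief-ray pivot — the
exit pupil at z ≈ 3.7 mm — does not move. This is the familiar
ocular-magnification correction (arc ≈ const·(AL − z_pivot)·e). It is why
the package distinguishes two conversions: projecting *visual stimuli*
onto an individual retina always uses that eye's ray-traced mapping, while
the *displacement field in mm* — a property of the retinal tissue — scales
exactly with r/r₀ (see below). Users should also note the fixation axis
and optical axis are treated as coincident.

## Receptive-field surface and k

D_gcrf(e) = k(e)·(1.12 + 0.0273e)^1.155 / [R_v(1+e/E_2v)² − R_o(1+e/20)²],
R_v = 0.011785, R_o = 0.008333, e in visual degrees, D in RF per solid
degree. Of the possible groupings of these terms only this ratio form is
positive over the macula; it is also the only one consistent with the
canonical density table (5969 RF/deg² at 1.41° and 560 at 8.6° for
E_2v ≈ 2, a 10.7× ratio).

k(e) is exposed as a user-replaceable function. The default is the
constant fixed in closed form by the 1.41° anchor:

    K_DEFAULT = 5969·[R_v(1+1.41/2)² − R_o(1+1.41/20)²]/(1.12+0.0273·1.41)^1.155
              ≈ 124.44

With that single calibration the surface predicts 563 RF/deg² at 8.6°
(printed value 560, +0.5%) and a G-III expected count of 871 RFs = 29.4 dB
at 1.41°, both genuine cross-checks. The implied foveal peak is
~41,000 RF/deg². Counts use the dB convention 10·log₁₀(count).

## Displacement model

Cumulative counts per radian of wedge angle:

* RF side (visual space, planar chart): C_gcrf(e) = ∫₀ᵉ D_gcrf(x)·x dx,
  trapezoidal at 0.01°.
* Body side (retinal sphere): C_gcb(e) = ∫₀^{d(e)} density(ρ)·r·sin(ρ/r) dρ
  with d(e) = deg_to_mm(e), trapezoidal at ≤0.01 mm. The spherical
  transverse metric (rather than planar ρ dρ) keeps the construction
  exactly consistent with mask-based body counting through J(e) and makes
  the cumulative count exactly invariant under global-expansion rescaling
  of the map. Halving either step changes results by <0.1%.

Per meridian (360 by default; synthetic maps are smooth enough that tests
use 36–90), E_2v is fitted by requiring C_gcrf(e_DZ) = C_gcb(e_DZ) at the
zone edge e_DZ = mm_to_deg(4.034·r/r₀) ≈ 14.1°; since C_gcrf is strictly
increasing in E_2v this is a monotone bracketing root search (Brent, on
[0.2, 20], relative tolerance 1e-6). Displacement inverts the monotone
tables: e′(e) solves C_gcb(e′) = C_gcrf(e), by linear inverse
interpolation on the 0.01° grid; e′ = e at and beyond the zone edge
(continuous there because of the fit constraint). The inversion is kept
exact rather than clamped to e′ ≥ e: on histology-like
(displacement-consistent) maps e′ ≥ e holds throughout, while a generic
fovea-peaked map may remap marginally inward near the zone edge — the
price of clamping would be breaking count conservation, which is the
model's defining property. Intermediate meridians use periodic linear
interpolation of e′ and E_2v.

**Axial length.** In visual degrees the whole construction is invariant
under Eq.-1/2 scaling (eccentricities × r/r₀, densities × (r₀/r)², zone
edge × r/r₀): every cumulative count is unchanged, hence the field is
fitted once at the map's native geometry and the displacement in degrees
is identical at all ALs by construction. Displacement in millimetres is
the reference-eye value scaled by r/r₀ (tissue homothety). Per-AL
refitting through the fixed anterior optics is still available
(`fit_E2v` accepts any eye) and shifts E_2v only slightly; it is an
analysis, not part of the canonical field. The precomputed lookup stores
planar displaced positions out to 7.5 mm at 0.05 mm steps for AL 18–35 mm
at 0.5 mm steps, each slice the r/r₀-scaled reference map, queried by
trilinear interpolation.

## Stimuli and counts

The 10-2 grid is the 68 odd-integer-coordinate points within √82 ≈ 9.06°
of fixation. Goldmann diameters come from the bowl geometry — size III is
4 mm² on a 300 mm bowl, 2·atan(√(4/π)/300) = 0.431° — with exact diameter
doubling per step (I–V: 0.108°, 0.216°, 0.431°, 0.862°, 1.724°).

Method 1 displaces only the stimulus center along its meridian; Method 2
displaces each of 72 edge points independently, producing the ovoid
parafoveal shapes (the foveal edge moves farther than the peripheral
edge). Counts are sums over binary masks (pixel-center-in-polygon on a
local lattice offset half a pixel from the shape centroid): RF counts sum
D_gcrf(e, meridian)·h² over the undisplaced 72-gon; body counts sum
density·J(e)·h² over the displaced polygon. The 72-gon is used on both
sides so its 0.13% area deficit cancels. The default mask pitch is the
0.008° used for histology-scale analysis; because binary-mask count error
scales with the inverse of the stimulus radius in pixels,
`auto_resolution` refines the pitch for small stimuli so every radius
spans ≥ ~27 px (G-I 0.002°, G-II 0.004°, G-III–V unchanged). With that
rule, Method-2 counts match expected RF counts within 0.7% at every 10-2
location and size on both synthetic maps. At the coarser 0.0391°
structural-map pitch, counts for sizes ≤ II are dominated by mask
digitization (a G-II disk is ~5.5 px across) and are not reliable
per-location; summaries over rings remain usable.

Densities in summaries are count divided by the undisplaced stimulus'
planar solid area; locations are grouped by eccentricity rounded to two
decimals; SDs are across locations within a ring (ddof = 1).

## OCT processing

Thickness rasters live on a degree field of view (reference 768×768,
30°×30°, 0.0391°/px) with the fovea at a stated pixel. Construction from
scattered B-scan samples uses a thin-plate-spline RBF interpolant with
mild smoothing and an anisotropy knob (default 10:1) that stretches the
kernel across the B-scan axis — any smooth scattered-data interpolant
would do; the fixture round-trip (RMSE < 1 µm on a ridge profile) pins
the behavior, not the basis. Pixels outside the sampled bounding box are
zero-padded and flagged invalid. The fovea is located by normalized
cross-correlation with a Gaussian-pit template (σ = 1°); NCC < 0.2 flags
low confidence (a warning, not a failure).

Magnification correction re-grids the degree raster onto retinal-mm
coordinates through the subject's eye (bilinear sampling along preserved
meridians). The thickness-to-density conversion divides the histology
density raster point-by-point by a fovea-aligned cohort-mean GCL
thickness map (masked below 5 µm for division stability) to get RGC/mm³,
then multiplies by an individual's thickness map; the histology density
is rescaled by (r₀/r)² and its coordinates by r/r₀ for the subject's AL.
A subject whose thickness equals the cohort mean at the canonical AL
recovers the histology density exactly (tested to machine precision).

The GCL-peak ellipse: 36 radial profiles from the fovea (0.3–3 mm,
half-pixel sampling, 0.08 mm Gaussian smoothing), each peak refined by
parabolic interpolation and rejected if it sits at the search-window
edge; an algebraic least-squares ellipse through the peaks (≥5 required)
gives semi-axes in mm. The scaling analysis regresses each axis on AL
(OLS) and compares, by mean absolute residual, against the geometric
prediction = regression value at AL₀ × AL/AL₀.

## Synthetic data: what it does and does not show

Two generators define the test conditions.

*Self-consistent density maps* invert the displacement construction:
given per-meridian E_2v and a prescribed displacement profile
ψ(e) = e + d₀(1−(e/e_DZ)²)² (d₀ = 2° by default; value and slope
continuous at the zone edge; monotone for d₀ < e_DZ/1.54), the body
density is defined by C_gcb(ψ(e)) = C_gcrf(e). Fitting recovers E_2v to
0.01% and the displacement to <0.02°, and the central retina is left
body-free, as after real Henle-fiber displacement. The quartic profile is
broader at mid-eccentricities than the histology-fitted displacement, so
Method-1's outer-ring overestimation on this fixture (~40%) is larger
than the ~9% seen with real histology; the sign pattern is what the
fixture is for.

*Generic synthetic density maps* are gamma-profile ridges
(ρ/β)^α·e^(−ρ/β), α = 2, peak 30,000 cells/mm² at 1 mm, with a
first-harmonic meridional modulation (default ±20%, maximum nasally) —
the qualitative structure (foveal trough, single parafoveal ridge, decay,
asymmetry) of the real map, with a closed-form wedge integral for
oracle tests. They are noise-free by design: the displacement fit assumes
smooth maps.

*Thickness cohorts* place an elliptical Gaussian GCL ridge (semi-axes
2.0×1.6 mm at AL₀, height 40 µm over a 10 µm base, multiplicative foveal
pit of σ = 0.35 mm) whose axes scale with AL/AL₀, evaluated through each
eye's own degree raster, with seeded additive Gaussian thickness noise
and optional axis jitter. AL is uniform on 21–27 mm, cohort size 28,
matching a young-healthy macular dataset. None of the generators emulate
OCT speckle, vessel shadows, segmentation failures, or disease; passing
tests demonstrate the correctness and internal consistency of the
machinery, not robustness to real-data artifacts.

Test and acceptance runs use reduced problem sizes chosen for CI
friendliness (96–192 px rasters, 10–50-eye cohorts, 36–90 meridians);
all are parameters, and defaults match the reference geometry.

## Known limitations

* The anterior-optics table is a reconstruction of the wide-angle eye
  family, validated against its published foveal conversion, not a
  transcription of the original table; absolute mm positions inherit its
  ~2% uncertainty. The displacement model itself is insensitive to this
  (both sides of the count match use the same mapping).
* k(e) is a constant by default; any eccentricity dependence can be
  supplied but none ships.
* Only spherical retinas / global expansion; no equatorial-stretch or
  elliptical growth variants, no age correction of thickness, no
  displaced-amacrine correction or midget/parasol splits.
* Left eyes are handled by mirroring into right-eye retinal coordinates
  (meridian 0° temporal, counter-clockwise for OD) at input boundaries.
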