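# Methods

## Model and assumptions

A camera at height *h* above a planar seabed observes two parallel
laser stripes projected by line lasers mounted rigidly to the vehicle
frame at ground separation *l = l₁ + l₂* (the optical-axis ground
track lies between them at distances *l₁*, *l₂* when the camera is
aligned). The camera may be pitched down by a tilt λ and rotated by a
pan γ relative to the laser direction. The estimators assume:

* negligible optical distortion and an uncropped frame whose center
  coincides with the optical center;
* known horizontal and vertical angles of view α_H, α_V (at the zoom
  used for the still);
* exactly parallel laser lines;
* zero camera roll — the model never includes roll, and the
  annotation layer works with horizontal reference rows throughout;
* a locally planar seabed. A uniform slope α along the laser
  direction is *not* a violation: it is absorbed into an apparent tilt
  λ = λ0 + α, every ground quantity is then measured in the inclined
  plane, and the slope itself is recoverable as λ − λ0 given the true
  tilt λ0 from an attitude sensor.

## Geometry and conventions

Raster coordinates are real-valued with the origin at the top-left
corner, *u* rightward, *v* downward, image center at (N/2, M/2), and
the center of pixel (row j, col i) at (i+0.5, j+0.5). The ground
frame has the lateral axis *x* rightward, the axial axis *y* along the
laser lines away from the camera, and the normal *z* up; the
world-to-camera rotation is pan about the plane normal followed by
tilt about the camera's horizontal axis. With this composition the
projections of the two laser lines intersect at the vanishing point

* vertical offset above center: (M/2)·tanλ / tan(α_V/2),
* horizontal offset: −(N/2)·tanγ / (tan(α_H/2)·cosλ),

so a downward tilt moves the vanishing point up and a pan to the right
moves it *left* of center (the world-fixed laser direction shifts
opposite to the camera's rotation). Both relations are exact, as are
their inverses (the tilt/pan estimators).

Two measurement-protocol details matter and are frozen here:

* **m0 is the height of the near reference row above the *bottom*
  image edge** (equivalently M − v_raster). This is the unique reading
  under which the tilt estimator inverts the projection exactly; it
  corresponds to measuring the row's position on the image's z-up
  physical axis rather than in raster row indices.
* **n1, n2, m may be measured at any row below the vanishing point**:
  only the slopes n1/m, n2/m enter the estimates (m-invariance, tested
  to machine precision). The annotation extractor uses the near
  reference row — the largest available lever arm — but externally
  supplied triples are accepted unchanged, and the uncertainty
  magnitudes inherit whatever row the triple was measured at.

## What the length and area mean under pan

A raster row back-projects to a ground line making angle −γ with the
lateral axis (exactly, not to first order). The length estimator
returns the *perpendicular* ground separation L of the two row traces;
the area S = L·l is the area of the strip of width l cut
perpendicular to the laser lines between the two traces. The
parallelogram inscribed by the two laser lines and the two row traces
has area S/cosγ; at survey pans (|γ| ≤ 3.5°) the two differ by less
than 0.2%, far below the measurement uncertainty, but the distinction
is kept exact in the forward model so that round-trip tests are
meaningful. The camera-height estimator h = (cosλ/cosγ)·l/(cotθ₁+cotθ₂)
is likewise the exact inverse of the projection; its γ-dependence is a
0.03% correction at the reference example's γ ≈ −1°.

## Uncertainties

All propagated uncertainties are *maximal* errors: absolute-value sums
of first-order contributions, not statistical quadratures. Defaults:
one pixel of error per measured pixel quantity (the floor for manual
annotation of an uncompressed still; configurable via
`pixel_error_px`) and Δl = 0.5 cm for the laser-separation calibration
(typical of hand-calibrated rigs; configurable on `LaserRig`). The
closed forms imply two structural facts covered by tests: ΔS/S − ΔL/L
= Δl/l identically, and every relative uncertainty shrinks
monotonically as resolution grows, which quantifies how coarse-graining
degrades the estimates. A finite-difference evaluation of the same
absolute-sum rule over (n′, n″, cosγ, cosλ, l) agrees with the closed
form for L to first order and serves as an independent cross-check in
the test suite.

## Synthetic data

`laserline.forward` is an exact pinhole renderer of the rig used both
as the test oracle and as the fixture generator. Default study
conditions mirror the reference deployment: a 1280×800 frame with
α_H = 50.43°, α_V = 29.67°, l = 67 cm (offsets ~33/34 cm), heights
80–160 cm, tilts 10–30°, pans within ±5° for "paper-like" sampling;
the generic round-trip sweep widens this to tilts 2–45°, pans ±20°,
heights 50–400 cm. Reference rows default to 0.92·M (near) and the
larger of 0.45·M and a point 0.12·M below the vanishing point (far).
Quantization rounds all seven pixel quantities to whole pixels with
seeded dithering of exact halves, emulating integer-pixel manual
annotation.

Synthetic stills draw the two projected lines with a Gaussian
cross-section (default width 2.5 px) in saturated green over flat,
gradient or seeded-speckle backgrounds. What the renderer does *not*
emulate: water-column attenuation and scattering, laser speckle and
intensity falloff with range, line bending over rough microtopography,
compression artifacts, and non-parallel lasers. Passing detection
tests therefore demonstrate the correctness of the extraction and
estimation pipeline on clean imagery, not robustness to turbid or
daylight-flooded footage.

## Detection

The extractor scores green excess G − (R+B)/2 normalised to the image
peak, thresholds at 0.25, clusters each row's surviving columns with
an 8 px gap criterion, keeps rows with exactly two clusters (requiring
at least half of the signal-bearing rows), takes intensity-weighted
centroids, and fits each line by iteratively reweighted least squares
discarding residuals beyond 2.5 median absolute deviations. Centroid
+ robust fit was chosen over transform-based line finders for
sub-pixel accuracy without accumulator tuning; all constants are
surfaced in `DetectionParams`. Rows above the vanishing point (where
the two stripes could merge or swap sides) are naturally excluded by
the two-cluster requirement and the robust fit.

## Numerical choices and degenerate inputs

* Angles are degrees at every interface and radians internally;
  lengths cm, areas cm².
* Coincident reference rows (n′ = n″ exactly) return the well-defined
  limit L = 0; separations below half a pixel are refused because the
  relative uncertainty diverges; a far row wider than the near row is
  refused as an annotation error.
* Annotated lines parallel to within 10⁻¹² rad put the vanishing point
  at infinity; the pipeline then falls back to the level-camera closed
  forms (zero tilt and pan).
* n0 — and, under strong pan, n1 — may be negative: a line's
  extrapolated raster coordinate can fall outside the image. Only
  n1 + n2 > 0 is required.
* The grid overlay exploits two exact facts: image slopes of
  laser-parallel ground lines vary linearly with ground offset, and
  the reciprocal of the line separation at a row grows linearly with
  perpendicular ground distance, so equal-area grid rows follow from
  inverting the length equation in closed form.

## Problem sizes

The validation example is a single closed-form evaluation
(microseconds). The statistical acceptance checks use 1000 random
scenes for the exact round-trip and quantization sweeps and 200
rendered 1280×800 stills for the detection pipeline; these sizes give
binomial 90%-coverage assertions comfortable margins while keeping the
default test run under a minute.

## Known limitations

* No lens-distortion or crop handling: the estimators consume
  distortion-free angles of view by assumption.
* One image in, one estimate out; batch processing is a thin loop over
  stills, with no cross-frame filtering or averaging.
* Height is the most alignment-sensitive output (it depends on the
  individual line slopes, not just their ratio of separations); field
  experience with imperfectly parallel lasers shows height errors of
  order 10% where area errors stay near 1–2%.
* The five-spot/ABISS style of camera-mounted laser scaling is a
  different method and is out of scope.
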