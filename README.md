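# laserline

Photogrammetric scaling of oblique seafloor imagery from two parallel
laser lines.

## The problem

Quantitative benthic surveys — counting organisms, litter or geologic
features per unit seafloor area — need the ground area covered by each
video still. ROV and towed cameras view the seabed obliquely, move
constantly, and pan/tilt independently of the vehicle, so the classic
solutions (nadir camera + scale bar, camera-mounted laser spots, an
altimeter-calibrated footprint) often do not apply.

An alternative rig mounts two line lasers rigidly on the *vehicle
frame* (not on the camera), projecting two parallel stripes on the
seabed at a known separation *l*. A single oblique still containing
both stripes then carries enough information to recover, from pixel
measurements alone:

* the camera's tilt λ and pan γ relative to the laser direction,
* the ground length *L* between any two reference image rows and the
  area *S = L·l* of the laser-delimited strip between them,
* the camera's height *h* above the seabed,
* the seabed slope, when the true camera tilt is known from an
  attitude sensor,
* maximal (absolute-sum) first-order uncertainties for all of these.

The only calibration inputs are the laser separation *l* (± Δl) and
the camera's horizontal/vertical angles of view α_H, α_V.

## The estimators

With image width *N* and height *M* in pixels, and the seven pixel
measurements *n′, n″, n0, n1, n2, m0, m* (laser-line separations at the
near/far reference rows, the left line's position and the near row's
height above the bottom edge, and the line slopes relative to the
vanishing point — see `ImageMeasurements`):

```
tan λ = [m0/M − 1/2 + (n′/(n1+n2))·(m/M)] · 2 tan(α_V/2)
tan γ = [1/2 − n0/N − (n1/(n1+n2))·(n′/N)] · 2 tan(α_H/2) · cos λ
L     = (n′/n″ − 1) · (N/n′) · l / (2 tan(α_H/2) · cos λ · cos γ)
S     = L · l
cot θᵢ = (nᵢ/N)·(M/m)·tan(α_H/2)/tan(α_V/2)          (i = 1, 2)
h     = (cos λ / cos γ) · l / (cot θ₁ + cot θ₂)
slope = λ − λ0
```

Each estimator is an exact inverse of the pinhole projection of the
rig (the package ships that projection as `laserline.forward`, used as
the test oracle). The uncertainty module propagates one-pixel
measurement errors and the separation calibration error Δl as maximal
absolute sums, e.g. `ΔL/L = (n″/n′ + n′/n″)/(n′−n″) + Δcosγ/cosγ +
Δcosλ/cosλ + Δl/l`.

## Worked example

The package's reference example is a deep-sea validation still
(1280×800 px, α_H = 50.43°, α_V = 29.67°, l = 67 ± 0.5 cm) with
measured pixel quantities n′ = 312, n″ = 232, n0 = 465, n1 = 52,
n2 = 29, m0 = 367, m = 143:

```python
import laserline as ll

cam = ll.CameraIntrinsics(alpha_h_deg=50.43, alpha_v_deg=29.67,
                          width_px=1280, height_px=800)
rig = ll.LaserRig(separation_cm=67.0, separation_sigma_cm=0.5)
meas = ll.ImageMeasurements(n_prime=312, n_dprime=232, n0=465,
                            n1=52, n2=29, m0=367, m=143)
rep = ll.measure(meas, cam, rig)
print(f"tilt {rep.pose.tilt_deg:.2f} deg, pan {rep.pose.pan_deg:.2f} deg")
print(f"L = {rep.ground.length_cm:.1f} +- {rep.ground.delta_length_cm:.1f} cm")
print(f"S = {rep.ground.area_cm2:.0f} +- {rep.ground.delta_area_cm2:.0f} cm2")
print(f"h = {rep.ground.height_cm:.1f} +- {rep.ground.delta_height_cm:.1f} cm")
```

prints

```
tilt 18.93 deg, pan -1.01 deg
L = 106.4 +- 5.5 cm
S = 7130 +- 425 cm2
h = 100.7 +- 5.8 cm
```

i.e. the camera was pitched ~19° down and panned ~1° left of the laser
direction; the strip between the two reference rows spans 106.4 cm of
seafloor (~0.71 m² between the lasers) and the camera hovered ~1 m
above the bottom. For that dive the reference object on the seafloor
spanned L_exp = 108 ± 3 cm (S_exp = 7236 ± 255 cm²) at a surveyed
camera height of 113 ± 1 cm: the area estimate lands within 1.5%, the
height within 11%.

The same pipeline is scriptable from the shell:

```
laserline measure --config rig.yaml --measurements still042.json
laserline simulate --scene scene.yaml --out-dir fixtures/ --image
laserline detect  --config rig.yaml --image still042.png
laserline grid    --config rig.yaml --measurements still042.json \
                  --lateral-spacing 67 --axial-spacing 50
```

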