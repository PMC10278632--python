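# Methods

This note records the physical models, the numerical choices and the
limits of validity behind `sfdi-forge`. Units are mm and mm⁻¹
throughout; one spectral channel is simulated (scalar intensity per
pixel).

## Material model

A turbid medium is described by `OpticalProperties(mu_a, mu_s, g, n)`.
Scattering anisotropy defaults to g = 0.8, representative of upper-GI
tissue, and the refractive index to n = 1.4; both are free parameters.
The reduced scattering coefficient μs′ = μs (1 − g) is the quantity the
imaging pipeline recovers, and `from_reduced` constructs media from it
consistently. Built-in tissue values (635 nm, mm⁻¹):

| tissue                    | μa    | μs′  |
|---------------------------|-------|------|
| healthy oesophageal       | 0.058 | 0.75 |
| squamous cell carcinoma   | 0.12  | 0.64 |
| Barrett's (mild inflam.)  | 0.057 | 0.51 |
| calibration reference     | 0.217 | 5.94 |
| tube wall                 | 0.076 | 2.99 |

## Photon transport (module `transport`)

A weighted-photon Monte-Carlo kernel with implicit capture (the weight
is multiplied by the single-scattering albedo at each interaction, the
absorbed fraction deposited), Henyey–Greenstein deflection sampled by
the closed-form inverse CDF, partial Fresnel escape at index-mismatched
boundaries (the escaping fraction is scored, the rest reflected), and
Russian roulette below 10⁻⁴ of the launch weight with survival
probability 0.1. The event cap per photon is 1024; halving it changes
half-space reflectance by well under the Monte-Carlo noise at the media
considered here. Energy bookkeeping is exact by construction: specular
+ diffuse + transmitted + absorbed + roulette residual + truncated
weight sums to the launched weight to ~1e−12, and runs are
bit-reproducible per (seed, config, properties).

The radial point response R(ρ) is binned to 15 transport mean free
paths by default; `hankel_rd` turns it into Rd(fx) by a zeroth-order
Hankel transform (midpoint quadrature, J₀ weights) and warns when more
than 1% of the escaped weight lies beyond the last bin. The
semi-infinite criterion treats a slab as effectively semi-infinite when
diffuse transmittance is at most 1% of diffuse reflectance (the
boundary value counts as satisfying it); for (μa = 0.1, μs′ = 1.0) the
criterion is met between 10 and 15 transport mean free paths.

## Diffusion forward model (module `optics`)

The spatial-frequency-domain diffusion solution for a semi-infinite
medium uses the boundary constant A = (1 − R_eff)/(2(1 + R_eff)) with
the Groenhuis polynomial R_eff = 0.0636 n + 0.668 + 0.710/n − 1.440/n².
Against the transport kernel it is 3–8% too reflective at
grid-interior properties (documented cross-check tolerances: 10% at
fx = 0, 15% across the look-up-table interior) — the familiar
near-source bias of the diffusion approximation, and the reason the
empirically derived look-up table exists. At fx > 0 the solution is
non-monotonic in μa below μs′ ≈ 0.6 (transport length comparable to
the modulation period); `build_model_lut` warns when a requested grid
enters that fold.

## Double integrating sphere (module `dis`)

The slab response comes from the transport kernel; sphere multiple
reflections are applied as the analytic integrating-sphere gain
ρw/(1 − ρw(1 − f_ports)) by default, with a stochastic cavity-bounce
mode for validation. Since MR and MT are normalised quantities the
gain cancels exactly; the baffle excludes specular sample returns, so
MR equals the slab's diffuse reflectance and MT its total
transmittance. Defaults mirror a standard bench: 100 mm spheres, wall
reflectance 0.99, 10 mm square ports, 1 mm sample, 0.7 reflectance
standard, plus a small stray-light floor (0.2% of source power) so the
empty-port and blocked-beam channels are non-trivial.

`invert_slab` matches (MR, MT) against smoothing-spline surfaces built
from seeded transport runs on a 14×14 log-spaced grid over
μa 0.01–0.45, μs′ 0.3–8.5 (8000 photons per node, roulette at 10⁻³),
seeded by a coarse grid search and refined by bounded least squares in
(log μa, log μs′). Round-trip accuracy is ~2% at 2×10⁵-photon forward
measurements and within 10% across the nine-material characterisation
span at 5×10⁴ photons; residuals above 10% of the measurement raise an
error that reports the forward-surface corners. An adding-doubling
forward model was deliberately not written: the Monte-Carlo surface
reuses the already-validated kernel instead of introducing a second
radiative-transfer implementation that would itself need an oracle.

## Renderer (module `render`)

Fast mode treats each pixel's neighbourhood as a locally planar
semi-infinite medium: per-pixel radiance is incident irradiance
(point projector, inverse-square × cosine, optional sampled-occlusion
shadows) times the diffuse response, with the DC component of the
pattern reflecting at Rd(0) and the AC component at the locally
realised projected frequency (the pattern coordinate is the projector
ray continued to the reference plane; its gradient along the surface
arc gives fx_local). This is exactly the physics the SFDI inversion
assumes, so forward + inverse are self-consistent by design — passing
closed-loop tests shows the pipeline's algebra and geometry are right,
not that the locally planar approximation holds on steep slopes (it
demonstrably degrades beyond ~60°).

The camera is a pinhole above the reference plane; pixel (0,0) is
top-left, x right, y down; the default planar bench is a 5 W projector
35 mm from the camera at 500 mm height (a 4° offset). Exposure follows
I_out = I_render · 2^t; auto-exposure picks t so the mean rendered
intensity sits mid-range, and the three phases of a stack share one
exposure. Monte-Carlo mode launches photons with entry positions
importance-sampled from the incident pattern and scores escape
positions into pixels; it supports homogeneous planar scenes (its role
is to be the statistical oracle for fast mode, and it agrees with it
to within the Monte-Carlo/diffusion cross-model gap). The roulette
threshold scales with the launch weight — with absolute thresholds the
tiny per-photon powers would trigger permanent roulette and a
heavy-tailed estimator.

Profile correction: `illumination_gain` converts a *per-pixel* height
map — what profilometry returns — into the illumination gain relative
to the flat reference plane, and `local_frequency` into the realised
projected frequency; dividing measured modulation by the gain and
re-inverting with the frequency correction (one refinement pass seeded
by the uncorrected inversion) is the standard profile-corrected SFDI
chain used by the spheroid recipe.

## Inverse pipeline (module `sfdi`)

Three-phase demodulation uses the exact equispaced-phase identities;
calibration multiplies the sample/reference modulation ratio by the
diffusion-model reflectance of the reference material per component.
The model LUT places (Rd_DC, Rd_AC) nodes on a log-spaced 30×30 grid
over μa 0.001–0.3, μs′ 0.1–8.5 (spacing is configurable); queries use
piecewise-cubic (Clough–Tocher) interpolation inside the node hull and
fall back to the nearest node outside, recording the affected pixels
in `oob_mask` — nearest-neighbour fallback is deliberately robust for
out-of-hull points and the mask is reported, never silently smoothed.

The empirical LUT lifts nine measured (DC, AC) points on a 3×3
property lattice to a 100×100 table by bilinear interpolation over the
lattice, linearly continued half a cell beyond each edge (the simplest
scheme consistent with a first linear extrapolation); the dense grid
snaps its nearest grid lines onto the exact lattice values so the
table reproduces its own calibration points, and queries interpolate
cubically in (DC, AC) space. Region statistics use medians throughout
(robust to interface spikes and to the quantised out-of-hull fallback).

## Profilometry (module `profilometry`)

The three-step estimator is the complex sum Σ I_k e^(−iφ_k), exact for
equispaced phases; pixels with negligible modulation are masked.
Unwrapping uses the quality-guided reliability-sorting algorithm from
scikit-image, with the global 2π branch pinned at a reference pixel,
and phase differences are formed on the wrapped principal branch
before unwrapping so common ramps cancel. Height follows
h = l0 Δφ/(Δφ − 2π f0 d) with near-singular denominators masked; the
sign convention (height toward the camera positive) is fixed by the
flat-plate oracle, which recovers a 10 mm plate to 0.002% and the
40 mm spheroid apex to 0.01% at default geometry (l0 = 500, d = 35,
f0 = 0.1 — f0 is a free design parameter). The mapping is not applied
to tube scenes: its geometric assumptions are planar.

## Tubular lumen (module `tube`)

Default geometry: 250 mm tube, 20 mm bore, 80 mm outer diameter,
camera 110 mm and projector 100 mm above the opening, end cap of wall
material. The pre-distorted pattern assigns each projector direction
the sinusoid value of the wall point it hits (z = a/ρ − s_p), which is
the analytic limit of the unwrap-texture-rewrap construction; a
Nyquist check rejects frequencies unresolvable at the distal end and
reports the maximum admissible one. Wall irradiance is a/r³ from the
on-axis projector — a ~40× falloff over the tube — and the camera
image is polar-unrolled to wall coordinates (z, azimuth) through the
exact inverse of the projection.

Two resolution choices matter and are stated here as design defaults:
tube renders use a 1024² camera because at 256² the distal rings alias
(≈1 px per period — a genuine design constraint of forward-viewing
tube SFDI at fx_wall = 0.1), and sectioning reduces the wall to 10
candidate rings of 25 mm before applying the greedy >10-count rule
(8-bit-normalised DC intensity; a ring opens a new section when its
mean deviates >10 counts from the running section mean). With the
default tube this yields exactly five sections, [0, 25, 50, 75, 100,
250] mm; a uniform image yields one.

Per-section empirical LUTs are built from renders of the nine
calibration materials (per-section median modulation as nodes); the
global LUT uses whole-wall medians. Recovery is per-pixel with the
pixel's own section's LUT. The within-section illumination spread is
the method's intrinsic error floor: in (DC, AC) space an illumination
gain moves a pixel radially, and near the corners of the calibration
hull that direction runs almost tangent to the response surface, so
hull-corner materials invert with several-fold larger per-section
errors than mid-grid ones (the distal 150 mm section, with a ~5×
internal spread, is worst). Sectioned recovery still beats the global
LUT by more than an order of magnitude on the same metric; adding
sections, or measuring the per-pixel gain explicitly, would shrink the
floor further.

## Synthetic data: what it does and does not show

The phantom generator reproduces the study conditions exactly — flat
and spheroid geometries, the two-half Barrett's sample, the 3×3
calibration lattice over μa 0.08–0.22 / μs′ 1.4–6.5, and the tube —
with noiseless, perfectly co-registered renders. Real acquisitions add
shot noise, projector/camera nonlinearity, defocus, speckle and
sub-surface volume effects at property boundaries; passing tests here
certify the algorithms and their geometry, not robustness to those
effects. The one deliberately modelled artefact class is geometric:
shading, shadowing, obliquity and the tube's illumination falloff, all
of which the inverse pipeline must (and does) correct or absorb.

## Problem sizes

Defaults were chosen so the full test suite runs in about two minutes
and the headline-experiment script in well under one: planar scenes at
256², calibration imaging at 128², tube renders at 1024² with a
120×90 wall map, 10⁵–3×10⁵ photons for transport cross-checks, and a
14×14 × 8000-photon grid for the slab-inversion surfaces. All are
parameters, not constants.
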