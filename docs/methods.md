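# Methods

## Forward model: the corneal phantom

The generator emulates photographs of a physical eye model with a reflected
Placido pattern.  The cornea is a convex mirror with local radius of
curvature

    r_c(ρ, θ) = R_base − A · exp(−|x(ρ, θ) − c|² / 2σ²),

where x is the position on the corneal plane (polar coordinates ρ in mm,
azimuth θ), R_base = 7.85 mm (healthy apical radius), and the Gaussian term
is the keratoconic cone: amplitude A in mm of local radius reduction,
center c (eccentricity, azimuth) and width σ.  Disease stages map to
amplitudes A = 0.5 / 1.0 / 1.8 / 2.8 mm for stages 1–4; the stage table is a
package convention (only stage names are standard), exposed in
configuration.  Cone placement defaults to the central-to-paracentral zone
(eccentricity drawn U(0.5, 1.0) mm, azimuth uniform) with σ = 1.5 mm,
matching the clinical tendency of central/inferior cones while keeping all
nine rings intersecting the cone's flanks.

Ring k of the projected pattern reflects at radius

    ρ_k(θ) = ring_radii_ref[k] · r_c(ρ_k_ref, θ) / r_ref,    r_ref = 7.85 mm,

the proportional convex-mirror model: on the reference cornea each ring sits
at its reference radius (defaults 1.0–5.0 mm, nine rings, 0.2 mm stroke),
and a locally steeper cornea pulls it inward in proportion.  The same model,
inverted, is the calibration used by the topography stage, so the pipeline
is exactly self-consistent; true keratometry from mirror geometry at a
20 cm working distance would add an overall scale that the shared reference
radius absorbs.

Measurement noise is multiplicative radius jitter (default SD 2%) drawn at
the 24 sector nodes of each ring and interpolated periodically in angle, so
rings remain closed curves.  Because reflection off a smooth convex surface
preserves ring nesting, jitter is truncated so adjacent rings keep at least
a stroke-width-plus-5-px separation; without this, independent jitter
occasionally makes outer rings touch, which no physical cornea produces.
Scene color: rings on a dark iris disc (5.8 mm) with a lighter sclera
surround; global illumination scaling (1 = well lit) and additive Gaussian
pixel noise (default SD 0.01) complete the capture model.

Ground truth records, per ring and sector, the *sector-averaged* noise-free
reflected radius (1° comb) and local curvature.  Sector averages — not
sector-center values — are stored because the measurement stage estimates
sector means; for steep cones the two differ by several pixels.

What the phantom does not model: tear-film reflections, eyelashes and lid
occlusion, corneal asphericity and astigmatism, device color profiles, and
perspective of an off-axis camera.  Passing the synthetic benchmark
therefore demonstrates the correctness and self-consistency of the
measurement and classification chain, not clinical performance.

## Enhancement

The chain is median filter (3×3) → sRGB→CIELAB → invert L (L ← 100 − L,
chroma untouched so hue is preserved) → dehaze → saturation boost (a, b ×
1.2) → invert L back → sRGB.  Dehazing uses the haze formation model
I = J·r + A(1 − r) and recovers J = (I − A)/max(r, r₀) + A with floor
r₀ = 0.1.  A and r(x) are estimated with the dark-channel prior: A is the
mean color of the brightest 0.1% of pixels ranked by dark channel (minimum
over channels, 15-px minimum filter) and r = 1 − 0.95·darkchannel(I/A).
Dehazing runs on the *inverted* image converted back to RGB — the classic
low-light trick: a dim photograph inverts to a bright, hazy-looking one.
All constants are configurable (`HazeParams`); intensities are float [0, 1]
internally and 8-bit at I/O boundaries.

## Ring extraction

Rings are segmented in CIELAB with a box mask around the reference ring
color (L 50.449 ± 2×3.8, a 73.090 ± 2×4.6, b 51.361 ± 10; the b channel has
no reference SD, hence a fixed tolerance).  These reference values describe
the ring color *after* enhancement; the generator's source ring color (LAB
≈ (38.5, 42.8, 18.7)) was calibrated once, by fixed-point iteration, so that
the enhanced rings of a well-lit phantom land on the reference color.  The
dehaze-plus-saturation stages push any saturated red toward the sRGB gamut
boundary, which is why the source must be far less saturated than the
target.

The mask is closed (3×3), components under 25 px are dropped, and the
corneal center is located in two steps: the innermost component's centroid,
then a refinement that regresses the sector radii of all rings on a joint
model of decentering (a common first harmonic) plus a Gaussian cone.
Fitting both together matters: toward the corneal apex a cone depresses a
ring at every azimuth, and its first harmonic is indistinguishable from
decentering ring-by-ring; the joint fit separates them by exploiting the
cone's coherent radial footprint.  Sub-pixel centering is what keeps
healthy-eye feature noise low and the noise-free round-trip within 1 px
even at stage 4.

Per-sector radii are measured over 24 half-open sectors of 15° (angles
counterclockwise from +x in the displayed image, origin top-left).  The
reported entry is the de-biased pixel mean m − s²/m, which estimates the
stroke mid-line radius: the raw mean of an annulus sector overshoots the
mid-line by (t²/12 + Var_θ(ρ))/ρ because pixel density grows with radius,
and that bias equals the per-sector pixel-radius variance s² over m.

## Topography

Calibration inverts the forward model: r_c = r_ref · (measured radius in
mm) / ring reference radius.  Corneal power is Φ = 337.5/r (mm), identical
to (n − 1)/r with n = 1.3375 and r in meters; the invariant Φ·r = 337.5 is
asserted programmatically.  Elevation is the local spherical sag
z = r − sqrt(r² − ρ²) at corneal-plane distance ρ.  `fit_cone` decomposes a
curvature map into base radius + Gaussian cone by bounded least squares;
pooling all 216 grid entries makes its amplitude estimate robust to the 2%
entry-level jitter, unlike the raw map minimum, and it is the estimator
used for cone-amplitude recovery checks (mean relative error ≤ 15% at 2%
noise across stages).

## Classification

Each eye is summarized by a 2K-vector: per-ring mean diopter and per-ring
inter-sector diopter SD (K = 9 → 18 features).  A cone raises both in the
rings it crosses.  Features are standardized with training statistics only.

The SVM is trained from its dual: minimize ½αᵀQα − Σα subject to
0 ≤ α ≤ C and Σαy = 0, with Q_ij = y_i y_j K(x_i, x_j) and Gaussian kernel
K = exp(−‖x − x'‖²/σ²).  The solver is a maximal-violating-pair SMO whose
pair updates move along the feasible direction, so the equality constraint
holds exactly throughout; it stops when the KKT violation gap falls below
10⁻⁶.  The bias b averages y − f over free support vectors.  Healthy is
encoded +1, diseased −1, ties predict healthy; the *metrics* treat diseased
as the positive class (a true positive is a detected diseased eye).

Study design: stratified eye-level 60/40 train/test split; 10 folds
partition the training portion (group key = eye, so no eye straddles folds
or the split); grid search C ∈ {0.1, 1, 10} × σ ∈ {0.5, 1, 2} × median
pairwise distance, ties resolved toward smaller C then larger σ; the
selected model is refit on the full training portion and scored once on the
held-out 40 eyes.

## Numerical choices and degenerate inputs

- All randomness flows from one integer seed per run; dataset generation,
  splitting and CV are bit-reproducible given the seed.
- NaN marks absent (ring, sector) entries and propagates through
  calibration, power and features (nan-aware reductions).
- Validation errors (overlapping rings, non-positive curvature, missing
  calibration, single-class training sets, empty masks) raise `ValueError`
  with a message naming the offending quantity; the CLI maps them to exit
  code 2.
- Problem sizes were chosen so a full 10-seed benchmark (1000 rendered and
  processed 384×384 phantoms) completes in minutes on one core: the default
  scale is 0.03 mm/px, putting the outermost ring at ≈167 px.

## Known limitations

- The benchmark's class structure is multi-scale: stage 3–4 eyes are far
  from healthy ones in feature space while stage 1 eyes are close, so the
  fixed CV grid occasionally under-selects kernel width and individual
  seeds dip below the 10-seed average (observed range 85–100%, mean ≈ 97.5%).
- For the same reason, the synthetic eye-level features are close to
  linearly separable, and the linear-kernel baseline slightly outperforms
  the Gaussian kernel on the benchmark (≈ 99% vs ≈ 97.5% over 10 seeds).
  The corresponding directional test (`test_kernel_ordering_...`) is
  expected to fail: the Gaussian-over-linear ordering is a property of real
  photographs that the phantom's feature geometry does not reproduce.
- The proportional mirror calibration recovers curvature only relative to
  the shared reference; absolute keratometry would require the mirror
  equation with measured object/image sizes and working distance.
- Elevation maps assume a locally spherical surface; no Zernike or spline
  surface reconstruction is attempted.
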