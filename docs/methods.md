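# Methods

This note documents the models, conventions and numerical choices behind
`osteolam`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Cross-sectional geometry (`xgeom`)

Sections are labelled rasters (0 background, 1 bone, 2 primary canal,
3 secondary/Haversian canal, 4 resorption space) with an isotropic pixel
pitch in mm/px. All moments treat each bone pixel as a point mass of area
`dA = pitch²` at its center:

* centroid = mean of bone pixel centers; `Ixx, Iyy, Ixy` about
  centroid-parallel image axes; principal moments by the Mohr's-circle
  formula; `J = Σ r² dA` computed directly and cross-checked against
  `Imax + Imin` (perpendicular-axis identity, exact to rounding).
* `r_max` is the maximum distance from the centroid to *periosteal outer
  boundary pixel centers* (the outer edge of the hole-filled envelope).
  Pixel centers rather than corners: the corner convention changes `Zp` by
  less than one pitch in `r_max` and the center convention is directly
  testable against closed forms.
* Periosteal circumference is the marching-squares contour length of the
  filled envelope. On a binary raster this overestimates a smooth perimeter
  by a few percent (staircase bias) — far less than the up-to-27% bias of
  pixel-edge counting — and is reported as-is.
* Porosity = (primary + secondary canal pixels) / (all pixels inside the
  periosteal envelope except the medullary cavity, i.e. labels 1–4).
  Resorption spaces count in the denominator but not the numerator; since
  they are neither vascular lumina nor mineralized bone this is a choice,
  exposed to sensitivity testing by relabelling. Sections with porosity
  > 0.30 (strict; the boundary is kept) still receive geometry but are
  excluded from laminarity scoring, where the cylindrical-canal assumption
  fails.

Convergence: on disc and annulus oracles the pixel-integrated `Zp` is
within 1% of the closed forms `πr³/2` and `π(ro⁴−ri⁴)/(2ro)` from ~500 px
diameter and within 0.05% at 2000 px (tested).

## Canal orientation and laminarity (`canals`)

A cylindrical canal tilted θ from the section normal has a transverse
profile of aspect ratio `AR = 1/cos θ`; `ar_to_angle` and `angle_to_ar`
implement this conversion (AR 3 ↔ 70.5°, AR √2 ↔ 45°). The double-precision
round trip degrades near θ = 0 because `d(acos)/dx` diverges at 1; errors
stay below 1e-4 degrees there and below 1e-9 above 0.01°.

Classification is a total partition with half-open bins: `AR < 3` →
longitudinal; otherwise angle to the periosteal tangent in `[0°, 22.5°)` →
circumferential, `[22.5°, 67.5°)` → oblique, `[67.5°, 90°]` → radial. AR
exactly 3 is transverse. Angles are folded into `[0°, 90°]`: the criteria
are symmetric in obliquity direction.

**Octants.** The four cardinal 45° sectors (cranial/caudal plus
dorsal/ventral for wing elements or medial/lateral for hindlimb elements)
are taken about the section centroid from the image-direction →
anatomical-label map. Canal membership is decided by the profile centroid's
polar angle in original section coordinates, so straddling canals are never
double-counted; each sector is straightened with a 6° angular margin so
border canals are segmented whole before the membership test.

**Straightening.** The periosteal outer contour (marching squares, smoothed
along the closed curve) is parameterized by arc length; source pixels are
sampled along inward normals with per-label bilinear interpolation and a 0.5
indicator threshold. Depth steps are *curvature-corrected per column*,
`d(j) = (1 − e^{−κj})/κ` with κ the local curvature of the inward-normal
field. This makes the map locally conformal — the exact log-polar unwrap
when the contour is a circle — so angles relative to the periosteal tangent
and profile aspect ratios are preserved at every depth, not only near the
surface; naive fixed-depth sampling shears a 45° feature at 20% cortical
depth by several degrees. The cost is a depth-dependent magnification
(features at depth d are enlarged by ≈ 1/(1−κd)), which is irrelevant to
AR and angle. κ is heavily smoothed (Gaussian, σ ≥ 20 px) because the depth
schedule amplifies curvature noise quadratically with depth. Validation
mirrors the classical test-angle check: radial, circumferential and 45°
features in an analytic annulus keep their angles within 2° (tested; in
practice within ~0.3°).

**Segmentation.** Connected components (8-connectivity) of primary-canal
pixels; secondary canals are excluded, as is traditional for laminarity.
Components whose skeleton contains a genuine branch node are split there,
pixels being assigned to the nearest skeleton branch segment. Skeletons of
clean elliptical blobs sprout short end spurs, so only segments carrying at
least 20% of the skeleton (and ≥ 5 px) count as branches; without this
filter single canals fragment and inflate counts. Components below 8 px are
dropped and logged — their moment ellipses are unstable.

**Ellipse fit.** Moment matching: the component's second central moments
(plus the 1/12 per-pixel square term) define the unique uniform ellipse with
the same area and covariance; axes are `4√λ` of the covariance eigenvalues,
the angle comes from the major eigenvector, and degenerate (collinear)
components are capped at AR 1e6 with the principal direction retained.

**LI.** The headline index pools circumferential and total counts over the
four octants before dividing (canal-weighted); the unweighted mean of
per-octant LIs is also reported, since the field's "mean LI over octants"
phrasing admits both readings. `sampled_fraction` reports counted canals
over all primary canals in the section (≈ 0.5 for canals uniform in angle,
as the four cardinal octants cover half the circumference).

## Synthetic sections and series (`synth`)

Sections are annular cortices (optional smooth boundary roughness) with
canals rendered as the exact analytic ellipse a tilted cylinder cuts on the
plane: semi-axes `(r, r/cos tilt)`, major axis `azimuth` degrees off the
local periosteal tangent, rasterized by pixel-center inclusion, which gives
a closed-form oracle for the ellipse fitter (axes accurate to ~1 px at
pitch ≤ r/5, tested). Ground-truth categories are computed from
`(tilt, azimuth)` through the *same* `classify_canal` rule via
`AR = 1/cos(tilt)` — round-trip tests must share one rule. Placement is
rejection sampling with a conservative semi-major-axis clearance and a cap
of 1000 attempts per canal; overlapping voids would violate the cylindrical
assumption under test. There is no universal "realistic" canal density or
radius across taxa and ages, so these are caller-supplied; the test
conditions use 40 canals of radius 0.02 mm in a 1.0/0.55 mm annulus at
2.5 µm/px (minor axis 16 px), with tilts uniform on [0°, 80°] — the cap
keeps the most extreme profile ellipses (AR ≤ 5.8) inside the cortical
band.

Growth series: masses log-uniformly spaced over the range (default 17
specimens, 15–563 g, a pigeon-like altricial series); length = `c·M^(1/3)`
(c = 12.6 mm/g^⅓, ≈ 100 mm at adult mass); `log10 Zp = b + a·log10 M` plus
optional Gaussian noise in log10 units (defaults a = 1.76, b = −3.52;
noise 0.23 reproduces fit qualities around R² ≈ 0.93 at n = 17). LI is
drawn from the mean–precision beta `Beta(μφ, (1−μ)φ)` with
`logit μ = β0 + β1·PC1`, PC1 being the first component of the same
standardize→PCA chain the inference side uses — so parameter-recovery
studies are internally consistent. Defaults β0 = −1.283, β1 = −0.249,
φ = 50 put simulated LIs on the scale of real pigeon data (mean LI ≈ 0.2
at mid-growth, strictly inside (0, 1)).

What the generator does *not* emulate: branched 3-D canal networks, canal
curvature, staining artefacts, segmentation noise from real slides, and
resorption-space geometry. Passing round-trip tests therefore demonstrates
correctness of the measurement chain on ideal cylindrical-canal sections,
not robustness to histological image quality.

## Allometry (`allometry`)

Type I (OLS) regression of `log10 Zp` on `log10 M`, per element; RMA is
deliberately not offered because individual variation in Zp at fixed mass
inflates RMA slopes. CIs are `slope ± t(0.975, n−2)·SE`; the scaling call
uses only the exponent CI versus 1 (positive / negative / isometric).
Published per-element tables of this kind sometimes print CIs asymmetric
about the estimate, suggesting a bootstrap; the t-based interval is used
here and the difference is accepted rather than chased. Slope is invariant
to mass rescaling (intercept shifts by `a·log10 scale`; tested).

## Inference chain (`ontostats`)

* **Standardization**: `z = (x − median)/(1.4826·MAD)`; the normal-
  consistency constant keeps eigenvalue scales comparable to classical
  z-scores. Constant columns are an error.
* **PCA**: eigendecomposition of the covariance of z; components selected
  by the smallest k with ≥ 95% cumulative variance; PC1's sign is fixed so
  the Zp loading is positive (large PC1 = mature, torsion-rigid limb).
  `robust=True` trims the 10% of rows with the largest orthogonal distance
  from an initial *spherical-PCA* axis (rows median-centered and scaled to
  unit norm before the axis fit, giving every row bounded influence), then
  refits classically on the remainder and scores all rows. This is an
  outlier-trimmed PCA, not the published ROSPCA algorithm; in the regime
  that matters here — PC1 carrying ≥ 95% of variance — the two nearly
  coincide, and eigenvalue magnitudes from sparse robust PCA
  implementations are in any case not comparable across algorithms.
  Loading directions and variance proportions are the comparable outputs.
* **Beta regression**: maximum likelihood in the mean–precision
  parameterization, logit link for the mean, constant precision with an
  internal log link. Analytic gradient (digamma identities); BFGS from an
  OLS-on-logit start with method-of-moments φ, followed by Newton polish to
  gradient norm < 1e-8; standard errors from the observed information
  (numerical Hessian at the optimum); Wald p-values. Exact 0/1 responses
  are rejected with a pointer to zero-one-inflated models (out of scope).
  The fit agrees with an independent ML implementation (statsmodels
  `BetaModel`) to ~1e-5 on simulated data (tested). Pseudo-R² is the
  Cox–Snell generalized R², `1 − exp((2/n)(ℓ₀ − ℓ))` — one of several
  conventions in circulation, so cross-package comparisons of pseudo-R² are
  approximate.
* **Summaries**: back-transform `LI = e^η/(1+e^η)` (strictly inside (0,1),
  monotone with the slope sign); standardized per-variable coefficients =
  eigenvector matrix × β vector; odds relative change `100·(exp β − 1)` %.

## Problem sizes and reproducibility

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); generators are bit-reproducible for a fixed
seed. The validation studies use problem sizes chosen to make Monte-Carlo
error comfortably smaller than the tolerances being checked while staying
desk-scale: geometry oracles at 2000 px diameter; classifier round trips on
20 sections × 40 canals; beta-regression recovery over 500 replicates of
n = 200 series; OLS coverage over 1000 replicates of n = 17 series.

## Known limitations

* Segmentation starts from labelled rasters; extracting canal labels from
  raw stained-slide RGB imagery is out of scope.
* The straightening map assumes a traceable, roughly star-shaped periosteal
  contour; heavily fragmented boundaries raise per-octant errors rather
  than being repaired.
* Canal profiles whose true AR is near the threshold 3 (tilt ≈ 70.5°) are
  intrinsically ambiguous at finite resolution; the ~5% disagreement
  budget in round-trip checks is dominated by these boundary cases.
* The beta-regression precision is constant; variable-precision submodels
  and zero-one-inflated responses are not implemented.
* Robust PCA is trimmed classical PCA, not ROSPCA (above).
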