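# osteolam

Cross-sectional geometry, vascular-canal orientation and ontogenetic
inference for avian cortical bone histology.

Limb bones of birds are loaded in torsion during locomotion, and two
microstructural readouts are commonly used to ask whether bone adapts to
that load over growth:

* the **polar section modulus** `Zp = J / r_max` (mm³), a proxy for
  torsional strength computed by pixel integration over a binary bone
  profile, with `J = Σ r² dA` the polar moment of area about the section
  centroid and `r_max` the largest centroid-to-periosteum distance;
* the **laminarity index** `LI ∈ [0, 1]`, the proportion of primary
  vascular canals whose transverse profiles are *circumferential*. A
  cylindrical canal tilted by θ from the section normal cuts the plane in an
  ellipse of aspect ratio `AR = 1/cos θ`; profiles with `AR < 3` are
  longitudinal, and more elongated profiles are circumferential, oblique or
  radial depending on the angle of the major axis to the local periosteal
  tangent (bins 0° ± 22.5°, between, 90° ± 22.5°).

`osteolam` implements the full measurement and inference chain:

1. **`xgeom`** — BoneJ-style slice geometry from labelled rasters
   (area, centroid, second moments, `Imax/Imin`, `J`, `Zp`, porosity,
   periosteal circumference), with the ≤ 30% porosity gate that excludes
   cancellous sections from laminarity scoring.
2. **`canals`** — the laminarity pipeline: the four cardinal anatomical
   octants are extracted, each curved cortical sector is *straightened* with
   an angle-preserving (conformal) unwrap, canal profiles are segmented
   (branched canals split at skeleton nodes; Haversian canals excluded),
   fitted with moment-matched ellipses and classified; LI pools
   circumferential over total counts across the four octants.
3. **`allometry`** — Type I regression of `log10 Zp` on `log10 mass` per
   element, with t-based 95% CIs on the exponent and the isometry call
   (isometry ⇔ a = 1).
4. **`ontostats`** — median/MAD standardization of (mass, length, Zp),
   PCA with the minimum number of components reaching 95% of variance
   (PC1 is the "ontogenetic axis"), maximum-likelihood **beta regression**
   of LI on the scores with a logit link,
   `logit(LI) = β0 + β1·PC1 + …`, back-transform `LI = e^η/(1+e^η)`,
   per-variable standardized coefficients (eigenvectors × β) and
   odds-change summaries `100·(exp(β) − 1)` %.
5. **`synth`** — synthetic sections with analytic ground truth (annular
   cortices, tilted-cylinder canal ellipses, ground-truth categories from
   the same classification rule) and simulated growth series with known
   power-law scaling and beta-distributed LI, so the whole chain is testable
   without any specimen data.

## Worked example

```python
import numpy as np
from osteolam import *

# a section whose canals are half longitudinal (tilt 0°) and half
# circumferential (tilt 75°, major axis along the periosteal tangent)
rng = np.random.default_rng(5)
canal_list = (random_canals(20, rng, tilt_range=(75.0, 75.0), azimuth_range=(0.0, 0.0))
              + random_canals(20, rng, tilt_range=(0.0, 0.0)))
spec = SyntheticSectionSpec(outer_radius=1.0, inner_radius=0.55,
                            pixel_pitch=2.5e-3, canal_list=canal_list, rng_seed=6)
section, truth = generate_section(spec)

geom = compute_section_geometry(section)
result, profiles = score_section(section)
print(f"Zp = {geom.Zp:.3f} mm^3, porosity = {geom.porosity:.3f}")
print(f"pooled LI = {result.pooled_li:.3f} (ground truth {ground_truth_li(truth):.3f})")
```

prints

```
Zp = 1.350 mm^3, porosity = 0.056
pooled LI = 0.423 (ground truth 0.500)
```

`Zp` is the torsional-rigidity proxy of the rendered annulus (canal voids
excluded from the integration), and the pooled LI recovered by octant
straightening, ellipse fitting and classification sits within sampling
error of the 0.5 built into the section (the four cardinal octants score
roughly half of all canals).

On the inference side:

```python
series = generate_ontogenetic_series(
    SyntheticSeriesSpec(n_specimens=60, zp_noise_sd=0.1, rng_seed=1))
fit = fit_loglog_allometry(series.mass_g, series.zp_mm3, element="humerus")
chain = run_ontogenetic_chain(series)
```

gives `a = 1.74, 95% CI [1.70, 1.79], R² = 0.99, positive` — strong positive
allometry of torsional rigidity, as expected from the generating exponent
1.76 — and a beta-regression fit `β0 = -1.319, β1 = -0.265` whose
`100·(exp(β1) − 1) = -23.3%` says the odds of laminar bone drop by about a
quarter per unit of growth along PC1.

A `click` CLI wraps the same functions
(`osteolam synth section|series`, `osteolam geometry`, `osteolam laminarity`,
`osteolam allometry`, `osteolam ontostats`); see `--help` on each.

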