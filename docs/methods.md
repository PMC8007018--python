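# Methods

## The geometric model

The tracheobronchial tree is reduced to three straight circular cylinders
meeting at the tracheal carina: the trachea (carina → cranial landmark P),
the right main bronchus (carina → R) and the left main bronchus
(carina → S). Coordinates are anatomical: x left–right (patient-left
positive), y superior–inferior (superior positive; the CT slice axis),
z anterior–posterior (anterior positive). Distances are centimetres,
angles degrees.

After translating the frame so the carina Q is the origin
(P′ = P − Q, etc.), each branch vector is parameterized in spherical
coordinates

    r     = ‖(x, y, z)‖                       branch length
    θ     = arccos(z / r)                      polar angle from the A–P axis
    φ     = arccos(x / √(x² + y²))             azimuth from the L–R axis

and reconstructed as (r sinθ cosφ, ±r sinθ sinφ, r cosθ). Together with a
mean lumen diameter per branch (d₁, d₂, d₃ — the arithmetic mean of the
per-slice diameter reads, following the cylindrical-branch assumption),
twelve parameters describe one airway.

**The y-sign convention.** Because θ, φ are recovered by arccos they lie in
[0°, 180°], so r sinθ sinφ ≥ 0: the spherical form cannot encode which side
of the carina a branch lies on, yet the trachea is superior and both
bronchi inferior. Reconstruction therefore takes explicit per-branch
y-signs (trachea +1, bronchi −1 by default) and extraction is insensitive
to the sign of y (y enters only squared). This is the only interpretation
under which the forward and inverse formulas are mutually consistent with
anatomy; the round-trip identity is enforced to 1e-9 relative in tests.

A branch vector lying exactly on the z-axis (x = y = 0) has an undefined
azimuth; the package raises rather than adopting a convention, since such
landmarks cannot occur in plausible supine anatomy.

**Bed angle.** The inclination of the trachea out of the couch plane is
90° − θ₁ (≈ 17–21° across groups, i.e. θ₁ ≈ 69–73°). Both readings of the
same geometry are available: `bed_angle()` returns the complement, θ₁ is a
field of the parameter set.

## Reference group statistics and model selection

The built-in per-group means and SDs (module `cohort`, `STUDY_GROUPS`)
describe the reference cohort of 20 patients — 7 children (ages 4–14),
6 adolescents/young adults (15–39), 7 adults (40–75). Group summaries use
the sample mean and the n−1 sample SD.

`select_model_parameters` turns a group summary into a buildable phantom
spec. Two modes:

* **derived** — round-half-up of the group means at build resolutions:
  lengths to integer cm, angles to integer degrees, diameters to 0.1 cm.
  Half-up (via `decimal`) reproduces 8.08→8, 11.75→12, 2.93→3, 0.95→1.0
  and avoids binary-float ties.
* **as_published** — the verbatim parameter lists of the three phantoms
  actually printed. These deviate from plain rounding in a few entries
  (AYA bronchial diameters 1.5 cm where the means round to 1.4; AYA θ₃
  92° vs mean 98.86°; adult θ₃ 128° vs mean 105.20°). Both modes are
  first-class so either can be pinned in analyses; `derived` is the
  default throughout.

An optional `pool_mature` flag recomputes the AYA and adult length and
diameter statistics over the pooled 13 patients (angles stay per group),
the harmonization appropriate when those groups show no significant
length/diameter differences. Off by default.

## Synthetic cohort generator

No imaging data are distributable, so every downstream stage is exercised
on synthetic patients that emulate the reference cohort:

* True parameters are drawn independently per parameter from normal
  distributions with the group means/SDs, truncated by rejection to
  validity ranges (r > 0.5 cm, angles in (5°, 175°), d > 0.2 cm). No
  between-parameter covariance is modelled — only marginal summaries are
  available — so joint structure (e.g. length–diameter correlation with
  body size) is absent from the synthetic data.
* Landmarks are the exact reconstructed endpoints plus Gaussian
  digitization noise on x and z (default SD 0.15 cm). The slice coordinate
  y is read off the scanner grid and carries no noise.
* Slice tables sample each branch's centerline every 0.25 cm in y (a
  typical planning-CT slice thickness), with independent Gaussian noise on
  x and z (SD 0.15 cm) and per-slice diameters d + N(0, 0.05 cm). The
  carina slice (y = 0) is emitted exactly at (0, 0): the carina landmark
  defines the frame origin, so its center has no measurement error by
  construction.
* Age is sampled uniformly within the group range and carried as metadata
  only; no parameter–age regression is modelled at patient level.

Noise defaults were chosen once so that synthetic accuracy summaries land
in the 0.1–0.4 cm range typical of slice-wise planning-CT centerline
agreement; they are configurable but the defaults above are the study
conditions used by all tests and the acceptance script. All randomness
flows through one `numpy` generator seeded per run; identical seed and
configuration reproduce every output byte-for-byte.

What passing tests on this generator do **not** show: real airways are
curved, non-circular (especially the bronchi, which run within the slice
plane) and their measured centers depend on the windowing and centroid
convention of the digitizer. The generator produces straight branches and
centers directly, so accuracy numbers on synthetic data characterize the
pipeline, not clinical measurement error.

## Slice-wise accuracy and agreement

A group model is evaluated against each member patient's slice table
(carina-normalized). For every slice whose y lies inside the model
branch's superior–inferior extent, the model centerline position is the
linear interpolation to the branch endpoint at that y; the signed
difference model − measured is taken in LR (x) and AP (z). Slices beyond
the model endpoint are excluded and counted — the model cannot be
extrapolated — since patient and model branch lengths generally differ;
the exclusion rule is this package's choice. At the carina the difference
is identically the zero vector.

Differences are summarized as mean ± sample SD of **absolute** differences
per segment (QP, QR, QS) × direction (LR, AP); the grand mean of the six
cell means is the headline single-number accuracy (< 0.4 cm on default
synthetic cohorts). Bland-Altman statistics (mean difference, SD, 95%
limits of agreement mean ± 1.96·SD) are computed per segment × direction,
pooled across patients within a group. Because a single group model is
compared with individual anatomies, the absolute difference grows with
distance from the carina (proportional bias); the tests assert that
positive correlation.

## Mann-Whitney U test

Group comparisons use a two-sided Mann-Whitney U computed from midranks.
For n₁ + n₂ ≤ 16 (covering 6/7-sized groups) the null distribution is
obtained exactly by enumerating all C(n₁+n₂, n₁) assignments of the pooled
values; the two-sided p-value is the null probability of a U at least as
far from n₁n₂/2 as observed (ties handled by the midranks; numerical
comparisons use a 1e-9 guard). Larger samples use the tie-corrected normal
approximation with continuity correction. The exact branch is validated
against an independent pair-counting permutation oracle, the approximate
branch against scipy.

## Mesh export

Each branch becomes a closed right circular cylinder (2·n_sides side
triangles, two fan-triangulated caps; 4·n_sides − 4 triangles total,
outward winding, default n_sides = 64). No CSG union is performed at the
carina: `overlapping` mode emits three closed components and print slicers
resolve the union; the junction is not blended, matching the piecewise
cylindrical model. `hollow` mode adds an outer shell offset by a wall
thickness (default 0.2 cm, a guess — whether the printed phantoms were
hollow, and at what wall, is not documented) and rejects walls ≥ the lumen
radius. Watertightness (every directed edge paired with its reverse) and
outward orientation (positive signed volume) are enforced per component;
STL is written in both the 50-byte-per-facet binary layout and the ASCII
grammar, in cm by default with an mm scale flag for printers.

## Problem sizes and numerical choices

Tests run the default 20-patient cohort, 10,000-sample round-trip checks,
500 patients per group for parameter recovery, and exact Mann-Whitney up
to C(16, 8) = 12,870 assignments; the acceptance script evaluates the
accuracy bound over 10 independent 20-patient cohorts (~20,000 slices
total). The whole suite completes in well under a minute. Tolerances:
1e-9 relative for geometric identities, 3 standard errors for Monte-Carlo
recovery, one unit in the last printed decimal for checks against rounded
reference fixtures (the fixture coordinates are themselves 4-dp roundings,
which shifts one derived angle by 0.01°).

## Known limitations

* Straight cylinders cannot represent tracheal curvature or the
  in-plane course of the main bronchi.
* Independent marginal sampling understates joint anatomical structure.
* The published AYA/adult θ₃ and AYA diameters are irreconcilable with
  plain rounding of the group means; `as_published` preserves them
  verbatim but cannot explain them.
* Accuracy numbers on synthetic cohorts characterize the pipeline under
  the stated noise model, not agreement with real CT measurements.
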