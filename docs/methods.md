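# Methods

## The export lattice and the aperture rule

The topographer dialect consumed here samples each corneal surface on a
fixed polar lattice: ring *i* at radius *i·0.2 mm*, semi-meridian *j* at
azimuth *j·360/256°*, elevations in mm along the instrument axis.  Only
the central disc of radius 4 mm is reconstructed (21 rings, 5376 samples
per surface, 10752 per eye): peripheral rings are dropped on read, and
an eye with any missing sample at r ≤ 4 mm is discarded rather than
imputed — beyond 4 mm tear-film breakup and eyelid shadowing make
acquisition unreliable, while the 0–4 mm region contains nearly all
keratoconus apexes.

Coordinate conventions: right-handed axes, origin at the intersection of
the instrument axis with the anterior surface, Z positive posterior
(into the eye).  Anterior elevations are then conicoid-sagitta-like
(≥ 0), the solid's centroid has positive Z, and the "apex" of a surface
is the global *minimizer* of its height field.  Azimuths run
counter-clockwise from +X; every reported variable is invariant to this
chirality choice.  Ring 0 carries 256 copies of the apex sample; they
are kept for point counting but collapsed (averaged, which also averages
their noise) before fitting.  The missing-value sentinel of the CSV
dialect is configurable because device exports vary by locale and
software version.

## Surface fitting

Over a 4 mm aperture a cornea is a graph z(x, y), so the surface
reconstruction is penalized least squares in a tensor-product cubic
B-spline space on a uniform clamped knot lattice covering
[−4, 4]² (64 spans per direction by default; the span count is
configurable up to the 255 used by commercial patch tools, which is a
software maximum rather than a method requirement):

    minimize  Σ_k (z_k − z(x_k, y_k))²  +  λ² J[z],
    J[z] = ∫∫_disc (z_xx² + 2 z_xy² + z_yy²) dx dy.

Choices that matter:

* **Stiffness normalization.**  The stiffness λ is a *length* (default
  10⁻³ mm).  With z in mm the data term carries mm² and J is
  dimensionless, so λ²·J is the unique dimensionally homogeneous
  weighting; λ is the deformation scale below which the fit stops
  following the data.  At the default the fit is near-interpolating
  (noise-free conicoid node residuals ≈ 10⁻⁶ mm), matching the regime
  the printed per-eye residual reports imply; λ → ∞ collapses the fit
  onto the best affine plane (the penalty's null space on the disc).
* **Penalty domain.**  J is integrated over the *disc*, not the bounding
  square: integrating over the data-free corners drags the rim flat and
  biases near-boundary evaluations by ~10⁻⁴ mm.  The integral uses
  Gauss–Legendre radial × trapezoidal azimuthal quadrature resolving the
  knot cells; basis functions whose support misses the disc entirely
  have neither data nor penalty and are excluded from the solve exactly.
* **Residual metric.**  Residuals are vertical (|Δz|), not
  surface-normal: corneal slopes over this aperture make the difference
  second-order, and the vertical form admits exact oracles.  Residuals
  are classified good < 10⁻⁴ mm, bad > 10⁻³ mm (the conventional
  deviation-map thresholds), intermediate between.
* **Equivariance.**  The square lattice plus isotropic penalty is
  exactly equivariant under its symmetry group (90° rotations,
  reflections), which the tests assert; under arbitrary rotations
  equivariance holds only up to spline approximation error.
* **Between-ring behaviour.**  Radial knot spacing (0.125 mm) is finer
  than the ring spacing (0.2 mm), so annuli near the rim contain
  data-free knot spans where the near-interpolating fit may wiggle by a
  few 10⁻⁴ mm off-lattice.  This is far below the 0.1 % tolerances of
  the integral geometry and is the price of the near-interpolating
  stiffness regime.

The solver is exposed as a scikit-learn estimator
(`SplineSurfaceSmoother`), since this one step genuinely is a
regression; the rest of the pipeline is tool-shaped.

## Solid model

The two fitted caps are sampled on a shared polar mesh (default 128
rings × 256 sectors, triangle fan at the pole — aligned with the data
lattice and free of the polar singularity) and closed by a ruled band
connecting boundary vertices at equal azimuth.  The ruled band is the
simplest closure consistent with a "bonding surface along Z" between the
rims.  The mesh is required to be watertight, genus 0, outward-oriented,
with every face labeled anterior/posterior/perimetric; assembly *fails*
rather than returning a defective mesh, and an intersection guard
(minimum admissible thickness 1 µm) reports the offending (r, θ).
Volume, surface areas and uniform-density center of mass come from exact
divergence-theorem integrals over the mesh (via trimesh).  Closed-form
checks (pillbox; two-sphere cornea) agree within 0.1 % at default
density and converge as density increases.

## Morphometric variables

18 per eye.  Definitions that were genuinely open and how they were
fixed:

* **Apex** = most anterior point (global extremum along the instrument
  axis), located by dense polar-grid seeding plus Nelder–Mead
  refinement; this is the only reading under which a healthy,
  rotationally symmetric cornea has apex deviation ≈ 0.  The same
  most-anterior convention is used for the posterior surface.  Flat or
  tied extrema tie-break toward the axis (smaller radius, then smaller
  azimuth), so a constant-thickness slab reports deviation exactly 0.
* **Thickness** is axial (along Z) by default; the two minimum-thickness
  contact points then share (x, y) and the cylinder axis through them is
  parallel to Z, making the cylinder-intersection volumes well-posed as
  2D quadrature of the thickness field over the (aperture-clipped) disc
  footprint.  A surface-normal thickness mode is provided for the
  thickness report itself; oblique cylinder axes are not supported (a
  mesh-boolean engine would be required).
* **Sagittal section areas** are full diametral sections (both
  semi-meridians) through the Z axis at the apex azimuth and at the
  minimum-thickness azimuth, computed from the mesh–plane intersection
  polygon; azimuths that coincide with mesh edges are nudged by a ≤ 10⁻⁶
  rad jitter to keep the intersection transversal (area change O(jitter²)).
  The slab fixture gives 8 × 0.55 = 4.40 mm², the full-plane value.
* **Deviations** are the XY-plane Euclidean distance of a single point
  from the instrument axis; averaging over repeated acquisitions belongs
  upstream (average the grids), not inside the operation.
* **Center of mass** assumes uniform density.

## Synthetic corneas

The generator stands in for the study data; its defaults define the
conditions every downstream claim is tested under.

Each surface is a conicoid, sagitta s(r; R, Q) = r² / (R + √(R² −
(1+Q) r²)); keratoconus adds a decentered Gaussian ectasia of amplitude
A and width σ that the anterior surface follows with amplitude A and the
posterior with (1 + f)·A, thinning the stroma locally by f·A.  Cell-wise
Gaussian noise (default sd 0.002 mm, a Scheimpflug-like couple of
microns) is reproducible from the per-eye seed.  Apex and
minimum-thickness ground truth are computed from the closed forms by the
same grid + simplex optimization, so pipeline recovery can be checked to
10⁻³ mm.

Cohort presets (means; eyes drawn per stage):

| preset   | R_ant (mm) | R_post | t0 (mm) | A (mm)      | f         |
|----------|-----------|--------|---------|-------------|-----------|
| healthy  | 7.8       | 6.5    | 0.55    | 0           | 0         |
| I        | 7.3       | 6.1    | 0.52    | 0.06–0.10   | 0.55–0.65 |
| II       | 6.8       | 5.7    | 0.49    | 0.10–0.16   | 0.60–0.70 |
| III–IV   | 6.3       | 5.2    | 0.45    | 0.16–0.26   | 0.65–0.75 |

Healthy values are conventional ophthalmic magnitudes (R_ant 7.8 mm,
Q ≈ −0.26, central thickness 0.55 mm).  Stage presets follow the
clinically documented progression: apical steepening per the
Amsler–Krumeich keratometry bands (K ≈ 45–48 D at stage I down past
55 D), central thinning (thinnest pachymetry ≈ 490/450/≤410 µm), and a
cone center decentered by 0.5–1.5 mm at a uniform azimuth — the typical
apex-to-axis distance of clinical cones.  Q grows more negative with
severity (progressive prolateness).  Severity allocation uses
largest-remainder rounding (41 keratoconic eyes at mix
51.2/36.6/12.2 % → 21/15/5).

What the generator does **not** emulate: microstructural irregularity
beyond a single smooth cone (Vogt striae, scarring), tear-film and
eyelid acquisition artifacts (missing-cell masks can be injected but are
not part of the presets), inter-map registration error of repeated
acquisitions, and any optical ray-tracing realism.  Consequently,
passing tests show the *pipeline* recovers known geometry and reproduces
the healthy-vs-keratoconus direction pattern under realistic magnitudes;
they do not certify clinical performance on patient data, and the
clinical cohort's printed means are deliberately not targeted (one of
them — an anterior area smaller than the flat-disc lower bound π·16 mm²
— cannot be produced by any surface over the full 4 mm aperture,
indicating an unknown area convention in the original tooling).
A healthy synthetic eye's thinnest point is exactly central, unlike real
corneas (thinnest point ~0.5–0.9 mm temporal), so the minimum-thickness
*deviation* variables discriminate more strongly here than clinically.

## Statistics

* Normality: Kolmogorov–Smirnov with Lilliefors correction (location and
  scale are estimated from the data); verdict normal iff p > 0.05.
  Requires n ≥ 4 and a non-constant sample.
* Two groups: Student's t when both groups screen normal, else
  Mann–Whitney U — exact enumeration when both n ≤ 10 without ties,
  tie-corrected normal approximation otherwise (the z statistic is
  reported alongside).
* Stages: Kruskal–Wallis with tie correction; Dunn's pairwise z on the
  joint ranking with Bonferroni (adjusted p = min(1, raw·#pairs));
  effect size (mean_normal − mean_stage)/pooled SD, positive when the
  normal group exceeds the stage group.  Stage summaries report both the
  95 % CI and the min–max range.  An empty stratum is dropped with a
  warning.
* ROC: AUC as the normalized Mann–Whitney U (ties half); Hanley–McNeil
  SE; CI = AUC ± 1.96·SE clipped to [0, 1]; p from the normal z against
  0.5; cut-off by Youden's J (the standard default where no selection
  criterion is stated); accuracy ratio ≡ 2·AUC − 1.  Direction "auto"
  orients AUC ≥ 0.5, but "larger" reports the raw orientation so that
  inverse variables (e.g. volumes, lower in disease) carry sub-0.5 areas
  and negative ratios, as diagnostic tables conventionally print them.
* DeLong variance and multivariable classifiers are out of scope; each
  variable is analyzed alone.

## Problem sizes and numerical defaults

Cohort-scale runs (the CLI and the acceptance script) use 32 fitting
spans and a 64 × 256 solid mesh — residuals ~10⁻⁵ mm and integral errors
well inside 0.1 %, at ~0.5 s/eye; precision work uses the 64-span,
128 × 256 defaults of `FitConfig`/`MorphometryConfig`.  Extremum
searches seed on an 81 × 256 polar grid before refinement.  Quadratures:
Gauss–Legendre radial (exact for the spline polynomial degree per span in
the penalty; 64 nodes for cylinder footprints) × 256-point trapezoid
azimuthally (spectrally accurate for smooth periodic integrands).  All
randomness flows through explicit integer seeds; reruns are
byte-identical.
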