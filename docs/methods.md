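# Methods

This note records the models, conventions, numerical choices and known
limitations behind `eyemap`, in the order the pipeline runs.

## Coordinate and unit conventions

The head frame is +x anterior, +z dorsal, −y toward the animal's left.
Viewing directions are azimuth az = atan2(n_y, n_x) and elevation
el = asin(n_z), in degrees; the anterior direction is (0°, 0°), a left
eye occupies negative azimuths, and mirroring across the sagittal plane
y = 0 maps (az, el) → (−az, el). At the poles azimuth is reported as 0°.
All lengths are micrometres except the intertegular width ITW (mm, the
field's standard body-size measure); all angles are serialized in
degrees. Transforms are 4×4 homogeneous matrices composing
right-to-left on column vectors; a `mirror` transform must have rotation
determinant −1 and is its own inverse.

## Interface extraction from labeled volumes

Each anatomical interface (cornea/background, lens/cone, cone/retina,
retina/lamina) is the 0.5-level set of the indicator of "label at or
below this depth", Gaussian-smoothed by 1 voxel and contoured with
marching cubes. Faces are kept only where the voxel labels just outside
and just inside match the interface; for the outer cornea an additional
inward walk must exit the lens into a deeper layer within twice the
median path length, which removes the lateral rim of a cut lens shell
(a face on the cut edge exits sideways into background, or grazes the
lens far longer than it is thick). Only the largest edge-connected
component survives; a dropped secondary component larger than 1% of the
faces (e.g. an ocellus stub sharing the lens label) raises a warning.

**Cut-edge curl.** The isosurface rounds the label cut edge over ~2–3
voxels, tilting normals there by up to ~10°. This is irrelevant to
areas (3% agreement with analytic truth holds untrimmed) but smears
normal-derived quantities, most visibly inflating the corneal
projection. `extract_interfaces(..., trim_boundary_voxels=3)` (the CLI
default for `eyemap surfaces`) removes that band at the cost of
shrinking the reported area by roughly perimeter × trim; leave the trim
at 0 when area is the quantity of interest.

## Corneal sampling

"Equally spaced" points on an arbitrary curved surface cannot form a
regular grid, so sampling is seeded blue noise: farthest-point
insertion over the mesh vertices down to ~1.1× the hexagonal-packing
count A/((√3/2)·s²) for spacing s (default 25 μm), four area-weighted
Lloyd relaxation passes with centroids re-projected onto the local
tangent plane (points stay within ~0.05 μm of the surface), then greedy
thinning of any pair closer than 0.7·s. The result is reproducible
bit-for-bit at fixed seed, keeps the count within ~12% of the packing
estimate, and guarantees the 0.7·s minimum separation. Sample normals
are area-weighted vertex normals averaged over a 2·s radius with a
Gaussian falloff (σ = 0.75·s); the falloff keeps the one-sided
averaging bias at open boundaries below ~0.5° on a 1 mm sphere, and
smoothing is discarded if it would flip a normal.

## Local radius of curvature

R comes from an algebraic least-squares sphere fit to the mesh vertices
within a 125 μm neighborhood (~5 facet widths at bee scale) — a single
scalar radius is exactly what ΔΦ = D/R requires. Fewer than 10 vertices
in range yields a missing R; a fit RMS above 5% of R flags the sample
unreliable (kept, not dropped). R is signed positive when the fitted
center lies inside the eye (convex cornea). The neighborhood radius
trades noise (smaller) against shape bias (larger): on the oblate test
ellipsoid (a = b = 1000, c = 500 μm) the polar estimate recovers the
analytic a²/c = 2000 μm within 5% at the default radius.

## Facet lattice

A facet measurement is one center plus six border points clicked on the
opposing outer borders of the six facets surrounding a central facet,
so opposing points span **three** across-flats widths and
D = mean(pair distance)/3. The span divisor is an explicit parameter
(`span`, CLI `--facet-span`) because other landmarking protocols click
the central facet's own borders (span 1). Pairing takes each point with
its most antipodal partner about the center and requires > 120°
separation; a pair deviating > 30% from the median span is flagged as
an outlier but still averaged.

The D field is interpolated to samples by inverse-distance weighting
(power 2, k = 6 nearest measurement centers, 3D Euclidean distance,
500 μm cutoff) — a convex combination, hence bounded by the measured
range. Total facet number integrates the lattice: each sample's
discrete Voronoi patch of corneal area contributes
patch_area/((√3/2)·D²) facets, the exact tiling count of a hexagonal
lattice with across-flats distance D. This is deliberate: landmark
protocols measure sparse facets, not all of them, so N must come from
the field, and hexagonal packing is the biological lattice.

## World grid and corneal projection

The world grid is a 1° (default) azimuth × elevation raster with
per-cell solid angle cos(el)·Δaz·Δel; the cells sum to 4π within 0.1%.
A CP cell is any cell containing at least one sample's viewing
direction, followed by a morphological closing computed with
great-circle disks (cell-space disks under-close near the poles where
azimuth cells narrow). The closing radius is 2 cells; the dilation
additionally exceeds the erosion by half the median angular
nearest-neighbour pitch of the samples, because a region sampled at
pitch δ has its outermost sample ~δ/2 inside the true boundary — with
that restitution, cap CPs match 2π(1−cos θ) within 2% at 1° resolution
and the estimate moves < 1% when the grid is refined. Binocular and
complete CPs are cell-wise AND/OR, so inclusion–exclusion of their
solid angles is exact by construction.

Scalars are projected into the CP by inverse-distance weighting on
great-circle distance (power 2, k = 6, 3° cutoff; nearest-neighbour
fill for CP cells beyond the cutoff). Band profiles over 10° strips use
solid-angle-weighted means for scalar layers but plain cell-count
percentages for CP-integral profiles — an intentional asymmetry
preserved from the original analysis style this package follows.
Map coordinates: equirectangular (x, y) = (az, el) and sinusoidal
x = az·cos(el) (equal-area, so pixel counts measure solid angle).

## Optics

- ΔΦ = (180/π)·D/R, with a two-point finite-difference variant
  (`if_angle_numeric`) retained purely as a cross-check oracle — the
  analytic form is exact on the locally fitted sphere and far less
  noisy.
- Thicknesses: one ray per sample from the corneal point along −n;
  first hits on the cone front, retina front and lamina interface at
  distances d₁ ≤ d₂ ≤ d₃ give L_lens = d₁, L_cone = d₂−d₁,
  L_retina = d₃−d₂. A missed interface leaves that thickness and the
  deeper ones missing; an ordering violation flags the sample.
  Duplicate hits on shared triangle edges are merged; accuracy against
  analytic shells is ≤ 0.5 μm.
- P = ΔΦ[rad]·D; S = (π/4)²·D²·Δρ²·kl/(2.3+kl) with Δρ = ΔΦ and
  l = L_retina. Both substitutions are assumptions, not measurements:
  crystalline-cone skew can decouple the true ommatidial axes from
  corneal normals, and rhabdoms need not lie perpendicular to the
  cornea, so S and P inherit those errors. The absorption coefficient
  (k = 0.0067 μm⁻¹) and the 2.3 denominator are explicit
  `OpticsConfig` fields rather than hidden constants.
- Facet-number approximations of the mean IF angle divide a solid angle
  Ω (2π for the hemispheric variant, the eye's own CP for the
  field-of-view variant) by the facet count N and convert the per-facet
  solid angle ω = Ω/N to an angular pitch. The packing constant is not
  uniquely defined, so hexagonal (ΔΦ = √(2ω/√3), the default), square
  (√ω) and circular (2√(ω/π)) conventions are all available and
  reported side by side where it matters.
- Missingness always propagates; nothing is imputed.

## Allometry

Y = b·xᵅ is fit by ordinary least squares on log₁₀-transformed data
(the base cancels in α); r and the two-sided p come from the same
regression, with p < 0.05 driving the "significant" flag that chooses
solid vs dashed fit lines in plots. OLS rather than reduced major axis
is the default reading of "fit after logarithmic transformation"; n = 2
gives an exact line with undefined p (reported not-significant).

Exponent maps fit the same regression per world-grid cell using the
eyes whose CP covers that cell, masked to cells with ≥ 4 contributing
individuals (`min_n`, exposed) and with a "fringe" recording cells seen
by 1–3. The per-cell fit is vectorized but numerically identical to
`fit_power_law` cell by cell, and is independent of eye ordering.

## Synthetic eyes: what they emulate, and what they don't

The generator produces spherical- or ellipsoidal-cap corneas with inner
interfaces at constant offsets along the inward normal — so every layer
thickness truth equals its offset *exactly*, by construction. Per-eye
truths (cap area, shell volume via the tube formula
∫(T − HT² + KT³/3)dA, CP solid angle as the Gauss-map area ∫K dA, facet
count ∫dA/((√3/2)D²)) are evaluated by Gauss–Legendre × trapezoid
quadrature of closed-form curvature integrands (exact to ≪ any test
tolerance; implicit-surface formulas give K and H). Landmark sets are
laid on tangent-plane hexagonal axes and projected to the surface
(distortion < 0.1% for D ≪ R, the biological regime). Volumes label
depth bins of the exact radial depth (spheres) or a Euclidean distance
transform (ellipsoids) inside the cap's angular region. The default
optic axis points where a bee's left eye does (az −60°, el +10°); the
default allometric size span is ×1.57 in linear eye size, the cube root
of the ~×3.9 eye-volume span of a wild bumblebee worker cohort.

What a green test on these eyes does **not** establish: robustness to
segmentation noise beyond voxelization, non-convex or locally concave
corneas, crystalline-cone skew (deliberately unmodeled — the IF ≠ IO
caveat above), spatially correlated landmark error, or real rhabdom
geometry.

**Statistical design of the exponent-recovery fixture.** With 2%
multiplicative noise the per-cell log₁₀-OLS slope sd is
σ = (0.02/ln 10)/√Sxx. At the biological ×1.57 size span σ ≈ 0.03, so a
worst-cell error bound of 0.05 over thousands of cells would fail in
every draw; the recovery fixture therefore uses a ×32 size span (the
same span as the power-law fit fixtures) and equal CP caps, where the
bound is a ~7σ certainty. This is a property of the fixture world, not
of bee cohorts — do not expect 0.05-tight local exponents from six real
individuals.

## Known limitations

- IF angle underestimates IO angle where crystalline cones are skewed;
  correcting this requires segmenting individual cones, which is out of
  scope here as it was for the analysis this package reimplements.
- The CP is a corneal construct: real fields of view also depend on
  ommatidial optics and can exceed it.
- Thickness rays assume locally layered anatomy; strongly oblique
  geometry near cut edges is flagged, not repaired.
- Mesh IO is ASCII PLY/OBJ/STL only; volumes are TIFF stacks; world
  grids export to CSV. No NRRD/NetCDF/Amira readers.
- `projected_area` unions projected triangles exactly via polygon
  union; meshes beyond ~10⁵ faces are slow — rasterize externally if
  that matters.
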