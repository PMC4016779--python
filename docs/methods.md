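# Methods

This note documents the models, parameters, and numerical choices behind
`nailmorph`, in the order the pipeline applies them, together with what the
synthetic phantoms do and do not establish about real scans.

## Coordinate and data conventions

Volumes are isotropic 3D scalar grids; the world position of voxel
`(i, j, k)` is `origin + spacing · (i, j, k)` and a voxel value represents
its center.  Anatomical axes are fixed to +x lateral, +y anterior,
+z proximal; right-sided specimens are the x-mirrored geometry.  Anisotropic
files are rejected unless explicitly overridden, because all geometric
tolerances downstream are stated in voxels.  Supported formats: MetaImage,
NIfTI-1, and single-directory TIFF stacks with a JSON spacing sidecar.

Landmarks (head apex, a point and direction of the shaft axis, the lateral
bone–cartilage border point, the head's lower border z, and a per-design
subcortical cut z) define the specimen frame and the VOI placement.  The
subcortical cut replaces an interactive cortical/cancellous separation with
a reproducible plane supplied as data.

## Image processing

* **Gaussian filter** — "support" is read as the truncation radius of the
  kernel: weights `exp(-‖d‖² / 2σ²)` sampled at integer offsets within
  Chebyshev radius `support`, renormalized to sum 1 (σ = 0.7, support = 1 by
  default, i.e. a 3×3×3 stencil).  Borders are mirror-reflected.  The
  normalized kernel has unit DC gain, so constant volumes pass unchanged;
  note that no symmetric padding preserves the mean of *non-constant*
  volumes exactly (border voxels receive total weight ≠ 1), so only the
  constant-volume mean, linearity and interior shift-equivariance are
  guaranteed (and tested).
* **Threshold** — foreground iff `value ≥ fraction × reference` with
  fraction 0.11.  The reference is configurable: the per-image maximum, or a
  fixed full-scale ceiling.  The tie rule (≥) is deterministic and
  documented in every report.  Phantom studies use the full-scale reference
  (32 767, an emulated native scanner range) with bone at gray 7 500:
  0.11 × 32 767 ≈ 3 604 sits roughly midway between marrow (0) and bone
  levels, where the partial-volume blur of the filter neither dilates nor
  erodes the segmentation (measured bias < 0.004 volume fraction).  With a
  per-image-max reference on a two-level phantom the same threshold would
  sit far below the bone/marrow midpoint and dilate the segmentation
  heavily; both readings remain available, and the choice is stamped into
  every output row.

## VOI geometry

The tube is an annulus with inner Ø 9 mm (the implant itself, excluded) and
outer Ø 12 mm.  The straight axis is the extended shaft axis; the bent axis
is the shaft direction rotated by 5° toward the lateral bone–cartilage
border (in the canonical frame, a rotation about the AP axis), anchored so
that in the AP projection its lateral coordinate at the border level equals
the border point's, and with zero deviation from the shaft axis in the
lateral projection.  The construction is formulated direction-vector-wise,
so it is equivariant under rigid rotations of the landmark set.  Both
designs span from the per-design subcortical cut (proximal) to the head's
lower border (distal).

Rasterization uses center-in-shell inclusion (boundaries inclusive), with no
partial-volume weighting.  A caveat discovered while validating against the
closed-form annulus volume: when analytic boundaries coincide with lattice
symmetry points (integer radii on a symmetric grid), the center rule is
systematically one-sided (−3 % for the 9/12 mm annulus at 0.5 mm voxels).
Synthetic solid grids therefore stagger voxel centers by a fixed generic
(irrational) sub-voxel offset per axis, which restores the expected ≲1 %
voxelization accuracy; real scans never have exactly aligned boundaries.

**Isovolumetric quarters.** Labeled voxels are grouped into z-slices
(optionally slices along the tube axis, `quarter_axis=voi_axis`); a slice
whose cumulative voxel-count midpoint falls in `((k−1)N/4, kN/4]` joins
quarter *k*, numbered 1–4 proximal → distal.  Cuts land on slice boundaries,
so each quarter deviates from N/4 by at most the largest single-slice count.
The midpoint rule reproduces equal counts exactly for uniform tubes and
behaves sensibly for ragged slice distributions.

## Morphometry

TV is the complete VOI volume: labeled voxel count × voxel volume, so
quarter TVs add up exactly.  BV is mesh-based: the binary segmentation,
restricted to the VOI and zero-padded by one voxel (closing the surface at
the cuts), is surfaced by marching cubes at iso-level 0.5; the enclosed
volume is the sum of signed tetrahedra over the oriented triangles
(divergence theorem), translation-invariant and apex-independent.

Two numerical points:

* Marching cubes on binary data yields closed but occasionally *non-manifold*
  surfaces — where foreground voxels touch only diagonally the surface
  pinches along an edge shared by four triangles.  The enclosed volume is
  still well defined; closure is therefore validated as "every edge shared
  by an even number of triangles, winding consistent", not as strict
  watertightness.  Meshes are kept verbatim (orientation repaired if
  needed); vertex-merging "cleanups" were observed to change enclosed
  volumes and are deliberately avoided.
* Quarter BV is the whole-VOI surface clipped to the quarter's slab.  The
  clip splits triangles exactly at the plane and sums the flux of the field
  `(s − s₀)·n̂` over the parts below; the virtual cap lies in the plane
  where the field vanishes, so no cap triangulation is needed and
  Σ quarter BV = whole BV to machine precision.  Meshing each quarter
  independently (also available, `morphometry.region_bv`) loses ~1 % at the
  internal cut chamfers.

The isolated-voxel surface is the octahedron spanning the six face
midpoints, volume 1/6 voxel — the small-structure limit of the method's
negative bias; mesh volumes of voxelized spheres converge to the analytic
value as r grows (−0.9 % at r = 10 voxels, −0.04 % at r = 40).

An alternative gray-level iso-surface at the threshold value
(`surface="gray"`) exists for sensitivity analysis.

## Synthetic phantoms

The phantom emulates the *measurement situation*, not trabecular biology: a
hemispherical head (radius 24 mm) on a cylindrical shaft (radius 15 mm,
wide enough that the bent tube clears the metaphyseal cortex), a closed
cortical shell (1.5 mm, via a Euclidean distance transform of the solid),
and a trabecular interior textured by a Gaussian random field (smoothing
scale 3 voxels).  Default spacing is 0.4 mm — a desk-scale stand-in for
82 µm scanner resolution; all structural scales are set in voxels so the
pipeline behaves equivalently.

**Exact fraction control.** Within each z-layer, concentric radial rings
(width 1.5 mm, edges aligned with the 4.5/6 mm tube radii) crossed with the
deficit sector each receive exactly `round(f·n)` bone voxels — the ring's
top field values — where `f = bvtv_profile(z)`, times `lateral_deficit`
inside the sector.  This pins the realized fraction per layer (recorded in
the ground-truth slab table, within ±0.01 for slabs of ≥10⁴ voxels) *and*
locally where the straight tube samples it, instead of letting the random
field's long-wavelength structure dominate thin annular regions.  Plain
per-layer thresholding was measured to leave quarter-scale fluctuations of
sd ≈ 0.08; finer cell-wise stratification fragmented the texture into dots
that the filter erodes.  The ring construction leaves the *bent* tube —
which crosses rings obliquely — with residual azimuthal fluctuation
(sd ≈ 0.05–0.07 per quarter); no validated quantity requires absolute bent
accuracy.

Gray levels: bone 7 500, marrow 0, additive Gaussian noise sd 150 (signal
separation ≈ 50 σ_noise, so segmentation errors come from partial volume,
not noise).  Identical spec + seed ⇒ bit-identical volumes (seeds split via
`SeedSequence`).

**Lateral deficit.** A 100° wedge centered on the lateral direction spanning
the head's full proximal–distal extent models the low-density greater-
tubercle region (anatomically it reaches from near the apex to below the
head equator; a deficit confined to the proximal half would spare the
distal half of the bent path entirely).  Deficit studies use a
multiplicative factor 0.25 and a bent entry ~7 mm lateral of the apex
(border landmark at 20° polar angle); these were chosen so the synthetic
bent/straight BV/TV ratios (≈0.25–0.6 per quarter) fall in the range
reported for cadaveric humeri, giving standardized effects d ≈ 2.5–10 —
amply powered for two-sided Mann–Whitney tests at p < 0.01 with 20 per
group.

**Pairs.** Left/right specimens of one synthetic donor share one texture
seed (the right side is the exact x-mirror) and receive per-side
multiplicative profile scales `1 + 0.1·a` with `(a_L, a_R)` bivariate normal
at correlation ρ (population value, "in expectation"; at ρ = 1 the sides are
bit-identical mirrors).  Because the texture is shared, the measured
right–left BV/TV correlation tracks the sample correlation of the generated
scales to within a few 0.001 — the morphometry adds essentially no
attenuation — and therefore inherits exactly the Fisher-z sampling spread of
a true ρ across study seeds.

**What passing tests do and do not show.** The phantoms validate geometry,
volumetry, fraction recovery and the statistical battery under known truth.
They do not establish segmentation accuracy on real HR-pQCT gray-value
distributions (beam hardening, marrow fat variation, cortical porosity), do
not model plate/rod trabecular microarchitecture, and say nothing about the
clinical comparison itself — the deficit magnitude is designed, not
discovered.

## Statistics

* **Mann–Whitney U** — `U = #{x_i > y_j} + ½·#ties`.  Exact p by full
  enumeration of all C(n+m, n) labelings when n+m ≤ 16 (mid-ranks under
  ties; a cached rank-position distribution when there are none); otherwise
  the normal approximation with tie-corrected variance and a continuity
  correction (the correction can be disabled, e.g. to verify the H = z²
  identity against Kruskal–Wallis).  The attained two-sided level at
  n = m = 8 is 0.0499.
* **Kruskal–Wallis** — mid-ranks with tie correction, chi-square tail
  (scipy); the all-values-identical degenerate case returns H = 0, p = 1.
* **Correlations** — Pearson by default (the conventional default of the
  statistics environments these studies use), Spearman by switch; two-sided
  p via the t-transform on n−2 df.  The report states which was used.
* **Normality screen** — Monte-Carlo Lilliefors KS as the primary, fully
  specified test: D = sup |F_n − Φ((x−x̄)/s)|, p = proportion of D* ≥ D over
  standard-normal samples of the same n with re-estimated parameters
  (seeded; 2000 replicates by default; the add-one p estimate never returns
  0).  Shapiro–Wilk (scipy's published approximation) is attached alongside.
* **Study report** — per-design adjacent-quarter tests, per-region
  straight-vs-bent tests, side and sex Kruskal–Wallis on whole-VOI BV/TV,
  and the right–left correlation grid over complete donor pairs only
  (unpaired specimens are excluded and logged).  Raw p-values, no
  multiplicity correction by default (a Holm adjustment is available).
  Report cells are invariant to manifest row order.

## Problem sizes

Default phantoms are ~1.5 M voxels (generation ≈ 1 s, both-design analysis
≈ 0.5 s), the paired study uses 20 donors (40 specimens), and the Monte-Carlo
calibrations use 2000 replicates — sizes chosen so the entire validation
suite completes in minutes on one CPU while every tolerance retains a clear
safety margin.

## Known limitations

* The bent-axis anchor (AP projection pinned at the bone–cartilage border
  level) is one deterministic reading of the implantation specification;
  the flag `bent_axis_anchor` stamps it into every output row.
* BV/TV recovery carries a small negative bias (−0.011 … −0.015 absolute)
  from partial-volume erosion of thin structures plus the marching-cubes
  small-blob deficit; it is inherent to the measurement chain, not to the
  generator, and is well inside the ±0.02 validation band.
* Quarter boundaries quantize to whole slices; for very coarse grids the
  per-quarter TVs can differ by up to one slice's volume.
* `Volume3D` holds the full volume in memory; scanner-resolution humeri
  (~2×10⁸ voxels) fit but are slow in pure NumPy.
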