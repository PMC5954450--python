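# Methods

## Scope and data model

The package analyses one cubic volume of interest (VOI) per specimen,
assumed pre-aligned: array axes are (z, y, x) = (proximodistal,
anteroposterior, mediolateral), direction vectors are reported as
(x, y, z). Voxels are isotropic with edge `voxel_size` in mm. Foreground
(bone) is 26-connected, background (marrow) 6-connected, and every volume
is treated as a closed object — one voxel of implicit background beyond
each face — for connectivity, thickness and meshing alike.

## Morphometric parameters

**Binarization** defaults to Otsu's criterion (the method and numeric
threshold are recorded in the volume's provenance; `isodata` and `mean`
are available). The original workflow used a packaged "optimise
threshold" routine whose algorithm is not published; numerical identity
with it is not claimed. **Purification** keeps the largest foreground
component and fills cavities (background components not touching the
stack boundary), after which Conn = 1 − χ counts independent loops.

**Connectivity.** χ is the 3D Euler characteristic with 26-connected
foreground (2×2×2 octant accumulation over the padded volume);
ConnD = Conn / (stack volume in mm³).

**Thickness.** Thickness at a voxel is the diameter of the greatest
sphere that fits in the phase and contains the voxel. Sphere radii are
Euclidean distances to the nearest opposite-phase voxel centre, with no
half-voxel discount and no discounting of surface-touching spheres; this
literal reading measures a w-voxel plate as w + 1 voxels and a
voxel-centred ball of radius r as almost exactly 2r, i.e. it can
overestimate the continuum value by up to about one voxel (the behaviour
of the standard tooling). The implementation prunes sphere centres to a
distance ridge (a centre is dropped when an adjacent centre's sphere
contains its own) and paints the remaining spheres in descending radius
order with bounding-box-restricted distance transforms; on small grids it
is voxel-identical to a brute-force maximal-sphere search, which the test
suite verifies. TbTh is the volume-weighted mean over bone, TbSp the same
over marrow.

**Surface.** BS/BV meshes the padded volume with marching cubes at level
0.5 after a Gaussian anti-aliasing of σ = 0.65 voxels. The smoothing
suppresses the staircase over-estimation of curved surfaces (a voxelized
sphere meshes ~8 % too large raw, < 2 % smoothed) at the cost of slightly
rounding sharp edges (a 30-voxel box meshes ~4 % small); both stay within
the phantom tolerances below.

**Fabric.** Mean intercept lengths are sampled over `n_directions = 512`
quasi-uniform directions (Fibonacci lattice, optional seeded random
rotation); for each direction a bundle of parallel rays (1-voxel spacing
in the perpendicular plane and along the ray) is traced with
nearest-neighbour sampling, and MIL = total in-volume ray length / number
of phase crossings. Directions without crossings are dropped; more than
20 % dropped aborts the analysis as "structure too coarse". The fabric
ellipsoid is fit by regressing 1/MIL² on the quadratic direction
monomials (the Harrigan–Mann tensor); a direct least-squares quadric on
the MIL point cloud was rejected because it loses positive-definiteness
for strongly anisotropic structures such as plate stacks. With ellipsoid
radii rᵢ = eigenvalue⁻¹ᐟ², DA = 1 − r_min/r_max ∈ [0, 1] and MDT is the
major axis (eigenvector of the smallest eigenvalue), sign-normalized to
z ≥ 0. For inter-specimen comparison MDT is mirrored for right femora
(x ↦ −x) *before* hemisphere projection.

## VOI selection and quality control

The central slice is the z index whose strictly-distal and
strictly-proximal head voxel counts are most balanced (ties toward the
distal side). The VOI is the largest odd-edged cube centred on that slice
containing only trabecular voxels (head minus cortex, cube fully inside
the stack), found exactly with a chessboard distance transform; among
equally large cubes the centre nearest the slice's trabecular centroid is
chosen — a reproducible surrogate for the original manual "maximum
spread" placement. Odd edges keep the cube symmetric about the central
slice. Specimens fail QC when relative resolution TbTh/voxel < 5 or
Conn < 50; they are flagged with reasons, never deleted, so the exclusion
is auditable.

## Comparative statistics

All traits and the size proxy vl are natural-log transformed. The species
covariance is Brownian motion on the supplied rooted tree: V[i,j] is the
root-to-MRCA path length, with off-diagonals multiplied by Pagel's λ.
λ is restricted to [0, 1] and profiled by REML by default ("ML"
selectable); REML was chosen because the variance-structure estimate is
much better calibrated at comparative sample sizes and it is the default
of the standard GLS tooling. Coefficients come from GLS at the estimated
λ, with t-tests on n − p degrees of freedom; inference is conditional on
λ̂ (no λ-uncertainty propagation), the common practice for this
estimator. λ = 0 reduces exactly to OLS.

Allometry: a_iso equals the trait's length dimension (0 for BV/TV and
DA, 1 for TbTh/TbSp, −1 for BS/BV, −3 for ConnD — the constant-
trabecular-geometry model). The deviation test refits the shifted
response log tp − a_iso·log vl with λ fixed at the primary fit's
estimate, making the shifted slope equal a_obs − a_iso exactly;
p ≥ 0.05 (boundary included) classifies as isometry, otherwise the sign
of the deviation decides positive/negative allometry.

Lifestyle contrasts fit log tp ~ log vl + indicator per unordered pair
(pairs with fewer than 3 species per group are skipped with a reason) and
correct with Benjamini–Hochberg, by default within the six pairs of one
trait (results are reported per parameter); a `global` family pooling all
traits × pairs is available. Multiple specimens per species must be
averaged on the log scale upstream; the trait table carries one row per
species.

## Synthetic data

Phantoms provide closed-form ground truth: balls, boxes and cylinders
(volume fraction, inscribed-sphere thickness, surface density,
anisotropy axis), plate stacks (thickness/gap/normal), rod lattices
(connectivity = cycle rank E − V + 1 of the L³ node lattice), and
correlated Gaussian random fields — white noise smoothed with an
axis-scaled kernel and thresholded at the empirical quantile, which pins
BV/TV exactly and makes anisotropy tunable through the kernel elongation.
Declared tolerances: BV/TV ± 0.02, TbTh/TbSp ± 1 voxel, BS/BV 4–10 %
relative depending on curvature, Conn exact.

The comparative simulator draws a pure-birth tree rescaled to unit
height (branch-length units are irrelevant to GLS), paints lifestyles
onto contiguous blocks of the leaf order (mimicking the real clustering
of lifestyles in clades; a `random` mode serves null checks), draws
log vl uniformly, and builds each trait as
intercept + slope·log vl + lifestyle offset + MVN(0, σ²V(λ)) residual.
Defaults mirror the study design: 69 species (27 arboreal, 19 fossorial,
15 semifossorial, 8 aerial), generating slopes equal to the observed
allometric exponents of the study system, vl from 0.8–6.5 mm,
σ = 0.15 log-units, λ = 0.8. What the simulator does *not* emulate:
measurement error in the morphometry, intraspecific variation,
non-Brownian (e.g. Ornstein–Uhlenbeck) evolution, correlated residuals
across traits, and phylogenetic signal in vl itself — so passing
recovery tests demonstrates correctness of the estimator under its own
model, not robustness to model violation.

## Numerical choices and problem sizes

Phantom validation runs on 33³–64³ grids with 128–256 MIL directions;
these sizes keep every geometric feature ≥ 2 voxels (the resolvability
bound) while the whole suite measures in seconds. Odd grid extents are
used for balls and cylinders so their centres coincide with voxel
centres; on even grids the half-voxel offset alone shifts inscribed-
sphere diameters by more than a voxel. Monte-Carlo checks use 100–500
replicates at the study size n = 69; recovery assertions use 2
Monte-Carlo standard errors.

## Known limitations

- Inference conditional on an estimated λ is anticonservative: under a
  null with intermediate true λ the pairwise lifestyle test's empirical
  type-I error is ≈ 0.08 (random group assignment) to ≈ 0.11
  (clade-clustered groups) at nominal 0.05, while with λ fixed at its
  true value it is calibrated (≈ 0.05). The reference R implementation
  (`nlme::gls` + `ape::corPagel`) reproduces the same rates, so this is a
  property of the method, not of this implementation. Treat borderline
  adjusted p-values accordingly.
- MIL direction count and ray spacing are not standardized across
  implementations; DA values are comparable in rank/order terms rather
  than absolutely.
- Thickness overestimates continuum values by up to one voxel by
  construction (see above); relative resolution inherits this bias.
- Automatic cortex segmentation, femur re-orientation and epiphyseal-
  plate detection are out of scope; the head/cortex masks and the
  juvenile flag are inputs.
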