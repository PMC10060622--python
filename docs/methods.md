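# Methods

## The zero-strain measurement model

A zero-strain test registers two scans of the same unloaded specimen.
Writing `f` for the fixed scan and `g` for the moving one, the registration
model is intensity conservation with a grey-level correction:

    r(x) = f(x) − g(x + u(x)) − s(x) · h(x)

where `u` is the displacement field, `s` an additive relative grey-change
field, and `h(x) = (f(x) + g̃(x))/2` the local mean intensity (g̃ is the
currently warped moving image). Both `u` and `s` are expanded in trilinear
basis functions on a regular grid of cubic cells with side `ns` voxels (the
nodal spacing, NS). Each outer iteration linearizes `r` around the current
`u` using the symmetric gradient `∇(f + g̃)/2`, solves the normal equations
by least squares over the masked voxels, adds the update to `u`, and
rewarps `g` (cubic spline interpolation); iteration stops when the largest
nodal update falls below `convergence_tol` (default 0.01 voxels) or after
`max_outer_iters` (default 30). The solver is deterministic: zero initial
field, direct or conjugate-gradient solves, no randomness.

Conditioning: a Laplacian (second-difference) penalty `λ‖L u‖²` on each
nodal component (and on `s`) regularizes nodes with little or no masked
support. `λ` (default 0.1) is dimensionless: the data term is normalized by
the masked-voxel count and the penalty by a gradient-energy scale frozen at
the first iteration, so the default transfers across intensity scales.
Since no reference value exists for the smoothing weight, it is exposed in
`RegistrationSettings`; the choice trades noise suppression against spatial
resolution of the displacement field, and the tests pin only its monotone
effect (the bending energy of `u` never increases with `λ`).

Both images are pre-smoothed with an identical Gaussian
(`presmooth_sigma`, default 1 voxel) before the residual is formed. This
widens the convergence basin for multi-voxel motions; σ = 1 was chosen
because larger kernels measurably degrade sub-voxel accuracy on sharp
trabecular edges while σ = 1 recovers pure translations to ~1e-5 voxels
and interior affine strains to a few hundred με on noiseless phantoms.

Linear systems up to 20 000 unknowns are solved by sparse LU; larger grids
(e.g. NS = 8 on a 160³ volume, 37 044 unknowns) use Jacobi-preconditioned
conjugate gradients (rtol 1e-9), with a direct fallback if CG does not
converge. The matrix is symmetric positive definite by construction.

## Strain differentiation

The grid is restricted by voxel detection — only cells with at least one
node inside the evaluation VOI are kept — and treated as an 8-node
hexahedral mesh. Within a cell the displacement is the trilinear
interpolant of its corner values, so the gradient at a corner reduces to
the three edge differences from that corner divided by the cell side. The
six small-strain components (ε_xx, ε_yy, ε_zz and engineering shears
γ_xy, γ_yz, γ_xz) are evaluated at each corner and averaged over a node's
incident elements, the standard FE nodal averaging. Whether nodal values
should be element-averaged or reported per element is a genuinely open
choice; averaging was selected as it matches what FE packages display at
nodes. Trilinear bases reproduce affine fields exactly, so an imposed
uniform strain tensor is recovered to machine precision — the pipeline's
strongest internal consistency check.

## Error metrics

All variation in a zero-strain pair is error. Reported per specimen and NS:

- random displacement error: SD of each Cartesian nodal displacement
  component, in μm (voxel values × voxel size exactly);
- systematic / random strain error: mean / SD of each signed component;
- MAER and SDER over the per-node mean absolute strain
  `m_k = (1/6) Σ_c |ε_c,k|`.

All SDs use the population (1/N) normalization so that MAER and SDER share
one convention; at the node counts of interest (N ≥ 14) the difference from
1/(N−1) is under 4%.

## SubROI analysis

The vertebral body is partitioned into 27 subROIs: the z-extent of the VOI
bounding box is split into three equal levels (bottom/middle/top), and each
level's in-plane VOI bounding box into 3 × 3 sectors named by the
anatomical convention y+ = anterior, x+ = right (AL, A, AR, L, C, R, PL, P,
PR). Boundary voxels and nodes go to the lower-index band (deterministic
tie-break). A subROI is excluded when its VOI volume is below 1% of the
whole body mask (shell included). Per-subROI strain metrics use the mesh
nodes whose coordinates fall inside the subROI; subROIs with fewer than two
nodes keep their morphometry but report no SDER.

## Morphometry

- BV/TV: bone voxels over VOI voxels, percent.
- St.Th. / St.Sp.: sphere-fitting local thickness of the structure /
  of the background inside the VOI. The thickness at a voxel is the
  diameter of the largest inscribed sphere containing it; implementation is
  the distance-transform construction (EDT → inscribed-sphere radii →
  sphere painting in descending radius order, radii binned at 0.25 voxel),
  which the tests verify against a brute-force sphere-fitting oracle on
  small inputs. A single isolated voxel has diameter 1 voxel. Separation
  spheres are bounded by the VOI as well as by bone, so separations
  truncate at the VOI boundary.
- St.N: the model-free 3D convention (BV/TV)/St.Th in 1/mm, which matches
  the magnitudes of the bundled reference dataset.
- Map statistics are voxel-weighted; spreads use the sample (n−1) SD, the
  convention of the reference tables.

## The synthetic phantom

The generator emulates the study conditions a precision analysis needs,
not vertebral anatomy:

- body: an elliptic cylinder (distinct in-plane semi-axes keep
  principal-axis rigid alignment well posed) with an optional dense shell;
- trabecular network: Gaussian-smoothed white noise thresholded at the
  quantile giving the target BV/TV inside the trabecular VOI (smoothing
  σ = half the mean structure thickness). Defaults: BV/TV 0.15 and
  structure thickness 5 voxels ≈ 195 μm at the 39 μm study voxel size —
  inside the healthy-to-lytic range of the reference dataset (7.4–72.6%,
  St.Th 154–398 μm);
- lesions: lytic spheres resorb trabecular bone to marrow grey; blastic
  spheres become near-uniform bone-grey tissue with internal texture an
  order of magnitude below the noise;
- greyscale: air 0, marrow 60, bone 160 (arbitrary units), additive
  Gaussian noise with SD 8 — a contrast-to-noise ratio ≈ 12, a realistic
  figure for in vivo-grade microCT, chosen because the source protocol
  reports no SNR; `noise_sd` is a free parameter meant to be swept;
- repeat scans: rigid motion about the volume centre (cubic resampling)
  plus fresh independent noise per scan; bubbles as small near-air
  ellipsoids in marrow.

What the phantom does **not** emulate: beam hardening and reconstruction
artifacts, anatomical vertebral shape, endplates, partial-volume blur at
bone–marrow interfaces, and spatially correlated scanner noise. Passing
tests therefore demonstrate the correctness and internal precision of the
pipeline under controlled texture and noise, not the absolute uncertainty
of any particular scanner protocol — which is exactly why the zero-strain
test must be rerun per specimen on real data.

## Preprocessing choices

- Median filter "support 0.5" → radius 0.5 voxel → the minimal 3×3×3
  neighbourhood, preserving 1–2-voxel trabeculae.
- Bone threshold: Otsu on a 256-bin histogram of the VOI, raised by 5%.
- Body mask: Gaussian (variance 5 voxel², support 7), single-level
  threshold (exposed parameter; no reference value exists), hole fill,
  largest component.
- Merged registration mask: intersection of the two scan masks (union
  would let one scan's content be correlated against the other's
  background).
- Evaluation VOI: the body mask shrunk isotropically (Euclidean erosion,
  default 25 voxels = 0.975 mm) to exclude the boundary band where DVC is
  least reliable.
- Rigid alignment: intensity centroid + inertia principal axes of the
  above-median-thresholded volumes, with eigenvector signs oriented for
  small rotations; near-spherical inertia falls back to translation-only.
  An optional Powell MSD refinement exists but is off by default — on
  textured phantoms the moment estimate alone is accurate to well under
  0.2 voxel / 0.2°, and the refinement was found to add error.

## Problem sizes and determinism

The test suite and the acceptance script run phantoms of 48³–160³ voxels
with NS ∈ {8, 16, 32} and 3–5 seeds per stochastic property; these sizes
give stable medians for the NS trend while keeping a full run in minutes
on one CPU. Physical-unit conversions use the study voxel size of 39 μm
throughout (NS 25/50/75/100 voxels ↔ 0.975/1.95/2.925/3.9 mm). Every
random quantity is drawn from `numpy` generators seeded from an explicit
seed; per-specimen seeds derive from a stable hash of the specimen id so
adding a specimen never changes the others' results.

## Known limitations

- The registration similarity is linearized intensity conservation, not
  mutual information; large grey-scale nonlinearities between scans are
  absorbed only to first order by the `s·h` term.
- Very large motions (≫ the texture correlation length) need the optional
  pre-smoothing or an external rigid pre-alignment; there is no multi-grid
  pyramid by default.
- Local thickness radii are binned at 0.25 voxel (quantization error
  ≤ 0.5 voxel in diameter, the tolerance the oracle tests assert).
- Statistical helpers implement exactly the study's designs (two-sided
  Mann–Whitney / Kruskal–Wallis at α = 0.05, OLS with slope t-test);
  no multiple-testing correction is applied, by design.
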