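# Methods

## Overview

`amyshape` implements a radial ("COI distance") shape analysis for small
subcortical structures: binary hemisphere masks become smoothed surfaces,
surfaces become 1000 corresponding radii via a fixed direction lattice, radii
are registered to a group template, and behaviour is tested point-wise with a
covariate-adjusted linear model under FDR and a cluster-extent rule.  A
synthetic cohort generator with closed-form ground truth makes the whole
chain verifiable.

## Surface extraction and smoothing

Masks are zero-padded and triangulated with marching cubes at iso-level 0.5;
vertices map to world millimetres through the voxel-centre affine.  The
largest connected component is kept and the mesh must be watertight.
Smoothing is plain umbrella-weight Laplacian relaxation,
`v ← v + λ(mean(neighbours) − v)`, default `iterations = 10`, `λ = 0.5` —
enough to remove marching-cubes staircase ripple at 1 mm voxels while keeping
shrinkage bounded; both parameters are exposed in the run configuration.
Laplacian relaxation shrinks high-curvature regions: on a digitized
(10, 7, 5.5) mm superellipsoid at 1 mm voxels the post-smoothing radial error
against the continuous shape is ~2–4% (median) and up to ~6% at the
sharpest poles; at 0.5 mm voxels the worst-case error falls below 3%, and the
geometric fidelity tests therefore digitize their analytic solids at
0.25–0.5 mm.  Because the same bias applies to every subject, it cancels out
of between-subject inference.

## Radial parameterization

The center of inertia is the unweighted mean of mesh vertex coordinates (the
area-weighted or volumetric centroid differs by well under 1% for these
shapes; the vertex mean is deterministic and cheap).  Principal covariance
axes are mapped to x > y > z by descending eigenvalue; the sign of each axis
is chosen so the third central moment of vertex coordinates along it is
non-negative, with the most symmetric axis flipped if needed to keep a
proper rotation.  This deterministic rule replaces manual inspection of
alignments; it is reliable only for shapes with a distinct skew along each
axis, which real amygdalae have and the synthetic base shape deliberately
includes.  Near-equal covariance eigenvalues (ratio < 1.01) trigger a
warning, since axis order is then unstable.

"1000 points distributed equally" is realized as a spherical Fibonacci
lattice of unit directions, fixed and deterministically ordered, so point
correspondence is simply direction index.  The radius along a direction is
the distance from the COI to the *farthest* ray–triangle intersection
(Möller–Trumbore, numba-jitted with a numpy fallback); rays crossing the
surface more than once are counted and logged, and a ray with no crossing
(COI not enclosed) is an error.

## Template and registration

The per-hemisphere template is the pointwise arithmetic mean of PCA-aligned
subject radii, built in one pass (no groupwise iteration).  Each subject is
then registered to the template surface by rigid point-to-point ICP:
deterministic moment-based initialization (matched principal axes), then
nearest-neighbour correspondence and Kabsch updates until the RMS
nearest-neighbour distance changes by < 1e-6 mm (max 100 iterations; the
objective is asserted non-increasing).  ICP is rigid only — head size enters
the statistics as the eTIV covariate, not as a registration scale.  The
analysis radii are re-sampled by ray casting the transformed subject mesh
along the template's direction lattice, so correspondence is defined in the
template frame.

### Rigid registration splits focal deformations

A consequence worth knowing when interpreting slopes: a focal radial
expansion of amplitude *A* over a cap also moves the shape's centroid and
its least-squares rigid alignment toward the cap.  Centring plus ICP
therefore absorbs roughly a third to a half of *A* into translation, which
*subtracts* from the measured radii at the cap and *adds* the complement at
the antipode.  In the powered synthetic demonstration the injected
0.08 mm/point coupling appears as a ~0.05 mm/point slope over the patch and
a slightly weaker positive slope in a mirror cluster on the opposite side of
the surface.  Detection and subregion attribution are unaffected (the patch
cluster dominates and sits in the correct subregion), but recovered slope
magnitudes under-estimate the generative amplitude, and mirror clusters
should be interpreted as registration artefacts of a focal effect, not as
independent findings.  This behaviour is intrinsic to COI/ICP radial
methods, not to this implementation.

## Subregion attribution

An atlas is any set of LB/SF/CM probability volumes with a shared affine.
Surface points are mapped back to native space through the inverse of the
stored alignment, then into atlas voxels through a native→atlas affine —
either supplied per subject or estimated deterministically by matching mask
centroids and principal second moments (a stand-in for an external
volumetric registration).  Probabilities are sampled by trilinear
interpolation (nearest-neighbour available as a flag); points outside the
atlas get probability 0 and are counted.  A point's label is the argmax
probability with ties broken LB > SF > CM (ties are measure-zero with
interpolation but possible with synthetic atlases); points with all-zero
probabilities are labelled `none`.  No probability threshold is applied
before the argmax.  Template-level maps average per-point probabilities
across subjects and relabel from the mean.  Tests use a synthetic azimuthal
three-wedge atlas (default split ≈ 50/42/8, mimicking the rough LB/SF/CM
makeup of an amygdala surface); any atlas in the stated NIfTI layout can be
supplied instead.

## Statistics

* **Vertex-wise model.** "Generalized linear model" is realized as
  Gaussian-identity OLS — radii are continuous and no other family is
  implied: `radius ~ intercept + score + age + eTIV`, two-sided *t* test on
  the score term.  Subjects missing the score (e.g. the one subject without
  a symptom total) are dropped for that scale only.
* **Multiplicity.** Benjamini–Hochberg step-up at α = 0.05 over the 1000
  points of one hemisphere × one scale; scales are corrected separately
  (pooling across scales is not implied anywhere and per-scale families keep
  analyses independent).
* **Clusters.** Point adjacency is the spherical Delaunay triangulation
  (convex hull) of the direction lattice; significant components with fewer
  than 15 points are eliminated (a 15-point component survives).  Cluster
  inference re-fits the same model to the per-subject *mean* radius over the
  cluster; displayed values are adjusted mean radii, grand mean + residual
  of `mean radius ~ age + eTIV`.
* **Degenerate fits.** A response constant across subjects is an error; an
  exactly linear response yields the determined coefficient with p = 0 and a
  warning at the cluster/volume level.
* **Score-level tests.** Pearson correlations use pairwise deletion with
  per-pair n reported; zero-variance columns warn and yield NaN.
  Mann–Whitney U uses midranks, exact enumeration when the pooled sample is
  ≤ 20 without ties, otherwise the tie- and continuity-corrected normal
  approximation.  The baseline/follow-up comparison is a random-intercept
  model with one two-level fixed factor on balanced pairs, which reduces
  exactly to the paired *t* test — it is computed in that closed form (and
  cross-checked against an explicit mixed-model fit in the tests).

## Synthetic cohort

The generator encodes the study conditions: 30 male subjects; POMS subscales
drawn as rounded truncated normals with the published means/SDs (tension
8.70 (4.84), depression 5.90 (5.37), anger 7.87 (6.94), fatigue 6.67 (4.79),
confusion 6.10 (4.39), vigor 17.63 (5.57)) truncated at 0 and the 65-item
instrument's subscale maxima — truncation at 0 slightly raises means and
lowers SDs relative to the parent parameters, which is accepted as the
simplest two-moment model; TMD computed by its identity; PCSS zero-inflated
(P(0) = 0.5, else truncated normal mean 5, SD 5, matching a low mean with
many zeros) with one of 30 subjects missing it; concussion counts 0/1/2 with
frequencies 19/6/5 of 30; age 21.69 (1.58) truncated to 18–25; eTIV
1466.89 (200.74) cm³; follow-up subscales for 14 subjects as baseline plus
rounded N(0, 4) shifts.

Masks are rasterized star bodies with radial function
`r(d) = r_se(d)·(1 + Σ s_i d_i³) + A·w(d) + noise(d)` where `r_se` is a
superellipsoid (semi-axes 10, 7, 5.5 mm, exponent 2.2, volume ≈ 1700 mm³,
inside the plausible 1000–2500 mm³ band), the fixed skew `s = (0.08, 0.06,
0.05)` makes PCA alignment well-posed, `w` is a flat-top cap (full amplitude
within 35°, cosine taper to zero at 55°, centred on +x inside the LB wedge;
the plateau covers ≈ 90 of 1000 directions, matching the ~100-point clusters
the method is meant to resolve), `A = beta_true × coupled score` on the
coupled hemisphere only, and the noise is a smooth Gaussian field (48
Gaussian caps, width 0.5 rad, coefficients iid per subject and hemisphere,
row-normalised so every direction's marginal SD is exactly `noise_sd`).
The flat plateau makes the mean radius over the effect directions exactly
`A` on the continuous shape.  Voxels are 1.0 mm isotropic, matching the
emulated acquisition's slice thickness.  Defaults `beta_true = 0.08` mm per
depression point and `noise_sd = 0.2` mm define the powered operating point.
Shapes that stop being star-shaped about their own centroid (checked by ray
casting the analytic surface from its estimated solid centroid whenever the
bump amplitude is large) are rejected with a diagnostic.

What the generator does *not* emulate: segmentation errors and partial
volume effects, anisotropic voxels, spatially varying or heavy-tailed score
distributions, correlated left/right shape noise, and any real
cytoarchitecture — the wedge atlas is geometry, not anatomy.  Passing tests
therefore demonstrate the pipeline's correctness and its operating
characteristics under these idealized conditions, not segmentation
robustness on real scans.

## Calibration

`amyshape.calibration.run_calibration` repeats cohort simulation plus the
full single-hemisphere pipeline.  With the coupling removed the fraction of
cohorts with any surviving cluster estimates the family-wise false-cluster
rate of FDR + extent filtering together (observed 0/40 at seed 1); at the
default operating point, detection is a surviving cluster covering at least
half of the injected plateau directions (observed 20/20) and attribution
compares the detected cluster's dominant subregion with the wedge containing
the patch (observed 20/20).  Run counts (40 null / 20 powered in the shipped
study and the acceptance test) were sized so the whole study completes in a
few minutes on one CPU while leaving the stated thresholds (< 10%, ≥ 80%,
≥ 90%) clearly decidable; each run re-executes the full geometric chain for
30 subjects.

## Numerical and design notes

* Ray casting uses tolerance 1e-9 on barycentric bounds and 1e-12 on the
  determinant; radii are the farthest crossing, so mild non-star-shapedness
  resolves to the outer surface.
* The direction lattice, hull adjacency and noise basis are cached per
  process; all randomness flows through explicit integer seeds
  (`numpy.random.default_rng` with derived keys), so identical configurations
  reproduce outputs bit-for-bit.
* Left and right hemispheres are parameterized independently; no mirroring.
* Whether radii should be re-sampled after ICP or the pre-registration radii
  reused is an open choice; re-sampling was chosen so that correspondence is
  exact in the template frame, and the decision is recorded in run metadata.
* Known limitations: slope attenuation and mirror clusters under rigid
  registration (above); smoothing shrinkage at coarse voxels; the
  moment-based affine is only a similarity-class stand-in for a real
  volumetric registration; the paired comparison assumes balanced complete
  pairs.
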