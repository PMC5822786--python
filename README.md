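# amyshape

Radial shape analysis of subcortical structures, built around the question of
whether local amygdala surface geometry tracks mood in a small imaging cohort
(30 collegiate football players assessed with the Profile of Mood States and
the post-concussion symptom scale).  The package turns per-subject binary
hemisphere masks and a behavioural score table into vertex-wise
shape–behaviour statistics with probabilistic subregion attribution, and
ships a synthetic cohort generator so every stage is testable without any
imaging data.

## The method

For each hemisphere mask the pipeline:

1. extracts a closed triangle mesh by marching cubes and smooths it with
   umbrella-weight Laplacian relaxation,
   `v ← v + λ (mean of neighbours − v)`;
2. centres the mesh at its **center of inertia** (COI, the vertex mean) and
   aligns its principal covariance axes to *x > y > z*, with axis signs fixed
   by the third central moment so alignment is deterministic;
3. samples **1000 corresponding surface points** as ray–surface intersections
   along a fixed spherical Fibonacci lattice; the *radius* `r_j` is the
   distance from the COI to the surface along direction `d_j`;
4. averages radii pointwise across subjects into a **template** and registers
   each subject to it with rigid point-to-point **ICP** (moment-based
   initialization, Kabsch updates), re-sampling radii in the template frame;
5. maps each surface point through a per-subject affine into a probabilistic
   subregion atlas (laterobasal LB / superficial SF / centromedial CM) and
   labels it with the most probable subregion;
6. fits, at every point, the Gaussian GLM
   `r_j ~ β0 + β·score + age + eTIV`, applies Benjamini–Hochberg FDR at
   α = 0.05 over the 1000 points, removes significant components smaller
   than **15 contiguous points**, and regresses each surviving cluster's
   per-subject mean radius on the score (reporting adjusted mean radii,
   i.e. grand mean + residual of `mean radius ~ age + eTIV`).

Score-level statistics (Pearson correlations with pairwise deletion,
Mann–Whitney U between concussion-history groups, and the baseline/follow-up
random-intercept comparison, computed in its closed paired-*t* form) round
out the battery.

The synthetic generator draws cohorts whose scores match the published
means/SDs and whose masks are rasterized star-shaped superellipsoids with a
closed-form radial function: a fixed mild skew (making PCA alignment
well-posed), a flat-top cosine-tapered bump of `beta_true` mm per point of a
chosen score over a chosen surface patch, and a smooth Gaussian field with
exact per-direction SD `noise_sd`.  Ground truth is therefore known in closed
form at every surface point.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1   # cohort + masks + atlas
python analysis/02_shape_pipeline.py  --seed 1   # full shape pipeline
python analysis/03_behavioural_statistics.py     # score-level statistics
python analysis/04_calibration.py     --seed 1   # operating characteristics
```

With seed 1 the pipeline prints:

```
pipeline completed in 5.52 s (30 subjects x 2 sides, 1000 points each)
surviving clusters (FDR q<0.05, extent >= 15):
side           scale  size   beta      t   p dominant_subregion
left poms_depression   212 0.0500 5.8867 0.0                 LB
left poms_depression   202 0.0472 5.6335 0.0                 SF
```

The generator coupled the left hemisphere's surface to the depression
subscale (0.08 mm/point over a laterobasal patch).  The pipeline finds a
212-point left-hemisphere cluster over that patch, attributed to LB, with a
cluster-level slope of 0.050 mm per depression point; no other scale and no
right-hemisphere analysis yields a surviving cluster.  The second, antipodal
cluster (dominant SF) is the mirror image that rigid registration of a
focal radial deformation necessarily produces — measured slopes split
between the deformed patch and its antipode (see `docs/methods.md`).  The
calibration study reports a 0/40 false-cluster rate on null cohorts and
20/20 detection with 20/20 correct attribution at the default operating
point.

The same stages are available as a CLI (`amyshape simulate|extract|
parameterize|map-atlas|stats|all`) for use on real mask/score data.

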