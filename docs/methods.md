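# Methods

## The measurement model

A posture observation is one photograph reduced to k = 30 ordered 2D
points along the dorsal outline, caudal → rostral (tail head → croup →
back → withers → neck → head).  Nuisance acting on the raw coordinates:
camera position/zoom/tilt (a similarity transform), the balance
movement of the neck (a rigid rotation of the neck/head subset about
its articulation with the back), the arbitrary along-curve spacing of
digitized outline points, and digitization noise.  Signal of interest:
everything that remains — chronic postural shape, which may differ
between populations (riding schools) and between individuals (horses,
each photographed repeatedly).

The pipeline removes each nuisance with a dedicated, order-fixed step:

1. **Derotation** (optional, raw coordinates): the signed angle at the
   triple (point 1, vertex 15, point 30) is set to a common reference
   by rigidly rotating points 16..30 about point 15.  The reference
   defaults to the circular mean of the measured angles over the
   sample (pooled across contexts), so the mean posture is unbiased;
   only the articulation *variance* is removed.  Derotation precedes
   superimposition and sliding so the sliding reference is free of
   articulation nuisance.
2. **Generalized Procrustes analysis**: each configuration is
   centered, scaled to unit centroid size (partial Procrustes, the
   dominant convention; full-Procrustes residual scaling is an
   option), and rotated to the consensus, iterating consensus ↔
   rotations from a first-configuration start until the RMS consensus
   change is below 1e-8 (max 100 iterations).  In 2D the optimal
   rotation is closed-form (atan2 of cross- and dot-products), so the
   fit is vectorized over specimens.  Reflections are never fitted:
   photographs are normalized to one facing direction beforehand (the
   reader can mirror flagged specimens; mirroring negates x, an exact
   involution).
3. **Semilandmark sliding**: sliders move along the chord through
   their two neighbours (one-sided chord at outline ends), by amounts
   t minimizing the bending energy dᵀBd of the deformation from the
   consensus, B being the TPS bending-energy matrix of the consensus.
   The joint solve over a specimen's sliders is one m × m linear
   system (m = number of sliders).  Passes alternate with re-GPA and
   an updated consensus (a flag freezes the first consensus instead);
   iteration stops when RMS slider movement < 1e-6 shape units, at 10
   passes, or as soon as a pass fails to lower the total bending
   energy — the re-superimposition noise floor — so the recorded
   energy trace is non-increasing by construction.  A
   minimum-Procrustes-distance criterion is available behind a flag
   for comparison.  Linearized tangents mean sliders are not
   re-projected onto a fitted curve; consequently a re-spacing of the
   digitized points *shared by every specimen* is unidentifiable, and
   only specimen-to-specimen spacing arbitrariness is removed (the
   test suite demonstrates both sides).
4. **Shape PCA**: SVD of the centered n × 2k matrix of aligned
   coordinates; at most min(n − 1, 2k − 4) components (the
   superimposition removes 4 degrees of freedom).  Sign convention:
   the largest-magnitude entry of each loading is positive.  Retention
   keeps the leading components with ≥ 10% of total variance,
   stopping at the first failure and capped at three for the
   comparison tables.  PC extremes are reconstructed as consensus +
   s·loading at the observed score extrema and rendered as TPS
   deformation grids (24 × 24 lattice over the consensus bounding box
   + 15% margin, emitted as coordinates; plotting is left to the
   caller).
5. **Mixed ANOVA**: per retained PC and recording context, the score
   of each photograph is modelled with a fixed factor and a random
   horse intercept, fitted by REML (statsmodels MixedLM).  The
   factor's F is the Wald quadratic form on its treatment-coded
   coefficients divided by df_num; the denominator df follows the
   containment rule for a horse-level factor, n_horses − df_num − 1.
   On balanced designs this coincides with the exact one-way ANOVA on
   per-horse means, which is provided as a cross-check mode.  Age
   enters as a single-df continuous covariate; p-values are read at
   the 5% level with no multiplicity correction (a flag exists).

## Method variants

Three point schemes ship with the package: `landmarks` (9 anatomical
points treated as fixed landmarks — the seven clay-mark positions,
the medial eye canthus and the mid-neck point, selected from the 30
digitized points via the scheme's `active` list), `mixed` (8 fixed
landmarks + 22 sliders) and `ssl` (1 fixed landmark + 29 sliders).
Named subsets restrict a scheme to the croup+back (points 1–15) or
neck+head (points 15–30); subsetting re-derives slider triples, making
boundary sliders one-sided.  The standard comparison runs nine
variants: landmarks, and {ssl, mixed} × {dorsum, derotated dorsum,
croup+back, neck+head}.  The exact outline indices of the clay marks
are not knowable from the source material at single-point resolution;
they are a documented template choice in the scheme files and fully
user-configurable.

## The synthetic generator

Real photographs of the field study are not available, so the
generator emulates its design: 11 schools × 8 horses × (10 standing +
20 walking) photographs (defaults).  The template outline is a
closed-form profile — Gaussian croup rise (height 0.18), back hollow
(depth 0.08) and withers peak (0.10) over a back of length 1.4,
followed by quadratic neck and head arcs — sampled at 30 points with
the articulation vertex at point 15.  Per photograph, the template
receives, in order: a school offset (a smooth bump confined to a named
region, default the back, with per-school coefficients graded evenly
over [−amplitude, +amplitude], amplitude 0.02); a per-horse smooth
random effect (sd 0.01 on three region bumps); a deterministic −8°
neck drop in the walking context; a neck-rotation nuisance N(0, 15°)
about the vertex; digitization noise N(0, 0.005) per coordinate; and a
camera similarity jitter (rotation sd 2°, log-scale sd 0.05, shift sd
0.05).  Shape scales are in template units (template centroid size
≈ 3.8): digitization noise ≈ 0.1% of size, individual effects about
twice that, school effects of the same order as individual ones —
subtle effects that the pipeline must recover, not hand it.  Covariates
(sex 50:35 gelding:mare, age 7–20, equid type 40:60 pony:horse,
proportions 20:60:20) are sampled for interface realism and carry no
shape effect unless injected.  All draws flow from one NumPy PCG64
generator seeded by `SimulationParams.seed`.

What the generator does **not** emulate: perspective distortion,
biomechanical coupling between neck and back (bow-and-string),
unbalanced designs (real schools had 1–13 horses), digitizer drift, or
outline self-occlusion.  Passing tests therefore certify the
algorithms and their statistical calibration, not field performance on
photographs.

## Verification experiments and problem sizes

* Pairwise Procrustes fits are checked against a brute-force
  0.001-radian rotation grid with per-angle optimal scale/translation
  (50 random 8-point pairs).
* The mixed-ANOVA null calibration simulates scores directly at the
  study design (11 × 8 × 10, horse sd = photo sd, no school effect),
  500 replicates; the 5%-level rejection rate must lie in
  [0.03, 0.07].
* The paired derotation experiment runs the full ssl dorsum pipeline
  twice per replicate (derotation on/off) on fresh datasets at the
  standing design (11 schools × 8 horses × 10 photographs, 15°
  nuisance), 50 replicates; the derotated arm must show the larger
  PC1 school F in ≥ 80% of pairs.
* Report determinism and the remaining identities run on small
  simulated sets (tens of specimens), where the quantities are exact.

These sizes were chosen so each experiment is statistically meaningful
yet completes in minutes on one CPU.

## Numerical choices

* TPS kernel U(r) = r² log r², U(0) = 0; the k = 3 bending-energy
  matrix is returned as exact zeros (three points admit only affine
  warps).  Ill-conditioned systems (condition number > 1e12, e.g.
  collinear references) either raise or, with `regularize=True`, take
  a 1e-8 kernel ridge plus pseudoinverse — logged, never silent.
* Procrustes distance is computed by explicit optimal rotation rather
  than 2 − 2·cov, avoiding catastrophic cancellation near zero.
* Sliding solves add a 1e-12 ridge before the batched solve and fall
  back to least squares for singular tangent systems.
* Angles are treated circularly (the resting neck angle sits near the
  ±180° wrap): sample references use the circular mean.
* Convergence failures warn and flag the result (`converged=False`);
  CLI exit code 3.

## Known limitations

* 2D only; no missing-landmark estimation; no curve re-fitting for
  slider projection.
* The containment denominator df is one convention among several for
  mixed-model F tests; alternatives (Satterthwaite, Kenward-Roger)
  are not implemented.  On the balanced designs analysed here the
  containment F is exact.
* Derotation by a measured three-point angle transfers that angle's
  measurement noise to the whole rotated subset; with no articulation
  nuisance present it can slightly reduce power (no systematic gain —
  verified in the tests), so it should be switched on only when the
  articulation is a real nuisance.
* The percent-variance and F tables of the original field study are
  not reproducible from first principles (its photographs are not
  public); validation is property- and simulation-based throughout.
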