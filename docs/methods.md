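# Methods

This note documents the models, conventions and numerical choices behind
`crestcurve`, in the order the pipeline applies them.

## Synthetic crest curves

The generator does not attempt to model tibial anatomy; it produces the
*minimal* parametric family that reproduces the qualitative structure a
diachronic crest-curvature study rests on. For arc parameter s ∈ [0, 1]:

    x(s) = A · sin(π s^p)     anterior–posterior bow, amplitude A (mm)
    y(s) = M · sin(2π s)      medio-lateral sigmoid, amplitude M (mm)
    z(s) = −L · s             proximo-distal run, chord length L (mm)

The single-period sine in y encodes the laterally concave-then-convex
course of the crest down the shaft. The apex-shift exponent p (default
0.8) moves the bow apex into the proximal half of the shaft, where
diachronic change concentrates; p = 1 gives a symmetric bow.

Per specimen, (A, M, L) are truncated-normal draws around the group means
(redrawn while ≤ 0, avoiding the point mass at zero that clipping creates),
with additive (A, M, L) offsets for males. The curve is emitted as a dense
polyline with a point count drawn uniformly from [1,800, 2,000] and
independent isotropic Gaussian noise per point.

**Default design.** Seven chronological groups with sample sizes
46/79/30/103/57/64/56 (male counts 24/32/20/58/37/33/29; total 435). The
A–P bow declines 8.0 → 4.0 mm across groups, the M–L sigmoid accentuates
2.0 → 5.0 mm, mean lengths sit near 355 mm with the 20th-century group
shortest (350) and the 21st-century group longest (360); between-specimen
SDs are 1.0 / 0.8 / 15 mm and the male offsets are (+0.4, +0.3, +28) mm.
These amplitudes are synthetic configuration values chosen once to produce
the qualitative diachronic contrast at a realistic anatomical scale — they
are *not* estimates of any real population, and no attempt is made to
calibrate them so that the pipeline reproduces any published table
cell-by-cell.

**Digitization noise: 0.05 mm.** With ~0.19 mm point spacing, independent
per-point noise much larger than the spacing turns the polyline into a
fractal scribble whose chord-sum arc length is grossly inflated (0.5 mm
noise inflates it ~6×) and drives repeat-digitization reliability toward
zero. 0.05 mm is at the scale of optical-digitization repeatability and
places the simulated repeat study in the 0.95–1.0 reliability zone — the
regime a usable digitization protocol must occupy. Even at 0.05 mm the
chord-sum length carries a small systematic inflation (~20%); it is
common to all specimens and harmless to the shape analysis, but absolute
curve lengths from noisy dense polylines should be read with that in mind.

What the generator does *not* emulate: bone surface geometry (only curves),
digitizer drift or operator bias (noise is zero-mean i.i.d.), asymmetric or
multi-modal group distributions, and correlated noise along the curve.
Passing tests therefore demonstrate the correctness and calibration of the
*pipeline*, not properties of real skeletal samples.

## Resampling

Semilandmark j (j = 0..19) is placed at arc-length fraction j/19 of the
piecewise-linear source polyline, by linear interpolation inside the
containing segment; endpoints (the two anatomical anchors) are preserved
bit-exactly, and consecutive duplicate points are collapsed first. No
spline smoothing: at ~1,900 points the chordal error is negligible, and
the operator stays simple and deterministic. Note that re-resampling the
20-gon itself is *not* exactly idempotent — the 20-gon's chord lengths are
unequal wherever curvature varies, so points shift at second order in
(curvature × gap), about 10⁻² mm on a 355 mm curve. The caliper ("book")
length of a mesh vertex cloud is the exact point-set diameter, computed
over convex-hull vertices with a brute-force fallback for degenerate
clouds; for an elongated bone the diameter direction coincides with the
osteometric long axis.

## Superimposition

GPA operates on centered, unit-centroid-size configurations and removes
orientation only (rotation-only GPA): each shape is rotated to the
evolving consensus (the normalized coordinate-wise mean) until the relative
change of the total Procrustes sum of squares falls below 1e-10 or 100
iterations. Rotations come from the SVD solution constrained to det +1;
reflections are never allowed.

Sliding uses the sample consensus as target (the alternative — a fixed
reference specimen — is left as an extension point). Each pass recomputes
interior tangents by central difference from the current coordinates,
moves each interior point by the closed-form 1D projection of its residual
onto the tangent (exact for the linearized objective), then re-runs GPA
and updates the consensus. Passes stop when the relative SS decrease is
below 1e-8, after 10 passes, or as soon as a pass fails to improve the
objective (that pass is reverted), which makes the logged objective
non-increasing by construction. Points whose neighbours coincide (zero
tangent) skip sliding for that pass and are counted in a warning.

Because any Procrustes alignment is only defined up to a global rotation,
the converged sample is rotated into a canonical anatomical pose —
anterior bow along +x, proximo-distal axis along −z, derived from the
consensus — so results are invariant to the arbitrary coordinate frames
the inputs were digitized in. For bow-free (collinear) consensus shapes
the pose is ambiguous and the GPA orientation is kept as-is.

Scale note: unit centroid size standardizes scale *inside* the shape
analysis; the allometry size variable is the curve arc length in mm,
carried through untouched.

## Shape statistics

- **PCA** is the SVD of centered flattened coordinates; components with
  numerically zero variance are dropped; signs follow a deterministic
  convention (largest-magnitude loading element positive).
- **Broken stick**: retain the leading run of components whose variance
  fraction strictly exceeds b_j = (1/p) Σ_{i=j..p} 1/i, with p the number
  of positive-variance components. Group tests run on max(1, retained)
  scores — a null sample can retain zero components, and testing at least
  PC1 keeps the test defined; an `n_pcs` override exists for sensitivity
  analysis.
- **Permutation Hotelling**: the observed and permuted statistics are
  computed from the label-invariant total scatter T via the identity
  W = T − (n₁n₂/n) dd′ and Sherman–Morrison, which reduces each
  permutation to one quadratic form; equality with the textbook formula is
  asserted in the test suite against an independently coded oracle.
  Perfect separation maps to +∞ and counts as exceeding. p-values use the
  add-one convention and never return 0. Singular scatter matrices fall
  back to the largest leading invertible variable subset, with a warning.
  Because PCA and the broken-stick choice depend only on the pooled
  sample, they commute with label permutation and the test stays exact —
  the type-I acceptance test verifies this empirically through the whole
  pipeline.
- **Per-cell seeds** derive from the master seed and the pair of group
  labels (CRC-keyed), so adding or removing a group leaves other cells'
  p-values untouched.
- **Allometry** is a per-stratum, per-retained-PC simple linear regression
  of score on curve length with the standard ANOVA F = R²(n−2)/(1−R²) on
  (1, n−2) df; strata with constant length report NaN. No multivariate
  Procrustes regression is attempted.
- **No multiple-testing correction** is applied across pairwise cells by
  default (raw p-values are reported, as is conventional for these
  matrices); Bonferroni/Holm can be applied downstream by the caller.
- **Reliability**: repeats of all specimens are jointly superimposed
  (GPA + sliding). Per specimen and semilandmark, the error is the RMS 3D
  deviation norm around the repeat mean (n−1 denominator); averaging over
  specimens then semilandmarks gives ME, and the same convention applied
  to specimen means around the grand mean gives SD. σ_xx′ = 1 − ME²/SD²,
  clipped to [0, 1]; zero between-specimen variance yields NaN. The
  formula is chosen over alternatives because it lives on [0, 1], equals 1
  at zero error, and makes a ≥ 0.95 acceptability threshold meaningful.

## Difference fields and ellipses

Group means are coordinate-wise averages of aligned shapes. The anatomical
frame is estimated from a mean curve: proximo-distal axis from first to
last semilandmark; anterior axis = the component, orthogonal to it, of the
displacement of the arc-length midpoint from the chord midpoint (the bow
direction defines "anterior"); medio-lateral axis completes the
right-handed triad. The pooled-consensus frame is shared across all group
comparisons so fields are commensurable. "Medial view" projections pair
the anterior and proximo-distal components; "anterior view" pairs the
medio-lateral and proximo-distal components. Which anatomical direction
the positive axes correspond to on real bones is a convention that cannot
be fixed from synthetic data; the frame is deterministic and documented,
nothing more. Score-space ellipses scale the group covariance by the
χ²₂ quantile at the coverage level (default 0.70).

## Problem sizes used in the validation suite

The test suite and acceptance script size their simulations to what the
statistics require, not more: 500 datasets × 40 specimens for type-I
calibration (B = 1,000; the binomial 99% band around 0.05 is then
±~0.022), 20 replicates of the extreme-pair power check, exhaustive
enumeration at n = 3 + 3 for permutation-test equivalence, and 15 × 3
repeat digitizations for reliability. Defaults for a real analysis remain
B = 10,000 and α = 0.05.

## Known limitations

- The parametric curve family has three effective shape dimensions, so
  synthetic PCA spectra are far more concentrated than real crest data.
- Sliding is capped at 10 passes; on noisy samples the objective is still
  decreasing slowly at the cap (relative steps ~1%), which is accepted —
  the optimum is flat and downstream statistics are insensitive to it.
- The pipeline's length-test matrix uses curve arc length; maximal caliper
  length from mesh vertices is available (`max_caliper_length`) but the
  generator produces no meshes.
- Straight (bow-free) curves have no defined anatomical frame; such
  samples keep their GPA orientation and difference-field projections
  require an explicit frame.
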