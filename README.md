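# crestcurve

3D sliding-semilandmark analysis of anterior tibial crest curvature.

Bioarchaeological work links the gradual decline of lower-limb loading —
from agricultural intensification through urbanization to industrialized
life — to changes in long-bone geometry. `crestcurve` implements the full
analytical chain used to ask that question of the tibia's anterior crest:
densely digitized 3D curves (one per bone, proximal tuberosity to medial
malleolus) are reduced to 20 equidistant semilandmarks, superimposed by
generalized Procrustes analysis with tangent sliding, and compared across
chronological groups with permutation tests, PCA, allometry regressions,
and per-semilandmark mean-shape difference fields. A synthetic-data
generator reproduces the diachronic structure such a study assumes
(declining anterior–posterior bow, accentuating medio-lateral sigmoid,
sex and size variation, digitization noise), so the entire pipeline runs,
and is tested, with no access to skeletal collections.

## The method

Given curves resampled to *k* = 20 semilandmarks:

- **Superimposition.** Each configuration is centered and scaled to unit
  centroid size; orientations are removed by iterative least-squares
  rotation to the evolving consensus (GPA). Interior semilandmarks then
  slide along their local tangent `t_i = unit(p_{i+1} − p_{i−1})` by the
  projection of `(consensus_i − p_i)` onto `t_i` — Procrustes-distance
  minimization, not bending energy — with the two anatomically anchored
  endpoints fixed; sliding and re-superimposition alternate until the
  total Procrustes sum of squares stabilizes. Rotations are proper
  (det +1): the sample contains a single side, so reflections are never
  legitimate.
- **Inference.** Aligned coordinates are decomposed by PCA; the number of
  shape variables is fixed by the broken-stick criterion
  `b_j = (1/p) Σ_{i=j..p} 1/i`; group pairs are compared on the retained
  scores with a permutation two-sample Hotelling test,
  `T² = (n₁n₂/(n₁+n₂)) d′ S_pooled⁻¹ d`, `p = (1 + #{T²* ≥ T²}) / (B+1)`,
  B = 10,000 by default, α = 0.05. Scalar size (curve length) is compared
  with two-sided permutation tests on mean differences.
- **Error study.** Repeat digitizations are jointly superimposed; the
  per-semilandmark repeat SD (ME) and the between-specimen SD on the same
  scale give the reliability coefficient `σ_xx′ = 1 − ME²/SD²`, judged
  against a 0.95 acceptability threshold.
- **Difference fields.** Group mean shapes are subtracted semilandmark by
  semilandmark; vectors are projected into the medial-view (A–P ×
  proximo-distal) and anterior-view (M–L × proximo-distal) planes of an
  anatomical frame estimated from the pooled consensus.

## Worked example

```python
import crestcurve as cc

config = cc.RunConfig(design=cc.default_study_design(),
                      out_dir="run", n_permutations=10_000, seed=1)
bundle = cc.run_study(config)
print(bundle.manifest["groups"])
print(bundle.shape_tests.to_dataframe().to_string())
```

prints the seven simulated chronological groups (435 specimens in total)

```
{'eneolithic': 46, 'bronze_age': 79, 'iron_age': 30, 'early_medieval': 103,
 'late_medieval': 57, '20th_century': 64, '21st_century': 56}
```

and the lower-triangular matrix of permutation p-values for pairwise shape
differences, with `*` flagging significance at α = 0.05:

```
               eneolithic bronze_age  iron_age early_medieval late_medieval 20th_century
bronze_age        0.006 *
iron_age         <0.001 *   <0.001 *
early_medieval   <0.001 *   <0.001 *   0.002 *
late_medieval    <0.001 *   <0.001 *  <0.001 *       <0.001 *
20th_century     <0.001 *   <0.001 *  <0.001 *       <0.001 *      <0.001 *
21st_century     <0.001 *   <0.001 *  <0.001 *       <0.001 *      <0.001 *     <0.001 *
```

Under the default synthetic design every group differs in its generative
bow/sigmoid amplitudes, so with these sample sizes almost all pairs
separate; temporally distant pairs saturate at the minimum attainable
p = 1/(B+1). The run directory also receives the semilandmark table, the
aligned sample (`aligned.h5`), PCA and allometry summaries, the curve-length
test matrix, difference-field CSVs for the extreme and adjacent
comparisons, PC1–PC2 ellipse specs, and a manifest with the config hash and
seed for reproduction.

The same pipeline is scriptable from a shell:

```sh
crestcurve simulate --out data/ --seed 1
crestcurve resample --in data/ --meta data/metadata.csv --out marks.csv
crestcurve align    --in marks.csv --out aligned.h5
crestcurve stats    --aligned aligned.h5 --meta marks.csv --seed 1 --out report/
crestcurve run      --out bundle/ --seed 1          # everything at once
```

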