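# couplemap

Microstructure–function coupling analysis for cortical parcellations.

`couplemap` implements a compact, fully tested pipeline for studying how
cortical microstructure relates to functional connectivity:

1. **Equivolumetric depth sampling** (`couplemap.equivolume`) — place
   intracortical surfaces at depths that preserve equal volume fractions
   between non-parallel inner/outer boundaries, and sample depth-wise
   intensity profiles on them.
2. **Connectome construction** (`couplemap.connectomes`) — microstructure
   profile covariance (**MPC**: parcel-pair partial correlation of depth
   profiles, controlling for the cortex-wide mean profile) and functional
   connectivity (**FC**: Fisher-z transformed timeseries correlation), with
   group aggregation.
3. **Row-wise coupling** (`couplemap.coupling`) — per-parcel Spearman
   correlation between MPC and FC rows, summarized by cytoarchitectonic class
   (idiotypic → unimodal → heteromodal → paralimbic).
4. **Twin heritability** (`couplemap.heritability`) — AE variance-component
   model for MZ/DZ twin cohorts via profile likelihood, with a boundary-aware
   likelihood-ratio test and rank-based inverse normal transform.
5. **Gradients** (`couplemap.gradients`) — diffusion-map embedding of
   thresholded, normalized-angle affinity matrices, Procrustes alignment, and
   MPC-vs-FC gradient difference maps.
6. **Spatial nulls** (`couplemap.spatial_null`) — spin permutation test for
   correlations between parcel-level cortical maps, respecting hemispheres and
   spatial autocorrelation.
7. **2-D decoding** (`couplemap.decoding2d`) — quadrant assignment in a
   two-axis embedding, chi-squared quadrant comparisons, and weighted-mean
   term ranking along binned axes.
8. **Synthetic cohorts** (`couplemap.synthetic`) — a seeded generative model
   (toy spherical cortex, laminar profiles on a sensory-fugal hierarchy,
   microstructure-coupled timeseries, twin cohorts with known heritability)
   used for end-to-end validation.

## Worked example

Simulate a small cohort, build group MPC and FC matrices, and summarize
microstructure–function coupling by cortical class:

```python
import numpy as np
from couplemap.synthetic import GenerativeSpec
from couplemap.pipeline import run_coupling_pipeline, idiotypic_vs_heteromodal

res = run_coupling_pipeline(GenerativeSpec(seed=0), n_subjects=8)
print(res.summary.round(3))
t, p = idiotypic_vs_heteromodal(res.coupling, res.cortex.atlas)
print(f"t = {t:.2f}, p = {p:.2e}")
```

Output:

```
              mean     sd   n
class
idiotypic    0.888  0.026  25
unimodal     0.861  0.033  25
heteromodal  0.758  0.052  25
paralimbic   0.750  0.055  25
t = 11.22, p = 1.37e-12
```

Coupling is strongest in idiotypic (primary sensory/motor) cortex and weakest
in paralimbic cortex, recovering the generative gradient.

Gradients and the MPC−FC gradient difference, with a spin test against the
coupling map:

```python
from couplemap.pipeline import gradient_delta
from couplemap.spatial_null import spin_test_correlation

delta, g_mpc, g_fc = gradient_delta(res.mpc, res.fc, atlas=res.cortex.atlas)
print("lambda_mpc:", np.round(g_mpc.eigenvalues[:3], 3))
print("mean |Delta G1| =", round(float(np.mean(np.abs(delta))), 3))

sp = spin_test_correlation(res.coupling, delta, res.cortex.atlas,
                           n_perm=1000, seed=0)
print(f"rho = {sp.observed:.3f}, p_spin = {sp.p_spin:.4f}")
```

Output:

```
lambda_mpc: [0.069 0.064 0.051]
mean |Delta G1| = 0.425
rho = -0.131, p_spin = 0.0859
```

Twin-based heritability of a simulated phenotype with true h² = 0.6:

```python
from couplemap.synthetic import simulate_twin_cohort
from couplemap.heritability import fit_ae

cohort = simulate_twin_cohort(n_mz_pairs=200, n_dz_pairs=200,
                              n_singletons=50, h2_true=0.6, seed=42)
fit = fit_ae(cohort.phenotypes.iloc[:, 0], cohort)
print(f"h2 = {fit.h2:.3f} (SE {fit.se_h2:.3f}), p = {fit.p_value:.2e}")
```

Output:

```
h2 = 0.589 (SE 0.041), p = 3.06e-24
```

Equivolumetric depths for a patch whose outer boundary has three times the
inner boundary's area (surfaces crowd toward the smaller inner surface):

```python
from couplemap.equivolume import equivolumetric_fraction, make_fraction_grid
print(np.round(equivolumetric_fraction(1.0, 3.0, make_fraction_grid(5)), 4))
# [0.2638 0.4574 0.618  0.7583 0.8844]
```

## Command line

Every stage is also exposed through the `couplemap` CLI:

```bash
couplemap simulate --out cohort/ --seed 1 --n-subjects 8
couplemap mpc  --subjects-dir cohort/ --out mpc.tsv
couplemap fc   --subjects-dir cohort/ --out fc.tsv
couplemap coupling --a mpc.tsv --b fc.tsv --atlas cohort/atlas.csv --out coupling.csv
couplemap gradients --matrix mpc.tsv --n-components 5 --out gradients.csv
couplemap spin --map-a coupling.csv --map-b coupling.csv --atlas cohort/atlas.csv --n-perm 1000 --seed 0
couplemap herit --pheno cohort/phenotypes.csv --pedigree cohort/pedigree.csv --out h2.csv
```

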