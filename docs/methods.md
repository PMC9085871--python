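# Methods

This document records the modeling assumptions, numerical choices, and known
limitations behind `couplemap`. Empirical figures quoted here were computed
with this package (`scripts/acceptance.py --seed 0` and the acceptance tests);
nothing below is asserted without having been run.

## 1. Equivolumetric depth sampling

`equivolumetric_fraction(area_inner, area_outer, alpha)` maps a cumulative
volume fraction `alpha` to a depth coordinate `rho` via

```
rho = (-A_in + sqrt(alpha * A_out^2 + (1 - alpha) * A_in^2)) / (A_out - A_in)
```

with the equal-area limit `rho = alpha` taken analytically when
`|A_out - A_in| <= 1e-9 * max(A_in, A_out)` to avoid catastrophic
cancellation.

**Geometry assumed.** The formula corresponds to a column whose
cross-sectional area varies *linearly* in the depth coordinate, from `A_in`
at `rho = 0` to `A_out` at `rho = 1`; `alpha` is the volume fraction
accumulated from the `A_in` side. Under that model the cumulative volume up
to `rho` is proportional to `A_in*rho + (A_out - A_in)*rho^2/2`, and
inverting it gives the expression above. Surfaces therefore crowd toward the
smaller bounding surface (at half volume with `A_in = 1`, `A_out = 3`,
`rho = 0.618`). The default fraction grid `k/(n+1), k = 1..n` is symmetric,
so the orientation convention does not change which set of surfaces is
produced.

**Numerical behavior** (computed): maximum deviation from the equal-area
limit at a relative area difference of `1e-6` is `1.3e-7`; the function is
strictly monotone in `alpha` on a 101-point grid for increasing, decreasing,
and equal areas.

## 2. MPC and FC construction

- **MPC** (`mpc_subject`): parcel-pair partial correlation of mean depth
  profiles, controlling for the cortex-wide mean profile. Implemented from
  the closed-form partial-correlation identity; verified against an
  independent oracle that regresses the mean profile out of each parcel
  profile by OLS and correlates residuals (max abs. difference `1.9e-15`
  over 100 random instances). Negative values are retained; the diagonal is
  zeroed. Group MPC is the element-wise mean of subject matrices.
- **FC** (`fc_subject`): Pearson correlation of parcel timeseries,
  Fisher-z transformed with correlations clipped to `1 - 1e-7` in magnitude
  so `atanh` stays finite. Group FC averages subject z-matrices.

Both require at least 3 depths/timepoints and raise on constant inputs
rather than silently emitting NaN.

## 3. Row-wise coupling

Per-parcel Spearman correlation between corresponding off-diagonal rows of
MPC and FC (the diagonal entry is excluded from both rows). Rows with zero
variance yield NaN with a warning. Class summaries report mean, SD (ddof=1),
and n per cytoarchitectonic class; the idiotypic-vs-heteromodal contrast is a
Welch t-test.

## 4. Twin AE model

`fit_ae` / `TwinAE` fit the classical AE variance decomposition
(`sigma_A^2 + sigma_E^2`; no shared-environment C term) to MZ/DZ twin data:

- Phenotypes are rank-based inverse-normal transformed by default
  (`Phi^{-1}(rank / (n + 1))`), making the Gaussian likelihood assumption
  mild but discarding scale information.
- Fixed effects: intercept, centered age, sex, age², age×sex.
- The kinship structure is block diagonal (pairs + singletons), so the model
  is fit by rotating each pair to independent sum/difference coordinates and
  profiling the likelihood over `h2` with weighted least squares; `h2` is
  optimized on the logit scale by BFGS from multiple starts (0.1, 0.5, 0.9)
  plus explicit boundary evaluation.
- The test of `h2 = 0` is a boundary LRT with the 50:50 mixture reference
  `p = 0.5 * P(chi2_1 >= LR)` (p = 1 when LR <= 0). The standard error is a
  numerical profile curvature and is reported as NaN on the boundary.

**Assumptions**: no C component (MZ/DZ covariance ratio exactly 2), no
assortative mating, no gene–environment interaction, homoscedastic residuals.
Falconer's moment estimator `2(r_MZ - r_DZ)` is used as an internal
cross-check in tests, not as the estimator.

**Computed calibration** (seed 0): mean estimates 0.205 / 0.498 / 0.800 at
true h² = 0.2 / 0.5 / 0.8 (500+500 pairs); LRT type-I error 0.025–0.06
across seeds at nominal 0.05 (1000 replicates in the acceptance test give
rates inside [0.03, 0.07]).

## 5. Diffusion-map gradients

- Affinity: row-wise top-decile thresholding (entries at or above the
  per-row 90th percentile are kept), then normalized-angle similarity
  `1 - arccos(corr)/pi` of thresholded rows.
- Embedding: anisotropic diffusion-map normalization with `alpha = 0.5`
  (`W' = D^-a W D^-a`), symmetric conjugation, dense `eigh`, trivial
  eigenvector removed. At `diffusion_time = 0` components are scaled
  "multiscale" by `lambda / (1 - lambda)`; at `t > 0` by `lambda^t`.
- Degenerate leading eigenspaces (disconnected thresholded graphs) are
  handled by pinning the exact trivial eigenvector and rotating the
  remaining degenerate directions into its orthogonal complement; the
  default policy embeds the whole graph, with `on_disconnected="largest"`
  as an alternative that NaN-fills the complement of the largest component.
- Sign convention: each component's largest-magnitude entry is made
  positive, which gives permutation equivariance up to that convention.
- Verified against a dense non-symmetric eigendecomposition of the Markov
  operator: eigenvalue error `9.7e-16`, subspace angle `2.4e-13` over 20
  random 50-node affinities (computed).

Alignment uses orthogonal Procrustes (rotation/reflection only, no scaling)
after z-scoring each component; standardizing before alignment keeps
components with closely spaced eigenvalues comparable across matrices. The
gradient-difference map applies one **joint** sign orientation to both
aligned first gradients (driven by the FC reference's idiotypic mean) so that
near-zero statistics cannot be inflated by independent per-map sign flips.

## 6. Spin test

Parcel centroids live on two unit hemispheres (the toy right hemisphere is
the x-mirrored left). Each permutation applies one uniform random rotation
(QR-based Haar sampling) to the left hemisphere and its mirrored version to
the right, then reassigns parcels within each hemisphere by greedy
nearest-first one-to-one matching. The p-value uses the permutation
convention `p = (1 + #{|null| >= |obs|}) / (1 + n_perm)`, so a degenerate
identity rotation table returns exactly 1.

**Computed calibration**: on 200 pairs of independent smooth maps
(100-parcel toy cortex, Gaussian-process maps with length scale 0.3), the
rejection rate at alpha = 0.05 is 0.045.

## 7. 2-D decoding

- Quadrants are defined on z-scored axes (sign of each standardized
  coordinate); parcels with NaN on either axis are left unassigned.
- Quadrant count comparisons use the Pearson chi-squared test without
  continuity correction (`[60,40]` vs `[40,60]` gives exactly 8.0).
- Term ranking sorts parcels along an axis (stable lexsort, ties broken by
  parcel index), splits them into `n_bins` nearly equal bins, shifts bin
  means to be non-negative, and computes the weighted mean bin position;
  rank 1 is the largest position, ties broken alphabetically by term name.
  Terms with zero total weight get NaN.

## 8. Synthetic generator: what it emulates and what it does not

`GenerativeSpec` produces a seeded toy dataset with known ground truth. Seeds
feed independent named `SeedSequence` streams, so the first subject's data is
bit-identical regardless of how many subjects are requested.

**Emulated:**

- A spherical two-hemisphere "cortex" with parcels as Fibonacci-lattice
  centroid patches and four equal-size cytoarchitectonic classes banded along
  z, ordered idiotypic → unimodal → heteromodal → paralimbic.
- A continuous sensory-fugal hierarchy: each parcel's laminar profile
  coefficients are interpolated between class-anchored curves according to
  its normalized hierarchy position, plus a low-amplitude parcel-specific
  signature on a cosine depth basis and per-subject/per-vertex Gaussian
  noise. This gives MPC matrices with graded, non-saturated off-diagonal
  structure.
- Microstructure-coupled functional timeseries: the timeseries covariance
  blends the noise-free partial-correlation similarity of the laminar
  profiles (the population quantity MPC estimates) with a block community
  structure, weighted by the geometric mean of per-class coupling strengths
  `kappa`. The default `kappa` decreases from idiotypic to transmodal
  cortex, which is the ground truth the coupling pipeline recovers.
- Twin cohorts with additive-genetic phenotype construction giving expected
  pair correlations `r_MZ = h2`, `r_DZ = h2 / 2`, shared age within pairs,
  shared sex within MZ pairs, and covariate effects matching the fitted
  design.

**Not emulated:** real cortical geometry, folding, or area distributions;
hemispheric asymmetries; distance-dependent connectivity and hemodynamics
(timeseries are i.i.d. Gaussian draws from a static covariance, with no
autocorrelation or physiological noise); measurement artifacts (motion,
field inhomogeneity); dominance or shared-environment genetic components;
non-Gaussian phenotypes. Parameter values (noise SDs, `kappa` profile,
community structure) are order-of-magnitude plausible, not fit to any
empirical dataset.

### Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_parcels` | 100 | parcels (25 per class, split across hemispheres) |
| `vertices_per_parcel` | 10 | vertices per parcel |
| `n_depths` | 12 | equivolumetric sampling depths |
| `hierarchy` | `"continuous"` | continuous interpolation between class curves (`"class"` = piecewise-constant) |
| `n_profile_basis` | 4 | cosine basis functions for parcel signatures |
| `parcel_effect_sd` | 0.08 | SD of parcel-specific signature coefficients |
| `subject_noise_sd` | 0.03 | per-subject profile perturbation SD |
| `vertex_noise_sd` | 0.05 | per-vertex profile noise SD |
| `kappa` | 0.9 / 0.5 / 0.1 / 0.1 | microstructure–function coupling per class (idiotypic → paralimbic) |
| `community_size` | 10 | parcels per functional community |
| `community_rho` | 0.6 | within-community covariance |
| `ts_length` | 400 | timepoints per subject |
| `ts_noise_sd` | 0.3 | timeseries measurement noise SD |

## 9. Limitations

- All validation is against the synthetic generator and analytic/numerical
  oracles; no empirical neuroimaging data is included, and figures computed
  here should not be read as empirical claims about real cortex.
- The diffusion map uses dense eigendecomposition, practical for parcel
  counts up to a few thousand but not for vertex-level graphs.
- The AE fitter supports twin pairs and singletons only (block-diagonal
  kinship); extended pedigrees are out of scope.
- The spin test assumes parcel centroids on (hemi)spheres; it is not
  applicable to volumetric or non-spherical parcel geometry.
- Monte-Carlo acceptance checks (type-I error, spin calibration, coupling
  recovery) use finite replicate counts and therefore have sampling error of
  roughly ±0.01–0.02 on reported rates.
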