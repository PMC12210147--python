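# Methods

## Model and procedure

`sdikit` operates on parcellated brain data: a symmetric nonnegative
region × region structural connectome per subject (weights in
FA × streamline-count units or any positive weighting) and a region × time
functional matrix per subject. The analysis chain is:

1. **Structural normalization.** Each edge is divided by the summed volumes of
   its endpoint regions, correcting the streamline count for parcel size.
   Subjects' normalized matrices are averaged per group into `A_u`, then
   symmetrically normalized, `A = D^{-1/2} A_u D^{-1/2}` with `D` the weighted
   degree. Isolated regions are a hard error, never silently regularized: an
   epsilon fix changes the harmonics unpredictably.
2. **Harmonics.** The symmetric normalized Laplacian `L = I − A` is
   eigendecomposed. This Laplacian form is the canonical choice here because
   the adjacency is normalized first; its spectrum lies in [0, 2] and the
   null-space vector of a connected graph is `D^{1/2}𝟙` (all one sign).
   Eigenvectors are sign-fixed (largest-magnitude entry positive, ties to the
   lowest region index) and degenerate blocks (eigenvalue gaps < 1e-8) are
   ordered lexicographically, so the basis is reproducible bit-for-bit.
3. **SDI.** Signals are z-scored per region across time (sample sd, n−1 —
   stated once, used everywhere), graph-Fourier transformed (`x̂ = Uᵀx`), and
   split by an ideal filter at the cutoff `C`: the smallest index at which the
   cumulative group-average energy spectral density reaches half its total,
   promoted (never demoted) past any degenerate-eigenvalue block it would
   split — the band split is only rotation-invariant inside a degenerate block
   if the block sits wholly on one side. SDI is the per-region ratio of
   decoupled to coupled L2 energy pooled over all timepoints (no windows); a
   log2 variant is available for display, group statistics use the raw ratio.
4. **Group inference.** Per-region OLS `sdi ~ 1 + group + gender + mean_fd`;
   the group coefficient's t (df = n − p) is reported with two-sided p. With
   no covariates this is exactly the pooled two-sample t. Positive t means
   patient > control. Maps are masked at Bonferroni `α/n_regions`. Symptom
   severity (patients only) is Pearson-correlated with SDI in the significant
   set under the 1/N rule — the reciprocal of the number of correlations as
   the maximum p, bounding expected false positives per battery at one.
5. **Spatial association.** Difference maps are split into positive and
   negative directions; the complementary regions are excluded (NaN), not kept
   as zeros — zeros would contribute spurious rank structure. Each direction
   is Spearman-correlated with annotation maps; significance comes from a spin
   null: uniform random 3-D rotations (QR-orthonormalized Gaussian, det +1)
   applied to the left-hemisphere centroids and their x-mirrored twin to the
   right, each region reassigned to the nearest rotated centroid within
   hemisphere, identity draws rejected. p uses the add-one convention
   `(1 + #{|z_perm| ≥ |z_obs|})/(n_perm + 1)` on Fisher-z values (|ρ| = 1 is
   capped at atanh(1 − 1e-12)), so p ∈ [1/(n_perm+1), 1]. Null draws whose
   spun overlap is degenerate (too few or constant values) count as extreme —
   conservative. A spatially naive shuffle null exists behind a flag for
   sensitivity.
6. **Transcriptome PLS.** The full signed t-map over all regions (not only the
   significant set) is the response; the expression matrix is
   column-standardized and the response centered. PLS is an explicit NIPALS
   deflation sequence for a univariate response — implemented in-package
   because the downstream bootstrap needs fixed weight/score/sign conventions;
   scikit-learn's `PLSRegression` (which coincides for univariate y) serves as
   the independent oracle in tests. Explained variance per component is the
   incremental R² of the response on cumulative scores. Component significance
   refits under spin permutations of the response. Gene Z-scores bootstrap the
   *regions* (observations — gene-wise resampling would break the regression),
   sign-align each resampled weight vector to the original, and divide the
   original weight by the bootstrap SE; |Z| > 2.58 defines the signed gene
   lists. Named gene-set weights are compared by two-sided label permutation
   over the union.
7. **Classification.** Stratified 10-fold CV; inside each training fold the
   covariate-adjusted comparison plus Bonferroni picks features, training
   statistics z-score them (with gamma fixed at 0.1 an unscaled RBF kernel
   would be degenerate), and an RBF-SVM (c = 10, γ = 0.1 by default; optional
   inner grid search) is evaluated on the held-out subjects. Patient is the
   positive class. A fold selecting no features is recorded as skipped, never
   silently fit on everything. ACC/SEN/SPE and rank-based AUC (midrank ties)
   are averaged over evaluable folds; a stability table counts how often each
   region is selected (≥ 8 of 10 folds = "stable"). Class imbalance is left to
   the plain SVM by default; a class-weight option exists.

## Cutoff sharing

The median-energy cutoff is estimated once from all subjects pooled, even when
patients and controls are decomposed on their own group bases. A per-group
cutoff would make SDI incomparable across the groups being compared — the same
argument that rules out per-subject cutoffs. The pooled estimate changes
nothing under the null (both groups' spectra are exchangeable) and keeps the
planted-effect recovery tests meaningful.

Per-group bases themselves carry a caveat the synthetic experiments expose:
two group connectomes estimated from finite, noisy samples yield slightly
different harmonics, and that difference alone induces genuine group SDI
offsets at every region. The pipeline's default follows the per-group design
for fidelity to the study layout; the recovery tests use the pooled basis
(`basis_mode="pooled"`), and analysts comparing groups should prefer it unless
the groups' anatomy is itself the question.

## The synthetic generator

The generator emulates the study's inputs with analytic ground truth:

- **Parcellation**: Fibonacci lattice on the unit sphere (hemispheres by the
  x-sign, log-normal volumes, median 1). Centroids exist because the spin test
  needs them.
- **Connectome**: distance-decaying edge weights with log-normal noise,
  thinned to a target density, minimum-spanning-tree edges added if sampling
  disconnects the graph (logged, never an error).
- **Signals**: band-projected harmonic mixtures
  `x = P_L diag(g_low) U_L ε_L + P_H diag(g_high) U_H ε_H`, with i.i.d.
  standard-normal spectral coefficients in time and per-region gain vectors.
  The projections `P_L, P_H` keep each part exactly band-limited, so
  `high_gain = 0` yields SDI ≡ 0 at the generating cutoff and expected SDI is
  monotone in the high/low gain ratio. Spectral noise is i.i.d. in time: SDI
  pools over time, so temporal autocorrelation is irrelevant to the statistic
  and omitting it keeps the ground truth analytic.
- **Band balance**: the uniform low-band gain is set to
  `sqrt((1−q)/q · mean(g_high²))` (q = coupled-band fraction, default 0.2), so
  the two bands carry equal expected energy and the estimated median-energy
  cutoff lands at the generating boundary.
- **Planted effects**: patients' `g_high` is multiplied by `effect_size` in
  the effect regions. Both groups share a baseline dip (`effect_baseline`,
  default 1/8) of the decoupled gain at those regions. The dip matters: a
  variance bump localized at a few regions bleeds into their graph neighbours
  through the band projectors and the per-region z-scoring — region-local
  scaling is not band-preserving — and at full baseline gain that leakage
  reaches |t| ≈ 10 at unplanted regions. Keeping the boost a small share of
  regional variance pushes the leakage below the noise floor while leaving the
  planted SDI contrast at `effect_size`. Gain magnitudes are calibrated to the
  package's own recovery targets, not to any empirical SDI distribution.
- **Covariates**: gender and head motion are drawn with a mild (≤ 15
  percentage point) group imbalance, intentionally, so covariate adjustment is
  consequential and testable. Severity (HAMD-like, location 24, scale 5,
  patients only) is a noisy linear readout of each patient's *realized*
  decoupling at the linked regions — planted gains are identical across
  patients, so realized spectral energy is the subject-level signal severity
  can track; the target correlation holds in expectation only, avoiding
  iterative calibration.
- **Expression / annotation maps**: planted genes are loading × (standardized
  planted map) + Gaussian noise; remaining genes and annotation maps are
  smooth Gaussian fields from a squared-exponential kernel on the centroids
  (sampled via eigendecomposition with clipped eigenvalues — such kernels are
  numerically rank-deficient). Columns are standardized. Linked annotation
  maps mix the standardized target at rate ρ.

What the generator does *not* emulate: hemodynamics, temporal autocorrelation,
scanner or motion artifacts, tractography biases, donor structure in
expression data, or spatial gene–gene covariance beyond smoothness. Passing
recovery tests therefore shows the estimators are correct and calibrated under
the stated model, not that effect sizes transfer to real MRI.

## Numerical and testing choices

- Bootstrap |Z| calibration is checked against near-white noise genes
  (kernel length scale 0.05). Smooth noise genes genuinely correlate with any
  smooth response in-sample — that is precisely why component significance
  uses the spin test rather than gene-level Z — so a ≤ 5% exceedance bound is
  only meaningful for spatially unstructured nulls.
- The chance-level classification baseline uses uncorrected in-fold selection
  (`correction="none"`): under permuted labels Bonferroni selects nothing and
  every fold is skipped, leaving no predictions to calibrate against.
- Recovery experiments plant spatially dispersed effect regions (every 10th
  region); clustered regions overlap their residual leakage neighbourhoods.
- The pure-coupled end-to-end invariant (SDI < 1e-8 through z-scoring) is
  exercised on a regular ring graph, where the first harmonic is constant and
  z-scoring cannot move energy out of the band; on irregular graphs z-scoring
  is mildly band-mixing by nature.
- Matrix TSV I/O serializes floats at 17 significant digits with the decimal
  point enforced; readers re-index by label and refuse duplicates, ragged rows
  and non-numeric cells with line numbers. Reports carry no timestamps, so
  reruns with equal seeds are byte-identical.
- Test problem sizes (≤ 200 regions for identities, 100 regions / 40 + 40
  subjects / 500 timepoints for recovery, 199 spins, 500 bootstraps) were
  chosen so the full suite and the acceptance script each finish in well under
  a minute on one CPU while keeping every Monte-Carlo margin wide.

## Known limitations

- The SDI cutoff rule (median energy split) is inherited from the method
  literature and flagged in output provenance; other rules would shift the
  absolute SDI scale.
- Spin-test reassignment is not a bijection (nearest-centroid matching can
  repeat regions); this is standard but slightly conservative.
- The per-group basis default inherits the basis-noise confound described
  above; pooled mode is the recommended sensitivity analysis.
- Enrichment of the gene lists (GO/KEGG) and fetching of real receptor or
  expression atlases are out of scope; the pipeline ends at ranked,
  exportable gene tables and user-supplied annotation maps.
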