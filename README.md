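# sdikit

Structure–function decoupling analysis of parcellated brain data.

Resting-state functional signals are shaped by the anatomical wiring they run
on, but not equally everywhere: primary sensory cortex tends to follow the
structural connectome closely, while transmodal association cortex "decouples"
from it. `sdikit` quantifies this with the **structural-decoupling index
(SDI)** and carries it through a complete case–control analysis: group
difference maps, spatial association with annotation maps (receptor densities,
meta-analytic term maps) under a spin-test null, transcriptome association by
PLS regression with bootstrap gene scoring, and SVM classification. It is
aimed at researchers analysing region × region structural connectomes and
region × time functional matrices (any parcellation; preprocessing upstream of
regional matrices is out of scope).

## The statistic

Given a group structural connectome, edges are volume-normalized
(`w_ij / (v_i + v_j)`), symmetrically normalized `A = D^{-1/2} A_u D^{-1/2}`,
and eigendecomposed via the normalized Laplacian `L = I − A = U Λ Uᵀ`. The
columns of `U` are *structural harmonics* ordered by graph frequency
`0 = λ₁ ≤ … ≤ λₙ ≤ 2`. A subject's z-scored regional time series `x` is
transformed (`x̂ = Uᵀx`), split with an ideal low/high-pass filter at a cutoff
`C` chosen so the group-average energy spectral density is halved, and
reconstructed into a structure-coupled part `x_C` and a decoupled part `x_D`.
Per region

```
SDI_r = ‖x_D[r, ·]‖₂ / ‖x_C[r, ·]‖₂
```

— the energy ratio of the decoupled to the coupled component, pooled over
time. Downstream: per-region OLS t-maps with covariate adjustment and
Bonferroni masking, Spearman/Fisher-z spatial correlations against
sphere-rotation ("spin") permutation nulls with the 1/N correction, PLS of the
t-map on a region × gene expression matrix with spin-tested components and
bootstrap gene Z-scores (|Z| > 2.58 lists), and 10-fold cross-validated
RBF-SVM classification with in-fold feature selection.

A first-class synthetic-data module (`sdikit.synth`) generates parcellations
on the sphere, connected weighted connectomes, harmonic-structured time series
with known per-region spectral gains, cohorts with planted group effects and
covariates, expression matrices with planted components, and smooth annotation
maps — so every stage has a ground-truthed recovery test without any external
download.

## Worked example

```python
import numpy as np
import sdikit as sk
from sdikit import gsp

parcellation = sk.gen_parcellation(60, seed=1)
sc = sk.gen_structural_connectome(parcellation, density=0.2, seed=1)
A, _ = sk.symmetric_normalize(sk.volume_normalize(sc, parcellation.volume))
basis = sk.harmonics(A).with_cutoff(12)

high_gain = np.ones(60); high_gain[:5] = 2.0   # extra decoupled energy in 5 regions
ts = sk.gen_subject_timeseries(basis, low_gain=2.0, high_gain=high_gain, T=400, seed=2)
maps, cutoff = gsp.sdi_pipeline([ts], basis)
print(cutoff, maps[0][:5].mean(), maps[0][5:].mean())
```

prints

```
16 1.621 0.958
```

the estimated median-energy cutoff (16 of 60 harmonics in the coupled band)
and the mean SDI in the boosted regions (1.62) versus the rest (0.96): the
regions given twice the decoupled-band gain show roughly twice the decoupling.
The scripts in `examples/` walk through each capability the same way — group
comparison, spin-test annotation associations, transcriptome PLS, and SVM
classification — each printing the numbers it computes and what they mean. A
thin CLI (`sdikit simulate|sdi|compare|assoc|pls|classify|run`) exposes the
same stages over TSV/JSON files.

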