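# Methods

`contranet` analyses hemispheric resting-state functional connectivity in
two complementary arms — multivariate pattern classification of tumour
grade and weighted graph-topology characterization — and ships a
synthetic-cohort generator that reproduces the study design those arms
were built for: two glioma groups (slow-growing low-grade, LGG, vs
fast-growing high-grade, HGG), 40 subjects each, one hemisphere
parcellated into 45 regions of interest (ROIs), 301 fMRI volumes at
TR = 1.5 s.

## Synthetic cohorts

Each subject's ROI panel is drawn as independent multivariate-normal
timepoints with a block-modular correlation matrix: correlation `intra_r`
inside modules and `inter_r` between modules (default three modules of 15
ROIs). Defaults encode the group contrast the topology arm targets — LGG
`intra_r = 0.45`, `inter_r = 0.25` (less segregated); HGG `intra_r = 0.60`,
`inter_r = 0.15` (more segregated). Block matrices with
`0 <= inter_r <= intra_r < 1` are positive semidefinite in practice; a
numerically indefinite matrix is repaired by clipping negative eigenvalues
at zero (tolerance 1e-10) and rescaling to unit diagonal.

Design choices worth knowing:

* **Temporally white series.** Every downstream statistic operates on
  correlation matrices, for which white generation with the target
  correlation structure suffices; BOLD autocorrelation and hemodynamics
  are deliberately not modelled, which keeps the Fisher-z sampling
  distribution analytically checkable (sd = 1/sqrt(T-3)).
* **Baseline offset 100.** Temporal SNR (mean/sd) is meaningless on
  zero-mean series, so a constant baseline is added; with unit-variance
  signals this puts synthetic subjects at tSNR ~ 100, comfortably above the
  QC gate of 45.
* **Confounds default to zero amplitude.** The generator can inject a
  shared global-signal component, a linear drift and motion-like spikes
  (with the matching regressor columns stored in the panel), but no
  quantitative confound model exists for the source data, so the clean
  configuration is the reference condition and confounds are opt-in.
* **Covariates.** Ages are N(38.79, 10.77^2) for LGG and N(51.28, 13.10^2)
  for HGG; tumour diameters N(55, 19^2) and N(48, 16^2) mm, truncated to
  [18, 90] years and [5, 120] mm. These match the study population's
  printed moments, so the descriptive tests and the covariate-adjusted
  ANOVA run under realistic covariate imbalance (the age difference is
  real; the diameter difference is not significant).
* **Seeding.** One master seed spawns per-subject integer seeds through a
  `SeedSequence` counter scheme; cohorts are bit-reproducible and subjects
  independent.

What passing tests on these cohorts do *not* show: robustness to
autocorrelated noise, scanner drift structure, imperfect parcellation, or
lesion-induced signal dropout. The generator validates the analysis
machinery, not the acquisition chain.

## Connectivity

Processing order: tSNR gate -> confound regression -> linear detrend ->
band-pass -> Pearson correlation -> Fisher z.

* **tSNR** is computed on the raw series (mean/sd per ROI); the subject
  gate compares the ROI-mean against the threshold (default 45). A
  zero-variance ROI reports +inf and is logged rather than failed.
* **Confound regression** is OLS against `[intercept | confounds]`;
  collinear columns are dropped with a warning. With no confounds this
  reduces to temporal demeaning.
* **Band-pass** is an ideal FFT mask over [0.009, 0.8] Hz after removing
  the best-fit line. At TR = 1.5 s the Nyquist frequency is 0.333 Hz, so
  the conventional upper edge is unreachable; the filter clamps to Nyquist
  (logged) and is effectively a high-pass — the deterministic,
  parameter-free reading of a rectangular passband.
* **Correlation** uses all timepoints; |r| = 1 is clamped to
  atanh(1 - 1e-7) with a warning, a zero-variance ROI is an error naming
  the ROI. The strict upper triangle in row-major order is the feature
  vector: 990 features for 45 ROIs.

## Classification

1. **Discriminative power** of a feature is |tau-b| between its values and
   the binary group label. tau-b (tie-corrected) is the right variant for
   massively tied binary labels; note its attainable maximum against a
   binary label is below 1 (9/sqrt(135) ~ 0.775 for 3-vs-3 perfect
   separation), which affects absolute power values but not rankings.
   Computed from pooled midranks via `C - D = 2U - nA*nB`, so ranks are
   shared across label permutations.
2. **Selection**: per leave-one-out fold, the top-k features (default
   k = 200) ranked on the n-1 training subjects; ties broken by ascending
   feature index. The **consensus set** is the intersection of all folds'
   top-k lists — the reported feature signature. Classification itself
   uses each fold's own top-k ranking (`feature_mode="per_fold"`): the
   consensus intersection depends on every subject, and classifying with
   it inflates cross-validated accuracy on null data to near 1 (classic
   selection bias), so the fixed-consensus variant is available
   (`feature_mode="consensus"`) but is only interpretable against a
   permutation null run in the same mode.
3. **Classifier**: linear-kernel SVM (C = 1.0, configurable), leave-one-out
   cross-validation (stratified ten-fold available). Specificity =
   accuracy on the first group (LGG role), sensitivity = accuracy on the
   second (HGG role), overall accuracy = their mean.
4. **Permutation test**: labels shuffled, the *entire* pipeline (per-fold
   ranking + CV) rerun per permutation (nested, default; a non-nested flag
   reuses the observed selection); p = (1 + #{null >= observed}) /
   (1 + n_perm), never zero, with >= making the count conservative.

## Graph topology

Connectivity matrices are thresholded **proportionally**: negatives are
zeroed (the conventional treatment of negative resting-state
correlations), then the `round(s * n(n-1)/2)` strongest positive weights
are retained at each sparsity level `s` in 10%..50% step 5%, equating
wiring cost across subjects. Ties at the cut go to the lexicographically
first (row, column) pair.

* **Global efficiency**: mean inverse shortest path length over ordered
  pairs, edge length = 1/weight (the standard mapping for
  correlation-weighted networks), unreachable pairs contributing 0 — hence
  well-defined on disconnected graphs.
* **Local efficiency**: per node, paths on the neighbour-induced subgraph
  with cube-root lengths `w^(-1/3)`; neighbour pairs contribute
  `(w_uj w_uh)^(1/3) / d_jh`, normalized by k(k-1); nodes with < 2
  neighbours contribute 0; the nodal mean is reported. This is the
  standard weighted formulation used by the brain-connectivity literature.
* **Null normalization**: both efficiencies are divided by their mean over
  rewired reference networks (default 1000) built by seeded double-edge
  swaps (~10 attempts per edge, preserving the degree sequence) followed
  by random reassignment of the exact original weight multiset. If no
  swap succeeds the null falls back to a weight shuffle on the original
  topology (logged).
* **Modularity**: best weighted Newman Q over seeded multi-level (Louvain)
  restarts (default 100); Q is evaluated by the package's own formula
  `(1/2W) sum_ij (w_ij - k_i k_j / 2W) delta(c_i, c_j)` and the partition
  is recomputed at every sparsity level.
* **Intra/intermodular connectivity**: mean retained edge weight within /
  between modules, each divided by the mean over all retained edges
  (pooled mean-ratio; a per-module-averaged variant is available). The
  mean-ratio reading — rather than raw sums — removes both global
  correlation-magnitude and edge-count differences, making values near 1
  interpretable. Scale invariance is tested. When a level has no
  between-module edges (common at low sparsity under strong modular
  structure, where the partition isolates the planted blocks), the metric
  is undefined at that level: it is recorded as NaN, the subject flagged,
  and the sparsity integration (arithmetic mean over levels, i.e. a
  normalized AUC on the even grid) skips it.

## Group statistics

* **Permutation group test**: group labels exchanged preserving sizes
  (default 10,000 permutations), two-sided via absolute mean differences
  (one-sided counting available), add-one p estimator. The null is built
  from permutations of the sorted pooled values, which makes p exactly
  invariant to group relabelling at equal sizes.
* **FDR**: Benjamini-Hochberg step-up across the six metric p-values.
* **ANCOVA**: OLS `metric ~ age + diameter + group` with the group term
  entered last in the sequential decomposition; classical eta squared
  (SS_group / SS_total; partial variant behind a flag). Residual df is
  n - 4.
* **Descriptives**: Pearson chi-square without continuity correction for
  the 2x2 sex table, and a pooled-variance two-sample t computable from
  printed summary statistics (so published patient tables can be checked
  without raw data; the diameter row illustrates the ~0.01 discrepancy
  that rounding printed summaries introduces).

## Problem sizes and numerical notes

Heavy end-to-end checks use reduced but faithful settings chosen as this
package's reference configuration for desk-scale validation: 50 rewired
nulls, 10 modularity restarts, 200-500 permutations, cohorts of 40 per
group. The operations' defaults remain the full-scale values (1000 nulls,
100 restarts, 10,000 permutations). All randomness flows through explicit
integer seeds via `numpy.random.SeedSequence`; graph kernels
(Floyd-Warshall all-pairs paths, local-efficiency subgraphs, double-edge
swaps) are numba-compiled and tested against naive networkx/scipy/igraph
oracles to 1e-12 on small graphs.

Known limitations: no signed-network variants or nodal hub statistics; no
image-level preprocessing (panels and label vectors are taken as given);
the generator's effect sizes produce much larger group contrasts than
clinical data (eta squared near 0.9 vs ~0.08 in patients), so passing the
contrast tests demonstrates correctness of the machinery, not expected
clinical effect sizes.
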