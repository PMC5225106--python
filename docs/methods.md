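# Methods

This note documents the models, conventions, and numerical choices the
package implements, and what its synthetic data do and do not emulate.

## Study design and data model

The package targets a full-factorial metabolite-profiling design:
genotype (wild type vs mutant) × condition (control CK, acclimated
freezing A, cold shock S) × timepoint (end of treatment, 24 h
recovery) × biological replicate (default 6), measured as a
samples × features table of GC-MS peak areas with one spiked internal
standard (ribitol). Defaults mirror a 2 × 3 × 2 × 6 layout with 263
features of which 78 carry metabolite annotations.

Intensities are treated as multiplicative: the generator draws log2
intensities as (feature baseline) + (cell effect) + (correlated
replicate noise) + (per-sample factor), then exponentiates. The
per-sample factor is shared between every feature and the internal
standard, so dividing by the standard is *exactly* the right
correction in the noiseless limit — this is the assumption behind
internal-standard normalization, made literal. Planted log2 effects
are therefore exact in expectation on the log scale.

What the generator does **not** emulate: retention-time drift, peak
co-elution and deconvolution errors, missing-not-at-random dropouts
tied to intensity, heteroscedastic detector noise, or batch structure.
Missing values are injected uniformly at random (default rate 0).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artifact of
real chromatography.

`simulate.study_preset()` configures the generator to reproduce the
qualitative biology the pipeline is meant to surface: the sucrose
genotype contrast (−14.723-fold at control, +2.751/+1.959 after
acclimated freezing, −1.558/−4.141 under shock), broad condition
responses in a quarter of the features, and four correlation blocks
whose within-block correlation rises from 0.3 (CK) and 0.5 (A) to 0.95
(S) — cold shock tightening metabolite coupling so shock networks come
out much denser than control networks. These values were fixed once as
the demo conditions.

## Normalization and missing values

Normalized value = feature area / ribitol area per sample; the
standard column is removed. A zero or missing standard is an error
naming the sample. The default missing-value policy drops features
missing in > 30 % of samples and imputes the remainder with half the
feature's observed minimum (the usual limit-of-detection surrogate);
`impute_half_min`, `drop_feature_above_rate`, and `fail` are available
separately. No log transform is applied at ingestion — scaling
decisions belong to the multivariate stage, which exposes a `log2`
option.

## Multivariate models

UV scaling subtracts the feature mean and divides by the n−1 sample
standard deviation; zero-variance features are excluded with a
warning. PCA is the SVD of the scaled matrix; explained variance per
component is σ²ᵢ/Σσ². Component signs are fixed so each loading
vector's largest-magnitude element is positive, making outputs
reproducible.

PLS-DA runs NIPALS on the scaled X and a centered class indicator
(one ± column for two classes, centered one-hot otherwise), deflating
X and Y per component. Convergence tolerance is 1e-10 on the score
vector with a 500-iteration cap — for a single-column Y NIPALS
converges in one pass. Fitted scores and coefficients agree with
scikit-learn's PLSRegression to ~1e-10 (cross-checked in tests); the
full-rank fit reproduces OLS.

Q² = 1 − PRESS/SS over stratified, seeded 7-fold cross-validation;
each fold re-centers on its training data. The default component count
is the smallest A whose incremental Q² is below 0.01, capped at 10.
The permutation test shuffles class labels, refits the whole CV
pipeline at the same A, and reports
p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), so the smallest possible p
at 100 permutations is 1/101. VIP uses SSYₐ = ‖qₐ‖² tₐ·tₐ as the
per-component explained-Y weight; mean(VIP²) = 1 is asserted as an
algebraic identity.

## Univariate screening

The signed fold change maps a ratio r to r (r ≥ 1) or −1/r (r < 1);
its log2 form is log2 r, so |f| = 2^|L| round-trips exactly. The
default test is the pooled-variance Student t (two-sided); Welch is a
flag. A zero pooled variance with unequal means reports the smallest
positive float instead of p = 0, with a warning. BH-FDR uses the
step-up procedure (statsmodels), validated in tests against a literal
step-up oracle. Discriminant selection is strictly VIP > 1 and
p < 0.05. The comparison grid is metadata-driven: any axis with two
levels can be contrasted within the level combinations of any other
axes; q-values are computed per comparison stratum across features.

## Correlation networks

Each genotype × condition group pools both timepoints and all
replicates (12 samples at defaults); a timepoint filter can restrict
this. Pearson r is computed per feature pair; p comes from
t = r√(n−2)/√(1−r²) with n−2 df. Pairs whose r is undefined (zero
variance) are excluded, never coerced to 0; |r| within 1e-12 of 1 is
reported as p = 0. The FDR family is all p(p−1)/2 pairs of one group's
matrix. Edges require strictly |r| > 0.9 and q < 0.05 (both
configurable); nodes are features with at least one edge.

Average degree is 2E/n. Density defaults to E/(n(n−1)) — half the
standard undirected density — because only this convention reproduces
the published group summaries from their printed node/edge counts
(1410/(68·67) = 0.309; 2700/(64·63) = 0.670 by rounding, 0.669 by
truncation); `standard_density` carries 2E/(n(n−1)). Properties can
also be computed directly from raw (n, E) counts via
`NetworkProperties.from_counts`, which deliberately does not enforce
the simple-graph bound E ≤ n(n−1)/2 so published count pairs can be
summarized exactly as printed.

The SDN keeps edges present in exactly one of two networks, tagged
with their source; a node is source-specific when all of its SDN edges
carry one tag. The reported edge ratio is (second network's specific
count)/(first's). SDN and intersection partition the edge union — a
tested invariant.

## Hierarchical clustering

Values are centered per feature by the mean over control samples
(optionally after log2), so deviations read against the unstressed
state. Clustering uses correlation distance (1 − r) with average
linkage by default (Euclidean, complete, single available); constant
rows/columns are excluded under correlation distance since their
distance is undefined. SciPy's linkage provides deterministic
tie-breaking. Trees are exported as Newick with heights converted to
branch lengths.

## LT50 fitting

The 4-parameter logistic y(T) = A + (B−A)/(1 + e^{(T−m)/s}) with s > 0
is fitted in plain temperature units (a log-dose axis is meaningless
for negative °C; the "log EC50" phrasing in dose–response software is
an artifact of its default parameterization). Optimization is a coarse
grid over (m, s) — 41 midpoints across the observed range × 12 scales
geometric from 5 % to 100 % of the range — with the asymptotes solved
linearly at each grid point, followed by Nelder–Mead refinement of all
four parameters (xatol 1e-10, fatol 1e-14, 4000 iterations). The fit
is deterministic given the data and shift-equivariant in temperature.

Two LT50s are reported because "50 % leakage" and "curve midpoint" are
different quantities unless the asymptotes are symmetric about 0.5:
the absolute crossing m + s·log((B−0.5)/(0.5−A)) (primary; undefined
and flagged when 0.5 ∉ (A, B)) and the midpoint m. Replicates are
pooled by default; `fit_lt50_per_replicate` gives per-replicate fits
with mean ± s.e.

## Problem sizes and numerical tolerances

The test and demonstration problem sizes were chosen to exercise each
property at the scale where it is informative: planted-block network
recovery and LT50 recovery at 100 seeded simulations, t-test
calibration on 2000 null features, PLS-DA null behavior over 50
replicate 24 × 10 datasets, and the default 72 × 263 design for
end-to-end runs. Algebraic identities (VIP mean-square, PCA variance
sum, reconstruction) are asserted at 1e-8; set-operation and oracle
equivalences at 1e-12.

## Known limitations

- PLS-DA supports multi-class Y, but Q² aggregates over all indicator
  columns; no per-class diagnostics.
- No OPLS-DA, Hotelling T² ellipses, or score-plot graphics.
- Network analysis stops at degree/density and set comparisons — no
  community detection or centrality measures.
- Bootstrap confidence intervals for LT50 are not implemented;
  replicate-level s.e. is the provided uncertainty.
- The missing-value model (uniform at random) understates the
  intensity-dependent censoring typical of real GC-MS data.
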