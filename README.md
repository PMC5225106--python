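# metabnet

Analysis toolkit for GC-MS metabolite-profiling studies of plant cold
stress, built around the comparison of a wild type and a mutant
(e.g. *Arabidopsis* WT vs the alcohol-dehydrogenase mutant *adh1*)
across control (CK), cold-acclimated freezing (A), and cold-shock (S)
treatments with a recovery timepoint. It is a library first — the
importable API plus the short scripts in `examples/` are the main
interface — with a thin `metabnet` command-line wrapper.

It covers the full downstream workflow once peaks have been integrated:

- **Normalization** of peak areas to a ribitol internal standard
  (`read_peak_table`, `normalize_internal_standard`, missing-value
  policies).
- **Multivariate models**: mean-centering/unit-variance (UV) scaling,
  PCA by SVD, and PLS-DA fitted by NIPALS with VIP scores, stratified
  7-fold cross-validated Q², and a class-label permutation test.
- **Univariate screening**: signed fold changes, Student/Welch
  t-tests, Benjamini–Hochberg FDR, and the discriminant rule
  VIP > 1 ∧ p < 0.05.
- **Correlation networks** per genotype × condition group
  (|r| > 0.9, FDR < 0.05 edges), their degree/density summaries, and
  network intersection / symmetric-difference (SDN) comparison.
- **Hierarchical clustering** of control-centered profiles
  (correlation distance, average linkage) with Newick dendrograms.
- **Freezing tolerance**: relative electrolyte leakage and LT50
  estimation by 4-parameter logistic fitting.
- **Synthetic data**: a seeded generator producing peak tables with
  planted effects and condition-dependent correlation blocks, and
  logistic leakage series — so every stage is testable end to end.

## The statistics at the core

Signed fold change: for group means $\bar{x}_A,\bar{x}_B > 0$ and
$r = \bar{x}_A/\bar{x}_B$, report $f = r$ if $r \ge 1$ else $-1/r$,
with log form $L = \operatorname{sign}(f)\log_2|f| = \log_2 r$.

VIP for a PLS model with $A$ components, weights $w_a$, scores $t_a$,
Y-loadings $q_a$ and $p$ features:

$$\mathrm{VIP}_j = \sqrt{\,p \cdot \frac{\sum_a \mathrm{SSY}_a\,(w_{ja}/\lVert w_a\rVert)^2}{\sum_a \mathrm{SSY}_a}}, \qquad \mathrm{SSY}_a = \lVert q_a\rVert^2\, t_a^\top t_a,$$

so $\overline{\mathrm{VIP}^2} = 1$ by construction. Predictivity is
$Q^2 = 1 - \mathrm{PRESS}/\mathrm{SS}$ over stratified 7-fold CV, and
the permutation p-value is
$(1 + \#\{Q^2_\text{perm} \ge Q^2\})/(n_\text{perm}+1)$.

Network edges require $|r| > 0.9$ and BH-FDR $q < 0.05$ over all
$p(p-1)/2$ pairs of one group's matrix. Average degree is $2E/n$;
density follows the $E/(n(n-1))$ convention (half the standard
undirected density, which is available via `standard_density`).

LT50 is fitted from relative leakage $y(T) = A + (B-A)/(1+e^{(T-m)/s})$
($s>0$, leakage grows as $T$ falls) and reported both as the absolute
50 % crossing and as the curve midpoint $m$.

## Worked example

`python examples/03_differential.py` simulates the study design with a
planted sucrose contrast and screens genotype differences per design
cell:

```
          comparison  fold  log2fc        p        q  selected
   WT_vs_adh1@CK/t2h -15.1   -3.91 4.13e-11 1.09e-08      True
WT_vs_adh1@CK/rec24h -16.6   -4.06 7.03e-11 1.85e-08      True
    WT_vs_adh1@A/t2h   2.7    1.43 2.54e-07  3.7e-06      True
 WT_vs_adh1@A/rec24h  1.95    0.96 1.88e-06 0.000145      True
    WT_vs_adh1@S/t2h -1.58  -0.658  0.00152   0.0121      True
 WT_vs_adh1@S/rec24h -4.55   -2.19 6.68e-07 0.000176      True
```

Each row is one design cell: `fold` is the signed fold change of WT
over *adh1* (−15.1 means 15.1-fold lower in WT), `log2fc` its log2
form, and `selected` marks the VIP > 1 ∧ p < 0.05 discriminant rule.
The recovered pattern is the planted one: a strong WT sucrose deficit
at control that flips positive after acclimated freezing and stays
negative under cold shock.

`python examples/06_lt50.py` fits a noisy leakage series simulated at
LT50 = −6.42 °C:

```
fitted asymptotes: 0.051 -> 0.942
LT50 (absolute 50% crossing): -6.43 C
LT50 (curve midpoint):        -6.41 C
```

The other examples cover normalization (01), PCA/PLS-DA (02), networks
and SDNs (04), clustering (05), and the full pipeline with a checksum
manifest (07).

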