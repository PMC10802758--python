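# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic cohorts do
and do not emulate, and the numerical decisions a maintainer would
want recorded. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

### Abundance model

Each cohort holds paired vascular-enriched and bulk log2 abundance
matrices over the same proteins and biological samples. On the log2
scale a protein `p` in sample `s` is

    x_ps = baseline_p + l_p * f_{m(p),s} + covariate terms
           + diagnosis shift + batch offset + sqrt(1 - l_p^2) * eps

* `f_m` — one latent factor per module (standard normal over samples),
  shared between the two fractions so modules are genuinely preserved
  across them. Factors are orthogonalized against the modelled design
  (diagnosis indicators, age, sex, PMI) and re-standardized: the only
  group or covariate structure in the data is what was planted, which
  makes planted slopes exactly recoverable by least squares on
  noise-free data (a property the test suite asserts at 1e-10).
* `l_p` — the protein's factor loading, drawn uniformly in
  `sqrt(r) ± loading_spread` (default spread 0.15, clipped to
  [0.05, 1]). The symmetric spread keeps the mean pairwise
  within-module correlation exactly at `within_module_cor = r`
  (default 0.6) while giving every module a hub gradient, which real
  co-expression modules have and which the preservation connectivity
  statistics presuppose. Loadings come from a separate `structure_seed`
  (default 1234) so that replicate cohorts — same configuration,
  different `seed` — share the same biology (membership and hubness)
  and differ only in noise, traits and factors.
* Per-protein residual variance is `1 - l_p^2` (background proteins:
  pure unit noise), so total variance is ~1 for all proteins.

### Defaults as study conditions

1,000 proteins; 20 samples per diagnosis group (CTL/AD/PSP, 60 total)
in three TMT batches with one GIS channel each; eight modules of sizes
150, 120, 100, 90, 80, 70, 60, 50; batch offsets (+1, −1, 0) log2;
covariate slopes age 0.02 log2/yr, sex 0.2, PMI 0.01 log2/h, each on a
random 20% of proteins; protected diagnosis effects +0.5 log2 (AD) on
module 1 and −0.5 (AD) / +0.4 (PSP) on module 4; missingness 5% MCAR;
GIS channels are each batch's biological-channel mean plus N(0, 0.05)
noise. Module-to-cell-type identities (endothelial, pericyte, SMC,
fibroblast, neuron, astrocyte, oligodendrocyte) drive the marker GMT
(20 markers per type; microglia/macrophage and OPC marker sets use
symbols absent from the matrix, exercising the downstream exclusion
path). Vascular/bulk enrichment: +2 log2 for the four vascular
cell-type modules, −1.5 for the neuronal module, +1.8 for the
disease-associated first module; 50 proteins exist only in the
vascular fraction and 30 only in bulk. No empirical variance
components were available for the motivating cohort; these values were
chosen once for testability at realistic magnitudes and are not
revisited.

Fractionation failures are simulated (off by default) as samples whose
neuron-module proteins shift up and endothelial-module proteins down
by 6 log2 units — a gross failure, as the flagging rule targets.

### GWAS and biofluid tables

Gene-level association tables draw background genes from Uniform(0,1)
marginals coupled across studies by a Gaussian copula (default
correlation 0.8): gene-level statistics from overlapping GWAS cohorts
sharing one LD structure are strongly correlated between studies, and
independent uniforms would make a multi-study ensemble implausibly
selective. Risk-module genes draw from Beta(a, 1) with a < 1
(left-shifted; a = 1 recovers the null) or sit at a fixed p. Biofluid
differential-abundance tables plant one brain module as concordantly
increased (positive log2FC, p below 0.01) among otherwise null
detected proteins.

### What the generator does not emulate

Peptide-to-protein rollup, intensity-dependent (non-MCAR) missingness
(an option exists but is off by default since the motivating analyses
do not model it), isoform redundancy, co-isolation interference,
heavy-tailed or correlated residuals, and batch×protein interaction
effects. Passing tests therefore demonstrate correctness of the
algorithms under a linear factor model with Gaussian noise, not
robustness to every artifact of real TMT data.

## Batch correction (GIS-ratio median polish)

Working additively in log2 space (equivalent to polishing sample/GIS
ratios), each iteration (a) subtracts, per protein and batch, the
median over the batch's denominator samples (GIS channels by default;
all non-GIS samples with `use_all_non_gis`), then (b) subtracts each
sample's median over proteins. Iteration stops when the largest
absolute adjustment of a full pass falls below `tolerance`
(default 1e-8 log2; `max_iterations` 250). Medians ignore missing
values. Denominator medians are recomputed from the updated matrix
each pass (true median polish). Finally each protein's pre-correction
median over the denominator samples is added back: with this
anchoring, correcting an already-corrected matrix is exactly a no-op
(asserted in the tests), and a matrix already satisfying both
centering conditions converges with zero adjustment in one pass. With
a single GIS channel per batch the polish converges in two iterations.

A protein unobserved in a batch's denominator channels cannot receive
a GIS term for that batch; such cells are flagged and centred on the
batch's remaining samples' median instead, since leaving them
uncentred would strand the raw batch offset (and the abundance
baseline) in a visible artifact.

## Cell-type scores, outlier flagging, regression

Cell-type scores are the marker mean-z: each protein is z-scored
across samples (zero-variance proteins score 0), and a sample's score
for a cell type is the mean z over that type's markers found in the
matrix (types matching fewer than 3 proteins are dropped with a
warning). This single per-sample covariate stands in for ensemble
deconvolution, whose component algorithms are external tools; the
downstream use is only a nuisance regressor and an outlier screen.

Fractionation outliers are samples with endothelial z below −2 *and*
neuronal z above +2 (both configurable); both conditions must hold, as
a failed vessel enrichment manifests as the combination.

The covariate regression fits, per protein, log2 abundance on nuisance
terms (neuronal score, age, sex, PMI, batch as indicator contrasts
against the first batch) plus protected diagnosis indicators (CTL
reference). Coefficients are medians over `n_boot = 1000`
case-resampled bootstrap refits (the nonparametric bootstrap resamples
cases, not residuals); only nuisance contributions are subtracted.
Continuous covariates are centred so the correction is
mean-preserving; subtracting batch terms centres samples to the
reference batch, which is irrelevant to the correlation-based
downstream stages. Missing cells are mean-imputed for the fit only and
stay missing in the output. With `n_boot=1, resample=False` the
operation reduces exactly to single-fit residualization (oracle test
at 1e-10). Rank-deficient designs (e.g., batch confounded with
diagnosis) raise an error naming the collinear columns.

`variance_partition` attributes per-protein variance fractions by
sequential sums of squares averaged over all orderings of the term
set (order-independent for the ≤6 terms used); fractions plus residual
sum to one by construction.

## Network construction

Single block throughout. Pairwise-complete biweight midcorrelation
with the standard 9-MAD tuning constant; a vector with zero MAD falls
back to Pearson for that pair (warned); pairs with fewer than 4 shared
observations get a missing correlation, treated as 0 (neutral
adjacency ≈ 0.002 at β = 9) in adjacency construction. Signed
adjacency `((1 + cor)/2)^β`, β = 9; mean-denominator TOM; average
linkage on 1 − TOM with deterministic lowest-index tie-breaking (own
implementation, verified against an independent average-linkage oracle
at 1e-12).

The adaptive cut is a dynamic-hybrid-style recursion: static
components below a cut height (0.99 of the top merge height) are
split top-down wherever the merge gap clears a deep-split-controlled
minimum and both sub-branches hold at least `min_module_size = 20`
objects; undersized side branches become strays. A surviving branch is
kept as a module only if its mean within-branch dissimilarity (core
scatter) stays below the deep-split bound. Deep-split levels 0–4 map
to core-scatter fractions (0.64, 0.73, 0.82, 0.91, 0.95) of the height
range between the 5th-percentile merge height and the cut height, with
the minimum gap at 3/4 of the remaining headroom; level 4 (the
default) is the most aggressive. The PAM stage assigns strays to the
module with the smallest mean dissimilarity, restricted to modules in
the same static component when `pam_respects_dendro`, and only when
that mean dissimilarity is below the cut height.

Eigenproteins are unit-variance first-principal-component score
vectors over standardized member rows (per-protein mean imputation for
this computation only), signed so the mean member correlation is
positive. Modules whose eigenproteins correlate above 1 − 0.07 merge
iteratively, closest pair first, recomputing after every merge — the
closest-first order makes the fixed point independent of label order.

Iterative kME reassignment recomputes eigenproteins and kME (bicor of
protein against eigenprotein) every iteration and applies three rules:
grey if all kME < 0.30; assign an unassigned protein to its argmax
module if any kME > 0.30; move an assigned protein when its best kME
exceeds the current module's by more than 0.10. Modules that shrink
below `min_module_size` dissolve back to grey (their members are
re-homed by the assignment rule next iteration) — without this,
sub-minimum residual modules produce threshold flapping and label
limit cycles. Iteration stops at a fixed point (or at a detected state
cycle / `reassign_max_iter = 30`, returning `converged=False`). Final
modules are renamed M1..Mk by decreasing size, an invariant maintained
after every public operation. Eigenproteins are recomputed each
iteration (rather than frozen) since the procedure is defined by its
fixed point.

## Module preservation

Six statistics per module, evaluated on the protein intersection:
density in the test network (mean signed correlation, mean adjacency,
proportion of variance explained by the set eigenprotein) and
reference–test connectivity agreement (correlation of intramodular
connectivity, of kME, and of the within-set correlation entries).
This named 3+3 subset is a deliberate simplification of the much
larger published preservation suite; acceptance is via planted-truth
behaviour, not numeric equality with any reference implementation.
Null distributions come from uniformly drawn same-size protein sets in
the test network (all proteins, grey included; 500 permutations,
seeded). `Zdensity`/`Zconnectivity` are the medians of their groups,
`Zsummary` their mean, with the one-sided upper normal tail for p
(computed via the survival function — no 1 − CDF cancellation, exact
to the far tail). Degenerate nulls (SD below 1e-12) yield Z = 0 rather
than an infinity. Classification: below 1.96 not preserved, 1.96–10
moderate, above 10 high.

In a replicate-cohort design the connectivity group carries little
signal (random sets replicate as well as modules, since the whole
network is preserved); Zsummary is then driven by density, which is
the intended behaviour of the composite. The permutation Z responds to
module cohesion in the low-to-mid correlation range and saturates at
high correlation, where null composition variance scales together
with the observed statistic.

## Differential and enrichment statistics

* **ANOVA + Tukey.** Per protein, one-way ANOVA across CTL/AD/PSP on
  non-missing values (proteins with fewer than 2 values in any group,
  or zero total variance, are reported skipped). Pairwise p-values are
  Tukey–Kramer on the pooled MSE. The studentized-range upper tail is
  computed by a vectorized double Gauss–Legendre quadrature written in
  a cancellation-free form (difference-of-powers expansion), accurate
  to ~1e-6 relative against an independent implementation at moderate
  p and stable far below 1e-10; the independent implementation remains
  the oracle in the tests. Tukey p below 10^-8.5 is replaced by
  min(1, 3 × two-tailed Welch t p) — 3 being the number of pairwise
  comparisons in a three-group design — with the substitution flagged.
* **Module–trait correlation.** bicor of each eigenprotein with each
  numeric trait (ordinal neuropathology scores as numeric; diagnosis
  expanded to binary indicators), two-sided p from
  `t = r sqrt((n−2)/(1−r²))`. Constant traits yield missing results.
* **Vascular/bulk enrichment.** Per protein, the mean over paired
  samples of (vascular − bulk) log2; proteins detected in only one
  fraction (after each fraction's own missingness filter) are
  "unique", not ratioed. The classifier-input rule selects proteins
  unique to the vascular fraction or ≥3-fold enriched there, with all
  three pairwise comparisons significant at 0.05.
* **Fisher set enrichment.** One-tailed hypergeometric tail on an
  explicit background; odds ratio with Haldane 0.5 correction when a
  2×2 cell is empty; BH FDR across the rows of each call. The
  cell-type test background is all network proteins (configurable).
* **GWAS risk enrichment.** Per gene, the ensemble p is the mean of
  −log10 p across the studies containing the gene (back-transformed).
  A module's observed score is the mean −log10 ensemble p over member
  genes below the nominal 0.05 cut (none → NES 0, never flagged); the
  null re-scores random same-size gene sets from the network
  background; NES standardizes observed against the null. The
  permutation p is the module's own null upper tail with the mid-p
  convention for ties (ties cannot occur with continuous p-values;
  they arise only in degenerate synthetic score distributions), BH
  across modules; flags at 5% and 10% FDR. Gene-to-protein collisions
  (isoforms) count a gene once per module.
* **Reporter-channel scaling / amyloid-beta ratios.** Linear-scale
  channels are multiplied by (max column sum)/(own column sum), so all
  channel sums equal the pre-scaling maximum. The two amyloid-beta
  C-terminal tryptic peptides (GAIIGLMVGGVV for the 1-40 species,
  GAIIGLMVGGVVIA for 1-42) are located by exact sequence match after
  peptide-level median-polish correction, and the per-sample 40/42 and
  per-peptide vascular/bulk log2 ratios reported.

## Pipeline and reproducibility

`run_pipeline` executes filter → batch correction → QC/flag →
regression → network → preservation → differential statistics →
enrichment, writing every intermediate table and a manifest with
parameters, per-stage seeds, package versions and input checksums. A
single global seed derives per-stage seeds by hashing the stage name
(all below 2^31), so stages can be rerun in isolation; reruns are
bitwise identical. All randomness flows through numpy's PCG64
(`default_rng`); determinism is asserted in the tests, and the
dependency floor is the versions the package is developed against —
no RNG algorithm change is expected within numpy's stability policy.

## Problem sizes used by the tests and acceptance script

Chosen as the package's own desk-scale defaults: the full cohort
(1,000 × 60) for batch correction, regression recovery (200 bootstrap
fits) and network recovery; a 500-protein five-module cohort pair for
preservation calibration (500 permutations; 20 scrambled-label seeds);
10,000 null proteins for ANOVA type-I control; 2,000 permutations and
20 null seeds for GWAS enrichment. The complete suite runs in a few
minutes on one CPU.

## Known limitations

The dynamic-hybrid cut is an adaptive re-derivation, not a port; only
its planted-structure behaviour is guaranteed, not branch-for-branch
agreement with any published implementation. The preservation suite is
the fixed 3+3 statistic subset. The kME reassignment can in principle
reach a label cycle rather than a fixed point (returned with
`converged=False`). Gene mapping uses the symbol prefix of
"Symbol|Accession" identifiers (first symbol wins on multi-symbol
entries), with no identifier service lookups. Missingness handling is
MCAR-oriented throughout; informative missingness would bias the
median polish and the mean-imputed eigenprotein computation alike.
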