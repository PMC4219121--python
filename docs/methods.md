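# Methods

This note documents the statistical procedures implemented in
`survpool`, the choices made where conventions diverge, and what the
synthetic-data generator does and does not emulate.

## Gene centring

Probe-level matrices are mapped to one row per Entrez gene id: probes
mapping to several genes are removed (their signal is unattributable),
probes with no mapping are removed, and multiple probes for the same
gene are averaged arithmetically per sample, ignoring missing values.
Input matrices are assumed to be on a log scale (the output of standard
single-channel or two-colour preprocessing), so the arithmetic mean is a
log-scale average. Raw-data preprocessing itself (probe-level
summarization, loess normalization of two-colour arrays) is out of
scope; the package consumes pre-normalized matrices.

Quantile normalization is available per dataset and is never applied
across datasets — cross-dataset scale is deliberately absorbed by
per-dataset dichotomization instead. The implementation is the
canonical algorithm: the reference distribution is the mean of the
per-column quantile functions on a common grid; each column's values
are replaced by the reference value at their rank, ties receiving the
mean of the reference values at the tied rank positions, and missing
entries excluded from ranking and restored as missing. Two consequences
worth knowing: with ties, the columns' value multisets agree only up to
the tie-averaging; and normalization reorders values *across rows
within a column* only never within, but it can change *row-wise*
(cross-sample) orderings, which is why the simulation pipeline does not
apply it by default before dichotomization.

The order of operations is normalize first (probe-level matrix), then
collapse to genes. The reverse order is defensible too; normalizing at
the probe level keeps the normalization target identical for every
probe of a gene.

## Dichotomization

For each dataset separately, a gene's cutoff is the median (default),
75th or 25th percentile of its non-missing values in that dataset
(linear-interpolation percentile definition, matching the default of
the common statistical environments). Labels:

- median / upper quartile: high iff value > cutoff; everything else
  low. Values exactly at the cutoff go to low, keeping the high group
  strictly above the cutoff.
- lower quartile: low iff value < Q1; everything else high.
- `extremes_only` (optional modifier): high > Q3, low < Q1, middle 50%
  excluded — the alternative reading of "quartile comparison"; the
  default keeps all samples in two groups.

Samples with missing expression for the query gene are excluded; a
dataset with fewer than two usable values is skipped for that gene.
Because labels depend only on within-dataset ranks, they are invariant
under any strictly monotone per-dataset transform — the property that
makes platform heterogeneity tolerable, and the property the test suite
asserts directly.

Multi-gene queries intersect the per-gene assignments: a sample is high
iff high for every query gene, excluded if excluded for any, and low
otherwise ("all high vs the rest"). Clinical filters (age interval,
stage, grade, histology, residual tumour, treatment flags) are applied
*before* cutoffs are computed — the query is defined on the selected
population — and samples missing a constrained covariate are dropped by
that constraint. Samples missing the queried endpoint are excluded
per-query (a cohort may carry OS but not DFS).

## Pooled survival analysis

The labelled samples of all contributing datasets are pooled and
analysed as two groups:

- **Kaplan-Meier**: product-limit estimator per group; censored samples
  at an event time remain at risk for that event.
- **Log-rank**: the standard two-group statistic, sum of observed minus
  expected deaths over distinct event times with the hypergeometric
  variance; p from chi-square with 1 df (two-sided).
- **Cox**: a single binary covariate (high vs low) maximizing the Efron
  tie-corrected partial likelihood. Efron is used because it is the
  default of the survival software this family of analyses
  traditionally runs on. The one-parameter problem is strictly concave,
  so a damped scalar Newton iteration (tolerance 1e-9 on β, max 50
  iterations) suffices and is fast enough to run once per gene in a
  transcriptome-wide screen. The 95% CI is Wald: exp(β ± 1.96·SE) with
  SE from the observed information. Monotone likelihood (the groups
  perfectly separate the event ordering) has no finite maximizer; the
  result is flagged, with an infinite CI, rather than raised.

The pooled analysis is **unstratified** by default (one global fit on
the combined samples); a dataset-stratified Cox (per-dataset baseline
hazards, shared β) is available as a sensitivity option. With
proportional hazards and per-dataset-balanced groups the two agree
closely; they diverge when baseline hazards differ strongly across
datasets.

A replication subtlety: pooling k copies of the same cohort would leave
the HR exactly unchanged under tie conventions that treat replicated
events independently, but replication manufactures tied event times
which Efron's correction down-weights, so the estimate is preserved
only up to that perturbation (the CI still shrinks).

## Transcriptome-wide screen

Each gene in the compendium's gene universe is put through the pooled
analysis; genes absent from all datasets, with degenerate groups, or
with a pooled group smaller than `min_group` (default 10 — smaller
groups make the asymptotics of both tests unreliable) are logged and
omitted. Benjamini-Hochberg is applied across all tested genes to the
log-rank p by default (the Cox Wald p is an option; the two are near
identical in practice). Significant genes are ranked by |log HR|, so
protective and deleterious effects compete on one scale, and the top-k
of each direction are reported.

**Concordance.** Harrell's C uses the gene's *continuous* expression as
the risk score. Raw intensities are not comparable across platforms, so
C is computed within each dataset and combined as the usable-pair-
weighted average of per-dataset indices (equivalently: concordant pairs
are only ever counted within a dataset); a pooled-within-dataset-rank
mode exists for sensitivity checks. Usable pairs are those orderable
under censoring (earlier member has the event; equal times usable only
as event-vs-censored; equal-time double events excluded — Harrell's
original rule); tied risks count 1/2. For genes with HR < 1 the risk is
negated before scoring, so the reported C is the discriminative ability
in the direction of the fitted effect (direction recorded alongside).

**Permutation p.** The survival information is shuffled against the
risk scores (within datasets, matching the combination) and
p = #{C_perm ≥ C_obs}/n_perm. A p of zero is accompanied by the add-one
estimate (r+1)/(n_perm+1), which is the honest upper bound "< 1/n_perm".
Permutation streams are derived from one master seed and the gene's
index in the sorted gene universe, so per-gene results are independent
of screen order. Following the workflow such screens are published
with, C and its permutation p are computed only for the ranked top rows
by default (`cindex="all"` computes them everywhere); the CLI default
is 1,000 shuffles for interactive latency, with 10,000 one flag away.

## miRNA host-gene surrogacy

Roughly half of human miRNAs are intronic, and many are co-transcribed
with their host gene, so a host transcript's array signal can act as a
surrogate for the miRNA. `mirna_query` delegates to the pooled analysis
of the host gene — the numbers are exactly the host gene's — and
annotates the result with the miRNA, host, and vetting status; any
status other than "correlated" sets a caution flag rather than blocking
the query. Vetting correlates host rows against matched direct miRNA
measurements over shared samples (Spearman by default, robust to scale;
Pearson by flag — the choice is a package decision, as the convention
is not settled), BH-adjusts across pairs, and calls "correlated" only
for adjusted p < 0.05 *and* positive correlation (a negative
correlation would invert the surrogate's direction).

## Synthetic compendium generator

Per dataset: latent gene expression ~ N(0,1) per gene and sample; 1-3
probes per gene, each latent plus N(0, 0.3) probe noise, all shifted
and scaled by dataset-specific constants; 5% extra multi-mapping probes
(for the filters to catch); 1% missing cells. Survival is exponential
with baseline mean 40 months (OS) / 30 months (DFS) — the order of
magnitude of ovarian-cancer cohort means, purely cosmetic — with the
hazard multiplied by exp(β_g) for every planted gene g the sample is
high for, *high being defined on the generated gene-centred matrix's
per-dataset median*. Planting on the dichotomized observed scale means
the generator's truth is in exactly the units the pipeline estimates,
making parameter recovery a clean end-to-end check without an
errors-in-variables gap. Censoring is independent exponential with its
rate solved numerically so the expected censored fraction hits the
target (default 30%); targets above 95% are rejected. Clinical
covariates are drawn from configurable marginals with 20% missingness.
One dataset is OS-only and one DFS-only (when there are ≥3), to
exercise endpoint-missingness paths. Everything is driven by one
mandatory seed; outputs are byte-identical per configuration.

What the generator does **not** emulate: microarray noise physics
(probe-sequence or GC effects), correlated gene-gene structure,
informative censoring, competing risks, or miRNA biology beyond a
shared latent factor. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
real-data pathologies.

**Calibration conditions used by the test suite.** Planted-HR recovery
uses a single planted gene (HR 2.0) in 5×200 samples at 30% censoring;
the reported 95% CI covers the truth at its nominal rate. The screen-
recovery check plants 10 effects jointly; because all planted effects
act on the hazard simultaneously, each gene's *marginal* screened HR is
attenuated relative to its conditional (planted) value — the familiar
non-collapsibility of hazard ratios under omitted covariates. The
recovery conditions are therefore 10 effects of |log HR| between
log 1.8 and log 2.2 (both directions) at 1,250 pooled samples, sizes at
which every planted gene is expected to clear BH significance and
outrank all null genes. Null calibration aggregates 20 null compendia
of 200 genes × 600 pooled samples. These problem sizes are the
package's own calibration choices and are stated in the corresponding
test docstrings.

## Degenerate inputs and numerical conventions

Constant genes put every sample in the low group (no error); a dataset
contributes nothing for a gene it lacks; a query to which no dataset
contributes is an error naming the genes and endpoint. Percentiles use
linear interpolation; survival times are stored in months (inputs in
days or years converted by /30.44 and ×12); a cohort needs ≥50 patients
to enter a compendium unless the threshold is lowered explicitly (small
series destabilize per-dataset cutoffs). Clinical vocabulary is matched
case-insensitively (FIGO stage Roman or Arabic, substages truncated to
the major stage; unknown histologies map to "other"); unmappable values
degrade to missing with a warning rather than aborting integration —
survival analysis tolerates missing covariates, not silently wrong
ones.

## Known limitations

No multivariable Cox adjustment for clinical covariates (the design
filters subpopulations rather than adjusting), no proportional-hazards
diagnostics, no time-varying effects, no gene-set enrichment of screen
hits, and no processing of raw array data. The C-index combination
across datasets assumes exchangeable discrimination across platforms;
datasets with very few usable pairs contribute accordingly little.
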