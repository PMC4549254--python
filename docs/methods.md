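# Methods

## Data model

Expression is handled as FPKM — a length- and depth-normalised
relative abundance — in a genes × samples matrix.  All ratio-based
quantities use a small-value floor: FPKM values in (0, 0.1) are raised
to 0.1.  The floor exists to keep log fold-changes finite; exact zeros
are preserved in the stored matrix (so the all-zero filter can see
them) and guarded up to the floor only when a ratio is computed.  The
per-gene fold-change of sample *c* is

    FC(g, c) = log2( max(v(g,c), 0.1) / mean_{c'∈S} max(v(g,c'), 0.1) )

over a designated sample set *S* (the 34 cells, or the cohort).  By
construction the row-mean of `2^FC`, times the floored mean, recovers
the floored mean exactly — a property the tests assert to 1e-9.

## Cleaning

Four pure per-gene filters, each emitting an auditable report
(counts, thresholds, removed gene list):

* **all-zero** — no positive FPKM among the cells;
* **procedure DEGs** — |log2(a/b)| > 2 in any of (pT, xenoT),
  (xenoT, bulkT), (pT, bulkT).  The threshold is two-sided: a shift in
  either direction indicates the xenografting/culture procedure, not
  tumor biology;
* **simple pattern** — expressed (FPKM > 0.1) in at most 2 cells;
  such genes correlate with each other through their shared near-zero
  baseline rather than through co-regulation;
* **ubiquitous** — expressed in *every* cell with all fold-changes in
  the open interval (−3, 3); near-constant housekeeping-like genes
  carry no subgroup signal and correlate trivially.  Boundary values
  retain the gene.

"Expressed" always means FPKM strictly above the floor.  Because each
filter is a predicate on the gene's own values, the filters commute;
a test verifies order-stability.

## Seed-and-expand module discovery

Correlations are Pearson coefficients of log2 fold-change vectors
(the same quantity that is clustered and plotted downstream; raw-FPKM
correlation is available as an option).  Seeds are the connected
components, with at least 5 members, of the graph with an edge where
r ≥ 0.9.  Components rather than cliques: the grouping language of the
underlying method does not require pairwise completeness, and
components are parameter-free.  Expansion adds every gene whose
*mean* correlation to the union of seeds is ≥ 0.75; `min` (every
seed) and `any` (at least one seed) rules are exposed as
configuration but the mean rule is the default — a single-seed rule
is noise-prone with 34 cells, a min rule makes expansion nearly
vacuous above the seed threshold.  A threshold sweep utility reports
module size and mean within-module correlation across expansion
thresholds; size is non-increasing and coherence non-decreasing in
the threshold, which is how the default 0.75 trades module size
against coherence.

## Subgrouping

Samples are clustered on the module fold-change submatrix with
agglomerative hierarchical clustering, Euclidean distance, complete
linkage (the defaults of the standard `hclust`-style routine; both
are configurable), and the dendrogram is cut into exactly two groups
— the analysis is two-state by design, and model selection over k is
a non-goal.  The group with the greater mean module fold-change is
deterministically labelled `up`.  PCA coordinates come from an SVD of
the mean-centred submatrix with samples as observations; component
signs are fixed by forcing each component's largest-magnitude gene
loading positive, so output is reproducible across BLAS builds.

## Clinical statistics

The `up` group is the index group throughout: odds ratios and hazard
ratios are reported for up vs down.  For a 2×2 table with down-column
(a = reference level, b = index level) and up-column (c, d):

* OR = (d·a)/(b·c), 95% CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d));
  any zero cell adds 0.5 to all cells (Haldane–Anscombe) and flags
  the result;
* chi-square is the uncorrected Pearson statistic with 1 df (Yates
  correction behind a flag — the uncorrected statistic is what the
  published survival row's ≈13.0 corresponds to);
* samples missing the variable are dropped and counted.

Logistic regression (statsmodels MLE, complete-case, dropped count
reported) exponentiates coefficients to ORs; perfect separation is
detected and the result withheld.  Survival machinery is lifelines:
product-limit curves (events before ties' censorings), the two-group
log-rank test, and Cox proportional hazards with Efron tie handling
and Wald CIs.  The per-gene screen dichotomises cohort samples at
each module gene's median fold-change and fits a univariate Cox
model; raw p-values are reported with a Benjamini–Hochberg column for
transparency, and "prognostic" means raw p < 0.05 with HR > 1 —
matching the per-gene convention of the underlying analysis rather
than a family-wise criterion.

## Regulator prioritisation and cell-cycle annotation

Candidate TFs must have a predicted binding site within 5 kb upstream
of at least ⌈coverage·|module|⌉ module genes (coverage 0.5, so ≥ 32
of 64; the ceiling keeps "≥ 50%" and the integer cutoff consistent
for even sizes and conservative for odd).  Candidates are ranked by
the mean over module genes of the Pearson correlation between the
TF's expression profile and the gene's profile; correlating against
the module-mean profile instead is a config option.  A TF removed by
cleaning is looked up in the pre-cleaning floored matrix and flagged.
Cell-cycle annotation is a straight gene→stage lookup with an
`unassigned` bucket; counts always sum to the module size.

## Synthetic data

The generator emulates the statistical regime the pipeline assumes:
34 cells, ~2000 genes, a 30-gene module driven by a binary latent
state with 13/34 cells "up" (mirroring the observed subgroup
geometry), 100 simple-pattern genes, 100 housekeeping genes, a bulk
quartet with 150 planted procedure DEGs (exact ±3 log2 multipliers,
so the DEG filter's recall on them is 1 by construction; shifts on
near-floor genes are forced upward because a down-shift there would
be erased by the floor), one planted regulator TF among 10 decoys,
and a 400-sample cohort with exponential survival, true hazard ratio
2.0 for latent-up samples and ~30% independent exponential censoring.

Key modelling choices:

* **Baseline** is log-normal per gene (ln-scale μ = 1, σ = 1) with
  log-normal per-cell biological noise, σ = 0.6 on the ln scale
  (≈ 0.9 log2 units) — the realistic single-cell regime.  A much
  smaller noise would make isolated dropout events dominate each
  gene's variance and manufacture spurious near-perfect correlations
  between genes sharing a single dropout cell.
* **Module effect** is symmetric in log space: module genes are
  multiplied by 2^effect in latent-up cells and by 2^−effect in
  latent-down cells (cell-cycle-like genes: abundant in cycling
  cells, essentially silent otherwise).  At effect 0 the module is
  distributionally identical to background, which the null tests
  rely on.  A one-sided multiplicative shift of 3 log2 units cannot
  survive the ubiquitous filter's (−3, 3) band, so the symmetric
  form is also what makes the planted structure detectable by the
  pipeline's own rules.
* **Dropout** is Bernoulli per gene-cell with an expression-dependent
  probability — logistic in ln-expression with width 0.25, midpoint
  calibrated by bisection so the matrix-wide expected rate equals
  `dropout_prob` (0.2).  Zeros therefore concentrate in weakly
  expressed transcripts, where capture failure actually occurs;
  uniform dropout at 20% would put large uncorrelated spikes into
  every gene and cap attainable gene-gene correlation well below the
  seed threshold.

What the generator does **not** model: count noise (the pipeline
consumes FPKM), gene-length/GC effects, per-cell capture-efficiency
factors, doublets, or continuous cell states.  Passing tests
therefore demonstrate that the pipeline recovers the planted
structure under its own assumptions, not performance on arbitrary
real data.

## Problem sizes and numerics

The validation suite uses 2000-gene matrices, 100-seed replications
for null/regulator/survival calibration and a 400-sample cohort —
sizes at which every property is measurable with comfortable margins
while the whole suite runs in well under a minute.  Correlation
matrices are dense float64; the 9,455² regime of a full transcriptome
fits in ~700 MB and runs through the same code path.  Convergence:
logistic and Cox fits use the backends' defaults (log-likelihood
change < 1e-8, ≤ 100 iterations); fold-change tolerances are 1e-9
relative; correlation symmetry is enforced to 1e-12 and entries
clipped to [−1, 1].  Ties in TF and seed-group orderings break
lexicographically so output order is deterministic.

## Known limitations

* Seed groups are connected components, so a single borderline edge
  can merge two otherwise distinct modules; the threshold sweep is
  the diagnostic.
* The two-group cut is forced; genuinely unimodal cohorts will still
  be split (the up/down mean gap and PC1 variance fraction indicate
  whether the split is meaningful).
* The per-gene survival screen's raw-p selection is intentionally
  uncorrected; use the BH column for a family-wise view.
* Cohort-scale clustering is O(n²) in samples; hundreds of samples
  are fine, tens of thousands are not the target.
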