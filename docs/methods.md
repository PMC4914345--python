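# Methods

## The screen

The pipeline identifies transcription factors (TFs) elevated or active in
basal-like breast cancer by three independent routes and intersects them.

**RNA: median-rank meta-analysis.**  Within each expression cohort, every
gene gets a one-sided Welch (unequal-variance) t-test p-value for higher
mean log-expression in the case group.  Genes are ranked by p within the
cohort (ties take the average rank).  Across cohorts, a gene's meta
statistic is the median of its per-cohort ranks, and the reported meta
p-value is the p actually observed in the cohort realising that median —
never an interpolated value.  For an even number of cohorts the
less-significant (larger) of the two middle ranks is used, so the reported
p always belongs to a real cohort; this is the conservative choice.  Genes
measured in fewer than half the cohorts (configurable) are excluded and
reported.  Selection takes TF-whitelist genes with meta p < 0.05; no
multiplicity correction is applied by default, mirroring the screen's
original raw-α design (a Benjamini–Hochberg option would be a one-line
addition on the output table).  The Welch test is used because the exact
per-cohort statistic of the original meta-analysis platform is
unpublished; Welch is the robust default for unequal group variances.

Under a global null the per-gene selection rate of a *single* cohort sits
exactly at α (the selection p is the t-test p).  Aggregating C > 1 cohorts
by the median rank is strictly conservative: a null gene's median rank
falls below the α-quantile only if at least ⌈C/2⌉ of its independent ranks
do, a binomial tail event (≈10⁻⁷ for C = 15, α = 0.05).  The calibration
tests therefore check exact nominal level on single-cohort screens and
conservativeness (rate ≤ α) on 15-cohort screens.

**DNA: promoter motif over-representation.**  The signature gene set is
the intersection of per-cohort selections (case-elevated, p < 0.01) over
three subtype-annotated cohorts.  Controls are a seeded uniform draw
(without replacement, drawn once, not resampled per run) from genes not
case-elevated.  Promoters are the region from 1 kb upstream of the TSS
through the end of exon 1, on the gene's strand, truncated at contig edges
with a warning; gene tables are 1-based inclusive, internal arithmetic
0-based half-open.

Motif scanning uses the matrix similarity score: with per-position
frequencies f_i(b) (counts plus a 0.25-per-base pseudocount, so no zero
frequencies) and information weights I(i) = Σ_b f_i(b)·ln(4·f_i(b)), a
window scores S = Σ_i I(i)·f_i(b_i), min–max normalised to [0, 1]; the
consensus scores exactly 1.  `N` contributes the position minimum.  Both
strands are scanned (the reverse strand by scoring the forward sequence
with the reverse-complemented matrix); the default threshold is 0.85, a
conventional matrix-similarity cutoff, since the original tool's cutoffs
are unpublished.  The tested frequency is binary per promoter — a promoter
either contains ≥1 site or not — which matches "% of promoters" semantics
and makes the binomial test well defined; a total-site-count mode would
change the test's meaning and is deliberately not offered.

Enrichment is an upper-tail exact binomial test of k_target out of
n_target at the plug-in null proportion k_control/n_control (floored at
0.5/n_control with a warning when no control promoter scores).  A
one-sided Fisher's exact test on the 2×2 occurrence table is always
computed alongside, because the two tests are both defensible here; the
binomial is the default decision rule and both p-values are written to the
output so the discrepancy is visible.  The plug-in binomial is mildly
approximate (the control proportion is estimated); with ≥300 controls its
realised type-I level sits within Monte-Carlo error of nominal in the
calibration tests.

**Protein: reference-normalised array comparison.**  Every spot is divided
by the TFIID reference spot of its own membrane, making results invariant
to per-membrane scale.  Replicates are averaged within each cell line, and
the unit of replication for the group test is the cell line (n = 4 vs 4 in
the original design), not the replicate — pooling replicates would treat
technical repeats as biological ones and be anticonservative.  The test is
Student's equal-variance t (two-sided; the fold-change condition already
enforces direction), and the filter is fold change > 1.4 AND p < 0.05,
both strict, with fold change computed on raw relative intensities.

**Integration.**  Motif hits map to TF genes through an explicit
motif→gene table (exact symbol match; the original literature curation is
an input, not reproducible code).  A gene with ≥2 of the three assay flags
is a candidate; output order is n_assays descending then symbol, so runs
are byte-stable, and all seven Venn-region counts are reported.

**Secondary growth screen.**  Values are percent growth relative to a
non-targeting control.  "Reduced" means mean ≤ 66 — the bound is inclusive
because the reporting bins are <33 / 33–66 / >66 and a boundary value of
66 in a luminal line is counted as that line's reduction in the published
classification.  Critical = reduced in ≥2 of 3 basal-like lines; among
critical siRNAs, 0 / 1 / ≥2 reduced luminal lines give
BLBC-specific / moderately-specific / general.  Calls use means only;
standard deviations are carried for display (an SD-aware z-score mode is
out of scope).  TFs excluded from the secondary screen are simply absent
from the input table.

**Survival.**  The marker is dichotomized strictly above the median by
default (the mean is available; the two conventions coexist in this
literature, so the method is a logged parameter).  Kaplan–Meier curves,
the log-rank (Mantel–Cox) test and the Cox proportional-hazards model are
provided by lifelines behind this module's interface; the Cox fit uses
Efron's tie correction, appropriate for the heavy ties a dichotomized
marker produces, with Wald 95 % intervals on the log scale.  Categorical
covariates are dummy-coded against explicit reference levels, and missing
categories can be kept as an explicit "missing" level so those subjects
stay in the fit.

## Synthetic data

One master seed feeds a fixed substream key per generator, so every output
is byte-identical under a seed and adding a generator never shifts the
others.  Defaults mirror the real design: 702 TF genes, 15 cohorts,
117 signature genes vs 1500 controls, 345 motifs, 2 kb promoters,
triplicate arrays over 4+4 cell lines, true array fold change 2, true
marker hazard ratio 1.42, ~30 % censoring.

- *Expression*: i.i.d. standard-normal log-expression; planted TFs gain a
  mean shift of `effect_size` (in noise-SD units) in the case group of
  every cohort.  Optional per-cohort gene dropout emulates platform
  differences; per-cohort sample sizes are configurable.
- *Promoters*: i.i.d. background with configurable GC; for each planted
  motif, a site sampled from the PWM (optionally the exact consensus) is
  written at a uniform position into `motif_plant_rate` of target
  promoters and `control_plant_rate` of controls.  The per-gene randomness
  is drawn whether or not the site is inserted, so runs at different rates
  under one seed are coupled monotonically.  Insertion positions are
  recorded in the planted truth.
- *Arrays*: multiplicative log-normal spot noise with coefficient of
  variation `array_cv`, a per-membrane scale factor (removed by reference
  normalisation) and a noisy reference spot; bound motifs carry the true
  group ratio `array_fc`.
- *Growth*: planted critical TFs get suppressed means (50 %) in basal-like
  lines and 95 % elsewhere unless an explicit per-line pattern overrides;
  Gaussian noise with `growth_noise_sd`, floored at 0.
- *Survival*: exponential baseline hazard (the simplest model satisfying
  proportional hazards exactly) with Bernoulli(½) covariates; censoring is
  exponential with its rate solved numerically so the expected censored
  fraction equals `censor_rate`.  Censoring tied to the event time (e.g.
  uniform on [0, T]) would be informative and bias the partial-likelihood
  estimate, so an independent censoring distribution is used.  A
  continuous-marker mode records a normal expression level whose hazard
  effect acts through the high/low indicator at the population median,
  emulating a dichotomized prognostic marker.

What the generator does **not** emulate: cross-gene correlation,
platform-specific intensity distributions, batch effects, motif clustering
or GC-matched control promoters, array spatial artifacts, and
non-proportional hazards.  Passing tests therefore certify the
*algorithms* — calibration of the filters, recoverability of planted
signals, agreement with independent oracles — not performance on real
cohorts.

## Numerical choices and degenerate inputs

- One-sided Welch p for a gene with zero variance in both groups and equal
  means is 0.5 (the one-sided p of t = 0), with a warning; zero variance
  with unequal means saturates at the appropriate extreme.
- p-values are clipped into (0, 1]; rank ties average; median-rank ties
  across cohorts break deterministically by (rank, p, cohort id).
- Scan hits are ordered by (position, strand); positions are 1-based on
  the forward strand for the leftmost matched base.
- A PWM that is uniform at every position has S_min = S_max and is
  rejected as degenerate; motifs shorter than 4 positions only warn.
- Boundary rules are strict where the design says "greater than"
  (fold change > 1.4, p < 0.05) and inclusive at the growth bound (≤ 66).
- Cox non-convergence or separation is surfaced by lifelines' own
  warnings; fits require at least one event.

## Problem sizes used in tests

The acceptance-level tests run the screen at desk scale — 5 cohorts ×
400 genes (80 TFs, 10 planted), 60 target vs ~200 control promoters of
400 bp, 30 motifs of length 8, 2000-motif null arrays, 200-rep null
calibrations, and 200 simulated survival cohorts of n = 2000 — sizes
chosen so the full suite exercises every stage, including the end-to-end
planted-truth recovery, in about a minute while keeping Monte-Carlo error
well inside the asserted bounds.  The full-scale defaults (345 motifs,
117 vs 1500 promoters of 2 kb) run end to end in a few minutes via
`tfscreen run-all`.

## Known limitations

- The identity of the real 702-gene TF whitelist, the licensed motif
  library and the literature-curated motif→gene map are external inputs;
  the package validates mechanics against synthetic stand-ins.
- The plug-in binomial enrichment test ignores uncertainty in the control
  proportion; with few controls prefer the Fisher option.
- The published cohort-level counts (132 RNA-selected TFs, 95 enriched
  motifs, 11 bound motifs, 33 candidates) depend on those external data
  and are not reproduced; the integration arithmetic and the secondary
  screen's published table are.
- Real tumor expression violates the generator's independence assumptions;
  calibration results transfer only to the extent those assumptions hold.
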