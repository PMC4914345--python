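# tfscreen

An integrated transcription-factor screen for basal-like breast cancer
(BLBC), implemented as a tested, reusable Python library.  Basal-like
tumors lack the receptors that current targeted therapies exploit, so the
screen looks for the transcription factors (TFs) that drive the subtype by
combining three independent assays and requiring agreement between at least
two of them:

1. **RNA** — for each of several expression cohorts with triple-negative /
   non-triple-negative annotation, every TF gene is tested with a one-sided
   Welch t-test for higher expression in the case group, genes are ranked by
   p-value within each cohort, and cohorts are combined by the **median
   rank**: the meta p-value reported for a gene is the p observed in the
   cohort that realises its median rank.  TFs with median-rank *p* < 0.05
   pass.
2. **DNA** — a signature gene set (genes case-elevated at *p* < 0.01 in each
   of three subtype cohorts) defines target promoters (TSS−1 kb through exon
   1); every TRANSFAC-format position weight matrix is scanned on both
   strands with the matrix similarity score
   MSS = (S − S_min)/(S_max − S_min), S = Σᵢ I(i)·fᵢ(bᵢ),
   I(i) = Σ_b fᵢ(b)·ln 4fᵢ(b), and per-promoter occurrence (≥1 site at
   MSS ≥ 0.85) is compared between target and control promoters with an
   upper-tail exact binomial test (*p* < 0.05).  Enriched motifs map to the
   TF genes that recognise them.
3. **Protein** — protein/DNA-binding array spot intensities, normalised to
   the TFIID reference spot of each membrane and averaged over replicates,
   are compared between basal-like and luminal cell-line groups with a
   Student's t-test on per-cell-line means; motifs with fold change > 1.4
   and *p* < 0.05 pass and map to TF genes.

Genes found by ≥ 2 of the 3 assays are candidates.  A secondary siRNA
screen then calls a candidate **critical** when knockdown reduces growth to
≤ 66 % of the non-targeting control in at least two of three basal-like
lines, and grades specificity by how many luminal lines are also reduced
(0 → BLBC-specific, 1 → moderately specific, ≥ 2 → general).  A survival
module (median/mean dichotomization, Kaplan–Meier, log-rank, Cox
proportional hazards with Efron ties) evaluates a marker's prognostic
value, e.g. the hazard ratio of high vs low SOX11 expression.

Because the original cohorts and the licensed motif library are not
redistributable, the package ships a seeded synthetic-data generator that
emulates every input with a planted, recoverable ground truth — the same
TFs are elevated in expression, own motifs planted into signature
promoters, and are more strongly bound on the arrays — so the whole
pipeline can be exercised and verified at desk scale.

## Worked example

The packaged secondary-screen table (29 siRNAs × 6 breast-cancer cell
lines, growth as % of non-targeting control) is analysed by
`examples/05_growth_screen.py`:

```
critical TFs (8): ['ATF4', 'CDC5L', 'FOSL2', 'FOXM1', 'MYC', 'NFKB2', 'SOX11', 'TFDP1']
class counts: {'not-critical': 21, 'moderately-specific': 4, 'general': 3, 'BLBC-specific': 1}
```

Eight TFs suppress growth by at least one third in ≥ 2 basal-like lines;
MYC, CDC5L and NFKB2 also hit ≥ 2 luminal lines (general growth factors),
ATF4, FOXM1, FOSL2 and TFDP1 hit exactly one, and SOX11 — reduced in all
three basal-like lines and no luminal line — is the sole basal-like-specific
hit.

`examples/07_full_pipeline.py` runs the entire primary screen on a
synthetic dataset with 10 planted TFs and prints the stage funnel and

```
recall of planted truth: 1.00
```

The other examples demonstrate each stage in isolation; each prints its
result with a note on what the numbers mean.  The `tfscreen` command
exposes the same stages as subcommands (`simulate`, `rna`, `dna`,
`protein`, `integrate`, `growth`, `survival`, `run-all`).

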