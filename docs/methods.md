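# Methods

## Wobble-decoding model

Each tRNA isodecoder family is summarised by its anticodon (5'→3', DNA
alphabet; the first base is position 34, the wobble base) and whether it is
a substrate of the ADAT2/3 deaminase (requires A34). Anticodon positions
35/36 pair strict Watson–Crick with codon positions 2/1; the wobble base
pairs with the codon third base according to a rule table that ships as
data (`data/pairing_rules.yaml`) so variant pairing hypotheses can be
tested without code changes:

| wobble base | codon third bases read |
|---|---|
| A | T |
| I (edited A) | A, T, C |
| G | C, T |
| C | G |
| T | A, G |

A family counts as a decoder of a codon only if it is charged with that
codon's amino acid; this keeps near-cognate pairings across split boxes
(e.g. an Ile anticodon over ATG) out of the table. Stop codons carry no
decoders and are excluded. Codon dependency classes follow from the decoder
sets: *strict* (edited decoders only), *dual* (both), *independent* (no
edited decoder). With the shipped human anticodon repertoire — the 8 edited
families plus the standard unedited isoacceptors, with no G34 tRNAs in the
edited boxes — the strict set is the 8 NNC codons GCC, CGC, ATC, CTC, CCC,
TCC, ACC, GTC, and the ADAT-sensitive set (read by any I34 tRNA) is
8 families × third base {A, T, C} = 24 codons.

Whether I34:G pairing is entirely absent is not settled; the default rules
forbid it (NNG codons are never read by edited tRNAs). Allowing it is a
one-line change to the rule file.

## Editing quantification

Inosine is read as guanosine by reverse transcription, so editing appears
as A→G at the wobble position of mature-tRNA alignments. Alignments are
held as a table (one row per reported mapping) with mismatch count (SAM
NM), mapping count (SAM NH) and pre-tRNA flags derived from the alignment
itself: a 5' soft-clip at reference position 1 is leader sequence, a 3'
soft-clip past the reference end is trailer sequence — unless the clip is a
prefix of CCA, the post-transcriptionally added tail, references being
stored without it — and an insertion at the annotated intron site is
intronic sequence. Filters retain ≤ 2 mismatches, ≤ 50 mappings, and no
pre-tRNA evidence; exclusions are tallied by first matching reason so
retained + excluded always equals input.

The wobble position is resolved per family from `anticodon_start` metadata,
never from a hardcoded index (D-loop length varies). Multimapping reads
contribute 1/NH per mapping by default ("fractional"), avoiding double
counting while honouring the ≤ 50-mapping retention rule; "full" weighting
is available. The editing rate is the weighted G fraction at the wobble
position. The default denominator is total coverage (A+C+G+T): C/T calls
are sequencing errors but remain observed alleles; `ag_only` (G/(A+G)) is
provided since the G-allele-ratio definition admits both readings. Wilson
95% intervals come from the weighted (G, coverage) pair; families under
`min_coverage` (default 20) are flagged rather than estimated. At 0.1%
uniform sequencing error the observed G fraction at a true rate of 0.85 is
biased by ~8×10⁻⁴ (errors off G slightly exceed errors onto G), which
costs a little Wilson coverage at very high depth; no correction is
applied because the bias is far below the biological contrasts of
interest. Abundance is the weighted read count per family scaled to reads
per million.

## Translation efficiency and differential calls

Counts are normalised per replicate to CPM (no pseudocount, so columns sum
to exactly 10⁶). TE per gene and replicate is
(RPF_CPM + 0.5)/(RNA_CPM + 0.5); the pseudocount sits only at the ratio
step, keeping TE finite for RNA-zero genes without distorting CPM. Genes
below 1 mean RNA CPM in either condition are excluded from differential
testing (TE is unstable at zero expression; configurable).

Differential translation is tested on log2 TE across replicates. The
default statistic is an empirical-Bayes **moderated t**: gene-wise
variances are modelled as s² ~ s₀²·F(d, d₀), the prior (d₀, s₀²) is fitted
by method of moments on log s² (trigamma inversion), and each gene's
posterior variance (d₀s₀² + d·s²)/(d₀+d) feeds a t statistic with d₀+d
degrees of freedom. The motivation is the study design itself: with two
replicates per condition an unmoderated t has 2 residual degrees of
freedom and a 5% critical value of 4.30, so essentially nothing can be
called regardless of effect size; variance moderation is the field's
standard answer, and the implementation agrees with the reference R
implementation (limma) to within ~0.01 in p on shared inputs (checked in
the test suite via Rscript). Plain Student's t (`t_log`) and an exact
label-permutation test are retained as options — noting that with 2+2
replicates only three distinct label splits exist, so the permutation p
cannot reach 0.05. Calls use the joint gate p < 0.05 and |log2 FC| ≥
log2(1.5), two-sided.

SILAC protein ratios are the arithmetic mean of all peptide H/L ratios of
the protein (mean of ratios, deliberately not ratio of means); replicate-
level means support a one-sample test of log2 ratio against 0 — moderated
t by default, matching few-replicate proteomics practice — with BH
adjustment across proteins and the joint gate adjusted p < 0.05 and
|log2 ratio| ≥ 0.5.

## Codon usage and enrichment

Codon usage of an ORF is the relative frequency of each of the 61 sense
codons (terminal stop dropped; in-frame internal stops are errors;
ambiguous codons are dropped up to a configurable tolerance). Per-gene
frequencies — not per-amino-acid RSCU — are the unit of analysis, so every
gene contributes equally regardless of length; pooled per-codon averaging
is available for genome-wide summaries. Gene-set comparisons (TE-down vs
TE-up, and TE-down vs all other classified genes) test each codon with a
two-sided Mann–Whitney on per-gene frequencies (exact for small groups,
tie-corrected normal approximation otherwise; all-tied columns give p = 1),
report the log2 ratio of pseudocount-stabilised (10⁻⁴) mean frequencies as
the effect size, and control FDR by BH across the 61 codons. Raw p and q
are both reported. Results are joined to the decoding table so strict/dual/
ADAT-sensitive behaviour can be summarised per dependency class.

## Synthetic data generator

The generator emulates the study design, one seeded `numpy` Generator per
call, fully deterministic given `SimConfig.seed`.

*tRNA-seq*: per family, `coverage` full-length reads over a simulated
mature reference (anticodon planted at position 33–35 so metadata-driven
indexing is exercised); each read carries G at the wobble position with the
family's editing rate — multiplied by `kd_editing_factor` under knockdown —
then uniform per-base substitution errors. Configurable fractions of reads
carry disjoint filter violations (3 extra mismatches, a leader/trailer/
intron signature, or 51 mappings). Reads are emitted as alignment tables
and as SAM with NM/NH tags; alignment itself is upstream of this pipeline,
so no FASTQ is produced.

*Transcriptome*: ORFs are assembled codon-by-codon — strict codons
(uniform over the 8) at the gene's target fraction, the remainder drawn
from the human genome-average codon usage renormalised over the 53
non-strict sense codons — ATG-initiated, stop-terminated, no internal
stops. Target fractions are uniform over (0.05, 0.30), bracketing the
~15% strict-codon content of the average human gene.

*Counts*: RNA counts are gamma-Poisson, i.e. marginally negative binomial
with variance m + φm² (φ = `dispersion`, default 0.1) around a lognormal
expression profile. The gamma factor represents biological
replicate-to-replicate expression variability and is **shared between the
RPF and input libraries of a replicate**, because both derive from the same
lysate; it therefore cancels in TE. This pairing is what makes TE
comparisons at n = 2 informative at all — modelling the two assays as
independent NB draws buries any TE signal under dispersion noise that the
real paired design never sees. RPF means are expression × TE, with
log2 TE = gene baseline − beta · strict_fraction · (1 − kd_editing_factor)
under knockdown, plus N(0, 0.25) noise per replicate in both conditions
(replicate-level rather than a gene-level knockdown offset, so that
beta = 0 is an exact null with calibrated tests). beta (default 2) is the
log2 TE decrement per unit strict-codon fraction × editing deficit; at the
default 4-fold knockdown the largest planted shifts are ≈ −0.5 log2 units,
detectable but deliberately not trivial at two replicates.

*Peptides*: per protein and technical replicate, `n_peptides` H/L ratios
lognormal (sdlog 0.1) around the protein's true ratio.

What the generator does **not** model: positional sequencing-error
profiles, fragment-length or ligation bias, isodecoder heterogeneity
within a family, per-family knockdown heterogeneity (one global editing
factor), transcriptional co-regulation between genes, and ribosome
dwell-time effects. Passing tests therefore demonstrate the statistical
machinery recovers planted structure under the assumed noise model, not
that real libraries are free of these additional effects.

## Problem sizes and numerical choices

The default study conditions are 8 families × 5,000 reads, 2,000 genes of
150–500 codons, 2 replicates per condition at 2×10⁶ reads per library, and
3 technical SILAC replicates × 10 peptides. The test suite and the
acceptance script run at these sizes (the acceptance script uses 100
editing-recovery seeds and 12 translatome seeds per arm). Ties in the
Mann–Whitney use the tie-corrected asymptotic p above 20 observations;
Wilson intervals accept weighted (fractional) counts; the trigamma
inversion in the variance-prior fit uses bracketed root finding on
(10⁻⁶, 10⁸) and falls back to an infinite-d₀ (common-variance) limit when
log-variance spread is at or below chi-square expectation. Degenerate
inputs are defined errors: empty ORFs, zero library sizes, non-positive
ratios, groups below three genes, coverage below the floor.

## Known limitations

- The editing estimator treats the wobble column as independent binomial
  evidence; correlated errors (e.g. RT fall-off at modified sites) would
  bias it and are not modelled.
- The moderated t assumes exchangeable gene variances on log2 TE; strong
  mean-variance trends would call for a trended prior, which is not
  implemented.
- Enrichment p-values treat genes as independent; co-regulated gene
  modules would inflate significance in real data.
- The CLI orchestrates single runs; there is no workflow-manager
  integration or plotting beyond the TSV outputs.
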