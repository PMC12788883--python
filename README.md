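# adatpipe

Analysis pipeline for **tRNA wobble A-to-I editing and codon-biased
translation**: from small-RNA-seq alignments and ribosome-profiling counts
to per-family inosine levels, differential translation efficiency, and
ADAT-sensitive codon enrichment in the affected gene sets.

## The problem

The ADAT2/3 deaminase edits adenosine to inosine at position 34 (the wobble
position) of eight human tRNA isoacceptor families (Ala-AGC, Arg-ACG,
Ile-AAT, Leu-AAG, Pro-AGG, Ser-AGA, Thr-AGT, Val-AAC). A34 pairs only with
U, while I34 pairs with A, U and C — and because the human genome encodes no
G34 tRNAs in those families, the **C-ending (NNC) codons of the eight boxes
can only be decoded through editing**. Depleting ADAT2 therefore lowers I34
levels and selectively slows translation of mRNAs rich in those codons.

The pipeline makes each link of that chain quantitative:

1. **Decoding model** — from an anticodon table and wobble pairing rules
   (A34→U; I34→A,U,C; G34→C,U; C34→G; U34→A,G; strict Watson–Crick at
   positions 35/36), classify all 61 sense codons as *strict* (decodable
   only via I34), *dual* (with or without editing) or *independent*, and
   derive the 24 ADAT-sensitive codons. DNA alphabet (T for U) throughout.
2. **Editing quantification** — inosine reads as G, so the editing rate of
   a family is the G fraction at its wobble position:
   `rate = G / (A+C+G+T)` over filtered alignments (≤2 mismatches, ≤50
   mappings, no pre-tRNA leader/trailer/intron evidence), with a Wilson
   95% interval, plus reads-per-million abundance.
3. **Translatome** — `TE = RPF_CPM / RNA_CPM` per replicate; differential
   translation between knockdown and control by a moderated t on log2 TE,
   gated at p < 0.05 and 1.5-fold. A SILAC branch aggregates peptide H/L
   ratios (protein ratio = mean of peptide ratios) and gates proteins at
   BH-adjusted p < 0.05 and |log2 ratio| ≥ 0.5.
4. **Codon enrichment** — per-gene relative usage of the 61 sense codons;
   per-codon two-sided Mann–Whitney between the TE-down set and the up /
   all-other sets, BH-corrected, joined to the decoding classes.
5. **Synthetic data** — a seeded generator producing every input (SAM
   alignments with planted editing, ORFs with controlled strict-codon
   content, negative-binomial RPF/RNA counts in which knockdown reduces TE
   in proportion to strict-codon content, peptide tables), so the whole
   analysis is testable without the original sequencing data.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (all computation lives in the `adatpipe` package; the scripts only
orchestrate and narrate):

```sh
python analysis/01_simulate_data.py      # inputs -> scratch/sim_bundle
python analysis/02_wobble_editing.py     # editing rates -> results/
python analysis/03_translation_efficiency.py
python analysis/04_codon_enrichment.py
python analysis/05_silac_proteome.py
```

`02_wobble_editing.py` prints, per family, the I34 fraction in control vs
knockdown — the simulated 4-fold editing knockdown is recovered from the
SAM alignments:

```
condition     control  knockdown  fold_change
tRNA-Ala-AGC    0.952      0.244        3.907
tRNA-Thr-AGT    0.794      0.208        3.817
...
mean fold reduction: 3.94x
```

`03_translation_efficiency.py` calls differential translation
(2,000 genes, 2 replicates per condition):

```
classes: {'unchanged': 1910, 'down': 54, 'up': 36}
mean strict-codon fraction by TE class:
down 0.256   unchanged 0.173   up 0.121
```

— genes dense in strict codons sink, as the decoding model predicts. And
`04_codon_enrichment.py` shows every strict NNC codon (including CGC, CCC,
GCC, ACC) significantly enriched in the TE-down set:

```
mean log2 usage change by dependency class (Down vs Up):
strict  1.086    dual -0.237    independent -0.220
8 ADAT-sensitive codons significantly enriched (q<0.05) in TE-down
```

The same machinery is exposed as a CLI (`adatpipe simulate | edit | te |
codons | run-all`) driven by a YAML config; `run-all` writes all TSV
tables plus a JSON run report with per-stage read/gene accounting.

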