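"""Synthetic data with the statistical structure the analysis assumes.

Generates every input the pipeline consumes, so each stage and the
end-to-end analysis are testable without the study's deposited raw data:

* mature tRNA references (FASTA + metadata TSV) and wobble-spanning read
  alignments (SAM / alignment table) in which reads carry G at the wobble
  position with the family's editing rate — reduced by ``kd_editing_factor``
  in the knockdown condition — plus uniform per-base sequencing error and a
  configurable fraction of filter-violating reads (excess mismatches,
  pre-tRNA leader/trailer/intron evidence, excess multimapping);
* ORFs assembled codon-by-codon with a per-gene target fraction of
  strictly editing-dependent (strict NNC) codons over a human-genome
  average background usage;
* replicate RPF / input-RNA count matrices under a negative-binomial model
  in which knockdown reduces a gene's TE in proportion to its strict-codon
  content: log2 TE_kd = log2 TE_ctrl − beta · strict_fraction · (1 −
  kd_editing_factor), with per-replicate Gaussian noise on log2 TE;
* SILAC peptide H/L ratio tables, lognormal around each protein's true
  ratio.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator`` per call, so identical configs give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decoding import SENSE_CODONS, build_decoding_table, default_families
from .editing import READ_COLUMNS, TRNAReference

__all__ = [
    "SimConfig",
    "DEFAULT_EDITING_RATES",
    "HUMAN_CODON_USAGE",
    "simulate_references",
    "simulate_trna_reads",
    "simulate_transcriptome",
    "simulate_counts",
    "simulate_peptides",
    "simulate_all",
    "write_sam",
    "write_references",
]

#: control-condition I34 fraction per edited isodecoder family (editing is
#: near-complete for most families in unperturbed cells)
DEFAULT_EDITING_RATES: dict[str, float] = {
    "tRNA-Ala-AGC": 0.95,
    "tRNA-Arg-ACG": 0.90,
    "tRNA-Ile-AAT": 0.90,
    "tRNA-Leu-AAG": 0.95,
    "tRNA-Pro-AGG": 0.85,
    "tRNA-Ser-AGA": 0.90,
    "tRNA-Thr-AGT": 0.80,
    "tRNA-Val-AAC": 0.90,
}

#: human genome-average codon usage, frequencies per thousand codons
HUMAN_CODON_USAGE: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "CAT": 10.9, "CAC": 15.1,
    "CAA": 12.3, "CAG": 34.2, "AAT": 17.0, "AAC": 19.1,
    "AAA": 24.4, "AAG": 31.9, "GAT": 21.8, "GAC": 25.1,
    "GAA": 29.0, "GAG": 39.6, "TGT": 10.6, "TGC": 12.6,
    "TGG": 13.2, "CGT": 4.5, "CGC": 10.4, "CGA": 6.2,
    "CGG": 11.4, "AGT": 12.1, "AGC": 19.5, "AGA": 12.2,
    "AGG": 12.0, "GGT": 10.8, "GGC": 22.2, "GGA": 16.5,
    "GGG": 16.5,
}

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    tRNA-seq branch: ``editing_rates`` (family → control I34 fraction),
    ``kd_editing_factor`` (multiplier on rates under knockdown; 0.25 is a
    4-fold editing reduction), ``coverage`` (wobble-spanning reads per
    family), ``seq_error`` (uniform per-base substitution probability) and
    the filter-violation fractions.

    Translatome branch: ``n_genes`` ORFs with lengths uniform in
    ``orf_length_range`` (codons) and per-gene strict-codon target
    fractions uniform in ``strict_fraction_range``; RNA counts are
    NB(lognormal expression, ``dispersion``) at library ``depth``; RPF
    counts follow expression × TE, where log2 TE loses
    ``beta · strict_fraction · (1 − kd_editing_factor)`` under knockdown
    and every replicate TE carries N(0, ``te_noise_log2``) noise. ``beta``
    is the log2 TE decrement per unit strict-fraction × editing deficit;
    beta = 0 is the null.

    SILAC branch: ``n_peptides`` peptides per protein per replicate, H/L
    ratios lognormal with sdlog ``peptide_sigma`` around the protein's
    true ratio, ``n_pep_replicates`` technical replicates.
    """

    seed: int = 0
    # tRNA-seq
    editing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDITING_RATES)
    )
    kd_editing_factor: float = 0.25
    coverage: int = 5000
    seq_error: float = 0.001
    frac_high_mismatch: float = 0.01
    frac_pretrna: float = 0.01
    frac_multimap: float = 0.01
    # transcriptome / counts
    n_genes: int = 2000
    orf_length_range: tuple[int, int] = (150, 500)
    strict_fraction_range: tuple[float, float] = (0.05, 0.30)
    beta: float = 2.0
    te_noise_log2: float = 0.25
    te_spread_log2: float = 1.0
    expr_sigma: float = 1.0
    dispersion: float = 0.1
    depth: float = 2e6
    n_reps: int = 2
    # proteomics
    n_peptides: int = 10
    peptide_sigma: float = 0.1
    n_pep_replicates: int = 3

    def __post_init__(self) -> None:
        probs = [
            self.kd_editing_factor,
            self.seq_error,
            self.frac_high_mismatch,
            self.frac_pretrna,
            self.frac_multimap,
            *self.editing_rates.values(),
            *self.strict_fraction_range,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.kd_editing_factor == 0:
            raise ValueError("kd_editing_factor must be in (0, 1]")
        if self.beta < 0 or self.depth <= 0 or self.dispersion < 0:
            raise ValueError("beta >= 0, depth > 0 and dispersion >= 0 required")
        if self.orf_length_range[0] < 1 or self.orf_length_range[0] > self.orf_length_range[1]:
            raise ValueError("invalid orf_length_range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("orf_length_range", "strict_fraction_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["orf_length_range"] = list(self.orf_length_range)
        data["strict_fraction_range"] = list(self.strict_fraction_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# tRNA references and reads


def simulate_references(cfg: SimConfig, length: int = 76) -> dict[str, TRNAReference]:
    """Mature references for the edited families, anticodon planted near
    position 34 (the exact offset varies to exercise metadata-driven
    indexing). Deterministic in ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed + 101)
    fams = {f.family_id: f for f in default_families()}
    refs: dict[str, TRNAReference] = {}
    for i, fam_id in enumerate(sorted(cfg.editing_rates)):
        fam = fams[fam_id]
        seq = rng.choice(list("ACGT"), size=length)
        start = int(rng.integers(33, 36))  # anticodon_start in {33,34,35}
        seq[start - 1 : start + 2] = list(fam.anticodon)
        # canonical tRNA introns sit one base 3' of the anticodon
        intron_start = start + 3 if i % 3 == 0 else 0
        refs[fam_id] = TRNAReference(
            family_id=fam_id,
            mature_sequence="".join(seq),
            anticodon_start=start,
            intron_start=intron_start,
        )
    return refs


def _bytes_to_strs(arr: np.ndarray) -> list[str]:
    return [row.tobytes().decode() for row in arr]


def _simulate_family_reads(
    rng: np.random.Generator,
    ref: TRNAReference,
    rate: float,
    cfg: SimConfig,
    prefix: str,
) -> pd.DataFrame:
    """Full-length reads over one family with planted editing and errors."""
    n = cfg.coverage
    L = len(ref.mature_sequence)
    ref_arr = np.frombuffer(ref.mature_sequence.encode(), dtype=np.uint8)
    reads = np.tile(ref_arr, (n, 1))
    wob = ref.wobble_position - 1
    edited = rng.random(n) < rate
    reads[edited, wob] = ord("G")
    # uniform substitution errors: shift to one of the 3 other bases
    err = rng.random((n, L)) < cfg.seq_error
    if err.any():
        idx = np.nonzero(err)
        cur = reads[idx]
        shift = rng.integers(1, 4, size=len(cur)).astype(np.uint8)
        base_idx = np.searchsorted(_BASE_BYTES, cur)
        reads[idx] = _BASE_BYTES[(base_idx + shift) % 4]

    # disjoint filter-violation assignments
    kinds = np.array(["ok", "mm", "pre", "multi"])
    probs = np.array(
        [
            1 - cfg.frac_high_mismatch - cfg.frac_pretrna - cfg.frac_multimap,
            cfg.frac_high_mismatch,
            cfg.frac_pretrna,
            cfg.frac_multimap,
        ]
    )
    kind = kinds[rng.choice(4, size=n, p=probs)]

    mm_rows = np.nonzero(kind == "mm")[0]
    for r in mm_rows:  # plant 3 extra substitutions off the wobble position
        pos = rng.choice([p for p in range(L) if p != wob], size=3, replace=False)
        cur = reads[r, pos]
        shift = rng.integers(1, 4, size=3).astype(np.uint8)
        reads[r, pos] = _BASE_BYTES[(np.searchsorted(_BASE_BYTES, cur) + shift) % 4]

    mismatches = (reads != ref_arr).sum(axis=1)
    n_mappings = np.ones(n, dtype=int)
    n_mappings[kind == "multi"] = 51

    leader = np.zeros(n, bool)
    trailer = np.zeros(n, bool)
    intron = np.zeros(n, bool)
    clip5 = np.array([""] * n, dtype=object)
    clip3 = np.array([""] * n, dtype=object)
    intron_insert = np.array([""] * n, dtype=object)
    pre_rows = np.nonzero(kind == "pre")[0]
    for r in pre_rows:
        choices = ["leader", "trailer"] + (["intron"] if ref.intron_start else [])
        what = choices[int(rng.integers(len(choices)))]
        extra = "".join(rng.choice(list("ACGT"), size=4))
        if what == "leader":
            leader[r] = True
            clip5[r] = extra
        elif what == "trailer":
            trailer[r] = True
            clip3[r] = "G" + extra  # never a CCA-tail prefix
        else:
            intron[r] = True
            intron_insert[r] = extra

    df = pd.DataFrame(
        {
            "read_id": [f"{prefix}_{ref.family_id}_{i}" for i in range(n)],
            "family_id": ref.family_id,
            "start": 1,
            "end": L,
            "seq": _bytes_to_strs(reads),
            "mismatches": mismatches,
            "n_mappings": n_mappings,
            "leader": leader,
            "trailer": trailer,
            "intron": intron,
            "clip5": clip5,
            "clip3": clip3,
            "intron_insert": intron_insert,
        }
    )
    return df


def simulate_trna_reads(
    cfg: SimConfig, refs: dict[str, TRNAReference] | None = None
) -> tuple[dict[str, pd.DataFrame], dict[str, TRNAReference]]:
    """Alignment tables for control and knockdown tRNA-seq.

    Control reads carry G at the wobble position with the family's editing
    rate; knockdown rates are multiplied by ``kd_editing_factor``. Extra
    columns (clip5/clip3/intron_insert) carry the raw pre-tRNA sequence for
    the SAM writer and are ignored by the analysis stages.
    """
    if refs is None:
        refs = simulate_references(cfg)
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, pd.DataFrame] = {}
    for cond, factor in (("control", 1.0), ("knockdown", cfg.kd_editing_factor)):
        frames = [
            _simulate_family_reads(
                rng, refs[fam], rate * factor, cfg, prefix=cond[:4]
            )
            for fam, rate in sorted(cfg.editing_rates.items())
        ]
        out[cond] = pd.concat(frames, ignore_index=True)
    return out, refs


def write_references(refs: dict[str, TRNAReference], fasta_path: str | Path, meta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for fam in sorted(refs):
            fh.write(f">{fam}\n{refs[fam].mature_sequence}\n")
    meta = pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "anticodon_start": r.anticodon_start,
                "gene_copies": r.gene_copies,
                "intron_start": r.intron_start,
            }
            for r in refs.values()
        ]
    ).sort_values("family_id")
    meta.to_csv(meta_path, sep="\t", index=False)


def write_sam(reads: pd.DataFrame, refs: dict[str, TRNAReference], path: str | Path) -> None:
    """Write the alignment table as SAM with NM/NH tags.

    Pre-tRNA evidence is emitted as the alignment signatures the reader
    recognises: 5' soft-clip at reference position 1 (leader), 3'
    soft-clip at the reference end (trailer), insertion at the annotated
    intron site (intron).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for fam in sorted(refs):
            fh.write(f"@SQ\tSN:{fam}\tLN:{len(refs[fam].mature_sequence)}\n")
        for row in reads.itertuples(index=False):
            ref = refs[row.family_id]
            aln_len = row.end - row.start + 1
            clip5 = getattr(row, "clip5", "") or ""
            clip3 = getattr(row, "clip3", "") or ""
            ins = getattr(row, "intron_insert", "") or ""
            seq = row.seq
            cigar = ""
            if clip5:
                cigar += f"{len(clip5)}S"
            if ins:
                at = ref.intron_start - row.start  # offset into aligned seq
                cigar += f"{at}M{len(ins)}I{aln_len - at}M"
                seq = seq[:at] + ins + seq[at:]
            else:
                cigar += f"{aln_len}M"
            if clip3:
                cigar += f"{len(clip3)}S"
            full = clip5 + seq + clip3
            fh.write(
                f"{row.read_id}\t0\t{row.family_id}\t{row.start}\t255\t{cigar}\t*\t0\t0\t"
                f"{full}\t*\tNM:i:{row.mismatches}\tNH:i:{row.n_mappings}\n"
            )


# ---------------------------------------------------------------------------
# transcriptome, counts, peptides


def simulate_transcriptome(
    cfg: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """ORFs with controlled strict-codon content.

    Each gene's body codons are drawn strict (uniform over the 8 strict NNC
    codons) with the gene's target probability, otherwise from the
    human-average background usage renormalised over non-strict sense
    codons; so a target of 0 yields an ORF with no strict codons. ORFs
    start with ATG and end with a stop, with no internal stops.

    Returns (gene_id → sequence, truth table with target and realized
    strict fractions and lengths).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    table = build_decoding_table(default_families())
    strict = np.array(sorted(table.strict_codons))
    background = np.array([c for c in SENSE_CODONS if c not in set(strict)])
    bg_w = np.array([HUMAN_CODON_USAGE[c] for c in background])
    bg_w = bg_w / bg_w.sum()

    lo, hi = cfg.orf_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    targets = rng.uniform(*cfg.strict_fraction_range, size=cfg.n_genes)
    total = int(lengths.sum())
    is_strict = rng.random(total) < np.repeat(targets, lengths)
    strict_draws = strict[rng.integers(0, len(strict), size=total)]
    bg_draws = background[rng.choice(len(background), size=total, p=bg_w)]
    codons = np.where(is_strict, strict_draws, bg_draws)
    stops = np.array(["TAA", "TAG", "TGA"])[rng.integers(0, 3, size=cfg.n_genes)]

    seqs: dict[str, str] = {}
    realized = np.empty(cfg.n_genes)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    for g in range(cfg.n_genes):
        s, e = offsets[g], offsets[g + 1]
        body = codons[s:e]
        gid = f"gene_{g:05d}"
        seqs[gid] = "ATG" + "".join(body) + stops[g]
        realized[g] = is_strict[s:e].sum() / (lengths[g] + 1)  # ATG counts in the ORF
    truth = pd.DataFrame(
        {
            "gene_id": list(seqs),
            "n_codons": lengths + 1,
            "strict_fraction_target": targets,
            "strict_fraction": realized,
        }
    ).set_index("gene_id")
    return seqs, truth


def simulate_counts(
    cfg: SimConfig, truth: pd.DataFrame
) -> dict[str, pd.DataFrame | pd.Series]:
    """Replicate RPF and input-RNA count matrices for control and knockdown.

    RNA counts are negative-binomial around a lognormal expression profile
    (gamma-Poisson: a per-replicate gamma expression factor with the
    configured dispersion, then Poisson sequencing noise). The gamma factor
    is biological replicate-to-replicate variability, and because the RPF
    and input libraries of a replicate derive from the same lysate it is
    shared between the two assays of that replicate — so it cancels in TE,
    the property that makes TE comparisons at n = 2 informative. RPF counts
    are Poisson around expression × TE. Per replicate, log2 TE = gene
    baseline − beta · strict_fraction · (1 − kd_editing_factor) under
    knockdown, plus N(0, te_noise_log2) replicate noise in both conditions.

    Returns dict with "rpf", "rna" (genes × replicates) and "conditions"
    (replicate → condition) plus the per-gene true TE shift
    ("true_te_shift_log2").
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = truth.index
    n = len(genes)
    expr = rng.lognormal(mean=0.0, sigma=cfg.expr_sigma, size=n)
    te_base_log2 = rng.normal(0.0, cfg.te_spread_log2, size=n)
    shift = -cfg.beta * truth["strict_fraction"].to_numpy() * (1 - cfg.kd_editing_factor)

    conds = {}
    rna_cols, rpf_cols = {}, {}
    for cond in ("control", "knockdown"):
        for r in range(1, cfg.n_reps + 1):
            label = f"{'ctrl' if cond == 'control' else 'kd'}_{r}"
            conds[label] = cond
            if cfg.dispersion > 0:
                bio = rng.gamma(1.0 / cfg.dispersion, cfg.dispersion, size=n)
            else:
                bio = np.ones(n)
            lam = expr * bio  # replicate's expression, shared by both assays
            rna_mean = cfg.depth * lam / lam.sum()
            rna_cols[label] = rng.poisson(rna_mean)
            te_log2 = te_base_log2 + (shift if cond == "knockdown" else 0.0)
            te_log2 = te_log2 + rng.normal(0.0, cfg.te_noise_log2, size=n)
            load = lam * 2.0 ** te_log2
            rpf_mean = cfg.depth * load / load.sum()
            rpf_cols[label] = rng.poisson(rpf_mean)
    return {
        "rna": pd.DataFrame(rna_cols, index=genes),
        "rpf": pd.DataFrame(rpf_cols, index=genes),
        "conditions": pd.Series(conds, name="condition"),
        "true_te_shift_log2": pd.Series(shift, index=genes, name="true_te_shift_log2"),
    }


def simulate_peptides(
    cfg: SimConfig, true_ratios: pd.Series
) -> pd.DataFrame:
    """SILAC peptide table: per protein and technical replicate,
    ``n_peptides`` H/L ratios lognormal (sdlog ``peptide_sigma``) around the
    protein's true ratio."""
    if (true_ratios <= 0).any():
        raise ValueError("true ratios must be positive")
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    for pid, ratio in true_ratios.items():
        for rep in range(1, cfg.n_pep_replicates + 1):
            vals = ratio * rng.lognormal(0.0, cfg.peptide_sigma, size=cfg.n_peptides)
            for j, v in enumerate(vals):
                rows.append((pid, f"{pid}_r{rep}_p{j}", v, rep))
    return pd.DataFrame(rows, columns=["protein_id", "peptide_id", "ratio", "replicate"])


def simulate_all(cfg: SimConfig, outdir: str | Path | None = None) -> dict:
    """Generate the full input bundle; optionally write it to ``outdir``
    (FASTA, SAM, TSVs, config YAML and a truth table)."""
    reads, refs = simulate_trna_reads(cfg)
    seqs, truth = simulate_transcriptome(cfg)
    counts = simulate_counts(cfg, truth)
    bundle = {"reads": reads, "refs": refs, "orfs": seqs, "truth": truth, **counts}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_references(refs, out / "trna_refs.fasta", out / "trna_refs.tsv")
        for cond, df in reads.items():
            write_sam(df, refs, out / f"trna_{cond}.sam")
        with open(out / "cds.fasta", "w") as fh:
            for gid, seq in seqs.items():
                fh.write(f">{gid}\n{seq}\n")
        counts["rna"].to_csv(out / "rna_counts.tsv", sep="\t", index_label="gene_id")
        counts["rpf"].to_csv(out / "rpf_counts.tsv", sep="\t", index_label="gene_id")
        counts["conditions"].rename_axis("replicate").to_csv(
            out / "conditions.tsv", sep="\t"
        )
        truth.join(counts["true_te_shift_log2"]).to_csv(
            out / "truth.tsv", sep="\t", index_label="gene_id"
        )
        cfg.to_yaml(out / "sim_config.yaml")
    return bundle
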