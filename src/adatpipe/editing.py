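"""Quantification of A-to-I editing at the tRNA wobble position.

Inosine reverse-transcribes as guanosine, so editing at tRNA position 34
appears as an A→G mismatch in reads over the mature reference. This module
takes alignments against mature tRNA references (SAM, or an equivalent
in-memory alignment table), applies the mature-tRNA read filters, piles up
base calls at each family's wobble position, and estimates the per-family
editing rate with a Wilson binomial interval, plus steady-state abundance
in reads per million.

Alignment table
---------------
Alignments are held as a pandas DataFrame with one row per mapping and
columns::

    read_id, family_id, start, end, seq, mismatches, n_mappings,
    leader, trailer, intron

``start``/``end`` are 1-based inclusive coordinates on the mature
reference; ``seq`` is the aligned read sequence over [start, end]
(clipped/inserted bases removed); ``mismatches`` is the edit distance to
the reference (SAM NM), ``n_mappings`` the number of reported mappings
(SAM NH); the three booleans flag pre-tRNA evidence (5' leader, 3' trailer
or intronic sequence). A 3' soft-clip that is a prefix of "CCA" is the
post-transcriptional CCA tail, not trailer sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TRNAReference",
    "READ_COLUMNS",
    "read_sam",
    "read_references",
    "filter_alignments",
    "pileup_at_wobble",
    "editing_rate",
    "abundance",
]

READ_COLUMNS = [
    "read_id",
    "family_id",
    "start",
    "end",
    "seq",
    "mismatches",
    "n_mappings",
    "leader",
    "trailer",
    "intron",
]

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class TRNAReference:
    """A mature tRNA reference sequence (stored without the 3' CCA tail).

    ``anticodon_start`` is the 1-based index of the first anticodon base,
    i.e. the wobble position (tRNA position 34). It is metadata, not a
    hardcoded index: variable D-loop lengths shift the anticodon within the
    sequence. ``intron_start`` (1-based, 0 = none) marks where an intron
    sits in the pre-tRNA, used to flag intron-carrying reads.
    """

    family_id: str
    mature_sequence: str
    anticodon_start: int
    gene_copies: int = 1
    intron_start: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.anticodon_start <= len(self.mature_sequence) - 2:
            raise ValueError(
                f"{self.family_id}: anticodon_start {self.anticodon_start} outside "
                f"mature sequence of length {len(self.mature_sequence)}"
            )

    @property
    def wobble_position(self) -> int:
        return self.anticodon_start

    @property
    def anticodon(self) -> str:
        i = self.anticodon_start - 1
        return self.mature_sequence[i : i + 3]


def read_references(fasta_path: str | Path, metadata_path: str | Path) -> dict[str, TRNAReference]:
    """Load mature references from FASTA plus a metadata TSV
    (family_id, anticodon_start[, gene_copies, intron_start])."""
    from Bio import SeqIO

    meta = pd.read_csv(metadata_path, sep="\t").set_index("family_id")
    refs: dict[str, TRNAReference] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.loc[rec.id]
        refs[rec.id] = TRNAReference(
            family_id=rec.id,
            mature_sequence=str(rec.seq).upper(),
            anticodon_start=int(row["anticodon_start"]),
            gene_copies=int(row.get("gene_copies", 1) or 1),
            intron_start=int(row.get("intron_start", 0) or 0),
        )
    return refs


def _trailer_clip_is_cca_tail(clip_seq: str) -> bool:
    return "CCA".startswith(clip_seq)


def read_sam(path: str | Path, refs: dict[str, TRNAReference]) -> pd.DataFrame:
    """Parse a SAM file of mature-tRNA alignments into the alignment table.

    Mismatches come from the NM tag, multimapping counts from NH (defaults
    1 when absent). Pre-tRNA evidence is derived from the alignment itself:
    a 5' soft-clip when the read starts at reference position 1 is leader
    sequence, a 3' soft-clip when it ends at the reference end is trailer
    sequence (unless it is a prefix of the CCA tail), and an insertion at
    the annotated intron site is intronic sequence.
    """
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            fam = aln.reference_name
            ref = refs.get(fam)
            if ref is None:
                raise ValueError(f"read {aln.query_name} maps to unknown family {fam!r}")
            start = aln.reference_start + 1  # to 1-based
            end = aln.reference_end  # pysam end is exclusive 0-based == inclusive 1-based
            if end > len(ref.mature_sequence):
                raise ValueError(
                    f"read {aln.query_name} extends past reference {fam} "
                    f"({end} > {len(ref.mature_sequence)})"
                )
            cig = aln.cigartuples or []
            qseq = aln.query_sequence or ""
            leader = trailer = intron = False
            if cig and cig[0][0] == 4 and start == 1:
                leader = True
            if cig and cig[-1][0] == 4 and end == len(ref.mature_sequence):
                clip = qseq[len(qseq) - cig[-1][1] :]
                trailer = not _trailer_clip_is_cca_tail(clip)
            # reconstruct the reference-aligned sequence; note insertions
            aligned = []
            qpos = 0
            rpos = start
            for op, length in cig:
                if op == 4:  # soft clip
                    qpos += length
                elif op == 0 or op == 7 or op == 8:  # M/=/X
                    aligned.append(qseq[qpos : qpos + length])
                    qpos += length
                    rpos += length
                elif op == 1:  # insertion: intronic if at the annotated site
                    if ref.intron_start and rpos == ref.intron_start:
                        intron = True
                    qpos += length
                elif op == 2:  # deletion consumes reference
                    aligned.append("-" * length)
                    rpos += length
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            rows.append(
                (
                    aln.query_name,
                    fam,
                    start,
                    end,
                    "".join(aligned),
                    int(nm),
                    int(nh),
                    leader,
                    trailer,
                    intron,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def filter_alignments(
    reads: pd.DataFrame,
    max_mismatches: int = 2,
    max_mappings: int = 50,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the mature-tRNA read filters.

    Retains alignments with at most ``max_mismatches`` mismatches, at most
    ``max_mappings`` reported mappings, and no pre-tRNA evidence (leader,
    trailer or intron). Returns the retained table and a tally of
    exclusions by reason (``mismatches``, ``multimapping``, ``pre_trna``,
    plus ``retained``); each excluded row is counted once, under the first
    reason in that order. Idempotent: filtering a filtered table excludes
    nothing further.
    """
    if max_mismatches < 0 or max_mappings < 0:
        raise ValueError("filter thresholds must be non-negative")
    too_many_mm = reads["mismatches"] > max_mismatches
    too_many_maps = ~too_many_mm & (reads["n_mappings"] > max_mappings)
    pre_trna = (
        ~too_many_mm
        & ~too_many_maps
        & (reads["leader"] | reads["trailer"] | reads["intron"])
    )
    keep = ~(too_many_mm | too_many_maps | pre_trna)
    tally = {
        "mismatches": int(too_many_mm.sum()),
        "multimapping": int(too_many_maps.sum()),
        "pre_trna": int(pre_trna.sum()),
        "retained": int(keep.sum()),
    }
    return reads.loc[keep].reset_index(drop=True), tally


def _read_weights(reads: pd.DataFrame, weighting: str) -> np.ndarray:
    if weighting == "fractional":
        return 1.0 / reads["n_mappings"].to_numpy(float)
    if weighting == "full":
        return np.ones(len(reads))
    raise ValueError(f"unknown weighting {weighting!r}")


def pileup_at_wobble(
    reads: pd.DataFrame,
    refs: dict[str, TRNAReference],
    weighting: str = "fractional",
) -> pd.DataFrame:
    """Weighted base counts at each family's wobble position.

    Reads not spanning the wobble position contribute nothing. With
    ``fractional`` weighting (default) each mapping contributes
    1/n_mappings, so a read with N reported mappings adds up to one unit of
    evidence in total; ``full`` weights every mapping 1.

    Returns a DataFrame indexed by family_id with columns A, C, G, T,
    coverage and n_not_spanning, covering every family in ``refs``.
    """
    unknown = set(reads["family_id"]) - set(refs)
    if unknown:
        raise ValueError(f"reads map to families without references: {sorted(unknown)}")
    counts = pd.DataFrame(
        0.0, index=pd.Index(sorted(refs), name="family_id"), columns=list(BASES)
    )
    not_spanning = pd.Series(0, index=counts.index, dtype=int)
    if len(reads):
        weights = _read_weights(reads, weighting)
        wob = reads["family_id"].map(lambda f: refs[f].wobble_position).to_numpy(int)
        start = reads["start"].to_numpy(int)
        end = reads["end"].to_numpy(int)
        if (start < 1).any() or (start > end).any():
            raise ValueError("read coordinates outside reference")
        spans = (start <= wob) & (wob <= end)
        offs = wob - start
        seqs = reads["seq"].to_numpy(object)
        base_at = np.array(
            [s[o] if sp else "" for s, o, sp in zip(seqs, offs, spans)], dtype=object
        )
        for base in BASES:
            mask = base_at == base
            if mask.any():
                add = (
                    pd.Series(weights[mask])
                    .groupby(reads["family_id"].to_numpy(object)[mask])
                    .sum()
                )
                counts.loc[add.index, base] += add
        ns = pd.Series(~spans).groupby(reads["family_id"].to_numpy(object)).sum()
        not_spanning.loc[ns.index] += ns.astype(int)
    out = counts.copy()
    out["coverage"] = counts.sum(axis=1)
    out["n_not_spanning"] = not_spanning
    return out


def editing_rate(
    pileup: pd.DataFrame,
    denominator: str = "total",
    min_coverage: float = 20,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-family A-to-I editing rate: the G fraction at the wobble position.

    ``denominator="total"`` (default) divides the G count by all observed
    bases, treating C/T calls as sequencing error but keeping them in the
    denominator; ``"ag_only"`` divides by A+G. The Wilson score interval at
    ``conf_level`` is computed on (G count, denominator). Families with
    coverage below ``min_coverage`` are flagged ``insufficient_coverage``
    and carry no estimate (NaN).
    """
    if denominator not in ("total", "ag_only"):
        raise ValueError(f"unknown denominator {denominator!r}")
    g = pileup["G"].to_numpy(float)
    denom = (
        pileup["coverage"].to_numpy(float)
        if denominator == "total"
        else (pileup["A"] + pileup["G"]).to_numpy(float)
    )
    ok = pileup["coverage"].to_numpy(float) >= min_coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(ok & (denom > 0), g / np.maximum(denom, 1e-300), np.nan)
    lo = np.full(len(pileup), np.nan)
    hi = np.full(len(pileup), np.nan)
    est = ok & (denom > 0)
    if est.any():
        lo[est], hi[est] = proportion_confint(
            g[est], denom[est], alpha=1 - conf_level, method="wilson"
        )
    out = pd.DataFrame(
        {
            "coverage": pileup["coverage"],
            "rate": rate,
            "ci_low": lo,
            "ci_high": hi,
            "insufficient_coverage": ~ok,
        },
        index=pileup.index,
    )
    return out


def abundance(reads: pd.DataFrame, refs: dict[str, TRNAReference], weighting: str = "fractional") -> pd.DataFrame:
    """Steady-state abundance per family: weighted read count and RPM.

    RPM sums to 1e6 over families. Raises if no reads were retained.
    """
    if not len(reads):
        raise ValueError("no retained reads: abundance undefined")
    weights = pd.Series(_read_weights(reads, weighting), index=reads.index)
    totals = weights.groupby(reads["family_id"]).sum()
    out = pd.DataFrame(0.0, index=pd.Index(sorted(refs), name="family_id"), columns=["count"])
    out.loc[totals.index, "count"] = totals
    out["rpm"] = out["count"] / out["count"].sum() * 1e6
    return out
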