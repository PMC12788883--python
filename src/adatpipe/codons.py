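"""Per-ORF codon usage and ADAT-sensitive codon enrichment tests.

Codon usage is the per-gene relative frequency of each of the 61 sense
codons (not per-amino-acid RSCU; an RSCU option exists but is off by
default). Gene sets defined by differential-translation or
differential-protein classes are compared codon-by-codon with a two-sided
Mann–Whitney (Wilcoxon rank-sum) test on per-gene frequencies, BH-corrected
across the 61 codons, and joined to the wobble-decoding table so that
strict (NNC) and dual ADAT-sensitive codons can be read off directly.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decoding import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, DecodingTable

__all__ = [
    "codon_usage_profile",
    "profiles_from_sequences",
    "profiles_from_fasta",
    "global_usage",
    "usage_change",
    "codon_enrichment_test",
    "gene_set_report",
]

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _split_codons(orf: str, ambiguity_tolerance: float) -> list[str]:
    orf = orf.upper().replace("U", "T")
    if len(orf) == 0:
        raise ValueError("empty ORF")
    if len(orf) % 3:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]  # terminal stop is not decoded by an elongator tRNA
    if not codons:
        raise ValueError("ORF contains only a stop codon")
    internal_stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if internal_stops:
        raise ValueError(f"in-frame internal stop at codon {internal_stops[0] + 1}")
    ambiguous = [c for c in codons if any(b not in "ACGT" for b in c)]
    if len(ambiguous) > ambiguity_tolerance * len(codons):
        raise ValueError(
            f"{len(ambiguous)}/{len(codons)} codons carry ambiguous bases "
            f"(tolerance {ambiguity_tolerance:.3g})"
        )
    return [c for c in codons if c not in set(ambiguous)]


def codon_usage_profile(
    orf: str, ambiguity_tolerance: float = 0.0
) -> tuple[pd.Series, int]:
    """Relative codon frequencies of one ORF over the 61 sense codons.

    The ORF must be in frame from the annotated CDS start; the terminal
    stop is dropped and an in-frame internal stop is an error. Codons with
    ambiguous bases are dropped if their fraction stays within
    ``ambiguity_tolerance``, else an error. Returns (frequency Series over
    all 61 sense codons summing to 1, number of counted codons).
    """
    codons = _split_codons(orf, ambiguity_tolerance)
    counts = Counter(codons)
    freq = pd.Series(0.0, index=pd.Index(SENSE_CODONS, name="codon"))
    for codon, n in counts.items():
        freq[codon] = n
    return freq / len(codons), len(codons)


def profiles_from_sequences(
    seqs: dict[str, str], ambiguity_tolerance: float = 0.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Codon-usage profiles for a gene_id -> ORF mapping.

    Returns (genes x 61 frequency DataFrame, per-gene codon counts).
    """
    rows, ns, ids = [], [], []
    for gid, seq in seqs.items():
        freq, n = codon_usage_profile(seq, ambiguity_tolerance)
        rows.append(freq.to_numpy())
        ns.append(n)
        ids.append(gid)
    idx = pd.Index(ids, name="gene_id")
    profiles = pd.DataFrame(np.array(rows), index=idx, columns=list(SENSE_CODONS))
    return profiles, pd.Series(ns, index=idx, name="n_codons")


def profiles_from_fasta(path: str | Path, ambiguity_tolerance: float = 0.0):
    """Profiles from a CDS FASTA keyed by gene id."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    return profiles_from_sequences(seqs, ambiguity_tolerance)


def global_usage(
    profiles: pd.DataFrame,
    weighting: str = "per_gene",
    n_codons: pd.Series | None = None,
) -> pd.Series:
    """Average codon usage over a gene set.

    ``per_gene`` (default) averages per-gene frequencies so every gene
    counts equally; ``per_codon`` pools codon counts, weighting genes by
    length (requires ``n_codons``). Output sums to 1.
    """
    if not len(profiles):
        raise ValueError("empty profile set")
    if weighting == "per_gene":
        return profiles.mean(axis=0)
    if weighting == "per_codon":
        if n_codons is None:
            raise ValueError("per_codon weighting needs per-gene codon counts")
        pooled = profiles.mul(n_codons.reindex(profiles.index), axis=0).sum(axis=0)
        return pooled / pooled.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def usage_change(
    set_a: pd.DataFrame, set_b: pd.DataFrame, pseudo_freq: float = 1e-4
) -> pd.Series:
    """Per-codon log2 ratio of mean usage between two gene sets.

    Means are stabilised with a small pseudo-frequency so codons absent
    from one set stay finite; the statistic is antisymmetric in (a, b).
    """
    if not len(set_a) or not len(set_b):
        raise ValueError("both gene sets must be non-empty")
    mean_a = set_a.mean(axis=0) + pseudo_freq
    mean_b = set_b.mean(axis=0) + pseudo_freq
    return np.log2(mean_a / mean_b)


def _rank_test(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all tied: no evidence either way
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def codon_enrichment_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    table: DecodingTable | None = None,
    pseudo_freq: float = 1e-4,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-codon enrichment of group_a over group_b.

    A two-sided Mann–Whitney test on per-gene codon frequencies for each of
    the 61 sense codons, BH-corrected across codons, with the log2 ratio of
    pseudo-stabilised mean usage as the effect size. When a decoding table
    is given, each codon is annotated with its editing-dependency class and
    ADAT-sensitivity flag.
    """
    if len(group_a) < min_group or len(group_b) < min_group:
        raise ValueError(
            f"each group needs >= {min_group} genes "
            f"(got {len(group_a)} and {len(group_b)})"
        )
    delta = usage_change(group_a, group_b, pseudo_freq)
    a = group_a.to_numpy(float)
    b = group_b.to_numpy(float)
    pvals = np.array(
        [_rank_test(a[:, j], b[:, j]) for j in range(len(SENSE_CODONS))]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "amino_acid": [CODON_TO_AA[c] for c in SENSE_CODONS],
            "mean_a": group_a.mean(axis=0),
            "mean_b": group_b.mean(axis=0),
            "delta_log2": delta,
            "p_value": pvals,
            "q_value": qvals,
        },
        index=pd.Index(SENSE_CODONS, name="codon"),
    )
    if table is not None:
        ann = table.annotate(list(SENSE_CODONS))
        out["dependency"] = ann["dependency"].to_numpy()
        out["adat_sensitive"] = ann["adat_sensitive"].to_numpy()
    return out


def gene_set_report(
    classes: pd.Series,
    profiles: pd.DataFrame,
    table: DecodingTable,
    max_missing_frac: float = 0.05,
    pseudo_freq: float = 1e-4,
) -> dict:
    """Codon-enrichment report for Down vs Up and Down vs All-other.

    ``classes`` maps gene_id -> {"up", "down", "unchanged"} (from
    differential TE or differential protein calls); "all other" is every
    classified gene outside the Down set. Profiles must cover the
    classified genes up to ``max_missing_frac``; beyond that an error lists
    the missing gene ids.

    Returns a dict with the two enrichment tables (``down_vs_up``,
    ``down_vs_all``), group sizes, and a per-dependency-class summary of
    mean enrichment (strict NNC vs dual vs independent) in Down vs Up.
    """
    classified = classes.dropna()
    missing = classified.index.difference(profiles.index)
    if len(missing) > max_missing_frac * max(len(classified), 1):
        raise ValueError(
            f"profiles missing for {len(missing)} classified genes: "
            f"{sorted(missing)[:20]}..."
        )
    classified = classified.drop(missing, errors="ignore")
    down = profiles.loc[classified.index[classified == "down"]]
    up = profiles.loc[classified.index[classified == "up"]]
    other = profiles.loc[classified.index[classified != "down"]]

    down_vs_up = codon_enrichment_test(down, up, table, pseudo_freq)
    down_vs_all = codon_enrichment_test(down, other, table, pseudo_freq)

    summary = (
        down_vs_up.groupby("dependency")["delta_log2"]
        .agg(["mean", "median", "count"])
        .rename(columns={"count": "n_codons"})
    )
    return {
        "down_vs_up": down_vs_up,
        "down_vs_all": down_vs_all,
        "group_sizes": {"down": len(down), "up": len(up), "all_other": len(other)},
        "dependency_summary": summary,
    }
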