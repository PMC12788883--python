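"""Anticodon→codon wobble-decoding model.

Builds a decoding table over the 61 sense codons from a set of tRNA
isoacceptor families and a wobble pairing-rule table, and classifies each
codon by its dependence on A-to-I editing of the wobble adenosine (A34→I34):

* ``strict`` — readable only by an inosine-edited (I34) tRNA; with the
  standard rules and a G34-free gene set these are C-ending (NNC) codons of
  the eight edited families.
* ``dual`` — readable both with and without editing (by the unedited A34
  tRNA or by another isoacceptor of the same amino acid).
* ``independent`` — not read by any edited tRNA.

Conventions: DNA alphabet throughout (T stands for U), matching FASTA/SAM
inputs. Anticodons are written 5'→3', so the wobble base (tRNA position 34)
is the first anticodon character and pairs with the third codon base;
anticodon positions 35/36 pair strict Watson–Crick with codon positions 2/1.
Decoders are restricted to families charged with the codon's amino acid, so
near-cognate pairings across a split codon box (e.g. an Ile tRNA over ATG)
never count. Stop codons carry no tRNA decoders and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

__all__ = [
    "TRNAFamily",
    "DecodingTable",
    "DEFAULT_PAIRING_RULES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "build_decoding_table",
    "classify_codon",
    "adat_sensitive_codons",
    "load_families",
    "default_families",
    "default_edited_families",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: codon → 1-letter amino acid, standard nuclear code, DNA alphabet
CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons

#: wobble base → codon third bases it can read ("I" = inosine-edited A34)
DEFAULT_PAIRING_RULES: dict[str, frozenset[str]] = {
    "A": frozenset("T"),
    "I": frozenset("ATC"),
    "G": frozenset("CT"),
    "C": frozenset("G"),
    "T": frozenset("AG"),
}


class InvalidFamilyError(ValueError):
    """Raised for malformed tRNA family definitions."""


@dataclass(frozen=True)
class TRNAFamily:
    """A tRNA isodecoder family (all genes sharing one anticodon).

    Parameters
    ----------
    family_id : str
        e.g. ``"tRNA-Val-AAC"``.
    amino_acid : str
        Three-letter amino-acid code (``"Val"``).
    anticodon : str
        Anticodon 5'→3' over {A,C,G,T}; the first base is the wobble
        position (tRNA position 34).
    edited : bool
        Whether the family is a substrate of the ADAT2/3 deaminase
        (requires an A at the wobble position).
    """

    family_id: str
    amino_acid: str
    anticodon: str
    edited: bool = False

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or any(b not in "ACGT" for b in self.anticodon):
            raise InvalidFamilyError(
                f"{self.family_id}: anticodon {self.anticodon!r} is not a 3-mer over ACGT"
            )
        if self.edited and self.wobble_base != "A":
            raise InvalidFamilyError(
                f"{self.family_id}: edited families must carry A at the wobble "
                f"position, got {self.wobble_base!r}"
            )

    @property
    def wobble_base(self) -> str:
        return self.anticodon[0]

    def decoded_codons(
        self,
        pairing_rules: dict[str, frozenset[str]] | None = None,
        edited_state: bool = False,
    ) -> set[str]:
        """Sense codons this family reads, in the given editing state.

        ``edited_state=True`` applies the inosine ("I") pairing rule at the
        wobble position; only meaningful for families with ``edited=True``.
        Codons of a different amino acid (possible across split boxes) and
        stop codons are never returned.
        """
        rules = DEFAULT_PAIRING_RULES if pairing_rules is None else pairing_rules
        wobble = "I" if edited_state else self.wobble_base
        third_bases = rules.get(wobble, frozenset())
        # codon positions 1,2 are Watson-Crick complements of anticodon 36,35
        stem = _COMPLEMENT[self.anticodon[2]] + _COMPLEMENT[self.anticodon[1]]
        codons = {stem + third for third in third_bases}
        return {
            c
            for c in codons
            if c in CODON_TO_AA and seq3(CODON_TO_AA[c]) == self.amino_acid
        }


@dataclass
class DecodingTable:
    """Per-codon decoding record over the 61 sense codons.

    ``frame`` columns: ``codon`` (index), ``amino_acid`` (3-letter),
    ``dependency`` (strict/dual/independent), ``decoders_unedited`` and
    ``decoders_edited`` (frozensets of family ids).
    """

    frame: pd.DataFrame = field(repr=False)

    def dependency(self, codon: str) -> str:
        if codon in STOP_CODONS:
            raise ValueError(f"{codon} is a stop codon; stop codons have no tRNA decoders")
        if codon not in self.frame.index:
            raise ValueError(f"{codon!r} is not a sense codon")
        return self.frame.at[codon, "dependency"]

    def codons_with(self, dependency: str) -> set[str]:
        return set(self.frame.index[self.frame["dependency"] == dependency])

    @property
    def strict_codons(self) -> set[str]:
        return self.codons_with("strict")

    @property
    def adat_sensitive(self) -> set[str]:
        """Codons read by an ADAT-edited (I34) tRNA: strict ∪ dual-via-I34."""
        has_edited = self.frame["decoders_edited"].map(len) > 0
        return set(self.frame.index[has_edited])

    def annotate(self, codons: pd.Index | list[str]) -> pd.DataFrame:
        """Dependency class and ADAT-sensitivity flag for a codon list."""
        sens = self.adat_sensitive
        sub = self.frame.loc[list(codons), ["amino_acid", "dependency"]].copy()
        sub["adat_sensitive"] = [c in sens for c in codons]
        return sub

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        for col in ("decoders_unedited", "decoders_edited"):
            out[col] = out[col].map(lambda s: ",".join(sorted(s)))
        out.to_csv(path, sep="\t", index_label="codon")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DecodingTable":
        frame = pd.read_csv(path, sep="\t", index_col="codon", keep_default_na=False)
        for col in ("decoders_unedited", "decoders_edited"):
            frame[col] = frame[col].map(
                lambda s: frozenset(s.split(",")) if s else frozenset()
            )
        return cls(frame)


def build_decoding_table(
    families: list[TRNAFamily],
    pairing_rules: dict[str, frozenset[str]] | None = None,
) -> DecodingTable:
    """Build the wobble-decoding table for a tRNA gene set.

    For every sense codon, records which families read it without editing
    (``decoders_unedited``) and which read it only through I34
    (``decoders_edited``), then classifies its editing dependency:
    strict ⇔ no unedited decoder but an edited one; independent ⇔ no edited
    decoder; dual otherwise. Codons of amino acids with no supplied family
    have empty decoder sets and are independent.

    Raises on duplicate family ids (each isodecoder family appears once).
    """
    seen: set[str] = set()
    for fam in families:
        if fam.family_id in seen:
            raise InvalidFamilyError(f"duplicate family_id {fam.family_id!r}")
        seen.add(fam.family_id)

    unedited: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    edited: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    for fam in families:
        for codon in fam.decoded_codons(pairing_rules, edited_state=False):
            unedited[codon].add(fam.family_id)
        if fam.edited:
            for codon in fam.decoded_codons(pairing_rules, edited_state=True):
                edited[codon].add(fam.family_id)

    records = []
    for codon in SENSE_CODONS:
        if not unedited[codon] and edited[codon]:
            dep = "strict"
        elif edited[codon]:
            dep = "dual"
        else:
            dep = "independent"
        records.append(
            {
                "codon": codon,
                "amino_acid": seq3(CODON_TO_AA[codon]),
                "dependency": dep,
                "decoders_unedited": frozenset(unedited[codon]),
                "decoders_edited": frozenset(edited[codon]),
            }
        )
    return DecodingTable(pd.DataFrame(records).set_index("codon"))


def classify_codon(codon: str, table: DecodingTable) -> str:
    """Editing-dependency class of a sense codon; errors on stop/malformed."""
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"{codon!r} is not a valid DNA triplet")
    return table.dependency(codon)


def adat_sensitive_codons(table: DecodingTable) -> set[str]:
    """All codons read by an ADAT-edited (I34) tRNA."""
    return table.adat_sensitive


def load_families(path: str | Path) -> list[TRNAFamily]:
    """Read families from a TSV with columns family_id, amino_acid, anticodon, edited."""
    df = pd.read_csv(path, sep="\t", dtype={"edited": int})
    return [
        TRNAFamily(r.family_id, r.amino_acid, r.anticodon, bool(r.edited))
        for r in df.itertuples(index=False)
    ]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("adatpipe").joinpath("data", name)))


def default_families() -> list[TRNAFamily]:
    """The shipped human isoacceptor set: 8 ADAT-edited families plus the
    standard unedited cytoplasmic anticodon repertoire (no G34 tRNAs in the
    edited amino-acid boxes)."""
    return load_families(_data_path("trna_families.tsv"))


def default_edited_families() -> list[TRNAFamily]:
    return [f for f in default_families() if f.edited]


def load_pairing_rules(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Pairing rules from YAML (wobble base → list of codon third bases)."""
    p = _data_path("pairing_rules.yaml") if path is None else Path(path)
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    return {k: frozenset(v) for k, v in raw.items()}
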