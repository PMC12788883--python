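"""Read filtering, wobble pileups, editing rates, abundance."""

import numpy as np
import pandas as pd
import pytest

from adatpipe.editing import (
    TRNAReference,
    abundance,
    editing_rate,
    filter_alignments,
    pileup_at_wobble,
    read_references,
    read_sam,
)
from adatpipe.simulate import SimConfig, simulate_trna_reads, write_references, write_sam
from conftest import make_reads

REF = TRNAReference("famA", "ACGTACGTAA", anticodon_start=4)
REFS = {"famA": REF, "famB": TRNAReference("famB", "ACGTACGTAA", anticodon_start=4)}


def full_span(fam, base, mm=0, nh=1, **flags):
    seq = list(REF.mature_sequence)
    seq[3] = base
    kw = dict(leader=False, trailer=False, intron=False)
    kw.update(flags)
    return (fam, 1, 10, "".join(seq), mm, nh, kw["leader"], kw["trailer"], kw["intron"])


class TestFilter:
    def test_each_violation_excluded_under_its_reason(self):
        reads = make_reads(
            [
                full_span("famA", "G"),
                full_span("famA", "G", mm=3),
                full_span("famA", "G", nh=51),
                full_span("famA", "G", leader=True),
                full_span("famA", "G", trailer=True),
                full_span("famA", "G", intron=True),
            ]
        )
        kept, tally = filter_alignments(reads)
        assert tally == {"mismatches": 1, "multimapping": 1, "pre_trna": 3, "retained": 1}
        assert len(kept) == 1

    def test_boundary_values_retained(self):
        reads = make_reads([full_span("famA", "G", mm=2, nh=50)])
        kept, tally = filter_alignments(reads)
        assert tally["retained"] == 1

    def test_idempotent(self):
        reads = make_reads(
            [full_span("famA", "G"), full_span("famA", "A", mm=3), full_span("famA", "G", nh=99)]
        )
        once, _ = filter_alignments(reads)
        twice, tally2 = filter_alignments(once)
        pd.testing.assert_frame_equal(once, twice)
        assert tally2 == {"mismatches": 0, "multimapping": 0, "pre_trna": 0, "retained": len(once)}

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            filter_alignments(make_reads([]), max_mismatches=-1)


class TestPileup:
    def test_single_read_counts_g(self):
        pile = pileup_at_wobble(make_reads([full_span("famA", "G")]), REFS)
        assert pile.loc["famA", "G"] == 1.0
        assert pile.loc["famA", "coverage"] == 1.0
        assert pile.loc["famB", "coverage"] == 0.0

    def test_fractional_weighting_splits_multimapper(self):
        reads = make_reads(
            [full_span("famA", "G", nh=2), full_span("famB", "G", nh=2)]
        )
        pile = pileup_at_wobble(reads, REFS, weighting="fractional")
        assert pile.loc["famA", "G"] == pytest.approx(0.5)
        assert pile.loc["famB", "G"] == pytest.approx(0.5)
        full = pileup_at_wobble(reads, REFS, weighting="full")
        assert full.loc["famA", "G"] == 1.0

    def test_read_not_spanning_wobble_contributes_nothing(self):
        reads = make_reads([("famA", 5, 10, "CGTAA", 0, 1, False, False, False)])
        pile = pileup_at_wobble(reads, REFS)
        assert pile.loc["famA", "coverage"] == 0.0
        assert pile.loc["famA", "n_not_spanning"] == 1

    def test_unknown_family_and_bad_coords_error(self):
        with pytest.raises(ValueError):
            pileup_at_wobble(make_reads([full_span("famX", "G")]), REFS)
        bad = make_reads([("famA", 0, 10, "XACGTACGTAA", 0, 1, False, False, False)])
        with pytest.raises(ValueError):
            pileup_at_wobble(bad, REFS)


def pile_from_counts(**counts):
    row = {b: float(counts.get(b, 0)) for b in "ACGT"}
    df = pd.DataFrame([row], index=pd.Index(["famA"], name="family_id"))
    df["coverage"] = df[list("ACGT")].sum(axis=1)
    df["n_not_spanning"] = 0
    return df


class TestEditingRate:
    def test_direct_ratio(self):
        est = editing_rate(pile_from_counts(A=60, G=40))
        assert est.loc["famA", "rate"] == pytest.approx(0.40)
        assert est.loc["famA", "ci_low"] < 0.40 < est.loc["famA", "ci_high"]

    def test_boundaries(self):
        assert editing_rate(pile_from_counts(G=100)).loc["famA", "rate"] == 1.0
        assert editing_rate(pile_from_counts(A=100)).loc["famA", "rate"] == 0.0

    def test_denominator_variants(self):
        pile = pile_from_counts(A=58, G=40, T=2)
        total = editing_rate(pile, denominator="total").loc["famA", "rate"]
        ag = editing_rate(pile, denominator="ag_only").loc["famA", "rate"]
        assert total == pytest.approx(0.40)
        assert ag == pytest.approx(40 / 98)
        assert total <= ag  # C+T > 0 shrinks the total-denominator rate

    def test_insufficient_coverage_flagged(self):
        est = editing_rate(pile_from_counts(A=5, G=5), min_coverage=20)
        assert est.loc["famA", "insufficient_coverage"]
        assert np.isnan(est.loc["famA", "rate"])

    def test_ci_orders_and_bounds(self):
        est = editing_rate(pile_from_counts(A=30, G=70))
        lo, r, hi = est.loc["famA", ["ci_low", "rate", "ci_high"]]
        assert 0 <= lo <= r <= hi <= 1


class TestAbundance:
    def test_rpm_normalisation(self):
        reads = make_reads([full_span("famA", "G")] * 75 + [full_span("famB", "A")] * 25)
        ab = abundance(reads, REFS)
        assert ab.loc["famA", "rpm"] == pytest.approx(750_000)
        assert ab.loc["famB", "rpm"] == pytest.approx(250_000)
        assert ab["rpm"].sum() == pytest.approx(1e6)

    def test_scale_invariance(self):
        r1 = make_reads([full_span("famA", "G")] * 3 + [full_span("famB", "A")])
        r10 = make_reads([full_span("famA", "G")] * 30 + [full_span("famB", "A")] * 10)
        pd.testing.assert_series_equal(abundance(r1, REFS)["rpm"], abundance(r10, REFS)["rpm"])

    def test_fractional_weights_sum(self):
        reads = make_reads([full_span("famA", "G", nh=2), full_span("famA", "A", nh=2)])
        ab = abundance(reads, REFS)
        assert ab.loc["famA", "count"] == pytest.approx(1.0)

    def test_no_reads_errors(self):
        with pytest.raises(ValueError):
            abundance(make_reads([]), REFS)


class TestSamRoundTrip:
    def test_sam_preserves_filters_and_rates(self, tmp_path):
        cfg = SimConfig(seed=11, coverage=300)
        reads, refs = simulate_trna_reads(cfg)
        write_references(refs, tmp_path / "r.fa", tmp_path / "r.tsv")
        write_sam(reads["control"], refs, tmp_path / "c.sam")
        refs2 = read_references(tmp_path / "r.fa", tmp_path / "r.tsv")
        back = read_sam(tmp_path / "c.sam", refs2)

        kept1, tally1 = filter_alignments(reads["control"])
        kept2, tally2 = filter_alignments(back)
        assert tally1 == tally2
        r1 = editing_rate(pileup_at_wobble(kept1, refs))["rate"]
        r2 = editing_rate(pileup_at_wobble(kept2, refs2))["rate"]
        pd.testing.assert_series_equal(r1, r2)

    def test_cca_tail_clip_is_not_trailer(self, tmp_path):
        ref = TRNAReference("famA", "ACGTACGTAA", anticodon_start=4)
        refs = {"famA": ref}
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:famA\tLN:10\n"
            "cca\t0\tfamA\t1\t255\t10M3S\t*\t0\t0\tACGTACGTAACCA\t*\tNM:i:0\tNH:i:1\n"
            "trail\t0\tfamA\t1\t255\t10M3S\t*\t0\t0\tACGTACGTAAGGG\t*\tNM:i:0\tNH:i:1\n"
        )
        df = read_sam(sam, refs)
        assert not df.set_index("read_id").loc["cca", "trailer"]
        assert df.set_index("read_id").loc["trail", "trailer"]
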