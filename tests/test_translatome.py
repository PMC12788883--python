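"""CPM, TE, differential translation, SILAC aggregation."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from adatpipe.translatome import (
    aggregate_silac,
    classify_protein,
    differential_protein,
    differential_te,
    filter_expressed,
    moderated_ttest_ind,
    normalize_cpm,
    translation_efficiency,
)

CONDS = pd.Series(
    {"ctrl_1": "control", "ctrl_2": "control", "kd_1": "knockdown", "kd_2": "knockdown"}
)


def te_frame(ctrl, kd, genes=None):
    genes = genes or [f"g{i}" for i in range(len(ctrl))]
    return pd.DataFrame(
        {"ctrl_1": [c[0] for c in ctrl], "ctrl_2": [c[1] for c in ctrl],
         "kd_1": [k[0] for k in kd], "kd_2": [k[1] for k in kd]},
        index=genes,
    )


class TestCPM:
    def test_identity_and_sums(self):
        counts = pd.DataFrame({"r1": [10, 999_990], "r2": [5, 15]}, index=["a", "b"])
        cpm = normalize_cpm(counts)
        assert cpm.loc["a", "r1"] == pytest.approx(10.0)
        assert np.allclose(cpm.sum(), 1e6)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"r1": [3, 7, 90]})
        assert np.allclose(normalize_cpm(counts), normalize_cpm(counts * 2))

    def test_zero_library_errors(self):
        with pytest.raises(ValueError):
            normalize_cpm(pd.DataFrame({"r1": [0, 0]}))


class TestTE:
    def test_worked_values(self):
        rpf = pd.DataFrame({"r": [100.0, 50.0, 10.0]}, index=list("abc"))
        rna = pd.DataFrame({"r": [50.0, 50.0, 0.0]}, index=list("abc"))
        te0 = translation_efficiency(rpf, rna, pseudocount=0.0)
        assert te0.loc["a", "r"] == pytest.approx(2.0)
        assert te0.loc["b", "r"] == pytest.approx(1.0)
        te = translation_efficiency(rpf, rna, pseudocount=0.5)
        assert te.loc["c", "r"] == pytest.approx(21.0)

    def test_mismatched_genes_error(self):
        rpf = pd.DataFrame({"r": [1.0]}, index=["a"])
        rna = pd.DataFrame({"r": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            translation_efficiency(rpf, rna)

    def test_expression_floor(self):
        rna_cpm = pd.DataFrame(
            {"ctrl_1": [5.0, 0.1], "ctrl_2": [5.0, 0.1], "kd_1": [5.0, 5.0], "kd_2": [5.0, 5.0]},
            index=["hi", "lo"],
        )
        assert list(filter_expressed(rna_cpm, CONDS)) == ["hi"]


class TestDifferentialTE:
    def test_identical_te_all_unchanged(self):
        te = te_frame([(2.0, 2.0)] * 5, [(2.0, 2.0)] * 5)
        res = differential_te(te, CONDS)
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["te_class"] == "unchanged").all()

    def test_strong_shift_called_down(self):
        rng = np.random.default_rng(0)
        # 200 null genes give the moderation a variance prior; one gene drops 4x
        ctrl = np.exp(rng.normal(0, 0.05, (201, 2)))
        kd = np.exp(rng.normal(0, 0.05, (201, 2)))
        ctrl[0] *= 4.0
        te = pd.DataFrame(
            np.hstack([ctrl, kd]), columns=["ctrl_1", "ctrl_2", "kd_1", "kd_2"]
        )
        res = differential_te(te, CONDS)
        assert res.loc[0, "log2fc"] == pytest.approx(-2.0, abs=0.3)
        assert res.loc[0, "te_class"] == "down"
        assert res.loc[0, "p_value"] < 0.05

    def test_class_partition_and_gate(self):
        rng = np.random.default_rng(1)
        te = pd.DataFrame(
            np.exp(rng.normal(0, 0.3, (300, 4))), columns=CONDS.index
        )
        res = differential_te(te, CONDS)
        assert set(res["te_class"]) <= {"up", "down", "unchanged"}
        called = res[res["te_class"] != "unchanged"]
        assert (called["p_value"] < 0.05).all()
        assert (called["log2fc"].abs() >= np.log2(1.5) - 1e-12).all()

    def test_too_few_replicates_error(self):
        te = te_frame([(1.0, 1.0)], [(1.0, 1.0)]).drop(columns="kd_2")
        with pytest.raises(ValueError):
            differential_te(te, CONDS.drop("kd_2"))

    def test_monotone_in_kd_te(self):
        """Raising a gene's knockdown TE never lowers its log2fc."""
        base = te_frame([(2.0, 2.1)] * 3, [(1.0, 1.1)] * 3)
        res1 = differential_te(base, CONDS, test="t_log")
        boosted = base.copy()
        boosted.loc["g0", ["kd_1", "kd_2"]] *= 3
        res2 = differential_te(boosted, CONDS, test="t_log")
        assert res2.loc["g0", "log2fc"] > res1.loc["g0", "log2fc"]

    def test_permutation_option_runs(self):
        te = te_frame([(4.0, 4.1)] * 3, [(1.0, 1.1)] * 3)
        res = differential_te(te, CONDS, test="permutation")
        # with 2+2 replicates the permutation p cannot reach 0.05
        assert (res["p_value"] >= 1 / 3 - 1e-12).all()


class TestModeratedT:
    def test_matches_limma_oracle(self, tmp_path):
        """The moderated t agrees with the reference empirical-Bayes
        implementation (limma) run through Rscript."""
        rng = np.random.default_rng(42)
        x = np.exp(rng.normal(0, 0.3, (150, 2)))
        y = np.exp(rng.normal(0, 0.3, (150, 2)))
        x[:15] *= 2.5
        mat = np.log2(np.hstack([x, y]))
        np.savetxt(tmp_path / "m.tsv", mat, delimiter="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'm <- as.matrix(read.table("{tmp_path / "m.tsv"}"))\n'
            "design <- cbind(Intercept=1, g=c(1,1,0,0))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            f'write.table(data.frame(p=fit$p.value[,"g"]), "{tmp_path / "p.tsv"}", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        p_ref = pd.read_csv(tmp_path / "p.tsv", sep=" ")["p"].to_numpy()
        p_mine = moderated_ttest_ind(mat[:, :2], mat[:, 2:])
        assert np.abs(p_mine - p_ref).max() < 0.02
        # same discoveries at 5%
        assert ((p_mine < 0.05) == (p_ref < 0.05)).mean() > 0.97


class TestSilac:
    def test_mean_of_peptides(self):
        pep = pd.DataFrame(
            {
                "protein_id": ["p1"] * 3 + ["p2"] + ["p3"] * 2,
                "ratio": [2.0, 2.0, 2.0, 0.5, 1.0, 3.0],
            }
        )
        out = aggregate_silac(pep)
        assert out.loc["p1", "ratio"] == pytest.approx(2.0)
        assert out.loc["p2", "ratio"] == pytest.approx(0.5)
        assert out.loc["p3", "ratio"] == pytest.approx(2.0)  # mean of ratios != ratio of means
        assert out.loc["p3", "log2_ratio"] == pytest.approx(1.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            aggregate_silac(pd.DataFrame({"protein_id": ["p"], "ratio": [-1.0]}))

    def test_protein_with_no_peptides_dropped_with_warning(self):
        pep = pd.DataFrame(
            {"protein_id": ["p1", "p2"], "ratio": [2.0, np.nan]}
        )
        with pytest.warns(UserWarning):
            out = aggregate_silac(pep)
        assert list(out.index) == ["p1"]

    @pytest.mark.parametrize(
        "log2_ratio,adj_p,expected",
        [(0.6, 0.01, "up"), (0.4, 0.001, "unchanged"), (-0.8, 0.2, "unchanged"), (-0.6, 0.01, "down")],
    )
    def test_joint_gate(self, log2_ratio, adj_p, expected):
        assert classify_protein(log2_ratio, adj_p) == expected

    def test_differential_protein_recovers_planted_classes(self):
        rng = np.random.default_rng(3)
        rows = []
        truth = {}
        for i in range(60):
            pid = f"p{i}"
            true = {0: 1.0, 1: 2.0, 2: 0.5}[i % 3]
            truth[pid] = {1.0: "unchanged", 2.0: "up", 0.5: "down"}[true]
            for rep in range(1, 4):
                for j in range(8):
                    rows.append((pid, true * rng.lognormal(0, 0.1), rep))
        pep = pd.DataFrame(rows, columns=["protein_id", "ratio", "replicate"])
        res = differential_protein(aggregate_silac(pep))
        agree = (res["protein_class"] == pd.Series(truth).reindex(res.index)).mean()
        assert agree > 0.95

    def test_all_identical_ratios_unchanged(self):
        pep = pd.DataFrame(
            {"protein_id": ["p"] * 3, "ratio": [2.0] * 3, "replicate": [1, 2, 3]}
        )
        res = differential_protein(aggregate_silac(pep), test="t_1samp")
        assert res.loc["p", "protein_class"] == "unchanged"
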