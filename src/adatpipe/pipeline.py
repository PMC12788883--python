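"""End-to-end orchestration: config validation, staged execution, run report.

Stages run in order — wobble-editing quantification, translation
efficiency, codon-usage enrichment — each reading files named in the
config and writing TSV tables plus a JSON run report that accounts for
every read and gene as used or excluded-with-reason. Stages whose inputs
are absent are skipped with a notice, so a tRNA-only config yields editing
outputs alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codons import gene_set_report, profiles_from_fasta
from .decoding import build_decoding_table, default_families
from .editing import (
    abundance,
    editing_rate,
    filter_alignments,
    pileup_at_wobble,
    read_references,
    read_sam,
)
from .translatome import (
    aggregate_silac,
    differential_protein,
    differential_te,
    filter_expressed,
    normalize_cpm,
    translation_efficiency,
)

log = logging.getLogger("adatpipe")

INPUT_KEYS = (
    "trna_fasta",
    "trna_meta",
    "sam_control",
    "sam_knockdown",
    "rpf_counts",
    "rna_counts",
    "conditions",
    "cds_fasta",
    "peptides",
)

_PARAM_RANGES = {
    "max_mismatches": (0, 1000),
    "max_mappings": (0, 100000),
    "min_coverage": (0, 1e12),
    "alpha": (0.0, 1.0),
    "fc": (1.0, 1000.0),
    "min_rna_cpm": (0.0, 1e6),
    "pseudocount": (0.0, 1e6),
    "adj_alpha": (0.0, 1.0),
    "log2_cut": (0.0, 100.0),
    "pseudo_freq": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults filled."""

    outdir: Path
    seed: int = 0
    inputs: dict[str, Path | None] = field(default_factory=dict)
    max_mismatches: int = 2
    max_mappings: int = 50
    weighting: str = "fractional"
    denominator: str = "total"
    min_coverage: float = 20.0
    alpha: float = 0.05
    fc: float = 1.5
    te_test: str = "t_log"
    min_rna_cpm: float = 1.0
    pseudocount: float = 0.5
    adj_alpha: float = 0.05
    log2_cut: float = 0.5
    pseudo_freq: float = 1e-4

    def echo(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "inputs"}
        d["outdir"] = str(self.outdir)
        d["inputs"] = {k: (str(v) if v else None) for k, v in self.inputs.items()}
        return d


class ConfigError(ValueError):
    """Aggregated configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


def validate_config(path: str | Path, strict: bool = False) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, aggregating all errors.

    Unknown keys warn (or error with ``strict=True``); missing input files
    and out-of-range parameters are collected and reported together.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    known = {"outdir", "seed", "inputs", "params"}
    unknown = set(raw) - known
    if unknown:
        msg = f"unknown top-level keys: {sorted(unknown)}"
        if strict:
            problems.append(msg)
        else:
            log.warning(msg)

    outdir = raw.get("outdir")
    if not outdir:
        problems.append("missing required key: outdir")

    inputs: dict[str, Path | None] = {k: None for k in INPUT_KEYS}
    for key, value in (raw.get("inputs") or {}).items():
        if key not in INPUT_KEYS:
            msg = f"unknown input key: {key}"
            if strict:
                problems.append(msg)
            else:
                log.warning(msg)
            continue
        p = Path(value)
        if not p.exists():
            problems.append(f"input file for {key!r} does not exist: {p}")
        inputs[key] = p

    params = raw.get("params") or {}
    cfg_kwargs: dict = {}
    for key, value in params.items():
        target = "te_test" if key == "test" else key
        if target not in PipelineConfig.__dataclass_fields__ or target in ("outdir", "seed", "inputs"):
            msg = f"unknown parameter: {key}"
            if strict:
                problems.append(msg)
            else:
                log.warning(msg)
            continue
        if key in _PARAM_RANGES:
            lo, hi = _PARAM_RANGES[key]
            if not (isinstance(value, (int, float)) and lo <= value <= hi):
                problems.append(f"parameter {key}={value!r} outside [{lo}, {hi}]")
                continue
        cfg_kwargs[target] = value
    if cfg_kwargs.get("weighting", "fractional") not in ("fractional", "full"):
        problems.append("weighting must be fractional or full")
    if cfg_kwargs.get("denominator", "total") not in ("total", "ag_only"):
        problems.append("denominator must be total or ag_only")
    if problems:
        raise ConfigError(problems)
    return PipelineConfig(
        outdir=Path(outdir), seed=int(raw.get("seed", 0)), inputs=inputs, **cfg_kwargs
    )


def _editing_stage(cfg: PipelineConfig, report: dict) -> pd.DataFrame | None:
    ins = cfg.inputs
    if not (ins.get("trna_fasta") and ins.get("trna_meta")):
        log.info("editing stage skipped: no tRNA reference inputs")
        report["stages"]["editing"] = {"skipped": True}
        return None
    refs = read_references(ins["trna_fasta"], ins["trna_meta"])
    tables = []
    stage: dict = {"skipped": False, "conditions": {}}
    for cond in ("control", "knockdown"):
        sam = ins.get(f"sam_{cond}")
        if sam is None:
            continue
        reads = read_sam(sam, refs)
        kept, tally = filter_alignments(reads, cfg.max_mismatches, cfg.max_mappings)
        pile = pileup_at_wobble(kept, refs, cfg.weighting)
        rates = editing_rate(pile, cfg.denominator, cfg.min_coverage)
        rpm = abundance(kept, refs, cfg.weighting)
        table = pile.join(rates.drop(columns="coverage")).join(rpm)
        table.insert(0, "condition", cond)
        tables.append(table)
        stage["conditions"][cond] = {"input_reads": len(reads), "tally": tally}
    report["stages"]["editing"] = stage
    if not tables:
        return None
    out = pd.concat(tables)
    out.to_csv(cfg.outdir / "editing_rates.tsv", sep="\t", index_label="family_id")
    return out


def _te_stage(cfg: PipelineConfig, report: dict):
    ins = cfg.inputs
    needed = ("rpf_counts", "rna_counts", "conditions")
    if not all(ins.get(k) for k in needed):
        log.info("translation stage skipped: missing count inputs")
        report["stages"]["translation"] = {"skipped": True}
        return None
    rpf = pd.read_csv(ins["rpf_counts"], sep="\t", index_col=0)
    rna = pd.read_csv(ins["rna_counts"], sep="\t", index_col=0)
    conditions = pd.read_csv(ins["conditions"], sep="\t", index_col=0)["condition"]
    rpf_cpm, rna_cpm = normalize_cpm(rpf), normalize_cpm(rna)
    expressed = filter_expressed(rna_cpm, conditions, cfg.min_rna_cpm)
    te = translation_efficiency(
        rpf_cpm.loc[expressed], rna_cpm.loc[expressed], cfg.pseudocount
    )
    res = differential_te(te, conditions, cfg.alpha, cfg.fc, cfg.te_test)
    res.to_csv(cfg.outdir / "te_results.tsv", sep="\t", index_label="gene_id")
    counts = res["te_class"].value_counts().to_dict()
    report["stages"]["translation"] = {
        "skipped": False,
        "genes_in": len(rna),
        "genes_tested": len(res),
        "genes_below_expression_floor": len(rna) - len(res),
        "classes": counts,
    }
    return res


def _codon_stage(cfg: PipelineConfig, report: dict, te_res, protein_res=None):
    ins = cfg.inputs
    if ins.get("cds_fasta") is None or te_res is None:
        log.info("codon stage skipped: needs CDS FASTA and TE results")
        report["stages"]["codon_enrichment"] = {"skipped": True}
        return None
    table = build_decoding_table(default_families())
    table.to_tsv(cfg.outdir / "decoding_table.tsv")
    profiles, _ = profiles_from_fasta(ins["cds_fasta"])
    out = {}
    for name, res_df, cls_col in (
        ("te", te_res, "te_class"),
        ("protein", protein_res, "protein_class"),
    ):
        if res_df is None:
            continue
        try:
            rep = gene_set_report(res_df[cls_col], profiles, table, pseudo_freq=cfg.pseudo_freq)
        except ValueError as exc:  # e.g. too few up/down genes to compare
            log.warning("codon enrichment (%s) not computed: %s", name, exc)
            report["stages"].setdefault("codon_enrichment", {"skipped": False})[name] = {
                "not_computed": str(exc)
            }
            continue
        for comp in ("down_vs_up", "down_vs_all"):
            rep[comp].to_csv(
                cfg.outdir / f"enrichment_{name}_{comp}.tsv", sep="\t", index_label="codon"
            )
        rep["dependency_summary"].to_csv(
            cfg.outdir / f"enrichment_{name}_summary.tsv", sep="\t"
        )
        out[name] = rep
        report["stages"].setdefault("codon_enrichment", {"skipped": False})[name] = {
            "group_sizes": rep["group_sizes"],
            "strict_mean_delta_down_vs_up": float(
                rep["down_vs_up"].query("dependency == 'strict'")["delta_log2"].mean()
            ),
        }
    return out


def _protein_stage(cfg: PipelineConfig, report: dict):
    ins = cfg.inputs
    if ins.get("peptides") is None:
        report["stages"]["proteomics"] = {"skipped": True}
        return None
    peptides = pd.read_csv(ins["peptides"], sep="\t")
    proteins = aggregate_silac(peptides)
    res = differential_protein(proteins, cfg.adj_alpha, cfg.log2_cut)
    res.drop(columns="replicate_ratios", errors="ignore").to_csv(
        cfg.outdir / "protein_results.tsv", sep="\t", index_label="protein_id"
    )
    report["stages"]["proteomics"] = {
        "skipped": False,
        "proteins": len(res),
        "classes": res["protein_class"].value_counts().to_dict(),
    }
    return res


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns and writes the run report.

    Deterministic for fixed inputs and config: rerunning changes no
    analytical output.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "stages": {},
    }
    _editing_stage(cfg, report)
    te_res = _te_stage(cfg, report)
    protein_res = _protein_stage(cfg, report)
    _codon_stage(cfg, report, te_res, protein_res)
    with open(cfg.outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
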