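"""End-to-end orchestration: mapping -> quantification -> specificity ->
bias simulation -> enrichment and statistics.

A run is driven by a :class:`PipelineConfig` (constructable from YAML),
either on file inputs (count TSV, tabular alignments, annotation TSV,
contaminant subject list) or on a freshly simulated synthetic study.  All
thresholds default to the standard conventions (e-value cutoff 1e-10,
minimum 4 reads, zero-TPM floor 2, splice-gap threshold 15 bases,
tau-extreme set size 500, alpha 0.05) and every run writes a manifest
recording thresholds, seed and input checksums, so any number in any
report is reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import bias as bias_mod
from . import mapping, quantify, stats, synthetic, tau as tau_mod

log = logging.getLogger("tissuespec")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and reproducibility knobs for one run."""

    out_dir: str = "tissuespec_out"
    # file inputs (ignored when synthetic is set)
    contig_counts: str | None = None
    alignments: str | None = None
    annotation: str | None = None
    contaminant_subjects: str | None = None
    library_sizes: dict[str, int] | None = None
    # synthetic mode
    synthetic: synthetic.SimulationConfig | None = None
    # thresholds (standard conventions)
    evalue_cutoff: float = 1e-10
    min_reads: int = 4
    floor_tpm: float = 2.0
    min_gap: int = 15
    top_k: int = 500
    alpha: float = 0.05
    enrichment_method: str = "fdr_bh"
    bias_mode: str = "dataset-per-level"
    bias_n_datasets: int | None = None
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self):
        for name in ("evalue_cutoff", "floor_tpm", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_reads", "min_gap", "top_k", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.library_sizes is not None:
            names = list(self.library_sizes)
            if len(set(names)) != len(names):
                raise ValueError("tissue names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            for key in ("library_sizes", "tissue_names"):
                if key in syn and syn[key] is not None:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = synthetic.SimulationConfig(**syn)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _load_inputs(config: PipelineConfig, out: Path):
    if config.synthetic is not None:
        study = synthetic.simulate_study(config.synthetic)
        fixture_dir = out / "fixture"
        paths = synthetic.write_fixture_bundle(study, fixture_dir)
        sizes = pd.Series(
            dict(zip(study.config.tissues, study.config.library_sizes)),
            name="library_size",
        ).astype(float)
        contaminants = set(study.contaminant_subjects)
        return (
            study.contig_table,
            str(paths["alignments"]),
            study.truth.annotation,
            contaminants,
            sizes,
            {k: str(v) for k, v in paths.items()},
        )
    missing = [
        name
        for name in ("contig_counts", "alignments", "annotation")
        if getattr(config, name) is None
    ]
    if missing or config.library_sizes is None:
        raise ValueError(
            f"non-synthetic runs need contig_counts, alignments, annotation "
            f"and library_sizes (missing: {missing})"
        )
    contig_table = pd.read_csv(config.contig_counts, sep="\t", index_col=0)
    annotation = pd.read_csv(config.annotation, sep="\t", index_col=0)
    contaminants: set[str] = set()
    if config.contaminant_subjects:
        contaminants = {
            s
            for s in Path(config.contaminant_subjects).read_text().splitlines()
            if s.strip()
        }
    sizes = pd.Series(config.library_sizes, name="library_size").astype(float)
    inputs = {
        "contig_counts": config.contig_counts,
        "alignments": config.alignments,
        "annotation": config.annotation,
    }
    return contig_table, config.alignments, annotation, contaminants, sizes, inputs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write every report plus ``manifest.json``.

    Returns a dict of the main in-memory results.  Stage failures raise
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    counts_io: dict[str, int] = {}

    try:
        stage = "inputs"
        contig_table, alignments_path, annotation, contaminant_ids, sizes, inputs = (
            _load_inputs(config, out)
        )
        tissues = [c for c in contig_table.columns if c != "length"]
        sizes = sizes.reindex(tissues)
        contig_counts = contig_table[tissues]
        counts_io["contigs_in"] = len(contig_table)
        log.info("inputs: %d contigs, %d libraries", len(contig_table), len(tissues))

        stage = "mapping"
        hits = mapping.parse_tabular_alignments(
            alignments_path, evalue_cutoff=config.evalue_cutoff
        )
        assignments = mapping.assign_genes(hits)
        clean, removed = mapping.flag_contaminants(assignments, contaminant_ids)
        counts_io["contigs_with_hit"] = len(assignments)
        counts_io["contaminant_contigs_removed"] = len(removed)
        mapping.assignments_to_frame(clean).to_csv(
            out / "assignments.tsv", sep="\t", index=False
        )
        removed.to_csv(out / "removed_contaminants.tsv", sep="\t", index=False)
        log.info(
            "mapping: %d/%d contigs assigned, %d contaminants removed",
            len(clean), len(contig_table), len(removed),
        )
        contig_counts = contig_counts.drop(
            index=[c for c in removed["contig_id"] if c in contig_counts.index]
        )

        stage = "quantification"
        assignment_map = {c: a.gene_id for c, a in clean.items()
                          if c in contig_counts.index}
        gene_counts = quantify.aggregate_contigs_to_genes(
            contig_counts, assignment_map
        )
        gene_tpm = quantify.compute_tpm(gene_counts, sizes)
        gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
        gene_tpm.round(4).to_csv(out / "gene_tpm.tsv", sep="\t")
        counts_io["genes_detected"] = len(gene_counts) - int(
            quantify.UNANNOTATED_ID in gene_counts.index
        )
        log.info("quantification: %d genes", counts_io["genes_detected"])

        stage = "specificity"
        gene_counts_annot = gene_counts.drop(
            index=quantify.UNANNOTATED_ID, errors="ignore"
        )
        tau_table = tau_mod.filter_low_reads(
            gene_counts_annot, sizes,
            min_reads=config.min_reads, floor_tpm=config.floor_tpm,
        )
        _write_tau_table(tau_table, out / "tau.tsv")
        counts_io["genes_with_tau"] = int(tau_table["tau"].notna().sum())
        results["tau_table"] = tau_table
        log.info(
            "specificity: tau for %d/%d genes",
            counts_io["genes_with_tau"], len(tau_table),
        )

        stage = "bias_simulation"
        bias_result = bias_mod.simulate_correlation_distribution(
            contig_counts, sizes,
            seed=config.seed, mode=config.bias_mode,
            n_datasets=config.bias_n_datasets,
            min_reads=config.min_reads, floor_tpm=config.floor_tpm,
        )
        (out / "bias_simulation.json").write_text(
            json.dumps(bias_result.to_dict(), indent=2) + "\n"
        )
        results["bias"] = bias_result
        log.info(
            "bias simulation: observed r=%.3f, mean simulated r=%.3f, t=%.2f",
            bias_result.observed_r, bias_result.mean_simulated_r,
            bias_result.t_statistic,
        )

        stage = "enrichment_and_stats"
        results.update(
            _enrichment_and_stats(
                config, out, tau_table, gene_counts_annot, annotation, sizes
            )
        )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "seed": config.seed,
            "thresholds": {
                k: config.to_dict()[k]
                for k in (
                    "evalue_cutoff", "min_reads", "floor_tpm", "min_gap",
                    "top_k", "alpha", "enrichment_method", "bias_mode",
                    "n_boot",
                )
            },
            "inputs": {
                name: {"path": str(p), "md5": _checksum(Path(p))}
                for name, p in inputs.items()
                if isinstance(p, str) and Path(p).is_file()
            },
            "counts": counts_io,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        results["manifest"] = manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return results


def _enrichment_and_stats(config, out, tau_table, gene_counts, annotation, sizes):
    results: dict = {}
    detected = tau_table.index[tau_table["tau"].notna()]
    annotated = annotation.index.intersection(detected)
    go_map = annotation.loc[annotated, "go_terms"] if "go_terms" in annotation else None

    k = min(config.top_k, len(detected) // 2)
    if k >= 1:
        high, low = stats.select_tau_extreme_sets(tau_table.loc[detected], k=k)
        results["high_tau_set"], results["low_tau_set"] = high, low
        if go_map is not None and len(annotated) > 0:
            for name, gene_set in (("high_tau", high), ("low_tau", low)):
                subset = [g for g in gene_set if g in annotated]
                enr = stats.go_overrepresentation(
                    subset, annotated, go_map,
                    alpha=config.alpha, method=config.enrichment_method,
                )
                enr.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
                results[f"enrichment_{name}"] = enr
    if go_map is not None:
        for tissue in gene_counts.columns:
            members = [
                g for g in annotated
                if tau_table.loc[g, "max_tissue"] == tissue
            ]
            if len(members) < 2:
                continue
            enr = stats.go_overrepresentation(
                members, annotated, go_map,
                alpha=config.alpha, method=config.enrichment_method,
            )
            enr.to_csv(out / f"enrichment_max_{tissue}.tsv", sep="\t", index=False)

    merged = tau_table.join(annotation, how="inner")
    merged["total_reads_gene"] = gene_counts.sum(axis=1).reindex(merged.index)
    corr_specs = {
        "tau_vs_omega": ("tau", "omega", "spearman", "none"),
        "total_vs_omega": ("total_reads_gene", "omega", "spearman", "none"),
        "length_vs_total": ("length_bp", "total_reads_gene", "spearman", "none"),
        "length_vs_tau": ("length_bp", "tau", "spearman", "none"),
    }
    correlations = {}
    for name, (xcol, ycol, method, transform) in corr_specs.items():
        sub = merged[[xcol, ycol]].dropna()
        if len(sub) >= 3 and sub[xcol].nunique() > 1 and sub[ycol].nunique() > 1:
            correlations[name] = stats.correlate(
                sub[xcol], sub[ycol], method=method, transform=transform
            )._asdict()
    results["correlations"] = correlations

    group_tests = {}
    with_tissue = merged[merged["max_tissue"].notna()]
    for var, method in (("omega", "kruskal"), ("tau", "anova")):
        groups = {
            t: g[var].dropna().to_numpy()
            for t, g in with_tissue.groupby("max_tissue")
        }
        groups = {t: v for t, v in groups.items() if v.size >= 2}
        if len(groups) >= 2:
            res = stats.group_compare(groups, method=method)
            group_tests[f"{var}_by_tissue"] = {
                "statistic": res.statistic,
                "df": list(res.df),
                "p_value": res.p_value,
                "method": res.method,
            }
    results["group_tests"] = group_tests

    summary = stats.summarize_by_max_tissue(
        tau_table, annotation, counts=gene_counts,
        n_boot=config.n_boot, seed=config.seed,
    )
    summary.round(6).to_csv(out / "tissue_summary.tsv", sep="\t")
    results["tissue_summary"] = summary

    (out / "stats.json").write_text(
        json.dumps(
            {"correlations": correlations, "group_tests": group_tests},
            indent=2, default=float,
        )
        + "\n"
    )
    return results


def _write_tau_table(tau_table: pd.DataFrame, path: Path) -> None:
    rendered = tau_table.copy()
    rendered["tau"] = [tau_mod.render_tau(t) for t in rendered["tau"]]
    rendered["max_tissue"] = rendered["max_tissue"].fillna("-")
    rendered.to_csv(path, sep="\t")


def make_expression_report(
    tpm: pd.DataFrame,
    tau_table: pd.DataFrame,
    gene_ids,
    library_sizes,
    tpm_decimals: int = 1,
    tau_decimals: int = 3,
) -> pd.DataFrame:
    """Formatted per-gene expression report: TPM per library to one
    decimal, tau to three decimals (or '-' when withheld by the read
    filter), and a final library-size footer row.

    Raises ``KeyError`` for gene ids absent from the TPM table.
    """
    gene_ids = list(gene_ids)
    missing = [g for g in gene_ids if g not in tpm.index]
    if missing:
        raise KeyError(f"unknown gene ids: {missing}")
    sizes = pd.Series(library_sizes).reindex(tpm.columns)
    rows = []
    for g in gene_ids:
        row = {c: f"{tpm.loc[g, c]:.{tpm_decimals}f}" for c in tpm.columns}
        t = tau_table.loc[g, "tau"] if g in tau_table.index else float("nan")
        row["tau"] = tau_mod.render_tau(t, tau_decimals)
        rows.append(row)
    footer = {c: f"{int(sizes[c]):,}" for c in tpm.columns}
    footer["tau"] = ""
    rows.append(footer)
    return pd.DataFrame(
        rows, index=pd.Index(gene_ids + ["Library size"], name="gene")
    )
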