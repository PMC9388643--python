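"""End-to-end orchestration: simulate/load -> filter -> classify ->
quantify -> co-express -> enrich -> report.

Every stage writes its artifacts before the next begins, the run is
deterministic given the seed, and the final report cross-checks its own
counts (e.g. per-biotype gene counts minus multi-label genes equal the
distinct lncRNA gene total).  When the inputs come from the synthetic
generator the report also scores the run against the planted ground
truth.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_io as aio
from .annotation_io import ValidationError
from .biotype_classifier import (
    OverlapConfig,
    aggregate_gene_biotypes,
    calls_to_frame,
    classify_transcripts,
    gene_biotype_summary,
)
from .coexpression import (
    NetworkConfig,
    compute_eigengenes,
    detect_modules,
    eigengene_frame,
    normalize_counts,
)
from .enrichment import GoAnnotation, assign_functions_to_lncrnas, enrich_modules
from .expression_specificity import (
    StageBins,
    assign_stages,
    call_confidence,
    call_specific,
    compute_tau,
    counts_to_tpm,
    summarize_by_group,
)
from .filter_cascade import (
    EvidenceBundle,
    FilterConfig,
    apply_strict_method,
    cascade_summary,
    trails_to_frame,
)
from .synthetic_data import (
    GroundTruthManifest,
    SimulationConfig,
    SyntheticDataset,
    simulate_dataset,
)


class StageFailure(Exception):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    outdir: str = "strictlnc_run"
    #: generate inputs in-process; otherwise read them from data_dir
    simulate: bool = True
    data_dir: str | None = None
    write_data: bool = True
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    stage_bins: StageBins = field(default_factory=StageBins)
    expressed_threshold: float = 3.0
    enrichment_q: float = 0.01
    tau_transform: str = "log2"

    def __post_init__(self):
        self.sim.seed = self.seed


def percentage(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * a/b, rounded half-up at the printed precision."""
    if denominator == 0:
        raise ValidationError("percentage with zero denominator")
    quantum = Decimal(1).scaleb(-decimals)
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def report_percentages(
    counts: dict[str, tuple[float, float]], decimals: int = 2
) -> dict[str, float]:
    """Derived percentage table; zero-denominator fields are omitted."""
    out = {}
    for name, (num, den) in counts.items():
        if den == 0:
            warnings.warn(f"{name}: zero denominator, field omitted")
            continue
        out[name] = percentage(num, den, decimals)
    return out


def load_dataset_dir(data_dir: str | Path) -> dict:
    """Read the on-disk layout written by SyntheticDataset.write."""
    d = Path(data_dir)
    reference = aio.read_annotation(d / "reference.gtf")
    candidates = aio.read_transcripts(d / "candidates.gtf")
    seqs = aio.read_fasta(d / "candidates.fa")
    for t in candidates:
        t.sequence = seqs[t.transcript_id]
    counts = pd.read_csv(d / "counts.tsv", sep="\t", index_col="gene_id")
    lengths = pd.read_csv(d / "lengths.tsv", sep="\t", index_col="gene_id")[
        "effective_length"
    ]
    metadata = pd.read_csv(d / "samples.tsv", sep="\t")
    gene2go = pd.read_csv(d / "gene2go.tsv", sep="\t", header=None,
                          names=["gene_id", "term_id"])
    manifest = None
    if (d / "manifest.json").exists():
        manifest = GroundTruthManifest.from_json(d / "manifest.json")
    return {
        "reference": reference,
        "candidates": candidates,
        "evidence": EvidenceBundle.load(d / "evidence"),
        "counts": counts,
        "lengths": lengths,
        "metadata": metadata,
        "gene2go": gene2go,
        "manifest": manifest,
    }


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; return the run report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    # ---- data ----------------------------------------------------------
    stage = "data"
    try:
        if config.simulate:
            ds = simulate_dataset(config.sim)
            if config.write_data:
                ds.write(outdir / "data")
            reference, candidates = ds.reference, ds.candidates
            evidence, counts = ds.evidence, ds.counts
            lengths, metadata = ds.effective_lengths, ds.metadata
            gene2go, manifest = ds.gene2go, ds.manifest
        else:
            if config.data_dir is None:
                raise ValidationError("data_dir required when simulate=False")
            loaded = load_dataset_dir(config.data_dir)
            reference = loaded["reference"]
            candidates = loaded["candidates"]
            evidence, counts = loaded["evidence"], loaded["counts"]
            lengths, metadata = loaded["lengths"], loaded["metadata"]
            gene2go, manifest = loaded["gene2go"], loaded["manifest"]
    except Exception as exc:  # noqa: BLE001 - reported with the stage name
        raise StageFailure(stage, exc) from exc
    report["stages"]["data"] = {
        "n_reference_genes": len(reference),
        "n_candidates": len(candidates),
        "n_samples": counts.shape[1],
    }

    # ---- filter --------------------------------------------------------
    stage = "filter"
    try:
        survivors, trails = apply_strict_method(
            candidates, None, evidence, config.filters
        )
        surviving_tx = [t for t in candidates if t.transcript_id in survivors]
        aio.write_gtf(surviving_tx, outdir / "survivors.gtf")
        trails_to_frame(trails).to_csv(outdir / "filter_trail.tsv", sep="\t",
                                       index=False)
        summary = cascade_summary(trails)
        _dump_json(summary, outdir / "filter_summary.json")
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    report["stages"]["filter"] = summary

    # ---- classify ------------------------------------------------------
    stage = "classify"
    try:
        calls = classify_transcripts(surviving_tx, reference, config.overlap)
        calls_to_frame(calls).to_csv(outdir / "biotypes.tsv", sep="\t", index=False)
        gene_table = aggregate_gene_biotypes(calls)
        gene_table.to_csv(outdir / "gene_biotypes.tsv", sep="\t", index=False)
        biotype_summary = gene_biotype_summary(gene_table)
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    report["stages"]["classify"] = biotype_summary

    # ---- quantify ------------------------------------------------------
    stage = "quantify"
    try:
        tpm = counts_to_tpm(counts, lengths)
        tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")
        confidence = call_confidence(tpm, config.expressed_threshold)
        confidence.to_csv(outdir / "confidence.tsv", sep="\t")
        tissue_of = pd.Series(
            metadata["tissue"].values, index=metadata["sample_id"].values
        )
        stages_of = assign_stages(metadata, config.stage_bins)

        coding_ids = [g.gene_id for g in reference]
        lnc_gene_ids = sorted({t.gene_id for t in surviving_tx})
        tau = compute_tau(tpm, tissue_of, config.tau_transform)
        tau_stage = compute_tau(
            tpm.loc[:, stages_of.dropna().index], stages_of.dropna(),
            config.tau_transform,
        )
        mrna_tau = tau.loc[tau.index.intersection(coding_ids)]
        tau_flagged, cutoff = call_specific(tau, mrna_tau)
        tau_flagged.to_csv(outdir / "tau_tissue.tsv", sep="\t",
                           index_label="gene_id")
        tau_stage.to_csv(outdir / "tau_stage.tsv", sep="\t", index_label="gene_id")
        expressed, group_summary = summarize_by_group(
            tpm, tissue_of, config.expressed_threshold
        )
        group_summary.to_csv(outdir / "group_summary.tsv", sep="\t")
        _dump_json(
            {"tau_cutoff_mrna_median": cutoff,
             "transform": config.tau_transform,
             "expressed_threshold": config.expressed_threshold},
            outdir / "specificity_params.json",
        )

        lnc_in_matrix = [g for g in lnc_gene_ids if g in tpm.index]
        hc = confidence.loc[
            confidence.index.intersection(lnc_in_matrix), "status"
        ].eq("HC").sum()
        lnc_tau = tau_flagged.loc[tau_flagged.index.intersection(lnc_in_matrix)]
        coding_tau = tau_flagged.loc[tau_flagged.index.intersection(coding_ids)]
        quant_summary = {
            "tau_cutoff": cutoff,
            "n_lncrna_hc": int(hc),
            "n_lncrna_lc": int(len(lnc_in_matrix) - hc),
            "n_lncrna_specific": int(lnc_tau["specific"].sum()),
            "n_lncrna_with_tau": int(len(lnc_tau)),
            "n_coding_specific": int(coding_tau["specific"].sum()),
            "n_coding_with_tau": int(len(coding_tau)),
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    report["stages"]["quantify"] = quant_summary

    # ---- coexpress -----------------------------------------------------
    stage = "coexpress"
    try:
        normalized = normalize_counts(counts)
        modules = detect_modules(normalized, config.network)
        modules.labels.to_frame().to_csv(outdir / "modules.tsv", sep="\t",
                                         index_label="gene_id")
        eigengenes, membership = compute_eigengenes(normalized, modules)
        eigengene_frame(eigengenes).to_csv(outdir / "eigengenes.tsv", sep="\t",
                                           index_label="sample_id")
        membership.to_frame().to_csv(outdir / "module_membership.tsv", sep="\t",
                                     index_label="gene_id")
        lnc_modules = modules.labels.loc[
            modules.labels.index.intersection(lnc_in_matrix)
        ]
        coexpress_summary = {
            "n_modules": modules.n_modules,
            "module_sizes": {str(k): v for k, v in sorted(modules.sizes.items())},
            "n_lncrna_in_modules": int((lnc_modules != 0).sum()),
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    report["stages"]["coexpress"] = coexpress_summary

    # ---- enrich --------------------------------------------------------
    stage = "enrich"
    try:
        annotation = GoAnnotation.from_frame(gene2go)
        background = [g for g in counts.index if g in set(coding_ids)]
        enr = enrich_modules(modules, background, annotation, config.enrichment_q)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        functions = assign_functions_to_lncrnas(modules, enr, lnc_in_matrix)
        functions.to_csv(outdir / "lncrna_functions.tsv", sep="\t", index=False)
        n_sig_modules = (
            enr[enr["significant"]]["module"].nunique() if len(enr) else 0
        )
        enrich_summary = {
            "n_modules_enriched": int(n_sig_modules),
            "n_lncrna_with_functions": int((functions["n_terms"] > 0).sum()),
        }
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    report["stages"]["enrich"] = enrich_summary

    # ---- report --------------------------------------------------------
    stage = "report"
    try:
        pct: dict[str, tuple[float, float]] = {}
        if modules.n_modules:
            pct["pct_modules_enriched"] = (n_sig_modules, modules.n_modules)
        if len(lnc_tau):
            pct["pct_lncrna_specific"] = (quant_summary["n_lncrna_specific"],
                                          quant_summary["n_lncrna_with_tau"])
        if len(coding_tau):
            pct["pct_coding_specific"] = (quant_summary["n_coding_specific"],
                                          quant_summary["n_coding_with_tau"])
        if len(lnc_in_matrix):
            pct["pct_lncrna_in_modules"] = (
                coexpress_summary["n_lncrna_in_modules"], len(lnc_in_matrix))
        report["percentages"] = report_percentages(pct)

        if manifest is not None:
            report["truth"] = _score_against_truth(
                manifest, survivors, calls, tau_flagged, modules,
                functions, counts.index,
            )
        canonical = json.dumps(report["stages"], sort_keys=True, default=str)
        report["config_echo"] = {
            "sim": asdict(config.sim) if config.simulate else None,
            "filters": asdict(config.filters),
            "overlap": asdict(config.overlap),
            "network": asdict(config.network),
        }
        report["counts_hash"] = hashlib.sha256(canonical.encode()).hexdigest()
        _dump_json(report, outdir / "report.json")
    except Exception as exc:
        raise StageFailure(stage, exc) from exc
    return report


def _score_against_truth(
    manifest: GroundTruthManifest,
    survivors: set[str],
    calls,
    tau_flagged: pd.DataFrame,
    modules,
    functions: pd.DataFrame,
    expressed_genes,
) -> dict:
    """Score a synthetic run against the planted manifest."""
    from sklearn.metrics import adjusted_rand_score

    expected = manifest.expected_survivors
    truth: dict = {
        "survivors_match_manifest": survivors == expected,
        "n_expected_survivors": len(expected),
        "n_false_positive_survivors": len(survivors - expected),
        "n_false_negative_survivors": len(expected - survivors),
    }
    recall = 100.0 * len(survivors & expected) / len(expected) if expected else 100.0
    truth["survivor_recall_pct"] = round(recall, 2)

    calls_by_tid = {c.transcript_id: c.labels for c in calls}
    n_bt, n_ok = 0, 0
    for tid, labels in manifest.transcript_biotypes.items():
        if tid in calls_by_tid:
            n_bt += 1
            if sorted(calls_by_tid[tid]) == labels:
                n_ok += 1
    truth["biotype_agreement_pct"] = round(100.0 * n_ok / n_bt, 2) if n_bt else 100.0

    planted_specific = pd.Series(
        {g: manifest.gene_specific_tissue.get(g) is not None for g in expressed_genes}
    )
    predicted = pd.Series(False, index=planted_specific.index)
    hit = tau_flagged.index.intersection(predicted.index)
    predicted.loc[hit] = tau_flagged.loc[hit, "specific"].values
    truth["specificity_accuracy_pct"] = round(
        100.0 * (planted_specific == predicted).mean(), 2
    )

    planted_modules = [manifest.gene_module.get(g, 0) for g in expressed_genes]
    detected = [int(modules.labels.get(g, 0)) for g in expressed_genes]
    truth["module_recovery_ari"] = round(
        float(adjusted_rand_score(planted_modules, detected)), 4
    )

    # lncRNAs planted into a module should inherit that module's planted term
    inherit_ok, inherit_total = 0, 0
    fn = functions.set_index("gene_id") if len(functions) else pd.DataFrame()
    for gid, m in manifest.gene_module.items():
        if m == 0 or gid not in getattr(fn, "index", []):
            continue
        if not (gid.startswith("LNC") or gid.startswith("RES")):
            continue
        inherit_total += 1
        terms = set(str(fn.loc[gid, "terms"]).split(";"))
        if manifest.module_terms.get(m) in terms:
            inherit_ok += 1
    truth["n_module_lncrnas_scored"] = inherit_total
    truth["function_inheritance_pct"] = (
        round(100.0 * inherit_ok / inherit_total, 2) if inherit_total else 100.0
    )
    return truth
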