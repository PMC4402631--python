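"""End-to-end orchestration: simulate/ingest -> QC -> outlier removal ->
segment filtering -> permutation mapping -> report.

A :class:`RunConfig` holds every stage's parameters in one auditable
place; :func:`run_pipeline` executes the stages in order, writes each
stage's report into the output directory, and records a manifest
sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenotypePanel, phenotype_codes
from .mapping import (
    MappingParams,
    MappingResult,
    SegmentFilterParams,
    filter_segments,
    permutation_mapping,
    significant_markers,
)
from .pca import OutlierParams, compute_pcs, two_stage_outlier_removal
from .qc import QCThresholds, apply_qc
from .segio import GeneticMap, annotate_segments, read_genetic_map, read_refined_ibd
from .sim import SimSpec, simulate_ibd_segments, simulate_panel

logger = logging.getLogger("pbla")

__all__ = ["InputPaths", "RunConfig", "ValidationReport", "validate_config", "run_pipeline"]

#: Default parameter values with their provenance, reported by validate_config.
_DEFAULTS = {
    "qc.maf_min": (0.05, "minor allele frequency filter"),
    "qc.hwe_p_min": (1e-6, "Hardy-Weinberg exact-test filter"),
    "qc.ind_missing_max": (0.07, "per-individual missingness filter"),
    "qc.marker_missing_max": (0.1, "per-marker missingness filter"),
    "outliers.n_pcs": (6, "PCs used for outlier detection"),
    "outliers.n_neighbors": (10, "nearest neighbours for density"),
    "outliers.density_cutoff": (0.15, "mean-kNN distance defining the main cluster"),
    "outliers.interior_min": (9, "neighbours required inside the cluster"),
    "seg_filter.lod_min": (3.0, "segment LOD threshold"),
    "seg_filter.length_min_cm": (1.0, "segment length threshold, cM"),
    "mapping.fwer_level": (0.05, "genome-wide significance level"),
    "mapping.coverage_fraction": (0.10, "low-IBD-detection mask quantile"),
    "mapping.n_permutations": (10_000, "desk-scale default; full analysis used millions"),
}


@dataclass
class InputPaths:
    """File inputs for a run on pre-existing data."""

    ped_prefix: str | None = None
    vcf: str | None = None
    segments: str | None = None
    genetic_map: str | None = None
    phenotypes: str | None = None


@dataclass
class RunConfig:
    """All pipeline parameters; exactly one of ``sim``/``inputs`` is used."""

    sim: SimSpec | None = None
    inputs: InputPaths | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    outliers: OutlierParams = field(default_factory=OutlierParams)
    seg_filter: SegmentFilterParams = field(default_factory=SegmentFilterParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    outdir: str = "pbla_run"
    run_outlier_stage: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "chromosomes" in sim_raw:
                from .sim import Chromosome

                sim_raw["chromosomes"] = [Chromosome(**c) for c in sim_raw["chromosomes"]]
            if "planted_locus" in sim_raw and sim_raw["planted_locus"] is not None:
                sim_raw["planted_locus"] = tuple(sim_raw["planted_locus"])
            if "maf_range" in sim_raw:
                sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
            kwargs["sim"] = SimSpec(**sim_raw)
        if "inputs" in raw and raw["inputs"] is not None:
            kwargs["inputs"] = InputPaths(**raw["inputs"])
        for key, klass in (
            ("qc", QCThresholds),
            ("outliers", OutlierParams),
            ("seg_filter", SegmentFilterParams),
            ("mapping", MappingParams),
        ):
            if key in raw and raw[key] is not None:
                kwargs[key] = klass(**raw[key])
        for key in ("outdir", "run_outlier_stage", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    defaults: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_config(config: RunConfig) -> ValidationReport:
    """Check parameter invariants; list violations, never raise.

    The report's ``defaults`` maps each defaulted parameter to its value
    and meaning so a run's effective settings are auditable.
    """
    report = ValidationReport(defaults={k: v for k, v in _DEFAULTS.items()})
    if config.sim is not None and config.inputs is not None:
        report.issues.append("exactly one of sim/inputs may be given, not both")
    if config.sim is None and config.inputs is None:
        report.issues.append("one of sim/inputs is required")
    if config.inputs is not None:
        ip = config.inputs
        if (ip.ped_prefix is None) == (ip.vcf is None):
            report.issues.append("inputs need exactly one of ped_prefix/vcf")
        for name in ("segments", "genetic_map"):
            if getattr(ip, name) is None:
                report.issues.append(f"inputs.{name} is required")
            elif not Path(getattr(ip, name)).exists():
                report.issues.append(f"inputs.{name}: file not found")
    try:
        if config.mapping.n_permutations < 1:
            report.issues.append("mapping.n_permutations must be >= 1")
    except (TypeError, ValueError) as exc:
        report.issues.append(str(exc))
    for name, value in (
        ("qc.maf_min", config.qc.maf_min),
        ("qc.hwe_p_min", config.qc.hwe_p_min),
        ("qc.ind_missing_max", config.qc.ind_missing_max),
        ("qc.marker_missing_max", config.qc.marker_missing_max),
    ):
        if not 0 <= value <= 1:
            report.issues.append(f"{name}={value} outside [0, 1]")
    if not 0 < config.mapping.fwer_level < 1:
        report.issues.append("mapping.fwer_level must lie in (0, 1)")
    if not 0 < config.mapping.coverage_fraction < 1:
        report.issues.append("mapping.coverage_fraction must lie in (0, 1)")
    if config.outliers.interior_min > config.outliers.n_neighbors:
        report.issues.append("outliers.interior_min cannot exceed n_neighbors")
    return report


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the cause."""


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        spec = config.sim
        panel, _ = simulate_panel(spec)
        segments, truth = simulate_ibd_segments(spec)
        gmap = GeneticMap.uniform(spec.chromosomes)
        labels = panel.phenotype_series()
        return panel, segments, gmap, labels, truth
    ip = config.inputs
    from .panelio import read_ped_map, read_phenotypes, read_vcf

    labels = read_phenotypes(ip.phenotypes) if ip.phenotypes else None
    if ip.ped_prefix:
        panel = read_ped_map(ip.ped_prefix)
    else:
        panel = read_vcf(ip.vcf, phenotypes=labels)
    if labels is None:
        labels = panel.phenotype_series()
    segments = read_refined_ibd(ip.segments)
    gmap = read_genetic_map(ip.genetic_map)
    return panel, segments, gmap, labels, None


def run_pipeline(config: RunConfig) -> MappingResult:
    """Execute all stages; artifacts land in ``config.outdir``.

    Stage order: QC -> PC-space outlier removal (removed samples are
    dropped from the labels and their segments discarded) -> segment
    annotation and LOD/length filtering -> permutation mapping with the
    low-coverage mask -> significant-marker report. Each stage writes a
    tab-separated report; ``manifest.json`` records version, seeds and
    parameters.
    """
    logging.basicConfig(level=config.log_level)
    report = validate_config(config)
    if not report.ok:
        raise StageError("validate: " + "; ".join(report.issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"pbla_version": __version__, "config": _config_dict(config), "stages": {}}

    def _stage(name, fn):
        try:
            logger.info("stage %s", name)
            return fn()
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise StageError(f"{name}: {exc}") from exc

    panel, segments, gmap, labels, truth = _stage("load", lambda: _load_inputs(config))
    manifest["stages"]["load"] = {"n_samples": panel.n_samples, "n_markers": panel.n_markers,
                                  "n_segments": len(segments)}

    def _qc():
        filtered, rep = apply_qc(panel, config.qc)
        rep.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        return filtered, rep

    panel_qc, qc_rep = _stage("qc", _qc)
    manifest["stages"]["qc"] = {"removed_individuals": len(qc_rep.removed_individuals),
                                "removed_markers": len(qc_rep.removed_markers)}

    if config.run_outlier_stage:
        def _outliers():
            emb = compute_pcs(panel_qc, config.outliers.n_pcs)
            kept, diag = two_stage_outlier_removal(emb, config.outliers)
            diag.to_csv(outdir / "outlier_diagnostics.tsv", sep="\t", index=False)
            return kept

        kept_ids = _stage("outliers", _outliers)
    else:
        kept_ids = list(panel_qc.sample_ids)
    manifest["stages"]["outliers"] = {"n_kept": len(kept_ids),
                                      "n_removed": panel_qc.n_samples - len(kept_ids)}

    labels = phenotype_codes(labels)
    labels = labels[labels.index.isin(kept_ids)]
    kept_set = set(kept_ids)
    seg_kept = segments[
        segments["sample1"].isin(kept_set) & segments["sample2"].isin(kept_set)
    ].reset_index(drop=True)

    def _filter():
        annotated = annotate_segments(seg_kept, gmap)
        kept, rep = filter_segments(annotated, config.seg_filter)
        pd.Series(rep).to_csv(outdir / "segment_filter_report.tsv", sep="\t", header=False)
        return kept, rep

    seg_filtered, filt_rep = _stage("segment_filter", _filter)
    manifest["stages"]["segment_filter"] = filt_rep

    def _map():
        res = permutation_mapping(seg_filtered, labels, panel_qc.markers, config.mapping)
        res.to_frame().to_csv(outdir / "mapping_results.tsv", sep="\t", index=False)
        significant_markers(res).to_csv(outdir / "significant_markers.tsv", sep="\t", index=False)
        return res

    result = _stage("mapping", _map)
    manifest["stages"]["mapping"] = {
        "threshold_statistic": result.threshold_statistic,
        "threshold_p": result.threshold_p,
        "gw_avg": result.gw_avg,
        "n_significant": int(result.significant.sum()),
        "seed": result.seed,
    }
    if truth is not None:
        manifest["truth"] = {k: v for k, v in truth.items() if k != "n_segments"}
    _write_manifest(outdir, manifest)
    return result


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return enc(config)


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
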