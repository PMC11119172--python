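"""End-to-end orchestration: raw matrix -> clusters -> confrontation -> DAPs.

One master seed fans out to per-stage seeds through a stable hash of the
stage name, so any stage can be re-run in isolation and a full re-run of
the same configuration is byte-identical.  Every stage writes plain TSV
plus a JSON run manifest (configuration echo, output checksums, warnings).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .confront import compare_covariates, match_clusters_to_classes
from .consensus import ClusteringConfig, run_consensus
from .containers import AECOPD, CONTROL, SCOPD, IgMapping, QuantMatrix, SampleAnnotation
from .dap import call_daps, run_dap
from .preprocess import (
    filter_by_missingness,
    log2_transform,
    make_subdatasets,
    sampmin_impute,
    unify_immunoglobulins,
)

__version__ = "0.1.0"


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode()) ^ (master_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    matrix_path: str | None = None
    annotation_path: str | None = None
    ig_mapping_path: str | None = None
    output_dir: str = "proteostrat_run"
    max_missing_frac: float = 0.10
    sampmin_factor: float = 0.95
    imputation_mode: str = "literal"
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    diagnosis_groups: tuple[str, str] = (CONTROL, SCOPD)
    exacerbation_groups: tuple[str, str] = (SCOPD, AECOPD)
    diagnosis_positive: str = SCOPD
    exacerbation_positive: str = AECOPD
    ci_mode: str = "paper"
    q_threshold: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clustering"]["k_candidates"] = list(d["clustering"]["k_candidates"])
        d["diagnosis_groups"] = list(d["diagnosis_groups"])
        d["exacerbation_groups"] = list(d["exacerbation_groups"])
        return d


@dataclass
class PipelineResult:
    """In-memory view of everything a run produced."""

    output_dir: Path
    subanalyses: dict  # name -> dict with labels, consensus, report, covariates
    dap_table: pd.DataFrame | None
    dap_counts: tuple[int, int] | None
    manifest: dict


def _preprocess_subdataset(sub: QuantMatrix, cfg: PipelineConfig):
    """Per-sub-dataset filtering and imputation (computed on its own samples)."""
    filtered, dropped = filter_by_missingness(sub, cfg.max_missing_frac)
    imputed = sampmin_impute(filtered, mode=cfg.imputation_mode)
    return filtered, imputed, dropped


def run_pipeline(
    config: PipelineConfig,
    matrix: QuantMatrix | None = None,
    annotation: SampleAnnotation | None = None,
    ig_mapping: IgMapping | None = None,
) -> PipelineResult:
    """Execute the full blind-stratification analysis.

    Stages: unify Ig codes (raw) -> log2 -> split into diagnosis and
    exacerbation sub-datasets -> per sub-dataset: missingness filter,
    SampMin imputation, consensus clustering, confrontation with clinical
    groups, covariate comparison -> differential abundance between the
    exacerbation sub-dataset's final clusters (non-imputed data).

    Inputs may be passed in memory or read from the configured paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "outputs": {},
        "warnings": [],
        "stages": [],
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": pio.sha256_of(path),
        }

    stage = "load"
    try:
        if matrix is None:
            if config.matrix_path is None:
                raise ValueError("no matrix given (in memory or via matrix_path)")
            matrix = pio.read_quant_matrix(config.matrix_path)
        if annotation is None:
            if config.annotation_path is None:
                raise ValueError("no annotation given")
            annotation = pio.read_annotation(config.annotation_path)
        if ig_mapping is None and config.ig_mapping_path:
            ig_mapping = pio.read_ig_mapping(config.ig_mapping_path)

        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            stage = "unify_immunoglobulins"
            unified = unify_immunoglobulins(matrix, ig_mapping or IgMapping())
            manifest["stages"].append(stage)

            stage = "log2_transform"
            logged = log2_transform(unified)
            manifest["stages"].append(stage)

            stage = "make_subdatasets"
            diagnosis, exacerbation = make_subdatasets(
                logged, annotation,
                diagnosis_groups=config.diagnosis_groups,
                exacerbation_groups=config.exacerbation_groups,
            )
            manifest["stages"].append(stage)

            subanalyses = {}
            dap_table = None
            dap_counts = None
            for name, sub, positive in (
                ("diagnosis", diagnosis, config.diagnosis_positive),
                ("exacerbation", exacerbation, config.exacerbation_positive),
            ):
                stage = f"{name}:preprocess"
                filtered, imputed, dropped = _preprocess_subdataset(sub, config)
                pio.write_quant_matrix(filtered, out / f"{name}_filtered.tsv")
                record(f"{name}_filtered", out / f"{name}_filtered.tsv")
                pio.write_quant_matrix(imputed, out / f"{name}_imputed.tsv")
                record(f"{name}_imputed", out / f"{name}_imputed.tsv")
                manifest["stages"].append(stage)

                stage = f"{name}:consensus"
                ccfg = dataclasses.replace(
                    config.clustering,
                    seed=derive_seed(config.seed, f"{name}:consensus"),
                )
                consensus = run_consensus(imputed, ccfg)
                manifest["warnings"].extend(
                    {"stage": stage, "message": w} for w in consensus.warnings
                )
                pio.write_labels(consensus.final_labels, out / f"{name}_labels.tsv")
                record(f"{name}_labels", out / f"{name}_labels.tsv")
                pio.write_table(consensus.area_table, out / f"{name}_delta_area.tsv")
                record(f"{name}_delta_area", out / f"{name}_delta_area.tsv")
                for k, M in consensus.consensus_matrices.items():
                    p = out / f"{name}_consensus_k{k}.tsv"
                    M.to_csv(p, sep="\t")
                    record(f"{name}_consensus_k{k}", p)
                manifest["stages"].append(stage)

                stage = f"{name}:confrontation"
                report = None
                if consensus.final_labels.nunique() >= 2:
                    report = match_clusters_to_classes(
                        consensus.final_labels, annotation, positive,
                        ci_mode=config.ci_mode, n_comparisons=2,
                    )
                    pio.write_table(report.to_frame(), out / f"{name}_confrontation.tsv")
                    record(f"{name}_confrontation", out / f"{name}_confrontation.tsv")
                manifest["stages"].append(stage)

                stage = f"{name}:covariates"
                covars = None
                if consensus.final_labels.nunique() == 2:
                    covars = compare_covariates(consensus.final_labels, annotation)
                    pio.write_table(covars, out / f"{name}_covariates.tsv")
                    record(f"{name}_covariates", out / f"{name}_covariates.tsv")
                manifest["stages"].append(stage)

                subanalyses[name] = {
                    "filtered": filtered,
                    "imputed": imputed,
                    "dropped_proteins": dropped,
                    "consensus": consensus,
                    "report": report,
                    "covariates": covars,
                }

            # DAP on the exacerbation sub-dataset's final clusters, from the
            # filtered but NOT imputed matrix
            exa = subanalyses["exacerbation"]
            if exa["consensus"].final_labels.nunique() == 2:
                stage = "dap"
                dap_table = run_dap(
                    exa["filtered"], exa["consensus"].final_labels,
                    q_threshold=config.q_threshold,
                )
                dap_counts = call_daps(dap_table, config.q_threshold)
                pio.write_table(dap_table, out / "dap_table.tsv")
                record("dap_table", out / "dap_table.tsv")
                manifest["stages"].append(stage)

            manifest["warnings"].extend(
                {"stage": "run", "message": str(w.message)} for w in wrec
            )
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        output_dir=out,
        subanalyses=subanalyses,
        dap_table=dap_table,
        dap_counts=dap_counts,
        manifest=manifest,
    )
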