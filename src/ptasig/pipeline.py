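"""End-to-end signature pipeline.

Chains the discovery stages: expression calls on the tissue atlas ->
breadth -> PTA classification -> pooled top-quartile filter on the
stromal matrix -> focal-subset enrichment call -> target-tissue flags ->
tissue-representation test of the signature against a random control
set.  Every run emits a JSON manifest (config, seed, input checksums,
per-stage gene counts) sufficient to reproduce it exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as pio
from .atlas import PtaAnnotation, TissueAtlas, annotate_atlas
from .errors import ConfigurationError, InputError, PipelineStageError
from .setstats import GeneSet, TissueRepresentationResult, tissue_representation_test
from .stromal import ExpressionMatrix, call_frc_enriched, pooled_quartile_filter, subset_correlation

log = logging.getLogger("ptasig.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_signature_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the signature workflow with their published
    defaults: breadth < 5 tissues, pooled top quartile, fold > 3,
    adjusted p <= 0.05."""

    breadth_threshold: int = 5
    expression_rule: str = "global-median"
    expression_threshold: Optional[float] = None
    quartile: float = 0.75
    fold_threshold: float = 3.0
    alpha: float = 0.05
    focal_subset: str = "FRC"
    target_tissues: Optional[list[str]] = None  # None -> use the atlas's own list
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_metric: str = "auto"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise InputError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    annotation: PtaAnnotation
    pta_genes: list[str]
    quartile_genes: list[str]
    enrichment_table: pd.DataFrame
    signature: GeneSet
    correlation: pd.DataFrame
    tissue_test: Optional[TissueRepresentationResult]
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_signature_pipeline(
    config: PipelineConfig,
    atlas: TissueAtlas | str | Path,
    stromal: ExpressionMatrix | str | Path,
    labels_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full signature discovery pipeline.

    ``atlas`` and ``stromal`` may be in-memory objects or TSV paths (a
    stromal path requires ``labels_path``).  When ``out_dir`` is given,
    every intermediate is written there (TSV/GMT/JSON) together with
    the run manifest; partial outputs are retained if a later stage
    fails.
    """
    checksums = {}
    if not isinstance(atlas, TissueAtlas):
        atlas_path = Path(atlas)
        checksums["atlas"] = pio.file_sha256(atlas_path)
        values = pio.read_matrix_tsv(atlas_path)
        targets = tuple(config.target_tissues or ())
        atlas = TissueAtlas(values=values, target_tissues=targets)
    elif config.target_tissues is not None:
        atlas = TissueAtlas(values=atlas.values, target_tissues=tuple(config.target_tissues))
    if not isinstance(stromal, ExpressionMatrix):
        stromal_path = Path(stromal)
        if labels_path is None:
            raise ConfigurationError("a stromal matrix path requires labels_path")
        checksums["stromal"] = pio.file_sha256(stromal_path)
        checksums["labels"] = pio.file_sha256(Path(labels_path))
        stromal = ExpressionMatrix(
            values=pio.read_matrix_tsv(stromal_path), sample_labels=pio.read_labels_tsv(labels_path)
        )

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    counts: dict[str, int] = {"n_genes_atlas": len(atlas.genes), "n_genes_stromal": len(stromal.genes)}

    annotation = _stage("classify_pta")(annotate_atlas)(
        atlas,
        rule=config.expression_rule,
        threshold=config.expression_threshold,
        breadth_threshold=config.breadth_threshold,
    )
    pta_genes = [g for g in annotation.pta_genes if g in set(stromal.genes)]
    counts["n_pta"] = int(annotation.is_pta.sum())
    counts["n_pta_in_stroma"] = len(pta_genes)
    log.info("PTA classification: %d PTA genes (%d also in stromal matrix)", counts["n_pta"], len(pta_genes))
    if out is not None:
        _write_annotation(annotation, out / "pta_annotation.tsv")

    quartile_genes = _stage("pooled_quartile_filter")(pooled_quartile_filter)(
        stromal, pta_genes, quantile=config.quartile
    )
    counts["n_top_quartile"] = len(quartile_genes)
    log.info("pooled top-quartile filter: n = %d genes", len(quartile_genes))
    if out is not None:
        pio.write_gmt([GeneSet.from_iterable("pta_top_quartile", quartile_genes)], out / "pta_top_quartile.gmt")

    enrichment_table, signature_genes = _stage("call_frc_enriched")(call_frc_enriched)(
        stromal,
        quartile_genes,
        focal_subset=config.focal_subset,
        fold_threshold=config.fold_threshold,
        alpha=config.alpha,
    )
    counts["n_signature"] = len(signature_genes)
    log.info("%s-enriched signature: n = %d genes", config.focal_subset, len(signature_genes))
    signature = GeneSet.from_iterable(f"{config.focal_subset}_enriched_pta", signature_genes)
    if out is not None:
        enrichment_table.to_csv(out / "enrichment_calls.tsv", sep="\t")
        pio.write_gmt([signature], out / "signature.gmt")

    correlation = _stage("subset_correlation")(subset_correlation)(stromal, quartile_genes)
    if out is not None:
        correlation.to_csv(out / "subset_correlation.tsv", sep="\t")

    tissue_test = None
    control_pool = [g for g in quartile_genes if g not in signature.as_set]
    if signature_genes and len(control_pool) >= len(signature_genes) and atlas.target_tissues:
        tissue_test = _stage("tissue_representation_test")(tissue_representation_test)(
            signature,
            GeneSet.from_iterable("non_enriched_pta_pool", control_pool),
            annotation,
            seed=config.seed,
        )
        counts["n_signature_in_target"] = tissue_test.contingency.a
        log.info(
            "tissue representation: %d/%d signature vs %d/%d control genes in target tissues (p = %.3g)",
            tissue_test.contingency.a, len(signature_genes),
            tissue_test.contingency.c, len(signature_genes),
            tissue_test.contingency.p_two_sided,
        )
    else:
        log.info("tissue representation test skipped (empty signature, small pool or no target tissues)")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "input_checksums": checksums,
        "stage_counts": counts,
        "tissue_test": None
        if tissue_test is None
        else {
            "table": list(tissue_test.contingency.table),
            "odds_ratio": tissue_test.contingency.odds_ratio,
            "p_two_sided": tissue_test.contingency.p_two_sided,
            "control_seed": tissue_test.seed,
        },
    }
    if out is not None:
        pio.write_json(manifest, out / "manifest.json")

    return PipelineResult(
        annotation=annotation,
        pta_genes=pta_genes,
        quartile_genes=quartile_genes,
        enrichment_table=enrichment_table,
        signature=signature,
        correlation=correlation,
        tissue_test=tissue_test,
        manifest=manifest,
    )


def _write_annotation(annotation: PtaAnnotation, path: Path) -> None:
    frame = annotation.frame.copy()
    frame["expressed_tissues"] = frame["expressed_tissues"].map(lambda t: ",".join(t))
    frame.to_csv(path, sep="\t")
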