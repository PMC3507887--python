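"""End-to-end orchestration: preprocessing, per-tissue differential
expression, cross-tissue concordance and GO enrichment, with a run manifest.

The in-memory entry points (:func:`analyze_two_tissue`,
:func:`analyze_tissue`) take the containers the synthetic generator or the
readers produce; :func:`run_pipeline` wraps them with file IO and writes all
output tables plus a manifest of checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosstissue import ConcordanceResult, concordance_summary, intersect_sdrg
from .differential import TissueResult, run_tissue_de
from .enrichment import annotations_from_table, read_gaf, run_enrichment
from .errors import ValidationError
from .io import (
    file_sha256,
    read_intensity_tsv,
    read_probe_map_tsv,
    write_table_tsv,
)
from .preprocess import (
    IntensityMatrix,
    classify_expressed,
    collapse_probes,
    log2_transform,
    merge_duplicates,
    normalize_median_null,
)

__all__ = ["PipelineConfig", "PipelineResult", "analyze_tissue", "analyze_two_tissue", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Knobs of the full analysis, defaulting to the study's constants:
    expressed threshold 7.2 (or "auto"), FDR gate q<0.05, fold-change gate 2,
    pi0 plotting window lambda=0.5, GO terms need >4 expressed genes."""

    intensities: str | None = None
    metadata: str | None = None
    probe_map: str | None = None
    gaf: str | None = None
    outdir: str = "results"
    expressed_threshold: float | str = 7.2
    q_threshold: float = 0.05
    fc_threshold: float = 2.0
    pi0_lambda: float = 0.5
    enrichment_min_genes: int = 5
    require_same_direction: bool = True
    classify_after_normalization: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("q_threshold", "fc_threshold", "pi0_lambda"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    tissues: dict[str, TissueResult]
    concordance: ConcordanceResult
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    expression_call: object = None
    manifest: dict = field(default_factory=dict)


def _preprocess(
    matrix: IntensityMatrix, probe_map: pd.DataFrame, config: PipelineConfig
):
    """log2 -> expressed/background call -> median normalization -> replicate
    merge -> probe collapse.  Returns (gene matrix, null probe matrix,
    merged metadata, call, replicate correlations)."""
    log2 = log2_transform(matrix)
    if config.classify_after_normalization:
        # classify on normalized averages: bootstrap the null set from a
        # provisional call on un-normalized averages, then re-call
        provisional = classify_expressed(log2, config.expressed_threshold)
        norm0 = normalize_median_null(log2, provisional)
        call = classify_expressed(
            IntensityMatrix(values=norm0.values, metadata=log2.metadata, scale="log2"),
            config.expressed_threshold,
        )
    else:
        call = classify_expressed(log2, config.expressed_threshold)
    norm = normalize_median_null(log2, call)
    merged, merged_meta, replicate_corr = merge_duplicates(norm.values, log2.metadata)
    norm.values = merged
    norm.metadata = merged_meta
    gene = collapse_probes(norm, probe_map)
    null_values = merged.loc[call.null_probes]
    return gene, null_values, merged_meta, call, replicate_corr


def analyze_tissue(
    matrix: IntensityMatrix,
    probe_map: pd.DataFrame,
    config: PipelineConfig,
    tissue: str,
) -> tuple[TissueResult, pd.DataFrame]:
    """Single-tissue analysis (classification on this tissue's arrays only).

    Returns the tissue result and the expression-call table.  Only genes
    whose retained probe is expressed enter the test; not-expressed probes
    supply the empirical null.
    """
    gene, null_values, meta, call, _ = _preprocess(matrix, probe_map, config)
    expressed_genes = gene.provenance.index[
        call.table.loc[gene.provenance.to_numpy(), "expressed"].to_numpy()
    ]
    result = run_tissue_de(
        gene.values.loc[expressed_genes],
        null_values,
        meta,
        tissue,
        q_threshold=config.q_threshold,
        fc_threshold=config.fc_threshold,
        lam=config.pi0_lambda,
    )
    return result, call.table


def analyze_two_tissue(
    heart: IntensityMatrix,
    pbmc: IntensityMatrix,
    probe_map: pd.DataFrame,
    config: PipelineConfig,
    annotations: dict | None = None,
) -> PipelineResult:
    """Joint analysis of both tissues with a pooled expressed/background call.

    Probes are classified on the average over all arrays of both tissues
    (one shared expressed set), each tissue is tested separately, and the
    two results are intersected into the SDRG list.  When GO annotations
    are given, enrichment runs per tissue on the calibrated gene p-values.
    """
    combined = IntensityMatrix(
        values=pd.concat([heart.values, pbmc.values], axis=1),
        metadata=pd.concat([heart.metadata, pbmc.metadata]),
    )
    gene, null_values, meta, call, replicate_corr = _preprocess(
        combined, probe_map, config
    )
    expressed_genes = gene.provenance.index[
        call.table.loc[gene.provenance.to_numpy(), "expressed"].to_numpy()
    ]
    tissues: dict[str, TissueResult] = {}
    for tissue in ("heart", "pbmc"):
        tissues[tissue] = run_tissue_de(
            gene.values.loc[expressed_genes],
            null_values,
            meta,
            tissue,
            q_threshold=config.q_threshold,
            fc_threshold=config.fc_threshold,
            lam=config.pi0_lambda,
        )
    concordance = intersect_sdrg(
        tissues["heart"], tissues["pbmc"],
        require_same_direction=config.require_same_direction,
    )
    enrich: dict[str, pd.DataFrame] = {}
    if annotations:
        for tissue, result in tissues.items():
            enrich[tissue] = run_enrichment(
                result.table["p_adj"],
                annotations,
                expressed_genes=result.table.index,
                min_genes=config.enrichment_min_genes,
            )
    return PipelineResult(
        tissues=tissues,
        concordance=concordance,
        enrichment=enrich,
        expression_call=call,
        manifest={"replicate_correlations": replicate_corr},
    )


def _de_output_table(result: TissueResult) -> pd.DataFrame:
    out = result.table.reset_index(names="gene")
    cols = [
        "gene", "mean_control", "mean_treated", "log2fc", "s2", "s2_tilde",
        "t", "df", "p_raw", "p_adj", "q", "call",
    ]
    return out[cols]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes every output table and a manifest.

    The manifest records the config hash, package version and a sha256 per
    output file, so identical inputs yield identical manifests.
    """
    for name in ("intensities", "metadata", "probe_map"):
        if getattr(config, name) is None:
            raise ValidationError(f"pipeline stage input: --{name.replace('_', '-')} is required")
    matrix = read_intensity_tsv(config.intensities, config.metadata)
    probe_map = read_probe_map_tsv(config.probe_map)
    annotations = read_gaf(config.gaf) if config.gaf else None

    tissues_present = sorted(set(matrix.metadata.loc[matrix.values.columns, "tissue"]))
    if set(tissues_present) != {"heart", "pbmc"}:
        raise ValidationError(
            f"pipeline stage preprocess: expected tissues heart+pbmc, found {tissues_present}"
        )
    heart_cols = matrix.tissue_samples("heart")
    pbmc_cols = matrix.tissue_samples("pbmc")
    heart = IntensityMatrix(
        values=matrix.values[heart_cols], metadata=matrix.metadata.loc[heart_cols]
    )
    pbmc = IntensityMatrix(
        values=matrix.values[pbmc_cols], metadata=matrix.metadata.loc[pbmc_cols]
    )
    result = analyze_two_tissue(heart, pbmc, probe_map, config, annotations=annotations)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    for tissue, tres in result.tissues.items():
        path = outdir / f"de_{tissue}.tsv"
        write_table_tsv(_de_output_table(tres), path)
        outputs[f"de_{tissue}"] = path
        # p-value-plot and volcano companions (plot-ready TSVs)
        diag = pd.DataFrame(
            {
                "gene": tres.table.index,
                "p_adj": tres.table["p_adj"],
                "log2fc": tres.table["log2fc"],
                "neg_log10_q": -np.log10(tres.table["q"].clip(lower=1e-300)),
            }
        )
        vpath = outdir / f"volcano_{tissue}.tsv"
        write_table_tsv(diag, vpath)
        outputs[f"volcano_{tissue}"] = vpath
    sdrg_path = outdir / "sdrg.tsv"
    write_table_tsv(result.concordance.table.reset_index(names="gene"), sdrg_path)
    outputs["sdrg"] = sdrg_path
    for tissue, table in result.enrichment.items():
        path = outdir / f"enrichment_{tissue}.tsv"
        write_table_tsv(table, path)
        outputs[f"enrichment_{tissue}"] = path
    call_path = outdir / "expression_calls.tsv"
    write_table_tsv(
        result.expression_call.table.reset_index(names="probe_id"), call_path
    )
    outputs["expression_calls"] = call_path

    manifest = {
        "config_hash": config.config_hash(),
        "version": __version__,
        "pi0": {t: r.pi0 for t, r in result.tissues.items()},
        "counts": {
            t: {"significant": r.n_significant, "up": r.n_up, "down": r.n_down}
            for t, r in result.tissues.items()
        },
        "sdrg": {
            "total": result.concordance.n_total,
            "up_both": result.concordance.n_up_both,
            "down_both": result.concordance.n_down_both,
            "discordant": result.concordance.n_discordant,
        },
        "outputs": {k: file_sha256(p) for k, p in outputs.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result.manifest = manifest
    return result
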