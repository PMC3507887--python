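"""Probe-level preprocessing: log2 transform, expressed/background calling,
median-of-background normalization, probe-to-gene collapse and duplicate
array merging.

The normalization scheme subtracts, within each array, the median of the
log2 intensities of the *not expressed* (background-level) probes, so the
background class doubles as a negative-control reference both here and for
the empirical-null p-value calibration downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from scipy.signal import argrelextrema

from .errors import ValidationError

__all__ = [
    "IntensityMatrix",
    "ExpressionCall",
    "NormalizedMatrix",
    "log2_transform",
    "classify_expressed",
    "normalize_median_null",
    "collapse_probes",
    "merge_duplicates",
]

REQUIRED_METADATA = ("subject_id", "tissue", "group", "replicate")
VALID_GROUPS = {"control", "treated"}


@dataclass
class IntensityMatrix:
    """Probe x sample matrix with per-sample metadata.

    ``values`` is indexed by probe id with one column per sample id;
    ``metadata`` is indexed by sample id with columns ``subject_id``,
    ``tissue``, ``group`` (control/treated) and ``replicate``.  ``scale``
    records whether values are raw intensities or log2.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self):
        v, m = self.values, self.metadata
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][:3].tolist()
            raise ValidationError(f"duplicated probe ids: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][:3].tolist()
            raise ValidationError(f"duplicated sample ids: {dup}")
        missing_cols = [c for c in REQUIRED_METADATA if c not in m.columns]
        if missing_cols:
            raise ValidationError(f"metadata missing columns: {missing_cols}")
        absent = [s for s in v.columns if s not in m.index]
        if absent:
            raise ValidationError(
                f"samples present in matrix but absent from metadata: {absent[:5]}"
            )
        bad_groups = set(m.loc[v.columns, "group"]) - VALID_GROUPS
        if bad_groups:
            raise ValidationError(f"invalid group labels: {sorted(bad_groups)}")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def tissue_samples(self, tissue: str) -> list[str]:
        m = self.metadata.loc[self.values.columns]
        return list(m.index[m["tissue"] == tissue])


@dataclass
class ExpressionCall:
    """Per-probe expressed / not-expressed partition.

    ``table`` has columns ``avg_log2`` and ``expressed``; a probe is
    expressed iff its average log2 intensity over all arrays is strictly
    greater than ``threshold``.
    """

    table: pd.DataFrame
    threshold: float
    mode: str = "fixed"

    @property
    def expressed_probes(self) -> pd.Index:
        return self.table.index[self.table["expressed"]]

    @property
    def null_probes(self) -> pd.Index:
        return self.table.index[~self.table["expressed"]]


@dataclass
class NormalizedMatrix:
    """Log2 matrix after per-array median-of-background subtraction.

    ``medians`` records the subtracted per-array medians; ``provenance``
    (gene level only) maps each retained row to the probe it came from.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    medians: pd.Series = None
    normalized: bool = True
    provenance: pd.Series = field(default=None, repr=False)


def log2_transform(raw: IntensityMatrix) -> IntensityMatrix:
    """Elementwise log2 of strictly positive raw intensities.

    A nonpositive cell is a hard error naming the probe and sample — raw
    bead intensities without background subtraction are positive by
    construction, so a nonpositive value indicates corrupted input.
    """
    vals = raw.values.to_numpy()
    bad = np.argwhere(~(vals > 0))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"nonpositive intensity {vals[i, j]!r} at probe "
            f"{raw.values.index[i]!r}, sample {raw.values.columns[j]!r}"
        )
    out = pd.DataFrame(np.log2(vals), index=raw.values.index, columns=raw.values.columns)
    return IntensityMatrix(values=out, metadata=raw.metadata, scale="log2")


def _auto_threshold(avg: np.ndarray) -> float:
    """Antimode between the two main modes of the average-log2 density."""
    kde = gaussian_kde(avg)
    grid = np.linspace(avg.min(), avg.max(), 512)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if maxima.size < 2:
        raise ValidationError(
            "average log2-intensity distribution looks unimodal; "
            "auto thresholding needs a bimodal background/expressed split — "
            "supply a fixed threshold instead"
        )
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = np.sort(top2)
    between = slice(lo, hi + 1)
    return float(grid[between][np.argmin(dens[between])])


def classify_expressed(
    log2: IntensityMatrix | pd.DataFrame, threshold: float | str = 7.2
) -> ExpressionCall:
    """Partition probes into expressed vs background by average log2 intensity.

    The average is taken over all arrays of the matrix; the comparison is a
    strict ``>`` (a probe sitting exactly at the threshold is background).
    ``threshold="auto"`` places the cut at the antimode between the two
    modes of the average-intensity distribution.
    """
    values = log2.values if isinstance(log2, IntensityMatrix) else log2
    if values.shape[1] < 2:
        raise ValidationError("classification needs at least 2 arrays")
    avg = values.mean(axis=1)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValidationError(f"threshold must be a number or 'auto', got {threshold!r}")
        thr = _auto_threshold(avg.to_numpy())
        mode = "auto"
    else:
        thr = float(threshold)
        mode = "fixed"
    table = pd.DataFrame({"avg_log2": avg, "expressed": avg > thr})
    return ExpressionCall(table=table, threshold=thr, mode=mode)


def normalize_median_null(
    log2: IntensityMatrix | pd.DataFrame, call: ExpressionCall,
    metadata: pd.DataFrame | None = None,
) -> NormalizedMatrix:
    """Subtract each array's median over not-expressed probes from all values."""
    if isinstance(log2, IntensityMatrix):
        values, metadata = log2.values, log2.metadata
    else:
        values = log2
    null_probes = call.null_probes.intersection(values.index)
    if len(null_probes) == 0:
        raise ValidationError("no not-expressed probes available for normalization")
    medians = values.loc[null_probes].median(axis=0)
    return NormalizedMatrix(
        values=values.sub(medians, axis=1),
        metadata=metadata,
        medians=medians,
    )


def collapse_probes(norm: NormalizedMatrix, probe_map: pd.DataFrame) -> NormalizedMatrix:
    """Collapse probes to genes, keeping the probe with the largest average.

    Probes absent from the map are dropped.  For a gene with several probes,
    exactly the probe with the largest average normalized log2 intensity is
    retained (ties broken toward the lexicographically smallest probe id).
    The retained probe of each gene is recorded in ``provenance``.
    """
    pm = probe_map.set_index("probe_id")["gene_symbol"] if "probe_id" in probe_map else probe_map
    mapped = norm.values.index.intersection(pm.index)
    if len(mapped) == 0:
        import warnings

        warnings.warn("no probes map to genes; collapse yields an empty matrix")
    sub = norm.values.loc[mapped]
    info = pd.DataFrame(
        {
            "probe_id": mapped.to_numpy(),
            "gene": pm.loc[mapped].to_numpy(),
            "avg": sub.mean(axis=1).to_numpy(),
        }
    )
    # max average per gene; ties broken toward the smallest probe id
    info = info.sort_values(
        ["gene", "avg", "probe_id"], ascending=[True, False, True], kind="stable"
    )
    keep = info.drop_duplicates("gene")
    out = sub.loc[keep["probe_id"]]
    out.index = pd.Index(keep["gene"].to_numpy(), name="gene")
    provenance = pd.Series(
        keep["probe_id"].to_numpy(), index=out.index, name="probe_id"
    )
    return NormalizedMatrix(
        values=out,
        metadata=norm.metadata,
        medians=norm.medians,
        provenance=provenance,
    )


def merge_duplicates(
    values: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Average replicate arrays of each (subject, tissue) on the log2 scale.

    Returns the merged matrix (one column per subject-tissue), the merged
    metadata, and a per-pair Pearson-correlation table quantifying replicate
    agreement.
    """
    meta = metadata.loc[values.columns]
    key = list(zip(meta["subject_id"], meta["tissue"]))
    groups: dict[tuple, list[str]] = {}
    for sample, k in zip(values.columns, key):
        groups.setdefault(k, []).append(sample)

    merged_cols = {}
    meta_rows = []
    corr_rows = []
    for (subject, tissue), samples in groups.items():
        grp = set(meta.loc[samples, "group"])
        if len(grp) > 1:
            raise ValidationError(
                f"replicates of subject {subject!r} ({tissue}) span groups {sorted(grp)}"
            )
        new_id = f"{tissue}_{subject}"
        merged_cols[new_id] = values[samples].mean(axis=1)
        meta_rows.append((new_id, subject, tissue, grp.pop(), 1))
        if len(samples) > 1 and len(values) > 1:
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    r = float(np.corrcoef(values[samples[i]], values[samples[j]])[0, 1])
                    corr_rows.append((subject, tissue, samples[i], samples[j], r))

    merged = pd.DataFrame(merged_cols)
    merged.index = values.index
    merged_meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "tissue", "group", "replicate"]
    ).set_index("sample_id")
    corr = pd.DataFrame(
        corr_rows, columns=["subject_id", "tissue", "sample_a", "sample_b", "pearson_r"]
    )
    return merged, merged_meta, corr
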