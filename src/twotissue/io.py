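"""Tab-separated readers and writers for the pipeline's artifacts.

Everything on disk is plain TSV (or GAF, itself a TSV dialect); matrices
carry the probe/gene id in the first column, metadata tables are keyed by
sample id.
"""

from __future__ import annotations

import hashlib

import pandas as pd

from .errors import ValidationError
from .preprocess import IntensityMatrix, REQUIRED_METADATA

__all__ = [
    "read_intensity_tsv",
    "read_metadata_tsv",
    "read_probe_map_tsv",
    "read_ct_tsv",
    "write_matrix_tsv",
    "write_table_tsv",
    "write_gaf",
    "file_sha256",
]


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    if "sample_id" not in meta.columns:
        raise ValidationError(f"{path}: metadata must have a sample_id column")
    missing = [c for c in REQUIRED_METADATA if c not in meta.columns]
    if missing:
        raise ValidationError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicated sample ids {dups[:5]}")
    return meta.set_index("sample_id")


def read_intensity_tsv(path, metadata_path) -> IntensityMatrix:
    """Read a probe x sample intensity TSV plus its sample metadata.

    The first column must be ``probe_id``; every remaining column must have
    a metadata row.  Non-numeric cells and duplicate ids are specific errors.
    """
    values = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str}, float_precision="round_trip"
    )
    if values.columns[0] != "probe_id":
        raise ValidationError(f"{path}: first column must be 'probe_id'")
    values = values.set_index("probe_id")
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValidationError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r} "
                f"(probe {bad.index[0]!r})"
            )
    meta = read_metadata_tsv(metadata_path)
    absent = [c for c in values.columns if c not in meta.index]
    if absent:
        raise ValidationError(
            f"{path}: column(s) {absent[:5]} missing from metadata {metadata_path}"
        )
    return IntensityMatrix(values=values, metadata=meta)


def read_probe_map_tsv(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("probe_id", "gene_symbol") if c not in pm.columns]
    if missing:
        raise ValidationError(f"{path}: probe map missing columns {missing}")
    if pm["probe_id"].duplicated().any():
        dups = pm.loc[pm["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"{path}: duplicated probe ids in map {dups[:5]}")
    return pm


def read_ct_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "gene": str},
        float_precision="round_trip",
    )
    required = ("sample_id", "group", "gene", "replicate", "ct")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: Ct table missing columns {missing}")
    return table


def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    """Write an id-indexed matrix with the index as the first column."""
    values.to_csv(path, sep="\t", lineterminator="\n")


def write_table_tsv(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_gaf(annotation_table: pd.DataFrame, path, db: str = "TwoTissueSim") -> None:
    """Serialize a (term_id, aspect, gene_symbol) table as GAF 2.2."""
    code = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for term_id, aspect, gene in annotation_table[
            ["term_id", "aspect", "gene_symbol"]
        ].itertuples(index=False):
            cols = [
                db,            # 1 DB
                gene,          # 2 DB object id
                gene,          # 3 DB object symbol
                "involved_in", # 4 qualifier
                term_id,       # 5 GO id
                "SIM:0000001", # 6 reference
                "IEA",         # 7 evidence
                "",            # 8 with/from
                code[aspect],  # 9 aspect
                "",            # 10 name
                "",            # 11 synonym
                "gene",        # 12 type
                "taxon:10116", # 13 taxon (rat)
                "20120219",    # 14 date
                db,            # 15 assigned by
                "",            # 16 extension
                "",            # 17 isoform
            ]
            fh.write("\t".join(cols) + "\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
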