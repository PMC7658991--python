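"""Readers and writers for the plain-text formats used across the pipeline.

Count matrices are carried in memory as pandas DataFrames with gene ids on
the index and sample ids on the columns; metadata, ligand-receptor pairs and
gene sets use DataFrames / dicts with fixed column names.  Everything here
round-trips losslessly through TSV (and MatrixMarket for counts).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

TISSUES = ("cartilage", "synovium", "subchondral_bone")

SAMPLE_TABLE_REQUIRED = ("sample_id", "patient_id", "tissue", "status")
SAMPLE_TABLE_COLUMNS = SAMPLE_TABLE_REQUIRED + (
    "center", "age", "sex", "kl", "osteophyte", "jsn",
)


class ValidationError(ValueError):
    """Raised when an input table violates its documented contract."""


def validate_count_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Check a genes×samples count matrix: unique ids, integral, non-negative."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dup[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count matrix contains non-numeric entries")
    if np.any(values < 0):
        g, s = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if not np.allclose(values, np.round(values)):
        g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise ValidationError(
            f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return df.astype(np.int64)


def read_count_matrix(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a count matrix from TSV (genes as rows) or an MTX triplet.

    For ``format='mtx'`` the path names the MatrixMarket file and sidecar
    name files ``<stem>.genes.txt`` / ``<stem>.samples.txt`` (one id per
    line) are expected next to it.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")  # strips .mtx
        genes = stem.with_suffix(".genes.txt").read_text().split()
        samples = stem.with_suffix(".samples.txt").read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes × "
                f"{len(samples)} samples"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValidationError(f"unknown count-matrix format {format!r}")
    return validate_count_matrix(df)


def write_count_matrix(df: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(df.to_numpy()))
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(df.index) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(df.columns) + "\n")
    else:
        raise ValidationError(f"unknown count-matrix format {format!r}")


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dup[:5]}")
    bad_tissue = set(df["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValidationError(f"unknown tissues: {sorted(bad_tissue)}")
    bad_status = set(df["status"]) - {"OA", "control"}
    if bad_status:
        raise ValidationError(f"unknown status values: {sorted(bad_status)}")
    return df.reset_index(drop=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return validate_sample_table(pd.read_csv(path, sep="\t"))


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_lr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValidationError(f"ligand-receptor table missing column {col!r}")
    if df.duplicated(subset=["ligand", "receptor"]).any():
        raise ValidationError("duplicate ligand-receptor rows")
    return df


def write_lr_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then tab-separated gene ids."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with <3 fields: {line[:50]!r}")
        sets[fields[0]] = fields[2:]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
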