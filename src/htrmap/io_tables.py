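"""Readers/writers for the cell, expression and spatial tables, plus joins.

Supported table dialects are CSV (UTF-8, header row) and Parquet; the
expression matrix is additionally accepted as an HDF5 file with a
``matrix`` dataset and aligned ``cell_label`` / ``gene`` label vectors.
A JSON sidecar carries the synthetic generator's planted ground truth.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import GroundTruth

logger = logging.getLogger(__name__)

REQUIRED_CELL_COLUMNS = (
    "cell_label", "class", "subclass", "supertype", "cluster",
    "neighborhood", "neurotransmitter",
)
TAXONOMY_COLUMNS = ("class", "subclass", "supertype", "cluster")
REQUIRED_SPATIAL_COLUMNS = (
    "cell_label", "x", "y", "ap_coordinate", "section_label",
    "division", "structure", "class", "subclass", "supertype", "cluster",
)


class SchemaError(ValueError):
    """A table is missing a required column or violates an invariant."""


class JoinError(ValueError):
    """A join between tables has no overlapping keys."""


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    return {
        ".csv": "csv",
        ".parquet": "parquet",
        ".pq": "parquet",
        ".h5": "hdf5",
        ".hdf5": "hdf5",
    }.get(suffix, "csv")


def _read_frame(path: str | Path, fmt: str) -> pd.DataFrame:
    if fmt == "csv":
        # "None" is a meaningful neurotransmitter label, not a missing value
        return pd.read_csv(path, keep_default_na=False, na_values=[""])
    if fmt == "parquet":
        return pd.read_parquet(path)
    raise ValueError(f"unsupported table format: {fmt!r}")


def _write_frame(df: pd.DataFrame, path: str | Path, fmt: str) -> None:
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "parquet":
        df.to_parquet(path, index=False)
    else:
        raise ValueError(f"unsupported table format: {fmt!r}")


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_cell_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read and validate a cell-metadata table; unknown columns are kept."""
    df = _read_frame(path, _infer_format(path, fmt))
    _check_columns(df, REQUIRED_CELL_COLUMNS, "cell table")
    if df["cell_label"].duplicated().any():
        raise SchemaError("cell table has duplicated cell_label values")
    if df[list(TAXONOMY_COLUMNS)].isna().any().any():
        raise SchemaError("cell table has null taxonomy labels")
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    _check_columns(df, REQUIRED_CELL_COLUMNS, "cell table")
    _write_frame(df, path, _infer_format(path, fmt))


def read_spatial_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    df = _read_frame(path, _infer_format(path, fmt))
    _check_columns(df, REQUIRED_SPATIAL_COLUMNS, "spatial table")
    if df["cell_label"].duplicated().any():
        raise SchemaError("spatial table has duplicated cell_label values")
    pairs = df[["structure", "division"]].drop_duplicates()
    if pairs["structure"].duplicated().any():
        raise SchemaError("a structure maps to more than one division")
    return df


def write_spatial_table(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    _check_columns(df, REQUIRED_SPATIAL_COLUMNS, "spatial table")
    _write_frame(df, path, _infer_format(path, fmt))


def read_expression_matrix(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a cells x genes matrix (wide CSV/Parquet, or HDF5).

    Missing values are treated as 0 (undetected) with a logged count so
    that threshold semantics are unaffected.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            matrix = np.asarray(f["matrix"])
            cells = [s.decode() if isinstance(s, bytes) else str(s) for s in f["cell_label"][()]]
            genes = [s.decode() if isinstance(s, bytes) else str(s) for s in f["gene"][()]]
        df = pd.DataFrame(matrix, index=pd.Index(cells, name="cell_label"), columns=genes)
    else:
        df = _read_frame(path, fmt)
        if "cell_label" not in df.columns:
            raise SchemaError("expression matrix is missing required column(s): cell_label")
        df = df.set_index("cell_label")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("expression matrix: %d missing values treated as 0", n_missing)
        df = df.fillna(0.0)
    if (df.to_numpy() < 0).any():
        raise SchemaError("expression matrix has negative values")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=df.to_numpy(dtype=float))
            f.create_dataset("cell_label", data=np.array(df.index.astype(str), dtype="S"))
            f.create_dataset("gene", data=np.array(df.columns.astype(str), dtype="S"))
    else:
        _write_frame(df.rename_axis("cell_label").reset_index(), path, fmt)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    payload = {
        "enrichment_fraction": gt.enrichment_fraction,
        "planted_prevalence": {
            "index": list(gt.planted_prevalence.index),
            "columns": list(gt.planted_prevalence.columns),
            "values": gt.planted_prevalence.to_numpy().tolist(),
        },
        "planted_enriched": {g: sorted(s) for g, s in gt.planted_enriched.items()},
        "planted_group_profiles": {
            "index": list(gt.planted_group_profiles.index),
            "columns": list(gt.planted_group_profiles.columns),
            "values": gt.planted_group_profiles.to_numpy().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())

    def frame(key, index_name):
        block = payload[key]
        return pd.DataFrame(
            block["values"],
            index=pd.Index(block["index"], name=index_name),
            columns=block["columns"],
        )

    return GroundTruth(
        planted_prevalence=frame("planted_prevalence", "cluster"),
        planted_enriched={g: set(v) for g, v in payload["planted_enriched"].items()},
        planted_group_profiles=frame("planted_group_profiles", "class"),
        enrichment_fraction=float(payload["enrichment_fraction"]),
    )


def join_expression(cells: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Inner join of metadata and expression on the unique cell label.

    Row order follows the expression matrix; cells lacking expression rows
    (and expression rows lacking metadata) are dropped with a logged count.
    The result carries the metadata columns plus one column per gene.
    """
    meta = cells.set_index("cell_label")
    shared = expr.index.intersection(meta.index)
    if len(shared) == 0:
        raise JoinError("no overlap between expression rows and cell labels")
    n_dropped_cells = len(meta) - len(shared)
    n_dropped_expr = len(expr) - len(shared)
    if n_dropped_cells or n_dropped_expr:
        logger.warning(
            "join_expression: dropped %d metadata rows and %d expression rows "
            "without a counterpart", n_dropped_cells, n_dropped_expr,
        )
    keep = expr.index[expr.index.isin(meta.index)]
    joined = meta.loc[keep].join(expr.loc[keep])
    return joined.reset_index()


def expand_memberships(cells: pd.DataFrame, membership: pd.DataFrame) -> pd.DataFrame:
    """Duplicate rows for cells belonging to several neighborhoods.

    ``membership`` has columns ``cell_label`` and ``neighborhood`` with one
    row per (cell, neighborhood) pair.  Cells absent from the membership
    table keep their single neighborhood label.  The expanded table is meant
    ONLY for neighborhood-grouped statistics; every other grouping must use
    the original, unduplicated table.
    """
    _check_columns(membership, ("cell_label", "neighborhood"), "membership table")
    in_membership = cells["cell_label"].isin(membership["cell_label"])
    kept = cells.loc[~in_membership]
    expanded = (
        cells.loc[in_membership]
        .drop(columns=["neighborhood"])
        .merge(membership, on="cell_label", how="inner")
    )
    out = pd.concat([kept, expanded], ignore_index=True)
    return out
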