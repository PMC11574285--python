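"""Co-localization percentages, co-transcription counts and correlations.

Co-localization is the asymmetric conditional statistic: the percentage of
cells detecting gene *y* (the conditioning gene) that also detect gene *x*.
Correlation matrices, by contrast, use the continuous expression values,
not the boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_core import PrevalenceTable


@dataclass
class ColocMatrix:
    """Conditioning gene (row) x co-detected gene (column), in percent.

    Rows whose conditioning gene is detected in zero cells are all-NaN.
    The diagonal is 100 for every gene with at least one detected cell.
    """

    values: pd.DataFrame
    n_conditioning: pd.Series  # detected-cell count per row gene


def coloc_matrix(mask: pd.DataFrame, genes: Sequence[str] | None = None) -> ColocMatrix:
    """entry[y, x] = 100 * |cells detecting x and y| / |cells detecting y|."""
    genes = list(genes) if genes is not None else list(mask.columns)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    m = mask[genes].to_numpy(dtype=bool)
    joint = m.T.astype(np.int64) @ m.astype(np.int64)  # |x and y| symmetric
    n_y = m.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(n_y[:, None] > 0, 100.0 * joint / n_y[:, None], np.nan)
    values = pd.DataFrame(pct, index=genes, columns=genes)
    return ColocMatrix(values=values, n_conditioning=pd.Series(n_y, index=genes))


def n_receptors_distribution(mask: pd.DataFrame) -> pd.DataFrame:
    """Distribution of per-cell detected-gene counts on two explicit bases.

    Indexed by k = 0..n_genes with columns ``pct_of_all_cells`` (sums to
    100 over all k) and ``pct_of_positive_cells`` (k >= 1 only, sums to 100
    over k >= 1; NaN at k = 0).
    """
    counts = mask.sum(axis=1).to_numpy()
    n_genes = mask.shape[1]
    ks = np.arange(n_genes + 1)
    freq = np.bincount(counts, minlength=n_genes + 1).astype(float)
    pct_all = 100.0 * freq / len(mask) if len(mask) else freq * np.nan
    n_pos = freq[1:].sum()
    pct_pos = np.full(n_genes + 1, np.nan)
    if n_pos > 0:
        pct_pos[1:] = 100.0 * freq[1:] / n_pos
    return pd.DataFrame(
        {"pct_of_all_cells": pct_all, "pct_of_positive_cells": pct_pos},
        index=pd.Index(ks, name="n_detected"),
    )


def at_least_k_other(mask: pd.DataFrame, gene: str, k: int = 1) -> float:
    """Among cells detecting ``gene``, percent also detecting >= k others."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if gene not in mask.columns:
        raise KeyError(f"unknown gene: {gene!r}")
    pos = mask[mask[gene]]
    if len(pos) == 0:
        return float("nan")
    others = pos.drop(columns=[gene]).sum(axis=1)
    return float((others >= k).mean() * 100.0)


def correlation_matrix(
    expr: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    subset: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of continuous expression values per gene pair.

    ``subset=(column, value)`` restricts to cells whose metadata column
    equals ``value`` (e.g. one neighborhood).  Constant genes yield NaN.
    """
    if subset is not None:
        if cells is None:
            raise ValueError("subset filtering requires the cell table")
        col, value = subset
        keep = cells.loc[cells[col] == value, "cell_label"]
        expr = expr.loc[expr.index.intersection(keep)]
    if len(expr) < 2:
        raise ValueError("need at least 2 cells after filtering")
    return expr.corr(method="pearson")


def group_profile_correlation(prev: PrevalenceTable):
    """Pearson r between per-group prevalence profiles.

    Returns ``(rmat, per_group_mean, per_group_sem, overall_mean)``:
    the group x group correlation matrix of prevalence profiles across the
    gene axis; per group, the mean r against all other groups with its
    standard error of the mean (the +/- convention); and the overall mean r
    over unordered group pairs.
    """
    if len(prev.values) < 2:
        raise ValueError("need at least 2 groups")
    rmat = prev.values.T.corr(method="pearson")
    off = rmat.where(~np.eye(len(rmat), dtype=bool))
    per_group_mean = off.mean(axis=1)
    n_other = off.notna().sum(axis=1)
    per_group_sem = off.std(axis=1, ddof=1) / np.sqrt(n_other)
    iu = np.triu_indices(len(rmat), k=1)
    overall_mean = float(np.nanmean(rmat.to_numpy()[iu]))
    return rmat, per_group_mean, per_group_sem, overall_mean
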