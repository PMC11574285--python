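"""Detection thresholding and prevalence / amount statistics by group.

Prevalence — the percentage of cells in a group whose expression of a gene
clears the detection threshold — is the pipeline's central statistic.  The
scRNA-seq threshold operates on log(CPM) values (default 3.5, strict >);
the spatial threshold (default 0.3) applies to panel expression values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Thresholds:
    """Detection and enrichment thresholds.

    ``strict_detection``: detection uses strict ``>`` (the boundary value is
    NOT detected).  ``strict_enrichment``: whether the enrichment comparison
    is strict ``>`` rather than the default inclusive ``>=``.
    """

    detection_scrna: float = 3.5
    detection_spatial: float = 0.3
    enrichment_fraction: float = 70.0
    strict_detection: bool = True
    strict_enrichment: bool = False

    def __post_init__(self):
        if not np.isfinite([self.detection_scrna, self.detection_spatial]).all():
            raise ValueError("detection thresholds must be finite")
        if not 0 < self.enrichment_fraction <= 100:
            raise ValueError("enrichment_fraction must lie in (0, 100]")

    def detection(self, which: str) -> float:
        if which == "scrna":
            return self.detection_scrna
        if which == "spatial":
            return self.detection_spatial
        raise ValueError(f"unknown dataset kind: {which!r}")


@dataclass
class PrevalenceTable:
    """Group x gene percent-detected values for one grouping level."""

    values: pd.DataFrame  # group x gene, percent in [0, 100]
    group_level: str
    n_per_group: pd.Series

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.values.rename_axis(self.group_level)
            .reset_index()
            .melt(id_vars=self.group_level, var_name="gene", value_name="prevalence")
        )
        tidy["n"] = tidy[self.group_level].map(self.n_per_group).astype(int)
        return tidy


def detect(expr: pd.DataFrame, thresholds: Thresholds = Thresholds(),
           which: str = "scrna") -> pd.DataFrame:
    """Boolean detection mask: ``expr > threshold`` (strict by default)."""
    t = thresholds.detection(which)
    mask = expr > t if thresholds.strict_detection else expr >= t
    mask.attrs["threshold"] = t
    mask.attrs["which"] = which
    return mask


def _align_labels(mask: pd.DataFrame, cells: pd.DataFrame, level: str) -> pd.Series:
    if level not in cells.columns:
        raise KeyError(f"unknown grouping level: {level!r}")
    labels = cells.set_index("cell_label")[level]
    missing = mask.index.difference(labels.index)
    if len(missing):
        raise KeyError(f"{len(missing)} mask rows have no metadata row")
    return labels.reindex(mask.index)


def prevalence_by_group(mask: pd.DataFrame, cells: pd.DataFrame,
                        level: str) -> PrevalenceTable:
    """Percent of cells detected, per group at ``level`` and per gene.

    Groups with zero cells are omitted (the ratio is undefined).
    """
    labels = _align_labels(mask, cells, level)
    grouped = mask.groupby(labels, observed=True)
    n = grouped.size()
    # exactly 100 * count / n (not mean * 100): the count is integral
    values = (100.0 * grouped.sum()).div(n, axis=0)
    return PrevalenceTable(values=values, group_level=level, n_per_group=n)


def prevalence_any(mask: pd.DataFrame, gene_set: Sequence[str]) -> float:
    """Percent of cells detecting at least one gene in ``gene_set``."""
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    return float(100.0 * int(mask[genes].any(axis=1).sum()) / len(mask))


def mean_amount_by_group(
    expr: pd.DataFrame,
    mask: pd.DataFrame,
    cells: pd.DataFrame,
    level: str,
    detected_only: bool = True,
) -> pd.DataFrame:
    """Per-group x gene mean expression, optionally over detected cells only.

    With ``detected_only`` a group with no detected cells for a gene is
    reported as missing (NaN).
    """
    labels = _align_labels(expr, cells, level)
    if detected_only:
        masked = expr.where(mask)
        return masked.groupby(labels, observed=True).mean()
    return expr.groupby(labels, observed=True).mean()


def prevalence_amount_r2(expr: pd.DataFrame, mask: pd.DataFrame) -> float:
    """Squared Pearson r between per-gene prevalence and mean detected amount.

    Measures how much of the across-gene variation in within-cell expression
    is shared with the variation in how widespread each gene is.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    prevalence = mask.mean(axis=0) * 100.0
    amount = expr.where(mask).mean(axis=0)
    valid = amount.notna()
    r = np.corrcoef(prevalence[valid], amount[valid])[0, 1]
    return float(r ** 2)


def top_groups_by_count(
    mask: pd.DataFrame,
    cells: pd.DataFrame,
    gene: str,
    level: str,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k groups by absolute number of cells detecting ``gene``.

    Ranked by count descending; ties broken lexicographically by group name.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if gene not in mask.columns:
        raise KeyError(f"unknown gene: {gene!r}")
    labels = _align_labels(mask, cells, level)
    counts = mask[gene].groupby(labels, observed=True).sum().astype(int)
    ranked = counts.sort_index().sort_values(ascending=False, kind="stable")
    out = ranked.head(k).rename("count").rename_axis(level).reset_index()
    return out
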