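"""Cross-modal mapping of expression-enriched clusters into space.

The bridge between modalities is the shared cluster vocabulary: clusters in
which at least the enrichment fraction (default 70%) of scRNA-seq cells
detect a gene are "enriched"; spatial cells belonging to those clusters
stand in for the gene's spatial distribution, which works even for genes
absent from the spatial panel.  A direct mode instead thresholds the
spatial panel expression itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .expression_core import PrevalenceTable, Thresholds, prevalence_by_group


@dataclass
class EnrichedClusterSet:
    """Per-gene set of clusters clearing the enrichment threshold.

    ``enriched_fraction`` is the percent of all gene-detecting scRNA-seq
    cells that belong to the retained clusters (the pie-chart inset
    statistic).
    """

    gene: str
    clusters: set[str]
    in_cluster_prevalence: pd.Series  # retained clusters only, percent
    enriched_fraction: float


@dataclass
class SectionProfile:
    """Per-section prevalence (and mean detected amount) along the AP axis."""

    table: pd.DataFrame  # index: section_label ordered by AP; columns below
    # columns: ap_center, prevalence, mean_amount (NaN when unavailable), n_cells

    @property
    def sections(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ConcordanceFit:
    slope: float
    intercept: float
    r_squared: float
    n_groups: int


def find_enriched_clusters(
    mask: pd.DataFrame,
    cells: pd.DataFrame,
    gene: str,
    thresholds: Thresholds = Thresholds(),
) -> EnrichedClusterSet:
    """Clusters whose in-cluster prevalence of ``gene`` clears the threshold.

    The comparison is inclusive (>=) by default; ``thresholds.strict_enrichment``
    switches to strict >.
    """
    if gene not in mask.columns:
        raise KeyError(f"unknown gene: {gene!r}")
    prev = prevalence_by_group(mask[[gene]], cells, "cluster")
    per_cluster = prev.values[gene]
    if thresholds.strict_enrichment:
        retained = per_cluster[per_cluster > thresholds.enrichment_fraction]
    else:
        retained = per_cluster[per_cluster >= thresholds.enrichment_fraction]
    labels = cells.set_index("cell_label")["cluster"].reindex(mask.index)
    detecting = mask[gene].to_numpy(dtype=bool)
    n_detecting = int(detecting.sum())
    if n_detecting:
        in_retained = labels.isin(retained.index).to_numpy() & detecting
        fraction = 100.0 * in_retained.sum() / n_detecting
    else:
        fraction = 0.0
    return EnrichedClusterSet(
        gene=gene,
        clusters=set(retained.index),
        in_cluster_prevalence=retained,
        enriched_fraction=float(fraction),
    )


def cross_reference(enriched: EnrichedClusterSet, spatial: pd.DataFrame) -> pd.DataFrame:
    """Spatial cells whose cluster label is in the enriched set.

    Works whether or not the gene is on the spatial panel — that is the
    point of the method.
    """
    return spatial[spatial["cluster"].isin(enriched.clusters)]


def prevalence_by_parcellation(
    spatial: pd.DataFrame,
    level: str = "division",
    mode: str = "crossref",
    subset: pd.DataFrame | None = None,
    gene: str | None = None,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Percent of cells per brain region, ranked descending.

    ``crossref`` mode counts cells of ``subset`` (enriched-cluster cells);
    ``direct`` mode counts cells whose spatial expression of ``gene``
    clears the spatial detection threshold.  Both normalize by the total
    cell count of each region.
    """
    if level not in ("division", "structure"):
        raise KeyError(f"unknown parcellation level: {level!r}")
    if mode == "crossref":
        if subset is None:
            raise ValueError("crossref mode requires the enriched-cluster subset")
        hit = spatial["cell_label"].isin(subset["cell_label"]).to_numpy()
    elif mode == "direct":
        if gene is None:
            raise ValueError("direct mode requires a gene")
        if gene not in spatial.columns:
            raise KeyError(f"gene {gene!r} is not on the spatial panel")
        t = thresholds.detection("spatial")
        values = spatial[gene].to_numpy(dtype=float)
        hit = values > t if thresholds.strict_detection else values >= t
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    df = pd.DataFrame({level: spatial[level].to_numpy(), "hit": hit})
    agg = df.groupby(level, observed=True)["hit"].agg(n_hits="sum", n_cells="size")
    agg["prevalence"] = 100.0 * agg["n_hits"] / agg["n_cells"]
    agg = agg.sort_index().sort_values("prevalence", ascending=False, kind="stable")
    return agg.reset_index()[[level, "prevalence", "n_hits", "n_cells"]]


def class_concordance(
    prev_scrna: PrevalenceTable,
    prev_spatial: PrevalenceTable,
    gene: str,
) -> ConcordanceFit:
    """OLS regression of spatial on scRNA-seq per-group prevalence.

    Fit over groups shared by the two tables; returns slope, intercept and
    the squared Pearson correlation.
    """
    a = prev_scrna.values[gene]
    b = prev_spatial.values[gene]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared groups")
    fit = _stats.linregress(a[shared].to_numpy(), b[shared].to_numpy())
    return ConcordanceFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_groups=len(shared),
    )


def ap_profile(
    spatial: pd.DataFrame,
    subset: pd.DataFrame,
    gene: str | None = None,
    thresholds: Thresholds = Thresholds(),
) -> SectionProfile:
    """Per-section prevalence of subset membership along the AP axis.

    Sections are ordered by their mean AP coordinate; sections with zero
    cells do not occur (sections are defined by the cells present).  When
    ``gene`` is on the spatial panel, the mean detected amount among subset
    cells is reported per section; otherwise the column is NaN.
    """
    in_subset = spatial["cell_label"].isin(subset["cell_label"]).to_numpy()
    df = pd.DataFrame(
        {
            "section_label": spatial["section_label"].to_numpy(),
            "ap": spatial["ap_coordinate"].to_numpy(dtype=float),
            "hit": in_subset,
        }
    )
    if gene is not None and gene in spatial.columns:
        t = thresholds.detection("spatial")
        values = spatial[gene].to_numpy(dtype=float)
        detected = values > t if thresholds.strict_detection else values >= t
        df["amount"] = np.where(in_subset & detected, values, np.nan)
    else:
        df["amount"] = np.nan
    agg = df.groupby("section_label", observed=True).agg(
        ap_center=("ap", "mean"),
        prevalence=("hit", lambda h: 100.0 * int(h.sum()) / len(h)),
        mean_amount=("amount", "mean"),
        n_cells=("hit", "size"),
    )
    agg = agg.sort_values("ap_center", kind="stable")
    return SectionProfile(table=agg)


def select_top_sections(
    profile: SectionProfile,
    k: int = 4,
    min_spacing: float | None = None,
) -> tuple[list[str], bool]:
    """Top-k sections by prevalence among adequately spaced local peaks.

    A section is a peak when its prevalence is >= both neighbors (profile
    ends compare against their single neighbor).  Peaks are taken greedily
    by prevalence (ties toward the more anterior section), keeping only
    peaks at AP distance >= ``min_spacing`` (default: 10% of the profile's
    AP range) from every already-selected one.  If fewer than k peaks
    survive, the highest remaining sections respecting the spacing rule
    fill the list and the returned flag is True.
    """
    tab = profile.table
    if len(tab) == 0:
        raise ValueError("profile is empty")
    prevalence = tab["prevalence"].to_numpy(dtype=float)
    ap = tab["ap_center"].to_numpy(dtype=float)
    names = list(tab.index)
    n = len(names)
    if min_spacing is None:
        span = float(ap.max() - ap.min())
        min_spacing = 0.1 * span

    is_peak = np.ones(n, dtype=bool)
    for i in range(n):
        if i > 0 and prevalence[i] < prevalence[i - 1]:
            is_peak[i] = False
        if i < n - 1 and prevalence[i] < prevalence[i + 1]:
            is_peak[i] = False

    def greedy(candidates: list[int], chosen: list[int]) -> list[int]:
        ordered = sorted(candidates, key=lambda i: (-prevalence[i], ap[i]))
        for i in ordered:
            if len(chosen) >= k:
                break
            if all(abs(ap[i] - ap[j]) >= min_spacing for j in chosen):
                chosen.append(i)
        return chosen

    chosen = greedy([i for i in range(n) if is_peak[i]], [])
    filled = False
    if len(chosen) < k:
        remaining = [i for i in range(n) if i not in chosen]
        before = len(chosen)
        chosen = greedy(remaining, chosen)
        filled = len(chosen) > before
    return [names[i] for i in chosen], filled
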