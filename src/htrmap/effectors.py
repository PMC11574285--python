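"""Aggregate receptor expression into effector families per cell.

The 14 receptor genes fall into four groups by main intracellular effector:
Htr1/5 (Gi-coupled, cAMP decrease), Htr2 (Gq-coupled, Ca2+ increase),
Htr4/6/7 (Gs-coupled, cAMP increase), and the ionotropic Htr3.  Summing raw
expression within each family and taking the argmax assigns each cell its
primary 5-HT pathway.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILY_ORDER: tuple[str, ...] = ("Htr1/5", "Htr2", "Htr4/6/7", "Htr3")
UNASSIGNED = "unassigned"

DEFAULT_FAMILY_MAP: dict[str, tuple[str, ...]] = {
    "Htr1/5": ("Htr1a", "Htr1b", "Htr1d", "Htr1f", "Htr5a", "Htr5b"),
    "Htr2": ("Htr2a", "Htr2b", "Htr2c"),
    "Htr4/6/7": ("Htr4", "Htr6", "Htr7"),
    "Htr3": ("Htr3a", "Htr3b"),
}


def validate_family_map(fmap: Mapping[str, Sequence[str]], genes: Sequence[str]) -> None:
    """Families must be disjoint and their union must cover ``genes``."""
    seen: set[str] = set()
    for fam, members in fmap.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"gene(s) in multiple families: {sorted(overlap)}")
        seen |= set(members)
    uncovered = set(genes) - seen
    if uncovered:
        raise ValueError(f"gene(s) not covered by any family: {sorted(uncovered)}")


def family_sums(expr: pd.DataFrame, fmap: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Per-cell sum of raw expression within each family (no thresholding)."""
    fmap = DEFAULT_FAMILY_MAP if fmap is None else fmap
    validate_family_map(fmap, expr.columns)
    order = [f for f in FAMILY_ORDER if f in fmap] + [f for f in fmap if f not in FAMILY_ORDER]
    out = pd.DataFrame(index=expr.index)
    for fam in order:
        members = [g for g in fmap[fam] if g in expr.columns]
        out[fam] = expr[members].sum(axis=1) if members else 0.0
    return out


def primary_family(sums: pd.DataFrame) -> pd.Series:
    """Argmax family per cell; all-zero cells are labeled ``unassigned``.

    Exact ties break toward the earlier column (the fixed family order);
    the number of ties is logged.
    """
    values = sums.to_numpy(dtype=float)
    top = values.max(axis=1)
    arg = values.argmax(axis=1)  # first max wins: fixed-order tie-break
    labels = pd.Series(np.asarray(sums.columns)[arg], index=sums.index, name="primary_family")
    labels[top <= 0] = UNASSIGNED
    n_tied = int(((values == top[:, None]).sum(axis=1) > 1)[top > 0].sum())
    if n_tied:
        logger.info("primary_family: %d exact ties broken by family order", n_tied)
    return labels


def family_composition(
    labels: pd.Series, cells: pd.DataFrame, level: str
) -> pd.DataFrame:
    """Per-group family counts and fractions (tidy: group, family, count,
    count_thousands, fraction).  Fractions sum to 1 within each group,
    including the unassigned label."""
    if level not in cells.columns:
        raise KeyError(f"unknown grouping level: {level!r}")
    groups = cells.set_index("cell_label")[level].reindex(labels.index)
    df = pd.DataFrame({"family": labels.to_numpy(), level: groups.to_numpy()})
    counts = df.groupby([level, "family"], observed=True).size().rename("count").reset_index()
    totals = counts.groupby(level, observed=True)["count"].transform("sum")
    counts["count_thousands"] = counts["count"] / 1000.0
    counts["fraction"] = counts["count"] / totals
    return counts
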