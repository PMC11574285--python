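"""Synthetic paired scRNA-seq / spatial datasets with planted ground truth.

The generator emulates the joint structure of the two source data modalities
the pipeline targets: a single-cell expression table whose cells carry a
4-level nested taxonomy (class > subclass > supertype > cluster) plus
neighborhood and neurotransmitter annotations, and a MERFISH-like spatial
table whose cells share the same cluster vocabulary but measure only a gene
panel subset and additionally carry section and parcellation labels.

The planted signal is a Bernoulli detection model: each (cluster, gene) pair
has a detection probability; a detected value is drawn from a normal
distribution truncated strictly above the detection threshold, an undetected
value is 0.  Thresholding the generated matrix therefore recovers the planted
Bernoulli draws exactly, which makes every downstream statistic checkable
against closed-form expectations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# The 14 serotonin-receptor genes in the default family, in panel order.
HTR_GENES: tuple[str, ...] = (
    "Htr1a", "Htr1b", "Htr1d", "Htr1f",
    "Htr2a", "Htr2b", "Htr2c",
    "Htr3a", "Htr3b",
    "Htr4", "Htr5a", "Htr5b", "Htr6", "Htr7",
)

# The 9 genes carried by the spatial gene panel; Htr2b, Htr3b, Htr5a, Htr5b
# and Htr6 are absent from the panel, which is exactly the situation the
# cross-referencing step exists to work around.
PANEL_GENES: tuple[str, ...] = (
    "Htr1a", "Htr1b", "Htr1d", "Htr1f",
    "Htr2a", "Htr2c", "Htr3a", "Htr4", "Htr7",
)

DEFAULT_NEIGHBORHOODS: tuple[str, ...] = (
    "Pallium-Glut",
    "Subpallium-GABA",
    "MB-HB-Glut-Sero-Dopa",
    "NN-IMN-GC",
)

DEFAULT_NEUROTRANSMITTERS: tuple[str, ...] = (
    "Glut", "GABA", "None", "Sero", "Chol", "Dopa",
)


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class TaxonomyShape:
    """Counts per nested taxonomy level.

    The total cluster count is the product of the four fields; every cluster
    maps to exactly one supertype, subclass and class by integer division.
    """

    n_class: int
    n_subclass_per_class: int
    n_supertype_per_subclass: int
    n_cluster_per_supertype: int

    @property
    def n_subclass(self) -> int:
        return self.n_class * self.n_subclass_per_class

    @property
    def n_supertype(self) -> int:
        return self.n_subclass * self.n_supertype_per_subclass

    @property
    def n_cluster(self) -> int:
        return self.n_supertype * self.n_cluster_per_supertype

    def validate(self) -> None:
        for name in dataclasses.fields(self):
            v = getattr(self, name.name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(
                    f"taxonomy_shape.{name.name} must be a positive integer, got {v!r}"
                )


@dataclass
class SyntheticConfig:
    """Full specification of a paired synthetic dataset.

    ``detection_prob`` is the planted cluster x gene matrix of Bernoulli
    detection probabilities; it is the single source of truth for every
    recoverable quantity.  ``amount_mean``/``amount_sd`` parameterize the
    per-gene normal from which detected log-expression amounts are drawn
    (truncated strictly above the detection threshold).
    """

    n_cells_scrna: int
    n_cells_spatial: int
    taxonomy_shape: TaxonomyShape
    genes: tuple[str, ...]
    panel_genes: tuple[str, ...]
    detection_prob: np.ndarray  # (n_cluster, n_genes)
    amount_mean: np.ndarray  # per gene, scRNA-seq log(CPM) scale
    amount_sd: np.ndarray
    spatial_amount_mean: np.ndarray  # per panel gene, spatial scale
    spatial_amount_sd: np.ndarray
    neighborhood_map: Mapping[str, str]
    neurotransmitter_map: Mapping[str, str]
    n_sections: int = 20
    section_axis_range: tuple[float, float] = (0.0, 10.0)
    plane_range: tuple[float, float] = (0.0, 10.0)
    n_divisions: int = 5
    n_structures_per_division: int = 4
    detection_threshold_scrna: float = 3.5
    detection_threshold_spatial: float = 0.3
    spatial_prevalence_scale: float = 1.0
    cluster_weights: np.ndarray | None = None
    seed: int = 0

    # -- label vocabularies ------------------------------------------------
    def cluster_labels(self) -> list[str]:
        return [f"cluster_{i:04d}" for i in range(self.taxonomy_shape.n_cluster)]

    def class_labels(self) -> list[str]:
        return [f"class_{i:02d}" for i in range(self.taxonomy_shape.n_class)]

    def validate(self) -> None:
        shape = self.taxonomy_shape
        shape.validate()
        if self.n_cells_scrna < 1 or self.n_cells_spatial < 1:
            raise ConfigurationError("cell counts must be positive")
        if not set(self.panel_genes) <= set(self.genes):
            raise ConfigurationError("panel_genes must be a subset of genes")
        if len(self.panel_genes) == 0:
            raise ConfigurationError("panel_genes must be non-empty")
        p = np.asarray(self.detection_prob, dtype=float)
        if p.shape != (shape.n_cluster, len(self.genes)):
            raise ConfigurationError(
                f"detection_prob shape {p.shape} does not match "
                f"({shape.n_cluster}, {len(self.genes)})"
            )
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ConfigurationError("detection probabilities must lie in [0, 1]")
        if not 0 < self.spatial_prevalence_scale <= 1:
            raise ConfigurationError("spatial_prevalence_scale must lie in (0, 1]")
        if self.n_sections < 1:
            raise ConfigurationError("n_sections must be positive")
        lo, hi = self.section_axis_range
        if not lo < hi:
            raise ConfigurationError("section_axis_range must be a proper interval")
        if self.cluster_weights is not None:
            w = np.asarray(self.cluster_weights, dtype=float)
            if w.shape != (shape.n_cluster,) or np.any(w < 0) or w.sum() <= 0:
                raise ConfigurationError("cluster_weights must be non-negative per cluster")

    # -- derived taxonomy --------------------------------------------------
    def taxonomy_frame(self) -> pd.DataFrame:
        """One row per cluster with its supertype/subclass/class labels."""
        shape = self.taxonomy_shape
        idx = np.arange(shape.n_cluster)
        supertype = idx // shape.n_cluster_per_supertype
        subclass = supertype // shape.n_supertype_per_subclass
        klass = subclass // shape.n_subclass_per_class
        return pd.DataFrame(
            {
                "cluster": self.cluster_labels(),
                "supertype": [f"supertype_{i:03d}" for i in supertype],
                "subclass": [f"subclass_{i:03d}" for i in subclass],
                "class": [f"class_{i:02d}" for i in klass],
            }
        )


@dataclass
class GroundTruth:
    """Planted quantities downstream stages must recover.

    ``planted_prevalence`` is the detection probability expressed in percent;
    ``planted_enriched`` lists, per gene, the clusters whose planted
    probability clears the enrichment threshold; ``planted_group_profiles``
    gives the expected per-class detection-probability profile used by the
    decoding tests.
    """

    planted_prevalence: pd.DataFrame  # cluster x gene, percent
    planted_enriched: dict[str, set[str]]
    planted_group_profiles: pd.DataFrame  # class x gene, probability
    enrichment_fraction: float


def _rng(seed: int, stream: int) -> np.random.Generator:
    # All sub-draws derive from the single root seed through fixed streams.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale default configuration: 10 classes / 40 clusters.

    Per-gene base prevalences are spread log-uniformly over roughly
    0.5%..50% to emulate the wide dynamic range seen across a receptor
    family, and per-cluster logit noise (sd 1.5) creates both depleted and
    enriched clusters for the more prevalent genes.
    """
    shape = overrides.pop(
        "taxonomy_shape",
        TaxonomyShape(
            n_class=10,
            n_subclass_per_class=2,
            n_supertype_per_subclass=1,
            n_cluster_per_supertype=2,
        ),
    )
    genes = tuple(overrides.pop("genes", HTR_GENES))
    panel = tuple(overrides.pop("panel_genes", tuple(g for g in PANEL_GENES if g in genes)))
    rng = _rng(seed, 0)
    # per-gene base prevalences span roughly 0.1%..35%, the dynamic
    # range observed across the receptor family in whole-brain data
    base = np.exp(np.linspace(np.log(0.001), np.log(0.35), num=len(genes)))
    base = rng.permutation(base)
    if "detection_prob" in overrides:
        detection_prob = np.asarray(overrides.pop("detection_prob"), dtype=float)
    else:
        logit = np.log(base / (1 - base))
        noise = rng.normal(0.0, 1.5, size=(shape.n_cluster, len(genes)))
        detection_prob = 1.0 / (1.0 + np.exp(-(logit[None, :] + noise)))
    # widespread genes also run hotter within cells: detected-amount means
    # rise with base prevalence, plus gene-level scatter
    default_amount_mean = 4.0 + 4.0 * base + rng.normal(0.0, 0.4, size=len(genes))

    classes = [f"class_{i:02d}" for i in range(shape.n_class)]
    nb_map = overrides.pop(
        "neighborhood_map",
        {
            c: DEFAULT_NEIGHBORHOODS[i * len(DEFAULT_NEIGHBORHOODS) // shape.n_class]
            for i, c in enumerate(classes)
        },
    )
    clusters = [f"cluster_{i:04d}" for i in range(shape.n_cluster)]
    if "neurotransmitter_map" in overrides:
        nt_map = overrides.pop("neurotransmitter_map")
    else:
        # roughly: half Glut, a fifth GABA, a quarter None, the rest rare
        cuts = np.cumsum([0.50, 0.20, 0.25, 0.02, 0.02, 0.01])
        pos = (np.arange(shape.n_cluster) + 0.5) / shape.n_cluster
        nt_idx = np.searchsorted(cuts, pos)
        nt_idx = np.clip(nt_idx, 0, len(DEFAULT_NEUROTRANSMITTERS) - 1)
        nt_map = {c: DEFAULT_NEUROTRANSMITTERS[i] for c, i in zip(clusters, nt_idx)}

    cfg = SyntheticConfig(
        n_cells_scrna=overrides.pop("n_cells_scrna", 20_000),
        n_cells_spatial=overrides.pop("n_cells_spatial", 20_000),
        taxonomy_shape=shape,
        genes=genes,
        panel_genes=panel,
        detection_prob=detection_prob,
        amount_mean=np.asarray(overrides.pop("amount_mean", default_amount_mean)),
        amount_sd=np.asarray(overrides.pop("amount_sd", np.full(len(genes), 1.0))),
        spatial_amount_mean=np.asarray(
            overrides.pop("spatial_amount_mean", np.full(len(panel), 1.5))
        ),
        spatial_amount_sd=np.asarray(
            overrides.pop("spatial_amount_sd", np.full(len(panel), 0.5))
        ),
        neighborhood_map=nb_map,
        neurotransmitter_map=nt_map,
        seed=seed,
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_taxonomy(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the per-cell metadata table (one row per cell).

    Cluster assignment is multinomial (uniform unless ``cluster_weights`` is
    set); the three coarser labels are a deterministic function of the
    cluster; neighborhood and neurotransmitter labels are attached through
    the configured maps.  Placeholder 2-D embedding coordinates are emitted.
    Pure function of ``config.seed``.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    shape = config.taxonomy_shape
    n = config.n_cells_scrna
    if config.cluster_weights is not None:
        w = np.asarray(config.cluster_weights, dtype=float)
        p = w / w.sum()
    else:
        p = np.full(shape.n_cluster, 1.0 / shape.n_cluster)
    cluster_idx = rng.choice(shape.n_cluster, size=n, p=p)
    tax = config.taxonomy_frame()
    cells = tax.iloc[cluster_idx].reset_index(drop=True)
    cells.insert(0, "cell_label", [f"cell_{i:07d}" for i in range(n)])
    cells["neighborhood"] = cells["class"].map(config.neighborhood_map)
    cells["neurotransmitter"] = cells["cluster"].map(config.neurotransmitter_map)
    emb = rng.normal(size=(n, 2))
    cells["embedding_x"] = emb[:, 0]
    cells["embedding_y"] = emb[:, 1]
    return cells


def _truncated_above(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    threshold: float,
    size: int,
) -> np.ndarray:
    """Draw values strictly above ``threshold`` from N(mean, sd)."""
    a = (threshold - mean) / sd
    draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
    # truncnorm includes the boundary with probability zero, but guard the
    # strict inequality against floating-point ties anyway
    return np.nextafter(draws, np.inf) if np.any(draws <= threshold) else draws


def generate_expression(cells: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Draw the cells x genes log(CPM)-scale expression matrix.

    Each (cell, gene) is detected with the planted probability of the cell's
    cluster; detected amounts come from the per-gene truncated normal
    strictly above ``detection_threshold_scrna``, undetected values are 0.
    Row order follows ``cells``.
    """
    config.validate()
    missing = set(cells["cluster"]) - set(config.cluster_labels())
    if missing:
        raise ConfigurationError(f"cells reference unknown clusters: {sorted(missing)[:3]}")
    rng = _rng(config.seed, 2)
    cluster_to_idx = {c: i for i, c in enumerate(config.cluster_labels())}
    cidx = cells["cluster"].map(cluster_to_idx).to_numpy()
    n, g = len(cells), len(config.genes)
    p = config.detection_prob[cidx, :]  # (n, g)
    detected = rng.random((n, g)) < p
    values = np.zeros((n, g))
    for j, gene in enumerate(config.genes):
        k = int(detected[:, j].sum())
        if k:
            values[detected[:, j], j] = _truncated_above(
                rng,
                float(config.amount_mean[j]),
                float(config.amount_sd[j]),
                config.detection_threshold_scrna,
                k,
            )
    return pd.DataFrame(values, index=pd.Index(cells["cell_label"], name="cell_label"),
                        columns=list(config.genes))


def generate_spatial(
    config: SyntheticConfig,
    prevalence_scale: float | None = None,
) -> pd.DataFrame:
    """Draw the MERFISH-like spatial cell table.

    Cells use the same cluster-label machinery as the scRNA-seq side; the
    anteroposterior coordinate is discretized into ordered section labels; a
    deterministic grid over the section-plane coordinates assigns the
    (division, structure) parcellation pair; expression is emitted only for
    the panel genes.  ``prevalence_scale`` (default: the configured
    ``spatial_prevalence_scale``) multiplies every detection probability to
    emulate the systematic sensitivity offset between modalities.
    """
    config.validate()
    scale = config.spatial_prevalence_scale if prevalence_scale is None else prevalence_scale
    if not 0 < scale <= 1:
        raise ConfigurationError("prevalence_scale must lie in (0, 1]")
    rng = _rng(config.seed, 3)
    shape = config.taxonomy_shape
    n = config.n_cells_spatial
    if config.cluster_weights is not None:
        w = np.asarray(config.cluster_weights, dtype=float)
        p = w / w.sum()
    else:
        p = np.full(shape.n_cluster, 1.0 / shape.n_cluster)
    cluster_idx = rng.choice(shape.n_cluster, size=n, p=p)
    tax = config.taxonomy_frame()
    cells = tax.iloc[cluster_idx].reset_index(drop=True)
    cells.insert(0, "cell_label", [f"spatial_{i:07d}" for i in range(n)])

    lo, hi = config.section_axis_range
    ap = rng.uniform(lo, hi, size=n)
    plo, phi_ = config.plane_range
    x = rng.uniform(plo, phi_, size=n)
    y = rng.uniform(plo, phi_, size=n)
    cells["x"] = x
    cells["y"] = y
    cells["ap_coordinate"] = ap
    cells["section_label"] = section_labels_for(ap, config)
    div, struct = parcellate(x, y, config)
    cells["division"] = div
    cells["structure"] = struct

    panel_idx = [config.genes.index(g) for g in config.panel_genes]
    p_panel = np.clip(config.detection_prob[cluster_idx][:, panel_idx] * scale, 0.0, 1.0)
    detected = rng.random((n, len(panel_idx))) < p_panel
    values = np.zeros((n, len(panel_idx)))
    for j, gene in enumerate(config.panel_genes):
        k = int(detected[:, j].sum())
        if k:
            values[detected[:, j], j] = _truncated_above(
                rng,
                float(config.spatial_amount_mean[j]),
                float(config.spatial_amount_sd[j]),
                config.detection_threshold_spatial,
                k,
            )
    for j, gene in enumerate(config.panel_genes):
        cells[gene] = values[:, j]
    return cells


def section_labels_for(ap: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Deterministic section label from an anteroposterior coordinate."""
    lo, hi = config.section_axis_range
    bins = np.clip(
        ((np.asarray(ap) - lo) / (hi - lo) * config.n_sections).astype(int),
        0,
        config.n_sections - 1,
    )
    return np.array([f"sec_{b:02d}" for b in bins])


def parcellate(
    x: np.ndarray, y: np.ndarray, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic grid parcellation: division from x, structure from y.

    Structure labels embed their division, so every structure maps to
    exactly one division by construction.
    """
    lo, hi = config.plane_range
    dbin = np.clip(
        ((np.asarray(x) - lo) / (hi - lo) * config.n_divisions).astype(int),
        0,
        config.n_divisions - 1,
    )
    sbin = np.clip(
        ((np.asarray(y) - lo) / (hi - lo) * config.n_structures_per_division).astype(int),
        0,
        config.n_structures_per_division - 1,
    )
    division = np.array([f"DIV{d}" for d in dbin])
    structure = np.array([f"DIV{d}-ST{s}" for d, s in zip(dbin, sbin)])
    return division, structure


def ground_truth(config: SyntheticConfig, enrichment_fraction: float = 70.0) -> GroundTruth:
    """Planted prevalence, enriched-cluster sets and class profiles."""
    config.validate()
    prev = pd.DataFrame(
        config.detection_prob * 100.0,
        index=pd.Index(config.cluster_labels(), name="cluster"),
        columns=list(config.genes),
    )
    enriched = {
        g: set(prev.index[prev[g] >= enrichment_fraction]) for g in config.genes
    }
    tax = config.taxonomy_frame()
    profiles = (
        pd.DataFrame(config.detection_prob, columns=list(config.genes))
        .assign(**{"class": tax["class"].to_numpy()})
        .groupby("class")
        .mean()
    )
    return GroundTruth(
        planted_prevalence=prev,
        planted_enriched=enriched,
        planted_group_profiles=profiles,
        enrichment_fraction=enrichment_fraction,
    )
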