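"""Enrichment, cross-referencing, parcellation, concordance, AP profiles."""

import numpy as np
import pandas as pd
import pytest

import htrmap as hm
from htrmap.synthetic import TaxonomyShape


def _planted_config(seed, probs_per_cluster, n_cells=800, **kw):
    n_clusters = len(probs_per_cluster)
    probs = np.zeros((n_clusters, 14))
    probs[:, 0] = probs_per_cluster
    return hm.default_config(
        seed=seed, n_cells_scrna=n_cells,
        taxonomy_shape=TaxonomyShape(n_clusters, 1, 1, 1),
        detection_prob=probs, **kw,
    )


def test_extreme_clusters_retained_and_excluded():
    cfg = _planted_config(41, [1.0, 0.0], n_cells=400)
    cells = hm.generate_taxonomy(cfg)
    mask = hm.detect(hm.generate_expression(cells, cfg))
    gene = cfg.genes[0]
    enriched = hm.find_enriched_clusters(mask, cells, gene)
    assert enriched.clusters == {"cluster_0000"}
    assert enriched.in_cluster_prevalence["cluster_0000"] == 100.0
    assert enriched.enriched_fraction > 95.0


def test_planted_probability_ladder_recovers_two_high_clusters():
    cfg = _planted_config(43, [0.9, 0.8, 0.5, 0.1], n_cells=800)
    cells = hm.generate_taxonomy(cfg)
    mask = hm.detect(hm.generate_expression(cells, cfg))
    enriched = hm.find_enriched_clusters(mask, cells, cfg.genes[0])
    assert enriched.clusters == {"cluster_0000", "cluster_0001"}


def test_unknown_gene_raises(small_mask, small_cells):
    with pytest.raises(KeyError):
        hm.find_enriched_clusters(small_mask, small_cells, "NotAGene")


def test_enrichment_threshold_monotone_shrinkage(small_mask, small_cells):
    gene = "Htr1f"
    previous = None
    for frac in (10.0, 30.0, 50.0, 70.0, 90.0, 100.0):
        t = hm.Thresholds(enrichment_fraction=frac)
        clusters = hm.find_enriched_clusters(small_mask, small_cells, gene, t).clusters
        if previous is not None:
            assert clusters <= previous
        previous = clusters


def test_inclusive_vs_strict_enrichment_boundary():
    cells = pd.DataFrame({
        "cell_label": [f"c{i}" for i in range(10)],
        "class": ["X"] * 10, "subclass": ["s"] * 10, "supertype": ["s"] * 10,
        "cluster": ["k"] * 10, "neighborhood": ["n"] * 10, "neurotransmitter": ["t"] * 10,
    })
    mask = pd.DataFrame({"g": [True] * 7 + [False] * 3},
                        index=pd.Index(cells["cell_label"], name="cell_label"))
    inclusive = hm.find_enriched_clusters(mask, cells, "g", hm.Thresholds())
    strict = hm.find_enriched_clusters(
        mask, cells, "g", hm.Thresholds(strict_enrichment=True))
    assert inclusive.clusters == {"k"}  # 70% >= 70%
    assert strict.clusters == set()  # 70% not > 70%


def test_cross_reference_subset_rules(small_mask, small_cells, small_spatial):
    empty = hm.EnrichedClusterSet("g", set(), pd.Series(dtype=float), 0.0)
    assert len(hm.cross_reference(empty, small_spatial)) == 0
    everything = hm.EnrichedClusterSet(
        "g", set(small_spatial["cluster"]), pd.Series(dtype=float), 100.0)
    assert len(hm.cross_reference(everything, small_spatial)) == len(small_spatial)
    enriched = hm.find_enriched_clusters(small_mask, small_cells, "Htr1f")
    subset = hm.cross_reference(enriched, small_spatial)
    expected = small_spatial[small_spatial["cluster"].isin(enriched.clusters)]
    pd.testing.assert_frame_equal(subset, expected)


def test_crossref_works_for_off_panel_gene(small_config, small_mask, small_cells, small_spatial):
    off_panel = sorted(set(small_config.genes) - set(small_config.panel_genes))[0]
    enriched = hm.find_enriched_clusters(small_mask, small_cells, off_panel)
    subset = hm.cross_reference(enriched, small_spatial)
    table = hm.prevalence_by_parcellation(small_spatial, "division", "crossref", subset=subset)
    assert set(table.columns) == {"division", "prevalence", "n_hits", "n_cells"}


def test_parcellation_prevalence_extremes_and_oracle(small_spatial):
    # whole table as subset -> every region 100%
    table = hm.prevalence_by_parcellation(small_spatial, "division", "crossref",
                                          subset=small_spatial)
    assert (table["prevalence"] == 100.0).all()
    # empty subset -> 0 everywhere
    empty = small_spatial.iloc[:0]
    table = hm.prevalence_by_parcellation(small_spatial, "division", "crossref", subset=empty)
    assert (table["prevalence"] == 0.0).all()
    # brute-force per-region ratio
    subset = small_spatial.iloc[::3]
    got = hm.prevalence_by_parcellation(small_spatial, "structure", "crossref", subset=subset)
    got = got.set_index("structure")
    in_subset = set(subset["cell_label"])
    for region in got.index:
        members = small_spatial[small_spatial["structure"] == region]
        expected = 100.0 * members["cell_label"].isin(in_subset).sum() / len(members)
        assert got.loc[region, "prevalence"] == pytest.approx(expected)


def test_direct_mode_matches_threshold_counting(small_spatial, small_config):
    gene = small_config.panel_genes[0]
    t = hm.Thresholds()
    got = hm.prevalence_by_parcellation(small_spatial, "division", "direct", gene=gene,
                                        thresholds=t).set_index("division")
    for region in got.index:
        members = small_spatial[small_spatial["division"] == region]
        expected = 100.0 * (members[gene] > t.detection_spatial).sum() / len(members)
        assert got.loc[region, "prevalence"] == pytest.approx(expected)


def test_structure_aggregation_identity(small_spatial):
    # count-weighted mean of structure prevalences within a division equals
    # the division prevalence, exactly
    subset = small_spatial.iloc[::4]
    div = hm.prevalence_by_parcellation(small_spatial, "division", "crossref",
                                        subset=subset).set_index("division")
    struct = hm.prevalence_by_parcellation(small_spatial, "structure", "crossref",
                                           subset=subset).set_index("structure")
    s2d = small_spatial[["structure", "division"]].drop_duplicates().set_index("structure")["division"]
    struct["division"] = s2d.reindex(struct.index)
    for d, block in struct.groupby("division"):
        weighted = (block["prevalence"] * block["n_cells"]).sum() / block["n_cells"].sum()
        assert weighted == pytest.approx(div.loc[d, "prevalence"])


def test_crossref_and_direct_agree_on_deterministic_panel_gene():
    # probabilities 0/1: cells of enriched clusters are exactly the cells
    # detecting the gene, so both modes rank regions identically
    probs = np.zeros((4, 14))
    probs[:2, 0] = 1.0
    cfg = hm.default_config(seed=47, n_cells_scrna=2_000, n_cells_spatial=2_000,
                            taxonomy_shape=TaxonomyShape(4, 1, 1, 1),
                            detection_prob=probs)
    gene = cfg.panel_genes[0]
    assert gene == cfg.genes[0]
    cells = hm.generate_taxonomy(cfg)
    mask = hm.detect(hm.generate_expression(cells, cfg))
    spatial = hm.generate_spatial(cfg)
    enriched = hm.find_enriched_clusters(mask, cells, gene)
    subset = hm.cross_reference(enriched, spatial)
    a = hm.prevalence_by_parcellation(spatial, "structure", "crossref", subset=subset)
    b = hm.prevalence_by_parcellation(spatial, "structure", "direct", gene=gene)
    pd.testing.assert_frame_equal(a, b)


def test_class_concordance_exact_cases():
    values = pd.DataFrame({"g": [10.0, 20.0, 40.0, 80.0]}, index=list("ABCD"))
    n = pd.Series([5] * 4, index=list("ABCD"))
    prev_a = hm.PrevalenceTable(values, "class", n)
    fit = hm.class_concordance(prev_a, prev_a, "g")
    assert fit.slope == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)
    prev_half = hm.PrevalenceTable(values * 0.5, "class", n)
    fit = hm.class_concordance(prev_a, prev_half, "g")
    assert fit.slope == pytest.approx(0.5)
    assert fit.intercept == pytest.approx(0.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_ap_profile_shapes_and_oracle(small_spatial):
    # uniform subset density -> flat profile at 100%
    prof = hm.ap_profile(small_spatial, small_spatial)
    assert (prof.table["prevalence"] == 100.0).all()
    assert prof.table["ap_center"].is_monotonic_increasing
    # subset confined to one section -> single nonzero section
    sec = small_spatial["section_label"].iloc[0]
    only = small_spatial[small_spatial["section_label"] == sec]
    prof = hm.ap_profile(small_spatial, only)
    nonzero = prof.table[prof.table["prevalence"] > 0]
    assert list(nonzero.index) == [sec]
    # brute-force equality on a random subset
    subset = small_spatial.iloc[::5]
    prof = hm.ap_profile(small_spatial, subset)
    in_subset = set(subset["cell_label"])
    for s in prof.table.index:
        members = small_spatial[small_spatial["section_label"] == s]
        expected = 100.0 * members["cell_label"].isin(in_subset).sum() / len(members)
        assert prof.table.loc[s, "prevalence"] == pytest.approx(expected)


def _profile(prevalences, ap=None):
    n = len(prevalences)
    ap = list(range(n)) if ap is None else ap
    tab = pd.DataFrame(
        {"ap_center": ap, "prevalence": prevalences,
         "mean_amount": np.nan, "n_cells": 10},
        index=pd.Index([f"sec_{i:02d}" for i in range(n)], name="section_label"),
    )
    return hm.SectionProfile(table=tab)


class TestTopSections:
    def test_unimodal_profile_returns_the_mode(self):
        prof = _profile([1, 2, 5, 9, 4, 2, 1])
        top, filled = hm.select_top_sections(prof, k=1)
        assert top == ["sec_03"]
        assert not filled

    def test_equal_close_peaks_keep_only_one(self):
        prof = _profile([0, 8, 0, 8, 0], ap=[0, 1, 2, 3, 4])
        top, _ = hm.select_top_sections(prof, k=4, min_spacing=3.0)
        assert len([s for s in top if s in ("sec_01", "sec_03")]) == 1

    def test_fill_flag_when_fewer_peaks_than_k(self):
        prof = _profile([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])  # single peak at the end
        top, filled = hm.select_top_sections(prof, k=3, min_spacing=2.0)
        assert filled
        assert len(top) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_peak_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 20, size=15).round(2)
        prof = _profile(list(values))
        spacing = 2.5
        top, _ = hm.select_top_sections(prof, k=4, min_spacing=spacing)
        # oracle: enumerate local maxima, rank by height then AP, greedy spacing
        peaks = [i for i in range(15)
                 if (i == 0 or values[i] >= values[i - 1])
                 and (i == 14 or values[i] >= values[i + 1])]
        chosen = []
        for i in sorted(peaks, key=lambda i: (-values[i], i)):
            if len(chosen) == 4:
                break
            if all(abs(i - j) >= spacing for j in chosen):
                chosen.append(i)
        if len(chosen) < 4:
            for i in sorted(set(range(15)) - set(chosen), key=lambda i: (-values[i], i)):
                if len(chosen) == 4:
                    break
                if all(abs(i - j) >= spacing for j in chosen):
                    chosen.append(i)
        assert top == [f"sec_{i:02d}" for i in chosen]
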