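from __future__ import annotations

import filecmp
import json

import numpy as np
import pytest

from casscan.cassette_arch import SHORT_FAMILIES
from casscan.genome_io import gene_midpoint
from casscan.homology import find_family_hits
from casscan.pipeline import detect_panel
from casscan.synthetic_panel import (
    SyntheticPanelConfig,
    _pathotype_probs,
    panel_to_disk,
    read_panel,
    simulate_panel,
    simulate_tree,
    _serialize_tree,
)


def test_tree_cherry():
    tree = simulate_tree(2, seed=0)
    assert len(tree.leaf_nodes()) == 2


def test_tree_too_small():
    with pytest.raises(ValueError):
        simulate_tree(1, seed=0)


def test_tree_deterministic_per_seed():
    a = _serialize_tree(simulate_tree(30, seed=42))
    b = _serialize_tree(simulate_tree(30, seed=42))
    assert a == b


def test_tree_seeds_differ():
    newicks = {_serialize_tree(simulate_tree(50, seed=s)) for s in range(5)}
    assert len(newicks) == 5


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------

def test_config_rejects_bad_probabilities():
    with pytest.raises(ValueError):
        SyntheticPanelConfig(n_strains=5, switch_prob=1.5)
    with pytest.raises(ValueError):
        SyntheticPanelConfig(n_strains=1)
    with pytest.raises(ValueError):
        SyntheticPanelConfig(n_strains=5, target_odds_ratio=0)


def test_config_rejects_infeasible_pathotype():
    with pytest.raises(ValueError, match="infeasible pathotype"):
        SyntheticPanelConfig(n_strains=5, baseline_pathogenic=0.0)


def test_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("n_strains: 8\nseed: 3\ndivergence: 0.0\n")
    cfg = SyntheticPanelConfig.from_yaml(p)
    assert (cfg.n_strains, cfg.seed, cfg.divergence) == (8, 3, 0.0)


def test_target_or_one_means_equal_probabilities():
    cfg = SyntheticPanelConfig(n_strains=5, target_odds_ratio=1.0,
                               baseline_pathogenic=0.4)
    p_long, p_short = _pathotype_probs(cfg)
    assert p_short == pytest.approx(p_long) == pytest.approx(0.4)


def test_target_or_solves_odds_ratio():
    cfg = SyntheticPanelConfig(n_strains=5, target_odds_ratio=2.67,
                               baseline_pathogenic=0.5)
    p_long, p_short = _pathotype_probs(cfg)
    odds = (p_short / (1 - p_short)) / (p_long / (1 - p_long))
    assert odds == pytest.approx(2.67)


# ---------------------------------------------------------------------------
# panel structure
# ---------------------------------------------------------------------------

def test_no_event_limit_all_long():
    cfg = SyntheticPanelConfig(n_strains=6, seed=2, divergence=0.0,
                               switch_prob=0.0, loss_prob=0.0)
    panel = simulate_panel(cfg)
    assert all(t["variant"] == "LONG" for t in panel.truth.values())
    rows = detect_panel(panel.genomes, panel.query_families, panel.uog_table)
    assert all(r["variant"] == "LONG" for r in rows)
    assert all(not r["inverted"] for r in rows)


def test_truth_covers_every_strain(default_panel):
    strains = {g.strain_id for g in default_panel.genomes}
    assert set(default_panel.truth) == strains
    assert set(default_panel.metadata) == strains


def test_cassette_sits_between_flanks(zero_div_panel):
    panel = zero_div_panel
    for genome in panel.genomes:
        truth = panel.truth[genome.strain_id]
        if truth["variant"] == "NONE":
            continue
        uog_map = panel.uog_table.for_strain(genome.strain_id)
        by_label = {uog_map[g.gene_id]: g for g in genome.genes
                    if g.gene_id in uog_map}
        fa, fb = truth["flanks"]
        span = truth["span"]
        assert by_label[fa].end < span[0]
        assert by_label[fb].start > span[1]
        # no other gene lies between the flanks and the cassette
        between = [g for g in genome.genes
                   if by_label[fa].end < g.start and g.end < by_label[fb].start]
        cassette_genes = [g for g in genome.genes
                          if span[0] <= g.start and g.end <= span[1]]
        assert between == cassette_genes


def test_adjacent_cassette_midpoint_gaps_below_5000(zero_div_panel):
    panel = zero_div_panel
    for genome in panel.genomes:
        truth = panel.truth[genome.strain_id]
        if truth["variant"] == "NONE":
            continue
        span = truth["span"]
        contig = genome.contigs[0]
        mids = sorted(
            gene_midpoint(g, contig) for g in genome.genes
            if span[0] <= g.start and g.end <= span[1]
        )
        assert all(b - a < 5000 for a, b in zip(mids, mids[1:]))


def test_short_strains_reversed_minus_strand(zero_div_panel):
    panel = zero_div_panel
    shorts = [s for s, t in panel.truth.items() if t["variant"] == "SHORT"]
    assert shorts
    for strain in shorts:
        genome = panel.genome(strain)
        span = panel.truth[strain]["span"]
        cassette_genes = [g for g in genome.genes
                          if span[0] <= g.start and g.end <= span[1]]
        assert len(cassette_genes) == 4
        assert all(g.strand == "-" for g in cassette_genes)
        assert [g.product for g in cassette_genes] == ["yihW", "yihV", "yihU", "yihT"]
        assert panel.truth[strain]["inverted"] is True


def test_short_without_inversion_config():
    cfg = SyntheticPanelConfig(n_strains=10, seed=7, divergence=0.0,
                               switch_prob=0.5, invert_short=False)
    panel = simulate_panel(cfg)
    shorts = [s for s, t in panel.truth.items() if t["variant"] == "SHORT"]
    assert shorts
    for strain in shorts:
        genome = panel.genome(strain)
        span = panel.truth[strain]["span"]
        genes = [g for g in genome.genes if span[0] <= g.start and g.end <= span[1]]
        assert all(g.strand == "+" for g in genes)
        assert {g.product for g in genes} == set(SHORT_FAMILIES)
        assert panel.truth[strain]["inverted"] is False


def test_uog_backbone_order_identical_across_strains(zero_div_panel):
    panel = zero_div_panel
    orders = []
    for genome in panel.genomes:
        uog_map = panel.uog_table.for_strain(genome.strain_id)
        orders.append([uog_map[g.gene_id] for g in genome.genes
                       if g.gene_id in uog_map])
    assert all(o == orders[0] for o in orders)


def test_divergence_keeps_planted_genes_above_threshold():
    cfg = SyntheticPanelConfig(n_strains=8, seed=13, divergence=0.2,
                               switch_prob=0.3)
    panel = simulate_panel(cfg)
    n_planted = n_hit = 0
    for genome in panel.genomes:
        truth = panel.truth[genome.strain_id]
        expected = 10 if truth["variant"] == "LONG" else 4
        hits = find_family_hits(panel.query_families, genome)
        n_planted += expected
        n_hit += len(hits)
    assert n_hit / n_planted >= 0.99


# ---------------------------------------------------------------------------
# determinism and disk round trip
# ---------------------------------------------------------------------------

def test_panel_byte_deterministic(tmp_path):
    cfg = SyntheticPanelConfig(n_strains=6, seed=21, divergence=0.1,
                               switch_prob=0.2, loss_prob=0.1)
    for d in ("p1", "p2"):
        panel_to_disk(simulate_panel(cfg), tmp_path / d)
    cmp = filecmp.dircmp(tmp_path / "p1", tmp_path / "p2")

    def assert_equal(dc):
        assert not dc.diff_files and not dc.left_only and not dc.right_only
        for sub in dc.subdirs.values():
            assert_equal(sub)

    assert_equal(cmp)


def test_disk_round_trip(default_panel, tmp_path):
    panel_to_disk(default_panel, tmp_path)
    back = read_panel(tmp_path)
    assert back.newick == default_panel.newick
    assert back.metadata == default_panel.metadata
    assert back.truth == default_panel.truth
    assert back.uog_table.entries == default_panel.uog_table.entries
    assert back.query_families.families == default_panel.query_families.families
    assert len(back.genomes) == len(default_panel.genomes)
    for a, b in zip(back.genomes, default_panel.genomes):
        assert a.strain_id == b.strain_id
        assert a.contigs == b.contigs
        assert a.genes == b.genes


def test_truth_json_counts_match_memory(default_panel, tmp_path):
    panel_to_disk(default_panel, tmp_path)
    doc = json.loads((tmp_path / "truth.json").read_text())
    on_disk = [t["variant"] for t in doc["strains"].values()]
    in_memory = [t["variant"] for t in default_panel.truth.values()]
    assert sorted(on_disk) == sorted(in_memory)


def test_file_inventory(tmp_path):
    cfg = SyntheticPanelConfig(n_strains=3, seed=1, divergence=0.0)
    panel_to_disk(simulate_panel(cfg), tmp_path)
    strains = sorted(p.name for p in (tmp_path / "strains").iterdir())
    assert len(strains) == 6  # 3 gff3 + 3 faa
    for name in ("uogs.tsv", "metadata.tsv", "tree.nwk", "truth.json",
                 "queries.faa", "config.json"):
        assert (tmp_path / name).exists()
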