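from __future__ import annotations

import numpy as np
import pytest

from casscan.cassette_arch import (
    CASSETTE_FAMILIES,
    CassetteMember,
    build_cassette,
    call_orientation,
    cassette_span,
    classify_variant,
    cluster_colocalized,
    flanking_uogs,
    scan_alternative_clusters,
)
from casscan.genome_io import UogTable
from casscan.homology import HomologyHit, QueryFamilySet
from conftest import make_genome, random_protein


def _hit(gene_id, family="yihT", strain="s"):
    return HomologyHit(family_id=family, strain_id=strain, gene_id=gene_id,
                       identity=100.0, coverage=100.0, score=100.0)


def _genome_with_midpoints(midpoints, circular=False, length=None, strain="s"):
    genes = [
        (f"g{i}", int(m) - 50, int(m) + 49, "+")
        for i, m in enumerate(midpoints)
    ]
    return make_genome(strain, genes, circular=circular, length=length)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def test_pair_within_gap_joins():
    genome = _genome_with_midpoints([1000, 5500])
    hits = [_hit("g0"), _hit("g1", "yihU")]
    clusters = cluster_colocalized(hits, genome)
    assert len(clusters) == 1  # 4500 < 5000 (midpoints 999.5/5499.5)


def test_pair_beyond_gap_splits():
    genome = _genome_with_midpoints([1000, 7000])
    clusters = cluster_colocalized([_hit("g0"), _hit("g1", "yihU")], genome)
    assert len(clusters) == 2


def test_single_linkage_chains():
    genome = _genome_with_midpoints([500, 4500, 8500])
    hits = [_hit("g0"), _hit("g1", "yihU"), _hit("g2", "yihV")]
    assert len(cluster_colocalized(hits, genome)) == 1


def test_exactly_5000_is_not_colocalized():
    genome = _genome_with_midpoints([1000, 6000])
    clusters = cluster_colocalized([_hit("g0"), _hit("g1", "yihU")], genome)
    assert len(clusters) == 2  # strict inequality


def test_circular_wraparound_joins():
    genome = _genome_with_midpoints([500, 99500], circular=True, length=100000)
    clusters = cluster_colocalized([_hit("g0"), _hit("g1", "yihU")], genome)
    assert len(clusters) == 1  # 1000 bp the short way around


def test_unknown_gene_is_contract_violation():
    genome = _genome_with_midpoints([1000])
    with pytest.raises(ValueError, match="unknown gene"):
        cluster_colocalized([_hit("nope")], genome)


def _brute_force_components(midpoints, max_gap, circular=False, length=None):
    """Oracle: connected components of the pairwise-distance graph."""
    n = len(midpoints)
    L = length or 10 ** 9
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            d = abs(midpoints[i] - midpoints[j])
            if circular:
                d = min(d, L - d)
            if d < max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


@pytest.mark.parametrize("seed", range(10))
def test_clustering_is_partition_matching_graph_components(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 40))
    circular = bool(rng.integers(2))
    length = 200000
    mids = sorted(int(m) for m in rng.integers(100, length - 100, size=n))
    mids = [m + 0.5 for m in dict.fromkeys(mids)]  # unique; genes are 100 bp
    genome = _genome_with_midpoints(mids, circular=circular, length=length)
    hits = [_hit(f"g{i}", CASSETTE_FAMILIES[i % 10]) for i in range(len(mids))]
    clusters = cluster_colocalized(hits, genome, max_gap=5000)
    # partition
    all_ids = sorted(h.gene_id for cl in clusters for h in cl)
    assert all_ids == sorted(h.gene_id for h in hits)
    got = {frozenset(int(h.gene_id[1:]) for h in cl) for cl in clusters}
    assert got == _brute_force_components(mids, 5000, circular, length)


@pytest.mark.parametrize("seed", range(5))
def test_raising_max_gap_only_coarsens(seed):
    rng = np.random.default_rng(100 + seed)
    mids = sorted(float(m) for m in rng.integers(100, 100000, size=25))
    genome = _genome_with_midpoints(mids)
    hits = [_hit(f"g{i}", CASSETTE_FAMILIES[i % 10]) for i in range(len(mids))]
    fine = cluster_colocalized(hits, genome, max_gap=2000)
    coarse = cluster_colocalized(hits, genome, max_gap=8000)
    coarse_sets = [{h.gene_id for h in cl} for cl in coarse]
    for cl in fine:
        ids = {h.gene_id for h in cl}
        assert any(ids <= cs for cs in coarse_sets)


def test_complete_linkage_available():
    genome = _genome_with_midpoints([500, 4500, 8500])
    hits = [_hit("g0"), _hit("g1", "yihU"), _hit("g2", "yihV")]
    clusters = cluster_colocalized(hits, genome, linkage="complete")
    assert len(clusters) == 2  # 500 vs 8500 violates the pairwise bound


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------

def test_classify_long():
    assert classify_variant(CASSETTE_FAMILIES) == "LONG"


def test_classify_short():
    assert classify_variant(["yihT", "yihU", "yihV", "yihW"]) == "SHORT"


def test_classify_partial_and_none():
    assert classify_variant(["yihT", "yihU"]) == "PARTIAL"
    assert classify_variant(list(CASSETTE_FAMILIES[:-1])) == "PARTIAL"
    assert classify_variant([]) == "NONE"


def test_classify_permutation_invariant():
    rng = np.random.default_rng(0)
    fams = list(CASSETTE_FAMILIES)
    for _ in range(5):
        rng.shuffle(fams)
        assert classify_variant(fams) == "LONG"
    assert classify_variant(["yihW", "yihT", "yihV", "yihU"]) == "SHORT"


# ---------------------------------------------------------------------------
# span
# ---------------------------------------------------------------------------

def test_span_two_genes():
    genome = make_genome("s", [("g0", 100, 400, "+"), ("g1", 600, 900, "+")])
    hits = [_hit("g0"), _hit("g1", "yihU")]
    assert cassette_span(hits, genome) == (100, 900, False)


def test_span_single_gene():
    genome = make_genome("s", [("g0", 50, 80, "+")])
    assert cassette_span([_hit("g0")], genome) == (50, 80, False)


def test_span_multi_contig_rejected():
    from casscan.genome_io import Contig, GeneRecord, GenomeAnnotation

    genome = GenomeAnnotation(
        "s",
        [Contig("c1", 1000, False), Contig("c2", 1000, False)],
        [GeneRecord("g0", "c1", 1, 100, "+"), GeneRecord("g1", "c2", 1, 100, "+")],
    )
    with pytest.raises(ValueError, match="multiple contigs"):
        cassette_span([_hit("g0"), _hit("g1", "yihU")], genome)


def test_span_wrapping_origin_is_flagged():
    genome = make_genome(
        "s", [("g0", 99500, 99900, "+"), ("g1", 200, 600, "+")],
        circular=True, length=100000,
    )
    start, end, wraps = cassette_span([_hit("g0"), _hit("g1", "yihU")], genome)
    assert wraps
    assert (start, end) == (99500, 100600)  # unwrapped frame


# ---------------------------------------------------------------------------
# flanking UOGs
# ---------------------------------------------------------------------------

def _uog_genome_and_table():
    genome = make_genome("s", [
        ("u1", 1, 500, "+"),
        ("c1", 2000, 4000, "+"),
        ("c2", 5000, 8000, "+"),
        ("u2", 10000, 10400, "+"),
    ], length=20000)
    uogs = UogTable(entries=[("s", "u1", "UOG217"), ("s", "u2", "UOG236")])
    return genome, uogs


def test_flanking_uogs_nearest_neighbors():
    genome, uogs = _uog_genome_and_table()
    hits = [_hit("c1", "yihT"), _hit("c2", "yihU")]
    cassette = build_cassette(hits, genome)
    assert cassette.span == (2000, 8000)
    ctx = flanking_uogs(cassette, uogs, genome)
    assert ctx.upstream_uog == ("UOG217", 1500)
    assert ctx.downstream_uog == ("UOG236", 2000)


def test_flank_missing_on_linear_edge():
    genome = make_genome("s", [
        ("u1", 1, 500, "+"), ("c1", 2000, 4000, "+"),
    ], length=5000)
    uogs = UogTable(entries=[("s", "u1", "UOG217")])
    cassette = build_cassette([_hit("c1", "yihT")], genome)
    ctx = flanking_uogs(cassette, uogs, genome)
    assert ctx.upstream_uog == ("UOG217", 1500)
    assert ctx.downstream_uog is None


def test_flank_wraps_on_circular_contig():
    genome = make_genome("s", [
        ("u1", 1, 500, "+"), ("c1", 2000, 4000, "+"),
    ], circular=True, length=5000)
    uogs = UogTable(entries=[("s", "u1", "UOG217")])
    cassette = build_cassette([_hit("c1", "yihT")], genome)
    ctx = flanking_uogs(cassette, uogs, genome)
    assert ctx.upstream_uog == ("UOG217", 1500)
    # downstream wraps around: gene u1 starts at 1, 5000 - 4000 + 1 = 1001
    assert ctx.downstream_uog == ("UOG217", 1001)


def test_empty_uog_table_gives_no_flanks():
    genome, _ = _uog_genome_and_table()
    cassette = build_cassette([_hit("c1", "yihT")], genome)
    ctx = flanking_uogs(cassette, UogTable(entries=[]), genome)
    assert ctx.upstream_uog is None and ctx.downstream_uog is None


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def test_orientation_forward():
    members = [
        CassetteMember("yihT", "g0", 100.0, "+"),
        CassetteMember("yihU", "g1", 600.0, "+"),
        CassetteMember("yihV", "g2", 1100.0, "+"),
        CassetteMember("yihW", "g3", 1600.0, "+"),
    ]
    assert call_orientation(members) == ("forward", False)


def test_orientation_reverse_inverted():
    members = [
        CassetteMember("yihW", "g0", 100.0, "-"),
        CassetteMember("yihV", "g1", 600.0, "-"),
        CassetteMember("yihU", "g2", 1100.0, "-"),
        CassetteMember("yihT", "g3", 1600.0, "-"),
    ]
    assert call_orientation(members) == ("reverse", True)


def test_orientation_mixed():
    members = [
        CassetteMember("yihU", "g0", 100.0, "+"),
        CassetteMember("yihT", "g1", 600.0, "+"),
        CassetteMember("yihV", "g2", 1100.0, "-"),
    ]
    assert call_orientation(members)[0] == "mixed"


def test_orientation_single_member_uses_strand():
    assert call_orientation([CassetteMember("yihT", "g0", 100.0, "-")]) == (
        "reverse", True,
    )


def test_planted_inversion_recovered(zero_div_panel):
    from casscan.cassette_arch import analyze_genome, best_context

    panel = zero_div_panel
    shorts = [s for s, t in panel.truth.items() if t["variant"] == "SHORT"]
    assert shorts, "fixture panel should contain SHORT strains"
    for strain in shorts[:3]:
        ctx = best_context(analyze_genome(
            panel.genome(strain), panel.query_families, panel.uog_table,
        ))
        assert ctx.inverted is True
        assert ctx.cassette.orientation == "reverse"


# ---------------------------------------------------------------------------
# alternative-cluster scan
# ---------------------------------------------------------------------------

def test_scan_distant_homologs_not_clustered():
    rng = np.random.default_rng(50)
    enzymes = QueryFamilySet(families={"enzA": random_protein(rng, 60),
                                       "enzB": random_protein(rng, 60)})
    genome = make_genome("s", [
        ("g0", 1000, 1180, "+", enzymes.families["enzA"]),
        ("g1", 51000, 51180, "+", enzymes.families["enzB"]),
    ], length=60000)
    report = scan_alternative_clusters(genome, enzymes)
    assert report["multi_member_clusters"] == []
    assert len(report["clusters"]) == 2
    assert report["max_identity"] == 100.0


def test_scan_adjacent_homologs_clustered():
    rng = np.random.default_rng(51)
    enzymes = QueryFamilySet(families={"enzA": random_protein(rng, 60),
                                       "enzB": random_protein(rng, 60)})
    genome = make_genome("s", [
        ("g0", 1000, 1180, "+", enzymes.families["enzA"]),
        ("g1", 2000, 2180, "+", enzymes.families["enzB"]),
    ], length=60000)
    report = scan_alternative_clusters(genome, enzymes)
    assert report["multi_member_clusters"] == [["g0", "g1"]]


def test_scan_synthetic_genome_only_cassette_locus(zero_div_panel):
    """No alternative co-localized clusters outside the planted locus."""
    panel = zero_div_panel
    genome = panel.genomes[0]
    report = scan_alternative_clusters(
        genome, panel.query_families, thresholds=(25.0, 50.0),
    )
    truth = panel.truth[genome.strain_id]
    if truth["variant"] == "NONE":
        assert report["multi_member_clusters"] == []
    else:
        assert len(report["multi_member_clusters"]) == 1


def test_duplicated_family_flagged():
    genome = make_genome("s", [
        ("g0", 1000, 1300, "+"), ("g1", 2000, 2300, "+"),
    ])
    hits = [_hit("g0", "yihT"), _hit("g1", "yihT")]
    cassette = build_cassette(hits, genome)
    assert cassette.duplicated_families == ("yihT",)
    assert len(cassette.members) == 1
    assert cassette.variant == "PARTIAL"
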