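"""Cassette architecture: co-localization clustering, variant classification,
span definition, synteny anchoring to flanking UOGs, and orientation calls.

Two homolog hits are co-localized iff they lie on the same contig and the
distance between their gene midpoints is strictly less than ``max_gap``
(default 5000 bp); clusters are the single-linkage closure of that relation
(complete linkage available for sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from casscan.genome_io import (
    Contig,
    GeneRecord,
    GenomeAnnotation,
    UogTable,
    circular_distance,
    gene_midpoint,
    spans_origin,
)
from casscan.homology import HomologyHit, QueryFamilySet, find_family_hits, max_identity_to_known_enzymes

logger = logging.getLogger(__name__)

#: reference family order of the full-length cassette along the chromosome
CASSETTE_FAMILIES: tuple[str, ...] = (
    "ompL", "yihO", "yihP", "yihQ", "yihR", "yihS", "yihT", "yihU", "yihV", "yihW",
)
#: family content of the truncated variant
SHORT_FAMILIES: frozenset[str] = frozenset({"yihT", "yihU", "yihV", "yihW"})

VARIANT_LONG = "LONG"
VARIANT_SHORT = "SHORT"
VARIANT_PARTIAL = "PARTIAL"
VARIANT_NONE = "NONE"

DEFAULT_MAX_GAP = 5000


class CassetteMember(NamedTuple):
    family_id: str
    gene_id: str
    midpoint: float  # unwrapped coordinate (may exceed contig length on wrap)
    strand: str


@dataclass
class Cassette:
    strain_id: str
    contig_id: str
    members: list[CassetteMember]
    span: tuple[int, int] | None
    variant: str
    orientation: str = "mixed"
    wraps_origin: bool = False
    duplicated_families: tuple[str, ...] = ()

    @property
    def families(self) -> frozenset[str]:
        return frozenset(m.family_id for m in self.members)


@dataclass
class SyntenyContext:
    cassette: Cassette
    upstream_uog: tuple[str, int] | None = None  # (uog_id, gap bp)
    downstream_uog: tuple[str, int] | None = None
    inverted: bool = False


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _resolve(hits: Sequence[HomologyHit], genome: GenomeAnnotation) -> list[tuple[HomologyHit, GeneRecord, float]]:
    index = genome.gene_index
    out = []
    for h in hits:
        gene = index.get(h.gene_id)
        if gene is None:
            raise ValueError(
                f"hit references unknown gene {h.gene_id!r} in strain "
                f"{genome.strain_id!r}"
            )
        contig = genome.contig(gene.contig_id)
        out.append((h, gene, gene_midpoint(gene, contig)))
    return out


def cluster_colocalized(
    hits: Sequence[HomologyHit],
    genome: GenomeAnnotation,
    max_gap: float = DEFAULT_MAX_GAP,
    linkage: str = "single",
) -> list[list[HomologyHit]]:
    """Cluster hits into co-localized groups per contig.

    Single linkage: two hits join iff same contig and midpoint distance
    < ``max_gap`` (strict); clusters are maximal under chaining. On circular
    contigs the midpoint distance wraps around the origin.
    """
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    by_contig: dict[str, list[tuple[HomologyHit, GeneRecord, float]]] = {}
    for item in _resolve(hits, genome):
        by_contig.setdefault(item[1].contig_id, []).append(item)

    clusters: list[tuple[float, list[HomologyHit]]] = []
    for contig_id in sorted(by_contig):
        contig = genome.contig(contig_id)
        items = sorted(by_contig[contig_id], key=lambda t: (t[2], t[0].gene_id))
        if linkage == "complete":
            groups = _complete_linkage(items, contig, max_gap)
        else:
            groups = _single_linkage(items, contig, max_gap)
        for grp in groups:
            leftmost = min(t[2] for t in grp)
            clusters.append((leftmost, [t[0] for t in grp]))
    clusters.sort(key=lambda c: c[0])
    return [members for _left, members in clusters]


def _single_linkage(items, contig: Contig, max_gap: float):
    groups: list[list] = [[items[0]]]
    for prev, cur in zip(items, items[1:]):
        if cur[2] - prev[2] < max_gap:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    # on a circle the last and first sorted hits are also adjacent
    if contig.circular and len(groups) > 1:
        wrap = circular_distance(items[-1][2], items[0][2], contig)
        if wrap < max_gap:
            groups[0] = groups.pop() + groups[0]
    return groups


def _complete_linkage(items, contig: Contig, max_gap: float):
    import numpy as np
    from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
    from scipy.spatial.distance import pdist

    if len(items) == 1:
        return [items]
    mids = np.array([[t[2]] for t in items], dtype=float)
    if contig.circular:
        dists = pdist(mids, metric=lambda u, v: circular_distance(u[0], v[0], contig))
    else:
        dists = pdist(mids)
    labels = fcluster(scipy_linkage(dists, method="complete"), t=max_gap * (1 - 1e-9),
                      criterion="distance")
    groups: dict[int, list] = {}
    for lab, item in zip(labels, items):
        groups.setdefault(int(lab), []).append(item)
    return [groups[k] for k in sorted(groups, key=lambda k: min(t[2] for t in groups[k]))]


# ---------------------------------------------------------------------------
# classification and span
# ---------------------------------------------------------------------------

def classify_variant(families: Iterable[str]) -> str:
    """LONG iff all ten families present; SHORT iff exactly the four-gene set;
    PARTIAL for any other non-empty set; NONE when empty.

    Depends only on the family *set* (duplicates and order ignored).
    """
    fams = frozenset(families)
    if not fams:
        return VARIANT_NONE
    if fams == frozenset(CASSETTE_FAMILIES):
        return VARIANT_LONG
    if fams == SHORT_FAMILIES:
        return VARIANT_SHORT
    return VARIANT_PARTIAL


def cassette_span(
    cluster: Sequence[HomologyHit],
    genome: GenomeAnnotation,
) -> tuple[int, int, bool]:
    """(start, end, wraps_origin) of a cluster.

    Linear contigs: (min gene start, max gene end, False). On circular contigs
    a cluster hugging the origin is reported on unwrapped coordinates (end may
    exceed the contig length) with the wrap flag raised; the unwrapped frame
    is the rotation minimizing the cluster extent.
    """
    items = _resolve(cluster, genome)
    contigs = {g.contig_id for _h, g, _m in items}
    if len(contigs) != 1:
        raise ValueError(f"cluster members on multiple contigs: {sorted(contigs)}")
    contig = genome.contig(contigs.pop())
    intervals = []
    for _h, g, _m in items:
        if spans_origin(g):
            intervals.append((g.start, g.end + contig.length))
        else:
            intervals.append((g.start, g.end))
    if not contig.circular:
        return min(s for s, _ in intervals), max(e for _, e in intervals), False
    # pick the rotation (anchor gene first) minimizing the unwrapped extent
    best: tuple[int, int, int] | None = None  # (extent, start, end)
    for anchor_start, _ in intervals:
        spans = [
            (s + contig.length, e + contig.length) if s < anchor_start else (s, e)
            for s, e in intervals
        ]
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        if best is None or hi - lo < best[0]:
            best = (hi - lo, lo, hi)
    _, lo, hi = best
    if hi > contig.length and lo > contig.length:
        lo -= contig.length
        hi -= contig.length
    wraps = hi > contig.length
    if wraps:
        logger.warning(
            "cassette span wraps the origin of circular contig %s (modular "
            "coordinate rule applied)", contig.contig_id,
        )
    return lo, hi, wraps


# ---------------------------------------------------------------------------
# synteny anchoring
# ---------------------------------------------------------------------------

def flanking_uogs(
    cassette: Cassette,
    uogs: UogTable,
    genome: GenomeAnnotation,
) -> SyntenyContext:
    """Nearest UOG genes up- and downstream of the cassette span.

    Upstream: largest gene end < span start; downstream: smallest gene start
    > span end (ascending contig coordinates). Distances are gap sizes. On
    circular contigs the search wraps; on linear contigs a missing neighbor
    yields None.
    """
    ctx = SyntenyContext(cassette=cassette, inverted=cassette.orientation == "reverse")
    if cassette.span is None:
        return ctx
    gene_to_uog = uogs.for_strain(cassette.strain_id)
    if not gene_to_uog:
        logger.warning("no UOG entries for strain %s; flanks undefined",
                       cassette.strain_id)
        return ctx
    contig = genome.contig(cassette.contig_id)
    span_start, span_end = cassette.span
    candidates = []  # (uog_id, start, end)
    for g in genome.genes:
        if g.contig_id != cassette.contig_id or g.gene_id not in gene_to_uog:
            continue
        s, e = g.start, (g.end + contig.length if spans_origin(g) else g.end)
        if contig.circular and span_end > contig.length and e <= span_end - contig.length:
            # cassette wraps: shift early-coordinate genes into the unwrapped frame
            s += contig.length
            e += contig.length
        candidates.append((gene_to_uog[g.gene_id], s, e))
    up = [(e, uid) for uid, s, e in candidates if e < span_start]
    down = [(s, uid) for uid, s, e in candidates if s > span_end]
    if up:
        e, uid = max(up)
        ctx.upstream_uog = (uid, int(span_start - e))
    elif contig.circular and candidates:
        e, uid = max((e, uid) for uid, s, e in candidates)
        ctx.upstream_uog = (uid, int(span_start + contig.length - e))
    if down:
        s, uid = min(down)
        ctx.downstream_uog = (uid, int(s - span_end))
    elif contig.circular and candidates:
        s, uid = min((s, uid) for uid, s, e in candidates)
        ctx.downstream_uog = (uid, int(s + contig.length - span_end))
    return ctx


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def call_orientation(
    members: Sequence[CassetteMember],
    reference_order: Sequence[str] = CASSETTE_FAMILIES,
) -> tuple[str, bool]:
    """Orientation of a cassette relative to the reference (long) layout.

    forward: family order along ascending coordinates matches the reference
    order restricted to present families, with majority + strand; reverse:
    matches the reversed order with majority - strand; mixed otherwise.
    The inverted flag is true iff the call is reverse — the reference (long)
    configuration read from its upstream flank defines forward.
    """
    if not members:
        raise ValueError("orientation of an empty cassette is undefined")
    ordered = sorted(members, key=lambda m: m.midpoint)
    observed = [m.family_id for m in ordered]
    restricted = [f for f in reference_order if f in set(observed)]
    plus = sum(1 for m in members if m.strand == "+")
    minus = len(members) - plus
    if len(members) == 1:
        orientation = "forward" if members[0].strand == "+" else "reverse"
    elif observed == restricted and plus > minus:
        orientation = "forward"
    elif observed == list(reversed(restricted)) and minus > plus:
        orientation = "reverse"
    else:
        orientation = "mixed"
    return orientation, orientation == "reverse"


# ---------------------------------------------------------------------------
# alternative-cluster scan
# ---------------------------------------------------------------------------

def scan_alternative_clusters(
    genome: GenomeAnnotation,
    enzyme_set: QueryFamilySet,
    max_gap: float = DEFAULT_MAX_GAP,
    thresholds: tuple[float, float] = (25.0, 50.0),
) -> dict:
    """Scan a genome for co-localized clusters of candidate enzyme homologs.

    Runs the family search with permissive thresholds, clusters the hits, and
    reports all clusters, the multi-member ones, and the genome-wide maximum
    identity to the enzyme set.
    """
    hits = find_family_hits(enzyme_set, genome, thresholds=thresholds)
    clusters = cluster_colocalized(hits, genome, max_gap=max_gap) if hits else []
    identities = max_identity_to_known_enzymes(genome, enzyme_set)
    max_identity = max(identities.values(), default=0.0)
    return {
        "strain": genome.strain_id,
        "clusters": [[h.gene_id for h in cl] for cl in clusters],
        "multi_member_clusters": [
            [h.gene_id for h in cl] for cl in clusters if len(cl) > 1
        ],
        "max_identity": max_identity,
    }


# ---------------------------------------------------------------------------
# per-genome driver
# ---------------------------------------------------------------------------

def build_cassette(
    cluster: Sequence[HomologyHit],
    genome: GenomeAnnotation,
    reference_order: Sequence[str] = CASSETTE_FAMILIES,
) -> Cassette:
    """Assemble a Cassette from one co-localized cluster.

    A family hit twice within one cluster is flagged and the lower-scoring
    copy dropped so the member list keeps one gene per family.
    """
    items = _resolve(cluster, genome)
    span_start, span_end, wraps = cassette_span(cluster, genome)
    contig = genome.contig(items[0][1].contig_id)
    best_by_family: dict[str, tuple[HomologyHit, GeneRecord, float]] = {}
    duplicated: set[str] = set()
    for h, g, mid in items:
        prev = best_by_family.get(h.family_id)
        if prev is None:
            best_by_family[h.family_id] = (h, g, mid)
        else:
            duplicated.add(h.family_id)
            if (h.score, h.identity, h.gene_id) > (prev[0].score, prev[0].identity, prev[0].gene_id):
                best_by_family[h.family_id] = (h, g, mid)
    members = []
    for fam in sorted(best_by_family):
        h, g, mid = best_by_family[fam]
        if wraps and mid < span_start:
            mid += contig.length  # unwrapped frame
        members.append(CassetteMember(fam, g.gene_id, mid, g.strand))
    members.sort(key=lambda m: m.midpoint)
    cassette = Cassette(
        strain_id=genome.strain_id,
        contig_id=items[0][1].contig_id,
        members=members,
        span=(span_start, span_end),
        variant=classify_variant(best_by_family),
        wraps_origin=wraps,
        duplicated_families=tuple(sorted(duplicated)),
    )
    if duplicated:
        logger.warning("strain %s: duplicated families %s within one cluster",
                       genome.strain_id, sorted(duplicated))
    cassette.orientation, _ = call_orientation(members, reference_order)
    return cassette


def analyze_genome(
    genome: GenomeAnnotation,
    families: QueryFamilySet,
    uogs: UogTable,
    max_gap: float = DEFAULT_MAX_GAP,
    thresholds: tuple[float, float] = (40.0, 70.0),
    reference_order: Sequence[str] = CASSETTE_FAMILIES,
    linkage: str = "single",
    hits: Sequence[HomologyHit] | None = None,
) -> list[SyntenyContext]:
    """Full per-genome detection: hits -> clusters -> cassettes -> synteny.

    Pass precomputed ``hits`` (e.g., from an imported BLAST table) to bypass
    the internal aligner. Returns one SyntenyContext per cluster, ordered by
    span start.
    """
    if hits is None:
        hits = find_family_hits(families, genome, thresholds=thresholds)
    if not hits:
        return []
    clusters = cluster_colocalized(hits, genome, max_gap=max_gap, linkage=linkage)
    results = []
    for cluster in clusters:
        cassette = build_cassette(cluster, genome, reference_order)
        results.append(flanking_uogs(cassette, uogs, genome))
    results.sort(key=lambda ctx: ctx.cassette.span[0])
    if len(results) > 1:
        logger.warning("strain %s carries %d candidate cassette loci",
                       genome.strain_id, len(results))
    return results


def best_context(results: Sequence[SyntenyContext]) -> SyntenyContext | None:
    """Strain-level call: the best-supported cluster (most families; ties ->
    leftmost span)."""
    if not results:
        return None
    return max(
        results,
        key=lambda ctx: (len(ctx.cassette.families), -ctx.cassette.span[0]),
    )


def context_row(ctx: SyntenyContext | None, strain_id: str | None = None) -> dict:
    """Flatten a SyntenyContext into a cassette_table row."""
    if ctx is None:
        return {
            "strain": strain_id, "contig": None, "variant": VARIANT_NONE,
            "span_start": None, "span_end": None, "orientation": None,
            "inverted": None, "families": None, "upstream_uog": None,
            "upstream_gap": None, "downstream_uog": None,
            "downstream_gap": None, "wraps_origin": None,
        }
    c = ctx.cassette
    return {
        "strain": c.strain_id,
        "contig": c.contig_id,
        "variant": c.variant,
        "span_start": c.span[0],
        "span_end": c.span[1],
        "orientation": c.orientation,
        "inverted": ctx.inverted,
        "families": ",".join(m.family_id for m in c.members),
        "upstream_uog": ctx.upstream_uog[0] if ctx.upstream_uog else None,
        "upstream_gap": ctx.upstream_uog[1] if ctx.upstream_uog else None,
        "downstream_uog": ctx.downstream_uog[0] if ctx.downstream_uog else None,
        "downstream_gap": ctx.downstream_uog[1] if ctx.downstream_uog else None,
        "wraps_origin": c.wraps_origin,
    }
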