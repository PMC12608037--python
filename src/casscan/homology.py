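"""Protein homology search: local alignment, family assignment, reciprocal best hits.

The internal aligner is a Gotoh local alignment (affine gaps, BLOSUM62 by
default).  Because several optimal-score alignments can exist, the reported
statistics are made well-defined by a lexicographic objective: among all local
alignments, maximize

    (score, #identical columns, -#alignment columns, #query residues aligned)

so identity and coverage are deterministic functions of the two sequences.
Gap runs in the two sequences may not abut directly (standard Gotoh
transition set: M->{M,X,Y}, X->{M,X}, Y->{M,Y}); a first gap residue costs
``gap_open + gap_extend``.

External hit tables in BLAST tabular (outfmt-6-like) layout can be imported
instead of running the internal aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from casscan.genome_io import GenomeAnnotation

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

DEFAULT_MIN_IDENTITY = 40.0
DEFAULT_MIN_COVERAGE = 70.0
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1


def _load_blosum62() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int32)
    for i, x in enumerate(AA_ALPHABET):
        for j, y in enumerate(AA_ALPHABET):
            out[i, j] = int(mat[x, y])
    return out


BLOSUM62 = _load_blosum62()


def encode_protein(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"non-amino-acid character {exc.args[0]!r} in protein sequence"
        ) from None


@njit(cache=False)
def _lex_better(s1, m1, c1, r1, s2, m2, c2, r2):  # pragma: no cover - jitted
    """True iff tuple 1 beats tuple 2: score desc, matches desc, columns asc,
    query residues desc."""
    if s1 != s2:
        return s1 > s2
    if m1 != m2:
        return m1 > m2
    if c1 != c2:
        return c1 < c2
    return r1 > r2


@njit(cache=False)
def _gotoh_core(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    """Local Gotoh DP with lexicographic tuple values and rolling rows.

    Tracked per cell and state: score s, identical columns mt, alignment
    columns c, query residues ar (comparison keys, c minimized) plus payload
    br (target residues) and the end cell of the global optimum.
    Returns (s, mt, c, ar, br, qend, tend); all zeros when no alignment with
    positive score exists.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(10 ** 9)
    go = gap_open + gap_extend
    ge = gap_extend

    # state 0 = M (match/mismatch), 1 = X (gap in b, consumes a), 2 = Y;
    # component 0..4 = s, mt, c, ar, br
    prev = np.zeros((3, 5, m + 1), dtype=np.int64)
    cur = np.zeros((3, 5, m + 1), dtype=np.int64)
    for st in range(3):
        for j in range(m + 1):
            prev[st, 0, j] = NEG

    best_s, best_mt, best_c, best_ar, best_br = 0, 0, 0, 0, 0
    best_i, best_j = 0, 0

    for i in range(1, n + 1):
        for st in range(3):
            cur[st, 0, 0] = NEG
            for comp in range(1, 5):
                cur[st, comp, 0] = 0
        for j in range(1, m + 1):
            # --- M state: best of (M,X,Y diag, restart) + aligned column
            ps, pmt, pc, par, pbr = 0, 0, 0, 0, 0  # restart
            for st in range(3):
                s2 = prev[st, 0, j - 1]
                if s2 <= NEG // 2:
                    continue
                if _lex_better(s2, prev[st, 1, j - 1], prev[st, 2, j - 1],
                               prev[st, 3, j - 1], ps, pmt, pc, par):
                    ps = s2
                    pmt = prev[st, 1, j - 1]
                    pc = prev[st, 2, j - 1]
                    par = prev[st, 3, j - 1]
                    pbr = prev[st, 4, j - 1]
            ident = 1 if a[i - 1] == b[j - 1] else 0
            cur[0, 0, j] = ps + sub[a[i - 1], b[j - 1]]
            cur[0, 1, j] = pmt + ident
            cur[0, 2, j] = pc + 1
            cur[0, 3, j] = par + 1
            cur[0, 4, j] = pbr + 1

            # --- X state: gap in b (consume a) from M or X above
            xs = prev[0, 0, j] - go
            xmt, xc, xar, xbr = (
                prev[0, 1, j], prev[0, 2, j] + 1, prev[0, 3, j] + 1, prev[0, 4, j],
            )
            s2 = prev[1, 0, j] - ge
            if _lex_better(s2, prev[1, 1, j], prev[1, 2, j] + 1,
                           prev[1, 3, j] + 1, xs, xmt, xc, xar):
                xs = s2
                xmt = prev[1, 1, j]
                xc = prev[1, 2, j] + 1
                xar = prev[1, 3, j] + 1
                xbr = prev[1, 4, j]
            if xs < NEG:
                xs = NEG
            cur[1, 0, j] = xs
            cur[1, 1, j] = xmt
            cur[1, 2, j] = xc
            cur[1, 3, j] = xar
            cur[1, 4, j] = xbr

            # --- Y state: gap in a (consume b) from M or Y on the left
            ys = cur[0, 0, j - 1] - go
            ymt, yc, yar, ybr = (
                cur[0, 1, j - 1], cur[0, 2, j - 1] + 1,
                cur[0, 3, j - 1], cur[0, 4, j - 1] + 1,
            )
            s2 = cur[2, 0, j - 1] - ge
            if _lex_better(s2, cur[2, 1, j - 1], cur[2, 2, j - 1] + 1,
                           cur[2, 3, j - 1], ys, ymt, yc, yar):
                ys = s2
                ymt = cur[2, 1, j - 1]
                yc = cur[2, 2, j - 1] + 1
                yar = cur[2, 3, j - 1]
                ybr = cur[2, 4, j - 1] + 1
            if ys < NEG:
                ys = NEG
            cur[2, 0, j] = ys
            cur[2, 1, j] = ymt
            cur[2, 2, j] = yc
            cur[2, 3, j] = yar
            cur[2, 4, j] = ybr

            # --- global best ends in M only (trailing gaps lower the score)
            if _lex_better(cur[0, 0, j], cur[0, 1, j], cur[0, 2, j], cur[0, 3, j],
                           best_s, best_mt, best_c, best_ar):
                best_s = cur[0, 0, j]
                best_mt = cur[0, 1, j]
                best_c = cur[0, 2, j]
                best_ar = cur[0, 3, j]
                best_br = cur[0, 4, j]
                best_i = i
                best_j = j
        tmp = prev
        prev = cur
        cur = tmp

    if best_s <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    return best_s, best_mt, best_c, best_ar, best_br, best_i, best_j


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of the optimal local alignment of query a vs target b."""

    score: int
    identity: float  # percent of alignment columns identical, 0-100
    coverage: float  # percent of query residues aligned, 0-100
    matches: int = 0
    columns: int = 0
    query_aligned: int = 0
    target_aligned: int = 0
    query_end: int = 0  # 1-based, inclusive; 0 when no alignment
    target_end: int = 0

    @property
    def query_start(self) -> int:
        return self.query_end - self.query_aligned + 1 if self.columns else 0

    @property
    def target_start(self) -> int:
        return self.target_end - self.target_aligned + 1 if self.columns else 0


def align_proteins(
    a: str,
    b: str,
    substitution: np.ndarray | None = None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Local alignment of protein ``a`` (query) vs ``b`` (target).

    Identity is percent identical columns over all alignment columns
    (gap columns included); coverage is percent of the query aligned.
    """
    if not a or not b:
        raise ValueError("align_proteins requires non-empty sequences")
    sub = BLOSUM62 if substitution is None else substitution
    s, mt, c, ar, br, qe, te = _gotoh_core(
        encode_protein(a), encode_protein(b), sub, gap_open, gap_extend
    )
    if c == 0:
        return AlignmentResult(score=0, identity=0.0, coverage=0.0)
    return AlignmentResult(
        score=int(s),
        identity=100.0 * mt / c,
        coverage=100.0 * ar / len(a),
        matches=int(mt),
        columns=int(c),
        query_aligned=int(ar),
        target_aligned=int(br),
        query_end=int(qe),
        target_end=int(te),
    )


# ---------------------------------------------------------------------------
# query families and hits
# ---------------------------------------------------------------------------

@dataclass
class QueryFamilySet:
    """Reference protein per gene family (the query set of the screen)."""

    families: dict[str, str]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("family set must be non-empty")
        for fid, seq in self.families.items():
            if not seq:
                raise ValueError(f"family {fid!r} has an empty sequence")

    @classmethod
    def from_fasta(cls, path) -> "QueryFamilySet":
        from Bio import SeqIO

        fams = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in fams:
                raise ValueError(f"duplicate family id {rec.id!r} in {path}")
            fams[rec.id] = str(rec.seq)
        return cls(families=fams)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for fid in sorted(self.families):
                fh.write(f">{fid}\n{self.families[fid]}\n")


@dataclass(frozen=True)
class HomologyHit:
    family_id: str
    strain_id: str
    gene_id: str
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100 and 0 <= self.coverage <= 100):
            raise ValueError("identity/coverage must lie in [0, 100]")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


@dataclass(frozen=True)
class OrthologPair:
    gene_a: tuple[str, str]  # (strain_id, gene_id)
    gene_b: tuple[str, str]
    identity: float


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_family_hits(
    families: QueryFamilySet,
    genome: GenomeAnnotation,
    thresholds: tuple[float, float] = (DEFAULT_MIN_IDENTITY, DEFAULT_MIN_COVERAGE),
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    prefilter_kmer: int | None = 5,
) -> list[HomologyHit]:
    """Assign genome genes to query families by best local-alignment score.

    Each gene is assigned to at most one family (highest score; ties broken by
    identity then family id); the hit is reported iff it meets both thresholds
    (identity is query-coverage computed with the family protein as query).
    ``prefilter_kmer`` skips alignments for gene/family pairs sharing no
    k-mer — an admissible shortcut for the default thresholds, disable with
    ``None`` for exhaustive scoring.
    """
    min_identity, min_coverage = thresholds
    fam_ids = sorted(families.families)
    fam_kmers = (
        {f: _kmer_set(families.families[f], prefilter_kmer) for f in fam_ids}
        if prefilter_kmer
        else None
    )
    hits: list[HomologyHit] = []
    for gene in genome.genes:
        if gene.protein_seq is None:
            continue
        gene_kmers = _kmer_set(gene.protein_seq, prefilter_kmer) if prefilter_kmer else None
        best: tuple[float, float, str, AlignmentResult] | None = None
        for fid in fam_ids:
            if (
                fam_kmers is not None
                and gene_kmers
                and fam_kmers[fid]
                and not (fam_kmers[fid] & gene_kmers)
            ):
                continue
            res = align_proteins(
                families.families[fid], gene.protein_seq,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if res.score <= 0:
                continue
            # family ids sorted ascending: keep strict improvement only, so
            # ties resolve to the lexicographically smallest family
            cand = (res.score, res.identity)
            if best is None or cand > (best[0], best[1]):
                best = (res.score, res.identity, fid, res)
        if best is None:
            continue
        score, identity, fid, res = best
        if identity >= min_identity and res.coverage >= min_coverage:
            hits.append(
                HomologyHit(
                    family_id=fid,
                    strain_id=genome.strain_id,
                    gene_id=gene.gene_id,
                    identity=identity,
                    coverage=res.coverage,
                    score=float(score),
                )
            )
    hits.sort(key=lambda h: (h.family_id, -h.score, h.gene_id))
    return hits


def _best_unique_hit(
    query_seq: str,
    targets: Sequence[tuple[str, str]],
    thresholds: tuple[float, float],
    gap_open: int,
    gap_extend: int,
) -> tuple[str, float] | None:
    """Best target for a query or None when the best is tied on (score, identity)."""
    min_identity, min_coverage = thresholds
    scored: list[tuple[float, float, str]] = []
    for tid, tseq in targets:
        res = align_proteins(query_seq, tseq, gap_open=gap_open, gap_extend=gap_extend)
        if res.score <= 0 or res.identity < min_identity or res.coverage < min_coverage:
            continue
        scored.append((res.score, res.identity, tid))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
        return None  # exact tie on (score, identity) disqualifies
    return scored[0][2], scored[0][1]


def reciprocal_best_hits(
    genome_a: GenomeAnnotation,
    genome_b: GenomeAnnotation,
    thresholds: tuple[float, float] = (DEFAULT_MIN_IDENTITY, DEFAULT_MIN_COVERAGE),
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[OrthologPair]:
    """Reciprocal best-hit ortholog pairs between two annotated genomes.

    (x, y) is reported iff y is x's unique best hit in b and x is y's unique
    best hit in a; genes whose top two candidates tie exactly on score and
    identity are excluded from pairing.
    """
    a_genes = [(g.gene_id, g.protein_seq) for g in genome_a.genes if g.protein_seq]
    b_genes = [(g.gene_id, g.protein_seq) for g in genome_b.genes if g.protein_seq]
    best_ab: dict[str, tuple[str, float]] = {}
    for gid, seq in a_genes:
        hit = _best_unique_hit(seq, b_genes, thresholds, gap_open, gap_extend)
        if hit is not None:
            best_ab[gid] = hit
    best_ba: dict[str, str] = {}
    for gid, seq in b_genes:
        hit = _best_unique_hit(seq, a_genes, thresholds, gap_open, gap_extend)
        if hit is not None:
            best_ba[gid] = hit[0]
    pairs = [
        OrthologPair(
            gene_a=(genome_a.strain_id, gid),
            gene_b=(genome_b.strain_id, tid),
            identity=identity,
        )
        for gid, (tid, identity) in sorted(best_ab.items())
        if best_ba.get(tid) == gid
    ]
    return pairs


def max_identity_to_known_enzymes(
    genome: GenomeAnnotation,
    enzyme_set: QueryFamilySet,
    min_score: int = 1,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> dict[str, float]:
    """Per-gene maximum percent identity over a set of reference enzymes.

    Genes with no alignment reaching ``min_score`` get 0.0.
    """
    out: dict[str, float] = {}
    for gene in genome.genes:
        if gene.protein_seq is None:
            continue
        best = 0.0
        for fid in sorted(enzyme_set.families):
            res = align_proteins(
                enzyme_set.families[fid], gene.protein_seq,
                gap_open=gap_open, gap_extend=gap_extend,
            )
            if res.score >= min_score and res.identity > best:
                best = res.identity
        out[gene.gene_id] = best
    return out


# ---------------------------------------------------------------------------
# BLAST tabular import / export
# ---------------------------------------------------------------------------

BLAST_TAB_COLUMNS = [
    "query", "target", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]


def write_hits_tsv(
    hits: Iterable[HomologyHit],
    path,
    families: QueryFamilySet,
    genome: GenomeAnnotation,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> None:
    """Export hits in 12-column BLAST tabular layout (evalue written as NA).

    The alignment is recomputed to recover endpoints; gap columns are folded
    into the mismatch count and ``gapopens`` reports gap columns.
    """
    index = genome.gene_index
    lines = []
    for h in hits:
        qseq = families.families[h.family_id]
        tseq = index[h.gene_id].protein_seq
        res = align_proteins(qseq, tseq, gap_open=gap_open, gap_extend=gap_extend)
        gaps = 2 * res.columns - res.query_aligned - res.target_aligned
        mism = res.columns - res.matches - gaps
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        h.family_id, h.gene_id, f"{res.identity:.2f}", res.columns,
                        mism, gaps, res.query_start, res.query_end,
                        res.target_start, res.target_end, "NA", res.score,
                    ],
                )
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_hits_tsv(
    path,
    families: QueryFamilySet,
    strain_id: str,
    thresholds: tuple[float, float] = (DEFAULT_MIN_IDENTITY, DEFAULT_MIN_COVERAGE),
) -> list[HomologyHit]:
    """Import an external BLAST tabular hit table, bypassing the aligner.

    Query coverage is derived from qstart/qend and the family sequence length.
    Each gene keeps only its best hit (bitscore, then identity, then family).
    """
    min_identity, min_coverage = thresholds
    best: dict[str, tuple[float, float, str, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            fid, gid = parts[0], parts[1]
            identity = float(parts[2])
            qstart, qend = int(parts[6]), int(parts[7])
            score = float(parts[11])
            if fid not in families.families:
                raise ValueError(f"hit table references unknown family {fid!r}")
            coverage = 100.0 * (qend - qstart + 1) / len(families.families[fid])
            cand = (score, identity, fid, coverage)
            if gid not in best or cand[:2] > best[gid][:2]:
                best[gid] = cand
    hits = [
        HomologyHit(
            family_id=fid, strain_id=strain_id, gene_id=gid,
            identity=identity, coverage=min(coverage, 100.0), score=score,
        )
        for gid, (score, identity, fid, coverage) in best.items()
        if identity >= min_identity and coverage >= min_coverage
    ]
    hits.sort(key=lambda h: (h.family_id, -h.score, h.gene_id))
    return hits
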