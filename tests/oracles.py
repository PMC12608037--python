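"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the package's optimized code paths: the alignment
oracle is a plain-Python tuple DP (plus an exponential enumerator for tiny
strings), the exact-test oracle works on integer hypergeometric weights with
Fraction arithmetic, and the parsimony oracle enumerates internal labelings.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from casscan.homology import BLOSUM62, _AA_INDEX

# objective: lexicographic max of (score, matches, -columns, query_residues)


def _key(t):
    s, m, c, r = t
    return (s, m, -c, r)


def oracle_align(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Optimal (score, matches, columns, query_aligned) by a plain tuple DP.

    Local alignment, affine gaps (first gap residue costs open+extend),
    Gotoh transition set (gap runs in the two sequences may not abut).
    Returns (0, 0, 0, 0) when no alignment has positive score.
    """
    ai = [_AA_INDEX[c] for c in a]
    bi = [_AA_INDEX[c] for c in b]
    n, m = len(ai), len(bi)
    go, ge = gap_open + gap_extend, gap_extend
    NONE = (-(10 ** 12), 0, 0, 0)
    M = [[NONE] * (m + 1) for _ in range(n + 1)]
    X = [[NONE] * (m + 1) for _ in range(n + 1)]
    Y = [[NONE] * (m + 1) for _ in range(n + 1)]
    best = (0, 0, 0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pred = max(
                (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], (0, 0, 0, 0)),
                key=_key,
            )
            ident = 1 if ai[i - 1] == bi[j - 1] else 0
            sub = int(BLOSUM62[ai[i - 1], bi[j - 1]])
            M[i][j] = (pred[0] + sub, pred[1] + ident, pred[2] + 1, pred[3] + 1)
            X[i][j] = max(
                (
                    (M[i - 1][j][0] - go, M[i - 1][j][1], M[i - 1][j][2] + 1,
                     M[i - 1][j][3] + 1),
                    (X[i - 1][j][0] - ge, X[i - 1][j][1], X[i - 1][j][2] + 1,
                     X[i - 1][j][3] + 1),
                ),
                key=_key,
            )
            Y[i][j] = max(
                (
                    (M[i][j - 1][0] - go, M[i][j - 1][1], M[i][j - 1][2] + 1,
                     M[i][j - 1][3]),
                    (Y[i][j - 1][0] - ge, Y[i][j - 1][1], Y[i][j - 1][2] + 1,
                     Y[i][j - 1][3]),
                ),
                key=_key,
            )
            best = max(best, M[i][j], key=_key)
    return best if best[0] > 0 else (0, 0, 0, 0)


def enumerate_alignments(a: str, b: str, gap_open: int = 11, gap_extend: int = 1):
    """Exponential enumeration of every local alignment of tiny strings.

    Yields (score, matches, columns, query_aligned) for each alignment that
    starts and ends with an aligned (match/mismatch) column, honoring the
    Gotoh transition restriction. Use only for len <= ~6.
    """
    ai = [_AA_INDEX[c] for c in a]
    bi = [_AA_INDEX[c] for c in b]
    go, ge = gap_open + gap_extend, gap_extend

    def walk(i, j, state, s, mt, c, ar):
        # alignment currently ends at (i, j); may stop if in M state
        if state == "M":
            yield (s, mt, c, ar)
        if i < len(ai) and j < len(bi):
            ident = 1 if ai[i] == bi[j] else 0
            yield from walk(i + 1, j + 1, "M",
                            s + int(BLOSUM62[ai[i], bi[j]]), mt + ident,
                            c + 1, ar + 1)
        if i < len(ai) and state in ("M", "X"):
            cost = go if state == "M" else ge
            yield from walk(i + 1, j, "X", s - cost, mt, c + 1, ar + 1)
        if j < len(bi) and state in ("M", "Y"):
            cost = go if state == "M" else ge
            yield from walk(i, j + 1, "Y", s - cost, mt, c, ar)

    for i0 in range(len(ai)):
        for j0 in range(len(bi)):
            ident = 1 if ai[i0] == bi[j0] else 0
            yield from walk(i0 + 1, j0 + 1, "M",
                            int(BLOSUM62[ai[i0], bi[j0]]), ident, 1, 1)


def best_alignment_by_enumeration(a, b, gap_open=11, gap_extend=1):
    best = (0, 0, 0, 0)
    for t in enumerate_alignments(a, b, gap_open, gap_extend):
        best = max(best, t, key=_key)
    return best if best[0] > 0 else (0, 0, 0, 0)


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full enumeration on integer weights.

    All tables with the observed margins whose (exactly computed) point
    probability is <= the observed one contribute.
    """
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        return Fraction(1)
    n = r1 + r2
    ks = range(max(0, c1 - r2), min(r1, c1) + 1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in ks}
    w_obs = weights[a]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), comb(n, c1))


def fitch_oracle(tree, states: dict, alphabet=("LONG", "SHORT")) -> int:
    """Minimum state changes by exhaustive internal-labeling enumeration.

    Tips outside the alphabet are unconstrained (their pendant edges are
    free), which is equivalent to pruning them.
    """
    alpha = list(alphabet)
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    informative = {
        leaf: states[leaf.taxon.label]
        for leaf in tree.leaf_node_iter()
        if states.get(leaf.taxon.label) in set(alpha)
    }
    if len(informative) < 2:
        raise ValueError("need >= 2 informative tips")
    best = None
    for labels in itertools.product(alpha, repeat=len(internal)):
        assign = dict(zip(internal, labels))
        cost = 0
        for nd in internal:
            parent = nd.parent_node
            if parent is not None and assign[parent] != assign[nd]:
                cost += 1
        for leaf, st in informative.items():
            if assign[leaf.parent_node] != st:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best
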