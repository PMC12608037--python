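"""Map cassette states onto a phylogeny: parsimony interspersion statistic,
permutation null, per-phylogroup summary, and iTOL-style annotation export.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

STATE_ALPHABET = ("LONG", "SHORT")

DEFAULT_PALETTE = {
    "LONG": "#1f77b4",
    "SHORT": "#d62728",
    "PARTIAL": "#ff7f0e",
    "NONE": "#7f7f7f",
}


def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string.

    Topology, multifurcations and labels are preserved; duplicate tip labels
    are an error.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and "(" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    return tree


def fitch_transitions(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    alphabet: Sequence[str] = STATE_ALPHABET,
) -> int:
    """Minimum number of state changes explaining the tip states (small
    parsimony, unit cost).

    Tips whose state is outside ``alphabet`` (or missing) are pruned before
    counting. Multifurcations are scored with Hartigan's generalization of
    the Fitch intersection/union rule, which attains the exact minimum on
    arbitrary (non-binary) trees. Fewer than two informative tips is an error.
    """
    alpha = set(alphabet)
    informative = {
        tip: st for tip, st in states.items() if st in alpha
    }
    n_tips = sum(
        1 for leaf in tree.leaf_node_iter()
        if leaf.taxon.label in informative
    )
    if n_tips < 2:
        raise ValueError(
            f"parsimony undefined: {n_tips} informative tip(s) in the alphabet"
        )
    cost = 0

    def visit(node) -> frozenset | None:
        nonlocal cost
        if node.is_leaf():
            st = informative.get(node.taxon.label)
            return frozenset((st,)) if st is not None else None
        child_sets = [s for s in (visit(ch) for ch in node.child_nodes()) if s]
        if not child_sets:
            return None
        if len(child_sets) == 1:
            return child_sets[0]
        votes: dict[str, int] = {}
        for s in child_sets:
            for st in s:
                votes[st] = votes.get(st, 0) + 1
        top = max(votes.values())
        cost += len(child_sets) - top
        return frozenset(st for st, v in votes.items() if v == top)

    visit(tree.seed_node)
    return cost


def permutation_null(
    tree: dendropy.Tree,
    states: Mapping[str, str],
    alphabet: Sequence[str] = STATE_ALPHABET,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Empirical null for the transition count under random tip relabeling.

    Shuffles the observed states among the informative tips. Returns the
    observed count, the permuted counts, and the clustering p-value
    P(perm <= observed) with the +1 small-sample correction — small values
    mean the states are more clade-clustered than random.
    """
    rng = np.random.default_rng(seed)
    alpha = set(alphabet)
    tips = sorted(t for t, s in states.items() if s in alpha)
    values = [states[t] for t in tips]
    observed = fitch_transitions(tree, states, alphabet)
    perm_counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        shuffled = list(values)
        rng.shuffle(shuffled)
        perm_counts[i] = fitch_transitions(
            tree, dict(zip(tips, shuffled)), alphabet
        )
    p_clustering = (1 + int((perm_counts <= observed).sum())) / (n_permutations + 1)
    return {
        "observed": observed,
        "permuted": perm_counts,
        "p_clustering": p_clustering,
        "percentile": float((perm_counts < observed).mean()),
    }


def phylogroup_summary(
    states: Mapping[str, str],
    phylogroups: Mapping[str, str],
) -> list[dict]:
    """Per-phylogroup counts of each cassette state.

    Returns rows (group, n_long, n_short, n_partial, n_none, both_present)
    sorted by group; both_present is true iff the group holds at least one
    LONG and one SHORT strain.
    """
    groups: dict[str, dict[str, int]] = {}
    for strain, state in states.items():
        group = phylogroups.get(strain)
        if group is None:
            continue
        g = groups.setdefault(
            group, {"LONG": 0, "SHORT": 0, "PARTIAL": 0, "NONE": 0}
        )
        g[state] = g.get(state, 0) + 1
    return [
        {
            "group": group,
            "n_long": g["LONG"],
            "n_short": g["SHORT"],
            "n_partial": g["PARTIAL"],
            "n_none": g["NONE"],
            "both_present": g["LONG"] > 0 and g["SHORT"] > 0,
        }
        for group, g in sorted(groups.items())
    ]


def write_phylogroup_summary(rows: Sequence[dict], path: str | Path) -> None:
    lines = ["group\tn_long\tn_short\tn_partial\tn_none\tboth_present"]
    for r in rows:
        lines.append(
            f"{r['group']}\t{r['n_long']}\t{r['n_short']}\t{r['n_partial']}"
            f"\t{r['n_none']}\t{str(r['both_present']).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_itol(
    states: Mapping[str, str],
    palette: Mapping[str, str] | None = None,
    dataset_label: str = "cassette variant",
) -> str:
    """Render a COLORSTRIP-format annotation dataset for the tip states."""
    colors = dict(DEFAULT_PALETTE)
    if palette:
        colors.update(palette)
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#000000",
        "LEGEND_TITLE\tcassette variant",
        "LEGEND_SHAPES\t" + "\t".join("1" for _ in sorted(colors)),
        "LEGEND_COLORS\t" + "\t".join(colors[k] for k in sorted(colors)),
        "LEGEND_LABELS\t" + "\t".join(sorted(colors)),
        "DATA",
    ]
    for tip in sorted(states):
        state = states[tip]
        lines.append(f"{tip}\t{colors.get(state, '#000000')}\t{state}")
    return "\n".join(lines) + "\n"


def read_itol(text: str) -> dict[str, str]:
    """Recover the tip -> state mapping from an exported COLORSTRIP dataset."""
    out: dict[str, str] = {}
    in_data = False
    for line in text.splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if not in_data or not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) >= 3:
            out[parts[0]] = parts[2]
    return out
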