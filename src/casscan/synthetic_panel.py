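"""Seeded synthetic strain panels: tree, genomes with a UOG backbone and a
planted cassette locus, protein divergence, and pathotype labels with a
configurable odds ratio — with full ground-truth bookkeeping.

The cassette state evolves along a Yule tree by a two-parameter Markov
process (LONG<->SHORT switching, absorbing loss). SHORT strains carry only
the four-gene truncated set, written in reversed gene order on the minus
strand when ``invert_short`` (emulating the observed orientation reversal of
the truncated variant). The locus sits strictly between two designated flank
UOGs whose backbone order is identical across strains.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from casscan.cassette_arch import CASSETTE_FAMILIES, SHORT_FAMILIES
from casscan.genome_io import (
    Contig,
    GeneRecord,
    GenomeAnnotation,
    UogTable,
    read_gff3,
    read_metadata,
    read_uog_table,
    write_gff3,
    write_metadata,
    write_uog_table,
)
from casscan.homology import QueryFamilySet
from casscan.phylo_map import read_tree

TRUTH_SCHEMA_VERSION = 1

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticPanelConfig:
    """Generator parameters; every random choice derives from ``seed``."""

    n_strains: int
    seed: int = 0
    n_uogs: int = 238
    protein_length: int = 80
    intergenic_gap: int = 200
    contig_length: int | None = None  # computed from gene content when None
    circular: bool = False
    flank_labels: tuple[str, str] = ("UOG217", "UOG236")
    root_state: str = "LONG"
    switch_prob: float = 0.05  # per-branch LONG<->SHORT
    loss_prob: float = 0.0  # per-branch absorbing loss
    invert_short: bool = True
    divergence: float = 0.05  # per-site protein substitution probability
    target_odds_ratio: float = 1.0
    baseline_pathogenic: float = 0.5  # P(pathogenic | LONG)
    n_phylogroups: int = 8
    clade_split: bool = False  # force a single clean LONG/SHORT clade boundary

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        for name in ("switch_prob", "loss_prob", "divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.target_odds_ratio <= 0:
            raise ValueError("target_odds_ratio must be > 0")
        if not 0.0 < self.baseline_pathogenic < 1.0:
            raise ValueError(
                "infeasible pathotype probabilities: baseline_pathogenic must "
                "lie strictly in (0, 1) for any odds ratio to be realizable"
            )
        if self.root_state not in ("LONG", "SHORT"):
            raise ValueError("root_state must be LONG or SHORT")
        gene_pitch = 3 * self.protein_length + 3 + self.intergenic_gap
        if gene_pitch >= 5000:
            raise ValueError(
                "adjacent cassette gene midpoints would be >= 5000 bp apart; "
                "reduce protein_length or intergenic_gap"
            )
        self.flank_labels = tuple(self.flank_labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticPanelConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class StrainPanel:
    tree: "dendropy.Tree"  # noqa: F821
    newick: str
    genomes: list[GenomeAnnotation]
    uog_table: UogTable
    metadata: dict[str, dict[str, str]]
    truth: dict[str, dict]
    query_families: QueryFamilySet
    config: SyntheticPanelConfig | None = None

    def genome(self, strain_id: str) -> GenomeAnnotation:
        for g in self.genomes:
            if g.strain_id == strain_id:
                return g
        raise KeyError(strain_id)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _yule_newick(n: int, rng: np.random.Generator, birth_rate: float = 1.0) -> str:
    """Pure-birth topology with branch lengths, serialized deterministically."""
    start = {0: 0.0, 1: 0.0}
    end: dict[int, float] = {}
    children: dict[int, tuple[int, int]] = {}
    active = [0, 1]
    next_id = 2
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        end[parent] = t
        c1, c2 = next_id, next_id + 1
        next_id += 2
        start[c1] = start[c2] = t
        children[parent] = (c1, c2)
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for leaf in active:
        end[leaf] = t_end

    label_counter = [0]

    def serialize(node: int) -> str:
        length = end[node] - start[node]
        if node in children:
            c1, c2 = children[node]
            return f"({serialize(c1)},{serialize(c2)}):{length:.6f}"
        label_counter[0] += 1
        return f"S{label_counter[0]:04d}:{length:.6f}"

    c1, c2 = 0, 1
    return f"({serialize(c1)},{serialize(c2)});"


def simulate_tree(n: int, seed: int, birth_rate: float = 1.0):
    """Yule (pure-birth) strain tree with n tips; deterministic per seed."""
    if n < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    newick = _yule_newick(n, rng, birth_rate)
    return read_tree(newick)


def _serialize_tree(tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
    ).strip() + "\n"


# ---------------------------------------------------------------------------
# state evolution and labels
# ---------------------------------------------------------------------------

def _evolve_states(tree, config: SyntheticPanelConfig,
                   rng: np.random.Generator) -> dict[str, str]:
    """Markov switch/loss process from the root state, preorder along the tree."""
    if config.clade_split:
        root_children = tree.seed_node.child_nodes()
        sizes = [len(ch.leaf_nodes()) for ch in root_children]
        short_child = root_children[int(np.argmin(sizes))]
        short_tips = {leaf.taxon.label for leaf in short_child.leaf_iter()}
        return {
            leaf.taxon.label: "SHORT" if leaf.taxon.label in short_tips else "LONG"
            for leaf in tree.leaf_node_iter()
        }
    node_state: dict[int, str] = {id(tree.seed_node): config.root_state}
    states: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = config.root_state
        else:
            state = node_state[id(node.parent_node)]
            if state != "NONE":
                if rng.random() < config.loss_prob:
                    state = "NONE"
                elif rng.random() < config.switch_prob:
                    state = "SHORT" if state == "LONG" else "LONG"
        node_state[id(node)] = state
        if node.is_leaf():
            states[node.taxon.label] = state
    return states


def assign_phylogroups(tree, k: int) -> dict[str, str]:
    """Label the k deepest clades PG1..PGk (split order: shallowest first)."""
    depths = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depths[id(node)] = (depths[id(parent)] + edge) if parent else 0.0

    def min_leaf(node):
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    frontier = [tree.seed_node]
    while len(frontier) < k:
        splittable = [nd for nd in frontier if not nd.is_leaf()]
        if not splittable:
            break
        target = min(splittable, key=lambda nd: (depths[id(nd)], min_leaf(nd)))
        frontier.remove(target)
        frontier.extend(target.child_nodes())
    frontier.sort(key=lambda nd: (depths[id(nd)], min_leaf(nd)))
    out: dict[str, str] = {}
    for i, clade in enumerate(frontier, 1):
        for leaf in clade.leaf_iter():
            out[leaf.taxon.label] = f"PG{i}"
    return out


def _pathotype_probs(config: SyntheticPanelConfig) -> tuple[float, float]:
    """(P(pathogenic|LONG), P(pathogenic|SHORT)) hitting the target OR."""
    p_long = config.baseline_pathogenic
    odds_short = config.target_odds_ratio * p_long / (1.0 - p_long)
    p_short = odds_short / (1.0 + odds_short)
    return p_long, p_short


# ---------------------------------------------------------------------------
# sequences and genomes
# ---------------------------------------------------------------------------

def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA20[i] for i in rng.integers(len(_AA20), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0.0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < divergence)
    for i in hits:
        alternatives = _AA20.replace(chars[i], "")
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _backbone_order(config: SyntheticPanelConfig) -> list[str]:
    labels = [f"UOG{i:03d}" for i in range(1, config.n_uogs + 1)]
    fa, fb = config.flank_labels
    if fa not in labels or fb not in labels:
        raise ValueError(
            f"flank labels {config.flank_labels} not in the UOG label range "
            f"(n_uogs={config.n_uogs})"
        )
    labels.remove(fb)
    labels.insert(labels.index(fa) + 1, fb)
    return labels


def _cassette_genes(state: str, config: SyntheticPanelConfig) -> list[tuple[str, str]]:
    """(family, strand) list in chromosomal order for one strain state."""
    if state == "LONG":
        return [(fam, "+") for fam in CASSETTE_FAMILIES]
    if state == "SHORT":
        short = [fam for fam in CASSETTE_FAMILIES if fam in SHORT_FAMILIES]
        if config.invert_short:
            return [(fam, "-") for fam in reversed(short)]
        return [(fam, "+") for fam in short]
    return []


def simulate_panel(config: SyntheticPanelConfig) -> StrainPanel:
    """Generate a complete panel; byte-deterministic for a fixed config."""
    ss = np.random.SeedSequence(config.seed)
    ss_tree, ss_refs, ss_states, ss_seqs, ss_patho = ss.spawn(5)

    rng_tree = np.random.default_rng(ss_tree)
    newick = _yule_newick(config.n_strains, rng_tree)
    tree = read_tree(newick)
    strains = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())

    rng_refs = np.random.default_rng(ss_refs)
    backbone = _backbone_order(config)
    uog_refs = {lab: _random_protein(config.protein_length, rng_refs)
                for lab in sorted(backbone)}
    family_refs = {fam: _random_protein(config.protein_length, rng_refs)
                   for fam in CASSETTE_FAMILIES}
    query_families = QueryFamilySet(families=dict(family_refs))

    states = _evolve_states(tree, config, np.random.default_rng(ss_states))
    phylogroups = assign_phylogroups(tree, config.n_phylogroups)
    p_long, p_short = _pathotype_probs(config)
    rng_patho = np.random.default_rng(ss_patho)

    seq_children = dict(zip(strains, ss_seqs.spawn(len(strains))))
    flank_a, flank_b = config.flank_labels
    insert_after = backbone.index(flank_a)

    genomes: list[GenomeAnnotation] = []
    uog_entries: list[tuple[str, str, str]] = []
    metadata: dict[str, dict[str, str]] = {}
    truth: dict[str, dict] = {}
    cds_len = 3 * config.protein_length + 3

    for strain in strains:
        state = states[strain]
        rng_seq = np.random.default_rng(seq_children[strain])
        plan: list[tuple[str, str, str]] = []  # (kind, label, strand)
        for idx, lab in enumerate(backbone):
            plan.append(("uog", lab, "+"))
            if idx == insert_after:
                for fam, strand in _cassette_genes(state, config):
                    plan.append(("cassette", fam, strand))
        genes: list[GeneRecord] = []
        contig_id = f"{strain}_chr"
        pos = config.intergenic_gap + 1
        span: list[int] | None = None
        for gi, (kind, label, strand) in enumerate(plan, 1):
            start, endpos = pos, pos + cds_len - 1
            pos = endpos + config.intergenic_gap + 1
            gene_id = f"{strain}_g{gi:04d}"
            ref = uog_refs[label] if kind == "uog" else family_refs[label]
            genes.append(
                GeneRecord(
                    gene_id=gene_id, contig_id=contig_id, start=start,
                    end=endpos, strand=strand,
                    protein_seq=_mutate(ref, config.divergence, rng_seq),
                    product=label,
                )
            )
            if kind == "uog":
                uog_entries.append((strain, gene_id, label))
            else:
                if span is None:
                    span = [start, endpos]
                span[1] = endpos
        length = config.contig_length or (pos - 1)
        if length < pos - 1:
            raise ValueError(
                f"contig_length {config.contig_length} too small for "
                f"{pos - 1} bp of gene content"
            )
        genomes.append(
            GenomeAnnotation(
                strain_id=strain,
                contigs=[Contig(contig_id, length, config.circular)],
                genes=genes,
            )
        )
        p = {"LONG": p_long, "SHORT": p_short}.get(state, p_long)
        pathotype = "pathogenic" if rng_patho.random() < p else "non-pathogenic"
        metadata[strain] = {"phylogroup": phylogroups[strain], "pathotype": pathotype}
        truth[strain] = {
            "variant": state,
            "inverted": state == "SHORT" and config.invert_short,
            "span": list(span) if span else None,
            "flanks": list(config.flank_labels),
        }

    return StrainPanel(
        tree=tree,
        newick=newick if newick.endswith("\n") else newick + "\n",
        genomes=genomes,
        uog_table=UogTable(entries=uog_entries),
        metadata=metadata,
        truth=truth,
        query_families=query_families,
        config=config,
    )


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def panel_to_disk(panel: StrainPanel, out_dir: str | Path) -> None:
    """Write the panel as plain-text files (GFF3 + FASTA per strain, shared
    TSV/Newick/JSON); reading the directory back reproduces the panel."""
    out = Path(out_dir)
    strain_dir = out / "strains"
    strain_dir.mkdir(parents=True, exist_ok=True)
    for genome in panel.genomes:
        write_gff3(
            genome,
            strain_dir / f"{genome.strain_id}.gff3",
            strain_dir / f"{genome.strain_id}.faa",
        )
    write_uog_table(panel.uog_table, out / "uogs.tsv")
    write_metadata(panel.metadata, out / "metadata.tsv")
    (out / "tree.nwk").write_text(panel.newick)
    panel.query_families.to_fasta(out / "queries.faa")
    truth_doc = {"schema_version": TRUTH_SCHEMA_VERSION, "strains": panel.truth}
    (out / "truth.json").write_text(
        json.dumps(truth_doc, indent=2, sort_keys=True) + "\n"
    )
    if panel.config is not None:
        (out / "config.json").write_text(
            json.dumps(asdict(panel.config), indent=2, sort_keys=True) + "\n"
        )


def read_panel(panel_dir: str | Path) -> StrainPanel:
    """Load a panel previously written by :func:`panel_to_disk`."""
    root = Path(panel_dir)
    newick = (root / "tree.nwk").read_text()
    tree = read_tree(newick)
    genomes = []
    for gff in sorted((root / "strains").glob("*.gff3")):
        genomes.append(read_gff3(gff, gff.with_suffix(".faa")))
    truth_doc = json.loads((root / "truth.json").read_text())
    config = None
    config_path = root / "config.json"
    if config_path.exists():
        data = json.loads(config_path.read_text())
        config = SyntheticPanelConfig(**data)
    return StrainPanel(
        tree=tree,
        newick=newick,
        genomes=genomes,
        uog_table=read_uog_table(root / "uogs.tsv"),
        metadata=read_metadata(root / "metadata.tsv"),
        truth=truth_doc["strains"],
        query_families=QueryFamilySet.from_fasta(root / "queries.faa"),
        config=config,
    )
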