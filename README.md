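# casscan

Detection and evolutionary analysis of co-localized bacterial gene cassettes.

Given annotated genomes (GFF3 + protein FASTA, GenBank, or a plain TSV
dialect), a query gene-family set, a universal single-copy ortholog (UOG)
membership table, a Newick phylogeny and strain metadata, `casscan`:

1. assigns genes to query families by protein similarity (internal Gotoh
   local aligner, or imported BLAST-tabular hit tables);
2. clusters co-localized hits into cassettes — two hits are co-localized iff
   their gene midpoints are < 5000 bp apart (single-linkage closure;
   complete linkage available);
3. classifies each cassette as LONG (all ten families
   `ompL, yihO…yihW`), SHORT (`yihT/U/V/W`), PARTIAL or NONE, and defines the
   span from the first gene's start to the last gene's end;
4. anchors each cassette to its nearest flanking UOGs (with circular-contig
   wraparound) and calls orientation/inversion relative to the reference
   long-variant layout;
5. tests cassette type × pathotype association with a from-first-principles
   two-sided Fisher exact test (log-space hypergeometric enumeration) and a
   sample odds ratio with Haldane–Anscombe correction;
6. maps cassette states onto the phylogeny: minimum state-transition count
   (Fitch/Hartigan small parsimony), a permutation null for clade
   clustering, per-phylogroup summaries and iTOL COLORSTRIP export;
7. ships a fully seeded synthetic strain-panel generator (Yule tree, UOG
   backbone, planted cassette locus with state switching/loss and an
   inversion tied to the short state, protein divergence, pathotype labels
   with a configurable odds ratio) with complete ground-truth bookkeeping,
   so every stage is testable offline.

## CLI

```sh
# generate a synthetic panel
casscan simulate --n-strains 60 --seed 7 --out panel/
# or with a YAML config (fields of SyntheticPanelConfig)
casscan simulate --config panel.yaml --out panel/

# detect cassettes
casscan detect --genomes panel/strains --queries panel/queries.faa \
    --uogs panel/uogs.tsv --max-gap 5000 --min-identity 40 \
    --min-coverage 70 --out cassettes.tsv

# genotype-pathotype association
casscan associate --cassettes cassettes.tsv --metadata panel/metadata.tsv \
    --out association.json

# tree annotation + interspersion statistic
casscan annotate-tree --tree panel/tree.nwk --cassettes cassettes.tsv \
    --metadata panel/metadata.tsv --permutations 1000 --seed 17 --out tree_out/
```

## Python API

```python
from casscan import (
    SyntheticPanelConfig, simulate_panel, detect_panel, associate,
    fitch_transitions, permutation_null,
)

panel = simulate_panel(SyntheticPanelConfig(n_strains=60, seed=7,
                                            target_odds_ratio=2.67))
rows = detect_panel(panel.genomes, panel.query_families, panel.uog_table)
result, report = associate(
    {r["strain"]: r["variant"] for r in rows},
    {s: m["pathotype"] for s, m in panel.metadata.items()},
)
```

## Tests and acceptance report

```sh
python -m pytest -q tests/          # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the reproducible headline quantity from
scratch (odds-ratio recovery at the study's design scale over 20 seeded
synthetic panels) and writes it as JSON.

## Conventions

- Coordinates are 1-based inclusive (GFF3). Origin-spanning genes on
  circular contigs use `end < start`; midpoints are unwrapped and reduced
  modulo the contig length. Cassette spans that wrap the origin are reported
  on unwrapped coordinates with a `wraps_origin` flag.
- Aligner: local alignment, BLOSUM62, gap open 11 / extend 1; identity is
  percent identical columns over all alignment columns, coverage is percent
  of the query aligned. Ambiguity between co-optimal alignments is resolved
  by a fixed lexicographic objective, so reported statistics are
  deterministic.
- Default homolog thresholds: identity ≥ 40%, query coverage ≥ 70%
  (config-exposed).
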