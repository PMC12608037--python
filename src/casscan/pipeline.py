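"""End-to-end detection across a strain panel."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from casscan.cassette_arch import (
    CASSETTE_FAMILIES,
    analyze_genome,
    best_context,
    context_row,
)
from casscan.genome_io import GenomeAnnotation, UogTable, read_annotation
from casscan.homology import QueryFamilySet


def detect_panel(
    genomes: Iterable[GenomeAnnotation],
    families: QueryFamilySet,
    uogs: UogTable,
    max_gap: float = 5000,
    thresholds: tuple[float, float] = (40.0, 70.0),
    reference_order: Sequence[str] = CASSETTE_FAMILIES,
    linkage: str = "single",
) -> list[dict]:
    """Run detection on every genome; one cassette_table row per strain.

    The strain-level call is the best-supported cluster (most families, ties
    to the leftmost); strains without any passing hit get a NONE row.
    """
    rows = []
    for genome in genomes:
        results = analyze_genome(
            genome, families, uogs,
            max_gap=max_gap, thresholds=thresholds,
            reference_order=reference_order, linkage=linkage,
        )
        rows.append(context_row(best_context(results), strain_id=genome.strain_id))
    rows.sort(key=lambda r: r["strain"])
    return rows


def variants_from_rows(rows: Iterable[dict]) -> dict[str, str]:
    """strain -> variant map from cassette_table rows."""
    return {r["strain"]: r["variant"] for r in rows}


def load_genome_dir(genome_dir: str | Path) -> list[GenomeAnnotation]:
    """Load every annotation in a directory (GFF3+FASTA, GenBank or TSV)."""
    root = Path(genome_dir)
    genomes = []
    seen = set()
    for path in sorted(root.rglob("*")):
        if path.suffix.lower() in (".gff", ".gff3", ".gb", ".gbk", ".gbff", ".tsv"):
            genome = read_annotation(path)
            if genome.strain_id in seen:
                raise ValueError(f"duplicate strain id {genome.strain_id!r}")
            seen.add(genome.strain_id)
            genomes.append(genome)
    if not genomes:
        raise ValueError(f"no annotation files found under {root}")
    return genomes
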