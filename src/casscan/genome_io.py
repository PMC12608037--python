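"""Genome annotation I/O and coordinate arithmetic on linear and circular contigs.

Coordinates are 1-based inclusive throughout (GFF3 convention). Origin-spanning
genes on circular contigs are represented with ``end < start`` and unwrapped
internally; midpoints are reduced modulo the contig length into ``(0, L]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from Bio import SeqIO

_VALID_STRANDS = ("+", "-")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


class Contig(NamedTuple):
    """Descriptor of one replicon: id, length in bp, and circularity."""

    contig_id: str
    length: int
    circular: bool = False


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene with 1-based inclusive coordinates.

    ``end < start`` is only legal for origin-spanning genes on circular
    contigs; validation of that condition happens in :class:`GenomeAnnotation`
    where the contig descriptor is known.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ParseError(f"gene {self.gene_id!r}: start {self.start} < 1")
        if self.strand not in _VALID_STRANDS:
            raise ParseError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        if self.protein_seq is not None:
            bad = set(self.protein_seq) - _AA_ALPHABET
            if bad:
                raise ParseError(
                    f"gene {self.gene_id!r}: non-amino-acid characters "
                    f"{sorted(bad)} in protein sequence"
                )


@dataclass
class GenomeAnnotation:
    """All annotated genes of one strain, sorted by (contig_id, start)."""

    strain_id: str
    contigs: list[Contig] = field(default_factory=list)
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(
            self.genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id)
        )
        self.validate()

    def validate(self) -> None:
        by_id = {c.contig_id: c for c in self.contigs}
        if len(by_id) != len(self.contigs):
            raise ParseError(f"strain {self.strain_id!r}: duplicated contig ids")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ParseError(
                    f"strain {self.strain_id!r}: duplicated gene id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
            contig = by_id.get(g.contig_id)
            if contig is None:
                raise ParseError(
                    f"gene {g.gene_id!r} references unknown contig {g.contig_id!r}"
                )
            if g.end < g.start and not contig.circular:
                raise ParseError(
                    f"gene {g.gene_id!r}: end {g.end} < start {g.start} "
                    f"on linear contig {g.contig_id!r}"
                )
            if not contig.circular and g.end > contig.length:
                raise ParseError(
                    f"gene {g.gene_id!r}: end {g.end} beyond contig length "
                    f"{contig.length}"
                )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class UogTable:
    """Membership of genes in universal single-copy orthologous groups."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (strain, gene, uog)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for strain, _gene, uog in self.entries:
            key = (strain, uog)
            if key in seen:
                raise ParseError(
                    f"UOG {uog!r} appears more than once in strain {strain!r} "
                    "(single-copy invariant)"
                )
            seen.add(key)

    def for_strain(self, strain_id: str) -> dict[str, str]:
        """gene_id -> uog_id for one strain."""
        return {g: u for s, g, u in self.entries if s == strain_id}


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------

def gene_midpoint(gene: GeneRecord, contig: Contig) -> float:
    """Midpoint genomic position of a gene in bp.

    Linear contigs: ``(start + end) / 2``.  Origin-spanning genes on circular
    contigs (``end < start``) are unwrapped before averaging and the result is
    reduced into ``(0, L]``.
    """
    if gene.contig_id != contig.contig_id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on {gene.contig_id!r}, not "
            f"{contig.contig_id!r}"
        )
    if gene.end < gene.start:
        if not contig.circular:
            raise ValueError(
                f"gene {gene.gene_id!r}: end < start on linear contig"
            )
        mid = (gene.start + gene.end + contig.length) / 2.0
        if mid > contig.length:
            mid -= contig.length
        return mid
    return (gene.start + gene.end) / 2.0


def circular_distance(a: float, b: float, contig: Contig) -> float:
    """Distance between two positions on one contig.

    Linear: ``|a - b|``.  Circular: the shorter way around,
    ``min(|a - b|, L - |a - b|)``.
    """
    d = abs(a - b)
    if contig.circular:
        return min(d, contig.length - d)
    return d


def spans_origin(gene: GeneRecord) -> bool:
    return gene.end < gene.start


def gene_length(gene: GeneRecord, contig: Contig) -> int:
    if spans_origin(gene):
        return contig.length - gene.start + 1 + gene.end
    return gene.end - gene.start + 1


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
    strain_id: str | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 annotation plus optional protein FASTA keyed by gene id.

    CDS features become genes. Contig lengths come from ``##sequence-region``
    directives or ``region`` features; a ``region`` feature carrying
    ``Is_circular=true`` marks the contig circular.
    """
    gff_path = Path(gff_path)
    if strain_id is None:
        strain_id = gff_path.stem
    lengths: dict[str, int] = {}
    circular: dict[str, bool] = {}
    genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            proteins[rec.id] = str(rec.seq)
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            attrs = _parse_gff3_attributes(attrs_s)
            if ftype == "region":
                lengths.setdefault(seqid, int(end_s))
                if attrs.get("Is_circular", "").lower() == "true":
                    circular[seqid] = True
                continue
            if ftype != "CDS":
                continue
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if gene_id is None:
                raise ParseError(f"{gff_path}:{lineno}: CDS without ID attribute")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=int(start_s),
                    end=int(end_s),
                    strand=strand,
                    protein_seq=proteins.get(gene_id),
                    product=attrs.get("product"),
                )
            )
    contigs = [
        Contig(cid, length, circular.get(cid, False))
        for cid, length in sorted(lengths.items())
    ]
    known = {c.contig_id for c in contigs}
    for g in genes:
        if g.contig_id not in known:
            # tolerate missing directives by inferring a linear contig
            end = max(x.end for x in genes if x.contig_id == g.contig_id)
            contigs.append(Contig(g.contig_id, end, False))
            known.add(g.contig_id)
    return GenomeAnnotation(strain_id=strain_id, contigs=sorted(contigs), genes=genes)


def read_genbank(path: str | Path, strain_id: str | None = None) -> GenomeAnnotation:
    """Read CDS features from a GenBank flat file (one or more records)."""
    path = Path(path)
    if strain_id is None:
        strain_id = path.stem
    contigs: list[Contig] = []
    genes: list[GeneRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        is_circ = rec.annotations.get("topology", "linear") == "circular"
        contigs.append(Contig(rec.id, len(rec.seq), is_circ))
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or quals.get("gene", [None])[0]
            )
            if gene_id is None:
                raise ParseError(f"{path}: CDS without locus_tag/protein_id")
            translation = quals.get("translation", [None])[0]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand != -1 else "-",
                    protein_seq=translation,
                    product=quals.get("product", [None])[0],
                )
            )
    return GenomeAnnotation(strain_id=strain_id, contigs=contigs, genes=genes)


_TSV_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "protein_seq"]


def read_tsv_annotation(path: str | Path, strain_id: str | None = None) -> GenomeAnnotation:
    """Read the plain TSV annotation dialect.

    Required columns: gene_id, contig, start, end, strand, protein_seq.
    Optional columns contig_length and circular override the inferred
    (linear, length = max end) contig descriptors.
    """
    path = Path(path)
    if strain_id is None:
        strain_id = path.stem
    genes: list[GeneRecord] = []
    lengths: dict[str, int] = {}
    circular: dict[str, bool] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in _TSV_COLUMNS if c not in header]
                if missing:
                    raise ParseError(f"{path}: missing columns {missing}")
                continue
            row = dict(zip(header, parts))
            seq = row.get("protein_seq", "") or None
            if seq in ("", ".", "NA"):
                seq = None
            genes.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    contig_id=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    protein_seq=seq,
                )
            )
            if row.get("contig_length"):
                lengths[row["contig"]] = int(row["contig_length"])
            if row.get("circular"):
                circular[row["contig"]] = row["circular"].lower() in ("true", "1", "yes")
    contig_ids = sorted({g.contig_id for g in genes} | set(lengths))
    contigs = [
        Contig(
            cid,
            lengths.get(cid, max((g.end for g in genes if g.contig_id == cid), default=0)),
            circular.get(cid, False),
        )
        for cid in contig_ids
    ]
    return GenomeAnnotation(strain_id=strain_id, contigs=contigs, genes=genes)


def read_annotation(
    path: str | Path,
    format: str | None = None,
    fasta_path: str | Path | None = None,
    strain_id: str | None = None,
) -> GenomeAnnotation:
    """Dispatching reader. ``format`` in {gff3, genbank, tsv}; guessed from
    the file extension when omitted."""
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = {
            ".gff": "gff3", ".gff3": "gff3",
            ".gb": "genbank", ".gbk": "genbank", ".gbff": "genbank",
            ".tsv": "tsv", ".txt": "tsv",
        }.get(ext)
        if format is None:
            raise ValueError(f"cannot guess annotation format of {path}")
    if format == "gff3":
        if fasta_path is None:
            for suffix in (".faa", ".fasta", ".fa"):
                cand = path.with_suffix(suffix)
                if cand.exists():
                    fasta_path = cand
                    break
        return read_gff3(path, fasta_path, strain_id)
    if format == "genbank":
        return read_genbank(path, strain_id)
    if format == "tsv":
        return read_tsv_annotation(path, strain_id)
    raise ValueError(f"unknown annotation format {format!r}")


# ---------------------------------------------------------------------------
# annotation writers
# ---------------------------------------------------------------------------

def write_gff3(
    genome: GenomeAnnotation,
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    """Write a GenomeAnnotation as GFF3 (+ sidecar protein FASTA)."""
    lines = ["##gff-version 3"]
    for c in genome.contigs:
        lines.append(f"##sequence-region {c.contig_id} 1 {c.length}")
    for c in genome.contigs:
        attrs = f"ID=region-{c.contig_id}"
        if c.circular:
            attrs += ";Is_circular=true"
        lines.append(
            f"{c.contig_id}\tcasscan\tregion\t1\t{c.length}\t.\t+\t.\t{attrs}"
        )
    for g in genome.genes:
        attrs = f"ID={g.gene_id}"
        if g.product:
            attrs += f";product={g.product}"
        lines.append(
            f"{g.contig_id}\tcasscan\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}"
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for g in genome.genes:
                if g.protein_seq is not None:
                    fh.write(f">{g.gene_id}\n{g.protein_seq}\n")


def write_tsv_annotation(genome: GenomeAnnotation, path: str | Path) -> None:
    header = _TSV_COLUMNS + ["contig_length", "circular"]
    by_id = {c.contig_id: c for c in genome.contigs}
    rows = ["\t".join(header)]
    for g in genome.genes:
        c = by_id[g.contig_id]
        rows.append(
            "\t".join(
                [
                    g.gene_id, g.contig_id, str(g.start), str(g.end), g.strand,
                    g.protein_seq or ".", str(c.length), str(c.circular).lower(),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def read_uog_table(path: str | Path) -> UogTable:
    """TSV with columns strain, gene_id, uog_id (header optional)."""
    entries: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:1] == ["strain"]:
                continue
            if len(parts) < 3:
                raise ParseError(f"{path}: UOG table rows need 3 columns")
            entries.append((parts[0], parts[1], parts[2]))
    return UogTable(entries=entries)


def write_uog_table(table: UogTable, path: str | Path) -> None:
    lines = ["strain\tgene_id\tuog_id"]
    lines += ["\t".join(e) for e in table.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    """Strain metadata TSV: strain, phylogroup, pathotype."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            row = dict(zip(header, parts))
            out[row["strain"]] = {
                "phylogroup": row.get("phylogroup", ""),
                "pathotype": row.get("pathotype", ""),
            }
    return out


def write_metadata(metadata: Mapping[str, Mapping[str, str]], path: str | Path) -> None:
    lines = ["strain\tphylogroup\tpathotype"]
    for strain in sorted(metadata):
        m = metadata[strain]
        lines.append(f"{strain}\t{m['phylogroup']}\t{m['pathotype']}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

CASSETTE_TABLE_COLUMNS = [
    "strain", "contig", "variant", "span_start", "span_end", "orientation",
    "inverted", "families", "upstream_uog", "upstream_gap", "downstream_uog",
    "downstream_gap", "wraps_origin",
]

_CASSETTE_INT_COLS = {"span_start", "span_end", "upstream_gap", "downstream_gap"}
_CASSETTE_BOOL_COLS = {"inverted", "wraps_origin"}


def write_results(objects, kind: str, path: str | Path) -> None:
    """Write result objects of a given kind.

    kinds: ``cassette_table`` / ``synteny_table`` (TSV rows; objects are
    mappings or carry ``to_row()``), ``association`` (JSON mapping), ``itol``
    (pre-rendered annotation text).
    """
    path = Path(path)
    if kind in ("cassette_table", "synteny_table"):
        rows = []
        for obj in objects:
            row = obj.to_row() if hasattr(obj, "to_row") else dict(obj)
            rows.append(row)
        lines = ["\t".join(CASSETTE_TABLE_COLUMNS)]
        for row in rows:
            cells = []
            for col in CASSETTE_TABLE_COLUMNS:
                v = row.get(col)
                if v is None:
                    cells.append(".")
                elif isinstance(v, bool):
                    cells.append(str(v).lower())
                else:
                    cells.append(str(v))
            lines.append("\t".join(cells))
        path.write_text("\n".join(lines) + "\n")
    elif kind == "association":
        path.write_text(json.dumps(objects, indent=2, sort_keys=True) + "\n")
    elif kind == "itol":
        path.write_text(objects if isinstance(objects, str) else "\n".join(objects))
    else:
        raise ValueError(f"unknown result kind {kind!r}")


def read_cassette_table(path: str | Path) -> list[dict]:
    """Read back a cassette_table TSV as typed row dicts."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            row: dict = {}
            for col, cell in zip(header, line.split("\t")):
                if cell == ".":
                    row[col] = None
                elif col in _CASSETTE_INT_COLS:
                    row[col] = int(cell)
                elif col in _CASSETTE_BOOL_COLS:
                    row[col] = cell == "true"
                else:
                    row[col] = cell
            rows.append(row)
    return rows


def write_bed(rows: Iterable[Mapping], path: str | Path) -> None:
    """Optional BED export of cassette spans (0-based half-open)."""
    lines = []
    for row in rows:
        if row.get("span_start") is None:
            continue
        lines.append(
            f"{row['contig']}\t{row['span_start'] - 1}\t{row['span_end']}"
            f"\t{row['strain']}:{row['variant']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
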