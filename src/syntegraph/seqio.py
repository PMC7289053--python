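"""Readers/writers for on-disk formats and assembly of annotated genomes.

Formats handled here: protein FASTA, BED6, GFF3 (gene features), 12-column
blast-tabular hit files, generic schema'd TSV tables, and Newick trees.
Every writer/reader pair is a lossless round trip for the dialect the
pipeline emits.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")


@dataclass
class GeneRecord:
    """One gene: coordinates on a chromosome plus its protein sequence.

    Coordinates are 0-based half-open throughout (BED convention); GFF3
    input is converted on load. ``ordinal`` is the rank of the gene's start
    coordinate on its chromosome and is the coordinate system used by
    collinearity chaining.
    """

    gene_id: str
    genome_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein: str
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein")


@dataclass
class AnnotatedGenome:
    """Ordered genes on chromosomes; the unit every pipeline stage consumes."""

    genome_id: str
    chromosomes: dict[str, list[GeneRecord]] = field(default_factory=dict)
    n_dropped: int = 0

    @classmethod
    def from_records(cls, genome_id: str, records: Iterable[GeneRecord],
                     n_dropped: int = 0) -> "AnnotatedGenome":
        """Group records by chromosome, sort by start, assign ordinals."""
        chroms: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicated gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)
            chroms.setdefault(rec.chrom, []).append(rec)
        for chrom in chroms:
            chroms[chrom].sort(key=lambda r: (r.start, r.end, r.gene_id))
            for i, rec in enumerate(chroms[chrom]):
                rec.ordinal = i
        ordered = {c: chroms[c] for c in sorted(chroms)}
        return cls(genome_id=genome_id, chromosomes=ordered, n_dropped=n_dropped)

    def genes(self) -> Iterator[GeneRecord]:
        for chrom in self.chromosomes.values():
            yield from chrom

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def gene_map(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes()}


# ---------------------------------------------------------------------------
# FASTA / BED / GFF3


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence dict (order preserved)."""
    seqs: dict[str, str] = {}
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicated FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        _BioSeqIO.write(records, fh, "fasta")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read BED6 rows as (chrom, start, end, name, strand)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            rows.append((chrom, int(start), int(end), name, strand))
    return rows


def write_bed6(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genome.genes():
            fh.write(
                f"{gene.chrom}\t{gene.start}\t{gene.end}\t{gene.gene_id}"
                f"\t0\t{gene.strand}\n"
            )


_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gff3_genes(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Extract gene rows from GFF3 as (chrom, start0, end, name, strand).

    GFF3 is 1-based inclusive; starts are shifted to 0-based half-open.
    Uses ``gene`` features, falling back to ``mRNA`` when no gene rows
    exist; records are keyed by the ID attribute, then Name.
    """
    by_type: dict[str, list[tuple[str, int, int, str, str]]] = {"gene": [], "mRNA": []}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in by_type:
                continue
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            name = attr.get("ID") or attr.get("Name")
            if name is None:
                raise ValueError(f"{path}:{ln}: feature without ID or Name")
            by_type[ftype].append((chrom, int(start) - 1, int(end), name, strand))
    return by_type["gene"] if by_type["gene"] else by_type["mRNA"]


def load_genome(fasta_path: str | Path, annot_path: str | Path,
                genome_id: str) -> AnnotatedGenome:
    """Reconcile a protein FASTA with a BED6 or GFF3 annotation.

    Genes present in only one of the two files are dropped with a logged
    warning; the count is exposed as ``AnnotatedGenome.n_dropped``. Zero
    reconciled genes or duplicated ids are fatal.
    """
    seqs = read_fasta(fasta_path)
    annot_path = Path(annot_path)
    if annot_path.suffix.lower() in (".gff", ".gff3"):
        annot = read_gff3_genes(annot_path)
    else:
        annot = read_bed6(annot_path)
    annot_ids = [name for _, _, _, name, _ in annot]
    if len(annot_ids) != len(set(annot_ids)):
        dupes = sorted({n for n in annot_ids if annot_ids.count(n) > 1})
        raise ValueError(f"duplicated gene ids in {annot_path}: {dupes[:5]}")

    records = []
    matched = set()
    for chrom, start, end, name, strand in annot:
        if name in seqs:
            matched.add(name)
            records.append(GeneRecord(
                gene_id=name, genome_id=genome_id, chrom=chrom,
                start=start, end=end, strand=strand, protein=seqs[name],
            ))
    n_dropped = (len(seqs) - len(matched)) + (len(annot) - len(matched))
    if n_dropped:
        logger.warning("genome %s: dropped %d unreconciled gene(s)",
                       genome_id, n_dropped)
    if not records:
        raise ValueError(
            f"genome {genome_id}: no genes reconciled between "
            f"{fasta_path} and {annot_path}"
        )
    return AnnotatedGenome.from_records(genome_id, records, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# Schema'd TSV tables

#: 12-column blast-tabular dialect (outfmt 6).
HIT_SCHEMA = {
    "query": str, "subject": str, "pct_identity": float, "aln_len": int,
    "mismatch": int, "gapopen": int, "qstart": int, "qend": int,
    "sstart": int, "send": int, "evalue": float, "score": float,
}

#: Synteny-network edge list.
EDGE_SCHEMA = {"gene_a": str, "gene_b": str, "block_id": str}

#: Community membership.
COMMUNITY_SCHEMA = {"gene_id": str, "community_id": str}


def write_table(rows: Sequence[dict], schema: dict[str, type],
                path: str | Path) -> None:
    """Write rows under a fixed column schema; blast-tabular style floats
    are emitted with repr so they round-trip exactly."""
    cols = list(schema)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            for col in cols:
                if col not in row:
                    raise ValueError(f"row missing column {col!r}")
            fh.write("\t".join(_fmt_cell(row[c], schema[c]) for c in cols) + "\n")


def _fmt_cell(value, typ) -> str:
    if typ is float:
        return repr(float(value))
    return str(value)


def read_table(path: str | Path, schema: dict[str, type]) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in schema:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rows = []
    for rec in df.to_dict("records"):
        out = {}
        for col, typ in schema.items():
            try:
                out[col] = typ(rec[col])
            except ValueError as exc:
                raise ValueError(f"{path}: bad value in column {col!r}") from exc
        rows.append(out)
    return rows


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_str: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (file path or literal string)."""
    s = str(path_or_str)
    if "(" not in s:
        s = Path(path_or_str).read_text()
    _check_parens(s)
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc
    return tree


def _check_parens(s: str) -> None:
    depth = 0
    for pos, ch in enumerate(s):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {pos}")
    if depth != 0:
        raise ValueError(f"unbalanced '(': {depth} unclosed at end of input")


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True,
    ).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
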