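"""Sequence, annotation-table and tree input/output.

All genomic coordinates are 0-based half-open internally; the loci table on
disk uses 1-based inclusive coordinates (NCBI viewer convention) and is
converted on read/write. Minus-strand loci are handled downstream by
reverse-complementing extracted windows so that "upstream" always means 5'
of the coding strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
GAP = "-"


class FormatError(ValueError):
    """Malformed input file."""


class AlphabetError(ValueError):
    """Residue outside the declared alphabet."""


class CoordinateError(ValueError):
    """Locus coordinates inconsistent or outside the contig."""


@dataclass
class SequenceRecord:
    """A named sequence (DNA or protein, optionally gapped when aligned)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=str(Seq(self.residues).reverse_complement()),
            description=self.description,
        )


@dataclass
class GeneLocus:
    """One annotated gene occurrence on a contig, with flanking-gene context.

    ``start``/``end`` are 0-based half-open on the forward strand of
    ``contig``. ``host_gene`` is set when the locus lies inside an intron of
    another gene (a hallmark of several scattered IFITM retrocopies).
    """

    locus_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    gene_name: str
    exon_count: Optional[int] = None
    upstream_gene: Optional[str] = None
    downstream_gene: Optional[str] = None
    host_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"locus {self.locus_id}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"locus {self.locus_id}: bad strand {self.strand!r}")


@dataclass
class Msa:
    """A multiple sequence alignment: >=2 equal-length gapped records."""

    records: list
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_cols(self) -> int:
        return len(self.records[0].residues)

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.records)


def _check_alphabet(rec: SequenceRecord, alphabet: str) -> None:
    if alphabet == "auto":
        return
    allowed = (DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET) | {GAP}
    for pos, ch in enumerate(rec.residues, start=1):
        if ch not in allowed:
            raise AlphabetError(
                f"record {rec.id!r}: illegal {alphabet} residue {ch!r} "
                f"at position {pos}"
            )


def read_fasta(path, alphabet: str = "auto") -> list:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased; CRLF line endings are tolerated; input order is
    preserved. ``alphabet`` may be ``dna``, ``protein`` or ``auto`` (no
    validation).
    """
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        out = SequenceRecord(
            id=rec.id,
            residues=str(rec.seq).upper(),
            description=rec.description,
        )
        _check_alphabet(out, alphabet)
        records.append(out)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


LOCI_COLUMNS = [
    "locus_id",
    "species",
    "contig",
    "start",
    "end",
    "strand",
    "gene_name",
    "exon_count",
    "upstream_gene",
    "downstream_gene",
    "host_gene",
]


def read_loci_table(path) -> list:
    """Read the TSV gene-loci annotation table.

    On-disk coordinates are 1-based inclusive and converted to 0-based
    half-open; blank optional fields become ``None``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty loci table")
    header = lines[0].split("\t")
    if header != LOCI_COLUMNS:
        raise FormatError(
            f"{path}: bad header {header!r}, expected {LOCI_COLUMNS!r}"
        )
    loci = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(LOCI_COLUMNS):
            raise FormatError(f"{path}: row has {len(f)} fields: {ln!r}")
        row = dict(zip(LOCI_COLUMNS, f))
        start1, end1 = int(row["start"]), int(row["end"])
        start0, end0 = start1 - 1, end1
        if start0 >= end0:
            raise CoordinateError(
                f"locus {row['locus_id']}: start {start1} >= end {end1}"
            )
        opt = lambda v: v if v.strip() else None
        exon = row["exon_count"].strip()
        loci.append(
            GeneLocus(
                locus_id=row["locus_id"],
                species=row["species"],
                contig=row["contig"],
                start=start0,
                end=end0,
                strand=row["strand"],
                gene_name=row["gene_name"],
                exon_count=int(exon) if exon else None,
                upstream_gene=opt(row["upstream_gene"]),
                downstream_gene=opt(row["downstream_gene"]),
                host_gene=opt(row["host_gene"]),
            )
        )
    return loci


def write_loci_table(loci: Iterable[GeneLocus], path) -> None:
    """Write loci back to 1-based inclusive TSV (inverse of read_loci_table)."""
    with open(path, "w") as fh:
        fh.write("\t".join(LOCI_COLUMNS) + "\n")
        for lo in loci:
            fh.write(
                "\t".join(
                    [
                        lo.locus_id,
                        lo.species,
                        lo.contig,
                        str(lo.start + 1),
                        str(lo.end),
                        lo.strand,
                        lo.gene_name,
                        "" if lo.exon_count is None else str(lo.exon_count),
                        lo.upstream_gene or "",
                        lo.downstream_gene or "",
                        lo.host_gene or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def read_newick(text_or_path, from_path: bool = False) -> dendropy.Tree:
    """Parse a Newick string (or file) into a dendropy Tree.

    Internal-node labels are interpreted as bootstrap support values.
    """
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if from_path:
        tree = dendropy.Tree.get(path=str(text_or_path), **kwargs)
    else:
        tree = dendropy.Tree.get(data=text_or_path, **kwargs)
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a dendropy tree to Newick, supports as internal labels.

    Round-trips with :func:`read_newick` to the same topology and branch
    lengths (1e-9).
    """
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_internal_node_labels=False,
        ).strip()
    )


def write_tsv(rows: list, columns: list, path) -> None:
    """Write a list of dicts as a TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join("" if row.get(c) is None else str(row.get(c)) for c in columns)
                + "\n"
            )
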