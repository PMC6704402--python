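"""Readers and writers for the standard formats the pipeline touches.

Strict dialects: every reader rejects malformed input rather than repairing
it, and every writer emits text the matching reader parses back losslessly.

Coordinate conventions
----------------------
Internally everything is 0-based half-open, with one exception:
:class:`VariantRecord.pos` stays 1-based to match VCF.  GFF3 (1-based
inclusive) is converted on read and back on write; conversions happen only
in this module.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "GeneModel",
    "VariantRecord",
    "SupportTree",
    "OrthoTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "write_newick",
    "read_orthotable",
    "write_orthotable",
    "write_partitions",
    "read_partitions",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "read_bedgraph",
    "read_counts",
    "write_counts",
]

NT_CHARS = frozenset("ACGTN")
# 20 canonical amino acids plus ambiguity codes, selenocysteine/pyrrolysine,
# stop '*' and alignment gap '-'.
AA_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class FormatError(ValueError):
    """Raised when a file violates the documented dialect."""


# ---------------------------------------------------------------------------
# sequence records


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (nucleotide or amino acid), uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def _validate_alphabet(rec: SeqRecord, alphabet: str) -> None:
    if alphabet == "nt":
        allowed = NT_CHARS
    elif alphabet == "aa":
        allowed = AA_CHARS
    elif alphabet == "auto":
        allowed = NT_CHARS | AA_CHARS
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    bad = set(rec.seq) - allowed
    if bad:
        raise FormatError(
            f"record {rec.id!r} contains characters {sorted(bad)} not in "
            f"{alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Order is preserved, sequences are uppercased and line wrapping is
    ignored.  Duplicate ids and empty records are hard errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FormatError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        rec = SeqRecord(id=bio.id, seq=str(bio.seq).upper())
        _validate_alphabet(rec, alphabet)
        records.append(rec)
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    recs = list(records)
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate ids among records to write")
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in recs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# newick trees with support values


@dataclass
class SupportTree:
    """A leaf-labelled tree whose internal-node labels are bootstrap supports.

    Supports are numbers in [0, 100] read from the internal-node label
    position (the dialect emitted by IQ-TREE/UFBoot and RAxML); unlabeled
    internal nodes carry no support.
    """

    tree: dendropy.Tree

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def support_of(self, node: dendropy.Node) -> float | None:
        if node.label is None:
            return None
        return float(node.label)

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s


def _validate_supports(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            val = float(node.label)
        except ValueError:
            raise FormatError(
                f"internal node label {node.label!r} is not a numeric support"
            ) from None
        if not 0.0 <= val <= 100.0:
            raise FormatError(f"support {val} outside [0, 100]")
        # canonicalize: integral supports print without decimal point
        node.label = f"{val:g}"


def parse_newick(text: str) -> SupportTree:
    """Parse a newick string; supports read from internal-node labels.

    Raises :class:`FormatError` with a character position on malformed input.
    """
    if not text.strip().endswith(";"):
        raise FormatError(
            f"newick string must end with ';' (at offset {len(text.rstrip())})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        col = getattr(exc, "col_num", None)
        where = f" at offset {col}" if col is not None else ""
        raise FormatError(f"newick parse error{where}: {exc}") from None
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf names {dup}")
    _validate_supports(tree)
    return SupportTree(tree=tree)


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# OrthoFinder Orthogroups.tsv dialect


@dataclass
class OrthoTable:
    """Orthogroup membership: og_id -> taxon -> list of protein ids.

    The taxon set is identical across rows; an absent taxon holds an empty
    list.  Protein ids are unique within a row.
    """

    taxa: list[str]
    rows: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        for og_id, row in self.rows.items():
            if set(row) != set(self.taxa):
                raise FormatError(f"row {og_id} taxon set differs from header")
            prots = [p for ps in row.values() for p in ps]
            if len(set(prots)) != len(prots):
                raise FormatError(f"duplicate protein ids in row {og_id}")

    @property
    def og_ids(self) -> list[str]:
        return list(self.rows)


def read_orthotable(path: str | Path) -> OrthoTable:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    Header row of taxon names (first column is the orthogroup id column);
    cells are comma+space separated protein lists, empty cell = absent taxon.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path} is empty")
    header = lines[0].split("\t")
    taxa = header[1:]
    if not taxa:
        raise FormatError("orthotable header has no taxon columns")
    n_cols = len(header)
    rows: dict[str, dict[str, list[str]]] = {}
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise FormatError(
                f"ragged row {i}: {len(cells)} columns, expected {n_cols}"
            )
        og_id = cells[0]
        if og_id in rows:
            raise FormatError(f"duplicate orthogroup id {og_id!r} at row {i}")
        rows[og_id] = {
            t: ([] if cell == "" else cell.split(", "))
            for t, cell in zip(taxa, cells[1:])
        }
    return OrthoTable(taxa=taxa, rows=rows)


def write_orthotable(table: OrthoTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.taxa) + "\n")
        for og_id, row in table.rows.items():
            cells = [", ".join(row[t]) for t in table.taxa]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# RAxML-style partition files

_PARTITION_RE = re.compile(r"^(\S+),\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)$")


def write_partitions(
    blocks: Sequence[tuple[str, int, int]],
    path: str | Path,
    model: str = "WAG",
) -> None:
    """Write RAxML-style partition lines ``MODEL, name = start-end``.

    ``blocks`` are (name, start, end) with 1-based inclusive coordinates,
    contiguous and ascending.  A gap or overlap between consecutive blocks
    is an error.
    """
    if not blocks:
        raise FormatError("no partition blocks to write")
    prev_end = blocks[0][1] - 1
    for name, start, end in blocks:
        if start > end:
            raise FormatError(f"block {name}: start {start} > end {end}")
        if start != prev_end + 1:
            raise FormatError(
                f"block {name} starts at {start}, expected {prev_end + 1} "
                "(gap or overlap between blocks)"
            )
        prev_end = end
    with open(path, "w") as fh:
        for name, start, end in blocks:
            fh.write(f"{model}, {name} = {start}-{end}\n")


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    blocks: list[tuple[str, int, int]] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        m = _PARTITION_RE.match(line.strip())
        if not m:
            raise FormatError(f"malformed partition line {i}: {line!r}")
        _, name, start, end = m.groups()
        blocks.append((name, int(start), int(end)))
    return blocks


# ---------------------------------------------------------------------------
# minimal VCF subset


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant observation.

    ``pos`` is 1-based (VCF convention).  Only depth and alt-read count are
    modelled; all other VCF fields are ignored, never required.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    coverage: int
    alt_count: int
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.coverage < 1:
            raise FormatError(f"coverage {self.coverage} < 1 at {self.contig}:{self.pos}")
        if not 0 <= self.alt_count <= self.coverage:
            raise FormatError(
                f"alt_count {self.alt_count} outside [0, coverage={self.coverage}] "
                f"at {self.contig}:{self.pos}"
            )
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise FormatError(
                f"only single-base SNVs supported, got {self.ref}>{self.alt} "
                f"at {self.contig}:{self.pos}"
            )

    @property
    def frequency(self) -> float:
        return self.alt_count / self.coverage


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a minimal VCF: CHROM, POS, REF, ALT plus DP/AD depth fields.

    Depth is taken from the first sample's DP/AD when a sample column is
    present, otherwise from INFO DP/AD.  Multi-allelic or non-SNV records
    are rejected.
    """
    import pysam

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"record at {rec.chrom}:{rec.pos} is not a biallelic SNV"
                )
            dp = ad = None
            if rec.samples:
                smp = rec.samples[0]
                dp = smp.get("DP")
                ad = smp.get("AD")
            if dp is None:
                dp = rec.info.get("DP")
            if ad is None:
                ad = rec.info.get("AD")
            if dp is None or ad is None:
                raise FormatError(
                    f"record at {rec.chrom}:{rec.pos} lacks DP/AD depth fields"
                )
            alt_count = ad[1] if isinstance(ad, (tuple, list)) else int(ad)
            # htslib stores QUAL as float32; round back to printed precision
            qual = round(float(rec.qual), 4) if rec.qual is not None else None
            records.append(
                VariantRecord(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    coverage=int(dp),
                    alt_count=int(alt_count),
                    quality=qual,
                )
            )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as a minimal single-sample VCF v4.2 text file."""
    contigs: dict[str, int] = {}
    for r in records:
        contigs[r.contig] = max(contigs.get(r.contig, 0), r.pos + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n"
        )
        for r in records:
            qual = "." if r.quality is None else f"{r.quality:g}"
            fh.write(
                f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t"
                f"DP={r.coverage}\tDP:AD\t{r.coverage}:"
                f"{r.coverage - r.alt_count},{r.alt_count}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 gene models


@dataclass
class GeneModel:
    """A stranded gene model with exons and an optional 3'-UTR.

    Intervals are 0-based half-open on the contig; exons sorted and
    non-overlapping; the 3'-UTR lies within the gene span.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise FormatError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def three_prime_end(self) -> int:
        """Position of the 3' terminus (0-based; the last transcribed base+1
        on '+', the first transcribed base on '-')."""
        return self.span[1] if self.strand == "+" else self.span[0]


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/exon/three_prime_UTR features) from GFF3.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        utrs = [
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="three_prime_UTR")
        ]
        utr3 = None
        if utrs:
            utr3 = (min(s for s, _ in utrs), max(e for _, e in utrs))
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                exons=exons,
                utr3=utr3,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (1-based inclusive), losslessly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g0, g1 = m.span
            if m.utr3 is not None:
                g0 = min(g0, m.utr3[0])
                g1 = max(g1, m.utr3[1])
            fh.write(
                f"{m.contig}\tglaucokit\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{m.contig}\tglaucokit\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.contig}\tglaucokit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}.t1\n"
                )
            if m.utr3 is not None:
                s, e = m.utr3
                fh.write(
                    f"{m.contig}\tglaucokit\tthree_prime_UTR\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.gene_id}.utr3;Parent={m.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# bedGraph coverage and count matrices


def read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Expand a bedGraph file into a per-base coverage array of ``length``."""
    cov = np.zeros(length, dtype=float)
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"malformed bedGraph line {i}: {line!r}")
        _, start, end, value = parts
        s, e = int(start), int(end)
        if not 0 <= s < e <= length:
            raise FormatError(f"bedGraph interval [{s},{e}) outside [0,{length})")
        cov[s:e] = float(value)
    return cov


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise FormatError("negative counts in matrix")
    if df.index.duplicated().any():
        raise FormatError("duplicate gene ids in count matrix")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
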