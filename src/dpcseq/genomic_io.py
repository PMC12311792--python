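"""Readers and writers for the genomic formats the pipeline touches.

Every coordinate in the package is 0-based, half-open (BED-native):
``start`` is the first base included, ``end`` the first base excluded.
Readers validate and reject malformed input with the offending line number;
they never silently repair. Files ending in ``.gz`` are read and written
through gzip transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} [{loc}]" if loc else message)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` with optional label and score."""

    chrom: str
    start: int
    end: int
    label: str | None = None
    score: float | None = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its strand, transcription start site and expression level.

    ``tss`` is the 0-based position of the transcription start site; for a
    plus-strand gene the body spans ``[tss, tss + length)``, for a
    minus-strand gene ``(tss - length, tss]`` i.e. ``[tss - length + 1,
    tss + 1)`` half-open. ``fpkm`` is the polyA+ RNA-seq expression value
    used to build the Q0-Q4 strata.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    length: int
    fpkm: float

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.fpkm < 0:
            raise ValueError(f"fpkm must be >= 0, got {self.fpkm}")
        if self.length <= 0:
            raise ValueError(f"gene length must be positive, got {self.length}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the gene body (half-open)."""
        return self.tss if self.strand == "+" else max(0, self.tss - self.length + 1)

    @property
    def end(self) -> int:
        return self.tss + self.length if self.strand == "+" else self.tss + 1


@dataclass
class ChromatinSegmentation:
    """Genome partition into labeled chromatin-state blocks.

    Within each chromosome the blocks are sorted, non-overlapping and cover
    the chromosome contiguously from 0 to its length, so state base counts
    sum exactly to the genome size.
    """

    intervals: list[GenomicInterval]
    state_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.state_set:
            self.state_set = frozenset(iv.label for iv in self.intervals)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            if iv.label is None:
                raise ValueError("segmentation interval lacks a state label")
            if iv.label not in self.state_set:
                raise ValueError(f"label {iv.label!r} not in state set")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            prev_end = 0
            for iv in ivs:
                if iv.start != prev_end:
                    raise ValueError(
                        f"segmentation not contiguous on {chrom}: "
                        f"expected start {prev_end}, got {iv.start}"
                    )
                prev_end = iv.end
        self._by_chrom = by_chrom

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: ivs[-1].end for c, ivs in self._by_chrom.items()}

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def state_bases(self) -> dict[str, int]:
        """Total bases covered by each state (zero for states never placed)."""
        bases = {s: 0 for s in self.state_set}
        for iv in self.intervals:
            bases[iv.label] += len(iv)
        return bases


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# BED

def read_bed(path, expected_columns: int | None = None) -> list[GenomicInterval]:
    """Parse a BED3/4/6 file into intervals, preserving order.

    Column 4 becomes ``label``, column 5 ``score``. Blank lines and lines
    starting with ``#``, ``track`` or ``browser`` are skipped.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"BED line has {len(fields)} columns, need >= 3", path, lineno
                )
            if expected_columns is not None and len(fields) < expected_columns:
                raise FormatError(
                    f"expected {expected_columns} columns, found {len(fields)}",
                    path,
                    lineno,
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", path, lineno)
            label = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise FormatError(f"non-numeric score {fields[4]!r}", path, lineno)
            try:
                intervals.append(GenomicInterval(chrom, start, end, label, score))
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno)
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.score is not None:
                fields.append(iv.label if iv.label is not None else ".")
            if iv.score is not None:
                fields.append(format(iv.score, "g"))
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# Gene tables

GENE_TABLE_COLUMNS = ("gene_id", "chrom", "strand", "tss", "length", "fpkm")


def read_gene_table(path) -> list[GeneModel]:
    """Read a tab-separated gene table with header ``gene_id chrom strand tss
    length fpkm``; gene ids must be unique."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENE_TABLE_COLUMNS:
            raise FormatError(
                f"gene table header must be {list(GENE_TABLE_COLUMNS)}, got {header}",
                path,
                1,
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise FormatError(
                    f"expected {len(GENE_TABLE_COLUMNS)} columns, found {len(fields)}",
                    path,
                    lineno,
                )
            gene_id, chrom, strand, tss, length, fpkm = fields
            if gene_id in seen:
                raise FormatError(f"duplicated gene_id {gene_id!r}", path, lineno)
            seen.add(gene_id)
            try:
                genes.append(
                    GeneModel(gene_id, chrom, strand, int(tss), int(length), float(fpkm))
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.length}\t"
                f"{format(g.fpkm, 'g')}\n"
            )


# --------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into ``{name: sequence}`` with sequences uppercased.

    Rejects duplicate record names, empty sequences, and characters outside
    the ACGTN alphabet.
    """
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise FormatError(f"duplicate FASTA name {record.id!r}", path)
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for record {record.id!r}", path)
            bad = set(seq) - NUCLEOTIDES
            if bad:
                raise FormatError(
                    f"non-nucleotide characters {sorted(bad)} in record {record.id!r}",
                    path,
                )
            sequences[record.id] = seq
    if not sequences:
        raise FormatError("no FASTA records found", path)
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read FASTQ as ``(name, sequence)`` pairs; qualities are discarded."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write reads as FASTQ with a uniform Phred quality."""
    with _open_text(path, "wt") as fh:
        for name, seq in reads:
            qual = chr(quality + 33) * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track, path, merge_runs: bool = True) -> None:
    """Write a binned coverage track as bedGraph rows ``chrom start end value``.

    With ``merge_runs`` adjacent bins holding the same value are collapsed
    into one row (run-length encoding), the convention genome browsers use.
    """
    with _open_text(path, "wt") as fh:
        for chrom in track.values:
            vals = track.values[chrom]
            bs = track.bin_size
            n = len(vals)
            i = 0
            while i < n:
                j = i + 1
                if merge_runs:
                    while j < n and vals[j] == vals[i]:
                        j += 1
                start = i * bs
                end = min(j * bs, track.chrom_sizes[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{format(float(vals[i]), 'g')}\n")
                i = j


def read_bedgraph(path) -> list[GenomicInterval]:
    """Read bedGraph rows back as score-carrying intervals."""
    rows = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(
                    f"bedGraph needs 4 columns, found {len(fields)}", path, lineno
                )
            try:
                rows.append(
                    GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), None, float(fields[3])
                    )
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno)
    return rows


# --------------------------------------------------------------------------
# Ct tables

CT_COLUMNS = ("locus", "genotype", "replicate", "ct_T", "ct_R")


def read_ct_csv(path):
    """Read a qPCR cycle-threshold table (CSV with columns locus, genotype,
    replicate, ct_T, ct_R) into :class:`~dpcseq.removal_stats.CtRecord`."""
    from dpcseq.removal_stats import CtRecord

    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if tuple(header) != CT_COLUMNS:
            raise FormatError(
                f"Ct table header must be {list(CT_COLUMNS)}, got {header}", path, 1
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(",")
            if len(fields) != len(CT_COLUMNS):
                raise FormatError(
                    f"expected {len(CT_COLUMNS)} columns, found {len(fields)}",
                    path,
                    lineno,
                )
            locus, genotype, replicate, ct_t, ct_r = fields
            try:
                records.append(
                    CtRecord(locus, genotype, int(replicate), float(ct_t), float(ct_r))
                )
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno)
    return records


def write_ct_csv(records, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(",".join(CT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.locus},{r.genotype},{r.replicate},"
                f"{format(r.ct_T, '.6g')},{format(r.ct_R, '.6g')}\n"
            )
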