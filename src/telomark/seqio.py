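"""Streaming readers for FASTQ and SAM/BAM and small writers.

All streams are single-pass generators: memory stays constant in the number
of records. Cell barcodes come either from a dedicated barcode read file,
from the leading k bases of a named read, or from alignment tags (default
``CB``, falling back to ``CR`` on request). Unmapped alignment records are
always traversed — telomere-like reads typically do not align.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence

import pysam


class FastqParseError(ValueError):
    """Malformed or truncated FASTQ; carries the 1-based line number."""

    def __init__(self, message: str, path: str, line: int):
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


class PairingError(ValueError):
    """Paired FASTQ files with different record counts."""


@dataclass
class SequencingRecord:
    read_id: str
    sequence: str
    mate_sequence: Optional[str] = None
    barcode: Optional[str] = None
    contig: Optional[str] = None
    quality: Optional[str] = None
    is_secondary: bool = False
    is_supplementary: bool = False
    is_duplicate: bool = False
    is_unmapped: bool = True


@dataclass(frozen=True)
class BarcodeSource:
    """Where per-fragment cell barcodes come from.

    kind "none": no barcodes; "file": a separate barcode read file whose i-th
    record carries the i-th fragment's barcode; "prefix": the leading
    ``length`` bases of the read named by ``read`` ("r1" or "r2").
    """

    kind: str = "none"
    path: Optional[str] = None
    read: str = "r1"
    length: int = 16

    def __post_init__(self) -> None:
        if self.kind not in ("none", "file", "prefix"):
            raise ValueError(f"unknown barcode source kind {self.kind!r}")
        if self.kind == "file" and not self.path:
            raise ValueError("barcode source 'file' requires a path")


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    raw = path.open("rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return _io.TextIOWrapper(raw, encoding="ascii")


def _fastq_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from a possibly-gzipped FASTQ file."""
    lineno = 0
    with _open_text(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError("expected '@' header", str(path), lineno)
            block = [handle.readline() for _ in range(3)]
            if any(not line for line in block):
                raise FastqParseError(
                    "truncated record (not a multiple of 4 lines)", str(path), lineno
                )
            seq, plus, qual = (line.rstrip("\n") for line in block)
            lineno += 3
            if not plus.startswith("+"):
                raise FastqParseError("expected '+' separator", str(path), lineno - 1)
            if len(qual) != len(seq):
                raise FastqParseError("quality length differs from sequence length", str(path), lineno)
            yield header[1:].split()[0], seq, qual


def read_fastq(
    r1: str | Path,
    r2: str | Path | None = None,
    barcode_source: BarcodeSource | None = None,
) -> Iterator[SequencingRecord]:
    """Stream FASTQ records; paired inputs yield one record per fragment."""
    barcode_source = barcode_source or BarcodeSource()
    streams = [_fastq_records(r1)]
    if r2 is not None:
        streams.append(_fastq_records(r2))
    bc_stream = None
    if barcode_source.kind == "file":
        bc_stream = _fastq_records(barcode_source.path)

    while True:
        firsts = []
        done = 0
        for s in streams:
            item = next(s, None)
            if item is None:
                done += 1
            firsts.append(item)
        if done == len(streams):
            if bc_stream is not None and next(bc_stream, None) is not None:
                raise PairingError("barcode file has more records than read files")
            return
        if done:
            raise PairingError("paired FASTQ files have different record counts")
        name, seq, qual = firsts[0]
        mate = firsts[1][1] if len(firsts) > 1 else None
        barcode = None
        if barcode_source.kind == "file":
            bc_item = next(bc_stream, None)
            if bc_item is None:
                raise PairingError("barcode file has fewer records than read files")
            barcode = bc_item[1]
        elif barcode_source.kind == "prefix":
            src = seq if barcode_source.read == "r1" else (mate or "")
            barcode = src[: barcode_source.length] or None
        yield SequencingRecord(
            read_id=name,
            sequence=seq,
            mate_sequence=mate,
            barcode=barcode,
            quality=qual,
        )


def read_alignment(
    path: str | Path,
    barcode_tag: str = "CB",
    fallback_tag: Optional[str] = None,
) -> Iterator[SequencingRecord]:
    """Stream SAM/BAM records, including unmapped ones (``until_eof``).

    The barcode comes from ``barcode_tag`` when present (optionally falling
    back to ``fallback_tag``, e.g. "CR"); a missing tag yields barcode=None,
    never an error. Secondary/supplementary/duplicate flags are surfaced so
    the counting layer can filter.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            barcode = None
            if aln.has_tag(barcode_tag):
                barcode = str(aln.get_tag(barcode_tag))
            elif fallback_tag and aln.has_tag(fallback_tag):
                barcode = str(aln.get_tag(fallback_tag))
            yield SequencingRecord(
                read_id=aln.query_name or "",
                sequence=aln.query_sequence or "",
                barcode=barcode,
                contig=aln.reference_name if not aln.is_unmapped else None,
                is_secondary=aln.is_secondary,
                is_supplementary=aln.is_supplementary,
                is_duplicate=aln.is_duplicate,
                is_unmapped=aln.is_unmapped,
            )


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a possibly-gzipped FASTA file."""
    name = None
    chunks: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if name is not None:
            yield name, "".join(chunks)


def write_fastq(path: str | Path, records: Sequence[tuple[str, str]] | Iterator[tuple[str, str]]) -> int:
    """Write (id, sequence) pairs as FASTQ with uniform quality; returns count."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for name, seq in records:
            out.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def write_fasta(path: str | Path, records, width: int = 80) -> int:
    n = 0
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n
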