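"""Nanopore telomere-read preprocessing, subtelomere boundary detection, and
training-set construction for the read-origin regressor.

Nanopore telomere reads begin with a ligated biotin adapter (CCCTCCGATA)
followed by the C-strand telomere repeat (TAACCC frame). After trimming the
adapter and dropping short reads (< 8 kb by default), the subtelomere
boundary is found by repeatedly scanning for TAACCC within 0-18 bp of the
current position; where the scan stalls, the subtelomere starts, and the
position equals the telomere length.

Training examples for the origin model are 50-bp windows labeled with
log10(1 + distance-from-telomere): 0 inside the telomere proper, the offset
past the boundary for subtelomeric windows, and fixed pseudo-distances for
chromatin (1e7) and centromere (5e7) windows. The reverse complement of every
window is appended so strand is uninformative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Mapping, Sequence

import numpy as np

from ._seq import revcomp

logger = logging.getLogger(__name__)

REGIONS = ("telomere", "subtelomere", "chromatin", "centromere")


@dataclass(frozen=True)
class NanoporeConfig:
    adapter: str = "CCCTCCGATA"
    min_read_length: int = 8000
    boundary_motif: str = "TAACCC"
    max_gap: int = 18  # inclusive offset window for the boundary scan
    adapter_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class TelomereReadRecord:
    read_id: str
    trimmed_sequence: str
    adapter_found: bool
    passed_length_filter: bool
    subtelomere_start: int

    @property
    def telomere_length(self) -> int:
        return self.subtelomere_start


def find_subtelomere_start(seq: str, config: NanoporeConfig | None = None) -> int:
    """Scan for the boundary motif within [0, max_gap] of the cursor.

    The cursor starts at 0; each leftmost match at offset o advances it past
    the matched motif (cursor += o + len(motif)). When no match falls inside
    the window, the cursor marks the subtelomere start.
    """
    config = config or NanoporeConfig()
    motif = config.boundary_motif
    m = len(motif)
    pos = 0
    n = len(seq)
    while pos < n:
        hit = seq.find(motif, pos, pos + config.max_gap + m)
        if hit == -1:
            break
        pos = hit + m
    return pos


def preprocess_read(
    raw: str,
    config: NanoporeConfig | None = None,
    read_id: str = "",
) -> TelomereReadRecord:
    """Trim the adapter (position 0 only, within ``adapter_mismatches``),
    apply the length filter to the trimmed read, and locate the boundary.

    Reads failing the length filter are flagged, never dropped.
    """
    config = config or NanoporeConfig()
    if not raw:
        raise ValueError("preprocess_read requires a non-empty read")
    adapter = config.adapter
    prefix = raw[: len(adapter)]
    adapter_found = (
        len(prefix) == len(adapter)
        and sum(a != b for a, b in zip(prefix, adapter)) <= config.adapter_mismatches
    )
    trimmed = raw[len(adapter) :] if adapter_found else raw
    return TelomereReadRecord(
        read_id=read_id,
        trimmed_sequence=trimmed,
        adapter_found=adapter_found,
        passed_length_filter=len(trimmed) >= config.min_read_length,
        subtelomere_start=find_subtelomere_start(trimmed, config),
    )


@dataclass
class TrainingExample:
    sequence: str  # exactly 50 bp
    label: float  # log10(1 + distance)
    region: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 50:
            raise ValueError("training sequences must be exactly 50 bp")
        if self.label < 0:
            raise ValueError("labels are log10(1 + d) and cannot be negative")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


def distance_label(distance: float) -> float:
    """log10(1 + d); d = 0 (telomere proper) maps to 0."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return math.log10(1.0 + distance)


CHROMATIN_PSEUDO_DISTANCE = 1e7
CENTROMERE_PSEUDO_DISTANCE = 5e7


def build_training_set(
    telomere_reads: Sequence[TelomereReadRecord],
    reference_regions: Mapping[str, Sequence[str]],
    n_per_class: int,
    seed: int,
    window: int = 50,
    chromatin_distance: float = CHROMATIN_PSEUDO_DISTANCE,
    centromere_distance: float = CENTROMERE_PSEUDO_DISTANCE,
) -> List[TrainingExample]:
    """Uniform random windows per class, log-distance labels, revcomp augmentation.

    Telomere/subtelomere windows come from the processed nanopore reads
    (boundary known: a window starting at s is labeled max(0, s - boundary));
    chromatin and centromere windows come from ``reference_regions`` and get
    the fixed pseudo-distances. Sequences shorter than the window are skipped
    with a logged count. Deterministic under ``seed``; output size is
    2 x (windows drawn) because every window's reverse complement is appended.
    """
    rng = np.random.default_rng(seed)
    examples: List[TrainingExample] = []

    usable_reads = [r for r in telomere_reads if len(r.trimmed_sequence) >= window]
    n_skipped = len(telomere_reads) - len(usable_reads)
    if usable_reads and n_per_class > 0:
        picks = rng.integers(0, len(usable_reads), size=n_per_class)
        for idx in picks:
            rec = usable_reads[idx]
            start = int(rng.integers(0, len(rec.trimmed_sequence) - window + 1))
            seq = rec.trimmed_sequence[start : start + window]
            d = max(0, start - rec.subtelomere_start)
            region = "telomere" if start + window <= rec.subtelomere_start else "subtelomere"
            examples.append(TrainingExample(seq, distance_label(d), region))

    for region, pseudo in (("chromatin", chromatin_distance), ("centromere", centromere_distance)):
        seqs = [s for s in reference_regions.get(region, ()) if len(s) >= window]
        n_skipped += len(reference_regions.get(region, ())) - len(seqs)
        if not seqs or n_per_class <= 0:
            continue
        picks = rng.integers(0, len(seqs), size=n_per_class)
        for idx in picks:
            seq = seqs[idx]
            start = int(rng.integers(0, len(seq) - window + 1))
            examples.append(
                TrainingExample(seq[start : start + window], distance_label(pseudo), region)
            )

    # optional subtelomeric windows drawn from a reference rather than reads
    subtel_ref = [s for s in reference_regions.get("subtelomere", ()) if len(s) >= window]
    if subtel_ref and n_per_class > 0:
        picks = rng.integers(0, len(subtel_ref), size=n_per_class)
        for idx in picks:
            seq = subtel_ref[idx]
            start = int(rng.integers(0, len(seq) - window + 1))
            examples.append(
                TrainingExample(seq[start : start + window], distance_label(start), "subtelomere")
            )

    if n_skipped:
        logger.info("build_training_set: skipped %d sequences shorter than %d bp", n_skipped, window)

    augmented = list(examples)
    for ex in examples:
        augmented.append(TrainingExample(revcomp(ex.sequence), ex.label, ex.region))
    return augmented


def write_training_set(examples: Iterable[TrainingExample], path: str | Path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write("sequence\tlabel\tregion\n")
        for ex in examples:
            out.write(f"{ex.sequence}\t{ex.label:.8g}\t{ex.region}\n")
            n += 1
    return n


def read_training_set(path: str | Path) -> List[TrainingExample]:
    examples = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("sequence"):
            raise ValueError("training-set TSV must start with a sequence/label/region header")
        for line in handle:
            seq, label, region = line.rstrip("\n").split("\t")
            examples.append(TrainingExample(seq, float(label), region))
    return examples


def write_read_records(records: Iterable[TelomereReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as out:
        out.write("read_id\tadapter_found\tpassed_length_filter\ttelomere_length\tread_length\n")
        for rec in records:
            out.write(
                f"{rec.read_id}\t{int(rec.adapter_found)}\t{int(rec.passed_length_filter)}\t"
                f"{rec.telomere_length}\t{len(rec.trimmed_sequence)}\n"
            )
            n += 1
    return n
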