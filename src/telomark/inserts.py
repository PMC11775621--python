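"""Detection of non-fragmenting Tn5 cargo insertions in long reads.

In this assay Tn5 carries a 95-bp non-fragmenting cargo flanked by the 19-bp
mosaic ends, so an insertion event leaves the full cargo embedded in the
mechanically sheared long read. Detection is seed-and-verify: exact seed hits
tiled across the cargo (both termini included, both orientations) propose a
95-bp interval that is then verified by Hamming distance against the full
cargo, so detection survives substitution noise that disrupts any single
seed. Around each event
the module measures target-site duplication (identical host sequence
immediately flanking both insert ends — the signature wild-type Tn5 leaves as
a 9-bp direct repeat), builds insertion-context base-frequency matrices, and
profiles the distance from insertion points to the nearest telomere motif.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

from ._seq import revcomp, validate_dna
from .motif import MotifScanConfig, is_telomere_like
from .orient import BaseFrequencyMatrix, base_frequency_matrix
from .quantify import compute_nta

logger = logging.getLogger(__name__)

#: 19-bp Tn5 mosaic end terminating the cargo on both sides
MOSAIC_END = "CTGTCTCTTATACACATCT"

#: the 95-bp non-fragmenting cargo (sense strand) used for the insertion atlas
CARGO_SENSE = (
    "CTGTCTCTTATACACATCTACGCGGTGGACAAAAAATTTCATTTGGAACTAGATTTGACC"
    "TCAGCTTCAATGCCAGAGATGTGTATAAGAGACAG"
)


@dataclass(frozen=True)
class CargoSpec:
    sense_sequence: str = CARGO_SENSE
    seed_length: int = 20
    max_mismatch_fraction: float = 0.1
    flank_window: int = 30

    def __post_init__(self) -> None:
        seq = validate_dna(self.sense_sequence, allow_n=False, what="cargo sense_sequence")
        object.__setattr__(self, "sense_sequence", seq)
        if len(seq) < 2 * self.seed_length:
            raise ValueError("cargo must be at least twice the seed length")
        if not (0.0 <= self.max_mismatch_fraction < 1.0):
            raise ValueError("max_mismatch_fraction must lie in [0, 1)")

    @property
    def length(self) -> int:
        return len(self.sense_sequence)

    @property
    def max_mismatches(self) -> int:
        return math.floor(self.max_mismatch_fraction * self.length)


@dataclass
class InsertEvent:
    read_id: str
    insert_start: int  # 0-based, half-open in read coordinates
    insert_end: int
    orientation: str  # "forward" | "reverse"
    left_flank: str
    right_flank: str
    mismatches: int = 0
    duplication_length: int = -1  # filled by duplication_length()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _seed_hits(read: str, seed: str) -> Iterable[int]:
    i = read.find(seed)
    while i != -1:
        yield i
        i = read.find(seed, i + 1)


def find_inserts(read: str, cargo: CargoSpec | None = None, read_id: str = "") -> List[InsertEvent]:
    """Locate cargo insertions in one long read.

    Exact seeds tiled across the cargo (both termini included, both
    orientations) each propose one full-length interval verified at
    ``max_mismatch_fraction``. Overlapping candidates resolve to the
    lowest-mismatch, leftmost event.
    """
    cargo = cargo or CargoSpec()
    L = cargo.length
    k = cargo.seed_length
    targets = {"forward": cargo.sense_sequence, "reverse": revcomp(cargo.sense_sequence)}
    # seeds tile the cargo (both termini included) so that a single seed
    # surviving substitution noise suffices to propose the event
    step = max(1, (L - k) // 5)
    offsets = sorted(set(list(range(0, L - k + 1, step)) + [L - k]))
    candidates: Dict[Tuple[int, str], int] = {}
    for orientation, target in targets.items():
        for offset in offsets:
            seed = target[offset : offset + k]
            for hit in _seed_hits(read, seed):
                start = hit - offset
                if start < 0 or start + L > len(read):
                    continue
                key = (start, orientation)
                if key in candidates:
                    continue
                mm = _hamming(read[start : start + L], target)
                if mm <= cargo.max_mismatches:
                    candidates[key] = mm
    # lowest mismatch count wins; ties broken leftmost, then forward
    ordered = sorted(
        candidates.items(),
        key=lambda item: (item[1], item[0][0], item[0][1] != "forward"),
    )
    accepted: List[Tuple[int, int, str, int]] = []
    for (start, orientation), mm in ordered:
        end = start + L
        if any(start < a_end and a_start < end for a_start, a_end, _, _ in accepted):
            continue
        accepted.append((start, end, orientation, mm))
    accepted.sort()
    events = []
    for start, end, orientation, mm in accepted:
        events.append(
            InsertEvent(
                read_id=read_id,
                insert_start=start,
                insert_end=end,
                orientation=orientation,
                left_flank=read[max(0, start - cargo.flank_window) : start],
                right_flank=read[end : end + cargo.flank_window],
                mismatches=mm,
            )
        )
    return events


def duplication_length(event: InsertEvent, d_max: int = 15) -> int:
    """Largest d <= d_max with the last d bases of the left flank equal to the
    first d bases of the right flank; 0 when the flanks share no such repeat."""
    if len(event.left_flank) < d_max or len(event.right_flank) < d_max:
        raise ValueError(
            f"flanks must be at least d_max={d_max} long "
            f"(got {len(event.left_flank)} / {len(event.right_flank)})"
        )
    for d in range(d_max, 0, -1):
        if event.left_flank[-d:] == event.right_flank[:d]:
            return d
    return 0


def annotate_duplications(events: Iterable[InsertEvent], d_max: int = 15) -> List[InsertEvent]:
    out = []
    for ev in events:
        ev.duplication_length = duplication_length(ev, d_max=d_max)
        out.append(ev)
    return out


def insertion_context_matrix(
    events: Iterable[InsertEvent],
    reads: Mapping[str, str],
    window: int = 20,
) -> BaseFrequencyMatrix:
    """Base-frequency matrix of the +/-window genomic context around insertion points.

    The cargo itself is removed; reverse-orientation events are reverse
    complemented before stacking so all contexts share the cargo's frame.
    Events whose window exceeds the read bounds are skipped (count logged).
    """
    contexts = []
    skipped = 0
    for ev in events:
        read = reads[ev.read_id]
        if ev.insert_start - window < 0 or ev.insert_end + window > len(read):
            skipped += 1
            continue
        ctx = read[ev.insert_start - window : ev.insert_start] + read[ev.insert_end : ev.insert_end + window]
        if ev.orientation == "reverse":
            ctx = revcomp(ctx)
        contexts.append(ctx)
    if skipped:
        logger.info("insertion_context_matrix: skipped %d events near read bounds", skipped)
    if not contexts:
        raise ValueError("no usable insertion events within read bounds")
    return base_frequency_matrix(contexts, length=2 * window)


def telomere_proximity_histogram(
    events: Iterable[InsertEvent],
    reads: Mapping[str, str],
    search_range: int = 60,
    motif: str = "TTAGGG",
) -> Dict[int, int]:
    """Signed offset from each insertion point to the nearest motif start.

    Offsets are measured in the host sequence with the insert excised
    (negative = motif upstream of the insertion point); events with no motif
    within +/-search_range are excluded. Ties between equally near motifs
    resolve to the upstream one.
    """
    hist: Counter = Counter()
    for ev in events:
        read = reads[ev.read_id]
        host = read[: ev.insert_start] + read[ev.insert_end :]
        point = ev.insert_start
        lo = max(0, point - search_range)
        hi = min(len(host), point + search_range + len(motif))
        segment = host[lo:hi]
        best = None
        i = segment.find(motif)
        while i != -1:
            offset = lo + i - point
            if -search_range <= offset <= search_range:
                if best is None or abs(offset) < abs(best) or (abs(offset) == abs(best) and offset < best):
                    best = offset
            i = segment.find(motif, i + 1)
        if best is not None:
            hist[best] += 1
    return dict(hist)


def nta_by_insert_status(
    reads: Iterable[Tuple[str, str]],
    cargo: CargoSpec | None = None,
    scan: MotifScanConfig | None = None,
) -> Tuple[float, float]:
    """(nTA over all reads, nTA over insert-bearing reads), cargo bases masked.

    Cargo bases are replaced by N before motif scanning so motifs inside the
    insert never count. The insert-only nTA is NaN when no read carries an
    insert.
    """
    cargo = cargo or CargoSpec()
    scan = scan or MotifScanConfig()
    n_all = telo_all = 0
    n_ins = telo_ins = 0
    for read_id, seq in reads:
        events = find_inserts(seq, cargo, read_id=read_id)
        masked = seq
        for ev in events:
            masked = masked[: ev.insert_start] + "N" * (ev.insert_end - ev.insert_start) + masked[ev.insert_end :]
        telo = is_telomere_like(masked, scan)
        n_all += 1
        telo_all += telo
        if events:
            n_ins += 1
            telo_ins += telo
    nta_all = compute_nta(telo_all, n_all) if n_all else math.nan
    nta_ins = compute_nta(telo_ins, n_ins) if n_ins else math.nan
    return nta_all, nta_ins


def write_events_tsv(events: Iterable[InsertEvent], path: str | Path) -> int:
    """BED-like TSV: read_id, insert_start, insert_end, orientation, duplication_length."""
    n = 0
    with open(path, "w") as out:
        out.write("read_id\tinsert_start\tinsert_end\torientation\tduplication_length\n")
        for ev in events:
            out.write(
                f"{ev.read_id}\t{ev.insert_start}\t{ev.insert_end}\t{ev.orientation}\t{ev.duplication_length}\n"
            )
            n += 1
    return n
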