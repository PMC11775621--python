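"""Telomere-motif read classification.

A read is "telomere-like" when it carries at least ``min_consecutive`` strictly
tandem (zero-gap) copies of the canonical telomere hexamer TTAGGG on either
strand. Three tandem copies is the default threshold, the same cutoff used by
whole-genome telomere-content estimators calibrated against terminal
restriction fragment data. Variant telomere repeats (TVRs) — hexamers matching
T**GGG other than the canonical motif, e.g. TAAGGG or TTTGGG — are tallied
separately; they carry no run-length requirement by default.

N bases never match the motif or a wildcard, so low-quality calls break runs
instead of inflating them. Forward- and reverse-strand runs are measured
separately and never merged into a single run.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable

from ._seq import revcomp, validate_dna

_WILDCARDS = {"*", "?", "N"}


@dataclass(frozen=True)
class MotifScanConfig:
    """Parameters of the motif scan.

    Parameters
    ----------
    canonical_motif :
        The telomere repeat unit (default ``TTAGGG``).
    min_consecutive :
        Minimum number of tandem copies for a read to count as telomere-like.
    variant_pattern :
        Wildcard pattern for variant repeats; ``*`` (or ``?``) matches any of
        A/C/G/T. Must have the same length as the canonical motif.
    scan_both_strands :
        Also scan for the reverse complement of the motif / pattern.
    variant_min_consecutive :
        Optional tandem-run requirement for variant repeats (default 1, i.e.
        every non-overlapping occurrence counts).
    """

    canonical_motif: str = "TTAGGG"
    min_consecutive: int = 3
    variant_pattern: str = "T**GGG"
    scan_both_strands: bool = True
    variant_min_consecutive: int = 1

    def __post_init__(self) -> None:
        motif = validate_dna(self.canonical_motif, allow_n=False, what="canonical_motif")
        object.__setattr__(self, "canonical_motif", motif)
        if not motif:
            raise ValueError("canonical_motif must be non-empty")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if self.variant_min_consecutive < 1:
            raise ValueError("variant_min_consecutive must be >= 1")
        pattern = self.variant_pattern.upper()
        if len(pattern) != len(motif):
            raise ValueError("variant_pattern must have the same length as canonical_motif")
        for ch in pattern:
            if ch not in _WILDCARDS and ch not in "ACGT":
                raise ValueError(f"invalid character {ch!r} in variant_pattern")
        object.__setattr__(self, "variant_pattern", pattern)

    # -- flat key/value serialization ------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"canonical_motif={self.canonical_motif}",
            f"min_consecutive={self.min_consecutive}",
            f"variant_pattern={self.variant_pattern}",
            f"scan_both_strands={'true' if self.scan_both_strands else 'false'}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifScanConfig":
        kv: Dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key.strip()] = value.strip()
        return cls(
            canonical_motif=kv.get("canonical_motif", "TTAGGG"),
            min_consecutive=int(kv.get("min_consecutive", 3)),
            variant_pattern=kv.get("variant_pattern", "T**GGG"),
            scan_both_strands=kv.get("scan_both_strands", "true").lower() in ("true", "1", "yes"),
        )

    def variant_regex(self) -> re.Pattern[str]:
        return re.compile("".join("[ACGT]" if ch in _WILDCARDS else ch for ch in self.variant_pattern))


@dataclass
class ReadMotifResult:
    """Per-read classification outcome."""

    read_id: str
    max_run_forward: int
    max_run_reverse: int
    is_telomere_like: bool
    variant_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def max_run(self) -> int:
        return max(self.max_run_forward, self.max_run_reverse)


def max_tandem_run(seq: str, motif: str) -> int:
    """Largest k such that ``motif`` repeated k times occurs contiguously in *seq*.

    Any non-matching character, including N, terminates a run. Returns 0 when
    the motif is absent.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = validate_dna(motif, allow_n=False, what="motif")
    seq = validate_dna(seq, what="read sequence")
    m = len(motif)
    best = 0
    i = seq.find(motif)
    while i != -1:
        j = i + m
        run = 1
        while seq.startswith(motif, j):
            run += 1
            j += m
        if run > best:
            best = run
        i = seq.find(motif, i + 1)
    return best


def is_telomere_like(seq: str, config: MotifScanConfig | None = None) -> bool:
    """Fast telomere-like check without variant tallies.

    Short-circuits as soon as a qualifying tandem run is found on either
    strand; used by the high-throughput counting paths.
    """
    config = config or MotifScanConfig()
    needle = config.canonical_motif * config.min_consecutive
    if needle in seq:
        return True
    if config.scan_both_strands and revcomp(needle) in seq:
        return True
    return False


def classify_read(seq: str, config: MotifScanConfig | None = None, read_id: str = "") -> ReadMotifResult:
    """Classify one read: tandem canonical runs on both strands + variant tallies."""
    config = config or MotifScanConfig()
    seq = validate_dna(seq, what="read sequence")
    fwd = max_tandem_run(seq, config.canonical_motif)
    rev = max_tandem_run(seq, revcomp(config.canonical_motif)) if config.scan_both_strands else 0
    telo = max(fwd, rev) >= config.min_consecutive
    variants = count_variant_repeats(seq, config)
    return ReadMotifResult(
        read_id=read_id,
        max_run_forward=fwd,
        max_run_reverse=rev,
        is_telomere_like=telo,
        variant_counts=variants,
    )


def _tally_variants(seq: str, config: MotifScanConfig) -> Counter:
    counts: Counter = Counter()
    canonical = config.canonical_motif
    prev_end = -1
    prev_hex = None
    run = 0

    def flush() -> None:
        nonlocal run, prev_hex
        if prev_hex is not None and run >= config.variant_min_consecutive:
            counts[prev_hex] += run
        run = 0
        prev_hex = None

    for match in config.variant_regex().finditer(seq):
        hexamer = match.group(0)
        if hexamer == canonical:
            flush()
            prev_end = match.end()
            continue
        if config.variant_min_consecutive == 1:
            counts[hexamer] += 1
            continue
        if hexamer == prev_hex and match.start() == prev_end:
            run += 1
        else:
            flush()
            prev_hex = hexamer
            run = 1
        prev_end = match.end()
    flush()
    return counts


def count_variant_repeats(seq: str, config: MotifScanConfig | None = None) -> Dict[str, int]:
    """Count non-overlapping variant telomere repeats (canonical excluded).

    Matches are found with a single non-overlapping left-to-right scan per
    strand. Reverse-strand occurrences are reported as their forward-strand
    (pattern-matching) hexamer.
    """
    config = config or MotifScanConfig()
    seq = validate_dna(seq, what="read sequence")
    counts = _tally_variants(seq, config)
    if config.scan_both_strands:
        counts += _tally_variants(revcomp(seq), config)
    return dict(counts)


def motif_run_histogram(results: Iterable[ReadMotifResult]) -> Dict[int, int]:
    """Histogram of maximal tandem-run length over telomere-like reads only."""
    hist: Counter = Counter()
    for res in results:
        if res.is_telomere_like:
            hist[res.max_run] += 1
    return dict(hist)


def summarize_variant_counts(results: Iterable[ReadMotifResult]) -> Dict[str, int]:
    """Aggregate variant-repeat tallies over a stream of results."""
    total: Counter = Counter()
    for res in results:
        total.update(res.variant_counts)
    return dict(total)
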