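"""Library- and cell-level normalized telomere abundance (nTA).

nTA = telomere-like reads / total reads. It is a depth-normalized fraction
computed per library (bulk) or per cell barcode (single-cell); multiplying by
10^6 gives repeats-per-million (RPM). For visualization the per-cell values
are rank-transformed to [0, 1] (average ranks for ties) to maximize contrast.

Counting semantics: in single-end mode each read is one counting unit; in
paired mode one FRAGMENT is the unit — a pair counts once, and is
telomere-like if either mate qualifies. Alignment streams include unmapped
and duplicate records by default (telomere-like reads typically do not map)
but exclude secondary and supplementary alignments to avoid double counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .motif import MotifScanConfig, ReadMotifResult, is_telomere_like
from .seqio import SequencingRecord

#: barcode label under which barcode-less records accumulate
NO_BARCODE = "no-barcode"

UNMAPPED = "unmapped"


@dataclass(frozen=True)
class CountingConfig:
    """Record-level filters and counting-unit options."""

    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = False
    min_total_for_rank: int = 1


@dataclass
class LibrarySummary:
    total_reads: int
    telomere_like_reads: int
    mode: str = "reads"  # "reads" (single-end) or "fragments" (paired)

    def __post_init__(self) -> None:
        if not (0 <= self.telomere_like_reads <= self.total_reads):
            raise ValueError(
                f"telomere_like_reads ({self.telomere_like_reads}) must lie in "
                f"[0, total_reads={self.total_reads}]"
            )

    @property
    def nta(self) -> float:
        return compute_nta(self.telomere_like_reads, self.total_reads)

    @property
    def rpm(self) -> float:
        return self.nta * 1e6

    def to_file(self, path: str | Path) -> None:
        nta = self.nta
        lines = [
            f"total_reads={self.total_reads}",
            f"telomere_like_reads={self.telomere_like_reads}",
            f"nta={'NA' if math.isnan(nta) else format(nta, '.6g')}",
            f"rpm={'NA' if math.isnan(nta) else format(self.rpm, '.6g')}",
            f"mode={self.mode}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CellCountTable:
    """Per-barcode counts; the single-cell product.

    ``cells`` has columns barcode, total, telomere_like, nta, rank_nta with
    one row per observed barcode; records without a barcode accumulate in the
    reserved :data:`NO_BARCODE` row (kept separately, excluded from ranking).
    """

    cells: pd.DataFrame
    no_barcode_total: int = 0
    no_barcode_telomere_like: int = 0
    mode: str = "reads"

    def to_tsv(self, path: str | Path, include_no_barcode: bool = True) -> None:
        df = self.cells.copy()
        if include_no_barcode and self.no_barcode_total > 0:
            extra = pd.DataFrame(
                [
                    {
                        "barcode": NO_BARCODE,
                        "total": self.no_barcode_total,
                        "telomere_like": self.no_barcode_telomere_like,
                        "nta": compute_nta(self.no_barcode_telomere_like, self.no_barcode_total),
                        "rank_nta": np.nan,
                    }
                ]
            )
            df = extra if df.empty else pd.concat([df, extra], ignore_index=True)
        df = df.copy()
        df["nta"] = df["nta"].map(lambda v: "NA" if pd.isna(v) else format(v, ".6g"))
        df["rank_nta"] = df["rank_nta"].map(lambda v: "NA" if pd.isna(v) else format(v, ".6g"))
        df.to_csv(path, sep="\t", index=False, columns=["barcode", "total", "telomere_like", "nta", "rank_nta"])


def compute_nta(telomere_like: int, total: int) -> float:
    """Exact quotient telomere_like / total; NaN marks the undefined 0-denominator case."""
    if telomere_like < 0 or total < 0:
        raise ValueError("counts must be non-negative")
    if telomere_like > total:
        raise ValueError(f"telomere_like ({telomere_like}) exceeds total ({total})")
    if total == 0:
        return math.nan
    return telomere_like / total


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Average ranks scaled to [0, 1] via (rank - 1) / (n - 1).

    A single value, or a constant vector, maps to 0.5.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("rank_transform requires at least one value")
    if arr.size == 1:
        return np.array([0.5])
    ranks = rankdata(arr, method="average")
    return (ranks - 1.0) / (arr.size - 1.0)


def _record_units(
    records: Iterable[SequencingRecord],
    scan: MotifScanConfig,
    counting: CountingConfig,
):
    """Yield (barcode, contig, telomere_like) per counting unit after filters."""
    for rec in records:
        if counting.exclude_secondary and rec.is_secondary:
            continue
        if counting.exclude_supplementary and rec.is_supplementary:
            continue
        if counting.exclude_duplicates and rec.is_duplicate:
            continue
        telo = is_telomere_like(rec.sequence, scan)
        if not telo and rec.mate_sequence is not None:
            telo = is_telomere_like(rec.mate_sequence, scan)
        yield rec.barcode, rec.contig, telo


def count_records(
    records: Iterable[SequencingRecord],
    scan: MotifScanConfig | None = None,
    counting: CountingConfig | None = None,
    paired: Optional[bool] = None,
) -> Tuple[LibrarySummary, CellCountTable, Dict[str, Tuple[int, int]]]:
    """Single pass over a record stream: library summary, per-cell table, per-contig tallies.

    ``paired=None`` auto-detects fragment mode from the first record carrying a
    mate. Memory is bounded by the number of distinct barcodes/contigs, not
    the number of records.
    """
    scan = scan or MotifScanConfig()
    counting = counting or CountingConfig()
    total = 0
    telo_total = 0
    mode = None if paired is None else ("fragments" if paired else "reads")
    by_barcode: Dict[str, list] = {}
    no_bc = [0, 0]
    by_contig: Dict[str, list] = {}
    for rec in records:
        if counting.exclude_secondary and rec.is_secondary:
            continue
        if counting.exclude_supplementary and rec.is_supplementary:
            continue
        if counting.exclude_duplicates and rec.is_duplicate:
            continue
        if mode is None:
            mode = "fragments" if rec.mate_sequence is not None else "reads"
        telo = is_telomere_like(rec.sequence, scan)
        if not telo and rec.mate_sequence is not None:
            telo = is_telomere_like(rec.mate_sequence, scan)
        total += 1
        telo_total += telo
        if rec.barcode:
            counts = by_barcode.setdefault(rec.barcode, [0, 0])
        else:
            counts = no_bc
        counts[0] += 1
        counts[1] += telo
        contig = rec.contig if rec.contig is not None else UNMAPPED
        ccounts = by_contig.setdefault(contig, [0, 0])
        ccounts[0] += 1
        ccounts[1] += telo
    mode = mode or "reads"
    summary = LibrarySummary(total_reads=total, telomere_like_reads=telo_total, mode=mode)
    table = _build_cell_table(by_barcode, no_bc, counting, mode)
    contig_counts = {k: (v[0], v[1]) for k, v in by_contig.items()}
    return summary, table, contig_counts


def _build_cell_table(
    by_barcode: Dict[str, list],
    no_bc: list,
    counting: CountingConfig,
    mode: str,
) -> CellCountTable:
    rows = [
        {"barcode": bc, "total": c[0], "telomere_like": c[1], "nta": compute_nta(c[1], c[0])}
        for bc, c in sorted(by_barcode.items())
    ]
    df = pd.DataFrame(rows, columns=["barcode", "total", "telomere_like", "nta"])
    df["rank_nta"] = np.nan
    eligible = df.index[df["total"] >= counting.min_total_for_rank]
    if len(eligible) > 0:
        df.loc[eligible, "rank_nta"] = rank_transform(df.loc[eligible, "nta"].to_numpy())
    return CellCountTable(
        cells=df,
        no_barcode_total=no_bc[0],
        no_barcode_telomere_like=no_bc[1],
        mode=mode,
    )


def per_cell_counts(
    results: Iterable[Tuple[Optional[str], ReadMotifResult]],
    counting: CountingConfig | None = None,
) -> CellCountTable:
    """Aggregate pre-classified (barcode, result) records into a cell table."""
    counting = counting or CountingConfig()
    by_barcode: Dict[str, list] = {}
    no_bc = [0, 0]
    for barcode, res in results:
        counts = by_barcode.setdefault(barcode, [0, 0]) if barcode else no_bc
        counts[0] += 1
        counts[1] += res.is_telomere_like
    return _build_cell_table(by_barcode, no_bc, counting, mode="reads")


def per_contig_counts(
    results: Iterable[Tuple[Optional[str], ReadMotifResult]],
) -> Dict[str, Tuple[int, int]]:
    """Per-contig (total, telomere_like); unmapped records tallied under "unmapped"."""
    by_contig: Dict[str, list] = {}
    for contig, res in results:
        key = contig if contig is not None else UNMAPPED
        counts = by_contig.setdefault(key, [0, 0])
        counts[0] += 1
        counts[1] += res.is_telomere_like
    return {k: (v[0], v[1]) for k, v in by_contig.items()}
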