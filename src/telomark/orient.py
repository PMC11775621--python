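"""Reference-free reorientation of paired telomere-like reads and base-frequency logos.

Telomere-like reads cannot reliably be aligned, so read pairs are oriented by
sequence content alone: if the G fraction of R1 (assessed from its 5' end) is
below the threshold (default 50%), both mates are reverse complemented and
swapped, which maps the pair onto the opposite strand so that the G-rich
(TTAGGG) strand always ends up as R1. Mates are expected in fragment
orientation — R1 the prefix and R2 the suffix read of the same strand; a raw
FASTQ R2 (sequenced from the complementary strand) should be reverse
complemented first. Stacked oriented reads then give a per-position
base-frequency matrix — the numerical form of a sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Tuple

import numpy as np
import pandas as pd

from ._seq import g_fraction, revcomp

BASES = ("A", "C", "G", "T", "N")


@dataclass(frozen=True)
class OrientConfig:
    g_fraction_threshold: float = 0.5
    assess_window: int | None = None  # None = whole read

    def __post_init__(self) -> None:
        if not (0.0 < self.g_fraction_threshold < 1.0):
            raise ValueError("g_fraction_threshold must lie in (0, 1)")
        if self.assess_window is not None and self.assess_window < 1:
            raise ValueError("assess_window must be >= 1")


@dataclass
class BaseFrequencyMatrix:
    """positions x {A,C,G,T,N} frequencies; rows sum to 1 over observed bases."""

    frequencies: pd.DataFrame  # index: position, columns: BASES
    n_reads: int

    def to_tsv(self, path: str | Path) -> None:
        self.frequencies.to_csv(path, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BaseFrequencyMatrix":
        df = pd.read_csv(path, sep="\t", index_col="position")
        return cls(frequencies=df, n_reads=-1)


def orient_pair(r1: str, r2: str, config: OrientConfig | None = None) -> Tuple[str, str]:
    """Orient a fragment-oriented read pair so the G-rich strand is R1.

    Returns ``(revcomp(r2), revcomp(r1))`` when the assessed G fraction of r1
    is below the threshold, else the pair unchanged. With mates in fragment
    orientation this maps (prefix, suffix) reads of one strand to (prefix,
    suffix) reads of the other; for pairs where one strand is G-rich (the
    telomere-like case) the operation is idempotent.
    """
    config = config or OrientConfig()
    if not r1 or not r2:
        raise ValueError("orient_pair requires two non-empty reads")
    window = r1 if config.assess_window is None else r1[: config.assess_window]
    if g_fraction(window) < config.g_fraction_threshold:
        return revcomp(r2), revcomp(r1)
    return r1, r2


def base_frequency_matrix(
    reads: Iterable[str],
    length: int,
    include_n_in_denominator: bool = True,
) -> BaseFrequencyMatrix:
    """Column-normalized per-position base counts over *reads*.

    Reads are truncated to *length* or padded with N. With
    ``include_n_in_denominator=False`` the N column is still reported but
    frequencies are normalized over A/C/G/T only.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    index = {b: i for i, b in enumerate(BASES)}
    counts = np.zeros((length, len(BASES)), dtype=np.int64)
    n_reads = 0
    for read in reads:
        n_reads += 1
        read = read[:length].upper().ljust(length, "N")
        for pos, base in enumerate(read):
            counts[pos, index.get(base, index["N"])] += 1
    if n_reads == 0:
        raise ValueError("base_frequency_matrix requires at least one read")
    denom = counts.sum(axis=1) if include_n_in_denominator else counts[:, :4].sum(axis=1)
    denom = np.where(denom == 0, 1, denom).astype(float)
    freq = counts / denom[:, None]
    df = pd.DataFrame(freq, columns=list(BASES))
    df.index.name = "position"
    return BaseFrequencyMatrix(frequencies=df, n_reads=n_reads)
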