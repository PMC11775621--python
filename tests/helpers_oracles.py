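"""Independent brute-force oracles used to validate the implementation paths."""

import numpy as np


def brute_max_tandem_run(seq: str, motif: str) -> int:
    """Try motif^k at every offset, for every k, largest k found."""
    best = 0
    k = 1
    while True:
        needle = motif * k
        if len(needle) > len(seq):
            break
        if any(seq[i : i + len(needle)] == needle for i in range(len(seq) - len(needle) + 1)):
            best = k
            k += 1
        else:
            break
    return best


def brute_duplication_length(left: str, right: str, d_max: int = 15) -> int:
    """Loop over all d, keep the largest with matching flank ends."""
    best = 0
    for d in range(1, d_max + 1):
        if left[-d:] == right[:d]:
            best = d
    return best


def brute_average_ranks(values) -> np.ndarray:
    """Average ranks (1-based) computed from first principles."""
    arr = np.asarray(values, dtype=float)
    ranks = np.empty(arr.size)
    for i, v in enumerate(arr):
        less = np.sum(arr < v)
        equal = np.sum(arr == v)
        # average of positions less+1 .. less+equal
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_spearman(x, y) -> float:
    """Pearson correlation of brute-force average ranks."""
    rx = brute_average_ranks(x)
    ry = brute_average_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_subtelomere_scan(seq: str, motif: str = "TAACCC", max_gap: int = 18) -> int:
    """Literal re-implementation of the boundary scan rule."""
    pos = 0
    while True:
        found = None
        for o in range(0, max_gap + 1):
            if seq[pos + o : pos + o + len(motif)] == motif:
                found = o
                break
        if found is None:
            return pos
        pos = pos + found + len(motif)
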