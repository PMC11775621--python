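"""Synthetic genomes and sequencing reads for end-to-end testing.

The genome model mirrors the compartment view used throughout the package:
each chromosome arm is, 5' to 3', a pure-TTAGGG telomere proper, a
subtelomere of tandem hexamer blocks (canonical and variant T**GGG repeats)
separated by random spacers, chromatin proper, and a centromere of tandem
171-bp monomer copies. ATAC-like fragments are sampled proportionally to
per-compartment accessibility weights; the telomere proper receives a
near-zero weight by default, encoding its protection from transposition, and
a condensation parameter c scales the chromatin-proper weight down as
condensation rises — so the expected telomere-like fraction (nTA) increases
with c. Long-read and nanopore simulators emit cargo insertions with a
configurable target-site duplication and telomere reads with known boundary
truth, respectively.

Every simulator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import revcomp
from .inserts import CargoSpec

CANONICAL = "TTAGGG"


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Per-arm compartment sizes; all arms share them.

    ``telomere_repeats`` counts TTAGGG copies (telomere length = 6x).
    ``subtel_block_density`` is the approximate fraction of subtelomeric bases
    covered by tandem hexamer blocks; ``tvr_rate`` the probability a block is
    a variant (T**GGG, non-canonical) repeat rather than canonical.
    """

    n_arms: int = 2
    telomere_repeats: int = 300
    subtelomere_length: int = 3000
    subtel_block_density: float = 0.5
    tvr_rate: float = 0.3
    chromatin_length: int = 50_000
    centromere_monomers: int = 100
    centromere_monomer_length: int = 171
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("telomere_repeats", "subtelomere_length", "chromatin_length", "centromere_monomers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")


@dataclass
class Compartment:
    arm: str
    label: str  # telomere | subtelomere | chromatin | centromere
    start: int  # 0-based half-open within the arm
    end: int


@dataclass
class SyntheticGenome:
    arms: Dict[str, str]
    compartments: List[Compartment]
    spec: SyntheticGenomeSpec

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.arms.values())

    def compartment_of(self, arm: str, pos: int) -> str:
        for c in self.compartments:
            if c.arm == arm and c.start <= pos < c.end:
                return c.label
        raise ValueError(f"position {pos} outside arm {arm}")

    def region_sequences(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for c in self.compartments:
            out.setdefault(c.label, []).append(self.arms[c.arm][c.start : c.end])
        return out


_VARIANT_MIDDLES = [a + b for a in "ACGT" for b in "ACGT" if a + b != "TA"]


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _strip_stray_variants(seq: str, rng: np.random.Generator, protect: set[int]) -> str:
    """Mutate accidental T**GGG matches in spacer sequence (canonical kept).

    ``protect`` holds start positions of deliberately emitted hexamers.
    """
    chars = list(seq)
    pat = re.compile("T[ACGT]{2}GGG")
    pos = 0
    while True:
        m = pat.search("".join(chars), pos)
        if not m:
            break
        if m.group(0) == CANONICAL or m.start() in protect:
            pos = m.start() + 1
            continue
        chars[m.start() + 5] = "C"  # break the GGG run
        pos = m.start() + 1
    return "".join(chars)


def _make_subtelomere(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> str:
    parts: List[str] = []
    emitted = 0
    protect: set[int] = set()
    while emitted < spec.subtelomere_length:
        if rng.random() < spec.subtel_block_density:
            n_copies = int(rng.integers(3, 11))
            if rng.random() < spec.tvr_rate:
                middle = _VARIANT_MIDDLES[int(rng.integers(0, len(_VARIANT_MIDDLES)))]
                hexamer = "T" + middle + "GGG"
            else:
                hexamer = CANONICAL
            block = hexamer * n_copies
            for k in range(n_copies):
                protect.add(emitted + 6 * k)
        else:
            block = _random_spacer(rng, int(rng.integers(15, 60)))
        parts.append(block)
        emitted += len(block)
    seq = "".join(parts)[: spec.subtelomere_length]
    return _strip_stray_variants(seq, rng, protect)


def make_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Deterministic synthetic genome; telomere proper is pure TTAGGG."""
    if (
        spec.telomere_repeats == 0
        and spec.subtelomere_length == 0
        and spec.chromatin_length == 0
        and spec.centromere_monomers == 0
    ):
        raise ValueError("genome would have zero length")
    rng = np.random.default_rng(spec.seed)
    monomer = _random_spacer(rng, spec.centromere_monomer_length)
    arms: Dict[str, str] = {}
    compartments: List[Compartment] = []
    for a in range(spec.n_arms):
        name = f"arm{a + 1}"
        telomere = CANONICAL * spec.telomere_repeats
        subtel = _make_subtelomere(spec, rng) if spec.subtelomere_length else ""
        chromatin = _random_spacer(rng, spec.chromatin_length)
        centromere = monomer * spec.centromere_monomers
        pieces = [
            ("telomere", telomere),
            ("subtelomere", subtel),
            ("chromatin", chromatin),
            ("centromere", centromere),
        ]
        pos = 0
        for label, seq in pieces:
            if seq:
                compartments.append(Compartment(name, label, pos, pos + len(seq)))
                pos += len(seq)
        arms[name] = "".join(seq for _, seq in pieces)
    return SyntheticGenome(arms=arms, compartments=compartments, spec=spec)


@dataclass(frozen=True)
class CondensationState:
    """Relative per-compartment accessibility; chromatin scales as 1/(1+c)."""

    telomere_weight: float = 0.001
    subtelomere_weight: float = 1.0
    chromatin_weight: float = 1.0
    centromere_weight: float = 0.2
    condensation: float = 0.0

    def __post_init__(self) -> None:
        weights = (
            self.telomere_weight,
            self.subtelomere_weight,
            self.chromatin_weight,
            self.centromere_weight,
        )
        if any(w < 0 for w in weights):
            raise ValueError("accessibility weights must be >= 0")
        if all(w == 0 for w in weights):
            raise ValueError("at least one compartment must have positive weight")
        if self.condensation < 0:
            raise ValueError("condensation must be >= 0")

    def weight(self, label: str) -> float:
        if label == "telomere":
            return self.telomere_weight
        if label == "subtelomere":
            return self.subtelomere_weight
        if label == "chromatin":
            return self.chromatin_weight / (1.0 + self.condensation)
        if label == "centromere":
            return self.centromere_weight
        raise ValueError(f"unknown compartment {label!r}")


def _compartment_sampler(genome: SyntheticGenome, state: CondensationState):
    comps = genome.compartments
    weights = np.array([state.weight(c.label) * (c.end - c.start) for c in comps], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("all compartment sampling weights are zero")
    return comps, weights / total


def simulate_atac_reads(
    genome: SyntheticGenome,
    state: CondensationState,
    n_fragments: int,
    read_length: int = 50,
    fragment_length: int = 150,
    barcodes: Optional[Sequence[str]] = None,
    barcode_states: Optional[Dict[str, CondensationState]] = None,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str, str, Optional[str]]], pd.DataFrame]:
    """Paired ATAC-like reads sampled by compartment accessibility.

    Returns ``(reads, truth)`` where reads are (read_id, r1, r2, barcode)
    tuples and truth records each fragment's arm, start, compartment, strand
    and barcode. Per-barcode condensation is supported via
    ``barcode_states``; otherwise all barcodes share ``state``.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    samplers = {None: _compartment_sampler(genome, state)}
    if barcode_states:
        for bc, st in barcode_states.items():
            samplers[bc] = _compartment_sampler(genome, st)
    bc_list = list(barcodes) if barcodes else []
    reads = []
    truth_rows = []
    for i in range(n_fragments):
        barcode = bc_list[int(rng.integers(0, len(bc_list)))] if bc_list else None
        comps, probs = samplers.get(barcode, samplers[None])
        comp = comps[int(rng.choice(len(comps), p=probs))]
        # keep the fragment inside its compartment when the compartment is
        # long enough, so the truth label describes the whole fragment
        start_hi = comp.end - fragment_length
        if start_hi > comp.start:
            start = int(rng.integers(comp.start, start_hi + 1))
        else:
            start = comp.start
        arm_seq = genome.arms[comp.arm]
        frag = arm_seq[start : start + fragment_length]
        if len(frag) < read_length:
            frag = frag.ljust(read_length, "A")  # arm-end truncation padding
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            r1, r2 = frag[:read_length], revcomp(frag)[:read_length]
        else:
            r1, r2 = revcomp(frag)[:read_length], frag[:read_length]
        read_id = f"frag{i}"
        reads.append((read_id, r1, r2, barcode))
        truth_rows.append(
            {
                "read_id": read_id,
                "arm": comp.arm,
                "start": start,
                "end": start + len(frag),
                "compartment": comp.label,
                "strand": strand,
                "barcode": barcode,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def sample_uniform_reads(
    genome: SyntheticGenome,
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
) -> List[str]:
    """WGS-style single-end reads: start positions uniform over the genome."""
    rng = np.random.default_rng(seed)
    arm_names = list(genome.arms)
    lengths = np.array([max(1, len(genome.arms[a]) - read_length + 1) for a in arm_names])
    probs = lengths / lengths.sum()
    arm_idx = rng.choice(len(arm_names), size=n_reads, p=probs)
    out = []
    for ai in arm_idx:
        seq = genome.arms[arm_names[ai]]
        start = int(rng.integers(0, max(1, len(seq) - read_length + 1)))
        out.append(seq[start : start + read_length])
    return out


def simulate_longreads_with_inserts(
    genome: SyntheticGenome,
    cargo: CargoSpec | None = None,
    insertion_rate: float = 1.0,
    duplication: int = 9,
    n_reads: int = 50,
    read_length: int | Tuple[int, int] = 2000,
    placement_state: Optional[CondensationState] = None,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Long reads with cargo insertions and a constructed target-site duplication.

    ``insertion_rate`` is the expected number of inserts per read (Poisson).
    When ``duplication = d > 0`` the d bases 5' of each insertion point are
    duplicated immediately 3' of the insert; insertion points are resampled
    when chance flank identity would make the measured duplication differ
    from the constructed one, so the truth table is exact.
    ``placement_state`` optionally
    weights insertion points by the compartment of the host position (e.g.
    telomere weight 0 protects the telomere proper); host segments themselves
    are sampled uniformly, mimicking mechanical shearing.
    """
    if not (0 <= duplication <= 15):
        raise ValueError("duplication must lie in [0, 15]")
    cargo = cargo or CargoSpec()
    rng = np.random.default_rng(seed)
    reads: List[Tuple[str, str]] = []
    truth_rows = []
    arm_names = list(genome.arms)
    arm_lengths = np.array([len(genome.arms[a]) for a in arm_names], dtype=float)
    arm_probs = arm_lengths / arm_lengths.sum()
    for i in range(n_reads):
        if isinstance(read_length, tuple):
            L = int(rng.integers(read_length[0], read_length[1] + 1))
        else:
            L = read_length
        ai = int(rng.choice(len(arm_names), p=arm_probs))
        arm = arm_names[ai]
        arm_seq = genome.arms[arm]
        if len(arm_seq) <= L:
            host_start = 0
            host = arm_seq
        else:
            host_start = int(rng.integers(0, len(arm_seq) - L + 1))
            host = arm_seq[host_start : host_start + L]
        n_inserts = int(rng.poisson(insertion_rate))
        # candidate insertion points, kept clear of the read ends and separated
        margin = cargo.flank_window + duplication + 1
        lo, hi = margin, len(host) - margin
        points: List[int] = []
        if hi > lo:
            attempts = 0
            while len(points) < n_inserts and attempts < 50 * max(1, n_inserts):
                attempts += 1
                p = int(rng.integers(lo, hi))
                if placement_state is not None:
                    label = genome.compartment_of(arm, host_start + p)
                    w = placement_state.weight(label)
                    wmax = max(
                        placement_state.weight(lbl)
                        for lbl in ("telomere", "subtelomere", "chromatin", "centromere")
                    )
                    if rng.random() >= (w / wmax if wmax > 0 else 0.0):
                        continue
                if any(abs(p - q) < cargo.length + 2 * margin for q in points):
                    continue
                # reject points where chance flank identity would extend the
                # constructed duplication, so truth d is exactly measurable
                left = host[p - cargo.flank_window : p]
                right = (host[p - duplication : p] if duplication else "") + host[p : p + cargo.flank_window]
                if _measured_duplication(left, right) != duplication:
                    continue
                points.append(p)
        points.sort()
        read_id = f"longread{i}"
        seq = host
        shift = 0
        for p in points:
            p_shifted = p + shift
            orientation = "forward" if rng.random() < 0.5 else "reverse"
            insert_seq = cargo.sense_sequence if orientation == "forward" else revcomp(cargo.sense_sequence)
            dup = host[p - duplication : p] if duplication else ""
            seq = seq[:p_shifted] + insert_seq + dup + seq[p_shifted:]
            truth_rows.append(
                {
                    "read_id": read_id,
                    "insert_start": p_shifted,
                    "insert_end": p_shifted + cargo.length,
                    "orientation": orientation,
                    "duplication": duplication,
                    "arm": arm,
                    "host_position": host_start + p,
                }
            )
            shift += cargo.length + len(dup)
        reads.append((read_id, seq))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "insert_start",
            "insert_end",
            "orientation",
            "duplication",
            "arm",
            "host_position",
        ],
    )
    return reads, truth


def simulate_nanopore_telomere_reads(
    genome: SyntheticGenome,
    adapter: str = "CCCTCCGATA",
    n_reads: int = 20,
    length_range: Tuple[int, int] = (6000, 14000),
    telomere_repeat_range: Tuple[int, int] = (200, 600),
    seed: int = 0,
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Nanopore-style telomere reads: adapter + C-strand repeat + subtelomere.

    Truth boundary = emitted repeat length (after adapter trimming). A short
    guard segment free of the boundary motif separates the telomere from the
    subtelomeric continuation so the boundary is exact on noise-free reads.
    """
    rng = np.random.default_rng(seed)
    c_repeat = "TAACCC"  # C-strand repeat, phased to the boundary-scan motif
    region_seqs = genome.region_sequences()
    subtel = region_seqs.get("subtelomere", [""])[0]
    chromatin = region_seqs.get("chromatin", [""])[0]
    continuation_src = revcomp(subtel + chromatin) if (subtel or chromatin) else ""
    reads = []
    truth_rows = []
    for i in range(n_reads):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        k = int(rng.integers(telomere_repeat_range[0], telomere_repeat_range[1] + 1))
        telomere = c_repeat * k
        guard = _guard_segment(rng, 25, c_repeat)
        remainder = max(0, L - len(telomere) - len(guard))
        if continuation_src and remainder:
            if len(continuation_src) > remainder:
                off = int(rng.integers(0, len(continuation_src) - remainder + 1))
                tail = continuation_src[off : off + remainder]
            else:
                reps = remainder // max(1, len(continuation_src)) + 1
                tail = (continuation_src * reps)[:remainder]
        else:
            tail = _random_spacer(rng, remainder)
        read = adapter + telomere + guard + tail
        read_id = f"teloread{i}"
        reads.append((read_id, read))
        truth_rows.append(
            {
                "read_id": read_id,
                "boundary": 6 * k,
                "trimmed_length": len(read) - len(adapter),
            }
        )
    return reads, pd.DataFrame(truth_rows)


def _measured_duplication(left: str, right: str, d_max: int = 15) -> int:
    best = 0
    for d in range(1, d_max + 1):
        if left[-d:] == right[:d]:
            best = d
    return best


def _guard_segment(rng: np.random.Generator, length: int, forbidden: str) -> str:
    while True:
        guard = _random_spacer(rng, length)
        if forbidden not in guard and forbidden not in (forbidden[-5:] + guard):
            return guard


def write_parameter_sidecar(path, **params) -> None:
    """Echo generation parameters next to simulator outputs."""
    import json

    with open(path, "w") as out:
        json.dump({k: _jsonable(v) for k, v in params.items()}, out, indent=2, sort_keys=True)
        out.write("\n")


def _jsonable(value):
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if hasattr(value, "__dict__"):
        return {k: _jsonable(v) for k, v in vars(value).items()}
    return str(value)
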