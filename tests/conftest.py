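import numpy as np
import pytest

import telomark as tm
from telomark.nanopore import distance_label

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_windows(rng: np.random.Generator, src: str, n: int, width: int = 50):
    starts = rng.integers(0, len(src) - width + 1, size=n)
    return [src[s : s + width] for s in starts]


@pytest.fixture(scope="session")
def small_genome() -> tm.SyntheticGenome:
    spec = tm.SyntheticGenomeSpec(
        n_arms=2,
        telomere_repeats=300,
        subtelomere_length=2000,
        chromatin_length=20_000,
        centromere_monomers=20,
        seed=5,
    )
    return tm.make_genome(spec)


@pytest.fixture(scope="session")
def trained_origin_model():
    """A model fit on separable synthetic windows, shared across tests.

    Three classes: pure-telomere windows (label 0), uniform-random chromatin
    windows (log10(1 + 1e7)) and windows of a fixed 171-bp centromeric
    monomer repeat (log10(1 + 5e7)). Returns the fitted model plus fresh
    held-out windows per class.
    """
    rng = np.random.default_rng(42)
    monomer = random_dna(rng, 171)
    cent_src = monomer * 3
    telo_src = "TTAGGG" * 20
    labels = {
        "telomere+subtelomere": 0.0,
        "chromatin": distance_label(1e7),
        "centromere": distance_label(5e7),
    }
    n_per = 2000
    seqs, ys = [], []
    for cls, src in (("telomere+subtelomere", telo_src), ("centromere", cent_src)):
        for w in random_windows(rng, src, n_per):
            seqs.append(w)
            ys.append(labels[cls])
    for _ in range(n_per):
        seqs.append(random_dna(rng, 50))
        ys.append(labels["chromatin"])
    model = tm.OriginCNNRegressor(epochs=80, random_state=0).fit(seqs, np.array(ys))
    test_sets = {
        "telomere+subtelomere": random_windows(rng, telo_src, 666),
        "centromere": random_windows(rng, cent_src, 666),
        "chromatin": [random_dna(rng, 50) for _ in range(668)],
    }
    return model, np.array(ys), test_sets, labels
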