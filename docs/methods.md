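# Methods

## The nTA statistic

A read is classified *telomere-like* when it contains at least
`min_consecutive` strictly tandem (zero-gap) copies of the canonical
telomere hexamer `TTAGGG` on either strand; the default threshold of 3 is
the cutoff classically calibrated against terminal restriction fragment
measurements for whole-genome data. "Tandem" is taken literally: runs are
measured per strand and any non-matching character — including N — breaks a
run, so low-quality bases can only shorten runs, never extend them.

The library- or cell-level statistic is

    nTA = telomere-like reads / total reads,

an exact quotient (NaN, not 0, when the denominator is 0). `RPM = nTA x 1e6`.
For per-cell visualization, nTA values are rank-transformed: average ranks
for ties, scaled by `(rank - 1)/(n - 1)` so the result lies in [0, 1] and is
comparable across libraries; a single cell or a constant vector maps to 0.5.

Counting units: in single-end mode each read is one unit; in paired mode one
fragment is the unit, and a fragment is telomere-like when either mate
qualifies — matching droplet-ATAC fragment semantics while keeping bulk
FASTQ behavior simple. Alignment streams include unmapped and duplicate
records (telomere-like reads rarely map) and exclude secondary and
supplementary records to avoid double counting; each exclusion is
configurable. Records without a cell barcode accumulate in a reserved
`no-barcode` row that never participates in the rank transform.

Variant telomere repeats (TVRs) are hexamers matching `T**GGG` other than
the canonical motif. They are tallied per concrete hexamer by a single
non-overlapping scan per strand with no run requirement (none is applied to
variants in the source analyses); an optional tandem-run threshold is
exposed in the configuration for stricter counting.

## Read-pair reorientation and logos

Telomere-like reads cannot be placed by alignment, so pairs are oriented by
content: if the G fraction of R1 — assessed over the whole read by default,
a 5'-prefix window is configurable — falls below 0.5, both mates are reverse
complemented and swapped. The operation assumes mates in *fragment
orientation* (R1 = prefix read, R2 = suffix read of the same strand); a raw
FASTQ R2, which reads the complementary strand, is reverse complemented
first (the CLI does this automatically). Under that convention the
transform maps the pair onto the opposite strand, so the G-rich (TTAGGG)
strand always ends up as R1 and the operation is idempotent whenever one
strand is G-rich — which is the telomere-like case it is used for. Logos
are plain per-position base-frequency matrices over {A,C,G,T,N}; ragged
reads are N-padded, and the N column can be excluded from the
normalization denominator.

## Tn5 cargo insertions in long reads

The insertion atlas assumes a 95-bp non-fragmenting cargo terminated on
both sides by the 19-bp Tn5 mosaic end, so an insertion leaves the intact
cargo embedded in a mechanically sheared long read. Detection is
seed-and-verify: exact `seed_length`-mers (default 20) tiled across the
cargo in both orientations propose full-length intervals that are verified
by Hamming distance at `max_mismatch_fraction` (default 0.1). Seeds are
tiled — not restricted to the termini — because with substitution noise of
a few percent the probability that a specific 20-mer survives intact is
only ~0.5; tiling keeps clean-read behavior identical while holding recall
above 95% at 5% substitution noise. Overlapping candidates resolve to the
lowest-mismatch event, ties leftmost, then forward orientation.

Target-site duplication is measured as the standard direct repeat: the
largest `d <= d_max` (default 15) such that the last `d` bases of the left
flank equal the first `d` bases of the right flank (flanks default to 30 bp
immediately outside the insert). Wild-type Tn5 is expected to leave a 9-bp
duplication; the measurement is symmetric and reports 0 when no repeat
exists. Note that on random sequence the flanks agree on at least one base
with probability ~1/4, so a "no duplication" event can measure d = 1–2 by
chance; analyses should read the distribution (modal value), not single
events. Insertion-context matrices stack the ±window host sequence around
each insertion point (cargo removed, reverse-orientation events reverse
complemented into the cargo frame); the proximity profile records the
signed offset from each insertion point to the nearest TTAGGG start within
±60 bp of the insert-excised host, ties resolving upstream. For
insert-conditioned nTA the detected cargo bases are masked with N before
motif scanning, so motifs inside the cargo never count.

## Nanopore telomere reads and the subtelomere boundary

Reads are expected to begin with the ligated biotin adapter `CCCTCCGATA`;
it is removed only when it matches at position 0 within
`adapter_mismatches` (default 0 — the adapter is short enough that a
mismatch allowance mostly admits false trims). Reads whose trimmed length
is below `min_read_length` (default 8000 bp) are flagged, never silently
dropped. The subtelomere boundary scan starts a cursor at 0 and repeatedly
looks for `TAACCC` starting within `[0, max_gap]` (default 18, inclusive)
of the cursor, jumping past each leftmost match; where the scan stalls is
the subtelomere start, and its coordinate equals the telomere length. The
window is inclusive so that a full 18-bp interruption (three non-matching
hexamers) is tolerated.

## The read-origin regressor

Training examples are 50-bp windows labeled with `log10(1 + d)` where `d`
is the distance from the telomere: 0 anywhere within the telomere proper,
the offset past the boundary for subtelomeric windows from nanopore reads,
and fixed pseudo-distances for reference windows — 1e7 for chromatin proper
(order of a chromosome-arm length) and 5e7 for the centromere; both are
configurable. The `1 + d` shift resolves the d = 0 case of a plain log. The
reverse complement of every window is appended so strand carries no signal.

The network is deliberately small to limit overfitting: one-hot ATCGN input
(50 x 5), two unpadded 1-D convolutions of kernel width 6 (matching the
telomere hexamer) with 20 filters each and rectifier nonlinearities, and a
dense head on the flattened feature map — 3 841 trainable parameters, no
pooling. The loss is mean squared error on the log-distance. Data are
split 80/20 into training and held-out sets inside `fit`; the per-epoch MSE
trace on both is recorded. Optimization is mini-batch Adam (defaults:
batch 64, learning rate 1e-3, 200 epochs); optimizer, batch size and
learning rate are recorded in the saved model artifact, and training is
bit-deterministic under `random_state`. Scalar predictions are binned to
the nearest class log-label with boundaries at the midpoints of the class
labels in log space; telomere-proper predictions (0) merge into the
subtelomere bin, since distance-0 windows are overwhelmingly subtelomeric
in short-read data.

## Correlation analyses

Per-feature association with per-cell nTA uses Spearman's rank correlation
(Pearson via flag) with two-sided p-values; Benjamini–Hochberg q-values are
reported next to the raw p-values. Constant vectors yield NaN and rank
last. The grouped ranking computes per-group correlations (groups =
cell-type x batch subsets), retains only groups with strictly more than
`min_cells` cells (default 1000) to reduce noise, and aggregates the
per-group correlations into mean, sample variance, and the literal
mean/variance ratio; the ratio de-emphasizes features whose correlation is
strong but unstable across groups (e.g. GC-content artifacts). Zero
variance yields a signed-infinity sentinel that sorts above all finite
ratios of the same sign; fewer than two retained groups is an error naming
the filter.

## Synthetic data

The genome generator emits arms laid out 5'→3' as telomere proper (pure
`TTAGGG` tandem repeats), subtelomere, chromatin proper, and centromere
(exact tandem copies of a random 171-bp monomer). The subtelomere consists
of blocks of 3–10 tandem hexamers — canonical with probability
`1 - tvr_rate`, otherwise a random `T**GGG` variant — separated by random
spacers sized to a target block density of 0.5, so the ≥3-run classifier
fires on a tunable fraction of subtelomeric fragments; accidental `T**GGG`
matches arising inside spacers are mutated away so the variant content is
exactly the designed one.

ATAC-like fragments are sampled proportionally to per-compartment
accessibility weights times compartment length. Defaults encode the
biology the package measures: telomere proper 0.001 (protected from
transposition), subtelomere 1.0, chromatin proper `1/(1 + c)` for
condensation parameter `c`, centromere 0.2. Raising `c` therefore raises
the expected nTA — the model of condensation driving the biomarker.
Fragments stay inside their sampled compartment when it is long enough, so
truth labels describe whole fragments. Long-read simulation shears the
genome uniformly and places cargo insertions (Poisson per read, optional
compartment weighting), duplicating the `d` bases 5' of each insertion
point after the insert; insertion points whose flank context would make the
measured duplication differ from the constructed `d` by chance are
resampled, keeping the truth table exact. Nanopore simulation emits
adapter + C-strand telomere repeat (phased to the `TAACCC` scan motif) + a
short motif-free guard + subtelomeric/chromatin continuation, so the truth
boundary is recovered exactly on noise-free reads. Every generator is a
pure function of its arguments and seed.

What the simulators do *not* model: sequencing error profiles of specific
instruments, PCR duplication, barcode errors, chimeric reads, and the
telomere-length heterogeneity across chromosome arms and individuals.
Passing tests therefore demonstrate correctness of the computational
pipeline under the stated genome/accessibility model, not performance on
real libraries.

## Problem sizes and numerical choices

The test suite and benchmark script run everything at desk scale, chosen so
results are statistically stable: genome arms of tens of kilobases for unit
tests; 50 000 fragments per condensation state for the monotonicity check;
150 000–500 000 uniform reads per genome for the telomere-length-ratio
benchmark (4 arms, 2 Mb non-telomeric sequence, 5000 vs 1250 telomere
hexamers per arm — the 4:1 design gives an expected nTA ratio of ~0.26,
slightly above 1/4 because the shorter-telomere genome is also slightly
smaller); and 6000 training windows / 80 epochs for the origin model's
separable three-class benchmark, which reaches ≥0.99 per-class recall.
Ties in rank transforms use average ranks; duplication ties report the
largest qualifying `d`; insert-candidate ties resolve lowest-mismatch,
leftmost, forward-first. Degenerate inputs (empty streams, constant
vectors, zero denominators) return explicit errors or NaN markers as
documented per function, never silent zeros.

## Known limitations

- nTA is a condensation biomarker, not a telomere-length estimate; the
  package deliberately does not fit length calibrations.
- The boundary scan assumes C-strand (`TAACCC`-frame) nanopore reads and
  exact motif matches; highly degenerate telomere starts shorten the
  detected telomere.
- The origin model is trained per dataset; no pretrained weights ship with
  the package, and hyperparameters were not searched beyond the stated
  defaults.
- Insert detection assumes substitution-dominated noise; long indels inside
  the cargo defeat the fixed-length Hamming verification.
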