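# Methods

This note records the models implemented in `hetspacer`, the defaults and
why they were chosen, what the simulator does and does not emulate, and
the numerical conventions that matter when comparing output to other
tools.

## Library architecture

Each amplification primer carries, 5′→3′ in sequencing order: a flow-cell
linker (upstream of the sequencing start, never present in reads), a 12 bp
sample index, a heterogeneity spacer of 0–7 bp, and the gene-specific
primer. The in-line sequenced prefix of every read is therefore
`index + spacer + gene primer`, 29–50 bp for the default primers. The two
mate-wise indices concatenate to a 24 bp dual barcode; a 24 × 24 index
design addresses 576 samples.

Default gene primers are the standard V3-V4 pair 341F
`CCTACGGGNGGCWGCAG` (17 bp) and 805R `GACTACHVGGGTATCTAATCC` (21 bp),
flanking a ~469 bp amplicon (431 bp insert). Any IUPAC primer pair can be
substituted; all primer matching expands degenerate codes.

## Index-set design

Objective: minimize `max_{c∈1..12, b∈{A,C,G,T}} |f_b(c) − 0.25|` over the
chosen k indices, subject to every pair being at Hamming distance
≥ `min_hamming` (default 3, which makes any single index error uniquely
correctable at matching tolerance 1; the ambiguity of two errors is
routed to undetermined rather than guessed).

The search is greedy forward selection — start from each candidate in
turn, repeatedly add the feasible candidate that minimizes the partial
objective, ties broken by lexicographic order — plus seeded restarts with
randomized near-best choices, followed by a local-search polish that
exchanges one or, on small instances, two members while it improves the
objective. The 2-exchange phase is capped by instance size
(`k²(n−k)² ≤ 3·10⁵`) so that a 24-from-96 design completes in seconds. On
pools small enough to enumerate (20 choose 8), the search returns the
exhaustive optimum on every seed tried; this is asserted in the test
suite, not assumed. The max-deviation objective (rather than chi-square)
was chosen because it is the quantity the balance claim is stated in and
is trivial to certify per cycle.

A perfectly balanced subset (deviation 0) requires k divisible by 4; the
designer warns otherwise. Infeasible distance constraints fail loudly,
naming the constraint.

## Spacer-set design

One spacer per requested length 0–7. The binding constraint is
*prefix-distinguishability*: for any two spacers s_i, s_j (|s_i| < |s_j|),
`s_i + primer` must not match a prefix of `s_j + primer`, otherwise the
spacer length could not be recovered from sequence alone. Matching is
IUPAC-compatible (a degenerate primer base conflicts with every base in
its expansion), which is stricter than literal equality and guarantees
distinguishability for any concrete read. Note this is a property of the
whole `spacer + primer` string: a primer that repeats its own prefix
(e.g. one starting `CC…`) shadows more candidate spacers.

Among feasible sets, a seeded randomized search minimizes the pooled
spacer block's composition deviation, *averaged* over spacer cycles: the
deepest cycle is always served by the single longest spacer and would
saturate a max-based objective, leaving it unable to rank candidates.

## Sample layout

`assign_samples` walks the fwd × rev grid diagonally (a Latin-square
enumeration), so each forward and each reverse index is used as evenly as
possible even when only part of the grid is populated; a random subset of
grid cells would concentrate some indices and forfeit the balance the
index sets were optimized for. The seed permutes index labels, not the
walk, keeping layouts balanced and reproducible. Spacer lengths are cycled
in sorted order, so per-length counts differ by at most one, and each
sample receives the same spacer length on both mates — this is what pins
the stitched-read length to `438 − 2s` for the default 250PE geometry.

## Demultiplexing

The barcode is the first 12 bases of each mate, concatenated. A sample
matches when its forward index is within `max_index_mismatch` (default 1)
of the first half AND its reverse index within the same tolerance of the
second half, independently per mate; zero or multiple qualifying samples
send the pair to the undetermined bin — ambiguity is never resolved by
guessing. After assignment the sample's recorded spacer length fixes the
primer offset (12 + s), where the gene primer is verified under
IUPAC-aware Hamming matching with tolerance `max_primer_mismatch`
(default 2, indel-free by design: substitutions dominate MiSeq errors and
fixed offsets keep the operation exact and fast). Failing pairs are
discarded and counted separately from undetermined. Accounting is checked:
assigned + undetermined + discarded always equals input pairs.

## Quality-control cascade (250PE)

Order is fixed, pair-synchronized throughout (either mate failing drops
the pair), and every truncation returns a prefix — interior bases and
their qualities are never edited:

1. **Sliding window**: truncate immediately before the start of the first
   30 bp window (step 1 base) whose mean phred is below 20. Any read —
   input or truncation survivor — shorter than one window is judged as a
   single whole-read window; applying the rule to survivors as well is
   what makes the operation idempotent.
2. **Pair length**: discard the pair if either mate kept less than 75 % of
   its pre-trim length (strictly less; 225 of 300 survives, 224 does not).
3. **Consecutive low quality**: truncate before the first run of ≥ 3 bases
   each below Q20. The run length is fixed at 3; the threshold is
   configurable (Q20 default, consistent with the window criterion; the
   historical QIIME default of Q3 is a valid setting).
4. **Ambiguity**: any non-ACGT call (after case normalization) drops the
   pair.
5. **Minimum length**: both mates must keep ≥ 150 bases (inclusive).

Only the 150 bp rule re-evaluates length after step 3; the 75 % rule is
not re-applied. Stage counts telescope and are asserted at run time.

The 300PE path applies *no* trimming before assembly — overlap consensus
does the error correction — and only the ambiguity and minimum-length
filters apply to the merged product.

## Pair resolution

`find_overlap` scores every overlap length from `min_overlap` (default 10)
up to the shorter mate between mate 1 and the reverse-complemented mate 2:
the candidate with the lowest Hamming mismatch ratio wins, ties going to
the longer overlap, and is accepted only at ratio ≤ `max_mismatch_ratio`
(default 0.25). These are FLASH-style defaults. The consensus copies
non-overlap flanks verbatim; inside the overlap, agreeing positions keep
the higher quality and disagreements take the higher-quality base with
quality `|q1 − q2|`, so an unresolved conflict is visibly low-confidence.
Merged length is exactly `len1 + len2 − overlap`.

250PE pairs merge when an acceptable overlap exists and are otherwise
stitched: `mate1 + revcomp(mate2)`, qualities carried, no separator
inserted, the junction position recorded in the header comment so
downstream consumers can split. With a 469 bp amplicon and 250 bp reads
there is no true overlap after prefix removal, so nearly all pairs stitch;
in ~10⁴ random-insert pairs a handful of spurious ≥ 10 bp flank overlaps
clear the 0.25 ratio and merge, which is expected behaviour of the
threshold, not an error. 300PE pairs must merge; those without an
acceptable overlap are rejected and counted.

## Diagnostics

Per-cycle base composition uses, at each cycle, only reads extending to
that cycle (per-cycle denominators are reported alongside). Balance score
is the max-deviation statistic above over a chosen cycle range. Plots are
optional and always derive from the serialized matrices — the numeric
artifact, not the image, is the test surface.

One caveat for spacer-benefit comparisons: increasing the number of
distinct spacer lengths does not strictly lower the primer-cycle balance
score at *every* step. A primer that repeats its first base (341F starts
`CC…`) leaves a point-mass cycle when staggered by a single offset, so
1 → 2 lengths can tie at the 0.75 bound; the score is monotonically
non-increasing in the number of lengths and strictly lower at 8 than at 1.

## Simulator

`simulate_run` emits reads with the exact library anatomy
(`index + spacer + template`, mate 2 from the reverse complement),
truncated to the protocol read length, and logs every pair to a ground
truth table (sample, template, spacer lengths, injected error positions).
Defaults mirror the targeted study conditions: 469 bp amplicon, 250 bp or
300 bp reads, a 20 % barcode-less random-sequence contaminant standing in
for a PhiX spike, and a 1.5 % mean substitution rate (reported MiSeq
machine error for such runs is ~1.2–1.7 %). Per-sample depth is a free
parameter; tests and the acceptance script use 30–1 250 pairs per sample
to keep desk-scale runtimes in seconds while leaving binomial noise well
below the asserted margins.

The quality model is a linear mean decay from `start_q` (38) at
`decay_per_cycle` (0.05/cycle) with a smooth softplus floor at Q2 and a
flat mate-2 penalty (4), per-base Gaussian noise (σ = 3) clipped to
[2, 40]. Substitution errors are quality-dependent: each base's error
probability is proportional to its phred error probability, scaled so the
read-mean equals the configured rate. Contaminant mates are random
sequence whose first 12 bp are kept ≥ 2 mismatches from every sheet index,
so they can never demultiplex even at tolerance 1.

Not emulated: indels (the whole pipeline is substitution-matched by
design), chimeras, optical/cluster artifacts, the PhiX genome itself, and
real instrument metrics (cluster density, %≥Q30). Passing tests therefore
demonstrate correctness of the algorithms under a substitution-dominated
error model, not robustness to indel-rich or chimeric data.

## Numerical conventions

- Phred scores are integers in [0, 60]; only phred+33 FASTQ is accepted,
  and +64-looking input fails loudly.
- Cycle numbers and reported coordinates are 1-based inclusive; internal
  slices are half-open.
- Composition rows must sum to 1 ± 1e-9 over live reads; violations raise.
- All randomized procedures (index search, spacer search, layout,
  simulation) take explicit seeds and are bit-reproducible; the simulator's
  FASTQ output is byte-identical across runs of the same config.
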