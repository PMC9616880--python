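# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of captorkit. It states nothing the tests or the
acceptance script do not themselves compute.

## Adaptor panel design

Each adaptor is `constant5 + variable + constant3`. Defaults: 72 adaptors,
30 nt per segment, k = 6. The 5' constant segment is a "burn-in" absorbing
the elevated error of the first bases of a nanopore read; the 3' constant
segment is shared to avoid preferential ligation. Both are seed-derived
random sequences passed through the same screens as the panel.

**k-mer-complete source.** The variable regions are windows of a de Bruijn
sequence B(4, k), built by Hierholzer's algorithm on the order-(k−1) graph
with lexicographic edge preference. The cyclic label sequence is rotated
by a seed-determined offset and linearised by appending its first k−1
symbols, so every k-mer occurs exactly once as a window; length 4^k+k−1.

**Window selection.** 72 × 30 nt = 2160 nt cannot contain all 4096 6-mers,
so selection greedily maximises the number of distinct 6-mers covered
(ties broken by leftmost window; deterministic). The default panel covers
1800 distinct 6-mers. A minimum pairwise edit distance of 10 between
variable regions is enforced — **also against the reverse complements of
already-chosen regions**. The forward-only constraint in an earlier design
allowed the 3' adaptor of a read, seen in reverse, to sit within a few
edits of another adaptor's variable region and produced ~4% misclassified
reads at realistic error rates; the two-strand constraint removes the
ambiguity. Distance 10 over 30 nt keeps adaptors classifiable at per-read
error rates well above 0.1/nt.

**Screens.** The hairpin screen finds the longest contiguous
Watson–Crick-paired stem with loop ≥ 3 nt (no wobble pairs, DNA) by an
O(n²) complementary-run recurrence; the threshold is stems > 8 nt. The
homology screen is the longest exact substring shared with a user-supplied
FASTA (both strands, binary search over length with hashed windows);
threshold > 20 nt. Both are validated against brute-force oracles in the
tests. Adaptors failing a screen have their variable region replaced by
the next candidate window, with a bounded retry budget.

## Staggered master mix

Adaptors are assigned in input order to groups of nine across eight
two-fold dilution levels (undiluted to 1:128). "Equal amounts of each
dilution mixed" is modelled as equal per-adaptor relative concentration
within a level, so the expected read fraction of a level-g adaptor is
2^−g/(9 · Σ_{j<8} 2^−j) — 1/2295 ≈ 0.044% at the lowest level. Group
assignment is deterministic; a seeded shuffle is available.

## Read simulator

The simulator is first-class, tested code: it is the ground truth every
downstream stage is validated against.

**Error model.** Per 6-mer and per class (mismatch, insertion, deletion):
`rate = clamp(base + gc_slope·GC_fraction + homopolymer_slope·(maxrun−1)
+ N(0, systematic_sd), 0, 0.5)`, with the per-6-mer normal offset frozen
by the seed — replicate libraries share it, making the error *systematic*.
Defaults (base 0.020/0.012/0.018, gc_slope 0.018, homopolymer_slope 0.006,
systematic_sd 0.010) give mean rates of 0.035 mismatch and 0.060 indel,
0.095 total — the magnitude reported for MinION sequencing, split roughly
one-third mismatch to two-thirds indel. The GC and homopolymer slopes make
GC-rich and repetitive 6-mers the worst, reproducing the qualitative
ranking seen in real data.

**Error channel.** Each emitted base uses the 6-mer context *ending* at
its template position (the first five positions use a left-truncated
context, equivalent to padding with A). At most one event per position:
deletion skips the base, insertion emits the base plus one uniform random
base, mismatch substitutes one of the other three. Rates are scaled per
read by the pore channel's error multiplier and clamped at 0.5.
Quality strings are constant placeholders (no analysis uses them). Half
the reads are emitted reverse-complemented. Positions are independent
given context; within-read error autocorrelation is not modelled.

**Reads and metadata.** A read is a manifest-weighted adaptor, an insert
drawn from the sample references, and (by default) an independently drawn
3' adaptor. Headers carry ONT-style `ch=` and `start_time=` fields; a
truth table records the adaptor, channel, time, insert source, orientation
and event counts per read.

**Mock-community pairs.** `simulate_mixture_pair` produces two conditions
× N replicates sharing the master mix. Condition B's feature abundances
are A's × 2^spec, with read depth scaled by Σ2^spec/n so that *expected
counts* (not just shares) follow the spec — a doubled feature yields
doubled counts. Each library draws a size scalar 2^N(0, 0.25) and a batch
scalar b ~ N(0, batch_sd); b perturbs the draw probability of every
feature *and* adaptor through fixed per-sequence loadings (×2^{b·loading}),
planting shared unwanted variation that control-anchored normalisation can
estimate. The benchmark used in the tests sets batch_sd = 1.5, making the
per-feature distortion comparable to the planted fold changes — a batch
effect worth correcting — and uses a *balanced* fold-change spec
(Σ2^spec = n features) so that proportion-based evaluation carries no
compositional offset.

## Classification and alignment

Reads are clipped to their first 500 nt. The aligner is an own unit-cost
semi-global dynamic programme (reference end-to-end, free query ends),
numba-compiled, with deterministic conventions frozen in tests: endpoint =
smallest query index attaining the minimal cost; traceback preference
match > mismatch > deletion > insertion; insertions attributed to the
preceding reference position (pileup convention); 0-based coordinates.
It is validated against an exhaustive alignment-path enumeration oracle.
One consequence of the tie-break: when a short reference matches only
partially, a mismatch path against flanking bases is preferred over an
equal-cost deletion path.

**Decision rule.** Candidates are ranked by full-adaptor alignment cost:
the shared constant segments anchor the variable region's position and
their error contribution is identical across candidates, so cost
differences reflect the variable region (which carries all the signal).
The `min_identity` threshold (default 0.7 ≈ 3× the typical per-base error,
far above random ~0.55) applies to the variable-region identity extracted
from the winning traceback; exact cost ties between distinct adaptors give
UNCLASSIFIED. For speed, a 6-mer seed index over the variable regions
shortlists candidates — scanning only the prefix window where the variable
region can lie (offset ± 12 nt of indel slop), because seeds from the
insert otherwise crowd out the true adaptor — and an exhaustive rescue
pass (all 72 adaptors, both orientations) fires whenever the best
shortlisted cost exceeds 0.12 × adaptor length or ties, preserving the
best-over-all-adaptors contract at ~1 ms/read. At the default error rate
essentially all reads classify correctly; rare (~5·10⁻⁵/read) genuine
inversions exist where a heavily errored read is strictly closer to a
wrong adaptor — no best-scoring rule can avoid those.

**Insert assignment.** The insert runs from the end of the 5' adaptor
alignment to the located start of any 3' adaptor (found via the shared
constant5). It is aligned to each feature reference; best identity ≥
threshold wins, ties are UNASSIGNED. Feature counts are mean aligned
depth: aligned insert bases / feature length.

## Error profiling

Rates are events/depth at positions with depth ≥ 10 (default; bounds the
variance of a rate estimate at ~0.15²/10), NaN elsewhere. 6-mer windows
with any undefined position are skipped. Window rate = unweighted mean of
its six positions; 6-mer rate = unweighted mean over instances. The
replicate-difference metric is the symmetric mean relative difference,
mean(100·|a−b|/((a+b)/2)) over shared 6-mers with (a+b)/2 > 0 — a
documented stand-in, not a claim about any published metric.

**What a recovered rate estimates.** Minimum-edit alignment cannot observe
generative events that cancel: an insertion and a deletion within one
homopolymer run restore the original sequence, and adjacent indel pairs
collapse into single mismatches. At ~0.1/nt this biases recovered rates
below the generative rates by up to ~0.02 for high-rate 6-mers — dozens of
standard errors at deep coverage, and intrinsic to *any* alignment-based
error profiler. The estimand of the pipeline is therefore the
**alignment-observable rate**. The parameter-recovery acceptance test
compares the full pipeline (simulate → classify → accumulate → window
averaging) against an independent oracle that passes each bare adaptor
template through the same error channel and aligns it directly back to its
reference — no classification, clipping or inserts — with combined
binomial standard errors; ≥ 95% of 6-mers must agree within 3 SE.

**Correction.** `subtract_profiles` computes max(0, sample − control) per
position and class (rates are probabilities, hence the clamp; the spec of
the operation is silent on negative differences). Summaries are medians
over positions where both profiles are defined, optionally restricted to a
variant mask. At the read level, the observable variant excess is
slightly below the allele fraction (the variant base itself is subject to
the error channel), typically by 10–20% at 0.1/nt error; the acceptance
check for correction efficacy therefore constructs event profiles
binomially from shared rate vectors — the construction the operation's
contract is defined on — and the read-level workflow is demonstrated in
`examples/06_error_correction.py`.

## Quantification and normalisation

**Ladder.** OLS of log2 count on log2 relative concentration (log-log
axes; the ladder is linear in log2 space by construction of the two-fold
series). Zero-count adaptors are excluded rather than pseudocounted —
pseudocounts would bend the low end of the ladder exactly where the LOQ
lives — and reported as not detected. The slope CI is standard OLS,
t(0.975, n−2)·SE.

**Segmental fit.** Continuous two-segment model y = b0 + b1·x +
b2·(x−c)₊, with c grid-searched over midpoints between consecutive
distinct sorted x. |b2| < 1e−8 flags a degenerate (collinear) fit. The
LOQ is 2^(fitted y at c): the observed-count coordinate of the kink, in
reads.

**Reliable depth.** The criterion — every manifest adaptor detected with
≥ 5 reads and ladder R² ≥ 0.95 — is this package's operationalisation and
is configurable. Subsampling operates on per-read classifications, which
is identical in distribution to classifying subsampled reads because
classification is per-read deterministic.

**TMM.** Implements the trimmed mean of M-values with double trimming
(30% per M tail, 5% per A tail), precision weights = inverse asymptotic
variance of M, reference sample = upper quartile closest to the mean, and
factors scaled to geometric mean 1. Verified against edgeR's
`calcNormFactors` to ~1e−10 in the tests (edgeR is the cross-check, never
the implementation).

**RUVg.** log(count+1) on control rows, row-centred; SVD over samples;
W = first k scaled left-singular directions (k = 1 default — the smallest
model, adequate for a single planted factor); each feature's log counts
regressed on [1, W] and the W component removed; result exponentiated and
clamped at 0.

**Fold-change evaluation.** Observed log2FC = log2(mean_B/mean_A) with a
0.5 pseudocount; `normalize="proportion"` scales columns to within-sample
shares first (cancels library size, introduces compositional closure),
`"none"` takes values as given. Detection is the effect-size rule
|log2FC| ≥ 1 — replicate counts at desk scale are too small for
significance testing, a deliberate divergence from inferential practice.
TPR is over features with |expected| ≥ threshold, TNR over expected = 0.

## What the simulator does and does not establish

Green tests establish that every analysis stage recovers the parameters of
the stated synthetic world: manifest-weighted adaptor draws, per-6-mer
systematic errors with GC/homopolymer structure, pore-multiplier and batch
distortions. Real nanopore data differ in ways the generator deliberately
omits: signal-level artefacts and base-caller idiosyncrasies, within-read
error autocorrelation, realistic quality scores, chimeric reads, and
length-dependent coverage biases. Headline numbers from real experiments
(e.g. a specific LOQ in reads, or an exact replicate-difference
percentage) are functions of those real-data properties and are not
reproduced here — the package reproduces the *methods* and their
qualitative behaviour at desk scale.

## Interface conventions

Coordinates are 0-based half-open everywhere (BED native). FASTQ parsing
is permissive (CRLF tolerated, '+' line content ignored); FASTA/FASTQ I/O
goes through Biopython. The library has no command-line interface: the
importable API plus `examples/` scripts are the surface, and
`captorkit.run_pipeline` provides the end-to-end driver with one seed
fanned out to per-stage substreams (CRC-derived, bit-reproducible).
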