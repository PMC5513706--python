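# Methods

This note documents the models and procedures `spacerkit` implements, the
defaults it ships, and the design choices made where the underlying method
left room.

## Amplicon model and the synthetic-data generator

The sequencing design amplifies single repeat–spacer–repeat units from a
CRISPR array using primers anchored in the direct-repeat sequence; the
shortest (~125 bp) amplicon dominates the reaction and is size-selected, so
one read covers one spacer flanked by repeat-derived anchors. The generator
reproduces exactly this layout:

    5'-[random 5-nt tail][forward anchor][spacer][reverse anchor][filler]-3'

* **Read length 150 nt**, matching a 150-cycle single-end run; the amplicon
  is shorter, so random filler pads the 3' end.
* **Anchors** default to the repeat-matching regions of the published
  *A. platensis* primer pairs (type III-D: SS-4F/SS-4R; type III-B:
  SS-19F/SS-19R, which carries IUPAC degeneracies R and Y). Degenerate
  positions are resolved uniformly per read.
* **Abundances** follow a truncated Zipf law by rank, `w_r ∝ r^(−a)` with
  default exponent `a = 1.5`. Deeply sequenced repertoires are
  singleton-dominated; the exponent is a parameter because the true
  environmental abundance law is unknown, and 1.5 reproduces a
  singleton-heavy frequency histogram at desk-scale depths.
* **Spacer lengths** per class: III-D ~ round(Normal(40, 2)), III-B ~
  round(Normal(36, 2)), clamped to [25, 60] nt. Only the qualitative
  ordering (III-B shorter) and the ~35–40 nt scale are established; the
  normal form is a modelling choice.
* **Errors** are iid substitutions at a configurable per-base rate over the
  whole read (anchors included). Indels are deliberately absent: the
  downstream merge rules are substitution- and end-trim-shaped, and typical
  short-read substitution error dominates. `mutate_spacer` additionally
  produces the two artifact classes the clustering is designed to absorb —
  end trims and point mutations — for constructing test pools directly.
* **Strand**: a configurable fraction of reads is emitted
  reverse-complemented; provenance (truth index, strand, error count) is
  recorded per read.

What the generator does **not** emulate: PCR chimeras and amplification
bias, multi-spacer "ladder" amplicons, quality-score structure (FASTQ
qualities are constant), indels, and contamination. Tests passing on this
synthetic data therefore validate the algorithmic contracts — losslessness,
determinism, statistical calibration — not robustness to every artifact of
real libraries.

## Extraction and dereplication

Anchor search is ungapped sliding-window Hamming scoring against IUPAC
pattern tables, vectorised over all placements; the best (fewest-mismatch,
leftmost on ties) forward-anchor placement is taken, then the best
reverse-anchor placement downstream of it. Default budget: ≤2 mismatches
per anchor. Both strands are scanned (plus first); the spacer is reported
in array orientation with the strand it was found on. Reads with no
acceptable layout, or an out-of-bounds spacer length (default 25–60 nt),
are counted as rejected, never dropped silently.

Dereplication counts exact duplicates, ranks unique sequences by abundance
(count desc, then longer sequence, then lexicographic — the tie-break makes
every greedy pass deterministic), and absorbs each sequence into the
highest-ranked retained sequence within Hamming distance `merge_mismatches`
(default 1; equal lengths only). A pigeonhole segment index makes this
near-linear; its outcome is tested against the all-pairs transcription.
Anchor tolerance and merge radius are deliberately separate parameters.

## Greedy clustering

Unique spacers are swept in rank order; each candidate is absorbed by the
*first* retained parent satisfying either rule:

* **sites rule** — ≤ `max_diff_sites` (default 4) mismatches in the best
  ungapped overlap with overhanging ends free, modelling end-trimming
  artifacts. The end-deletion allowance is literally unbounded in the
  original formulation, which degenerates (any two sequences eventually
  share a tiny perfect core), so a minimum overlap is imposed — default
  20 nt, about half a spacer — and exposed as a parameter.
* **k-mer rule** — the parent has been observed ≥ `high_freq_threshold`
  (default 100) times and shares any exact `kmer_len`-mer (default 12) with
  the candidate, same orientation only (pools are strand-resolved; whether
  reverse complements should count is genuinely open, and the conservative
  same-strand reading is the default).

Absorption bookkeeping (member lists, which rule fired) is an additive
artifact for testability; the procedure itself only discards. A 12-mer
inverted index over high-frequency parents accelerates the second rule;
both rules are verified equivalent to a no-index brute-force transcription
on hundreds of random instances. Note the k-mer rule is intentionally
over-conservative: two unrelated random 40-mers share a 12-mer with
probability ≈5×10⁻⁵, so at realistic pool sizes a handful of genuinely
distinct spacers will be absorbed by chance — a property, not a bug, of a
procedure built to under-count acquisition events.

## Diversity

Chao-1 uses the bias-corrected point estimate
`Ŝ = S_obs + f1(f1−1)/(2(f2+1))`, which stays defined on
singleton-dominated pools where `f2 = 0` (the classical `f1²/2f2` does
not). The variance branches on `f2`:

* `f2 > 0`:  `var = f1(f1−1)/(2(f2+1)) + f1(2f1−1)²/(4(f2+1)²) +
  f1²f2(f1−1)²/(4(f2+1)⁴)`
* `f2 = 0, f1 > 0`:  `var = f1(f1−1)/2 + f1(2f1−1)²/4 − f1⁴/(4Ŝ)`

and the 95% lower bound is the log-normal construction on
`T = Ŝ − S_obs`: `lower95 = S_obs + T/C`,
`C = exp(1.96·sqrt(ln(1 + var/T²)))`. Which estimator variant the original
analysis used is not recorded; these standard forms are declared rather
than inferred. For a perfectly even (homogeneous-detection) pool the
estimator is near-unbiased rather than strictly below the truth, which is
why the Monte-Carlo lower-bound test compares means with a 3-SEM allowance.

Saturation curves subsample the pool's *observations* (count mass, not
distinct sequences) as nested prefixes of one shuffled observation stream
per replicate — progressively larger subsets, so each replicate's unique
curve is monotone by construction — and count distinct sequences directly
(`unique`) or after re-clustering (`clustered`). Clustered-mode curves are
quadratic in the number of parents and intended for desk-scale pools;
unique-mode curves are cheap at any scale, and a without-replacement
subsample admits an exact coupon-collector expectation
`E[distinct] = Σ_i (1 − P(hypergeom = 0))` used in tests.

## Coincidence

`P(a,b) = Σ_s p_a(s)·p_b(s)` over shared sequences, with `p` the
observation frequencies — the definition follows random draws of sequenced
spacers, so observation weighting (not per-unique-sequence weighting) is
used. Equality is exact dereplicated-sequence identity; cluster-level
equality would double-count what clustering already merged. The diagonal is
the within-sample Simpson collision probability, `P = 0` is reported with a
NaN log-sentinel (never a fabricated floor), and log10 is the transform.
The Cauchy–Schwarz bound `P(a,b) ≤ √(P(a,a)P(b,b))` and the exact
replicate-merge averaging identity serve as invariant tests.

## Assembly and mapping

Greedy assembly repeatedly merges the contig pair with the longest *exact*
suffix–prefix overlap ≥ `min_overlap` (default 15 nt), same orientation,
deterministic tie-break by list position. Exactness is deliberate: a
mismatch-tolerant merge chains unrelated spacers into chimeras. The
original "greedy" script's parameters are unrecorded; 15 nt is declared as
the default here.

Mapping is an exhaustive vectorised window comparison of each query (and
its reverse complement) against every reference placement with
≤ `max_mismatches` substitutions — contract-identical to the naive scan it
is tested against — with hits intersecting excluded BED intervals (native
CRISPR arrays) removed. Coordinates are 0-based half-open on the forward
strand. The chance-match baseline assumes an iid uniform-base linear
genome: `E = n · 2(G−L+1) · Σ_{i≤m} C(L,i)(3/4)^i(1/4)^(L−i)`; the exact
`G−L+1` edge term is kept. The k and mismatch allowance of the original
k-mer mapping are unrecorded; both are explicit parameters.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data at
desk scale, chosen to exercise every code path with tight statistical
checks: extraction round-trips on 10⁴ reads; richness recovery on 5 × 5×10⁴
reads from Zipf(1.5) pools of richness 500 at 0.2% per-base error;
clustering equivalence on 100 random instances of up to 300 records;
saturation on pools of 10⁵ observations (richness 100 uniform and 10⁵
Zipf); random-match calibration on 100-kb genomes. A finite Zipf(1.5)
sample of 5×10⁴ reads contains ~480 of 500 truth spacers, so recovery is
judged against the sampled truth and the ±10% band around nominal richness,
not against full richness. Headline full-depth counts from the original
multi-million-read datasets (≈2×10⁶ unique spacers, ≈2×10⁵ clusters)
require the deposited raw data and are out of the desk-scale scope.

All randomness flows through `numpy.random.default_rng` seeds; fixed seeds
give bit-identical FASTQ output and curves. Degenerate inputs (empty pools,
single-record pools, no valid anchor, no valid overlap) return explicit
empties or sentinels (`inf` mismatches, NaN log-probabilities) rather than
raising mid-pipeline; precondition violations raise `ValueError` at the
boundary.

## Known limitations

* Substitution-only error and artifact model; indel-heavy platforms would
  need the (absent) gapped comparison the clustering deliberately avoids.
* Clustered-mode saturation does not scale past ~10³–10⁴ parents.
* The coincidence score is exact-identity based; two samples of one locus
  sequenced with very different error rates will score lower than their
  biological overlap (dereplication mitigates, not eliminates, this).
* Chao-1 lower bounds inherit the estimator's assumptions (closed pool,
  exchangeable sampling); PCR abundance distortion violates them in real
  libraries.
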