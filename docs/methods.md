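# Methods

## The encoding

A width-k encoder emits one color per sequenced position: the modulo-4 sum
of the integer codes (A=0, C=1, G=2, T=3) of the k bases ending there. The
first k−1 windows overhang the insert start, so a known adaptor
p ∈ {A,C,G,T}^(k−1) is prepended; decoding inverts the sum one position at
a time using the adaptor and the previously decoded bases. Without the
adaptor a read of n ≥ k−1 colors has exactly 4^(k−1) valid decodings (the
decoded bases pin down the adaptor's suffix sums mod 4, so distinct
adaptors give distinct decodings; shorter reads can only realize 4^n).

Two structural facts matter downstream:

1. **SNP signature.** A single base substitution changes exactly
   min(k, bases-to-end) consecutive colors, all shifted by the same amount
   d = δ(new) − δ(old) mod 4. Near the read end the signature truncates.
2. **Error cascade.** A single color change by d shifts the decoded bases
   by the sequence s_j = −(s_{j−1} + … + s_{j−k+1}) mod 4 starting from
   s = d, which is periodic with period k: d, −d, then k−2 zeros. The
   corruption therefore recurs indefinitely — a color error can never be
   explained by any finite set of substitutions confined to a window — but
   the oft-repeated stronger claim that *every* downstream base differs is
   true only for k = 2. For k ≥ 3, bases at offsets ≢ 0, 1 (mod k) from
   the flip are restored. Tests assert the exact periodic pattern.

A corollary the package computes rather than assumes: for k=2, a pair of
*adjacent* color errors mimics a clean SNP exactly when both apply the same
shift — 3 of the 9 wrong-value combinations, i.e. **1/3** of adjacent error
pairs (`adjacent_error_snp_fraction`). The folklore figure of one quarter
does not hold under the modulo-sum code.

## Scoring

Integer scores throughout: color match CM ≥ 0, color mismatch CE < 0, base
match BM ≥ 0, base mismatch BE < 0, affine gaps ρ < ε < 0. Defaults
CM=0, CE=−125, BM=50, BE=−150, ρ=−175, ε=−50. Per-pair 4×4 matrices for
Pi and Delta are accepted by the aligner; scenario classification and the
simplified insertion recursion require uniform scores.

For width k, the preference between "one SNP plus j stray color errors" and
"k−j color errors" is decided by the strictly increasing gap sequence

    g(j) = [(k−j)CE + j·CM + BM] − [(k−j)CM + j·CE + BE],  j = 0..k−1.

`classify_scenario` returns 1 + min{j : g(j) > 0}: scenario 1 never calls
SNPs, higher scenarios trade error tolerance for SNP sensitivity. Because
g(k−1) = (CM−CE) + (BM−BE) > 0 under the sign constraints, scenarios k and
k+1 (5 and 6 at k=5) are unreachable; a vectorized grid search over
CE, BE ∈ [−300, −1], CM, BM ∈ [0, 100] re-derives this numerically. With
the default BM/BE/CM, the color-error scores −25, −50, −75, −150, −200
fall in scenarios 1, 2, 3, 3, 4; −200 sits exactly on the 3/4 boundary
(g(2) = 0), which the classifier resolves upward while flagging the tie
explicitly (`tie_with=3`) — ties are reported, never silently absorbed.

## The aligner

Glocal semantics: the read is consumed completely; the reference is local
(score starts at 0 at any reference offset, flanks are free). Each DP cell
(i, j) carries sub-cells (s, v, h) per context σ ∈ 4^(k−1) — the last k−1
decoded read bases. The s and v states consume color c_i while appending a
base b to the context, charged Pi(c_i, Phi_k(φ·b)) (color substitutions are
applied before the base operator); s additionally charges Delta(b, y_j), v
charges the affine gap. h consumes a reference base only, context unchanged.
Structural exclusions: no alignment begins or ends with a deletion, and
insertions are never adjacent to deletions (v never draws on h, h never on
v). Initialization plants score 0 on the adaptor context in read row 0 at
every reference offset; termination maximizes over s and v sub-cells in the
last read row.

Numerics and determinism:

* Unreachable sub-cells hold the sentinel −2^40 in int64; penalties
  accumulate on it harmlessly (bounded by (n+m)·max-penalty ≪ 2^39, the
  reachability threshold), so no masking is needed.
* Tie-breaking is fixed: terminal cells prefer s over v, then the smaller
  reference end, then the lexicographically smallest context; traceback
  prefers s over h over v and scans predecessor contexts in lexicographic
  order. Tracebacks are therefore byte-reproducible.
* The row recursion is vectorized over (j, σ, predecessor) with numpy
  gathers; the h state uses the prefix-max identity
  h(j) = ε·j + (ρ−ε) + max_{j'<j}(s(j') − ε·j').
* The first inserted base of a leading insertion is charged ρ (standard
  affine convention).

When Pi is uniform the insertion recursion is simplified: the inserted base
is forced to its color-matched decoding (one predecessor per context
instead of 3|Λ|), which pushes any color substitution to the insertion-run
boundary without changing the optimal score. `align(method="auto")` uses it
whenever the scheme permits; the general recursion remains the reference
path and equivalence is property-tested on hundreds of random instances.

`candidate_count(k)` reports the complexity coefficient 2·4^(k−1)(1+3·4) =
26·4^(k−1) per cell. That accounting counts h as a predecessor of v; the
implemented recursion excludes that edge, so the figure is an upper bound
on the work actually done. Total runtime is O(nm·4^k).

With decoding pinned to the literal color-matched path
(`forbid_color_errors=True`), the k=1 DP reduces exactly to a textbook
glocal affine-gap Smith-Waterman on the base sequence; the test suite
checks this against an independent Gotoh implementation.

## The brute-force oracle

`brute_force_align` is the correctness gate: it enumerates every monotone
matching between read and reference positions (deletions only strictly
between aligned pairs, no insertion/deletion adjacency — gap costs follow
in closed form from the run structure) jointly with all 4^n decodings of
the color string, and maximizes the same decomposition
color-cost + Delta-sum + gap-cost. It is exhaustive by construction,
shares no recursion with the DP, and handles n ≤ 7, m ≤ 8, any k. The
equivalence suite compares DP and oracle scores on 500+ random tiny
instances with random valid schemes; agreement is exact.

## The simulation framework

Each simulated read is a length-L sequence with 10 bp flanks on each side
kept as its private reference (so indels and off-by-one explanations are
available to the aligner, but genome-scale search is out of scope — each
read is aligned only to its own origin). Generative model, in order:

1. **Source.** Reads are drawn from a supplied FASTA (uniform random start,
   forward strand) or generated i.i.d. uniform over ACGT. Because every
   read is aligned only to its own flanked region, source composition has
   no material effect on the metrics; non-ACGT characters in a source are
   replaced by random bases with a logged warning.
2. **SNPs** (0, 1 or 2): distinct uniform positions, new base uniform over
   the 3 alternatives. SNPs within k−1 bases of the read end are allowed;
   their color signature truncates naturally.
3. **Encoding** behind the adaptor T·(k−1) (the SOLiD primer convention;
   the choice is immaterial to the metrics since encoding and alignment use
   the same adaptor).
4. **Color errors:** each color flips independently with its positional
   rate to a uniformly chosen wrong color — either a uniform rate from the
   grid {0, 0.01, …, 0.20} or the measured 50-cycle SOLiD v2 profile
   (0.014 at cycle 1 rising to 0.184 at cycle 50, mean ≈ 4.6%). For k=1
   the code is the identity, errors are base changes, SNP and error
   positions are kept disjoint, and alignment runs in
   `forbid_color_errors` mode (plain Smith-Waterman, as appropriate when
   bases are observed directly).

**Metrics.** The *true score* is the score of the generative trace: every
base aligned at the origin, SNPs as base mismatches with matching colors,
injected errors as color mismatches, no gaps. A read is *correct* when the
optimal alignment score equals it (the optimum can never be lower, since
the generative trace is in the search space). Power = fraction correct.
From each traceback, SNP calls are aligned positions whose decoded base
differs from the reference. The FP rate is the fraction of 0-SNP reads
with any call; the FN rate is the fraction of SNP-bearing reads none of
whose injected positions is called (`fn_mode="any_missed"` instead counts
a read as FN when any injected SNP is missed). All randomness flows from a
single `numpy` generator seeded by the experiment config; identical
configs give identical metrics.

**Scale.** The default experiment size is 1,000 reads, which resolves
power differences of a couple of percent (binomial σ ≈ 1% at p ≈ 0.9);
the expensive k=5 scoring-scheme sweeps use 100 reads. The acceptance
tests use these sizes with a fixed seed and two-sigma slack on stochastic
comparisons.

**What the generator does and does not emulate.** It reproduces the error
structure that drives encoded-alignment behavior: positionally ramping
color error rates, SNP color signatures, and flanked local references. It
does not model real genomic repeat structure or mapping ambiguity (each
read is aligned to its own origin only), indel polymorphisms in the
sample, reverse-strand reads, quality values, or correlated/systematic
error modes beyond the per-cycle rates. Passing simulations therefore
speak to the scoring and algorithmic claims, not to end-to-end mapping
accuracy on a real genome.

## Known limitations and observed deviations

* A false positive floor is intrinsic to 2-base encoding under the default
  scores: adjacent equal-shift error pairs (q²/3 per pair) decode as clean
  SNPs that outscore the truth (BE + 2CM = −150 > BM + 2CE = −200), giving
  FP ≈ 4% at a 5% uniform error rate — the flip side of the Eq.-1-style
  preference that makes true SNPs callable at all. Raising k suppresses
  this as q^k.
* Scenario-boundary ties (e.g. CE=−200 with the default BM/BE) are
  reported, not hidden; exact score ties in the DP resolve by the fixed
  tie-break order.
* k is accepted up to 8 (with a warning above 5); memory and time grow as
  4^k and the k=5 DP already costs ~50 ms per 50 bp read on one core.
* The insertion-run color-error repositioning means tracebacks (not
  scores) may differ between the general and simplified recursions when
  multiple optima exist.
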