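# kcolor

Generalized *k*-base (color-space) DNA encoding, glocal alignment, and
SNP-discovery simulation.

## The problem

Ligation-based sequencers (ABI SOLiD) do not read bases directly: each cycle
observes two adjacent bases and emits one of four *colors*. A color error is
a purely technical event, while a true single-nucleotide variant (SNP) leaves
a characteristic two-color signature — so an aligner that works in color
space can tell machine noise from biology. `kcolor` generalizes this idea
from 2 to *k* simultaneously observed bases and asks what higher-order
encodings would buy: each color is the modulo-4 sum of the integer codes
(A=0, C=1, G=2, T=3) of *k* consecutive bases,

    Phi_k(B_1..B_k) = (sum_i delta(B_i)) mod 4,

encoded behind a known (k−1)-base adaptor that anchors decoding. An interior
SNP then changes exactly *k* consecutive colors (all consistently), while an
isolated color error corrupts the decoding arbitrarily far downstream — the
wider the encoding, the easier the two are to tell apart.

The package is for people studying encoding schemes and alignment scoring
for encoded sequencing data: it provides the encoder/decoder, an exact
dynamic-programming aligner, a brute-force oracle, and a simulation
framework for power and false SNP discovery rates.

## The algorithm

A k-base encoded read `c = c_1..c_n` is aligned to a reference `y = y_1..y_m`
*glocally*: every color is consumed, the reference contributes free flanks.
Because a color decodes to a base only given the previous k−1 decoded bases,
each DP cell (i, j) holds 3 × 4^(k−1) sub-cells indexed by context σ (the
last k−1 decoded read bases) and state:

* `s` — read base aligned to `y_j`: charge `Pi(c_i, Phi_k(phi·b)) + Delta(b, y_j)`
  over the 4 predecessor contexts φ consistent with σ;
* `v` — read base inserted: same color charge plus affine gap (open ρ,
  extend ε); never follows a deletion;
* `h` — reference base deleted: gap charge only, context unchanged; never
  follows an insertion, and alignments never start or end with one.

`Pi` scores the observed color against the color implied by the decoded base
path (match CM / mismatch CE), `Delta` the decoded base against the
reference (BM / BE). Default integer scores: CM=0, CE=−125, BM=50, BE=−150,
ρ=−175, ε=−50. When `Pi` is uniform, the insertion recursion simplifies:
inserted bases are forced to their color-matched decoding, pinning color
errors to run boundaries without changing the optimum. Per cell the maxima
range over 26 × 4^(k−1) candidate values, so runtime is O(nm·4^k).

Whether an optimal alignment explains k consistent color changes as one SNP
or as k color errors is governed by `BE + k·CM > BM + k·CE`; the package
classifies any uniform scheme into the corresponding preference scenarios
and shows two of the six conceivable scenarios are algebraically impossible.

## Worked example

Encode a 12 bp read carrying one SNP (`TTTAAGCCCGGG`, G at position 6)
behind a `T` adaptor, and align it to the reference it came from:

```
$ cat reads.csfasta
>r1
T222302322300
$ kcolor align --k 2 --ref ref.fa --reads reads.csfasta
read  score  ref_start  ref_end  cigar  decoded        color_error_positions  snp_positions
r1    400    10         21       12M    TTTAAGCCCGGG   -                      15
```

Score 400 = 11 base matches (+50 each) and one base mismatch (−150): the
aligner decodes the read, sees two consistent color changes, and calls a SNP
at reference position 15 with *zero* color errors — rather than explaining
the signature as two independent machine errors (which would score
50 − 2·125 = −200 < −150 at that position).

Simulating 200 reads at a 5% color error rate with one SNP each:

```
$ kcolor simulate --k 3 --length 50 --n-reads 200 --error-rate 0.05 --snps 1 --seed 11
error_model   k  length  seed  snps  power  fp_snp_rate  fn_snp_rate  n_reads  n_correct  n_fp  n_fn
uniform:0.05  3  50      11    1     0.88   0            0.14         200      176        0     28
```

`power` is the fraction of reads whose best alignment score equals the score
of the true generative alignment; `fp_snp_rate` / `fn_snp_rate` are the
false positive and false negative SNP discovery rates read off the
tracebacks.

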