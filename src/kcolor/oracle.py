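"""Exhaustive reference implementations for testing the aligner and encoder.

``brute_force_align`` enumerates, on tiny instances, every decoding of the
color string jointly with every legal alignment shape, scoring each in
closed form.  It shares no code with the dynamic program: alignment shapes
are generated as monotone matchings between read and reference positions,
and gap penalties fall out of the run structure of each matching.  A shape
is legal when no inter-pair gap has both read and reference bases skipped
(that would juxtapose an insertion and a deletion), deletions occur only
strictly between aligned pairs (no leading/trailing deletion), and the
whole read is consumed.

The total score of (decoding x, shape) decomposes as

    color cost of x  +  sum of Delta over aligned pairs  +  affine gap cost,

because the color cost depends only on the decoded base path, never on
which operation consumed each color.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, product

import numpy as np

from .encoding import EncodedRead, base_codes, decode_read, encode_read
from .scoring import ScoringScheme

__all__ = ["brute_force_align", "adjacent_error_snp_fraction"]

_MAX_N = 7
_MAX_M = 8


def _all_decodings(colors: tuple[int, ...], adaptor: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All 4**n base paths and their per-path color costs.

    Returns (X, ncolor_mismatch) where X has shape (4**n, n) and
    ncolor_mismatch counts, per path, the colors whose implied value differs
    from the observed one (for later scoring with uniform or per-pair Pi the
    implied colors are returned instead of a precomputed cost).
    """
    n = len(colors)
    grids = np.meshgrid(*([np.arange(4, dtype=np.int64)] * n), indexing="ij")
    X = np.stack([g.ravel() for g in grids], axis=1)  # (4**n, n)
    prev = np.concatenate(
        [np.tile(base_codes(adaptor).astype(np.int64), (X.shape[0], 1)), X], axis=1
    ) if adaptor else X
    # implied color at read position i = sum of the k bases ending there
    implied = np.zeros_like(X)
    for i in range(n):
        lo = max(0, i + (len(adaptor)) - (k - 1))
        window = prev[:, lo : i + len(adaptor) + 1]
        implied[:, i] = window.sum(axis=1) % 4
    return X, implied


def _legal_matchings(n: int, m: int):
    """Yield (aligned pairs, gap score opens/extends) for every legal shape.

    Pairs are ((i, j), ...) with 1-based monotone indices.  The gap cost is
    returned as (n_open, n_extend) so the caller can apply any rho/eps.
    """
    for a in range(0, min(n, m) + 1):
        read_subsets = combinations(range(1, n + 1), a)
        for ri in read_subsets:
            for rj in combinations(range(1, m + 1), a):
                pairs = tuple(zip(ri, rj))
                n_open = n_extend = 0
                legal = True
                # interior gaps
                for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
                    r, d = i2 - i1 - 1, j2 - j1 - 1
                    if r > 0 and d > 0:
                        legal = False
                        break
                    if r > 0:
                        n_open += 1
                        n_extend += r - 1
                    if d > 0:
                        n_open += 1
                        n_extend += d - 1
                if not legal:
                    continue
                # leading / trailing read overhangs are insertions; reference
                # overhangs are free (local in the reference)
                if a == 0:
                    if n > 0:
                        n_open, n_extend = 1, n - 1
                    yield pairs, n_open, n_extend
                    continue
                lead = pairs[0][0] - 1
                trail = n - pairs[-1][0]
                if lead > 0:
                    n_open += 1
                    n_extend += lead - 1
                if trail > 0:
                    n_open += 1
                    n_extend += trail - 1
                yield pairs, n_open, n_extend


def brute_force_align(
    read: EncodedRead,
    reference: str,
    scheme: ScoringScheme,
    *,
    forbid_color_errors: bool = False,
) -> int:
    """Maximum alignment score by exhaustive enumeration (tiny instances only)."""
    n, m = len(read.colors), len(reference)
    if n > _MAX_N or m > _MAX_M:
        raise ValueError(f"instance too large for brute force (n<={_MAX_N}, m<={_MAX_M})")
    k = read.k
    ref = base_codes(reference).astype(np.int64)
    Pi = scheme.pi_matrix()
    Delta = scheme.delta_matrix()

    X, implied = _all_decodings(read.colors, read.adaptor, k)
    obs = np.asarray(read.colors, dtype=np.int64)
    colorcost = Pi[obs[None, :], implied].sum(axis=1)
    if forbid_color_errors:
        ok = (implied == obs[None, :]).all(axis=1)
        X, colorcost = X[ok], colorcost[ok]

    best = None
    for pairs, n_open, n_extend in _legal_matchings(n, m):
        gap = n_open * scheme.gap_open + n_extend * scheme.gap_extend
        sc = colorcost + gap
        for (i, j) in pairs:
            sc = sc + Delta[X[:, i - 1], ref[j - 1]]
        top = int(sc.max())
        if best is None or top > best:
            best = top
    assert best is not None
    return best


def adjacent_error_snp_fraction(
    k: int = 2, x: str = "ACGTACGTAC", adaptor: str = "T"
) -> Fraction:
    """Fraction of adjacent color-error pairs that decode to a clean SNP.

    Enumerates every pair of adjacent color positions and every combination
    of wrong values at the two positions, decodes the corrupted read with
    the true adaptor, and counts the combinations whose decoding differs
    from the original sequence at exactly one base with all downstream bases
    restored.  Under the modulo-sum code the two wrong values must apply the
    same shift, giving 1/3 -- the counter computes this rather than assuming
    the oft-quoted one-quarter.
    """
    if k != 2:
        raise ValueError("the adjacent-pair counter is defined for k=2")
    if len(adaptor) != k - 1:
        raise ValueError("adaptor length must be k-1")
    enc = encode_read(x, adaptor)
    n = len(enc.colors)
    hits = total = 0
    for pos in range(n - 1):
        c1, c2 = enc.colors[pos], enc.colors[pos + 1]
        for w1, w2 in product(range(4), range(4)):
            if w1 == c1 or w2 == c2:
                continue
            total += 1
            colors = list(enc.colors)
            colors[pos], colors[pos + 1] = w1, w2
            decoded = decode_read(EncodedRead(adaptor=adaptor, colors=tuple(colors)))
            diffs = [i for i, (a, b) in enumerate(zip(x, decoded)) if a != b]
            if len(diffs) == 1:
                hits += 1
    return Fraction(hits, total)
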