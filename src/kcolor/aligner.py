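"""Glocal dynamic-programming alignment of a k-base encoded read.

The read is consumed in color space, global in the read and local in the
reference: every color must be accounted for, while the reference may
contribute free flanks on either side.  Because a color only decodes to a
base given the k-1 preceding decoded bases, every DP cell (i, j) carries
one sub-cell per context sigma in Lambda^(k-1) -- the last k-1 decoded read
bases -- for each of the three states:

    s  -- the current read base is aligned to reference base y_j,
    v  -- the current read base is inserted (absent from the reference),
    h  -- reference base y_j is deleted (absent from the read).

Consuming color c_i while extending context phi by base b costs
``Pi(c_i, Phi_k(phi . b))``: the observed color against the color the
decoded base path implies.  The context transition constrains predecessors:
phi must share its last k-2 bases with sigma's first k-2.  Deletions (h)
consume no color and leave the context unchanged.  Alignments never begin
or end with a deletion, and an insertion is never adjacent to a deletion.

Two recursions are provided.  The general one scores color substitutions
inside insertion runs with per-pair Pi.  When Pi is uniform (a single match
and a single mismatch value), the insertion recursion simplifies: the
inserted base is forced to the color-matched decoding, pinning any color
substitution to the boundary of the run without changing the optimal score.

Scores are integers throughout; unreachable sub-cells hold a saturating
negative sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np

from .encoding import ALPHABET, EncodedRead, EncodingError, base_codes
from .scoring import ScoringScheme, validate_scheme

__all__ = [
    "AlignmentEvent",
    "Alignment",
    "align",
    "align_simplified_insertion",
    "candidate_count",
    "score_alignment_events",
]

NEG = -(1 << 40)  # unreachable sentinel; all true scores are > _NEG_THRESH
_NEG_THRESH = -(1 << 39)


@dataclass(frozen=True)
class AlignmentEvent:
    """One traceback step.

    op is "M" (aligned base), "I" (base in read only) or "D" (base in
    reference only).  M and I consume one color; for those, ``base`` is the
    decoded read base, ``observed_color`` the color read off the machine and
    ``implied_color`` the color the decoded base path implies, so
    ``color_error == (observed_color != implied_color)``.  Positions are
    1-based; ``read_pos`` is the color index for M/I, ``ref_pos`` the
    reference base index for M/D.
    """

    op: Literal["M", "I", "D"]
    read_pos: int = 0
    ref_pos: int = 0
    base: str = ""
    ref_base: str = ""
    observed_color: int = -1
    implied_color: int = -1

    @property
    def color_error(self) -> bool:
        return self.op in "MI" and self.observed_color != self.implied_color

    @property
    def is_base_mismatch(self) -> bool:
        return self.op == "M" and self.base != self.ref_base


@dataclass(frozen=True)
class Alignment:
    """Result of a glocal alignment: the read span is always the whole read."""

    score: int
    ref_start: int  # 1-based inclusive; ref_start > ref_end means empty span
    ref_end: int
    events: tuple[AlignmentEvent, ...]
    decoded_read: str
    read_name: str = ""

    @property
    def cigar(self) -> str:
        out: list[str] = []
        for ev in self.events:
            if out and out[-1][-1] == ev.op:
                n = int(out[-1][:-1]) + 1
                out[-1] = f"{n}{ev.op}"
            else:
                out.append(f"1{ev.op}")
        return "".join(out)

    @property
    def color_error_positions(self) -> tuple[int, ...]:
        return tuple(ev.read_pos for ev in self.events if ev.color_error)

    @property
    def snp_positions(self) -> tuple[int, ...]:
        """1-based reference positions aligned to a differing decoded base."""
        return tuple(ev.ref_pos for ev in self.events if ev.is_base_mismatch)


def candidate_count(k: int, alphabet_size: int = 4) -> int:
    """Per-cell candidate bound 2*|L|^(k-1)*(1 + 3*|L|), i.e. 26*4^(k-1).

    This is the published complexity accounting: per context, an h sub-cell
    maximizes over 2 values and the s and v sub-cells over 3*|L| each.  The
    count treats h as a predecessor of v; the implemented recursion excludes
    that edge (no deletion adjacent to an insertion), so this is an upper
    bound on the work actually done.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return 2 * alphabet_size ** (k - 1) * (1 + 3 * alphabet_size)


@lru_cache(maxsize=16)
def _context_tables(k: int):
    """Window bookkeeping for width k.

    Contexts are integers in base 4, oldest base most significant, so
    integer order == lexicographic order.  A window prepends one base t to
    context sigma's bases; tables give, per (sigma, t): the predecessor
    context phi, the implied window color, and the new (last) base.
    """
    nctx = 4 ** (k - 1)
    sig = np.arange(nctx, dtype=np.int64)
    csum = np.zeros(nctx, dtype=np.int64)
    tmp = sig.copy()
    for _ in range(k - 1):
        csum += tmp & 3
        tmp >>= 2
    csum %= 4
    t = np.arange(4, dtype=np.int64)
    win = t[None, :] * nctx + sig[:, None]  # (nctx, 4)
    pred = win >> 2
    col = (t[None, :] + csum[:, None]) % 4
    wbase = win & 3
    return nctx, csum, pred, col, wbase


def _adaptor_context(adaptor: str, k: int) -> int:
    codes = base_codes(adaptor)
    ctx = 0
    for c in codes:
        ctx = ctx * 4 + int(c)
    return ctx


def _fill(
    colors: Sequence[int],
    ref: np.ndarray,
    pctx: int,
    k: int,
    Pi: np.ndarray,
    Delta: np.ndarray,
    rho: int,
    eps: int,
    simplified: bool,
    forbid_color_errors: bool,
):
    """Fill the three (n+1, m+1, nctx) lattices S, V, H."""
    n, m = len(colors), len(ref)
    nctx, csum, pred, col, wbase = _context_tables(k)
    S = np.full((n + 1, m + 1, nctx), NEG, dtype=np.int64)
    V = np.full_like(S, NEG)
    H = np.full_like(S, NEG)
    S[0, :, pctx] = 0

    # Dref[j-1, sigma, t] = Delta[window base, y_j]
    Dref = np.moveaxis(Delta[wbase][:, :, ref], 2, 0)  # (m, nctx, 4)
    jj = np.arange(1, m + 1, dtype=np.int64)[:, None]

    for i in range(1, n + 1):
        c = colors[i - 1]
        pi_t = Pi[c][col]  # (nctx, 4)
        if forbid_color_errors:
            pi_t = np.where(col == c, pi_t, NEG)

        M3 = np.maximum(np.maximum(S[i - 1], V[i - 1]), H[i - 1])  # (m+1, nctx)
        S[i, 1:] = np.max(M3[:m][:, pred] + pi_t[None] + Dref, axis=2)

        VS = np.maximum(S[i - 1] + rho, V[i - 1] + eps)  # (m+1, nctx)
        if simplified:
            tstar = (c - csum) % 4  # the color-matched window per context
            phi_idx = pred[np.arange(nctx), tstar]
            V[i] = Pi[c, c] + VS[:, phi_idx]
        else:
            V[i] = np.max(VS[:, pred] + pi_t[None], axis=2)

        # h within the row: H[i,j] = max(S[i,j-1]+rho, H[i,j-1]+eps)
        B = S[i, :m] - eps * np.arange(m, dtype=np.int64)[:, None]
        H[i, 1:] = eps * jj + (rho - eps) + np.maximum.accumulate(B, axis=0)

    return S, V, H


def _traceback(
    read: EncodedRead,
    ref: np.ndarray,
    S: np.ndarray,
    V: np.ndarray,
    H: np.ndarray,
    k: int,
    Pi: np.ndarray,
    Delta: np.ndarray,
    rho: int,
    eps: int,
    simplified: bool,
    forbid_color_errors: bool,
) -> Alignment:
    colors = read.colors
    n, m = len(colors), len(ref)
    nctx, csum, pred, col, wbase = _context_tables(k)

    # terminal: best over S and V in read row n; ties prefer s over v, then
    # the smaller reference end, then the lexicographically smallest context
    best = max(int(S[n].max()), int(V[n].max()))
    if best <= _NEG_THRESH:
        raise AssertionError("no feasible alignment; the s path should always exist")
    state, j, sigma = None, -1, -1
    for st, lattice in (("S", S), ("V", V)):
        if state is None:
            for jj in range(m + 1):
                row = lattice[n, jj]
                hits = np.flatnonzero(row == best)
                if hits.size:
                    state, j, sigma = st, jj, int(hits[0])
                    break
    ref_end = j

    events: list[AlignmentEvent] = []
    i = n
    while i > 0 or state != "S":
        target = int({"S": S, "V": V, "H": H}[state][i, j, sigma])
        moved = False
        if state == "S":
            c = colors[i - 1]
            for prev_state, lattice, dj in (("S", S, 1), ("H", H, 1), ("V", V, 1)):
                if moved:
                    break
                for t in range(4):
                    if forbid_color_errors and col[sigma, t] != c:
                        continue
                    phi = int(pred[sigma, t])
                    pv = int(lattice[i - 1, j - 1, phi])
                    if pv <= _NEG_THRESH:
                        continue
                    sc = pv + int(Pi[c, col[sigma, t]]) + int(Delta[wbase[sigma, t], ref[j - 1]])
                    if sc == target:
                        events.append(
                            AlignmentEvent(
                                op="M",
                                read_pos=i,
                                ref_pos=j,
                                base=ALPHABET[int(wbase[sigma, t])],
                                ref_base=ALPHABET[int(ref[j - 1])],
                                observed_color=c,
                                implied_color=int(col[sigma, t]),
                            )
                        )
                        state, i, j, sigma = prev_state, i - 1, j - 1, phi
                        moved = True
                        break
        elif state == "V":
            c = colors[i - 1]
            if simplified:
                ts = [int((c - csum[sigma]) % 4)]
            else:
                ts = [t for t in range(4) if not (forbid_color_errors and col[sigma, t] != c)]
            for prev_state, lattice, gap in (("S", S, rho), ("V", V, eps)):
                if moved:
                    break
                for t in ts:
                    phi = int(pred[sigma, t])
                    pv = int(lattice[i - 1, j, phi])
                    if pv <= _NEG_THRESH:
                        continue
                    sc = pv + int(Pi[c, col[sigma, t]]) + gap
                    if sc == target:
                        events.append(
                            AlignmentEvent(
                                op="I",
                                read_pos=i,
                                base=ALPHABET[int(wbase[sigma, t])],
                                observed_color=c,
                                implied_color=int(col[sigma, t]),
                            )
                        )
                        state, i, sigma = prev_state, i - 1, phi
                        moved = True
                        break
        else:  # H
            for prev_state, lattice, gap in (("S", S, rho), ("H", H, eps)):
                pv = int(lattice[i, j - 1, sigma])
                if pv > _NEG_THRESH and pv + gap == target:
                    events.append(
                        AlignmentEvent(op="D", ref_pos=j, ref_base=ALPHABET[int(ref[j - 1])])
                    )
                    state, j = prev_state, j - 1
                    moved = True
                    break
        if not moved:
            raise AssertionError("traceback failed to find a consistent predecessor")

    pctx = _adaptor_context(read.adaptor, k)
    if sigma != pctx:
        raise AssertionError("traceback did not terminate on the adaptor context")
    events.reverse()
    decoded = "".join(ev.base for ev in events if ev.op in "MI")
    return Alignment(
        score=best,
        ref_start=j + 1,
        ref_end=ref_end,
        events=tuple(events),
        decoded_read=decoded,
        read_name=read.name,
    )


def align(
    read: EncodedRead,
    reference: str,
    scheme: ScoringScheme,
    *,
    method: Literal["auto", "general", "simplified"] = "auto",
    forbid_color_errors: bool = False,
    validate: bool = True,
) -> Alignment:
    """Optimal glocal alignment of an encoded read against a DNA reference.

    ``method="simplified"`` uses the uniform-score insertion recursion (it
    requires uniform Pi); ``"auto"`` selects it whenever the scheme allows.
    ``forbid_color_errors`` restricts decoding to the literal color-matched
    base path, which for k=1 reduces the DP to a standard glocal
    Smith-Waterman with affine gaps on the decoded sequence.
    """
    if len(read.colors) < 1:
        raise ValueError("read must contain at least one color")
    if not reference:
        raise ValueError("reference must be non-empty")
    if validate:
        rep = validate_scheme(scheme)
        if not rep.ok:
            raise ValueError(f"invalid scoring scheme: {'; '.join(rep.violations)}")
    if method == "simplified" and scheme.pi is not None:
        raise ValueError("the simplified insertion recursion requires uniform color scores")
    simplified = method == "simplified" or (method == "auto" and scheme.pi is None)

    k = read.k
    ref = base_codes(reference)
    Pi = scheme.pi_matrix()
    Delta = scheme.delta_matrix()
    pctx = _adaptor_context(read.adaptor, k)
    S, V, H = _fill(
        read.colors, ref, pctx, k, Pi, Delta, scheme.gap_open, scheme.gap_extend,
        simplified, forbid_color_errors,
    )
    return _traceback(
        read, ref, S, V, H, k, Pi, Delta, scheme.gap_open, scheme.gap_extend,
        simplified, forbid_color_errors,
    )


def align_simplified_insertion(
    read: EncodedRead,
    reference: str,
    scheme: ScoringScheme,
    **kw,
) -> Alignment:
    """Alignment via the uniform-score insertion simplification.

    Falls back to the general recursion when the scheme carries per-pair
    color scores, for which the simplification does not hold.
    """
    if scheme.pi is not None:
        return align(read, reference, scheme, method="general", **kw)
    return align(read, reference, scheme, method="simplified", **kw)


def score_alignment_events(
    events: Sequence[AlignmentEvent], scheme: ScoringScheme
) -> int:
    """Re-derive an alignment score from its event trace.

    Validates the structural constraints the DP enforces: no leading or
    trailing deletion and no insertion adjacent to a deletion.
    """
    if not events:
        raise ValueError("empty event trace")
    if events[0].op == "D" or events[-1].op == "D":
        raise ValueError("alignment must not begin or end with a deletion")
    Pi = scheme.pi_matrix()
    Delta = scheme.delta_matrix()
    code = {b: i for i, b in enumerate(ALPHABET)}
    total = 0
    prev_op = None
    for ev in events:
        if prev_op is not None and {ev.op, prev_op} == {"I", "D"}:
            raise ValueError("insertion adjacent to deletion is not permitted")
        if ev.op == "M":
            total += int(Pi[ev.observed_color, ev.implied_color])
            total += int(Delta[code[ev.base], code[ev.ref_base]])
        elif ev.op == "I":
            total += int(Pi[ev.observed_color, ev.implied_color])
            total += scheme.gap_extend if prev_op == "I" else scheme.gap_open
        elif ev.op == "D":
            total += scheme.gap_extend if prev_op == "D" else scheme.gap_open
        else:
            raise ValueError(f"malformed event op {ev.op!r}")
        prev_op = ev.op
    return total
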