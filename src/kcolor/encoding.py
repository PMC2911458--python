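"""Generalized k-base encoding and decoding of DNA sequence.

A k-base encoder observes k consecutive bases at a time and emits a single
"color" per sequenced position: the modulo-4 sum of the integer codes of the
k bases in the window (A=0, C=1, G=2, T=3).  SOLiD-style two-base encoding
is the k=2 member of this family; k=1 degenerates to observing each base
directly.  Because the first window overhangs the start of the insert, a
known adaptor of k-1 bases is prepended before encoding, and the same
adaptor anchors decoding: without it a color string has 4**(k-1) equally
valid decodings.

Two structural properties of the code drive everything downstream:

1. A single base substitution changes exactly ``min(k, bases-to-end)``
   consecutive colors (all windows covering the changed base).
2. A single color change cascades: every decoded base at or after the
   changed color differs from the original.

Property 1 is the signature that lets an aligner distinguish a true SNP
(k consistent color changes) from a technical color error (an isolated
change that property 2 would otherwise turn into garbage downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ALPHABET",
    "BASE_TO_CODE",
    "CODE_TO_BASE",
    "EncodedRead",
    "EncodingError",
    "base_codes",
    "codes_to_str",
    "encode_window",
    "decode_window",
    "encode_read",
    "decode_read",
    "enumerate_decodings",
    "color_diff_signature",
]

ALPHABET = "ACGT"
BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}
CODE_TO_BASE = dict(enumerate(ALPHABET))

_CODES = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_CODE.items():
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


class EncodingError(ValueError):
    """Raised for invalid bases, colors, adaptors or window lengths."""


def base_codes(seq: str | Sequence[str]) -> np.ndarray:
    """Translate a DNA string to integer codes (A=0, C=1, G=2, T=3).

    Case-insensitive; any character outside ACGT raises ``EncodingError``.
    """
    if not isinstance(seq, str):
        seq = "".join(seq)
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODES[raw]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise EncodingError(f"invalid DNA base {bad!r} (expected one of ACGT)")
    return codes


def codes_to_str(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


def _check_colors(colors: Iterable[int]) -> tuple[int, ...]:
    out = tuple(int(c) for c in colors)
    for c in out:
        if not 0 <= c <= 3:
            raise EncodingError(f"invalid color {c} (expected 0-3)")
    return out


@dataclass(frozen=True)
class EncodedRead:
    """A k-base encoded read: a k-1 base adaptor plus a color string.

    The csfasta-style text form is the adaptor characters immediately
    followed by the color digits, e.g. ``T3130`` for k=2.
    """

    adaptor: str
    colors: tuple[int, ...]
    name: str = ""

    def __post_init__(self) -> None:
        base_codes(self.adaptor)  # validates
        object.__setattr__(self, "adaptor", self.adaptor.upper())
        object.__setattr__(self, "colors", _check_colors(self.colors))
        if len(self.colors) < 1:
            raise EncodingError("an encoded read must contain at least one color")

    @property
    def k(self) -> int:
        return len(self.adaptor) + 1

    def __len__(self) -> int:
        return len(self.colors)

    def to_line(self) -> str:
        return self.adaptor + "".join(str(c) for c in self.colors)

    @classmethod
    def from_line(cls, line: str, k: int, name: str = "") -> "EncodedRead":
        if k < 1:
            raise EncodingError(f"encoding width k must be >= 1, got {k}")
        adaptor, digits = line[: k - 1], line[k - 1 :]
        if len(adaptor) != k - 1:
            raise EncodingError(f"read line too short for a k={k} adaptor: {line!r}")
        if not digits or not all(ch in "0123" for ch in digits):
            raise EncodingError(
                f"color characters must be digits 0-3 after a {k - 1}-base adaptor: {line!r}"
            )
        return cls(adaptor=adaptor, colors=tuple(int(ch) for ch in digits), name=name)


def encode_window(bases: str | Sequence[str]) -> int:
    """Color of one window: sum of the base codes, modulo four."""
    codes = base_codes(bases)
    if codes.size < 1:
        raise EncodingError("encoding window must contain at least one base")
    return int(codes.sum() % 4)


def decode_window(context: str | Sequence[str], color: int) -> str:
    """The unique base B with ``encode_window(context + B) == color``."""
    (color,) = _check_colors([color])
    ctx = base_codes(context) if len(context) else np.empty(0, dtype=np.uint8)
    return ALPHABET[(color - int(ctx.sum())) % 4]


def encode_read(x: str, adaptor: str = "", k: int | None = None, name: str = "") -> EncodedRead:
    """Encode a DNA sequence behind a k-1 base adaptor.

    The window slides over the concatenation adaptor+x; one color is emitted
    per base of ``x``, so the output length equals ``len(x)``.  ``k`` is
    implied by the adaptor length and only needs to be supplied as a
    cross-check.
    """
    if k is not None and k != len(adaptor) + 1:
        raise EncodingError(f"adaptor {adaptor!r} implies k={len(adaptor) + 1}, not k={k}")
    if not x:
        raise EncodingError("cannot encode an empty sequence")
    kk = len(adaptor) + 1
    full = np.concatenate([base_codes(adaptor), base_codes(x)]) if adaptor else base_codes(x)
    csum = np.concatenate([[0], np.cumsum(full, dtype=np.int64)])
    colors = (csum[kk:] - csum[:-kk]) % 4
    return EncodedRead(adaptor=adaptor, colors=tuple(int(c) for c in colors), name=name)


def decode_read(read: EncodedRead) -> str:
    """Invert :func:`encode_read` using the read's own adaptor."""
    k = read.k
    ctx = [int(c) for c in base_codes(read.adaptor)]
    out = []
    for c in read.colors:
        b = (c - sum(ctx)) % 4
        out.append(b)
        ctx.append(b)
        if k > 1:
            ctx = ctx[-(k - 1):]
        else:
            ctx = []
    return codes_to_str(out)


def enumerate_decodings(colors: Iterable[int], k: int) -> list[str]:
    """All distinct decodings of a color string without a known adaptor.

    One decoding per possible adaptor; whenever the read carries at least
    k-1 colors these are pairwise distinct, giving exactly 4**(k-1)
    decodings (the decoded bases determine the adaptor's suffix sums mod 4).
    Shorter reads can only realize 4**n decodings.
    """
    if k < 1:
        raise EncodingError(f"encoding width k must be >= 1, got {k}")
    colors = _check_colors(colors)
    out = []
    for idx in range(4 ** (k - 1)):
        digits = [(idx // 4**d) % 4 for d in reversed(range(k - 1))]
        adaptor = codes_to_str(digits)
        out.append(decode_read(EncodedRead(adaptor=adaptor, colors=colors)))
    return sorted(set(out))


def color_diff_signature(x: str, x_mut: str, adaptor: str = "") -> list[int]:
    """0-based color positions where the encodings of x and x_mut differ."""
    if len(x) != len(x_mut):
        raise EncodingError("sequences must have equal length to compare encodings")
    a = encode_read(x, adaptor)
    b = encode_read(x_mut, adaptor)
    return [i for i, (ca, cb) in enumerate(zip(a.colors, b.colors)) if ca != cb]
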