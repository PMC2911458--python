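"""Simulation of k-base encoded sequencing: power and SNP discovery rates.

Each simulated read is drawn from a reference source (a supplied FASTA
sequence or i.i.d. random sequence), kept together with 10 bp of flank on
each side as its private local reference.  SNPs are injected into the read
sequence, the read is encoded behind an adaptor, and color errors are
injected independently per position -- either at a uniform rate or with the
per-cycle rates measured from a 50 bp SOLiD v2 run.  For k=1 the code is
the identity, so errors are base changes, SNPs and errors never co-occur,
and alignment is the standard glocal Smith-Waterman on the literal
sequence (the aligner's ``forbid_color_errors`` mode).

A read is scored *correct* when the optimal alignment against its flanked
reference has exactly the score of the generative trace (every base aligned,
SNPs as base mismatches, injected errors as color mismatches, no gaps).
Power is the fraction correct.  The false positive SNP rate is the fraction
of 0-SNP reads whose optimal traceback calls any SNP; the false negative
rate is the fraction of SNP-carrying reads whose traceback recovers none of
the injected SNP positions (``fn_mode="any_missed"`` instead counts a read
as FN when at least one injected SNP is missed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .aligner import Alignment, align
from .encoding import ALPHABET, EncodedRead, base_codes, codes_to_str, encode_read
from .scoring import ScoringScheme, default_scheme

__all__ = [
    "FLANK",
    "ErrorModel",
    "SimulatedRead",
    "SimulationConfig",
    "SimulationMetrics",
    "ReadOutcome",
    "real_world_error_model",
    "sample_reads",
    "inject_snps",
    "inject_color_errors",
    "build_read",
    "true_alignment_score",
    "evaluate_read",
    "run_experiment",
]

logger = logging.getLogger(__name__)

FLANK = 10  # reference bases kept on each side of the read's origin

# Per-cycle color-error rates measured from a 50 bp ABI SOLiD v2 run.
REAL_WORLD_RATES = (
    0.014, 0.005, 0.006, 0.007, 0.006, 0.006, 0.006, 0.008, 0.008, 0.008,
    0.007, 0.006, 0.009, 0.009, 0.009, 0.009, 0.008, 0.015, 0.015, 0.012,
    0.012, 0.011, 0.021, 0.021, 0.018, 0.019, 0.014, 0.037, 0.033, 0.031,
    0.029, 0.022, 0.055, 0.052, 0.051, 0.043, 0.036, 0.087, 0.084, 0.076,
    0.071, 0.060, 0.125, 0.118, 0.118, 0.108, 0.092, 0.179, 0.175, 0.184,
)


@dataclass(frozen=True)
class ErrorModel:
    """Per-position substitution rates, uniform or positional."""

    rates: tuple[float, ...] | float

    def __post_init__(self) -> None:
        rates = self.rates
        flat = (rates,) if isinstance(rates, (int, float)) else tuple(rates)
        for r in flat:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"error rate {r} outside [0, 1]")

    @classmethod
    def uniform(cls, rate: float) -> "ErrorModel":
        return cls(rates=float(rate))

    @classmethod
    def positional(cls, rates: Sequence[float]) -> "ErrorModel":
        return cls(rates=tuple(float(r) for r in rates))

    def vector(self, length: int) -> np.ndarray:
        if isinstance(self.rates, (int, float)):
            return np.full(length, float(self.rates))
        if len(self.rates) != length:
            raise ValueError(
                f"positional error model has {len(self.rates)} rates but the "
                f"read length is {length}"
            )
        return np.asarray(self.rates, dtype=float)


def real_world_error_model() -> ErrorModel:
    """The measured 50-cycle SOLiD error profile (use with 50 bp reads)."""
    return ErrorModel.positional(REAL_WORLD_RATES)


@dataclass
class SimulatedRead:
    original: str                      # read sequence before SNPs/errors
    region: str                        # original + FLANK bases each side
    source_pos: int                    # 0-based start of `original` in the source
    snps: tuple[tuple[int, str, str], ...] = ()      # (0-based pos, old, new)
    color_errors: tuple[tuple[int, int, int], ...] = ()  # (0-based pos, old, new)
    encoded: EncodedRead | None = None
    mutated: str = ""                  # read sequence after SNPs
    true_score: int | None = None


@dataclass(frozen=True)
class SimulationConfig:
    k: int = 2
    read_length: int = 50
    n_reads: int = 1000
    error_model: ErrorModel = field(default_factory=lambda: ErrorModel.uniform(0.0))
    n_snps: int = 0
    scheme: ScoringScheme = field(default_factory=default_scheme)
    seed: int = 0
    reference: str | None = None       # DNA string source; None = random reads
    adaptor_base: str = "T"
    fn_mode: Literal["all_missed", "any_missed"] = "all_missed"


@dataclass(frozen=True)
class ReadOutcome:
    correct: bool
    snps_called: tuple[int, ...]       # 0-based positions in the *read* frame
    injected: tuple[int, ...]
    score: int
    true_score: int


@dataclass(frozen=True)
class SimulationMetrics:
    power: float
    fp_snp_rate: float
    fn_snp_rate: float
    n_reads: int
    n_correct: int
    n_fp: int
    n_fn: int
    n_zero_snp_reads: int
    n_snp_reads: int


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64)


def _sanitize_source(seq: str, rng: np.random.Generator) -> np.ndarray:
    """Source codes with non-ACGT characters replaced by random bases."""
    arr = np.frombuffer(seq.upper().encode("ascii", "replace"), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for i, b in enumerate(ALPHABET):
        codes[arr == ord(b)] = i
    bad = codes < 0
    if bad.any():
        logger.warning(
            "replacing %d non-ACGT characters in the reference with random bases",
            int(bad.sum()),
        )
        codes[bad] = _random_codes(rng, int(bad.sum()))
    return codes


def sample_reads(
    source: str | None,
    n_reads: int,
    length: int,
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    """Draw read skeletons (sequence + flanked region) from the source.

    ``source=None`` generates i.i.d. random regions; a DNA string source is
    sampled at uniform random start positions on the forward strand.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    span = length + 2 * FLANK
    out: list[SimulatedRead] = []
    if source is None:
        for _ in range(n_reads):
            region = codes_to_str(_random_codes(rng, span))
            out.append(
                SimulatedRead(original=region[FLANK:FLANK + length], region=region, source_pos=FLANK)
            )
        return out
    codes = _sanitize_source(source, rng)
    if codes.size < span:
        raise ValueError(
            f"reference source ({codes.size} bp) is shorter than read length + "
            f"2*{FLANK} flank = {span} bp"
        )
    starts = rng.integers(0, codes.size - span + 1, size=n_reads)
    for s in starts:
        region = codes_to_str(codes[s : s + span])
        out.append(
            SimulatedRead(
                original=region[FLANK:FLANK + length], region=region, source_pos=int(s) + FLANK
            )
        )
    return out


def inject_snps(read: SimulatedRead, n_snps: int, rng: np.random.Generator) -> SimulatedRead:
    """Substitute ``n_snps`` distinct positions, each to a different base."""
    L = len(read.original)
    if n_snps > L:
        raise ValueError("cannot place more SNPs than read positions")
    codes = base_codes(read.original).astype(np.int64)
    positions = np.sort(rng.choice(L, size=n_snps, replace=False)) if n_snps else np.empty(0, int)
    snps = []
    for pos in positions:
        old = int(codes[pos])
        new = (old + int(rng.integers(1, 4))) % 4
        codes[pos] = new
        snps.append((int(pos), ALPHABET[old], ALPHABET[new]))
    read.snps = tuple(snps)
    read.mutated = codes_to_str(codes)
    return read


def inject_color_errors(
    encoded: EncodedRead,
    model: ErrorModel,
    rng: np.random.Generator,
    forbidden: frozenset[int] = frozenset(),
) -> tuple[EncodedRead, tuple[tuple[int, int, int], ...]]:
    """Flip each color independently per its positional rate.

    A flipped color is drawn uniformly from the three wrong values.
    ``forbidden`` positions are never flipped (used at k=1 where base errors
    must avoid SNP positions).
    """
    n = len(encoded.colors)
    rates = model.vector(n)
    mask = rng.random(n) < rates
    shifts = rng.integers(1, 4, size=n)  # drawn unconditionally for reproducibility
    colors = list(encoded.colors)
    errors = []
    for pos in range(n):
        if not mask[pos] or pos in forbidden:
            continue
        old = colors[pos]
        new = (old + int(shifts[pos])) % 4
        colors[pos] = new
        errors.append((pos, old, new))
    return replace(encoded, colors=tuple(colors)), tuple(errors)


def true_alignment_score(
    read: SimulatedRead, scheme: ScoringScheme, k: int
) -> int:
    """Score of the generative trace: all bases aligned at the true origin.

    SNPs contribute base mismatches with matching colors; injected color
    errors contribute color mismatches; there are no gaps.  For k=1 the
    injected "color" errors are base changes, scored as base mismatches.
    """
    L = len(read.original)
    n_err = len(read.color_errors)
    n_snp = len(read.snps)
    if k == 1:
        mism = n_snp + n_err
        return (L - mism) * scheme.base_match + mism * scheme.base_mismatch + L * scheme.color_match
    return (
        (L - n_snp) * scheme.base_match
        + n_snp * scheme.base_mismatch
        + (L - n_err) * scheme.color_match
        + n_err * scheme.color_mismatch
    )


def build_read(
    skeleton: SimulatedRead,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SimulatedRead:
    """Inject SNPs and errors and attach the encoded read and true score."""
    read = inject_snps(skeleton, config.n_snps, rng)
    adaptor = config.adaptor_base * (config.k - 1)
    encoded = encode_read(read.mutated, adaptor)
    forbidden = (
        frozenset(pos for pos, _, _ in read.snps) if config.k == 1 else frozenset()
    )
    encoded, errors = inject_color_errors(encoded, config.error_model, rng, forbidden)
    read.encoded = encoded
    read.color_errors = errors
    read.true_score = true_alignment_score(read, config.scheme, config.k)
    return read


def _called_read_positions(al: Alignment) -> tuple[int, ...]:
    """0-based read-frame positions of SNP calls (ref position - FLANK - 1)."""
    return tuple(p - FLANK - 1 for p in al.snp_positions)


def evaluate_read(read: SimulatedRead, config: SimulationConfig) -> ReadOutcome:
    """Align one constructed read to its flanked region and judge the outcome."""
    assert read.encoded is not None and read.true_score is not None
    al = align(
        read.encoded,
        read.region,
        config.scheme,
        method="auto",
        forbid_color_errors=(config.k == 1),
    )
    called = _called_read_positions(al)
    injected = tuple(pos for pos, _, _ in read.snps)
    return ReadOutcome(
        correct=al.score == read.true_score,
        snps_called=called,
        injected=injected,
        score=al.score,
        true_score=read.true_score,
    )


def run_experiment(
    config: SimulationConfig, return_outcomes: bool = False
) -> SimulationMetrics | tuple[SimulationMetrics, list[ReadOutcome]]:
    """Run one cell of the simulation grid and aggregate the metrics."""
    rng = np.random.default_rng(config.seed)
    skeletons = sample_reads(config.reference, config.n_reads, config.read_length, rng)
    outcomes: list[ReadOutcome] = []
    for skel in skeletons:
        read = build_read(skel, config, rng)
        outcomes.append(evaluate_read(read, config))

    n = len(outcomes)
    n_correct = sum(o.correct for o in outcomes)
    zero = [o for o in outcomes if not o.injected]
    snp = [o for o in outcomes if o.injected]
    n_fp = sum(bool(o.snps_called) for o in zero)
    if config.fn_mode == "all_missed":
        n_fn = sum(not (set(o.injected) & set(o.snps_called)) for o in snp)
    else:
        n_fn = sum(not set(o.injected) <= set(o.snps_called) for o in snp)
    metrics = SimulationMetrics(
        power=n_correct / n if n else 0.0,
        fp_snp_rate=n_fp / len(zero) if zero else 0.0,
        fn_snp_rate=n_fn / len(snp) if snp else 0.0,
        n_reads=n,
        n_correct=n_correct,
        n_fp=n_fp,
        n_fn=n_fn,
        n_zero_snp_reads=len(zero),
        n_snp_reads=len(snp),
    )
    if return_outcomes:
        return metrics, outcomes
    return metrics
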