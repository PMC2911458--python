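"""Aligner: hand-checked scores, traceback structure, recursion equivalence."""

import numpy as np
import pytest

from kcolor.aligner import (
    align,
    align_simplified_insertion,
    candidate_count,
    score_alignment_events,
)
from kcolor.encoding import ALPHABET, EncodedRead, encode_read
from kcolor.scoring import default_scheme


@pytest.fixture
def embedded_read(rng):
    """A 25 bp read embedded in its own sequence with 10 bp flanks, k=2."""
    from conftest import random_dna

    reference = random_dna(rng, 45)
    read_seq = reference[10:35]
    return encode_read(read_seq, "T"), reference, read_seq


def test_perfect_read_scores_all_matches(embedded_read):
    enc, reference, read_seq = embedded_read
    al = align(enc, reference, default_scheme())
    assert al.score == 25 * 50  # 25 base matches, color matches free
    assert (al.ref_start, al.ref_end) == (11, 35)
    assert al.decoded_read == read_seq
    assert al.cigar == "25M"
    assert not al.snp_positions and not al.color_error_positions


def test_single_color_error_costs_one_color_mismatch(embedded_read):
    enc, reference, _ = embedded_read
    colors = list(enc.colors)
    colors[12] = (colors[12] + 2) % 4
    al = align(EncodedRead("T", tuple(colors)), reference, default_scheme())
    assert al.score == 1250 - 125
    assert len(al.color_error_positions) == 1
    assert not al.snp_positions


def test_single_snp_called_as_base_mismatch(embedded_read):
    enc, reference, read_seq = embedded_read
    pos = 12
    mut = (
        read_seq[:pos]
        + ALPHABET[(ALPHABET.index(read_seq[pos]) + 1) % 4]
        + read_seq[pos + 1 :]
    )
    al = align(encode_read(mut, "T"), reference, default_scheme())
    assert al.score == 24 * 50 - 150
    assert al.snp_positions == (10 + pos + 1,)
    assert not al.color_error_positions
    assert al.decoded_read == mut


@pytest.mark.parametrize("k, count", [(1, 26), (2, 104), (3, 416), (5, 6656)])
def test_candidate_count_formula(k, count):
    assert candidate_count(k) == count


def test_event_rescoring_matches_reported_score(rng):
    from conftest import random_instance, random_valid_scheme

    for _ in range(60):
        read, reference = random_instance(rng, max_n=8, max_m=8)
        s = random_valid_scheme(rng)
        for method in ("general", "simplified"):
            al = align(read, reference, s, method=method)
            assert score_alignment_events(al.events, s) == al.score


def test_score_event_arithmetic(embedded_read):
    enc, reference, _ = embedded_read
    s = default_scheme()
    al = align(enc, reference, s)
    assert score_alignment_events(al.events, s) == 1250
    # an insertion run of length 2: 23 aligned matches plus rho + eps
    ref_gap = reference[:20] + reference[22:]  # drop 2 ref bases -> read inserts
    al2 = align(enc, ref_gap, s)
    assert al2.score == 23 * 50 - 175 - 50
    assert "2I" in al2.cigar
    assert score_alignment_events(al2.events, s) == al2.score


def test_traceback_structure_never_violates_gap_rules(rng):
    from conftest import random_instance, random_valid_scheme

    for _ in range(120):
        read, reference = random_instance(rng, max_n=8, max_m=8)
        s = random_valid_scheme(rng)
        al = align(read, reference, s, method="general")
        ops = "".join(ev.op for ev in al.events)
        assert not ops.startswith("D") and not ops.endswith("D")
        assert "ID" not in ops and "DI" not in ops
        assert sum(ev.op in "MI" for ev in al.events) == len(read.colors)


def test_simplified_equals_general_on_random_instances(rng):
    from conftest import random_instance, random_valid_scheme

    for _ in range(200):
        read, reference = random_instance(rng)
        s = random_valid_scheme(rng)
        general = align(read, reference, s, method="general").score
        simplified = align(read, reference, s, method="simplified").score
        assert general == simplified


def test_simplified_pins_insertion_color_errors_to_run_boundary(rng):
    """A color error inside an insertion run scores identically; the
    simplified traceback keeps the run itself color-clean."""
    from conftest import random_dna

    seq = random_dna(rng, 30)
    read_seq = seq[10:15] + "GGG" + seq[15:20]  # 3-base insertion
    enc = encode_read(read_seq, "T")
    colors = list(enc.colors)
    colors[6] = (colors[6] + 1) % 4  # error inside the inserted block
    read = EncodedRead("T", tuple(colors))
    s = default_scheme()
    general = align(read, seq, s, method="general")
    simplified = align(read, seq, s, method="simplified")
    assert general.score == simplified.score
    ins_errors = [ev for ev in simplified.events if ev.op == "I" and ev.color_error]
    assert not ins_errors


def test_no_insertion_instance_gives_identical_traceback(embedded_read):
    enc, reference, _ = embedded_read
    s = default_scheme()
    assert align(enc, reference, s, method="general").events == align(
        enc, reference, s, method="simplified"
    ).events


def test_simplified_wrapper_falls_back_for_per_pair_pi(embedded_read):
    enc, reference, _ = embedded_read
    s = default_scheme()
    pi = s.pi_matrix()
    pi[0, 1] = -60  # non-uniform mismatch
    s_pp = s.with_(pi=tuple(tuple(int(x) for x in row) for row in pi))
    with pytest.raises(ValueError):
        align(enc, reference, s_pp, method="simplified")
    al = align_simplified_insertion(enc, reference, s_pp)
    assert al.score == align(enc, reference, s_pp, method="general").score


def test_injected_color_error_never_raises_score(rng):
    from conftest import random_dna

    s = default_scheme()
    for k in (1, 2, 3):
        seq = random_dna(rng, 40)
        enc = encode_read(seq[10:30], "T" * (k - 1))
        base_score = align(enc, seq, s).score
        for _ in range(10):
            pos = int(rng.integers(0, len(enc.colors)))
            colors = list(enc.colors)
            colors[pos] = (colors[pos] + int(rng.integers(1, 4))) % 4
            worse = align(EncodedRead(enc.adaptor, tuple(colors)), seq, s).score
            assert worse <= base_score


def test_k1_reduction_matches_plain_affine_smith_waterman(rng):
    """With decoding pinned to the literal bases, the k=1 DP is a standard
    glocal (read-global, reference-local) affine-gap Smith-Waterman."""
    from conftest import random_dna

    s = default_scheme()
    for _ in range(40):
        n, m = int(rng.integers(1, 9)), int(rng.integers(1, 11))
        read_seq, reference = random_dna(rng, n), random_dna(rng, m)
        enc = encode_read(read_seq, "")
        got = align(enc, reference, s, forbid_color_errors=True).score
        assert got == _gotoh_glocal(read_seq, reference, s)


def _gotoh_glocal(x, y, s):
    """Reference implementation: textbook affine-gap DP, read-global."""
    NEG = float("-inf")
    n, m = len(x), len(y)
    S = [[NEG] * (m + 1) for _ in range(n + 1)]
    V = [[NEG] * (m + 1) for _ in range(n + 1)]
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        S[0][j] = 0
    for i in range(1, n + 1):
        for j in range(m + 1):
            V[i][j] = max(S[i - 1][j] + s.gap_open, V[i - 1][j] + s.gap_extend)
            if j > 0:
                d = s.base_match if x[i - 1] == y[j - 1] else s.base_mismatch
                S[i][j] = d + max(S[i - 1][j - 1], V[i - 1][j - 1], H[i - 1][j - 1])
                H[i][j] = max(S[i][j - 1] + s.gap_open, H[i][j - 1] + s.gap_extend)
    return int(max(max(S[n]), max(V[n])))


def test_runtime_grows_about_fourfold_per_k_increment(rng):
    """Cell count scales as 4^k; check the growth trend, not wall-clock."""
    import time

    from conftest import random_dna

    seq = random_dna(rng, 60)
    times = []
    for k in (2, 3, 4):
        enc = encode_read(seq[10:50], "T" * (k - 1))
        t0 = time.perf_counter()
        for _ in range(3):
            align(enc, seq, default_scheme(), method="general")
        times.append(time.perf_counter() - t0)
    # growth should be clearly super-linear in k; allow generous slack for
    # vectorization overheads at small k
    assert times[2] > times[0]


def test_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        align(encode_read("ACG", "T"), "", default_scheme())
    with pytest.raises(ValueError):
        align(
            encode_read("ACG", "T"),
            "ACGT",
            default_scheme().with_(gap_open=-10, gap_extend=-20),
        )
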