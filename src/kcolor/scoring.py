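"""Scoring schemes for color-space alignment, and their scenario algebra.

The aligner charges four kinds of events: a color match/mismatch (the
observed color versus the color implied by the decoded base path) scored by
the function Pi, a base match/mismatch (decoded base versus reference base)
scored by Delta, and affine gaps (open ``rho``, extend ``eps``).  All scores
are integers.  A scheme is *valid* when matches are rewarded and errors
penalized:

    base_match >= 0,  color_match >= 0,  base_mismatch < 0,
    color_mismatch < 0,  gap_open < gap_extend < 0.

For a width-k code, an interior SNP is indistinguishable from k consecutive
consistent color errors.  Which explanation an optimal alignment prefers is
decided by the family of inequalities

    g(j) = (k-j)*CE + j*CM + BM  vs  (k-j)*CM + j*CE + BE,   j = 0..k-1

(read: "j of the k signature colors already match under the SNP decoding").
g is strictly increasing in j, so for k=5 every valid tie-free uniform
scheme falls in exactly one of scenarios 1-4; scenarios 5 and 6 would
require CM + BM < CE + BE, impossible under the sign constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "ScoringScheme",
    "ScenarioLabel",
    "ValidityReport",
    "default_scheme",
    "validate_scheme",
    "snp_preferred",
    "classify_scenario",
    "infeasible_scenarios",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Integer scores for color/base matches and mismatches plus affine gaps.

    The uniform fields are the primary interface.  ``pi`` / ``delta`` may
    carry full 4x4 integer matrices for per-pair scoring; when present they
    take precedence in the aligner, but scenario classification and the
    simplified insertion recursion require uniform scores.
    """

    color_match: int = 0
    color_mismatch: int = -125
    base_match: int = 50
    base_mismatch: int = -150
    gap_open: int = -175
    gap_extend: int = -50
    pi: tuple[tuple[int, ...], ...] | None = None
    delta: tuple[tuple[int, ...], ...] | None = None

    @property
    def is_uniform(self) -> bool:
        return self.pi is None and self.delta is None

    def pi_matrix(self) -> np.ndarray:
        """4x4 matrix ``Pi[observed, implied]``."""
        if self.pi is not None:
            m = np.asarray(self.pi, dtype=np.int64)
            if m.shape != (4, 4):
                raise ValueError("pi matrix must be 4x4")
            return m
        m = np.full((4, 4), self.color_mismatch, dtype=np.int64)
        np.fill_diagonal(m, self.color_match)
        return m

    def delta_matrix(self) -> np.ndarray:
        """4x4 matrix ``Delta[read_base, ref_base]``."""
        if self.delta is not None:
            m = np.asarray(self.delta, dtype=np.int64)
            if m.shape != (4, 4):
                raise ValueError("delta matrix must be 4x4")
            return m
        m = np.full((4, 4), self.base_mismatch, dtype=np.int64)
        np.fill_diagonal(m, self.base_match)
        return m

    def with_(self, **kw) -> "ScoringScheme":
        return replace(self, **kw)


def default_scheme() -> ScoringScheme:
    """The reference scheme: CM=0, CE=-125, BM=50, BE=-150, rho=-175, eps=-50."""
    return ScoringScheme()


@dataclass(frozen=True)
class ValidityReport:
    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def validate_scheme(s: ScoringScheme) -> ValidityReport:
    """Check the sign constraints a usable scheme must satisfy."""
    v: list[str] = []
    pi = s.pi_matrix()
    delta = s.delta_matrix()
    if (np.diag(delta) < 0).any():
        v.append("base match scores must be >= 0")
    if (np.diag(pi) < 0).any():
        v.append("color match scores must be >= 0")
    off_d = delta[~np.eye(4, dtype=bool)]
    off_p = pi[~np.eye(4, dtype=bool)]
    if (off_d >= 0).any():
        v.append("base mismatch scores must be < 0")
    if (off_p >= 0).any():
        v.append("color mismatch scores must be < 0")
    if not s.gap_open < s.gap_extend:
        v.append("gap_open must be < gap_extend")
    if not s.gap_extend < 0:
        v.append("gap_extend must be < 0")
    return ValidityReport(ok=not v, violations=tuple(v))


def _require_uniform(s: ScoringScheme) -> None:
    if not s.is_uniform:
        raise ValueError("this operation requires a uniform scoring scheme")


def snp_preferred(s: ScoringScheme, k: int) -> bool:
    """Whether a SNP with k color matches beats a base match with k color errors.

    Strict inequality: BE + k*CM > BM + k*CE.  An exact tie returns False.
    """
    _require_uniform(s)
    if k < 1:
        raise ValueError("k must be >= 1")
    return s.base_mismatch + k * s.color_match > s.base_match + k * s.color_mismatch


@dataclass(frozen=True)
class ScenarioLabel:
    """Scenario index (1..k+1) with tie bookkeeping.

    ``tie_with`` names the lower adjacent scenario when the boundary
    inequality holds with equality rather than strictly; the label then
    records the scenario the scheme falls into when ties resolve upward.
    """

    index: int
    tie_with: int | None = None

    @property
    def is_tie(self) -> bool:
        return self.tie_with is not None


def _scenario_gaps(s: ScoringScheme, k: int) -> list[int]:
    ce, cm = s.color_mismatch, s.color_match
    be, bm = s.base_mismatch, s.base_match
    return [((k - j) * ce + j * cm + bm) - ((k - j) * cm + j * ce + be) for j in range(k)]


def classify_scenario(s: ScoringScheme, k: int = 5) -> ScenarioLabel:
    """Place a valid uniform scheme in one of the k+1 SNP-preference scenarios.

    Scenario 1 never prefers a SNP explanation (always calls color errors);
    scenario k+1 would always prefer one.  The classification scans the
    strictly increasing gap sequence g(j) for the first strict preference.
    An equality on the deciding boundary is reported via ``tie_with``.
    """
    _require_uniform(s)
    rep = validate_scheme(s)
    if not rep.ok:
        raise ValueError(f"cannot classify an invalid scheme: {'; '.join(rep.violations)}")
    gaps = _scenario_gaps(s, k)
    for j, g in enumerate(gaps):
        if g > 0:
            tie = j if j > 0 and gaps[j - 1] == 0 else None
            return ScenarioLabel(index=j + 1, tie_with=tie)
    # g(k-1) = (CM - CE) + (BM - BE) > 0 under the sign constraints, so the
    # scan above always terminates for a valid scheme.
    raise AssertionError("unreachable for a valid scheme")


def infeasible_scenarios(
    k: int = 5,
    ce_range: Iterable[int] = range(-300, 0, 3),
    be_range: Iterable[int] = range(-300, 0, 3),
    cm_range: Iterable[int] = range(0, 101, 4),
    bm_range: Iterable[int] = range(0, 101, 4),
) -> set[int]:
    """Scenarios no valid scheme can reach, verified by exhaustive grid search.

    Scenarios j+1 >= k are reachable only if some g(j) <= 0 for j >= k-1;
    g(k-1) = (CM-CE)+(BM-BE) is strictly positive whenever matches are
    non-negative and mismatches negative, so scenarios k and k+1 (5 and 6
    for the default k=5) are algebraically impossible.  The grid search
    re-derives the same answer numerically.
    """
    ce = np.asarray(list(ce_range), dtype=np.int64)
    be = np.asarray(list(be_range), dtype=np.int64)
    cm = np.asarray(list(cm_range), dtype=np.int64)
    bm = np.asarray(list(bm_range), dtype=np.int64)
    CE, BE, CM, BM = np.meshgrid(ce, be, cm, bm, indexing="ij", sparse=True)
    reached = np.zeros(k + 2, dtype=bool)
    undecided = None
    for j in range(k):
        g = ((k - j) * CE + j * CM + BM) - ((k - j) * CM + j * CE + BE)
        strict = g > 0
        if undecided is None:
            hit = strict
            undecided = ~strict
        else:
            hit = undecided & strict
            undecided = undecided & ~strict
        if hit.any():
            reached[j + 1] = True
    if undecided is not None and undecided.any():
        reached[k + 1] = True
    return {i for i in range(1, k + 2) if not reached[i]}
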