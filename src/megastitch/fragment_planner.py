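"""Plan overlapping fragment windows for sequences beyond a predictor's limit.

Structure predictors cap the length of a single run (2500 residues for the
deployments this package targets), so a megaprotein must be predicted as
overlapping fragments and reassembled. The planner computes the minimal
number of equal-length windows that cover the sequence with at least a
requested mutual overlap, spacing the window starts evenly so the plan is a
deterministic function of its parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["FragmentPlan", "plan_fragments", "validate_plan", "CoverageReport"]

DEFAULT_TARGET_LEN = 1500
DEFAULT_MIN_OVERLAP = 500
DEFAULT_MAX_LEN = 2500


@dataclass(frozen=True)
class FragmentPlan:
    """Ordered overlapping residue windows covering [1, L], 1-based inclusive."""

    L: int
    target_len: int
    min_overlap: int
    max_len: int
    intervals: tuple[tuple[int, int], ...]

    @property
    def n_fragments(self) -> int:
        return len(self.intervals)

    def overlaps(self) -> list[tuple[int, int]]:
        """Shared interval of each consecutive fragment pair."""
        out = []
        for (a1, b1), (a2, b2) in zip(self.intervals, self.intervals[1:]):
            out.append((a2, min(b1, b2)))
        return out

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "target_len": self.target_len,
            "min_overlap": self.min_overlap,
            "max_len": self.max_len,
            "intervals": [list(iv) for iv in self.intervals],
        }

    @staticmethod
    def from_dict(d: dict) -> "FragmentPlan":
        return FragmentPlan(
            L=int(d["L"]),
            target_len=int(d["target_len"]),
            min_overlap=int(d["min_overlap"]),
            max_len=int(d["max_len"]),
            intervals=tuple((int(a), int(b)) for a, b in d["intervals"]),
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def plan_fragments(
    L: int,
    target_len: int = DEFAULT_TARGET_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_len: int = DEFAULT_MAX_LEN,
) -> FragmentPlan:
    """Compute the minimal even-spaced overlapping fragment plan for length L.

    The fragment count n is the smallest integer with
    ``n*target_len - (n-1)*min_overlap >= L`` (each extra fragment adds
    ``target_len - min_overlap`` fresh residues). Starts are spaced evenly:
    ``start_i = 1 + round((i-1) * (L - target_len) / (n-1))`` and every
    window has length ``target_len`` (so realized overlaps are >= the
    requested minimum). A sequence that fits in one window gets [1, L].
    """
    if not (0 < min_overlap < target_len <= max_len):
        raise ParameterError(
            f"need 0 < min_overlap ({min_overlap}) < target_len ({target_len}) "
            f"<= max_len ({max_len})"
        )
    if L < 1:
        raise ParameterError(f"sequence length must be >= 1, got {L}")

    if L <= target_len:
        intervals: list[tuple[int, int]] = [(1, L)]
    else:
        step = target_len - min_overlap
        n = math.ceil((L - min_overlap) / step)
        intervals = []
        for i in range(1, n + 1):
            start = 1 + _round_half_up((i - 1) * (L - target_len) / (n - 1))
            end = min(start + target_len - 1, L)
            intervals.append((start, end))

    plan = FragmentPlan(
        L=L,
        target_len=target_len,
        min_overlap=min_overlap,
        max_len=max_len,
        intervals=tuple(intervals),
    )
    _check_plan_invariants(plan)
    return plan


def _check_plan_invariants(plan: FragmentPlan) -> None:
    ivs = plan.intervals
    if ivs[0][0] != 1 or ivs[-1][1] != plan.L:
        raise ParameterError("plan does not span [1, L]")
    for a, b in ivs:
        if b - a + 1 > plan.max_len:
            raise ParameterError(f"fragment [{a},{b}] exceeds max_len {plan.max_len}")
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 <= a1:
            raise ParameterError("intervals not sorted by start")
        ov = b1 - a2 + 1
        if ov < plan.min_overlap:
            raise ParameterError(
                f"overlap {ov} between [{a1},{b1}] and [{a2},{b2}] below "
                f"min_overlap {plan.min_overlap}"
            )


@dataclass
class CoverageReport:
    """Per-residue fragment multiplicity summary for a plan."""

    multiplicity: np.ndarray  # length L, counts per residue 1..L
    uncovered: list[int]  # residue numbers with multiplicity 0
    overlap_lengths: list[int]  # consecutive-pair overlaps
    min_multiplicity: int = field(init=False)
    max_multiplicity: int = field(init=False)

    def __post_init__(self) -> None:
        self.min_multiplicity = int(self.multiplicity.min())
        self.max_multiplicity = int(self.multiplicity.max())

    @property
    def has_gap(self) -> bool:
        return bool(self.uncovered)

    def to_dict(self) -> dict:
        return {
            "min_multiplicity": self.min_multiplicity,
            "max_multiplicity": self.max_multiplicity,
            "uncovered_residues": self.uncovered,
            "overlap_lengths": self.overlap_lengths,
        }


def validate_plan(plan: FragmentPlan) -> CoverageReport:
    """Report per-residue coverage multiplicity and flag uncovered residues.

    Pure report: a gapped (hand-made) plan is described, not rejected.
    """
    mult = np.zeros(plan.L, dtype=int)
    for a, b in plan.intervals:
        mult[a - 1 : b] += 1
    uncovered = [int(i + 1) for i in np.flatnonzero(mult == 0)]
    overlaps = [
        max(0, min(b1, b2) - a2 + 1)
        for (a1, b1), (a2, b2) in zip(plan.intervals, plan.intervals[1:])
    ]
    return CoverageReport(multiplicity=mult, uncovered=uncovered, overlap_lengths=overlaps)
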