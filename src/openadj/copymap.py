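"""Mapping copy-number segmentation boundaries to breakends (the Δ step function).

Each internal boundary of a copy-number segmentation where the copy value
changes marks a putative breakage site.  An interval of length ``L`` (default
10 kb) is centered on the boundary, and a breakend is matched to it when it is
the unique breakend falling inside.  Matched breakends receive a change-in-copy
value Δ — the sign of the copy change read across the breakend toward its
counterpart side, so both flanks of a deletion read Δ = -1; everything else
gets Δ = 0.  Magnitudes are deliberately collapsed to sign:
absolute tumor copy number is unreliable, the direction of the step across a
boundary much less so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd

from .core import AdjacencySet, CopySegment

__all__ = [
    "DEFAULT_L",
    "BoundaryInterval",
    "DeltaProfile",
    "build_boundary_intervals",
    "assign_delta",
]

DEFAULT_L = 10_000
"""Default boundary-interval length in bp."""


@dataclass(frozen=True)
class BoundaryInterval:
    """Length-L interval centered on a copy-number segment boundary.

    ``center`` is the midpoint between the left segment's end and the right
    segment's start (half-integer for abutting segments); ``sign`` is +1 when
    copy number increases left-to-right across the boundary, -1 when it
    decreases.
    """

    chrom: str
    center: float
    lo: int
    hi: int
    sign: int

    def __contains__(self, pos: int) -> bool:
        return self.lo <= pos <= self.hi


def build_boundary_intervals(
    segments: Sequence[CopySegment],
    L: int = DEFAULT_L,
    max_gap: Optional[int] = None,
) -> List[BoundaryInterval]:
    """Build one interval per copy-changing internal segment boundary.

    Boundaries are formed between consecutive segments on a chromosome whose
    values differ and whose gap does not exceed ``max_gap`` (default: ``L``;
    copy number is undefined across larger gaps).  Chromosome ends produce no
    interval.  The interval covers ``L`` consecutive positions placed
    symmetrically around the boundary midpoint (clipped at coordinate 1).

    Raises
    ------
    ValueError
        If ``L <= 0`` or segments on a chromosome overlap.
    """
    if L <= 0:
        raise ValueError(f"interval length L must be positive, got {L}")
    if max_gap is None:
        max_gap = L
    intervals: List[BoundaryInterval] = []
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start, s.end))
    for chrom, seg_iter in groupby(ordered, key=lambda s: s.chrom):
        segs = list(seg_iter)
        for left, right in zip(segs, segs[1:]):
            if right.start <= left.end:
                raise ValueError(
                    f"overlapping copy segments on {chrom}: "
                    f"{left.start}-{left.end} and {right.start}-{right.end}"
                )
            gap = right.start - left.end - 1
            if gap > max_gap or left.value == right.value:
                continue
            center = (left.end + right.start) / 2.0
            lo = max(1, int(math.floor(center - L / 2.0)) + 1)
            hi = lo + L - 1
            sign = 1 if right.value > left.value else -1
            intervals.append(
                BoundaryInterval(chrom=chrom, center=center, lo=lo, hi=hi, sign=sign)
            )
    return intervals


@dataclass
class DeltaProfile:
    """Per-breakend change-in-copy values for one adjacency set.

    ``delta`` maps every breakend uid of the set to a value in {-1, 0, +1};
    ``matched`` holds the uids matched to a boundary interval; ``p_delta`` is
    the fraction of breakends with nonzero Δ.
    """

    delta: Dict[str, int]
    matched: Set[str]
    p_delta: float
    matched_center: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, uid: str) -> int:
        return self.delta[uid]

    def to_frame(self, adjset: AdjacencySet) -> pd.DataFrame:
        """Tabulate per-breakend Δ values for serialization."""
        rows = []
        for b in sorted(adjset.breakends, key=lambda b: b.sort_key):
            rows.append(
                {
                    "uid": b.uid,
                    "chrom": b.chrom,
                    "pos": b.pos,
                    "orient": b.orient,
                    "delta": self.delta[b.uid],
                    "matched_interval_center": self.matched_center.get(b.uid, math.nan),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["uid", "chrom", "pos", "orient", "delta", "matched_interval_center"],
        )


def assign_delta(
    adjset: AdjacencySet, intervals: Sequence[BoundaryInterval]
) -> DeltaProfile:
    """Assign the Δ step function to every breakend of ``adjset``.

    A breakend matches an interval iff it lies inside it and is the only
    breakend of the set inside it.  A breakend inside two intervals (two close
    boundaries) is ambiguous and left unmatched.  Matched breakends take the
    copy change read *across* the breakend toward its counterpart side —
    Δ(x) = N(x') - N(x) collapsed to sign — so a "+" breakend takes the
    interval's left-to-right sign and a "-" breakend its negation (both
    flanks of a deletion thus read Δ = -1).  Unmatched breakends take 0.
    """
    breakends = adjset.breakends
    delta: Dict[str, int] = {b.uid: 0 for b in breakends}
    matched: Set[str] = set()
    matched_center: Dict[str, float] = {}

    by_chrom: Dict[str, List[BoundaryInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    # interval -> breakends inside it, breakend -> intervals containing it
    occupants: Dict[BoundaryInterval, List[str]] = {iv: [] for iv in intervals}
    containing: Dict[str, List[BoundaryInterval]] = {b.uid: [] for b in breakends}
    for b in breakends:
        for iv in by_chrom.get(b.chrom, ()):
            if b.pos in iv:
                occupants[iv].append(b.uid)
                containing[b.uid].append(iv)

    for b in breakends:
        ivs = containing[b.uid]
        if len(ivs) != 1:
            continue
        iv = ivs[0]
        if len(occupants[iv]) != 1:
            continue
        delta[b.uid] = iv.sign if b.orient == "+" else -iv.sign
        matched.add(b.uid)
        matched_center[b.uid] = iv.center

    n = len(breakends)
    p_delta = (sum(1 for v in delta.values() if v != 0) / n) if n else 0.0
    return DeltaProfile(
        delta=delta, matched=matched, p_delta=p_delta, matched_center=matched_center
    )
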