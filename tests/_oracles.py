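"""Independent brute-force oracles and random-instance generators for tests.

Everything here deliberately avoids the package's optimized code paths:
matching and delta assignment are re-derived by exhaustive scans, and the
truth classifier re-derives both openness signatures directly from simulation
ground truth (ideal counterpart positions and base-level copy numbers) rather
than from distance-threshold matching.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from openadj.core import (
    AdjacencySet,
    Breakend,
    CopySegment,
    canonical_adjacency,
    counterpart_position,
)
from openadj.copymap import BoundaryInterval


# ---------------------------------------------------------------- matching


def brute_counterpart_pairs(adjset: AdjacencySet, D: int) -> Set[frozenset]:
    """All-pairs re-derivation of counterpart matching.

    Enumerates every unordered breakend pair, applies the four criteria
    literally, then resolves conflicts greedily in the same canonical order
    as the implementation (the tie-break is a shared convention, the
    filtering is independent).
    """
    bes = adjset.breakends
    candidates = []
    for i in range(len(bes)):
        for j in range(i + 1, len(bes)):
            a, b = bes[i], bes[j]
            if b.sort_key < a.sort_key:
                a, b = b, a
            if a.chrom != b.chrom:
                continue
            if not (0 <= b.pos - a.pos <= D):
                continue
            if not (a.orient == "+" and b.orient == "-"):
                continue
            if adjset.has_pair(a.uid, b.uid):
                continue
            if any(
                c.chrom == a.chrom and a.pos < c.pos < b.pos
                for c in bes
                if c.uid not in (a.uid, b.uid)
            ):
                continue
            candidates.append((a, b))
    candidates.sort(key=lambda p: (p[0].chrom, p[0].pos, p[1].pos, p[0].uid, p[1].uid))
    used: Set[str] = set()
    pairs: Set[frozenset] = set()
    for a, b in candidates:
        if a.uid in used or b.uid in used:
            continue
        used.update((a.uid, b.uid))
        pairs.add(frozenset((a.uid, b.uid)))
    return pairs


def brute_spectrum_counts(
    breakends: Sequence[Breakend], D: int
) -> Dict[Tuple[str, str], int]:
    """All-pairs re-derivation of the orientation spectrum."""
    counts: Dict[Tuple[str, str], int] = {}
    for i in range(len(breakends)):
        for j in range(i + 1, len(breakends)):
            a, b = breakends[i], breakends[j]
            if b.sort_key < a.sort_key:
                a, b = b, a
            if a.chrom != b.chrom or b.pos - a.pos > D:
                continue
            if any(
                c.chrom == a.chrom and a.pos < c.pos < b.pos
                for c in breakends
                if c.uid not in (a.uid, b.uid)
            ):
                continue
            key = (a.orient, b.orient)
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------- delta


def brute_delta(
    adjset: AdjacencySet, intervals: Sequence[BoundaryInterval]
) -> Dict[str, int]:
    """Interval-membership re-derivation of the Δ step function."""
    bes = adjset.breakends
    out: Dict[str, int] = {}
    for b in bes:
        inside = [
            iv for iv in intervals if iv.chrom == b.chrom and iv.lo <= b.pos <= iv.hi
        ]
        if len(inside) != 1:
            out[b.uid] = 0
            continue
        iv = inside[0]
        others = [
            c
            for c in bes
            if c.uid != b.uid and c.chrom == iv.chrom and iv.lo <= c.pos <= iv.hi
        ]
        if others:
            out[b.uid] = 0
        else:
            out[b.uid] = iv.sign if b.orient == "+" else -iv.sign
    return out


# ------------------------------------------------- truth-label classifier


def _copy_at(segments: Sequence[CopySegment], chrom: str, pos: int) -> Optional[float]:
    for s in segments:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s.value
    return None


def truth_classify(
    adjset: AdjacencySet, segments: Sequence[CopySegment]
) -> List[Tuple[bool, bool]]:
    """Re-derive both openness signatures from ground truth.

    Counterpart-asymmetry is evaluated on ideal counterpart coordinates
    (pos +- 1, orientation mirrored) instead of distance-threshold matching;
    copy-number asymmetry from base-level copy numbers at each breakend and
    its ideal counterpart position.  Valid only for exact (jitter-free)
    simulated observations.
    """
    by_coord: Dict[Tuple[str, int, str], Breakend] = {}
    for b in adjset.breakends:
        by_coord[(b.chrom, b.pos, b.orient)] = b

    def observed_counterpart(b: Breakend) -> Optional[Breakend]:
        t = counterpart_position(b)
        return by_coord.get((t.chrom, t.pos, t.orient))

    def true_delta(b: Breakend) -> int:
        t = counterpart_position(b)
        n_here = _copy_at(segments, b.chrom, b.pos)
        n_there = _copy_at(segments, t.chrom, t.pos)
        if n_here is None or n_there is None:
            return 0
        return int(np.sign(n_there - n_here))

    results = []
    for A in adjset:
        x, y = A.breakends
        cp_asym = False
        for a, b in ((x, y), (y, x)):
            ap = observed_counterpart(a)
            if ap is None:
                continue
            w = adjset.partner_of(ap.uid)
            bp = observed_counterpart(b)
            if bp is None or bp.uid != w.uid:
                cp_asym = True
        copy_asym = true_delta(x) != true_delta(y)
        results.append((cp_asym, copy_asym))
    return results


# ------------------------------------------------- random instances


def random_adjacency_set(rng: np.random.Generator, max_adjacencies: int = 100) -> AdjacencySet:
    """A dense random adjacency set (positions 1..5000 on two chromosomes)."""
    n_adj = int(rng.integers(2, max_adjacencies + 1))
    breakends = []
    for i in range(2 * n_adj):
        breakends.append(
            Breakend(
                chrom=f"chr{int(rng.integers(1, 3))}",
                pos=int(rng.integers(1, 5001)),
                orient="+" if rng.random() < 0.5 else "-",
                uid=f"u{i}",
            )
        )
    adjacencies = [
        canonical_adjacency(breakends[2 * i], breakends[2 * i + 1], set_id="rand")
        for i in range(n_adj)
    ]
    return AdjacencySet(set_id="rand", adjacencies=adjacencies)


def random_segments(rng: np.random.Generator) -> List[CopySegment]:
    """A random stepwise copy profile over the same 1..5000-ish region."""
    out = []
    for chrom in ("chr1", "chr2"):
        pos = 1
        while pos < 6000:
            length = int(rng.integers(100, 2500))
            value = int(rng.integers(0, 5))
            out.append(CopySegment(chrom, pos, pos + length - 1, value))
            pos += length
            if rng.random() < 0.2:  # occasional gap
                pos += int(rng.integers(1, 2000))
    return out
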