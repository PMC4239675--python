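"""Counterpart breakend matching and orientation spectra.

The two breakends produced by a single break sit on adjacent nucleotides with
convergent ``(+, -)`` orientation.  In called structural-variant data the two
sides of a break surface as endpoints of *different* novel adjacencies; finding
them again ("counterpart matching") is the positional evidence on which the
counterpart-asymmetry signature rests.

Two breakends x, x' (x lower or equal in coordinate) are declared counterparts
when all four criteria hold:

1. same chromosome and ``0 <= x'.pos - x.pos <= D``;
2. convergent orientation: x is ``+`` and x' is ``-``;
3. the pair {x, x'} is not itself a detected adjacency;
4. no other breakend of the analyzed set lies strictly between them.

``D`` defaults to 2 kb; callers typically localize breakpoints to well under
that.  The orientation spectrum applies the same "consecutive, nothing
between" pair rule without criteria (2)-(3), so the ``(+, -)`` class at a
threshold equals the candidate counterpart count and the four class
proportions can be compared against the uniform null of 0.25 each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy import stats

from .core import AdjacencySet, Breakend

__all__ = [
    "DEFAULT_D",
    "CounterpartPairing",
    "OrientationSpectrum",
    "EnrichmentResult",
    "match_counterparts",
    "orientation_spectrum",
    "convergence_enrichment",
    "sweep_orientation_spectrum",
]

DEFAULT_D = 2000
"""Default counterpart distance threshold in bp."""

ORIENTATION_CLASSES: Tuple[Tuple[str, str], ...] = (
    ("+", "-"),
    ("-", "+"),
    ("+", "+"),
    ("-", "-"),
)


@dataclass
class CounterpartPairing:
    """A partial matching of breakends into counterpart pairs.

    ``pairs`` holds unordered uid pairs; each uid occurs in at most one pair.
    ``records`` keeps the matched breakends for serialization.
    """

    pairs: Set[FrozenSet[str]]
    D: int
    records: List[Tuple[Breakend, Breakend]] = field(default_factory=list)
    _mate: Dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._mate = {}
        for pair in self.pairs:
            a, b = sorted(pair)
            if a in self._mate or b in self._mate:
                raise ValueError(f"breakend matched twice in pairing: {a!r}/{b!r}")
            self._mate[a] = b
            self._mate[b] = a

    def __len__(self) -> int:
        return len(self.pairs)

    def mate(self, uid: str) -> Optional[str]:
        """The uid matched as counterpart of ``uid``, or None."""
        return self._mate.get(uid)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate pairs as uid_a, uid_b, chrom, pos_a, pos_b, distance."""
        rows = []
        for x, xp in sorted(self.records, key=lambda r: r[0].sort_key):
            rows.append(
                {
                    "uid_a": x.uid,
                    "uid_b": xp.uid,
                    "chrom": x.chrom,
                    "pos_a": x.pos,
                    "pos_b": xp.pos,
                    "distance": xp.pos - x.pos,
                }
            )
        return pd.DataFrame(
            rows, columns=["uid_a", "uid_b", "chrom", "pos_a", "pos_b", "distance"]
        )


@dataclass
class OrientationSpectrum:
    """Counts of close breakend pairs by orientation class.

    Classes are read in coordinate-sorted order; at coincident positions the
    canonical sort ("+" before "-") fixes the reading.
    """

    D: int
    counts: Dict[Tuple[str, str], int]
    total: int

    def proportion(self, cls: Tuple[str, str]) -> float:
        if self.total == 0:
            raise ValueError("orientation spectrum has no qualifying pairs")
        return self.counts.get(cls, 0) / self.total


class EnrichmentResult(NamedTuple):
    """Convergent-orientation enrichment test result."""

    proportion: float
    pvalue: float
    n_convergent: int
    total: int


def _sorted_position_groups(
    breakends: Sequence[Breakend],
) -> Dict[str, List[List[Breakend]]]:
    """Per-chromosome lists of breakend groups sharing a position, sorted."""
    out: Dict[str, List[List[Breakend]]] = {}
    for chrom, it in groupby(
        sorted(breakends, key=lambda b: b.sort_key), key=lambda b: b.chrom
    ):
        groups = [list(g) for _, g in groupby(it, key=lambda b: b.pos)]
        out[chrom] = groups
    return out


def _qualifying_pairs(
    breakends: Sequence[Breakend], D: int
) -> List[Tuple[Breakend, Breakend]]:
    """All same-chromosome pairs within D with no breakend strictly between.

    "Strictly between" refers to the open position interval, so a pair is
    either coincident or drawn from two position-adjacent groups; the first
    element is the lower one in canonical sort order.
    """
    pairs: List[Tuple[Breakend, Breakend]] = []
    for groups in _sorted_position_groups(breakends).values():
        for gi, group in enumerate(groups):
            # coincident pairs within one position group
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    pairs.append((group[i], group[j]))
            # pairs spanning two adjacent position groups
            if gi + 1 < len(groups):
                nxt = groups[gi + 1]
                if nxt[0].pos - group[0].pos <= D:
                    for a in group:
                        for b in nxt:
                            pairs.append((a, b))
    return pairs


def match_counterparts(adjset: AdjacencySet, D: int = DEFAULT_D) -> CounterpartPairing:
    """Match the breakends of ``adjset`` into counterpart pairs.

    Applies the four criteria (distance, convergent orientation, not an
    adjacency, nothing strictly between) and resolves the rare conflicts that
    coincident breakends can create greedily in canonical order, so that each
    breakend lands in at most one pair and the result is deterministic.
    """
    if D < 0:
        raise ValueError(f"distance threshold D must be >= 0, got {D}")
    candidates = []
    for a, b in _qualifying_pairs(adjset.breakends, D):
        if a.orient == "+" and b.orient == "-" and not adjset.has_pair(a.uid, b.uid):
            candidates.append((a, b))
    candidates.sort(key=lambda p: (p[0].chrom, p[0].pos, p[1].pos, p[0].uid, p[1].uid))
    used: Set[str] = set()
    pairs: Set[FrozenSet[str]] = set()
    records: List[Tuple[Breakend, Breakend]] = []
    for x, xp in candidates:
        if x.uid in used or xp.uid in used:
            continue
        used.update((x.uid, xp.uid))
        pairs.add(frozenset((x.uid, xp.uid)))
        records.append((x, xp))
    return CounterpartPairing(pairs=pairs, D=D, records=records)


def orientation_spectrum(adjset: AdjacencySet, D: int = DEFAULT_D) -> OrientationSpectrum:
    """Classify every qualifying close breakend pair by orientation.

    Uses the same pair rule as :func:`match_counterparts` (same chromosome,
    distance <= D, nothing strictly between) without the orientation or
    adjacency filters, so the ``(+, -)`` count equals the candidate
    counterpart count before criterion (3).
    """
    if D < 0:
        raise ValueError(f"distance threshold D must be >= 0, got {D}")
    counts: Dict[Tuple[str, str], int] = {cls: 0 for cls in ORIENTATION_CLASSES}
    total = 0
    for a, b in _qualifying_pairs(adjset.breakends, D):
        counts[(a.orient, b.orient)] += 1
        total += 1
    return OrientationSpectrum(D=D, counts=counts, total=total)


def convergence_enrichment(spectrum: OrientationSpectrum) -> EnrichmentResult:
    """Test enrichment of the convergent ``(+, -)`` class against the 0.25 null.

    One-sided exact binomial test of ``P(X >= observed)`` under a uniform
    choice among the four orientation classes.
    """
    if spectrum.total == 0:
        raise ValueError("cannot test enrichment on an empty orientation spectrum")
    k = spectrum.counts.get(("+", "-"), 0)
    n = spectrum.total
    test = stats.binomtest(k, n, p=0.25, alternative="greater")
    return EnrichmentResult(proportion=k / n, pvalue=test.pvalue, n_convergent=k, total=n)


def sweep_orientation_spectrum(
    adjset: AdjacencySet, grid: Sequence[int]
) -> pd.DataFrame:
    """Orientation-class proportions over a grid of distance thresholds.

    Returns one row per D with columns D, total and the four class
    proportions (NaN where no pair qualifies); used to draw spectrum-vs-D
    curves.
    """
    rows = []
    for D in grid:
        spec = orientation_spectrum(adjset, D)
        row: Dict[str, float] = {"D": D, "total": spec.total}
        for cls in ORIENTATION_CLASSES:
            name = f"p_{cls[0]}{cls[1]}"
            row[name] = spec.counts[cls] / spec.total if spec.total else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
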