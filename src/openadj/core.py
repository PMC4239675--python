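"""Core domain types for rearrangement breakends, adjacencies and copy segments.

A double-stranded DNA break between nucleotides ``n`` and ``n+1`` produces two
*counterpart* breakends: ``(n, +)``, which retains the lower-coordinate side of
the chromosome, and ``(n+1, -)``, which retains the upper side.  Breakends that
are fused together in the rearranged (derivative) tumor genome, but not in the
reference, form a *novel adjacency* — the unit of evidence produced by
structural-variant callers and consumed by every downstream analysis in this
package.

Coordinates are 1-based nucleotide indices throughout the in-memory model;
0-based half-open disk formats (BEDPE/BED) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Tuple

__all__ = [
    "Breakend",
    "BreakendTemplate",
    "Adjacency",
    "AdjacencySet",
    "CopySegment",
    "canonical_adjacency",
    "counterpart_position",
]

_ORIENT_RANK = {"+": 0, "-": 1}


@dataclass(frozen=True)
class Breakend:
    """An oriented genomic position: one side of a double-stranded break.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    pos : int
        1-based nucleotide index.
    orient : str
        ``"+"`` if the breakend retains the lower-coordinate side of the
        break, ``"-"`` if it retains the upper side.
    uid : str
        Identifier unique within a dataset.  Coincident breakends (same
        chrom/pos/orient arising from different adjacencies) are legal and
        kept distinct by uid.
    """

    chrom: str
    pos: int
    orient: str
    uid: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if self.orient not in _ORIENT_RANK:
            raise ValueError(f"orientation must be '+' or '-', got {self.orient!r}")

    @property
    def sort_key(self) -> Tuple[str, int, int, str]:
        """Canonical sort key: (chrom, pos, '+' before '-', uid)."""
        return (self.chrom, self.pos, _ORIENT_RANK[self.orient], self.uid)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}{self.orient}"


class BreakendTemplate(NamedTuple):
    """The (chrom, pos, orient) triple of an ideal counterpart breakend."""

    chrom: str
    pos: int
    orient: str


def counterpart_position(x: Breakend) -> BreakendTemplate:
    """Return the ideal counterpart position of ``x``.

    A break between nucleotides ``n`` and ``n+1`` yields the pair
    ``(n, +)`` / ``(n+1, -)``; the counterpart of one is the other.

    Raises
    ------
    ValueError
        If the counterpart position would fall below coordinate 1.
    """
    if x.orient == "+":
        return BreakendTemplate(x.chrom, x.pos + 1, "-")
    if x.pos - 1 < 1:
        raise ValueError(f"counterpart of {x} would lie below position 1")
    return BreakendTemplate(x.chrom, x.pos - 1, "+")


@dataclass(frozen=True)
class Adjacency:
    """An unordered pair of breakends fused in the derivative genome.

    Stored in canonical endpoint order (see :func:`canonical_adjacency`);
    equality therefore ignores the order in which endpoints were supplied.

    ``event_label`` carries simulation truth only: ``(event_index, k)`` of the
    k-break that created this adjacency.
    """

    first: Breakend
    second: Breakend
    set_id: str = ""
    event_label: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.first.uid == self.second.uid:
            raise ValueError(f"self-adjacency: both endpoints have uid {self.first.uid!r}")

    @property
    def breakends(self) -> Tuple[Breakend, Breakend]:
        return (self.first, self.second)

    @property
    def uids(self) -> frozenset:
        return frozenset((self.first.uid, self.second.uid))

    def other(self, uid: str) -> Breakend:
        """Return the endpoint that does not carry ``uid``."""
        if uid == self.first.uid:
            return self.second
        if uid == self.second.uid:
            return self.first
        raise KeyError(uid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Adjacency):
            return NotImplemented
        return (
            {self.first, self.second} == {other.first, other.second}
            and self.set_id == other.set_id
        )

    def __hash__(self) -> int:
        return hash((frozenset((self.first, self.second)), self.set_id))


def canonical_adjacency(
    x: Breakend,
    y: Breakend,
    set_id: str = "",
    event_label: Optional[Tuple[int, int]] = None,
) -> Adjacency:
    """Build an :class:`Adjacency` with endpoints in canonical order.

    The sort key is (chrom, pos, orient with "+" < "-", uid), so
    ``canonical_adjacency(x, y) == canonical_adjacency(y, x)`` always.
    """
    if x.uid == y.uid:
        raise ValueError(f"self-adjacency: both endpoints have uid {x.uid!r}")
    if y.sort_key < x.sort_key:
        x, y = y, x
    return Adjacency(x, y, set_id=set_id, event_label=event_label)


@dataclass
class AdjacencySet:
    """A named collection of adjacencies analyzed as one unit.

    ``k_hat`` is an optional externally supplied estimate (in [0, 1]) of the
    fraction of the set's adjacencies attributed to simultaneous multi-break
    ((k>2)-break) events; used only for cohort-level correlation.
    """

    set_id: str
    adjacencies: list
    k_hat: Optional[float] = None
    _by_uid: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k_hat is not None and not (0.0 <= self.k_hat <= 1.0):
            raise ValueError(f"k_hat must lie in [0, 1], got {self.k_hat}")
        self._by_uid = {}
        for adj in self.adjacencies:
            for b in adj.breakends:
                if b.uid in self._by_uid:
                    raise ValueError(
                        f"breakend uid {b.uid!r} appears in more than one adjacency"
                    )
                self._by_uid[b.uid] = adj

    def __len__(self) -> int:
        return len(self.adjacencies)

    def __iter__(self) -> Iterator[Adjacency]:
        return iter(self.adjacencies)

    @property
    def breakends(self) -> list:
        """All endpoint breakends, in adjacency order."""
        return [b for adj in self.adjacencies for b in adj.breakends]

    def adjacency_of(self, uid: str) -> Adjacency:
        """The adjacency having the breakend ``uid`` as an endpoint."""
        return self._by_uid[uid]

    def partner_of(self, uid: str) -> Breakend:
        """The breakend fused to ``uid`` (the other endpoint of its adjacency)."""
        return self._by_uid[uid].other(uid)

    def has_pair(self, uid_a: str, uid_b: str) -> bool:
        """True if breakends ``uid_a`` and ``uid_b`` form an adjacency here."""
        adj = self._by_uid.get(uid_a)
        return adj is not None and uid_b in adj.uids

    def contains_uid(self, uid: str) -> bool:
        return uid in self._by_uid


@dataclass(frozen=True)
class CopySegment:
    """A constant-copy-number genomic segment (1-based, inclusive ends).

    ``value`` may be on an absolute or relative scale; only differences across
    segment boundaries matter downstream.
    """

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"segment start must be >= 1, got {self.start}")
        if self.value < 0:
            raise ValueError(f"copy value must be non-negative, got {self.value}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1
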