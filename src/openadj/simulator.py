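"""k-break rearrangement simulator with per-adjacency ground truth.

A derivative tumor genome is produced from a reference by a sequence of
k-breaks.  Each k-break cuts the genome at k locations and re-fuses all 2k
resulting free ends under the two model assumptions: no breakpoint is ever
reused, and every free end is fused (no new telomeres; new circular
chromosomes are allowed and may be lost, which is how deletions arise).

The simulator tracks every fusion as a junction carrying the index and k of
the event that created it, so downstream classification can be scored against
truth: adjacencies from 2-breaks are closed by construction, adjacencies from
(k>2)-breaks are open.  The observation step adds the imperfections of real
sequencing data — detection dropout and positional jitter — and derives the
true copy-number profile of the derivative genome as a segmentation.

Simulator conventions the model itself does not dictate (uniform cut
positions, uniform fusion matchings, cuts restricted to linear retained
chromosomes) are exactly that: conventions, documented here and in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import AdjacencySet, Breakend, CopySegment, canonical_adjacency
from .counterparts import DEFAULT_D

__all__ = [
    "RefSegment",
    "Junction",
    "Molecule",
    "DerivativeGenome",
    "KBreakEvent",
    "SimulatedObservation",
    "simulate_history",
    "observe",
    "derive_copy_profile",
    "bernoulli_cohort",
    "cae_of_delta_pairs",
]

DEFAULT_MIN_SPACING = 3 * DEFAULT_D
"""Default minimum spacing (bp) between any two cut bonds of a history.

Keeps breakpoints of distinct cuts far enough apart that exact-resolution
counterpart matching and boundary-interval assignment have no spurious
candidates; set to 0 for a "realistic" mode without the guarantee.
"""

DEFAULT_EDGE_MARGIN = 50_000
"""Cuts are kept at least this far from chromosome ends."""


@dataclass(frozen=True)
class RefSegment:
    """An oriented reference interval inside a derivative chromosome.

    ``start <= end`` always; ``strand`` +1 traverses start→end, -1 end→start.
    """

    chrom: str
    start: int
    end: int
    strand: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def reversed_(self) -> "RefSegment":
        return replace(self, strand=-self.strand)


@dataclass(frozen=True)
class Junction:
    """A novel fusion between two breakends, with truth provenance."""

    a: Breakend
    b: Breakend
    event_index: int
    k: int


@dataclass
class Molecule:
    """A derivative chromosome: ordered oriented segments joined by junctions.

    Linear molecules have ``len(junctions) == len(segments) - 1`` and original
    telomeres at both ends; circular ones have one junction per segment, the
    last closing the loop.
    """

    segments: List[RefSegment]
    junctions: List[Junction]
    circular: bool = False
    lost: bool = False

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class DerivativeGenome:
    """The rearranged genome: linear chromosomes plus (possibly lost) circles."""

    reference: Dict[str, int]
    chromosomes: List[Molecule]
    circles: List[Molecule] = field(default_factory=list)

    def retained_molecules(self) -> List[Molecule]:
        return list(self.chromosomes) + [c for c in self.circles if not c.lost]


@dataclass
class KBreakEvent:
    """Truth record of one k-break."""

    index: int
    k: int
    cut_bonds: List[Tuple[str, int]]  # (chrom, lower nucleotide of broken bond)
    created: List[Junction]


@dataclass
class SimulatedObservation:
    """What a sequencing experiment would report for a simulated genome."""

    adjset: AdjacencySet
    segments: List[CopySegment]
    truth_fraction: float
    noise: Dict[str, object]


# --------------------------------------------------------------------------
# internal piece bookkeeping during one k-break
# --------------------------------------------------------------------------


@dataclass
class _FreeEnd:
    breakend: Breakend
    cut_id: int


@dataclass
class _Piece:
    segments: List[RefSegment]
    junctions: List[Junction]
    left: Optional[_FreeEnd]  # None = original telomere
    right: Optional[_FreeEnd]

    def reversed_(self) -> "_Piece":
        return _Piece(
            segments=[s.reversed_() for s in reversed(self.segments)],
            junctions=list(reversed(self.junctions)),
            left=self.right,
            right=self.left,
        )


def _split_segment(
    seg: RefSegment, local_j: int, cut_id: int
) -> Tuple[RefSegment, RefSegment, _FreeEnd, _FreeEnd, int]:
    """Split one oriented segment between local offsets j and j+1.

    Returns (left part, right part, left free end, right free end, ref bond).
    The bond is identified by its lower nucleotide n (break between n, n+1):
    the piece retaining the lower-coordinate side gets breakend (n, +), the
    other gets (n+1, -).
    """
    if not (1 <= local_j <= seg.length - 1):
        raise ValueError(f"cut offset {local_j} outside segment of length {seg.length}")
    if seg.strand == 1:
        n = seg.start + local_j - 1
        left_seg = replace(seg, end=n)
        right_seg = replace(seg, start=n + 1)
        left_bnd = Breakend(seg.chrom, n, "+", uid=f"b{cut_id}p")
        right_bnd = Breakend(seg.chrom, n + 1, "-", uid=f"b{cut_id}m")
    else:
        p = seg.end - local_j + 1  # ref position of local offset j
        n = p - 1
        left_seg = replace(seg, start=p)
        right_seg = replace(seg, end=n)
        left_bnd = Breakend(seg.chrom, p, "-", uid=f"b{cut_id}m")
        right_bnd = Breakend(seg.chrom, n, "+", uid=f"b{cut_id}p")
    return (
        left_seg,
        right_seg,
        _FreeEnd(left_bnd, cut_id),
        _FreeEnd(right_bnd, cut_id),
        n,
    )


def _cut_molecule(
    mol: Molecule, cuts: List[Tuple[int, int, int]]
) -> List[_Piece]:
    """Split a linear molecule at the given (seg_index, local_j, cut_id) cuts."""
    # process cuts right-to-left so earlier indices stay valid
    cuts = sorted(cuts, key=lambda c: (c[0], c[1]), reverse=True)
    pieces: List[_Piece] = [
        _Piece(list(mol.segments), list(mol.junctions), left=None, right=None)
    ]
    for seg_index, local_j, cut_id in cuts:
        piece = pieces[0]
        seg = piece.segments[seg_index]
        left_seg, right_seg, left_end, right_end, _ = _split_segment(
            seg, local_j, cut_id
        )
        left_piece = _Piece(
            segments=piece.segments[:seg_index] + [left_seg],
            junctions=piece.junctions[:seg_index],
            left=piece.left,
            right=left_end,
        )
        right_piece = _Piece(
            segments=[right_seg] + piece.segments[seg_index + 1 :],
            junctions=piece.junctions[seg_index:],
            left=right_end,
            right=piece.right,
        )
        pieces = [left_piece, right_piece] + pieces[1:]
    return pieces


def _sample_matching(
    ends: List[_FreeEnd], rng: np.random.Generator, max_tries: int = 10_000
) -> List[Tuple[_FreeEnd, _FreeEnd]]:
    """Uniform perfect matching on free ends, conditioned on no counterpart
    pair being re-fused (every break must be effective)."""
    idx = np.arange(len(ends))
    for _ in range(max_tries):
        perm = rng.permutation(idx)
        pairs = [
            (ends[perm[i]], ends[perm[i + 1]]) for i in range(0, len(ends), 2)
        ]
        if all(a.cut_id != b.cut_id for a, b in pairs):
            return pairs
    raise RuntimeError("failed to sample a counterpart-free fusion matching")


def _reassemble(
    pieces: List[_Piece],
    fusions: List[Tuple[_FreeEnd, _FreeEnd]],
    event_index: int,
    k: int,
) -> Tuple[List[Molecule], List[Molecule], List[Junction]]:
    """Glue pieces along the fusion matching into linear and circular products."""
    mate: Dict[str, _FreeEnd] = {}
    for a, b in fusions:
        mate[a.breakend.uid] = b
        mate[b.breakend.uid] = a
    owner: Dict[str, int] = {}  # breakend uid -> piece index
    side: Dict[str, str] = {}
    for i, p in enumerate(pieces):
        if p.left is not None:
            owner[p.left.breakend.uid] = i
            side[p.left.breakend.uid] = "left"
        if p.right is not None:
            owner[p.right.breakend.uid] = i
            side[p.right.breakend.uid] = "right"

    created: List[Junction] = []
    visited = [False] * len(pieces)
    linear: List[Molecule] = []
    circular: List[Molecule] = []

    def _walk(start_idx: int, oriented: _Piece) -> Tuple[Molecule, bool]:
        """Extend from ``oriented`` (entered from its left) to the right."""
        segments = list(oriented.segments)
        junctions = list(oriented.junctions)
        visited[start_idx] = True
        start_left = oriented.left  # None (telomere) or the circle-closing end
        current = oriented
        while current.right is not None:
            end = current.right
            other = mate[end.breakend.uid]
            if start_left is not None and other.breakend.uid == start_left.breakend.uid:
                # closes a circle
                j = Junction(end.breakend, other.breakend, event_index, k)
                created.append(j)
                junctions.append(j)
                return Molecule(segments, junctions, circular=True), True
            nxt_idx = owner[other.breakend.uid]
            nxt = pieces[nxt_idx]
            if side[other.breakend.uid] == "right":
                nxt = nxt.reversed_()
            visited[nxt_idx] = True
            j = Junction(end.breakend, other.breakend, event_index, k)
            created.append(j)
            junctions.append(j)
            segments.extend(nxt.segments)
            junctions.extend(nxt.junctions)
            current = nxt
        return Molecule(segments, junctions, circular=False), False

    # paths: start at every unvisited telomeric left end
    for i, p in enumerate(pieces):
        if visited[i]:
            continue
        if p.left is None:
            mol, _ = _walk(i, p)
            linear.append(mol)
        elif p.right is None:
            mol, _ = _walk(i, p.reversed_())
            linear.append(mol)
    # remaining pieces belong to cycles
    for i, p in enumerate(pieces):
        if not visited[i]:
            mol, closed = _walk(i, p)
            assert closed, "non-telomeric component failed to close into a circle"
            circular.append(mol)
    return linear, circular, created


# --------------------------------------------------------------------------
# public simulation API
# --------------------------------------------------------------------------


def simulate_history(
    reference: Mapping[str, int],
    events: Sequence[int],
    circle_loss_p: float = 1.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    min_spacing: int = DEFAULT_MIN_SPACING,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
) -> Tuple[DerivativeGenome, List[KBreakEvent]]:
    """Apply a sequence of k-breaks to a reference genome.

    Parameters
    ----------
    reference : mapping chrom -> length (bp)
    events : sequence of k values, applied in order; every k >= 2.
    circle_loss_p : probability that each newly formed circular chromosome is
        lost (a loss of the covered sequence; default 1, the deletion
        interpretation).
    min_spacing : minimum distance between any two cut bonds of the history
        (0 disables; bonds are still never reused).
    edge_margin : cuts avoid this many bp at each chromosome end.

    Returns the final genome and the per-event truth log.  Deterministic
    given ``seed`` (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    for k in events:
        if k < 2:
            raise ValueError(f"every event must have k >= 2, got {k}")
    total_cuts = sum(events)
    if sum(reference.values()) < 10 * max(total_cuts, 1):
        raise ValueError("reference too small for the requested number of cuts")

    genome = DerivativeGenome(
        reference=dict(reference),
        chromosomes=[
            Molecule([RefSegment(chrom, 1, length, 1)], [], circular=False)
            for chrom, length in reference.items()
        ],
    )
    used_bonds: Dict[str, List[int]] = {chrom: [] for chrom in reference}
    history: List[KBreakEvent] = []
    cut_counter = 0

    for event_index, k in enumerate(events):
        # sample k cut sites on linear retained chromosomes
        cuts: List[Tuple[int, int, int, int]] = []  # (mol_idx, seg_idx, local_j, cut_id)
        bonds: List[Tuple[str, int]] = []
        mols = genome.chromosomes
        weights = np.array([m.length for m in mols], dtype=float)
        for _ in range(k):
            for _try in range(10_000):
                mi = int(rng.choice(len(mols), p=weights / weights.sum()))
                mol = mols[mi]
                seg_lens = np.array([s.length for s in mol.segments], dtype=float)
                si = int(rng.choice(len(seg_lens), p=seg_lens / seg_lens.sum()))
                seg = mol.segments[si]
                if seg.length < 2:
                    continue
                local_j = int(rng.integers(1, seg.length))  # 1..length-1
                # reference bond (lower nucleotide)
                n = seg.start + local_j - 1 if seg.strand == 1 else seg.end - local_j
                chrom_len = genome.reference[seg.chrom]
                if n < edge_margin or n > chrom_len - edge_margin:
                    continue
                near = any(
                    abs(n - m) < max(min_spacing, 1) for m in used_bonds[seg.chrom]
                ) or any(
                    c == seg.chrom and abs(n - m) < max(min_spacing, 1)
                    for c, m in bonds
                )
                if near:
                    continue
                cuts.append((mi, si, local_j, cut_counter))
                bonds.append((seg.chrom, n))
                cut_counter += 1
                break
            else:
                raise RuntimeError(
                    "could not place a cut satisfying spacing/margin constraints"
                )

        # cut the affected molecules
        by_mol: Dict[int, List[Tuple[int, int, int]]] = {}
        for mi, si, lj, cid in cuts:
            by_mol.setdefault(mi, []).append((si, lj, cid))
        pieces: List[_Piece] = []
        survivors: List[Molecule] = []
        for mi, mol in enumerate(mols):
            if mi in by_mol:
                pieces.extend(_cut_molecule(mol, by_mol[mi]))
            else:
                survivors.append(mol)
        free_ends = [e for p in pieces for e in (p.left, p.right) if e is not None]
        assert len(free_ends) == 2 * k

        fusions = _sample_matching(free_ends, rng)
        linear, circular, created = _reassemble(pieces, fusions, event_index, k)
        for mol in circular:
            mol.lost = bool(rng.random() < circle_loss_p)
        genome.chromosomes = survivors + linear
        genome.circles.extend(circular)
        for chrom, n in bonds:
            used_bonds[chrom].append(n)
        history.append(
            KBreakEvent(index=event_index, k=k, cut_bonds=bonds, created=created)
        )

    return genome, history


def derive_copy_profile(
    genome: DerivativeGenome, ploidy_offset: int = 1
) -> List[CopySegment]:
    """Segment the true copy-number profile of the derivative genome.

    Copy number at a reference base = number of retained derivative segments
    covering it, plus ``ploidy_offset`` for the unrearranged homologous
    chromosome (so a flat diploid background reads 2 and a heterozygous
    deletion reads 1).  Returns maximal constant-value segments covering every
    reference chromosome.
    """
    cover: Dict[str, List[Tuple[int, int]]] = {chrom: [] for chrom in genome.reference}
    for mol in genome.retained_molecules():
        for seg in mol.segments:
            cover[seg.chrom].append((seg.start, 1))
            cover[seg.chrom].append((seg.end + 1, -1))
    out: List[CopySegment] = []
    for chrom, length in genome.reference.items():
        points = sorted(cover[chrom])
        boundaries = sorted({1, length + 1} | {p for p, _ in points})
        depth = 0
        pi = 0
        prev_value: Optional[int] = None
        seg_start = 1
        for b in boundaries:
            if b > length:
                break
            while pi < len(points) and points[pi][0] <= b:
                depth += points[pi][1]
                pi += 1
            value = depth + ploidy_offset
            if prev_value is None:
                prev_value, seg_start = value, b
            elif value != prev_value:
                out.append(CopySegment(chrom, seg_start, b - 1, prev_value))
                prev_value, seg_start = value, b
        out.append(CopySegment(chrom, seg_start, length, prev_value if prev_value is not None else ploidy_offset))
    return out


def _jitter_positions(
    pos: int, sd: float, rng: np.random.Generator, chrom_len: Optional[int] = None
) -> int:
    shift = rng.normal(0.0, sd)
    shift = int(round(np.clip(shift, -3.0 * sd, 3.0 * sd)))
    new = max(1, pos + shift)
    if chrom_len is not None:
        new = min(new, chrom_len)
    return new


def observe(
    genome: DerivativeGenome,
    history: Sequence[KBreakEvent],
    dropout_p: float = 0.0,
    jitter_sd: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    set_id: str = "sim",
    ploidy_offset: int = 1,
    seg_jitter_sd: float = 0.0,
) -> SimulatedObservation:
    """Derive the observable data from a simulated derivative genome.

    Collects the novel adjacencies present on retained derivative
    chromosomes, drops each independently with probability ``dropout_p``,
    perturbs breakend positions with integer Gaussian jitter (sd
    ``jitter_sd``, clipped at +-3 sd, orientation never flipped), and derives
    the true copy profile (boundaries optionally jittered with sd
    ``seg_jitter_sd``).  ``truth_fraction`` — the share of observed
    adjacencies created by (k>2)-breaks — is computed on the post-dropout
    set.
    """
    if not (0.0 <= dropout_p < 1.0):
        raise ValueError(f"dropout_p must lie in [0, 1), got {dropout_p}")
    if rng is None:
        rng = np.random.default_rng(seed)

    junctions: List[Junction] = []
    for mol in genome.retained_molecules():
        junctions.extend(mol.junctions)

    adjacencies = []
    n_from_multibreak = 0
    for j in junctions:
        if dropout_p > 0 and rng.random() < dropout_p:
            continue
        a, b = j.a, j.b
        if jitter_sd > 0:
            a = replace(a, pos=_jitter_positions(a.pos, jitter_sd, rng, genome.reference.get(a.chrom)))
            b = replace(b, pos=_jitter_positions(b.pos, jitter_sd, rng, genome.reference.get(b.chrom)))
        adjacencies.append(
            canonical_adjacency(a, b, set_id=set_id, event_label=(j.event_index, j.k))
        )
        if j.k > 2:
            n_from_multibreak += 1
    truth_fraction = n_from_multibreak / len(adjacencies) if adjacencies else 0.0

    segments = derive_copy_profile(genome, ploidy_offset=ploidy_offset)
    if seg_jitter_sd > 0:
        segments = _jitter_segments(segments, seg_jitter_sd, rng)

    adjset = AdjacencySet(set_id=set_id, adjacencies=adjacencies)
    noise = {
        "dropout_p": dropout_p,
        "jitter_sd": jitter_sd,
        "seg_jitter_sd": seg_jitter_sd,
        "seed": seed,
    }
    return SimulatedObservation(
        adjset=adjset, segments=segments, truth_fraction=truth_fraction, noise=noise
    )


def _jitter_segments(
    segments: Sequence[CopySegment], sd: float, rng: np.random.Generator
) -> List[CopySegment]:
    """Perturb internal segmentation boundaries, preserving their order."""
    out: List[CopySegment] = []
    by_chrom: Dict[str, List[CopySegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        # internal boundary after segment i sits at segs[i].end
        ends = [s.end for s in segs[:-1]]
        jittered = []
        lo = segs[0].start
        for i, e in enumerate(ends):
            hi = segs[i + 1].end - 1
            shift = int(round(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd)))
            jittered.append(int(np.clip(e + shift, lo, hi)))
            lo = jittered[-1] + 1
        starts = [segs[0].start] + [e + 1 for e in jittered]
        stops = jittered + [segs[-1].end]
        for s, st, en in zip(segs, starts, stops):
            out.append(CopySegment(chrom, st, en, s.value))
    return out


# --------------------------------------------------------------------------
# Bernoulli-model cohort generator (CAE calibration)
# --------------------------------------------------------------------------


def bernoulli_cohort(
    n_adj: int,
    frac_k: float,
    p_delta: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, float]:
    """Generate endpoint Δ pairs under the CAE derivation's random model.

    A ``frac_k`` share of the ``n_adj`` adjacencies (the multi-break ones)
    receives independent endpoint values Δ ∈ {-1, 0} with P(Δ != 0) =
    ``p_delta``; the rest (2-break adjacencies) receive equal endpoint
    values, nonzero with the same probability.  Returns an (n_adj, 2) integer
    array of Δ pairs and the realized multi-break fraction.
    """
    if not (0.0 <= frac_k <= 1.0):
        raise ValueError(f"frac_k must lie in [0, 1], got {frac_k}")
    if not (0.0 < p_delta < 1.0):
        raise ValueError(f"p_delta must lie in (0, 1), got {p_delta}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_k = int(round(frac_k * n_adj))
    pairs = np.zeros((n_adj, 2), dtype=int)
    # multi-break adjacencies: independent endpoints
    pairs[:n_k, :] = -(rng.random((n_k, 2)) < p_delta).astype(int)
    # 2-break adjacencies: shared endpoint value
    shared = -(rng.random(n_adj - n_k) < p_delta).astype(int)
    pairs[n_k:, 0] = shared
    pairs[n_k:, 1] = shared
    rng.shuffle(pairs, axis=0)
    return pairs, (n_k / n_adj if n_adj else 0.0)


def cae_of_delta_pairs(pairs: np.ndarray) -> float:
    """CAE computed directly from an array of endpoint Δ pairs.

    Uses the empirical nonzero fraction of all endpoints as p_Δ, exactly as
    the pipeline does for a real adjacency set.
    """
    from .measures import cae_from_counts

    pairs = np.asarray(pairs)
    n = len(pairs)
    n_asym = int((pairs[:, 0] != pairs[:, 1]).sum())
    p_hat = float((pairs != 0).mean())
    return cae_from_counts(n_asym, p_hat, n)
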