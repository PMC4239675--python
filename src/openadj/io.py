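"""Readers and writers for BEDPE adjacencies, SEG copy segmentations and
the simple TSV dialects used by the pipeline.

Disk conventions
----------------
* **BEDPE** (canonical adjacency format): 0-based half-open intervals; each
  breakend is encoded as the 1-bp interval of its retained terminal base, so
  the internal 1-based breakend position is the *end* coordinate of its side.
  ``strand1``/``strand2`` map directly to the internal orientations ("+"
  retains the lower-coordinate side).  The ``name`` column carries the
  adjacency-set id, optionally followed by simulation truth as
  ``set_id;ev=<event>;k=<k>``.  Ten or more columns are the standard layout;
  an 8-column dialect without name/score (chrom1 start1 end1 chrom2 start2
  end2 strand1 strand2) is also accepted.
* **SEG**: TSV with columns (sample,) chrom, start, end, value; 1-based
  inclusive coordinates, header tolerated.  A headerless 4-column file is
  read as BED4 (0-based half-open) and converted.
* **Adjacency TSV escape hatch**: chrom1, pos1, orient1, chrom2, pos2,
  orient2, set_id with 1-based positions, header required.

Readers reject malformed records with the offending line number rather than
silently coercing them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .core import Adjacency, AdjacencySet, Breakend, CopySegment, canonical_adjacency

__all__ = [
    "read_bedpe",
    "write_bedpe",
    "read_seg",
    "write_seg",
    "read_adjacency_tsv",
    "write_truth_json",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed record, annotated with file and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _parse_name(name: str) -> Tuple[str, Optional[Tuple[int, int]]]:
    """Split a BEDPE name field into (set_id, optional (event, k) truth)."""
    if ";" not in name:
        return name, None
    parts = name.split(";")
    set_id = parts[0]
    ev = k = None
    for p in parts[1:]:
        if p.startswith("ev="):
            ev = int(p[3:])
        elif p.startswith("k="):
            k = int(p[2:])
    if ev is not None and k is not None:
        return set_id, (ev, k)
    return set_id, None


def _format_name(adj: Adjacency) -> str:
    set_id = adj.set_id or "."
    if adj.event_label is not None:
        ev, k = adj.event_label
        return f"{set_id};ev={ev};k={k}"
    return set_id


def _check_strand(s: str, path: PathLike, lineno: int, col: str) -> str:
    if s not in ("+", "-"):
        raise ParseError(path, lineno, f"unknown strand symbol {s!r} in {col}")
    return s


def read_bedpe(path: PathLike) -> List[AdjacencySet]:
    """Read BEDPE into adjacency sets grouped by the name column's set id.

    Returns sets in order of first appearance; records without a name (or the
    8-column dialect) all land in one set with an empty id.
    """
    groups: Dict[str, List[Adjacency]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) >= 10:
                name = fields[6]
                strand1, strand2 = fields[8], fields[9]
            elif len(fields) == 8:
                name = "."
                strand1, strand2 = fields[6], fields[7]
            else:
                raise ParseError(
                    path,
                    lineno,
                    f"expected >=10 or exactly 8 columns, got {len(fields)}",
                )
            try:
                end1 = int(fields[2])
                end2 = int(fields[5])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
            _check_strand(strand1, path, lineno, "strand1")
            _check_strand(strand2, path, lineno, "strand2")
            set_id, truth = _parse_name("" if name == "." else name)
            # 0-based half-open end == 1-based position of the last retained base
            x = Breakend(fields[0], end1, strand1, uid=f"L{lineno}a")
            y = Breakend(fields[3], end2, strand2, uid=f"L{lineno}b")
            adj = canonical_adjacency(x, y, set_id=set_id, event_label=truth)
            if set_id not in groups:
                groups[set_id] = []
                order.append(set_id)
            groups[set_id].append(adj)
    return [AdjacencySet(set_id=sid, adjacencies=groups[sid]) for sid in order]


def write_bedpe(sets: Sequence[AdjacencySet], path: PathLike) -> None:
    """Write adjacency sets as 10-column BEDPE (score column fixed at 0)."""
    with open(path, "w") as fh:
        for adjset in sets:
            for adj in adjset:
                f, s = adj.first, adj.second
                fh.write(
                    "\t".join(
                        [
                            f.chrom,
                            str(f.pos - 1),
                            str(f.pos),
                            s.chrom,
                            str(s.pos - 1),
                            str(s.pos),
                            _format_name(adj),
                            "0",
                            f.orient,
                            s.orient,
                        ]
                    )
                    + "\n"
                )


def read_adjacency_tsv(path: PathLike) -> List[AdjacencySet]:
    """Read the simple 1-based adjacency TSV dialect (header required)."""
    groups: Dict[str, List[Adjacency]] = {}
    order: List[str] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["chrom1", "pos1", "orient1", "chrom2", "pos2", "orient2", "set_id"]
                if [h.strip() for h in header[:7]] != expected:
                    raise ParseError(
                        path, lineno, f"expected header {expected}, got {header[:7]}"
                    )
                continue
            if len(fields) < 7:
                raise ParseError(path, lineno, f"expected 7 columns, got {len(fields)}")
            try:
                pos1, pos2 = int(fields[1]), int(fields[4])
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-integer position: {exc}") from exc
            _check_strand(fields[2], path, lineno, "orient1")
            _check_strand(fields[5], path, lineno, "orient2")
            set_id = fields[6]
            x = Breakend(fields[0], pos1, fields[2], uid=f"L{lineno}a")
            y = Breakend(fields[3], pos2, fields[5], uid=f"L{lineno}b")
            adj = canonical_adjacency(x, y, set_id=set_id)
            if set_id not in groups:
                groups[set_id] = []
                order.append(set_id)
            groups[set_id].append(adj)
    return [AdjacencySet(set_id=sid, adjacencies=groups[sid]) for sid in order]


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_seg(path: PathLike) -> List[CopySegment]:
    """Read a SEG-style copy segmentation.

    Accepts 5-column (sample, chrom, start, end, value; 1-based inclusive) or
    4-column input; a headerless 4-column file is interpreted as BED4
    (0-based half-open) and converted.  Returns segments sorted by
    (chrom, start); overlapping segments on a chromosome are an error.
    """
    segments: List[CopySegment] = []
    with open(path) as fh:
        saw_header = False
        bed4 = False
        first_data = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) == 5:
                sample_offset = 1
            elif len(fields) == 4:
                sample_offset = 0
            else:
                raise ParseError(path, lineno, f"expected 4 or 5 columns, got {len(fields)}")
            if first_data and not _looks_numeric(fields[sample_offset + 1]):
                saw_header = True
                first_data = False
                continue
            if first_data:
                bed4 = len(fields) == 4 and not saw_header
                first_data = False
            try:
                chrom = fields[sample_offset]
                start = int(fields[sample_offset + 1])
                end = int(fields[sample_offset + 2])
                value = float(fields[sample_offset + 3])
            except ValueError as exc:
                raise ParseError(path, lineno, f"malformed segment record: {exc}") from exc
            if bed4:
                start += 1  # 0-based half-open -> 1-based inclusive
            try:
                segments.append(CopySegment(chrom, start, end, value))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(
                f"overlapping copy segments in {path}: "
                f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
            )
    return segments


def write_seg(
    segments: Sequence[CopySegment], path: PathLike, sample: str = "sample"
) -> None:
    """Write segments as headered 5-column SEG (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tvalue\n")
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            value = int(s.value) if float(s.value).is_integer() else s.value
            fh.write(f"{sample}\t{s.chrom}\t{s.start}\t{s.end}\t{value}\n")


def write_truth_json(
    path: PathLike,
    events: Sequence,
    truth_fraction: float,
    seed: Optional[int],
    config: Dict,
) -> None:
    """Write the simulation truth file (events, k values, truth fraction, config)."""
    payload = {
        "events": [
            {
                "index": e.index,
                "k": e.k,
                "cut_bonds": [[c, int(n)] for c, n in e.cut_bonds],
                "n_created": len(e.created),
            }
            for e in events
        ],
        "truth_fraction": truth_fraction,
        "seed": seed,
        "config": config,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
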