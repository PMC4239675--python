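"""Open-adjacency classification via counterpart- and copy-number asymmetry.

An adjacency {x, y} is *closed* when the counterparts {x', y'} of its
endpoints are themselves fused — forced whenever the adjacency arose from a
2-break (an ordinary DCJ rearrangement).  Adjacencies from simultaneous
multi-break events (k > 2 cuts) need not close, and two observable signatures
expose this:

* **counterpart-asymmetry** — a matched counterpart of one endpoint is fused
  to some breakend other than the other endpoint's counterpart;
* **copy-number asymmetry** — the change-in-copy values differ across the two
  endpoints, Δ(x) != Δ(y).  Under no breakpoint reuse, fused breakends rise
  and fall in copy together, so closed adjacencies are always copy-symmetric;
  asymmetry therefore certifies openness.

"Open" is the union of the two signatures; each component flag is reported
separately so that the copy-only CAE statistic can ignore counterpart
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

from .copymap import DeltaProfile
from .core import Adjacency, AdjacencySet
from .counterparts import CounterpartPairing

__all__ = [
    "OpenCall",
    "counterpart_asymmetric",
    "copy_asymmetric",
    "classify_adjacencies",
    "calls_to_frame",
]


@dataclass(frozen=True)
class OpenCall:
    """Classification of one adjacency; ``open`` is the OR of the two flags."""

    adjacency: Adjacency
    counterpart_asym: bool
    copy_asym: bool

    @property
    def open(self) -> bool:
        return self.counterpart_asym or self.copy_asym


def _asymmetric_from(
    x, y, pairing: CounterpartPairing, evidence: AdjacencySet
) -> bool:
    """Openness evidence from endpoint ``x`` of adjacency {x, y}.

    True when x has a matched counterpart x' whose own fusion partner w is
    demonstrably not y's counterpart: either y is unmatched (had w been y's
    counterpart the matcher would have paired them) or y's matched counterpart
    differs from w.
    """
    xp_uid = pairing.mate(x.uid)
    if xp_uid is None:
        return False
    # criterion (3) of matching excludes {x, x'} being an adjacency, so x'
    # can never be an endpoint of {x, y} itself
    assert xp_uid != y.uid, "counterpart matched inside its own adjacency"
    w = evidence.partner_of(xp_uid)
    yp_uid = pairing.mate(y.uid)
    return yp_uid is None or yp_uid != w.uid


def counterpart_asymmetric(
    A: Adjacency,
    pairing: CounterpartPairing,
    adjset: AdjacencySet,
    evidence: Optional[AdjacencySet] = None,
) -> bool:
    """True iff adjacency ``A`` shows counterpart-asymmetry.

    ``evidence`` is the adjacency collection in which counterpart fusion
    partners are looked up; it defaults to ``adjset`` (per-set scope) and may
    be a genome-wide pool when matching was performed across sets.  False when
    neither endpoint has a matched counterpart (no evidence either way).
    """
    if evidence is None:
        evidence = adjset
    x, y = A.breakends
    return _asymmetric_from(x, y, pairing, evidence) or _asymmetric_from(
        y, x, pairing, evidence
    )


def copy_asymmetric(A: Adjacency, delta: DeltaProfile) -> bool:
    """True iff Δ differs across the two endpoints of ``A``."""
    x, y = A.breakends
    try:
        return delta[x.uid] != delta[y.uid]
    except KeyError as exc:
        raise ValueError(f"breakend {exc.args[0]!r} missing from delta profile") from exc


def classify_adjacencies(
    adjset: AdjacencySet,
    pairing: CounterpartPairing,
    delta: Optional[DeltaProfile] = None,
    evidence: Optional[AdjacencySet] = None,
) -> List[OpenCall]:
    """Classify every adjacency of ``adjset`` as open or closed.

    With ``delta=None`` (no usable copy profile) classification degrades to
    counterpart evidence only and every ``copy_asym`` flag is False.
    """
    calls = []
    for A in adjset:
        calls.append(
            OpenCall(
                adjacency=A,
                counterpart_asym=counterpart_asymmetric(A, pairing, adjset, evidence),
                copy_asym=copy_asymmetric(A, delta) if delta is not None else False,
            )
        )
    return calls


def calls_to_frame(calls: List[OpenCall]) -> pd.DataFrame:
    """Tabulate open calls for serialization."""
    rows = []
    for c in calls:
        a = c.adjacency
        rows.append(
            {
                "set_id": a.set_id,
                "chrom1": a.first.chrom,
                "pos1": a.first.pos,
                "orient1": a.first.orient,
                "chrom2": a.second.chrom,
                "pos2": a.second.pos,
                "orient2": a.second.orient,
                "counterpart_asym": c.counterpart_asym,
                "copy_asym": c.copy_asym,
                "open": c.open,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "chrom1",
            "pos1",
            "orient1",
            "chrom2",
            "pos2",
            "orient2",
            "counterpart_asym",
            "copy_asym",
            "open",
        ],
    )
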