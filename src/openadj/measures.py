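"""Set-level statistics: open adjacency rate, copy-number asymmetry enrichment,
and cohort-level comparisons.

For an adjacency set Ã with open calls O and copy-asymmetric subset C:

* ``OAR = |O| / |Ã|`` — a lower bound on the fraction of adjacencies formed
  in simultaneous (k>2)-break events, since only such events can produce open
  adjacencies.
* ``CAE = |C| / (2 p_Δ (1 - p_Δ) |Ã|)`` — an estimate of the same fraction
  from copy-number asymmetry alone.  Under a Bernoulli model in which each
  breakend co-locates with a copy loss with probability p_Δ (endpoints
  dependent for 2-break adjacencies, independent for multi-break ones), a
  multi-break adjacency is copy-asymmetric with probability 2 p_Δ (1 - p_Δ),
  so dividing |C| by that rate undoes the thinning.  CAE is undefined when
  p_Δ is 0 or 1 (no asymmetry is observable).

Cohort operations compare these statistics between labeled groups (rank-sum
test) or correlate them with an external per-set (k>2)-fraction annotation
k̂ (Pearson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .copymap import DeltaProfile
from .core import AdjacencySet
from .signatures import OpenCall

__all__ = [
    "DEFAULT_MIN_SET_SIZE",
    "UndefinedCAEError",
    "SetMeasures",
    "oar",
    "cae",
    "cae_from_counts",
    "set_measures",
    "group_compare",
    "correlate_khat",
    "filter_small_sets",
    "measures_to_frame",
]

DEFAULT_MIN_SET_SIZE = 15
"""Sets with fewer adjacencies than this are dropped from cohort analyses."""


class UndefinedCAEError(ValueError):
    """Raised when CAE is undefined because p_delta is 0 or 1."""


class TestResult(NamedTuple):
    statistic: float
    pvalue: float


class CorrelationResult(NamedTuple):
    r: float
    pvalue: float
    n: int


@dataclass
class SetMeasures:
    """Summary statistics for one adjacency set."""

    set_id: str
    n_adjacencies: int
    n_open: int
    n_copy_asym: int
    p_delta: float
    oar: float
    cae: float  # NaN when undefined
    k_hat: Optional[float] = None


def oar(calls: Sequence[OpenCall]) -> float:
    """Open adjacency rate |O| / |Ã| of a classified adjacency set."""
    if not calls:
        raise ValueError("cannot compute OAR of an empty adjacency set")
    return sum(1 for c in calls if c.open) / len(calls)


def cae_from_counts(n_copy_asym: int, p_delta: float, n_adjacencies: int) -> float:
    """CAE from its three ingredients: |C| / (2 p_Δ (1 - p_Δ) |Ã|)."""
    if n_adjacencies <= 0:
        raise ValueError("cannot compute CAE of an empty adjacency set")
    if p_delta <= 0.0 or p_delta >= 1.0:
        raise UndefinedCAEError(
            f"CAE is undefined for p_delta = {p_delta}: with every breakend "
            "(or none) co-locating with a copy change, copy-number asymmetry "
            "carries no signal"
        )
    return n_copy_asym / (2.0 * p_delta * (1.0 - p_delta) * n_adjacencies)


def cae(calls: Sequence[OpenCall], delta: DeltaProfile) -> float:
    """Copy-number asymmetry enrichment of a classified adjacency set.

    Uses only the ``copy_asym`` flags, never counterpart evidence.
    """
    if not calls:
        raise ValueError("cannot compute CAE of an empty adjacency set")
    n_asym = sum(1 for c in calls if c.copy_asym)
    return cae_from_counts(n_asym, delta.p_delta, len(calls))


def set_measures(
    adjset: AdjacencySet,
    calls: Sequence[OpenCall],
    delta: Optional[DeltaProfile] = None,
) -> SetMeasures:
    """Bundle OAR/CAE and their ingredients for one adjacency set.

    CAE is reported as NaN when no delta profile is available or p_Δ makes it
    undefined.
    """
    n_open = sum(1 for c in calls if c.open)
    n_copy = sum(1 for c in calls if c.copy_asym)
    p_delta = delta.p_delta if delta is not None else math.nan
    if delta is None:
        cae_value = math.nan
    else:
        try:
            cae_value = cae_from_counts(n_copy, delta.p_delta, len(calls))
        except UndefinedCAEError:
            cae_value = math.nan
    return SetMeasures(
        set_id=adjset.set_id,
        n_adjacencies=len(calls),
        n_open=n_open,
        n_copy_asym=n_copy,
        p_delta=p_delta,
        oar=n_open / len(calls),
        cae=cae_value,
        k_hat=adjset.k_hat,
    )


def _extract(measures: Sequence[SetMeasures], statistic: str) -> np.ndarray:
    if statistic not in ("oar", "cae"):
        raise ValueError(f"statistic must be 'oar' or 'cae', got {statistic!r}")
    values = np.array([getattr(m, statistic) for m in measures], dtype=float)
    return values


def group_compare(
    measures_a: Sequence[SetMeasures],
    measures_b: Sequence[SetMeasures],
    statistic: str = "oar",
    alternative: str = "two-sided",
) -> TestResult:
    """Rank-sum (Mann-Whitney U) comparison of a statistic between two groups.

    Exact permutation null for small groups (both sizes <= 8), normal
    approximation with tie correction otherwise.  NaN values (undefined CAE)
    are dropped.
    """
    a = _extract(measures_a, statistic)
    b = _extract(measures_b, statistic)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must contain at least one defined value")
    if 2 <= len(a) <= 8 and 2 <= len(b) <= 8:
        method = stats.PermutationMethod(n_resamples=20_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def correlate_khat(
    measures: Sequence[SetMeasures], statistic: str = "oar"
) -> CorrelationResult:
    """Pearson correlation of a statistic against the external k̂ annotation.

    Only sets carrying a k̂ annotation and a defined statistic participate;
    at least three such sets and nonzero variance on both axes are required.
    """
    values = []
    khats = []
    for m in measures:
        v = getattr(m, statistic)
        if m.k_hat is not None and not math.isnan(v):
            values.append(v)
            khats.append(m.k_hat)
    _extract(measures, statistic)  # validates statistic name
    if len(values) < 3:
        raise ValueError(
            f"need >= 3 sets with k_hat and defined {statistic}, got {len(values)}"
        )
    v = np.asarray(values, dtype=float)
    k = np.asarray(khats, dtype=float)
    if v.std() == 0 or k.std() == 0:
        raise ValueError("zero variance in statistic or k_hat; correlation undefined")
    r, p = stats.pearsonr(v, k)
    return CorrelationResult(r=float(r), pvalue=float(p), n=len(values))


def filter_small_sets(
    sets: Sequence[AdjacencySet], min_size: int = DEFAULT_MIN_SET_SIZE
) -> List[AdjacencySet]:
    """Retain adjacency sets with at least ``min_size`` adjacencies."""
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    return [s for s in sets if len(s) >= min_size]


def measures_to_frame(measures: Sequence[SetMeasures]) -> pd.DataFrame:
    """Tabulate per-set measures for serialization."""
    rows = []
    for m in measures:
        rows.append(
            {
                "set_id": m.set_id,
                "n_adjacencies": m.n_adjacencies,
                "n_open": m.n_open,
                "n_copy_asym": m.n_copy_asym,
                "p_delta": m.p_delta,
                "oar": m.oar,
                "cae": m.cae,
                "k_hat": math.nan if m.k_hat is None else m.k_hat,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "n_adjacencies",
            "n_open",
            "n_copy_asym",
            "p_delta",
            "oar",
            "cae",
            "k_hat",
        ],
    )
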