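import math

import numpy as np
import pytest

from conftest import classify_exact, simulate_exact
from openadj.copymap import DeltaProfile
from openadj.core import AdjacencySet, Breakend, canonical_adjacency
from openadj.measures import (
    SetMeasures,
    UndefinedCAEError,
    cae_from_counts,
    correlate_khat,
    filter_small_sets,
    group_compare,
    oar,
    set_measures,
)
from openadj.signatures import OpenCall
from openadj.simulator import bernoulli_cohort, cae_of_delta_pairs


def _calls(flags):
    """OpenCalls from (counterpart_asym, copy_asym) tuples."""
    out = []
    for i, (cp, cn) in enumerate(flags):
        a = canonical_adjacency(
            Breakend("chr1", 10 * i + 1, "+", f"a{i}"),
            Breakend("chr2", 10 * i + 1, "-", f"b{i}"),
        )
        out.append(OpenCall(adjacency=a, counterpart_asym=cp, copy_asym=cn))
    return out


def _m(oar_value, cae_value=math.nan, k_hat=None):
    return SetMeasures("s", 20, 0, 0, 0.5, oar_value, cae_value, k_hat)


class TestOAR:
    def test_arithmetic(self):
        calls = _calls([(True, False)] * 3 + [(False, False)] * 9)
        assert oar(calls) == 0.25

    def test_zero_open(self):
        assert oar(_calls([(False, False)] * 5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oar([])

    def test_bounded_by_truth_fraction_in_exact_simulation(self):
        for seed in range(20):
            _, _, obs = simulate_exact([2, 2, 2, 5], seed=seed)
            calls, _, _ = classify_exact(obs)
            assert 0.0 <= oar(calls) <= obs.truth_fraction + 1e-12


class TestCAE:
    def test_arithmetic(self):
        assert cae_from_counts(4, 0.5, 16) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_undefined_at_degenerate_p_delta(self, p):
        with pytest.raises(UndefinedCAEError):
            cae_from_counts(1, p, 16)

    def test_ignores_counterpart_flags(self):
        """CAE is built from copy asymmetry alone."""
        flags_with = [(True, True), (True, False), (False, False), (False, True)]
        flags_without = [(False, True), (False, False), (False, False), (False, True)]
        delta = DeltaProfile(delta={}, matched=set(), p_delta=0.4)
        from openadj.measures import cae

        assert cae(_calls(flags_with), delta) == cae(_calls(flags_without), delta)

    def test_unbiased_under_bernoulli_model(self):
        rng = np.random.default_rng(99)
        vals = [
            cae_of_delta_pairs(bernoulli_cohort(2000, 0.6, 0.4, rng=rng)[0])
            for _ in range(50)
        ]
        assert abs(np.mean(vals) - 0.6) < 0.05


class TestGroupCompare:
    def test_identical_groups(self):
        g = [_m(v) for v in (0.1, 0.2, 0.3, 0.4)]
        res = group_compare(g, list(g), "oar")
        assert res.pvalue == pytest.approx(1.0)

    def test_extreme_groups_attain_exact_minimum(self):
        # all-0 vs all-1, n=4 vs 4: exact two-sided permutation p = 2/70
        a = [_m(0.0)] * 4
        b = [_m(1.0)] * 4
        res = group_compare(a, b, "oar")
        assert res.pvalue == pytest.approx(2 / 70)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [_m(0.1)], "oar")

    def test_nan_cae_dropped(self):
        a = [_m(0.1, cae_value=math.nan), _m(0.1, cae_value=0.2), _m(0.1, cae_value=0.3)]
        b = [_m(0.9, cae_value=0.8), _m(0.9, cae_value=0.9)]
        res = group_compare(a, b, "cae")
        assert 0 <= res.pvalue <= 1


class TestCorrelateKhat:
    def test_perfect_correlation(self):
        ms = [_m(v, k_hat=v) for v in (0.1, 0.4, 0.8)]
        res = correlate_khat(ms, "oar")
        assert res.r == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(4)
        ms = [_m(float(rng.random()), k_hat=float(rng.random())) for _ in range(400)]
        res = correlate_khat(ms, "oar")
        assert abs(res.r) < 0.15

    def test_insufficient_or_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate_khat([_m(0.1, k_hat=0.5), _m(0.2, k_hat=0.6)], "oar")
        with pytest.raises(ValueError):
            correlate_khat([_m(0.5, k_hat=v) for v in (0.1, 0.5, 0.9)], "oar")

    def test_recovers_truth_fraction_from_exact_simulations(self):
        """OAR tracks the per-set multi-break truth fraction closely."""
        mixes = [
            [2] * 12,
            [2] * 9 + [4],
            [2] * 6 + [4, 4, 4],
            [2] * 3 + [5, 5, 4],
            [6, 6, 6],
        ]
        ms = []
        for rep in range(4):
            for i, ks in enumerate(mixes):
                _, _, obs = simulate_exact(ks, seed=rep * 10 + i, set_id=f"s{rep}_{i}")
                obs.adjset.k_hat = obs.truth_fraction
                calls, _, delta = classify_exact(obs)
                ms.append(set_measures(obs.adjset, calls, delta))
        res = correlate_khat(ms, "oar")
        assert res.r > 0.8


class TestFilterSmallSets:
    def _sets(self, sizes):
        out = []
        uid = 0
        for si, n in enumerate(sizes):
            adjacencies = []
            for _ in range(n):
                adjacencies.append(
                    canonical_adjacency(
                        Breakend("chr1", uid * 10 + 1, "+", f"u{uid}"),
                        Breakend("chr2", uid * 10 + 1, "-", f"v{uid}"),
                        set_id=f"s{si}",
                    )
                )
                uid += 1
            out.append(AdjacencySet(set_id=f"s{si}", adjacencies=adjacencies))
        return out

    def test_boundary(self):
        kept = filter_small_sets(self._sets([14, 15, 40]), min_size=15)
        assert [s.set_id for s in kept] == ["s1", "s2"]

    def test_min_one_is_identity_and_empty_ok(self):
        sets = self._sets([3, 5])
        assert filter_small_sets(sets, min_size=1) == sets
        assert filter_small_sets([], min_size=15) == []
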