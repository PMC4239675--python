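from collections import Counter

import numpy as np
import pytest

from conftest import classify_exact, simulate_exact
from openadj.simulator import (
    bernoulli_cohort,
    derive_copy_profile,
    observe,
    simulate_history,
)

SMALL_REF = {"chrA": 200_000, "chrB": 150_000}
SMALL = dict(min_spacing=10, edge_margin=100)


class TestSimulateHistory:
    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_history(SMALL_REF, [1], seed=0, **SMALL)

    def test_deletion_from_lost_circle(self):
        """A 2-break whose circle is lost leaves one adjacency and a
        single-copy drop flanked by both its breakends."""
        for seed in range(40):
            genome, history, obs = simulate_exact([2], seed=seed)
            if len(obs.adjset) == 1:  # circle-forming fusion sampled
                (adj,) = obs.adjset.adjacencies
                lost = [s for s in obs.segments if s.value == 1]
                assert len(lost) == 1
                (dropped,) = lost
                ends = sorted((adj.first.pos, adj.second.pos))
                assert ends == [dropped.start - 1, dropped.end + 1]
                return
        pytest.fail("no circle-forming 2-break sampled in 40 seeds")

    def test_balanced_2break_keeps_profile_flat(self):
        for seed in range(40):
            genome, history, obs = simulate_exact([2], seed=seed)
            if len(obs.adjset) == 2:  # inversion/translocation fusion
                assert all(s.value == 2 for s in obs.segments)
                return
        pytest.fail("no balanced 2-break sampled in 40 seeds")

    def test_3break_creates_three_open_adjacencies(self):
        genome, history = simulate_history(
            {"chr1": 80_000_000}, [3], circle_loss_p=0.0, seed=5,
            min_spacing=6000, edge_margin=60_000,
        )
        (event,) = history
        assert event.k == 3 and len(event.created) == 3

    def test_no_breakpoint_reuse(self):
        for seed in range(10):
            _, history = simulate_history(
                SMALL_REF, [2, 3, 4, 2], seed=seed, **SMALL
            )
            bonds = [b for e in history for b in e.cut_bonds]
            assert len(bonds) == len(set(bonds))

    def test_degree_constraint(self):
        """Every non-telomeric segment end is fused to exactly one partner."""
        for seed in range(10):
            genome, _ = simulate_history(SMALL_REF, [2, 5, 3], seed=seed, **SMALL)
            for mol in genome.chromosomes:
                assert not mol.circular
                assert len(mol.junctions) == len(mol.segments) - 1
            for mol in genome.circles:
                assert mol.circular
                assert len(mol.junctions) == len(mol.segments)

    def test_base_conservation(self):
        """Retained + lost molecules exactly tile the reference (base-wise)."""
        for seed in range(5):
            genome, _ = simulate_history(
                SMALL_REF, [2, 4, 3], circle_loss_p=0.5, seed=seed, **SMALL
            )
            for chrom, length in SMALL_REF.items():
                cover = np.zeros(length + 2, dtype=int)
                for mol in genome.chromosomes + genome.circles:
                    for seg in mol.segments:
                        if seg.chrom == chrom:
                            cover[seg.start : seg.end + 1] += 1
                assert (cover[1 : length + 1] == 1).all()

    def test_copy_profile_matches_segment_coverage(self):
        for seed in range(5):
            genome, _ = simulate_history(
                SMALL_REF, [3, 2], circle_loss_p=1.0, seed=seed, **SMALL
            )
            profile = derive_copy_profile(genome, ploidy_offset=1)
            for chrom, length in SMALL_REF.items():
                cover = np.ones(length + 2, dtype=int)
                for mol in genome.retained_molecules():
                    for seg in mol.segments:
                        if seg.chrom == chrom:
                            cover[seg.start : seg.end + 1] += 1
                segs = [s for s in profile if s.chrom == chrom]
                assert segs[0].start == 1 and segs[-1].end == length
                for s in segs:
                    assert (cover[s.start : s.end + 1] == s.value).all()

    def test_deterministic_given_seed(self):
        a = simulate_history(SMALL_REF, [2, 4], seed=123, **SMALL)
        b = simulate_history(SMALL_REF, [2, 4], seed=123, **SMALL)
        assert [e.cut_bonds for e in a[1]] == [e.cut_bonds for e in b[1]]


class TestObserve:
    def test_exact_observation_collects_surviving_fusions(self):
        genome, history, obs = simulate_exact([2, 2, 5], seed=8)
        surviving = [j for m in genome.retained_molecules() for j in m.junctions]
        assert len(obs.adjset) == len(surviving)
        assert obs.noise["dropout_p"] == 0.0

    def test_dropout_thins_binomially(self):
        genome, history = simulate_history(
            {"chr1": 80_000_000}, [20], circle_loss_p=0.0, seed=3,
            min_spacing=6000, edge_margin=60_000,
        )
        n_full = len(observe(genome, history, seed=0).adjset)
        rng = np.random.default_rng(1)
        counts = [
            len(observe(genome, history, dropout_p=0.3, rng=rng).adjset)
            for _ in range(200)
        ]
        assert np.mean(counts) == pytest.approx(0.7 * n_full, rel=0.05)

    def test_jitter_moves_positions_but_not_orientation(self):
        genome, history = simulate_history(
            {"chr1": 80_000_000}, [6], circle_loss_p=0.0, seed=3,
            min_spacing=6000, edge_margin=60_000,
        )
        exact = observe(genome, history, seed=0)
        noisy = observe(genome, history, jitter_sd=50.0, seed=0)
        by_uid = {b.uid: b for b in exact.adjset.breakends}
        moved = 0
        for b in noisy.adjset.breakends:
            ref = by_uid[b.uid]
            assert b.orient == ref.orient
            assert abs(b.pos - ref.pos) <= 150  # clipped at 3 sd
            moved += b.pos != ref.pos
        assert moved > 0

    def test_truth_fraction_definitions(self):
        _, _, obs2 = simulate_exact([2, 2], seed=4)
        assert obs2.truth_fraction == 0.0
        genome, history = simulate_history(
            {"chr1": 80_000_000}, [8], circle_loss_p=1.0, seed=4,
            min_spacing=6000, edge_margin=60_000,
        )
        obs8 = observe(genome, history, seed=0)
        assert obs8.truth_fraction == 1.0

    def test_oar_tracks_truth_fraction_monotonically(self):
        """Averaged over seeds, OAR rises with the share of multi-break events."""
        mixes = [[2] * 8, [2] * 4 + [4, 4], [4] * 4]
        mean_oars = []
        for i, ks in enumerate(mixes):
            oars = []
            for seed in range(12):
                _, _, obs = simulate_exact(ks, seed=500 + 20 * i + seed)
                calls, _, _ = classify_exact(obs)
                oars.append(sum(c.open for c in calls) / len(calls))
            mean_oars.append(np.mean(oars))
        assert mean_oars[0] < mean_oars[1] < mean_oars[2]


class TestBernoulliCohort:
    def test_no_multibreak_share_is_never_asymmetric(self):
        pairs, truth = bernoulli_cohort(500, 0.0, 0.5, seed=0)
        assert truth == 0.0
        assert (pairs[:, 0] == pairs[:, 1]).all()

    def test_asymmetric_share_matches_2p_1mp(self):
        rng = np.random.default_rng(12)
        frac = np.mean(
            [
                (lambda p: (p[:, 0] != p[:, 1]).mean())(
                    bernoulli_cohort(2000, 1.0, 0.5, rng=rng)[0]
                )
                for _ in range(30)
            ]
        )
        assert frac == pytest.approx(2 * 0.5 * 0.5, abs=0.02)

    def test_values_restricted_to_loss_or_none(self):
        pairs, _ = bernoulli_cohort(1000, 0.4, 0.3, seed=9)
        assert set(np.unique(pairs)) <= {-1, 0}

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_cohort(10, 1.5, 0.5)
        with pytest.raises(ValueError):
            bernoulli_cohort(10, 0.5, 0.0)
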