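"""Circuit-topology relations, censuses, profiles and densities.

The census implementation is checked against an independent O(m²)
interval-arithmetic oracle written here from the definitions.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpcircuit.contacts import ContactCriteria
from idpcircuit.synth import (
    ContactSchedule,
    make_contact_scaffold,
    make_fluctuation_ensemble,
)
from idpcircuit.topology import (
    Relation,
    classify_relation,
    inverse_parallel_counts,
    local_inverse_parallel_profile,
    sample_frames,
    topology_census,
    topology_density,
)

from conftest import random_contact_map


def oracle_census(pairs) -> tuple[int, int, int]:
    """Brute-force S/P/X counts from closed-interval arithmetic."""
    pairs = sorted(pairs)
    n_s = n_p = n_x = 0
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (i1, j1), (i2, j2) = pairs[a], pairs[b]
            if j1 <= i2 or j2 <= i1:
                n_s += 1
            elif (i1 <= i2 and j2 <= j1) or (i2 <= i1 and j1 <= j2):
                n_p += 1
            else:
                n_x += 1
    return n_s, n_p, n_x


class TestClassifyRelation:
    @pytest.mark.parametrize("c1,c2,expected", [
        ((1, 10), (12, 20), Relation.S),    # disjoint
        ((1, 10), (3, 7), Relation.P),      # strict nesting
        ((3, 7), (1, 10), Relation.Pinv),   # nesting seen from the inside
        ((1, 10), (5, 15), Relation.X),     # interleaved
        ((1, 10), (10, 20), Relation.S),    # touching end-to-start
        ((1, 10), (1, 7), Relation.P),      # shared start
        ((2, 10), (1, 10), Relation.Pinv),  # shared end
    ])
    def test_cases(self, c1, c2, expected):
        assert classify_relation(c1, c2) is expected

    def test_directional_inverse(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pairs = sorted(random_contact_map(rng, 50, 2))
            if len(pairs) < 2:
                continue
            r = classify_relation(pairs[0], pairs[1])
            rr = classify_relation(pairs[1], pairs[0])
            if r is Relation.P:
                assert rr is Relation.Pinv
            elif r is Relation.Pinv:
                assert rr is Relation.P
            else:
                assert rr is r

    def test_identical_contacts_rejected(self):
        with pytest.raises(ValueError):
            classify_relation((1, 10), (1, 10))


class TestCensus:
    def test_empty_map(self):
        c = topology_census(np.empty((0, 2), dtype=int))
        assert (c.n_S, c.n_P, c.n_X) == (0, 0, 0)

    def test_nested_ladder_all_parallel(self):
        ladder = [(1, 20), (2, 19), (3, 18), (4, 17)]
        c = topology_census(np.array(ladder))
        assert (c.n_P, c.n_S, c.n_X) == (6, 0, 0)
        assert oracle_census(ladder) == (0, 6, 0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_oracle_and_is_complete(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(0, 60))
        pairs = random_contact_map(rng, 200, m, exclusion=0)
        c = topology_census(np.array(sorted(pairs)) if pairs else np.empty((0, 2), int))
        assert (c.n_S, c.n_P, c.n_X) == oracle_census(pairs)
        n = len(pairs)
        assert c.total == n * (n - 1) // 2

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_chain_reversal_symmetry(self, seed):
        """Reversing residue numbering preserves the unordered census."""
        rng = np.random.default_rng(seed)
        pairs = random_contact_map(rng, 100, 25, exclusion=0)
        if not pairs:
            return
        n = 101
        reversed_pairs = {(n - j, n - i) for i, j in pairs}
        a = topology_census(np.array(sorted(pairs)))
        b = topology_census(np.array(sorted(reversed_pairs)))
        assert (a.n_S, a.n_P, a.n_X) == (b.n_S, b.n_P, b.n_X)


class TestInverseParallel:
    def test_hand_enumeration(self):
        # (10,20) is enclosed by (5,30); (5,30) by nothing
        arr = np.array([(5, 30), (10, 20)])
        assert inverse_parallel_counts(arr).tolist() == [0, 1]

    def test_against_oracle(self):
        rng = np.random.default_rng(3)
        pairs = sorted(random_contact_map(rng, 80, 20, exclusion=0))
        got = inverse_parallel_counts(np.array(pairs))
        for k, (i, j) in enumerate(pairs):
            want = sum(
                1 for (a, b) in pairs
                if (a, b) != (i, j) and a <= i and j <= b
            )
            assert got[k] == want


class TestLocalProfile:
    def test_single_frame_hand_case(self):
        frame = make_contact_scaffold(35, [(5, 30), (10, 20)], seed=2)
        ens = make_fluctuation_ensemble(frame, 0.0, 1, seed=0)
        prof = local_inverse_parallel_profile(ens)
        assert prof.mean[10 - 1] == 1.0
        assert prof.mean[20 - 1] == 1.0
        assert prof.mean[5 - 1] == 0.0
        assert prof.mean[30 - 1] == 0.0

    def test_rigid_ensemble_zero_sem(self):
        frame = make_contact_scaffold(35, [(5, 30), (10, 20)], seed=2)
        ens = make_fluctuation_ensemble(frame, 0.0, 4, seed=0)
        prof = local_inverse_parallel_profile(ens)
        assert np.all(prof.sem == 0.0)

    def test_duplication_scales_sem(self):
        """Doubling every frame keeps means and divides SEM by sqrt(2)."""
        base = make_contact_scaffold(30, [(4, 26)], seed=5)
        ens = make_fluctuation_ensemble(
            base, 0.0, 6, [ContactSchedule.fraction((8, 22), 6, 0.5)], seed=6)
        single = local_inverse_parallel_profile(ens)
        from idpcircuit.io import Ensemble
        doubled = Ensemble(ens.frames + ens.frames)
        twice = local_inverse_parallel_profile(doubled)
        assert np.allclose(single.mean, twice.mean)
        assert np.allclose(twice.sem, single.sem / np.sqrt(2))

    def test_profile_peak_inside_enclosed_region(self):
        """A persistent enclosing pair concentrates inverse-parallel weight
        on the contacts it encloses."""
        planted = [(2, 34), (10, 20), (12, 18)]
        frame = make_contact_scaffold(36, planted, seed=7)
        ens = make_fluctuation_ensemble(frame, 0.0, 2, seed=8)
        prof = local_inverse_parallel_profile(ens)
        # brute-force recomputation per residue
        expect = np.zeros(36)
        pairs = sorted(planted)
        for (i, j) in pairs:
            enc = sum(1 for (a, b) in pairs if (a, b) != (i, j) and a <= i and j <= b)
            expect[i - 1] += enc
            expect[j - 1] += enc
        assert np.allclose(prof.mean, expect)
        assert prof.mean.argmax() + 1 in (12, 18)


class TestDensity:
    def test_identical_frames_single_bin(self):
        frame = make_contact_scaffold(30, [(2, 28), (5, 20)], seed=9)
        ens = make_fluctuation_ensemble(frame, 0.0, 5, seed=1)
        hist, *_ = topology_density(ens, bins=5)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist > 0).sum() == 1

    def test_two_state_split(self):
        f1 = make_contact_scaffold(30, [(2, 28), (5, 20)], seed=9)
        f2 = make_contact_scaffold(30, [(2, 10), (15, 25)], seed=10)
        e1 = make_fluctuation_ensemble(f1, 0.0, 4, seed=2)
        e2 = make_fluctuation_ensemble(f2, 0.0, 4, seed=3)
        hist, s_edges, px_edges, pts = topology_density([e1, e2], bins=4)
        assert hist.sum() == pytest.approx(1.0)
        nonzero = sorted(hist[hist > 0].ravel())
        assert nonzero == [0.5, 0.5]


class TestSampling:
    def test_stride_from_time_stamps(self):
        frame = make_contact_scaffold(10, [], seed=0)
        ens = make_fluctuation_ensemble(frame, 0.0, 8, seed=0, sampling_interval_ns=5.0)
        assert sample_frames(ens, 10.0) == [0, 2, 4, 6]

    def test_too_fine_interval_rejected(self):
        frame = make_contact_scaffold(10, [], seed=0)
        ens = make_fluctuation_ensemble(frame, 0.0, 4, seed=0, sampling_interval_ns=25.0)
        with pytest.raises(ValueError, match="finer"):
            sample_frames(ens, 5.0)
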