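"""Haplotype-conditioned clustering, disunion and cluster statistics."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapsv.hap_cluster import (
    ClusterParams,
    cluster_signatures,
    cluster_stats,
    haplotype_multiplier,
    pair_mergeable,
    significantly_different,
    split_by_haplotype,
)

from helpers import brute_force_clusters, cluster_of, clusters_as_sets, sig

TOL = 1e-9


class TestHaplotypeMultiplier:
    def test_same_haplotype_uses_sr(self):
        p = ClusterParams(SR=0.7, DR=1.5)
        assert haplotype_multiplier(sig(0, 100, hap=1), sig(10, 100, hap=1), p) == 0.7

    def test_different_haplotypes_use_dr(self):
        p = ClusterParams(SR=0.7, DR=1.5)
        assert haplotype_multiplier(sig(0, 100, hap=1), sig(10, 100, hap=2), p) == 1.5

    @pytest.mark.parametrize("h1, h2", [(0, 2), (1, 0), (0, 0)])
    def test_untagged_pair_is_neutral(self, h1, h2):
        p = ClusterParams(SR=0.7, DR=1.5)
        assert haplotype_multiplier(sig(0, 100, hap=h1), sig(10, 100, hap=h2), p) == 1.0


class TestPairMergeable:
    def test_identical_signatures_merge(self):
        p = ClusterParams(F=1.0)
        s = sig(1000, 100)
        assert pair_mergeable(s, s, p)

    def test_positional_condition_with_cross_haplotype_multiplier(self):
        # offsets of 600 exceed F=500 but not F*DR = 750 for a cross-hap pair
        p = ClusterParams(F=500, CR=0.3, DR=1.5)
        s1 = sig(0, 100, "INS", hap=1)
        s2 = sig(600, 700, "INS", hap=2)
        assert pair_mergeable(s1, s2, p)
        # same offsets with a same-haplotype pair: F*SR = 400 < 600
        s3 = sig(600, 700, "INS", hap=1)
        assert not pair_mergeable(s1, s3, ClusterParams(F=500, CR=0.3, SR=0.8))

    def test_relative_condition(self):
        # max(10, 10, 20)/100 = 0.2 < CR = 0.3 for an untagged pair
        p = ClusterParams(F=5, CR=0.3)
        assert pair_mergeable(sig(0, 100, "INS"), sig(10, 120, "INS"), p)
        # ratio 0.2 is not < CR*SR = 0.15 for a same-haplotype pair
        p2 = ClusterParams(F=5, CR=0.3, SR=0.5)
        assert not pair_mergeable(sig(0, 100, "INS", hap=2), sig(10, 120, "INS", hap=2), p2)

    def test_strict_inequality_at_boundary(self):
        # distance exactly F does not merge (strict <)
        p = ClusterParams(F=500, CR=0.001)
        assert not pair_mergeable(sig(0, 10000), sig(500, 10000, right=10500), p)


class TestClusterSignatures:
    def test_identical_pair_forms_one_cluster(self):
        s1, s2 = sig(100, 80, read_id="a"), sig(100, 80, read_id="b")
        (c,) = cluster_signatures([s1, s2], ClusterParams())
        assert cluster_stats(c).n == 2

    def test_transitive_closure_chains(self):
        # A-B mergeable, B-C mergeable, A-C not: one cluster of three
        p = ClusterParams(F=150, CR=0.001)
        a, b, c = sig(0, 1000), sig(100, 1000), sig(200, 1000)
        assert not pair_mergeable(a, c, p)
        (cl,) = cluster_signatures([a, b, c], p)
        assert len(cl.signatures) == 3

    def test_types_and_chromosomes_never_mix(self):
        sigs = [
            sig(100, 80, "DEL"),
            sig(100, 80, "INS"),
            sig(100, 80, "DEL", chrom="chr2"),
        ]
        clusters = cluster_signatures(sigs, ClusterParams())
        assert len(clusters) == 3

    def test_matches_bruteforce_on_random_sets(self):
        """Windowed clustering equals the O(n^2) closure (spot check; the
        full 1000-trial equivalence runs in the acceptance suite)."""
        rng = random.Random(42)
        p = ClusterParams(F=200, CR=0.3, SR=0.8, DR=1.3)
        for _ in range(50):
            sigs = [
                sig(
                    rng.randrange(0, 20_000),
                    rng.randrange(50, 2000),
                    hap=rng.choice([0, 1, 2]),
                    read_id=f"r{i}",
                )
                for i in range(rng.randrange(2, 60))
            ]
            assert clusters_as_sets(cluster_signatures(sigs, p)) == brute_force_clusters(
                sigs, p
            )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_order_invariance_and_partition(self, seed):
        """Any permutation of the input yields the same partition, and the
        partition conserves every signature exactly once."""
        rng = random.Random(seed)
        sigs = [
            sig(
                rng.randrange(0, 5000),
                rng.randrange(50, 500),
                hap=rng.choice([0, 1, 2]),
                read_id=f"r{i}",
            )
            for i in range(rng.randrange(1, 30))
        ]
        p = ClusterParams()
        ref = cluster_signatures(sigs, p)
        flattened = [s for c in ref for s in c.signatures]
        assert sorted(flattened, key=str) == sorted(sigs, key=str)
        shuffled = sigs[:]
        rng.shuffle(shuffled)
        assert clusters_as_sets(cluster_signatures(shuffled, p)) == clusters_as_sets(ref)

    def test_neutral_multipliers_equal_untagged_run(self):
        """With SR = DR = 1 clustering ignores haplotype labels entirely."""
        rng = random.Random(7)
        sigs = [
            sig(
                rng.randrange(0, 5000),
                rng.randrange(50, 500),
                hap=rng.choice([0, 1, 2]),
                read_id=f"r{i}",
            )
            for i in range(40)
        ]
        erased = [
            sig(s.left, s.length, s.sv_type, 0, s.read_id, s.chrom, s.source, s.right)
            for s in sigs
        ]
        p = ClusterParams(SR=1.0, DR=1.0)
        got = {
            frozenset((s.left, s.length, s.read_id) for s in c.signatures)
            for c in cluster_signatures(sigs, p)
        }
        want = {
            frozenset((s.left, s.length, s.read_id) for s in c.signatures)
            for c in cluster_signatures(erased, p)
        }
        assert got == want

    def test_dr_monotonicity(self):
        """Raising DR never decreases the number of merged cross-haplotype
        pairs (it loosens the cross-haplotype conditions)."""
        rng = random.Random(3)
        sigs = [
            sig(
                rng.randrange(0, 3000),
                rng.randrange(50, 400),
                hap=rng.choice([1, 2]),
                read_id=f"r{i}",
            )
            for i in range(40)
        ]

        def n_cross_merged(dr):
            p = ClusterParams(DR=dr)
            return sum(
                1
                for i, s1 in enumerate(sigs)
                for s2 in sigs[i + 1 :]
                if s1.haplotype != s2.haplotype and pair_mergeable(s1, s2, p)
            )

        counts = [n_cross_merged(dr) for dr in (1.0, 1.3, 1.8, 2.5)]
        assert counts == sorted(counts)

    def test_sr_monotonicity(self):
        """Lowering SR never increases same-haplotype merges."""
        rng = random.Random(4)
        sigs = [
            sig(rng.randrange(0, 3000), rng.randrange(50, 400), hap=1, read_id=f"r{i}")
            for i in range(40)
        ]

        def n_same_merged(sr):
            p = ClusterParams(SR=sr)
            return sum(
                1
                for i, s1 in enumerate(sigs)
                for s2 in sigs[i + 1 :]
                if pair_mergeable(s1, s2, p)
            )

        counts = [n_same_merged(sr) for sr in (1.0, 0.8, 0.5, 0.2)]
        assert counts == sorted(counts, reverse=True)


class TestSignificantlyDifferent:
    def test_equal_means_never_differ(self):
        assert not significantly_different(100, 5, 100, 50)

    def test_separated_tight_groups_differ(self):
        # lengths {48,50,52} vs {98,100,102}: population SDs ~1.633
        sd = (8 / 3) ** 0.5
        assert significantly_different(50, sd, 100, sd)

    def test_wide_spread_masks_difference(self):
        assert not significantly_different(100, 5, 110, 20)


class TestSplitByHaplotype:
    def test_single_haplotype_cluster_unchanged(self):
        c = cluster_of(sig(0, 100, hap=1), sig(2, 100, hap=1), sig(1, 100, hap=0))
        assert split_by_haplotype(c) == [c]

    def test_identical_lengths_unchanged(self):
        c = cluster_of(
            sig(0, 100, hap=1), sig(1, 100, hap=1), sig(2, 100, hap=2), sig(3, 100, hap=2)
        )
        assert split_by_haplotype(c) == [c]

    def test_disunion_assigns_untagged_to_nearest_mean(self):
        c = cluster_of(
            sig(0, 48, hap=1),
            sig(1, 50, hap=1),
            sig(2, 52, hap=1),
            sig(3, 98, hap=2),
            sig(4, 100, hap=2),
            sig(5, 102, hap=2),
            sig(6, 95, hap=0),
        )
        parts = split_by_haplotype(c)
        assert len(parts) == 2
        by_hap = {p.signatures[0].haplotype: p for p in parts}
        assert {s.length for s in by_hap[1].signatures} == {48, 50, 52}
        # the untagged length-95 signature joins the nearer (haplotype 2) side
        assert {s.length for s in by_hap[2].signatures} == {95, 98, 100, 102}

    def test_untagged_tie_goes_to_haplotype_1(self):
        c = cluster_of(sig(0, 60, hap=1), sig(1, 100, hap=2), sig(2, 80, hap=0))
        parts = split_by_haplotype(c)
        hap1 = next(p for p in parts if any(s.haplotype == 1 for s in p.signatures))
        assert any(s.length == 80 for s in hap1.signatures)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, seed):
        """Disunion never loses or duplicates signatures."""
        rng = random.Random(seed)
        c = cluster_of(
            *[
                sig(
                    i,
                    rng.randrange(50, 300),
                    hap=rng.choice([0, 1, 2]),
                    read_id=f"r{i}",
                )
                for i in range(rng.randrange(1, 20))
            ]
        )
        parts = split_by_haplotype(c)
        merged = sorted(
            (s for p in parts for s in p.signatures), key=lambda s: s.read_id
        )
        assert merged == sorted(c.signatures, key=lambda s: s.read_id)


class TestClusterStats:
    def test_counts(self):
        st_ = cluster_stats(cluster_of(sig(0, 50, hap=1), sig(1, 60, hap=2), sig(2, 70, hap=0)))
        assert (st_.n, st_.m, st_.h1, st_.h2) == (3, 2, 1, 1)

    def test_singleton_sd_is_zero(self):
        st_ = cluster_stats(cluster_of(sig(0, 10 + 40, hap=1)))
        assert (st_.m1, st_.sd1) == (50.0, 0.0)

    def test_means(self):
        st_ = cluster_stats(cluster_of(sig(10, 80), sig(20, 120)))
        assert st_.mean_len == pytest.approx(100.0, abs=TOL)
        assert st_.mean_pos == pytest.approx(15.0, abs=TOL)
        assert st_.sd1 == 0.0  # no tagged signatures
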