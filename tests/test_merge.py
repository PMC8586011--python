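"""Reciprocal overlap, non-overlapping grouping, CAST clustering and the
two-caller consensus merge."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svpop.merge import (
    cast_cluster,
    merge_within_sample,
    partition_components,
    reciprocal_overlap,
)

from conftest import make_call


class TestReciprocalOverlap:
    def test_identity_is_one(self):
        a = make_call(0, 100)
        assert reciprocal_overlap(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert reciprocal_overlap(make_call(0, 100), make_call(200, 100)) == 0.0

    def test_half_overlap(self):
        # [0,100) vs [50,150): shared 50 bp, min(50/100, 50/100) = 0.5
        assert reciprocal_overlap(make_call(0, 100), make_call(50, 100)) == 0.5

    def test_different_chrom_or_type_is_zero(self):
        a = make_call(0, 100)
        assert reciprocal_overlap(a, make_call(0, 100, chrom="chr2")) == 0.0
        assert reciprocal_overlap(a, make_call(0, 100, sv_type="DUP")) == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(
        s1=st.integers(0, 1000), l1=st.integers(1, 500),
        s2=st.integers(0, 1000), l2=st.integers(1, 500),
    )
    def test_symmetry_and_range(self, s1, l1, s2, l2):
        a, b = make_call(s1, l1), make_call(s2, l2)
        f = reciprocal_overlap(a, b)
        assert f == reciprocal_overlap(b, a)
        assert 0.0 <= f <= 1.0


class TestPartitionComponents:
    def test_disjoint_singletons(self):
        svs = [make_call(0, 50), make_call(100, 50), make_call(200, 50)]
        groups = partition_components(svs)
        assert [len(g) for g in groups] == [1, 1, 1]

    def test_transitive_chain(self):
        # A intersects B, B intersects C, A and C disjoint -> one group
        a, b, c = make_call(0, 100), make_call(80, 100), make_call(160, 100)
        groups = partition_components([a, b, c])
        assert len(groups) == 1 and set(groups[0]) == {a, b, c}

    def test_touching_intervals_do_not_intersect(self):
        groups = partition_components([make_call(0, 100), make_call(100, 100)])
        assert len(groups) == 2

    def test_matches_quadratic_union_find(self):
        rng = np.random.default_rng(42)
        svs = [
            make_call(int(rng.integers(0, 5000)), int(rng.integers(50, 400)))
            for _ in range(200)
        ]
        groups = partition_components(svs)

        # O(n^2) union-find oracle over all intersecting pairs
        parent = list(range(len(svs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(svs)), 2):
            if min(svs[i].end, svs[j].end) > max(svs[i].start, svs[j].start):
                parent[find(i)] = find(j)
        oracle: dict[int, set] = {}
        for i, sv in enumerate(svs):
            oracle.setdefault(find(i), set()).add(sv)
        assert {frozenset(g) for g in groups} == {
            frozenset(g) for g in oracle.values()
        }

        # groups are disjoint and cover the input
        assert sum(len(g) for g in groups) == len(svs)


def _partition_score(partition, affinity, threshold=0.5):
    """Within-cluster sum of (affinity - threshold); the quantity CAST
    greedily improves."""
    return sum(
        affinity(a, b) - threshold
        for cluster in partition
        for a, b in itertools.combinations(cluster, 2)
    )


def _all_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


class TestCastCluster:
    def test_empty_group(self):
        assert cast_cluster([]) == []

    def test_clique_single_cluster(self):
        svs = [make_call(0, 100), make_call(10, 100), make_call(5, 110)]
        for a, b in itertools.combinations(svs, 2):
            assert reciprocal_overlap(a, b) >= 0.5
        assert len(cast_cluster(svs)) == 1

    def test_outlier_separated(self):
        a, b = make_call(0, 100), make_call(5, 100)  # affinity > 0.9
        c = make_call(95, 300)  # low affinity to both
        clusters = cast_cluster([a, b, c])
        assert sorted(len(c) for c in clusters) == [1, 2]
        assert {a, b} in [set(c) for c in clusters]

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        svs = [
            make_call(int(rng.integers(0, 300)), int(rng.integers(50, 300)))
            for _ in range(8)
        ]
        first = cast_cluster(svs)
        assert first == cast_cluster(list(reversed(svs)))

    def test_near_optimal_on_small_groups(self):
        """On groups of <= 6 random intervals CAST reaches the score of
        the best partition found by exhaustive enumeration in >= 90% of
        seeded trials (it is a heuristic; exact optimality everywhere is
        not guaranteed)."""
        rng = np.random.default_rng(1)
        agree = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(2, 7))
            svs = [
                make_call(int(rng.integers(0, 400)), int(rng.integers(50, 400)))
                for _ in range(n)
            ]
            clusters = cast_cluster(svs)
            cast_score = _partition_score(clusters, reciprocal_overlap)
            best = max(
                _partition_score(p, reciprocal_overlap)
                for p in _all_partitions(svs)
            )
            if cast_score >= best - 1e-9:
                agree += 1
        assert agree / trials >= 0.90

    def test_no_cross_type_merging(self):
        a = make_call(0, 100, sv_type="DEL")
        b = make_call(0, 100, sv_type="DUP")
        clusters = cast_cluster([a, b])
        assert len(clusters) == 2


class TestMergeWithinSample:
    def test_two_caller_consensus_kept_with_sniffles_representative(self):
        sn = make_call(1000, 300, caller="sniffles")
        nv = make_call(1010, 310, caller="nanovar")
        merged = merge_within_sample({"sniffles": [sn], "nanovar": [nv]})
        assert len(merged) == 1
        assert merged[0].representative is sn
        assert merged[0].caller_support == {"sniffles", "nanovar"}

    def test_single_caller_call_dropped(self):
        lone = make_call(1000, 300, caller="nanosv")
        assert merge_within_sample({"nanosv": [lone]}) == []

    def test_representative_priority_order(self):
        nv = make_call(1000, 300, caller="nanovar")
        ns = make_call(1002, 300, caller="nanosv")
        merged = merge_within_sample({"nanovar": [nv], "nanosv": [ns]})
        assert merged[0].representative is nv

    def test_idempotent_on_merged_representatives(self):
        rng = np.random.default_rng(3)
        callsets = {
            caller: [
                make_call(
                    int(base + rng.integers(-20, 20)), 300, caller=caller
                )
                for base in range(0, 30_000, 1000)
            ]
            for caller in ("sniffles", "nanovar", "nanosv")
        }
        merged = merge_within_sample(callsets)
        again = merge_within_sample(
            {"sniffles": [m.representative for m in merged]}, min_callers=1
        )
        assert [m.representative for m in again] == [
            m.representative for m in merged
        ]

    def test_perfect_callers_recover_exact_truth(self, toy_genome):
        from svpop.simulate import (
            NOISE_FREE_PROFILES,
            SimParams,
            simulate_callsets,
            simulate_population,
        )

        params = SimParams(n_samples=3, n_svs=200, seed=5)
        truth = simulate_population(params, toy_genome)
        callsets = simulate_callsets(truth, NOISE_FREE_PROFILES, seed=5)
        sample = truth.samples[0]
        carried = {
            truth.svs[i].key
            for i in np.flatnonzero(truth.genotypes.loc[sample].to_numpy() > 0)
        }
        merged = merge_within_sample(
            {c: callsets[c][sample] for c in callsets}
        )
        assert {m.representative.key for m in merged} == carried
        assert all(m.n_callers == 3 for m in merged)
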