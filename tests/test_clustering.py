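"""Hamming-distance clustering: linkage, maxclust cut, cluster rankings."""

import numpy as np
import pytest

from consrank.clustering import (
    DistanceVector,
    complete_linkage,
    default_t,
    distance_vector,
    flat_clusters_maxclust,
    per_cluster_rankings,
)
from consrank.contacts import ContactMap, hamming_distance, make_contact

from conftest import contact, random_maps
from oracles import brute_force_scores, naive_complete_linkage


class TestDistanceVector:
    def test_length_two_models(self):
        maps = [
            ContactMap("a", frozenset({contact(1, 1)})),
            ContactMap("b", frozenset({contact(2, 2)})),
        ]
        dv = distance_vector(maps)
        assert len(dv.d) == 1 and dv.d[0] == 2

    def test_identical_maps_all_zero(self):
        cs = frozenset({contact(1, 1), contact(2, 2)})
        dv = distance_vector([ContactMap(f"m{i}", cs) for i in range(3)])
        assert list(dv.d) == [0, 0, 0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_calls(self, seed):
        rng = np.random.default_rng(seed)
        maps = random_maps(rng, 6)
        dv = distance_vector(maps)
        k = 0
        for i in range(6):
            for j in range(i + 1, 6):
                assert dv.d[k] == hamming_distance(maps[i], maps[j])
                assert dv.pair(i, j) == dv.d[k]
                k += 1

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            DistanceVector(n=3, d=np.array([1, 2]))


class TestCompleteLinkage:
    def test_two_separated_groups_merge_last(self):
        c = lambda i: contact(i, i)
        g1 = [ContactMap(f"a{i}", frozenset({c(1), c(2), c(10 + i)})) for i in range(3)]
        g2 = [ContactMap(f"b{i}", frozenset({c(30), c(31), c(40 + i)})) for i in range(3)]
        dv = distance_vector(g1 + g2)
        Z = complete_linkage(dv)
        # final merge joins all six models at the largest height
        assert Z[-1, 3] == 6
        assert Z[-1, 2] == max(dv.d)

    def test_equidistant_points_merge_at_common_height(self):
        # three mutually disjoint maps of equal size: all distances equal
        maps = [
            ContactMap(f"m{i}", frozenset({contact(10 * i + 1, 1), contact(10 * i + 2, 2)}))
            for i in range(3)
        ]
        Z = complete_linkage(distance_vector(maps))
        assert set(Z[:, 2]) == {4.0}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_oracle_random_integer_distances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 26))
        d = rng.integers(0, 12, size=n * (n - 1) // 2).astype(np.int64)
        Z = complete_linkage(DistanceVector(n=n, d=d))
        Z_ref = naive_complete_linkage(d, n)
        np.testing.assert_array_equal(Z, Z_ref)


class TestMaxclust:
    def test_t_equal_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        maps = random_maps(rng, 8)
        # force all pairwise distances > 0 by de-duplicating contact sets
        seen = set()
        uniq = []
        for m in maps:
            if m.contacts not in seen:
                seen.add(m.contacts)
                uniq.append(m)
        dv = distance_vector(uniq)
        if (dv.d == 0).any():
            pytest.skip("degenerate random draw")
        Z = complete_linkage(dv)
        cs = flat_clusters_maxclust(Z, len(uniq), [m.model_id for m in uniq])
        assert cs.n_clusters == len(uniq)

    def test_t_one_single_cluster(self):
        rng = np.random.default_rng(2)
        maps = random_maps(rng, 7)
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 1, [m.model_id for m in maps])
        assert cs.n_clusters == 1
        assert cs.populations == (7,)

    def test_planted_two_groups_recovered(self):
        c = lambda i: contact(i, i)
        g1 = [ContactMap(f"a{i}", frozenset({c(1), c(2), c(3), c(10 + i)})) for i in range(5)]
        g2 = [ContactMap(f"b{i}", frozenset({c(30), c(31), c(32), c(40 + i)})) for i in range(3)]
        maps = g1 + g2
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 4, [m.model_id for m in maps])
        groups = {frozenset(c) for c in cs.clusters}
        assert frozenset(f"a{i}" for i in range(5)) in groups
        assert frozenset(f"b{i}" for i in range(3)) in groups
        # most populated first, numbered from 0
        assert cs.labels["a0"] == 0 and cs.labels["b0"] == 1
        assert cs.populations == tuple(sorted(cs.populations, reverse=True))

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        maps = random_maps(rng, 20)
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, default_t(20), [m.model_id for m in maps])
        assert sum(cs.populations) == 20
        assert set(cs.labels) == {m.model_id for m in maps}
        for ci, members in enumerate(cs.clusters):
            assert all(cs.labels[m] == ci for m in members)

    def test_permutation_invariance_with_distinct_heights(self):
        # merge ties are broken by input position, so exact invariance is
        # guaranteed (and tested) for tie-free distance sets
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        n = 12
        d = rng.choice(np.arange(1, 500), size=n * (n - 1) // 2, replace=False)
        ids = [f"m{i:03d}" for i in range(n)]
        cs1 = flat_clusters_maxclust(
            complete_linkage(DistanceVector(n=n, d=d.astype(np.int64))), 3, ids
        )
        perm = rng.permutation(n)
        D = squareform(d)
        d2 = squareform(D[np.ix_(perm, perm)], checks=False)
        ids2 = [ids[i] for i in perm]
        cs2 = flat_clusters_maxclust(
            complete_linkage(DistanceVector(n=n, d=d2.astype(np.int64))), 3, ids2
        )
        assert {frozenset(c) for c in cs1.clusters} == {frozenset(c) for c in cs2.clusters}


class TestDefaultT:
    @pytest.mark.parametrize("n,expected", [(40, 4), (1916, 191), (9, 1), (100, 10)])
    def test_floor_rule(self, n, expected):
        assert default_t(n) == expected

    def test_rejects_tiny_ensembles(self):
        with pytest.raises(ValueError):
            default_t(1)


class TestPerClusterRankings:
    def test_identical_cluster_scores_one(self):
        cs_contacts = frozenset({contact(1, 1), contact(2, 2)})
        maps = [ContactMap(f"m{i}", cs_contacts) for i in range(4)]
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 1, [m.model_id for m in maps])
        rankings = per_cluster_rankings(cs, maps)
        assert all(e.S_norm == 1.0 for e in rankings[0].entries)

    def test_only_top_clusters_ranked(self):
        c = lambda i: contact(i, i)
        groups = [
            [ContactMap(f"g{g}m{i}", frozenset({c(100 * g + 1), c(100 * g + 2), c(100 * g + 10 + i)}))
             for i in range(size)]
            for g, size in enumerate((4, 3, 2))
        ]
        maps = [m for g in groups for m in g]
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 3, [m.model_id for m in maps])
        rankings = per_cluster_rankings(cs, maps, top_clusters=2)
        assert sorted(rankings) == [0, 1]

    def test_singleton_cluster_degenerate_ranking(self):
        maps = [
            ContactMap("a", frozenset({contact(1, 1), contact(2, 2)})),
            ContactMap("b", frozenset({contact(1, 1), contact(2, 2)})),
            ContactMap("lone", frozenset({contact(50, 50)})),
        ]
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 2, [m.model_id for m in maps])
        rankings = per_cluster_rankings(cs, maps)
        lone_cluster = cs.labels["lone"]
        entry = rankings[lone_cluster].entries[0]
        assert entry.S_norm == 1.0 and entry.rank == 1

    def test_within_cluster_order_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        maps = random_maps(rng, 18)
        Z = complete_linkage(distance_vector(maps))
        cs = flat_clusters_maxclust(Z, 3, [m.model_id for m in maps])
        rankings = per_cluster_rankings(cs, maps)
        by_id = {m.model_id: m for m in maps}
        for ci, ranking in rankings.items():
            members = [by_id[mid] for mid in cs.clusters[ci]]
            if len(members) < 2:
                continue
            expected = brute_force_scores(members)
            for e in ranking.entries:
                assert e.S_norm == pytest.approx(expected[e.model_id][1], abs=1e-12)
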