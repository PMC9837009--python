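"""Levenshtein distance, DBSCAN, single linkage, and centroid selection."""

import functools
import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoscreen.clusterlib import (
    NOISE,
    ClusterParams,
    ClusterResult,
    DistanceMatrix,
    centroid,
    dbscan,
    levenshtein,
    pairwise_distances,
    read_distance_matrix,
    single_linkage,
    write_distance_matrix,
)
from exoscreen.errors import CoordinateError, MetricViolationError

dots = st.text(alphabet="().", min_size=0, max_size=12)


@functools.lru_cache(maxsize=None)
def lev_recursive(a: str, b: str) -> int:
    """Brute-force recursive edit-distance oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
        lev_recursive(a[1:], b) + 1,
        lev_recursive(a, b[1:]) + 1,
    )


def random_matrix(rng, n, scale=10.0):
    m = rng.random((n, n)) * scale
    m = np.triu(m, k=1)
    m = m + m.T
    return DistanceMatrix(tuple(f"i{k}" for k in range(n)), m)


def components_below(D: DistanceMatrix, t: float) -> list[set[str]]:
    """Oracle: connected components of the graph with edges strictly < t."""
    parent = {lab: lab for lab in D.labels}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(D.n), 2):
        if D.values[i, j] < t:
            parent[find(D.labels[i])] = find(D.labels[j])
    groups = {}
    for lab in D.labels:
        groups.setdefault(find(lab), set()).add(lab)
    return list(groups.values())


def partition_sets(result: ClusterResult) -> set[frozenset]:
    return {frozenset(m) for m in result.members.values()}


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("GGAG", "GCAG", 1),
            ("", "", 0),
            ("abc", "", 3),
            ("...................", "..(((.........))).."
             , 6),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(s=dots)
    @settings(max_examples=50, derandomize=True)
    def test_identity(self, s):
        assert levenshtein(s, s) == 0

    @given(a=dots, b=dots)
    @settings(max_examples=150, derandomize=True)
    def test_matches_recursive_oracle_and_symmetry(self, a, b):
        d = levenshtein(a, b)
        assert d == lev_recursive(a, b)
        assert d == levenshtein(b, a)

    @given(a=dots, b=dots, c=dots)
    @settings(max_examples=150, derandomize=True)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) >= 0
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestPairwiseDistances:
    def test_identical_strings_zero_matrix(self):
        D = pairwise_distances({"a": "((.))", "b": "((.))", "c": "((.))"})
        assert np.all(D.values == 0)

    def test_single_item(self):
        D = pairwise_distances({"only": "..."})
        assert D.values.shape == (1, 1) and D.values[0, 0] == 0

    def test_study_configuration_has_two_distance_scales(self):
        from exoscreen import synthdata

        structures = synthdata.make_dotbracket_set(synthdata.DotBracketSpec(), seed=0)
        D = pairwise_distances({s.sequence_id: s.dot_bracket for s in structures})
        # recompute each cell independently with the recursive oracle
        for i, j in itertools.combinations(range(D.n), 2):
            a = structures[i].dot_bracket
            b = structures[j].dot_bracket
            assert D.values[i, j] == lev_recursive(a, b)
        off = sorted({D.values[i, j] for i, j in itertools.combinations(range(D.n), 2)})
        # 11 identical unfolded records, 2 mutually-close hairpins, far apart
        hairpin = {"6", "7"}
        within_unfolded = [
            D.get(a, b)
            for a, b in itertools.combinations([l for l in D.labels if l not in hairpin], 2)
        ]
        assert set(within_unfolded) == {0.0}
        assert D.get("6", "7") < min(D.get("6", "0"), D.get("7", "0"))

    def test_negative_metric_rejected(self):
        with pytest.raises(MetricViolationError):
            pairwise_distances({"a": "x", "b": "y"}, metric=lambda a, b: -1)

    def test_matrix_io_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        D = random_matrix(rng, 5)
        path = tmp_path / "d.tsv"
        write_distance_matrix(D, path)
        back = read_distance_matrix(path)
        assert back.labels == D.labels
        assert np.allclose(back.values, D.values)


class TestDbscan:
    def test_two_tight_groups(self):
        labels = ("a", "b", "c", "d", "e")
        v = np.full((5, 5), 10.0)
        for grp in [(0, 1, 2), (3, 4)]:
            for i in grp:
                for j in grp:
                    v[i, j] = 0.0
        D = DistanceMatrix(labels, v)
        result = dbscan(D, ClusterParams(eps=1, min_samples=2))
        assert partition_sets(result) == {
            frozenset("abc"), frozenset("de")
        }
        assert result.n_clusters == 2 and not result.noise

    def test_eps_above_maximum_gives_one_cluster(self):
        rng = np.random.default_rng(2)
        D = random_matrix(rng, 6)
        result = dbscan(D, ClusterParams(eps=D.values.max() + 1, min_samples=2))
        assert result.n_clusters == 1

    def test_study_configuration_recovers_published_partition(self):
        from exoscreen import synthdata

        structures = synthdata.make_dotbracket_set(synthdata.DotBracketSpec(), seed=5)
        D = pairwise_distances({s.sequence_id: s.dot_bracket for s in structures})
        result = dbscan(D, ClusterParams(eps=4.0, min_samples=2))
        assert result.n_clusters == 2
        assert frozenset(("6", "7")) in partition_sets(result)

    def test_isolated_point_is_noise_and_convertible_to_singleton(self):
        v = np.array([[0.0, 0.0, 9.0], [0.0, 0.0, 9.0], [9.0, 9.0, 0.0]])
        D = DistanceMatrix(("a", "b", "far"), v)
        result = dbscan(D, ClusterParams(eps=1, min_samples=2))
        assert result.noise == ("far",)
        assert result.assignments["far"] == NOISE
        as_singletons = result.noise_as_singletons()
        assert as_singletons.n_clusters == 2
        assert as_singletons.assignments["far"] == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        base = random_matrix(rng, 8, scale=4.0)
        perm = rng.permutation(8)
        permuted = DistanceMatrix(
            tuple(base.labels[i] for i in perm), base.values[np.ix_(perm, perm)]
        )
        p = ClusterParams(eps=2.0, min_samples=2)
        assert partition_sets(dbscan(base, p)) | {frozenset({x}) for x in dbscan(base, p).noise} == \
            partition_sets(dbscan(permuted, p)) | {frozenset({x}) for x in dbscan(permuted, p).noise}


class TestSingleLinkage:
    def test_two_separated_groups_largest_gap(self):
        labels = tuple("abcde")
        v = np.full((5, 5), 2.0)
        np.fill_diagonal(v, 0.0)
        for grp in [(0, 1, 2), (3, 4)]:
            for i in grp:
                for j in grp:
                    if i != j:
                        v[i, j] = 0.3
        D = DistanceMatrix(labels, v)
        result = single_linkage(D, ClusterParams(cut="largest-gap"))
        assert partition_sets(result) == {frozenset("abc"), frozenset("de")}

    def test_all_equal_distances_one_cluster(self):
        v = np.full((4, 4), 1.5)
        np.fill_diagonal(v, 0.0)
        result = single_linkage(
            DistanceMatrix(tuple("abcd"), v), ClusterParams(cut="largest-gap")
        )
        assert result.n_clusters == 1

    def test_threshold_cut_equals_connected_components(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            D = random_matrix(rng, n)
            t = float(rng.random() * 10)
            result = single_linkage(D, ClusterParams(cut=t))
            assert partition_sets(result) == {
                frozenset(c) for c in components_below(D, t)
            }

    def test_order_invariance(self):
        rng = np.random.default_rng(19)
        base = random_matrix(rng, 9)
        perm = rng.permutation(9)
        permuted = DistanceMatrix(
            tuple(base.labels[i] for i in perm), base.values[np.ix_(perm, perm)]
        )
        p = ClusterParams(cut="largest-gap")
        assert partition_sets(single_linkage(base, p)) == partition_sets(
            single_linkage(permuted, p)
        )

    def test_agrees_with_dbscan_min_samples_one(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            D = random_matrix(rng, 7)
            t = float(rng.random() * 10 + 0.1)
            a = single_linkage(D, ClusterParams(cut=t))
            b = dbscan(D, ClusterParams(eps=t, min_samples=1))
            assert partition_sets(a) == partition_sets(b)

    def test_singleton_matrix(self):
        D = DistanceMatrix(("x",), np.zeros((1, 1)))
        result = single_linkage(D, ClusterParams(cut="largest-gap"))
        assert result.members == {1: ("x",)}


class TestCentroid:
    def test_two_members_reports_pairwise_distance(self):
        v = np.array([[0.0, 2.3], [2.3, 0.0]])
        D = DistanceMatrix(("m1", "m2"), v)
        assert centroid(D, ["m1", "m2"]) == ("m1", 2.3, 0.0)

    def test_singleton(self):
        D = DistanceMatrix(("x",), np.zeros((1, 1)))
        assert centroid(D, ["x"]) == ("x", 0.0, 0.0)

    def test_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(37)
        for _ in range(20):
            D = random_matrix(rng, 6)
            c, avg, sd = centroid(D, D.labels)
            means = {
                lab: np.mean([D.get(lab, o) for o in D.labels if o != lab])
                for lab in D.labels
            }
            assert means[c] == pytest.approx(min(means.values()))
            others = [D.get(c, o) for o in D.labels if o != c]
            assert avg == pytest.approx(np.mean(others))
            assert sd == pytest.approx(np.std(others))

    def test_unknown_member_raises(self):
        D = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(CoordinateError):
            centroid(D, ["a", "zz"])


class TestDistanceMatrixInvariants:
    def test_asymmetry_rejected(self):
        v = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(MetricViolationError):
            DistanceMatrix(("a", "b"), v)

    def test_nonzero_diagonal_rejected(self):
        v = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(MetricViolationError):
            DistanceMatrix(("a", "b"), v)
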