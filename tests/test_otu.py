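"""Single-linkage clustering, barcode-gap detection and recursive partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekit.distance import DistanceMatrix, distance_matrix
from barcodekit.otu import (
    Partition,
    abgd_partition,
    find_gap,
    partition_agreement,
    single_linkage_clusters,
)
from barcodekit.simulate import SimConfig, make_scenario


def dm_from_pairs(ids, pairs):
    n = len(ids)
    vals = np.zeros((n, n))
    idx = {x: i for i, x in enumerate(ids)}
    for (a, b), d in pairs.items():
        vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = d
    return DistanceMatrix(ids=list(ids), values=vals)


def brute_force_components(dm, threshold):
    """Union-find oracle for connected components at d <= threshold."""
    n = len(dm.ids)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = dm.values[i, j]
            if not np.isnan(d) and d <= threshold:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(dm.ids[i])
    return {frozenset(g) for g in groups.values()}


class TestSingleLinkage:
    def test_threshold_above_max_is_one_otu(self):
        dm = dm_from_pairs("abc", {("a", "b"): 0.01, ("a", "c"): 0.1, ("b", "c"): 0.11})
        assert single_linkage_clusters(dm, 0.2).n_otus == 1

    def test_example_split(self):
        dm = dm_from_pairs("ABC", {("A", "B"): 0.01, ("A", "C"): 0.10, ("B", "C"): 0.11})
        part = single_linkage_clusters(dm, 0.05)
        groups = {frozenset(g) for g in part.groups().values()}
        assert groups == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_zero_threshold_all_singletons(self):
        dm = dm_from_pairs("abcd", {(a, b): 0.02 for a, b in [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]})
        assert single_linkage_clusters(dm, 0.0).n_otus == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        base = rng.uniform(0, 0.2, size=(n, n))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix(ids=[f"t{i:02d}" for i in range(n)], values=vals)
        threshold = float(rng.uniform(0, 0.2))
        part = single_linkage_clusters(dm, threshold)
        got = {frozenset(g) for g in part.groups().values()}
        assert got == brute_force_components(dm, threshold)

    def test_missing_distances_never_link(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        dm = DistanceMatrix(ids=["a", "b"], values=vals)
        assert single_linkage_clusters(dm, 1.0).n_otus == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        n = 20
        base = rng.uniform(0, 0.2, size=(n, n))
        vals = (base + base.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix(ids=[f"t{i}" for i in range(n)], values=vals)
        counts = [
            single_linkage_clusters(dm, t).n_otus for t in np.linspace(0, 0.25, 26)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFindGap:
    def test_straddling_prior_example(self):
        # gap 0.002 -> 0.050 straddles P=0.005; width 0.048 > 1.0 * 0.005
        t = find_gap(np.array([0.001, 0.002, 0.050, 0.051]), 0.005, 1.0)
        assert t == pytest.approx(0.026)

    def test_uniform_spacing_no_gap(self):
        assert find_gap(np.linspace(0.01, 0.1, 10), 0.005, 1.0) is None

    def test_identical_distances_no_gap(self):
        assert find_gap(np.full(6, 0.03), 0.001, 1.0) is None

    def test_threshold_strictly_between_observed_distances(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = np.sort(rng.uniform(0, 0.3, size=15))
            t = find_gap(d, 0.01, 0.8)
            if t is not None:
                assert not np.any(np.isclose(d, t))
                assert d.min() < t < d.max()

    def test_gap_below_prior_ignored(self):
        # jump 0.001->0.010 sits entirely below P=0.02, so it is not a gap
        d = np.array([0.0005, 0.001, 0.010, 0.012, 0.014, 0.016, 0.018])
        assert find_gap(d, 0.02, 1.0) is None


class TestAbgd:
    def test_clean_gap_recovers_truth_across_priors(self):
        res = make_scenario("clean_gap", SimConfig(seed=6))
        dm = distance_matrix(res.dataset)
        scan = abgd_partition(dm)
        cfg = res.config
        in_range = [
            p
            for p, part in zip(scan.priors, scan.partitions)
            if cfg.intra_theta <= p <= cfg.inter_depth / 2
        ]
        assert in_range, "prior grid must cover the tested range"
        for p, part in zip(scan.priors, scan.partitions):
            if cfg.intra_theta <= p <= cfg.inter_depth / 2:
                identical, ari = partition_agreement(part, res.truth_partition)
                assert identical and ari == 1.0

    def test_all_identical_sequences_single_otu(self):
        from conftest import make_dataset

        ds = make_dataset([(f"s{i}", "ACGT" * 20, "sp") for i in range(4)])
        dm = distance_matrix(ds)
        scan = abgd_partition(dm)
        assert all(k == 1 for k in scan.group_counts())

    def test_nested_gaps_need_recursion(self):
        """Two-level structure: recursion must find the finer partition.

        Groups A and B sit 2% apart, but at the top level that gap is
        filled by group C's internal distance ladder (0.5% steps up to
        2%); only the A+B vs C gap (~2% -> ~11%) is detectable globally.
        Splitting A from B requires recursing into the A+B component.
        """
        from conftest import make_dataset

        s_ab_base = "A" * 200
        s_b = "G" * 4 + "A" * 196  # 2% from A
        def c_seq(k):  # ~10-12% from A/B, ladder of 0.5% steps within C
            return "A" * 100 + "G" * 20 + "A" * 20 + "G" * k + "A" * (60 - k)

        ds = make_dataset(
            [("a1", s_ab_base, "sp"), ("a2", s_ab_base, "sp"),
             ("b1", s_b, "sp"), ("b2", s_b, "sp")]
            + [(f"c{k}", c_seq(k), "sp") for k in range(5)]
        )
        dm = distance_matrix(ds)
        scan = abgd_partition(dm, pmin=0.006, pmax=0.0061, steps=1, x=1.0)
        part = scan.partitions[0]
        groups = {frozenset(g) for g in part.groups().values()}
        assert groups == {
            frozenset({"a1", "a2"}),
            frozenset({"b1", "b2"}),
            frozenset({f"c{k}" for k in range(5)}),
        }
        # one-shot single linkage at the top-level threshold cannot do this
        top = single_linkage_clusters(dm, scan.thresholds[0])
        assert top.n_otus < part.n_otus

    def test_partition_invariant_to_specimen_order(self):
        res = make_scenario("clean_gap", SimConfig(n_species=4, seed=8))
        dm = distance_matrix(res.dataset)
        perm = np.random.default_rng(0).permutation(len(dm.ids))
        dm2 = DistanceMatrix(
            ids=[dm.ids[k] for k in perm], values=dm.values[np.ix_(perm, perm)]
        )
        s1 = abgd_partition(dm, steps=5)
        s2 = abgd_partition(dm2, steps=5)
        for p1, p2 in zip(s1.partitions, s2.partitions):
            assert p1.relabeled().assignment == p2.relabeled().assignment

    def test_histogram_and_stability(self):
        res = make_scenario("clean_gap", SimConfig(n_species=4, seed=9))
        dm = distance_matrix(res.dataset)
        scan = abgd_partition(dm, nbins=10)
        assert len(scan.histogram) == 10
        assert scan.histogram["count"].sum() == len(dm.condensed())
        covered = sum(1 for lo, hi, k in scan.stability_ranges)
        assert covered >= 1


class TestPartitionAgreement:
    def test_relabeling_is_identical(self):
        p1 = Partition({"a": "x", "b": "x", "c": "y"})
        p2 = Partition({"a": "OTU_9", "b": "OTU_9", "c": "OTU_1"})
        identical, ari = partition_agreement(p1, p2)
        assert identical and ari == 1.0

    def test_singletons_vs_one_group_ari_nonpositive(self):
        # direct ARI formula on the 4x1 contingency table: index 0,
        # expected 0, max 3 -> ARI = 0
        p1 = Partition({x: x for x in "abcd"})
        p2 = Partition({x: "g" for x in "abcd"})
        identical, ari = partition_agreement(p1, p2)
        assert not identical and ari <= 0.0

    def test_splitting_a_group_lowers_ari(self):
        p1 = Partition({"a": "1", "b": "1", "c": "2", "d": "2"})
        p2 = Partition({"a": "1", "b": "3", "c": "2", "d": "2"})
        identical, ari = partition_agreement(p1, p2)
        assert not identical and ari < 1.0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_agreement(Partition({"a": "1"}), Partition({"b": "1"}))

    def test_tsv_roundtrip(self, tmp_path):
        p = Partition({"a": "OTU_1", "b": "OTU_2"})
        p.write_tsv(tmp_path / "p.tsv")
        back = Partition.read_tsv(tmp_path / "p.tsv")
        assert back.assignment == p.assignment
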