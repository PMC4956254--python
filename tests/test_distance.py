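"""K2P distances, the distance matrix, and rank-wise divergence summaries."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodekit.distance import (
    DistanceMatrix,
    SaturatedPairError,
    SiteComparison,
    count_differences,
    distance_matrix,
    genus_pair_ranges,
    k2p_distance,
    summarize_by_rank,
)

from conftest import make_dataset


class TestCountDifferences:
    def test_one_transition(self):
        c = count_differences("ACGT", "GCGT")
        assert (c.P, c.Q, c.L) == (0.25, 0.0, 4)

    def test_one_transversion(self):
        c = count_differences("ACGT", "ACGA")
        assert (c.P, c.Q, c.L) == (0.0, 0.25, 4)

    def test_pairwise_deletion_of_n_and_gap(self):
        c = count_differences("ACGT", "ANG-")
        assert (c.P, c.Q, c.L) == (0.0, 0.0, 2)

    def test_no_comparable_sites_returns_none(self):
        assert count_differences("NN--", "ACGT") is None

    def test_all_six_transversion_pairs(self):
        # A-C, A-T, G-C, G-T are transversions; A-G, C-T transitions
        c = count_differences("AAGGCT", "CTCTTC")
        assert c.Q == pytest.approx(4 / 6)
        assert c.P == pytest.approx(2 / 6)


class TestK2P:
    def test_identity_is_zero(self):
        assert k2p_distance(SiteComparison(0.0, 0.0, 100)) == 0.0

    def test_closed_form_value(self):
        # -0.5 ln(0.75) - 0.25 ln(0.90) = 0.1701813...
        d = k2p_distance(SiteComparison(P=0.1, Q=0.05, L=100))
        assert d == pytest.approx(0.1701813, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturatedPairError):
            k2p_distance(SiteComparison(P=0.5, Q=0.25, L=4))

    @given(
        st.floats(0.0, 0.4),
        st.floats(0.0, 0.4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_correction_never_below_p_distance(self, p, q):
        if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
            return
        assert k2p_distance(SiteComparison(p, q, 100)) >= p + q - 1e-12

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.0, 0.2, 21)
        d_p = [k2p_distance(SiteComparison(p, 0.05, 100)) for p in grid]
        d_q = [k2p_distance(SiteComparison(0.05, q, 100)) for q in grid]
        assert np.all(np.diff(d_p) > 0) and np.all(np.diff(d_q) > 0)


class TestDistanceMatrix:
    def test_identical_sequences_distance_zero(self):
        ds = make_dataset([("a", "ACGT" * 5, "sp"), ("b", "ACGT" * 5, "sp")])
        dm = distance_matrix(ds)
        assert dm.get("a", "b") == 0.0

    def test_matches_per_pair_recomputation(self):
        ds = make_dataset(
            [("a", "ACGTACGTAC", "s1"), ("b", "ACGAACGTAC", "s2"), ("c", "GCGTACTTAC", "s3")]
        )
        dm = distance_matrix(ds)
        for x, sx in [("a", 0), ("b", 1), ("c", 2)]:
            for y, sy in [("a", 0), ("b", 1), ("c", 2)]:
                if x >= y:
                    continue
                expected = k2p_distance(
                    count_differences(ds.records[sx].sequence, ds.records[sy].sequence)
                )
                assert dm.get(x, y) == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self):
        ds = make_dataset([("a", "ACGTAA", "s1"), ("b", "ACTTAA", "s2"), ("c", "GGTTAA", "s3")])
        dm = distance_matrix(ds)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_invariant_to_record_order(self):
        recs = [("a", "ACGTAA", "s1"), ("b", "ACTTAA", "s2"), ("c", "GGTTAA", "s3")]
        dm1 = distance_matrix(make_dataset(recs))
        dm2 = distance_matrix(make_dataset(recs[::-1]))
        for x in "abc":
            for y in "abc":
                assert dm1.get(x, y) == dm2.get(x, y)

    def test_saturated_pair_recorded_not_dropped(self):
        # maximally divergent: every site a transversion
        ds = make_dataset([("a", "AAAAAAAA", "s1"), ("b", "CCCCCCCC", "s2"), ("c", "AAAAAAAC", "s1")])
        dm = distance_matrix(ds)
        assert ("a", "b") in dm.undefined_pairs
        assert math.isnan(dm.get("a", "b"))
        assert not math.isnan(dm.get("a", "c"))

    def test_complete_deletion_drops_column_globally(self):
        ds = make_dataset([("a", "ACGT", "s1"), ("b", "ACGA", "s2"), ("c", "NCGT", "s3")])
        pairwise = distance_matrix(ds, deletion="pairwise")
        complete = distance_matrix(ds, deletion="complete")
        # under complete deletion column 1 disappears for every pair,
        # so a-b's single mismatch is now 1 of 3 sites, not 1 of 4
        assert complete.get("a", "b") > pairwise.get("a", "b")

    def test_tsv_roundtrip(self, tmp_path):
        ds = make_dataset([("a", "ACGTAA", "s1"), ("b", "ACTTAA", "s2")])
        dm = distance_matrix(ds)
        dm.write_tsv(tmp_path / "dm.tsv")
        back = DistanceMatrix.read_tsv(tmp_path / "dm.tsv")
        assert back.ids == dm.ids and back.model == "K2P"
        assert np.allclose(back.values, dm.values)


def test_k2p_matrix_matches_r_ape_oracle(tmp_path):
    """Independent oracle: ape's dist.dna(model='K80', pairwise.deletion=TRUE)."""
    from barcodekit.io import write_fasta
    from barcodekit.simulate import SimConfig, make_scenario

    res = make_scenario("none", SimConfig(n_species=4, n_per_species=2, seed=11))
    # corrupt a few sites to exercise pairwise deletion
    import dataclasses

    recs = res.dataset.records
    recs[0] = dataclasses.replace(
        recs[0], sequence="N" * 5 + recs[0].sequence[5:-5] + "-" * 5
    )
    write_fasta(res.dataset, tmp_path / "seqs.fasta")
    dm = distance_matrix(res.dataset)
    script = textwrap.dedent(
        f"""
        suppressMessages(library(ape))
        s <- read.dna('{tmp_path / "seqs.fasta"}', format='fasta')
        m <- as.matrix(dist.dna(s, model='K80', pairwise.deletion=TRUE))
        write.csv(m, '{tmp_path / "ape.csv"}')
        """
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ape = pd.read_csv(tmp_path / "ape.csv", index_col=0)
    mine = dm.to_frame().loc[ape.index, ape.columns]
    assert np.nanmax(np.abs(ape.to_numpy() - mine.to_numpy())) < 1e-10


TOY = [
    # two congeneric species plus one other genus, same family
    ("a1", "A" * 60, "sp_a", "gen_1", "fam_1"),
    ("a2", "G" + "A" * 59, "sp_a", "gen_1", "fam_1"),
    ("b1", "A" * 10 + "GGGG" + "A" * 46, "sp_b", "gen_1", "fam_1"),
    ("c1", "A" * 30 + "G" * 8 + "A" * 22, "sp_c", "gen_2", "fam_1"),
]


class TestSummaries:
    def test_conspecific_pair_summary(self):
        ds = make_dataset(TOY)
        dm = distance_matrix(ds)
        s = summarize_by_rank(dm, ds.taxonomy_frame(), "species")
        assert s.n_comparisons == 1
        expected = 100 * dm.get("a1", "a2")
        assert s.min == s.mean == s.max == pytest.approx(expected)

    def test_genus_excludes_conspecific_pairs(self):
        ds = make_dataset(TOY)
        dm = distance_matrix(ds)
        s = summarize_by_rank(dm, ds.taxonomy_frame(), "genus")
        assert s.n_comparisons == 2  # a1-b1, a2-b1 only

    def test_family_excludes_congeneric_pairs(self):
        ds = make_dataset(TOY)
        dm = distance_matrix(ds)
        s = summarize_by_rank(dm, ds.taxonomy_frame(), "family")
        assert s.n_comparisons == 3  # c1 against a1, a2, b1

    def test_identical_dataset_species_mean_zero(self):
        ds = make_dataset([("x1", "ACGT" * 3, "sp"), ("x2", "ACGT" * 3, "sp")])
        dm = distance_matrix(ds)
        assert summarize_by_rank(dm, ds.taxonomy_frame(), "species").mean == 0.0

    def test_missing_rank_comparisons_raise(self):
        ds = make_dataset([("a1", "ACGT", "sp_a", "g1"), ("b1", "ACGA", "sp_b", "g2")])
        dm = distance_matrix(ds)
        with pytest.raises(ValueError, match="species"):
            summarize_by_rank(dm, ds.taxonomy_frame(), "species")


class TestGenusRanges:
    def test_two_singleton_species(self):
        ds = make_dataset(
            [("a1", "A" * 20, "sp_a", "gen_1"), ("b1", "A" * 19 + "G", "sp_b", "gen_1")]
        )
        dm = distance_matrix(ds)
        out = genus_pair_ranges(dm, ds.taxonomy_frame())
        assert len(out) == 1
        assert out.loc[0, "min"] == out.loc[0, "max"] == pytest.approx(100 * dm.get("a1", "b1"))

    def test_single_species_genus_excluded(self):
        ds = make_dataset(TOY)
        out = genus_pair_ranges(distance_matrix(ds), ds.taxonomy_frame())
        assert list(out["genus"]) == ["gen_1"]
        assert (out["n_species"] == 2).all()

    def test_empty_when_no_multispecies_genus(self):
        ds = make_dataset([("a1", "ACGT", "sp_a", "g1"), ("b1", "ACGA", "sp_b", "g2")])
        out = genus_pair_ranges(distance_matrix(ds), ds.taxonomy_frame())
        assert out.empty
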