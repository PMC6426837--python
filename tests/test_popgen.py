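"""Allele profiles, heterozygosity, fixed differences and distances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracle
from conftest import make_dataset, random_dataset
from hemiclone.popgen import (
    allele_profile,
    euclidean_distance,
    fixed_difference_count,
    nei_distance,
    observed_heterozygosity,
    summary_table,
)


class TestAlleleProfile:
    def test_single_heterozygote(self):
        ds = make_dataset([["0/1"]], taxa=["T"])
        p = allele_profile(ds, "T")
        assert p.allele_set(0) == {0, 1}
        np.testing.assert_allclose(p.freqs[0], [0.5, 0.5])

    def test_three_genotype_counts(self):
        ds = make_dataset(
            [["0/0"], ["0/1"], ["1/1"]], taxa=["T", "T", "T"]
        )
        p = allele_profile(ds, "T")
        np.testing.assert_allclose(p.freqs[0], [0.5, 0.5])
        assert p.n_nonmissing[0] == 3

    def test_frequency_estimate_within_three_se(self):
        rng = np.random.default_rng(42)
        n, ptrue = 200, 0.3
        calls = (rng.random((n, 1, 2)) < ptrue).astype(np.int16)
        # allele 1 has frequency ptrue; profile reports both
        genos = [
            ["{}/{}".format(*sorted(calls[i, 0]))] for i in range(n)
        ]
        ds = make_dataset(genos, taxa=["T"] * n)
        p = allele_profile(ds, "T")
        se = math.sqrt(ptrue * (1 - ptrue) / (2 * n))
        assert abs(p.freqs[0, 1] - ptrue) < 3 * se

    def test_all_missing_locus_flagged(self):
        ds = make_dataset([["-", "0/1"]], taxa=["T"])
        p = allele_profile(ds, "T")
        assert not p.has_data[0] and p.has_data[1]


class TestObservedHeterozygosity:
    def test_all_homozygous_is_zero(self):
        ds = make_dataset([["0/0", "1/1"], ["0/0", "1/1"]], taxa=["T", "T"])
        assert observed_heterozygosity(ds, "T").H_O == 0.0

    def test_half_heterozygous_loci(self):
        ds = make_dataset([["0/1", "0/1", "0/0", "1/1"]], taxa=["T"])
        assert observed_heterozygosity(ds, "T").H_O == pytest.approx(0.5)

    def test_all_missing_flagged_not_zero(self):
        ds = make_dataset([["-", "-"]], taxa=["T"])
        r = observed_heterozygosity(ds, "T")
        assert not r.defined

    def test_f1_hybridogen_het_matches_construction(self):
        # parents fixed-different at d of L loci, monomorphic-shared at rest:
        # F1 heterozygosity must be exactly d / L
        d, L = 12, 40
        a_row = ["0/0"] * L
        b_row = ["1/1"] * d + ["0/0"] * (L - d)
        f1_row = ["0/1"] * d + ["0/0"] * (L - d)
        ds = make_dataset(
            [a_row, b_row, f1_row], taxa=["A", "B", "F1"]
        )
        assert observed_heterozygosity(ds, "F1").H_O == pytest.approx(d / L)

    def test_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(8)
        ds = random_dataset(rng, 10, 30, taxa=["T1", "T2"])
        for t in ("T1", "T2"):
            assert observed_heterozygosity(ds, t).H_O == pytest.approx(
                oracle.observed_het(ds, t)
            )


class TestFixedDifferences:
    def test_identical_taxa_zero(self):
        ds = make_dataset(
            [["0/0", "0/1"], ["0/0", "0/1"]], taxa=["A", "B"]
        )
        assert fixed_difference_count(ds, "A", "B").fixed_diff_count == 0

    def test_forced_two_of_three(self):
        ds = make_dataset(
            [
                ["0/0", "0/0", "0/1"],
                ["0/0", "0/0", "0/0"],
                ["1/1", "1/1", "0/1"],
                ["1/1", "1/1", "1/1"],
            ],
            taxa=["A", "A", "B", "B"],
        )
        s = fixed_difference_count(ds, "A", "B")
        assert s.fixed_diff_count == 2
        assert s.fixed_diff_locus_ids == ["loc0", "loc1"]
        assert s.n_loci_compared == 3

    @pytest.mark.parametrize("tloc", [0.0, 0.05])
    def test_matches_brute_force_oracle(self, tloc):
        rng = np.random.default_rng(99)
        for _ in range(40):
            ds = random_dataset(
                rng, 6, 30, missing_rate=0.15, taxa=["A", "B"]
            )
            s = fixed_difference_count(ds, "A", "B", tloc=tloc)
            count, compared = oracle.fixed_diff(ds, "A", "B", tloc=tloc)
            assert s.fixed_diff_count == count
            assert s.n_loci_compared == compared

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        ds = random_dataset(rng, 8, 25, missing_rate=0.1, taxa=["A", "B"])
        ab = fixed_difference_count(ds, "A", "B", tloc=0.05)
        ba = fixed_difference_count(ds, "B", "A", tloc=0.05)
        assert ab.fixed_diff_count == ba.fixed_diff_count
        assert ab.n_loci_compared == ba.n_loci_compared

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_nondecreasing_in_tloc(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, 8, 20, missing_rate=0.1, taxa=["A", "B"])
        counts = [
            fixed_difference_count(ds, "A", "B", tloc=t).fixed_diff_count
            for t in (0.0, 0.05, 0.2, 0.4)
        ]
        assert counts == sorted(counts)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(12)
        ds = random_dataset(rng, 8, 25, missing_rate=0.1, taxa=["A", "B"])
        base = fixed_difference_count(ds, "A", "B").fixed_diff_count
        # swap allele codes at every locus (0 <-> 1)
        flipped = type(ds)(
            ds.individuals,
            ds.loci,
            np.where(ds.calls == -1, -1, 1 - ds.calls),
            ds.taxon_map,
        )
        assert (
            fixed_difference_count(flipped, "A", "B").fixed_diff_count == base
        )
        # shuffle individual order
        perm = rng.permutation(ds.n_individuals)
        shuffled = type(ds)(
            [ds.individuals[i] for i in perm],
            ds.loci,
            ds.calls[perm],
            ds.taxon_map,
        )
        assert (
            fixed_difference_count(shuffled, "A", "B").fixed_diff_count == base
        )


class TestEuclideanDistance:
    def test_identical_profiles_zero(self):
        ds = make_dataset(
            [["0/1", "0/0"], ["0/1", "0/0"]], taxa=["A", "B"]
        )
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert euclidean_distance(pa, pb) == 0.0

    def test_opposite_fixation_closed_form(self):
        k, L = 5, 8
        a_row = ["0/0"] * L
        b_row = ["1/1"] * k + ["0/0"] * (L - k)
        ds = make_dataset([a_row, b_row], taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert euclidean_distance(pa, pb) == pytest.approx(math.sqrt(k))

    def test_matches_oracle(self):
        rng = np.random.default_rng(31)
        ds = random_dataset(rng, 10, 40, missing_rate=0.2, taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert euclidean_distance(pa, pb) == pytest.approx(
            oracle.euclidean(ds, "A", "B"), abs=1e-12
        )

    def test_no_shared_loci_errors(self):
        ds = make_dataset([["0/0", "-"], ["-", "1/1"]], taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        with pytest.raises(ValueError, match="no locus"):
            euclidean_distance(pa, pb)


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        ds = make_dataset([["0/1"], ["0/1"]], taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert nei_distance(pa, pb) == pytest.approx(0.0)

    def test_disjoint_is_infinite(self):
        ds = make_dataset([["0/0"], ["1/1"]], taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert math.isinf(nei_distance(pa, pb))

    def test_two_locus_hand_computation(self):
        # p = (0.5, 0.5) vs q = (0.9, 0.1) at both loci:
        # jx = 0.5, jy = 0.82, jxy = 0.5 at each locus,
        # D = -ln(0.5 / sqrt(0.5 * 0.82)) computed independently here
        ds = make_dataset(
            [
                ["0/0", "0/0"],
                ["1/1", "1/1"],
                ["0/0", "0/0"],
                ["0/0", "0/0"],
                ["0/0", "0/0"],
                ["0/0", "0/0"],
                ["0/1", "0/1"],
            ],
            taxa=["A", "A", "B", "B", "B", "B", "B"],
        )
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        expected = -math.log(0.5 / math.sqrt(0.5 * 0.82))
        assert expected == pytest.approx(0.2473481, abs=1e-6)
        assert nei_distance(pa, pb) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle(self):
        rng = np.random.default_rng(77)
        ds = random_dataset(rng, 12, 30, missing_rate=0.1, taxa=["A", "B"])
        pa, pb = allele_profile(ds, "A"), allele_profile(ds, "B")
        assert nei_distance(pa, pb) == pytest.approx(
            oracle.nei(ds, "A", "B"), abs=1e-12
        )


class TestHybridogenVsHostLaw:
    def test_no_fixed_differences_lineage_vs_host(self):
        """A hybridogen always carries a host-derived allele, so the
        lineage can never be fixed-different from its host species."""
        import hemiclone as hc

        for seed in range(10):
            sc = hc.default_scenario(seed)
            sc.n_loci = 500
            ds, _ = hc.simulate_dataset(sc)
            for lineage, host in (("AxB", "A"), ("AxX", "A"), ("BxX", "B")):
                s = fixed_difference_count(ds, lineage, host)
                assert s.fixed_diff_count == 0


class TestSummaryTable:
    def test_matrix_layout(self):
        ds = make_dataset(
            [["0/0", "0/0"], ["1/1", "0/0"], ["0/1", "0/1"]],
            taxa=["A", "B", "H"],
        )
        het, mat = summary_table(ds)
        assert het.loc["H", "H_O"] == 1.0
        # lower triangle = fixed-difference counts, upper = Euclidean
        assert mat.loc["B", "A"] == 1
        assert mat.loc["A", "B"] == pytest.approx(1.0)
        assert np.isnan(mat.loc["A", "A"])
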