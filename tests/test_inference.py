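"""Diagnostic panels, hybridogen detection, classification, resurrection test."""

import itertools

import numpy as np
import pytest

import _oracles as oracle
from conftest import make_dataset
import hemiclone as hc
from hemiclone.genodata import GenotypeDataset, LocusMeta
from hemiclone.inference import (
    AMBIGUOUS,
    HYBRIDOGEN_LIKE,
    SEXUAL_LIKE,
    classify_individuals,
    diagnostic_loci,
    hybridogen_score,
    resurrection_test,
)


class TestDiagnosticLoci:
    def test_identical_taxa_empty_panel(self):
        ds = make_dataset([["0/1", "0/0"], ["0/1", "0/0"]], taxa=["A", "B"])
        assert diagnostic_loci(ds, "A", "B").n_loci == 0

    def test_two_disjoint_one_shared(self):
        ds = make_dataset(
            [["0/0", "0/0", "0/1"], ["1/1", "1/1", "0/0"]],
            taxa=["A", "B"],
        )
        panel = diagnostic_loci(ds, "A", "B")
        assert panel.locus_ids == ["loc0", "loc1"]
        assert panel.side_a[0] == {0} and panel.side_b[0] == {1}

    def test_forced_diagnostic_count_recovered(self):
        sc = hc.default_scenario(13)
        sc.n_loci = 500
        sc.sexual_n = {"A": 30, "B": 30}
        sc.lineages, sc.remnants = [], []
        sc.dropout_by_taxon = {}
        sc.call_missing_rate = 0.0
        sc.genotyping_error_rate = 0.0
        ds, _ = hc.simulate_dataset(sc)
        panel = diagnostic_loci(ds, "A", "B")
        forced = {f"L{j + 1:03d}" for j in range(40)}  # first forced block
        assert forced <= set(panel.locus_ids)


class TestHybridogenScore:
    def _panel_ds(self):
        # 12 diagnostic loci between A and B
        L = 12
        rows = [
            ["0/0"] * L,  # A reference
            ["1/1"] * L,  # B reference
            ["0/0"] * L,  # sexual-like individual
            ["0/1"] * L,  # perfect F1
        ]
        return make_dataset(
            rows,
            individuals=["a", "b", "sex", "f1"],
            taxa={"a": "A", "b": "B"},
        )

    def test_homozygous_a_side_scores_zero(self):
        ds = self._panel_ds()
        panel = diagnostic_loci(ds, "A", "B")
        call = hybridogen_score(ds, "sex", panel)
        assert call.f_het == 0.0
        assert call.classification == SEXUAL_LIKE

    def test_full_fixed_heterozygosity_scores_one(self):
        ds = self._panel_ds()
        panel = diagnostic_loci(ds, "A", "B")
        call = hybridogen_score(ds, "f1", panel)
        assert call.f_het == 1.0
        assert call.classification == HYBRIDOGEN_LIKE

    def test_too_few_loci_is_ambiguous(self):
        ds = self._panel_ds()
        panel = diagnostic_loci(ds, "A", "B")
        call = hybridogen_score(ds, "f1", panel, min_loci=20)
        assert call.classification == AMBIGUOUS

    def test_error_tolerance_on_simulated_hybridogens(self):
        """Under 2% allele-flip error, >= 99% of hybridogen individuals
        keep f_het >= 0.95, and sexual parents always score < 0.1."""
        from hemiclone.inference import _panel_het_fractions

        hyb_scores, sexual_scores = [], []
        for r in range(10):
            sc = hc.default_scenario(300 + r)
            sc.n_loci = 3000
            sc.genotyping_error_rate = 0.02
            sc.dropout_by_taxon = {}
            ds, truth = hc.simulate_dataset(sc)
            panel = diagnostic_loci(ds, "A", "B", tloc=0.05)
            f, _ = _panel_het_fractions(ds, panel)
            for i, ind in enumerate(ds.individuals):
                taxon = truth.loc[ind, "taxon"]
                if taxon == "AxB":
                    hyb_scores.append(f[i])
                elif taxon in ("A", "B"):
                    sexual_scores.append(f[i])
        hyb_scores = np.array(hyb_scores)
        assert (hyb_scores >= 0.95).mean() >= 0.99
        assert max(sexual_scores) < 0.1


class TestClassification:
    def test_reference_individuals_self_consistent(self):
        ds = make_dataset(
            [["0/0"] * 15, ["0/0"] * 15, ["1/1"] * 15, ["1/1"] * 15],
            individuals=["a1", "a2", "b1", "b2"],
            taxa={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        table = classify_individuals(ds, ["A", "B"])
        for ind in ("a1", "a2"):
            assert table.loc[ind, "assigned_label"] == "A"
        for ind in ("b1", "b2"):
            assert table.loc[ind, "assigned_label"] == "B"

    def test_overlapping_refs_rejected(self):
        ds = make_dataset(
            [["0/0"], ["1/1"]], individuals=["a", "b"],
            taxa={"a": "A", "b": "B"},
        )
        with pytest.raises(ValueError, match="at least 2|share"):
            classify_individuals(ds, ["A"])

    def test_six_taxon_recovery(self):
        """Full mixture of 3 sexual + 3 hybridogen classes recovers truth."""
        sc = hc.default_scenario(101)
        sc.n_loci = 1000
        ds, truth = hc.simulate_dataset(sc)
        table = classify_individuals(ds, ["A", "B", "X"])
        correct = 0
        for ind in ds.individuals:
            row, t = table.loc[ind], truth.loc[ind]
            if t["truth_class"] == "hybridogen":
                want = {t["taxon"][0], t["taxon"][2]}  # e.g. AxB
                got = (
                    {row["parent_a"], row["parent_b"]}
                    if row["assigned_class"] == "hybridogen"
                    else set()
                )
                correct += want == got
            else:
                correct += (
                    row["assigned_class"] == "sexual"
                    and row["assigned_label"] == t["taxon"]
                )
        assert correct / ds.n_individuals >= 0.98

    def test_resurrected_individuals_called_sexual(self):
        """Offspring of two ghost-carrying lineages look like the pure
        sexual ghost species, not like hybridogens."""
        sc = hc.default_scenario(55)
        sc.n_loci = 1000
        sc.resurrections = [hc.ResurrectionSpec("RES", "AxX", "BxX", n=10)]
        ds, truth = hc.simulate_dataset(sc)
        table = classify_individuals(ds, ["A", "B", "X"])
        res = truth.index[truth["truth_class"] == "resurrected"]
        assert (table.loc[res, "assigned_class"] == "sexual").all()
        assert (table.loc[res, "assigned_label"] == "X").all()


class TestResurrectionTest:
    def test_cross_offspring_consistent(self):
        # P formed from one haplotype of each founder: shares everywhere
        L = 8
        f1 = ["0/0"] * L
        f2 = ["1/1"] * L
        p = ["0/1"] * L
        ds = make_dataset(
            [f1, f2, p], individuals=["x", "y", "z"],
            taxa={"x": "F1", "y": "F2", "z": "P"},
        )
        v = resurrection_test(ds, "P", "F1", "F2")
        assert v.fixed_diff_counts == (0, 0)
        assert v.verdict == "resurrection-consistent"
        assert v.shared_allele_fraction == (1.0, 1.0)

    def test_single_disjoint_locus_flips_verdict(self):
        L = 8
        f1 = ["0/0"] * L
        f2 = ["0/0"] * L
        p = ["0/0"] * (L - 1) + ["1/1"]
        ds = make_dataset(
            [f1, f2, p], individuals=["x", "y", "z"],
            taxa={"x": "F1", "y": "F2", "z": "P"},
        )
        v = resurrection_test(ds, "P", "F1", "F2", tau=0)
        assert v.fixed_diff_counts == (1, 1)
        assert v.verdict == "pure-remnant"
        assert v.fixed_diff_loci[0] == ["loc7"]
        # with tau = 1 the same data is within tolerance
        assert resurrection_test(ds, "P", "F1", "F2", tau=1).verdict == (
            "resurrection-consistent"
        )

    def test_same_label_rejected(self):
        ds = make_dataset([["0/0"]], taxa=["P"])
        with pytest.raises(ValueError, match="differ"):
            resurrection_test(ds, "P", "P", "F2")

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_zero_fixed_difference_guarantee_exhaustive(self, L):
        """Any offspring of gametes drawn from the founder lineages has
        zero fixed differences vs both founders — checked over all
        3^L founder genotype configurations against the brute-force
        set-intersection oracle."""
        for config in itertools.product([0, 1, 2], repeat=L):
            # founder genotype per locus: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1
            geno = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
            f1_calls = [geno[c] for c in config]
            f2_calls = [geno[c] for c in reversed(config)]
            # offspring: one gamete from each founder genotype
            child = [
                (f1_calls[j][j % 2], f2_calls[j][(j + 1) % 2])
                for j in range(L)
            ]
            calls = np.array(
                [f1_calls, f2_calls, child], dtype=np.int16
            )
            ds = GenotypeDataset(
                ["f1", "f2", "p"],
                [LocusMeta(f"l{j}") for j in range(L)],
                calls,
                {"f1": "F1", "f2": "F2", "p": "P"},
            )
            v = resurrection_test(ds, "P", "F1", "F2", tau=0)
            assert v.fixed_diff_counts == (0, 0)
            assert oracle.fixed_diff(ds, "P", "F1")[0] == 0
            assert oracle.fixed_diff(ds, "P", "F2")[0] == 0

    def test_invariant_to_relabeling_and_order(self):
        sc = hc.default_scenario(71)
        sc.n_loci = 400
        ds, _ = hc.simulate_dataset(sc)
        base = resurrection_test(ds, "X", "AxX", "BxX")
        flipped = GenotypeDataset(
            ds.individuals,
            ds.loci,
            np.where(ds.calls == -1, -1, 1 - ds.calls),
            ds.taxon_map,
        )
        perm = np.random.default_rng(0).permutation(ds.n_individuals)
        shuffled = GenotypeDataset(
            [ds.individuals[i] for i in perm],
            ds.loci,
            ds.calls[perm],
            ds.taxon_map,
        )
        for other in (flipped, shuffled):
            v = resurrection_test(other, "X", "AxX", "BxX")
            assert v.verdict == base.verdict
            assert v.fixed_diff_counts == base.fixed_diff_counts

    def test_power_monotone_in_drift_and_loci(self):
        """The remnant call gets easier with more drift and more loci."""
        from hemiclone.simulate import RemnantSpec

        def mean_count(f_drift: float, L: int, reps: int = 8) -> float:
            total = 0
            for r in range(reps):
                sc = hc.default_scenario(8000 + r)
                sc.n_loci = L
                sc.remnants = [
                    RemnantSpec("X", species="X", f_drift=f_drift, n=7)
                ]
                ds, _ = hc.simulate_dataset(sc)
                v = resurrection_test(ds, "X", "AxX", "BxX")
                total += max(v.fixed_diff_counts)
            return total / reps

        by_drift = [mean_count(f, 1500) for f in (0.01, 0.05, 0.2)]
        assert by_drift[0] <= by_drift[1] <= by_drift[2]
        by_loci = [mean_count(0.05, L) for L in (400, 1500, 3000)]
        assert by_loci[0] <= by_loci[1] <= by_loci[2]
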