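import numpy as np
import pandas as pd
import pytest

from pedkit.demography import CensusTable
from pedkit.genedrop import (
    ancestry_proportions,
    count_meioses,
    enumerate_transmissions,
    founder_inbreeding_attribution,
    prob_homozygous_group,
    run_genedrop,
    translocation_ancestry,
)
from pedkit.pedigree import NONTRANSLOCATED, build_pedigree, founder_groups
from pedkit.relatedness import (
    ancestry_matrix_exact,
    inbreeding_coefficients,
    tabular_relationship,
)
from pedkit.simulate import random_pedigree

from conftest import census_of, rec, transloc

R_SMALL = 20_000


class TestRunGenedrop:
    def test_replicate_count_validated(self, ped5):
        with pytest.raises(ValueError, match="R"):
            run_genedrop(ped5, R=0)

    def test_founder_alleles_all_own_and_never_ibd(self, ped5):
        result = run_genedrop(ped5, R=500, seed=1)
        a = result.ids.index("A")
        fa = result.founder_ids.index("A")
        assert result.copies[a, fa] == 2 * result.R
        assert result.ibd[a].sum() == 0

    def test_tally_conservation_exact_integers(self):
        p = random_pedigree(6, 40, seed=3, translocated_fraction=0.5)
        result = run_genedrop(p, R=1000, seed=9)
        assert (result.copies.sum(axis=1) == 2 * result.R).all()
        # IBD via f needs two copies from f in that replicate
        assert (result.ibd * 2 <= result.copies).all()
        assert (result.ibd.sum(axis=1) <= result.R).all()

    def test_bitwise_reproducibility(self, ped5):
        a = run_genedrop(ped5, R=2000, seed=42)
        b = run_genedrop(ped5, R=2000, seed=42)
        for field in ("copies", "ibd", "hom"):
            assert np.array_equal(getattr(a, field), getattr(b, field))
        c = run_genedrop(ped5, R=2000, seed=43)
        assert not np.array_equal(a.copies, c.copies)


class TestEnumerationOracle:
    def test_ped5_exact_values(self, ped5):
        result = enumerate_transmissions(ped5)
        assert result.R == 2 ** count_meioses(ped5) == 64
        F = result.inbreeding_estimates()
        assert F["E"] == 0.25
        e = result.ids.index("E")
        fa = result.founder_ids.index("A")
        # IBD via A in exactly 1/8 of outcomes
        assert result.ibd[e, fa] / result.R == 0.125

    def test_enumeration_equals_tabular_on_random_pedigrees(self):
        for seed in range(8):
            p = random_pedigree(4, 6, seed=seed)
            F_tab = inbreeding_coefficients(tabular_relationship(p))
            F_enum = enumerate_transmissions(p).inbreeding_estimates()
            assert np.allclose(F_tab.to_numpy(), F_enum.to_numpy(), atol=1e-12)

    def test_too_many_meioses_refused(self):
        p = random_pedigree(5, 30, seed=0)
        with pytest.raises(ValueError, match="meioses"):
            enumerate_transmissions(p, max_meioses=12)


class TestAncestry:
    def test_rows_sum_exactly_one(self):
        p = random_pedigree(8, 60, seed=5, translocated_fraction=0.4)
        ancestry = ancestry_proportions(run_genedrop(p, R=500, seed=2))
        assert (ancestry.proportions.sum(axis=1) == 1.0).all()

    def test_ped5_expectations(self, ped5):
        ancestry = ancestry_proportions(enumerate_transmissions(ped5))
        assert ancestry.proportions.loc["E", "X"] == 0.5
        assert ancestry.proportions.loc["E", "Y"] == 0.5

    def test_local_only_individual_fully_nontranslocated(self):
        p = build_pedigree([
            rec("L1", sex="male"), rec("L2", sex="female"),
            transloc("T", "X"), rec("K", "L1", "L2"),
        ])
        ancestry = ancestry_proportions(enumerate_transmissions(p))
        assert ancestry.proportions.loc["K", NONTRANSLOCATED] == 1.0
        assert translocation_ancestry(ancestry)["K"] == 0.0

    def test_translocation_ancestry_complement(self, ped5):
        ancestry = ancestry_proportions(enumerate_transmissions(ped5))
        ta = translocation_ancestry(ancestry)
        # founders from donors and the F1 of two donors are fully translocated
        assert ta["A"] == ta["B"] == ta["C"] == ta["E"] == 1.0

    def test_montecarlo_close_to_exact_recursion(self):
        p = random_pedigree(10, 190, seed=21, translocated_fraction=0.3)
        groups = founder_groups(p)
        result = run_genedrop(p, R=R_SMALL, seed=7, groups=groups)
        estimate = ancestry_proportions(result).proportions
        exact = ancestry_matrix_exact(p, groups)
        se = np.sqrt(exact * (1 - exact) / (2 * R_SMALL))
        assert ((estimate - exact).abs() <= 4 * se + 1e-12).all().all()


class TestHomozygousGroup:
    def test_half_translocated_parents(self):
        # K1 and K2 each have one translocated parent (donors X and Y). K1
        # always carries exactly one X allele, so P(hom X) = 0 for K1; their
        # offspring Z is homozygous nontranslocated iff both parents transmit
        # their local allele: 1/2 * 1/2 = 1/4.
        p = build_pedigree([
            transloc("T1", "X", sex="male"), transloc("T2", "Y", sex="female"),
            rec("L1", sex="male"), rec("L2", sex="female"),
            rec("K1", "T1", "L2", "male"),
            rec("K2", "L1", "T2", "female"),
            rec("Z", "K1", "K2"),
        ])
        result = enumerate_transmissions(p)
        hom_x = prob_homozygous_group(result, "X")
        hom_local = prob_homozygous_group(result, NONTRANSLOCATED)
        assert hom_x["K1"] == 0.0
        assert hom_local["K1"] == 0.0
        assert hom_x["Z"] == 0.0
        assert hom_local["Z"] == 0.25

    def test_ped5_group_x(self, ped5):
        result = enumerate_transmissions(ped5)
        assert prob_homozygous_group(result, "X")["E"] == 0.25

    def test_founder_homozygous_for_own_group(self, ped5):
        result = enumerate_transmissions(ped5)
        assert prob_homozygous_group(result, "X")["A"] == 1.0

    def test_not_square_of_ancestry_in_general(self):
        # Sire-daughter mating with a translocated sire: E's X ancestry is
        # 3/4 but P(hom X) is 1/2, not (3/4)^2 -- allele origins are
        # correlated through the shared ancestor.
        p = build_pedigree([
            transloc("A", "X", sex="male"), rec("B", sex="female"),
            rec("C", "A", "B", "female"), rec("E", "A", "C"),
        ])
        result = enumerate_transmissions(p)
        ancestry = ancestry_proportions(result)
        assert ancestry.proportions.loc["E", "X"] == 0.75
        hom = prob_homozygous_group(result, "X")
        assert hom["E"] == 0.5
        assert hom["E"] != ancestry.proportions.loc["E", "X"] ** 2

    def test_unknown_group_rejected(self, ped5):
        with pytest.raises(KeyError):
            prob_homozygous_group(enumerate_transmissions(ped5), "nope")


class TestInbreedingAttribution:
    def test_ped5_population_of_e(self, ped5):
        census = CensusTable(census_of({2001: [("E", "c1", "breeder")]}))
        result = enumerate_transmissions(ped5)
        attribution = founder_inbreeding_attribution(result, census)
        assert attribution.values.loc["A", 2001] == 0.125
        assert attribution.values.loc["B", 2001] == 0.125
        F = inbreeding_coefficients(tabular_relationship(ped5))
        assert attribution.values[2001].sum() == F["E"]

    def test_halfsib_attributed_to_shared_sire_only(self, halfsib):
        census = CensusTable(census_of({2001: [("E", "c1", "breeder")]}))
        attribution = founder_inbreeding_attribution(
            enumerate_transmissions(halfsib), census)
        assert attribution.values.loc["A", 2001] == 0.125
        assert attribution.values.loc["B", 2001] == 0.0
        assert attribution.values.loc["B2", 2001] == 0.0

    def test_all_founder_population_zero(self, ped5):
        census = CensusTable(census_of({
            2000: [("A", "c1", "breeder"), ("B", "c1", "breeder")],
        }))
        attribution = founder_inbreeding_attribution(
            enumerate_transmissions(ped5), census)
        assert (attribution.values[2000] == 0.0).all()

    def test_sums_match_population_mean_inbreeding(self):
        p = random_pedigree(6, 30, seed=13)
        members = [i for i in p.ids if not p.is_founder(i)][-10:]
        census = CensusTable(census_of({
            2005: [(i, "c1", "helper") for i in members],
        }))
        F = inbreeding_coefficients(tabular_relationship(p))
        result = run_genedrop(p, R=R_SMALL, seed=3)
        attribution = founder_inbreeding_attribution(result, census)
        total = attribution.values[2005].sum()
        mean_F = F[members].mean()
        se = np.sqrt(mean_F * (1 - mean_F) / (R_SMALL * len(members)))
        assert abs(total - mean_F) <= 4 * se + 1e-9
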