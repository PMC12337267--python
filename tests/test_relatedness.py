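import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedkit.demography import CensusTable
from pedkit.pedigree import build_pedigree, founder_groups, translocation_cohorts
from pedkit.relatedness import (
    ATOL,
    cohort_contribution_series,
    contribution_series,
    founder_contribution_matrix,
    founder_contribution_vector,
    inbreeding_coefficients,
    tabular_relationship,
)
from pedkit.simulate import random_pedigree

from conftest import census_of, rec, transloc


class TestTabularMethod:
    def test_full_sib_mating(self, ped5):
        rm = tabular_relationship(ped5)
        assert rm.loc("C", "D") == 0.5
        F = inbreeding_coefficients(rm)
        assert F["E"] == 0.25
        assert F[["A", "B", "C", "D"]].eq(0).all()

    def test_half_sib_mating(self, halfsib):
        F = inbreeding_coefficients(tabular_relationship(halfsib))
        assert F["E"] == 0.125

    def test_parent_offspring_mating(self, parent_offspring):
        F = inbreeding_coefficients(tabular_relationship(parent_offspring))
        assert F["E"] == 0.25

    @pytest.mark.parametrize("seed", range(4))
    def test_matrix_invariants(self, seed):
        p = random_pedigree(8, 40, seed=seed)
        rm = tabular_relationship(p)
        A = rm.A
        assert np.allclose(A, A.T, atol=ATOL)
        diag = np.diag(A)
        assert (diag >= 1.0 - ATOL).all()
        # founders: pairwise zero off-diagonal
        fidx = [rm.ids.index(f) for f in p.founders]
        off = A[np.ix_(fidx, fidx)] - np.eye(len(fidx))
        assert np.abs(off).max() == 0.0
        # A[i,j] <= min(A[i,i], A[j,j]) elementwise
        cap = np.minimum.outer(diag, diag)
        assert (A <= cap + ATOL).all()


class TestFounderContributions:
    def test_parent_offspring_half(self, ped5):
        g = founder_contribution_vector(ped5, "A")
        assert g["C"] == 0.5
        assert g["E"] == 0.5

    def test_conservation_in_ped5(self, ped5):
        G = founder_contribution_matrix(ped5)
        assert G["E"].sum() == 1.0

    def test_great_grandchild_single_line(self):
        # C = A x U0, D = C x U1, E = D x U2: three outcrossed generations
        records = [
            rec("A", sex="male"), rec("U0", sex="female"),
            rec("U1", sex="female"), rec("U2", sex="female"),
            rec("C", "A", "U0", "male"),
            rec("D", "C", "U1", "male"),
            rec("E", "D", "U2", "male"),
        ]
        g = founder_contribution_vector(build_pedigree(records), "A")
        assert g["E"] == 0.125

    def test_monotone_dilution_halves_per_outcross(self):
        records = [rec("A", sex="male"), rec("M0", sex="female")]
        child, parent = None, "A"
        for k in range(5):
            mate = f"M{k}"
            if k > 0:
                records.append(rec(mate, sex="female"))
            child = f"G{k}"
            records.append(rec(child, parent, mate, "male"))
            parent = child
        g = founder_contribution_vector(build_pedigree(records), "A")
        for k in range(5):
            assert g[f"G{k}"] == 0.5 ** (k + 1)

    def test_non_founder_rejected(self, ped5):
        with pytest.raises(ValueError, match="not a pedigree founder"):
            founder_contribution_vector(ped5, "C")

    def test_equivalence_with_relationship_row(self):
        p = random_pedigree(6, 30, seed=11)
        rm = tabular_relationship(p)
        G = founder_contribution_matrix(p)
        for f in p.founders:
            fi = rm.ids.index(f)
            for i in p.ids:
                if not p.is_founder(i):
                    assert G.loc[f, i] == pytest.approx(
                        rm.A[fi, rm.ids.index(i)], abs=ATOL
                    )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_property(self, seed):
        p = random_pedigree(5, 25, seed=seed)
        G = founder_contribution_matrix(p)
        assert np.allclose(G.sum(axis=0).to_numpy(), 1.0, atol=ATOL)


class TestContributionSeries:
    def test_population_of_single_inbred_descendant(self, ped5):
        census = CensusTable(census_of({2001: [("E", "c1", "breeder")]}))
        series = contribution_series(ped5, census)
        assert series.values.loc["A", 2001] == 0.5
        assert series.values.loc["B", 2001] == 0.5

    def test_mixed_population(self, ped5):
        census = CensusTable(census_of({
            2001: [("C", "c1", "breeder"), ("D", "c1", "breeder"),
                   ("E", "c1", "juvenile")],
        }))
        series = contribution_series(ped5, census)
        assert series.values.loc["A", 2001] == pytest.approx(0.5)
        assert series.population_sizes[2001] == 3

    def test_all_founder_population_each_1_over_n(self):
        p = build_pedigree([rec("A"), rec("B"), rec("C")])
        census = CensusTable(census_of({
            2000: [("A", "c1", "breeder"), ("B", "c1", "breeder"),
                   ("C", "c2", "floater")],
        }))
        series = contribution_series(p, census)
        assert np.allclose(series.values[2000].to_numpy(), 1 / 3, atol=ATOL)

    def test_rows_sum_to_one_per_year(self, halfsib):
        census = CensusTable(census_of({
            2000: [("C", "c1", "breeder"), ("D", "c1", "breeder")],
            2001: [("E", "c1", "juvenile")],
        }))
        series = contribution_series(halfsib, census)
        assert series.values.sum(axis=0).to_numpy() == pytest.approx([1.0, 1.0], abs=ATOL)

    def test_unknown_individual_rejected(self, ped5):
        census = CensusTable(census_of({2001: [("ZZ", "c1", "breeder")]}))
        with pytest.raises(ValueError, match="ZZ"):
            contribution_series(ped5, census)


class TestCohortContributions:
    def test_single_member_cohort_identity(self, ped5):
        census = CensusTable(census_of({2001: [("E", "c1", "breeder")]}))
        series = contribution_series(ped5, census)
        cohorts = translocation_cohorts(ped5)
        cohort_series = cohort_contribution_series(series, cohorts)
        assert cohort_series.loc["2000 X", 2001] == series.values.loc["A", 2001]

    def test_additivity_covers_translocated_total(self, ped5):
        census = CensusTable(census_of({
            2001: [("C", "c1", "breeder"), ("E", "c1", "juvenile")],
        }))
        series = contribution_series(ped5, census, founder_groups(ped5))
        cohort_series = cohort_contribution_series(
            series, translocation_cohorts(ped5))
        translocated_total = series.values.loc[["A", "B"], 2001].sum()
        assert cohort_series[2001].sum() == pytest.approx(translocated_total)

    def test_dead_end_cohort_drops_to_zero(self):
        # Translocated founder T in the 2000 census only, leaves no offspring.
        p = build_pedigree([
            transloc("T", "X", 2000), rec("L1", sex="male"),
            rec("L2", sex="female"), rec("K", "L1", "L2"),
        ])
        census = CensusTable(census_of({
            2001: [("T", "c1", "floater"), ("K", "c2", "juvenile")],
            2002: [("K", "c2", "helper")],
        }))
        series = contribution_series(p, census)
        cohort_series = cohort_contribution_series(
            series, translocation_cohorts(p))
        assert cohort_series.loc["2000 X", 2001] == 0.5
        assert cohort_series.loc["2000 X", 2002] == 0.0

    def test_non_founder_cohort_member_rejected(self, ped5):
        from pedkit.pedigree import TranslocationCohort
        census = CensusTable(census_of({2001: [("E", "c1", "breeder")]}))
        series = contribution_series(ped5, census)
        bad = TranslocationCohort(2000, "X", frozenset({"C"}))
        with pytest.raises(ValueError, match="not pedigree founders"):
            cohort_contribution_series(series, [bad])
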