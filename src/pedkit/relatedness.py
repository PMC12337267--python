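"""Exact pedigree algebra: relationship matrix, inbreeding, founder contributions.

The additive (numerator) relationship matrix A is built by the tabular
method: processing individuals in topological order,

    A[i, j] = (A[j, sire(i)] + A[j, dam(i)]) / 2      for j placed before i,
    A[i, i] = 1 + A[sire(i), dam(i)] / 2,

with founders assumed non-inbred and mutually unrelated (diagonal 1, zero to
all non-descendants). The pedigree inbreeding coefficient is F_P(i) =
A[i, i] - 1, the expected proportion of the genome identical by descent given
the observed pedigree.

Expected founder genetic contributions use the genome-proportion recursion
g[f, i] = (g[f, sire(i)] + g[f, dam(i)]) / 2 with g[f, f] = 1, which for a
founder f equals A[f, i]; per-year population contributions standardize the
summed proportions by that year's census size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import FounderGroupSet, Pedigree, TranslocationCohort

#: Absolute tolerance for conservation/symmetry assertions.
ATOL = 1e-9


@dataclass(frozen=True)
class RelationshipMatrix:
    """Additive relationship matrix over ``ids`` (topological order)."""

    ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.A.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")

    def loc(self, i: str, j: str) -> float:
        idx = {v: k for k, v in enumerate(self.ids)}
        return float(self.A[idx[i], idx[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class ContributionSeries:
    """Standardized expected genetic contributions of founders per census year.

    ``values`` is a founder x year DataFrame; entry (f, t) is the expected
    fraction of year t's gene pool descending from founder f. Columns for
    census years with no individuals are all-NaN. ``population_sizes`` maps
    year -> N_t.
    """

    values: pd.DataFrame
    population_sizes: pd.Series

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.values.columns]


def tabular_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method."""
    ids = pedigree.ids
    idx = pedigree.index
    n = len(ids)
    A = np.zeros((n, n))
    for k, i in enumerate(ids):
        sire, dam = pedigree.parents(i)
        if sire is None:
            A[k, k] = 1.0
        else:
            s, d = idx[sire], idx[dam]
            row = 0.5 * (A[s, :k] + A[d, :k])
            A[k, :k] = row
            A[:k, k] = row
            A[k, k] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(ids=ids, A=A)


def inbreeding_coefficients(rm: RelationshipMatrix) -> pd.Series:
    """F_P per individual: diagonal of A minus one. Founders are 0."""
    return pd.Series(np.diag(rm.A) - 1.0, index=rm.ids, name="F_P")


def founder_contribution_matrix(
    pedigree: Pedigree, founder_ids: list[str] | None = None
) -> pd.DataFrame:
    """Expected genome proportions g[f, i] for each founder f (rows) and
    individual i (columns), by the halving recursion down the pedigree.
    """
    founders = pedigree.founders if founder_ids is None else list(founder_ids)
    for f in founders:
        if not pedigree.is_founder(f):
            raise ValueError(f"{f!r} is not a pedigree founder")
    ids = pedigree.ids
    idx = pedigree.index
    G = np.zeros((len(founders), len(ids)))
    frow = {f: r for r, f in enumerate(founders)}
    for k, i in enumerate(ids):
        sire, dam = pedigree.parents(i)
        if sire is None:
            if i in frow:
                G[frow[i], k] = 1.0
        else:
            G[:, k] = 0.5 * (G[:, idx[sire]] + G[:, idx[dam]])
    return pd.DataFrame(G, index=founders, columns=ids)


def founder_contribution_vector(pedigree: Pedigree, founder_id: str) -> pd.Series:
    """Expected genome proportion inherited from ``founder_id`` per individual."""
    return founder_contribution_matrix(pedigree, [founder_id]).iloc[0]


def contribution_series(
    pedigree: Pedigree,
    census: "CensusTable",
    groups: FounderGroupSet | None = None,
) -> ContributionSeries:
    """Per-founder expected genetic contribution to each census year.

    C_f(t) = (1/N_t) * sum over individuals alive in year t of g[f, i]; for
    every year with N_t > 0 the founder contributions sum to 1. A founder's
    series is 0 before its first year in the population and NaN in empty
    census years.
    """
    frame = census.frame
    years = census.years
    if not years:
        raise ValueError("census has no years")
    founders = pedigree.founders
    if groups is not None:
        # Order founders donor groups first, preserving topological order inside.
        order = {f: k for k, f in enumerate(founders)}
        founders = sorted(
            founders, key=lambda f: (groups.labels.index(groups.group_of(f)), order[f])
        )
    G = founder_contribution_matrix(pedigree, founders)
    values = pd.DataFrame(np.nan, index=founders, columns=years)
    sizes = pd.Series(0, index=years, dtype=int, name="N")
    for year, sub in frame.groupby("year"):
        members = sub["id"].tolist()
        missing = [m for m in members if m not in pedigree]
        if missing:
            raise ValueError(f"census year {year}: not in pedigree: {missing[:3]}")
        sizes.loc[year] = len(members)
        values[year] = G[members].mean(axis=1)
    return ContributionSeries(values=values, population_sizes=sizes)


def cohort_contribution_series(
    series: ContributionSeries, cohorts: list[TranslocationCohort]
) -> pd.DataFrame:
    """Cohort x year contributions: elementwise sum of member founder series."""
    rows = {}
    for cohort in cohorts:
        missing = sorted(set(cohort.member_ids) - set(series.values.index))
        if missing:
            raise ValueError(
                f"cohort {cohort.label}: members are not pedigree founders: "
                f"{missing[:3]}"
            )
        rows[cohort.label] = series.values.loc[sorted(cohort.member_ids)].sum(
            axis=0, skipna=False
        )
    return pd.DataFrame(rows).T


def ancestry_matrix_exact(
    pedigree: Pedigree, groups: FounderGroupSet
) -> pd.DataFrame:
    """Individual x founder-group expected ancestry proportions by exact
    recursion (no simulation). Rows sum to 1 to machine precision."""
    G = founder_contribution_matrix(pedigree)
    out = pd.DataFrame(
        0.0, index=pedigree.ids, columns=groups.labels
    )
    for label in groups.labels:
        members = [f for f in G.index if f in groups.groups[label]]
        if members:
            out[label] = G.loc[members].sum(axis=0)
    return out
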