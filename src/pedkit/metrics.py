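"""Population-level ancestry structure: mixing metric m_d, group counts,
per-year ancestry composition.

m_d measures how evenly group ancestries are mixed *within* individuals: 0
when each individual's ancestry is confined to a single group, 1 when every
individual carries the population-average ancestry vector, undefined when
only one group has any ancestry in the population. With individual ancestry
vectors q_i and population mean Q over groups present,

    m_d = 1 - [sum_i sum_g |q_ig - Q_g|] / [2 N sum_g Q_g (1 - Q_g)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genedrop import AncestryMatrix


@dataclass(frozen=True)
class MixingResult:
    """m_d for one population; ``value`` is None when undefined (one group)."""

    value: float | None
    n_groups: int
    year: int | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _frame(matrix: AncestryMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.proportions if isinstance(matrix, AncestryMatrix) else matrix


def mixing_metric_md(
    matrix: AncestryMatrix | pd.DataFrame, year: int | None = None
) -> MixingResult:
    """m_d over the rows of an ancestry matrix (one population/year).

    Only groups with nonzero population-mean ancestry enter the metric;
    undefined (value None) when fewer than two such groups exist.
    """
    q = _frame(matrix)
    if len(q) == 0:
        raise ValueError("m_d requires at least one individual")
    Q = q.mean(axis=0)
    present = Q > 0
    n_groups = int(present.sum())
    if n_groups < 2:
        return MixingResult(value=None, n_groups=n_groups, year=year)
    qs = q.loc[:, present].to_numpy()
    Qs = Q[present].to_numpy()
    deviation = np.abs(qs - Qs).sum()
    ceiling = 2.0 * len(q) * float((Qs * (1.0 - Qs)).sum())
    value = 1.0 - deviation / ceiling
    if -1e-12 < value < 0.0:
        value = 0.0
    return MixingResult(value=value, n_groups=n_groups, year=year)


def founder_group_counts(
    matrix: AncestryMatrix | pd.DataFrame, threshold: float = 0.0
) -> pd.Series:
    """Number of founder groups each individual is expected to inherit
    alleles from: count of groups with ancestry strictly above ``threshold``.

    The default threshold 0 counts any group with nonzero estimated ancestry
    (in simulation mode: any group from which >= 1 allele copy was ever
    inherited across replicates). Founders always count 1.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    q = _frame(matrix)
    return (q > threshold).sum(axis=1).rename("n_founder_groups")


def population_ancestry_series(
    matrix: AncestryMatrix | pd.DataFrame, census: "CensusTable"
) -> pd.DataFrame:
    """Year x group matrix of population-mean expected ancestry proportions."""
    q = _frame(matrix)
    rows = {}
    for year, sub in census.frame.groupby("year"):
        members = sub["id"].tolist()
        missing = [m for m in members if m not in q.index]
        if missing:
            raise ValueError(
                f"census year {year}: no ancestry for {missing[:3]}"
            )
        rows[int(year)] = q.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T.sort_index()


def donor_shares(
    series: pd.DataFrame, nontranslocated_label: str = "nontranslocated"
) -> pd.DataFrame:
    """Each donor group's share of translocation ancestry, per year.

    Donor column divided by (1 - nontranslocated column); NaN in years with
    no translocation ancestry.
    """
    transloc = 1.0 - series[nontranslocated_label]
    donors = series.drop(columns=[nontranslocated_label])
    return donors.div(transloc.where(transloc > 0), axis=0)


def md_series(
    matrix: AncestryMatrix | pd.DataFrame, census: "CensusTable"
) -> pd.DataFrame:
    """Per-year m_d, number of ancestry groups present, and median
    founder-group count over the census population."""
    q = _frame(matrix)
    counts = founder_group_counts(q)
    rows = []
    for year, sub in census.frame.groupby("year"):
        members = sub["id"].tolist()
        res = mixing_metric_md(q.loc[members], year=int(year))
        rows.append(
            {
                "year": int(year),
                "m_d": math.nan if res.value is None else res.value,
                "n_groups": res.n_groups,
                "median_group_count": float(counts.loc[members].median()),
            }
        )
    return pd.DataFrame(rows).set_index("year").sort_index()
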