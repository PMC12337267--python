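"""Census-based demographic summaries.

A post-breeding census lists, per year, every individual in the population
with its cluster (territory) and role. From the census and the pedigree this
module derives: the census size series with interyear percentage change,
counts of potential breeding groups (clusters holding at least one adult
male and one adult female), establishment and persistence of translocated
birds, breeding-pair type tallies with a pair-network export, and the
Spearman rank correlation used to compare the size and breeding-group
series.

Conventions: an individual is *adult* in a census year if it hatched (or was
released) in a strictly earlier year; a translocated bird is *established*
if it appears in a census of a year strictly after its release year
(releases occur in fall, after that year's census).
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .pedigree import (
    FEMALE,
    MALE,
    TRANSLOCATED,
    Pedigree,
    TranslocationCohort,
)

ROLES = frozenset({"breeder", "helper", "juvenile", "floater", "unknown"})


class CensusTable:
    """Post-breeding census records: (year, individual, cluster, role) rows.

    (year, individual) pairs are unique; roles are one of
    breeder/helper/juvenile/floater/unknown. Missing interior years are
    tolerated with a warning (monitoring gaps).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"year", "id", "cluster", "role"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"census table missing columns: {sorted(missing)}")
        frame = frame.loc[:, ["year", "id", "cluster", "role"]].copy()
        frame["year"] = frame["year"].astype(int)
        frame["id"] = frame["id"].astype(str)
        frame["cluster"] = frame["cluster"].astype(str)
        frame["role"] = frame["role"].astype(str)
        bad_roles = set(frame["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown census roles: {sorted(bad_roles)}")
        dup = frame.duplicated(subset=["year", "id"])
        if dup.any():
            pair = frame.loc[dup, ["year", "id"]].iloc[0]
            raise ValueError(
                f"duplicate census row for individual {pair['id']!r} in "
                f"year {pair['year']}"
            )
        self.frame = frame.sort_values(["year", "id"]).reset_index(drop=True)
        years = sorted(self.frame["year"].unique())
        if years:
            gaps = sorted(set(range(years[0], years[-1] + 1)) - set(years))
            if gaps:
                _warnings.warn(f"census has no rows for years {gaps}", stacklevel=2)

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.frame["year"].unique())

    def individuals(self, year: int) -> list[str]:
        return self.frame.loc[self.frame["year"] == year, "id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class NestRecord:
    """One monitored nest: year, cluster, breeder pair, fledglings."""

    year: int
    cluster: str
    breeder_male: str
    breeder_female: str
    fledgling_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.breeder_male == self.breeder_female:
            raise ValueError(f"nest {self.cluster}/{self.year}: identical breeders")


def census_size_series(census: CensusTable) -> pd.DataFrame:
    """Census size N per year plus interyear percentage change.

    change_t = 100 * (N_t - N_{t-1}) / N_{t-1}; missing for the first year.
    """
    sizes = census.frame.groupby("year")["id"].nunique().sort_index()
    change = 100.0 * sizes.diff() / sizes.shift(1)
    return pd.DataFrame({"N": sizes, "pct_change": change})


def _hatch_year(pedigree: Pedigree, individual_id: str) -> int | None:
    rec = pedigree.record(individual_id)
    if rec.birth_year is not None:
        return rec.birth_year
    return rec.translocation_year


def potential_breeding_groups(
    census: CensusTable, pedigree: Pedigree
) -> pd.DataFrame:
    """Per-year count of potential breeding groups (PBGs) and their
    translocation composition.

    A PBG is a cluster occupied (roles breeder/helper/juvenile) by at least
    one adult male and one adult female. Adult = hatched or released strictly
    before the census year; individuals with no recorded year are treated as
    adults (pre-monitoring residents). Unknown-sex adults never satisfy the
    male/female requirement. Each PBG is classified by the origin of its
    adults: only translocated, only nontranslocated, or combined.
    """
    occupying = {"breeder", "helper", "juvenile"}
    rows = []
    for year, sub in census.frame.groupby("year"):
        n_pbg = only_t = only_n = combined = 0
        occ = sub[sub["role"].isin(occupying)]
        for _, grp in occ.groupby("cluster"):
            has_m = has_f = False
            any_t = any_n = False
            for i in grp["id"]:
                rec = pedigree.record(i)
                hatched = _hatch_year(pedigree, i)
                if hatched is not None and hatched >= year:
                    continue  # not adult
                if rec.sex == MALE:
                    has_m = True
                elif rec.sex == FEMALE:
                    has_f = True
                if rec.origin == TRANSLOCATED:
                    any_t = True
                else:
                    any_n = True
            if has_m and has_f:
                n_pbg += 1
                if any_t and any_n:
                    combined += 1
                elif any_t:
                    only_t += 1
                else:
                    only_n += 1
        rows.append(
            {
                "year": int(year),
                "n_pbg": n_pbg,
                "only_translocated": only_t,
                "only_nontranslocated": only_n,
                "combined": combined,
            }
        )
    return pd.DataFrame(rows).set_index("year").sort_index()


def establishment_summary(
    cohorts: list[TranslocationCohort],
    census: CensusTable,
    pedigree: Pedigree,
    nests: list[NestRecord] | None = None,
) -> pd.DataFrame:
    """Per released bird: establishment, persistence, and nesting years.

    established = appears in >= 1 census of a year strictly after release;
    persistence_years = number of census years containing the bird;
    span_years = last - first census year + 1 (0 if never censused);
    nesting_years = distinct years in which a nest names it as breeder.
    Aggregate rates by cohort/donor/sex via groupby on the returned frame.
    """
    seen_years: dict[str, list[int]] = {}
    for _, row in census.frame.iterrows():
        seen_years.setdefault(row["id"], []).append(int(row["year"]))
    nest_years: dict[str, set[int]] = {}
    for nest in nests or []:
        for breeder in (nest.breeder_male, nest.breeder_female):
            nest_years.setdefault(breeder, set()).add(nest.year)
    rows = []
    for cohort in cohorts:
        for i in sorted(cohort.member_ids):
            years = sorted(seen_years.get(i, []))
            established = any(y > cohort.year for y in years)
            rows.append(
                {
                    "id": i,
                    "cohort": cohort.label,
                    "translocation_year": cohort.year,
                    "donor_population": cohort.donor_population,
                    "sex": pedigree.record(i).sex if i in pedigree else "unknown",
                    "established": established,
                    "persistence_years": len(years),
                    "span_years": (years[-1] - years[0] + 1) if years else 0,
                    "nesting_years": len(nest_years.get(i, ())),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "cohort", "translocation_year", "donor_population", "sex",
            "established", "persistence_years", "span_years", "nesting_years",
        ],
    )


PAIR_CLASSES = ("translocated-translocated", "translocated-local", "local-local")


@dataclass
class PairTypeSummary:
    """Distinct breeding pairs by translocation class, with fledgling totals."""

    counts: pd.DataFrame
    edges: pd.DataFrame
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)


def pair_type_summary(
    nests: list[NestRecord], pedigree: Pedigree
) -> PairTypeSummary:
    """Classify distinct breeding pairs and sum fledglings per class.

    Pair identity is the unordered breeder pair; the same pair nesting in
    several years counts once, with fledglings summed. Classes:
    translocated-translocated, translocated-local, local-local ("local" =
    any nontranslocated bird). The edge list (source, target, weight,
    pair_class) supports network plots of breeding pairs.
    """
    fledged: dict[tuple[str, str], int] = {}
    for nest in nests:
        key = tuple(sorted((nest.breeder_male, nest.breeder_female)))
        fledged[key] = fledged.get(key, 0) + len(nest.fledgling_ids)
    edges = []
    for (a, b), total in sorted(fledged.items()):
        n_transloc = sum(
            1 for i in (a, b) if i in pedigree and pedigree.record(i).origin == TRANSLOCATED
        )
        pair_class = PAIR_CLASSES[2 - n_transloc]
        edges.append(
            {"source": a, "target": b, "weight": total, "pair_class": pair_class}
        )
    edge_frame = pd.DataFrame(
        edges, columns=["source", "target", "weight", "pair_class"]
    )
    counts = (
        edge_frame.groupby("pair_class")
        .agg(pairs=("weight", "size"), fledglings=("weight", "sum"))
        .reindex(PAIR_CLASSES, fill_value=0)
    )
    graph = nx.from_pandas_edgelist(
        edge_frame, edge_attr=["weight", "pair_class"]
    ) if len(edge_frame) else nx.Graph()
    return PairTypeSummary(counts=counts, edges=edge_frame, graph=graph)


def spearman_rho(x: pd.Series, y: pd.Series) -> float:
    """Spearman rank correlation of two year-paired series (average ranks on
    ties). NaN when either series is constant (correlation undefined)."""
    x, y = pd.Series(x), pd.Series(y)
    if len(x) != len(y):
        raise ValueError("series must be paired (equal length)")
    if len(x) < 3:
        raise ValueError("need at least 3 paired years")
    if x.nunique() < 2 or y.nunique() < 2:
        return math.nan
    rho = scipy.stats.spearmanr(x.to_numpy(), y.to_numpy()).statistic
    return float(rho)
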