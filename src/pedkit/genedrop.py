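"""Single-locus gene-drop simulation and its exhaustive-enumeration twin.

Each pedigree founder carries two unique alleles (a paternal and a maternal
copy). A replicate transmits alleles down the pedigree: every non-founder
inherits one uniformly random allele from each parent. Tallies over
replicates estimate, per individual,

* ancestry: the proportion of allele copies originating in each founder
  group;
* homozygous-group probability: the fraction of replicates in which *both*
  alleles originate in a given group's founders (not the squared ancestry in
  general -- allele origins are correlated through the pedigree);
* founder-attributed inbreeding: the fraction of replicates in which the two
  alleles are the *identical copy* from a given founder, i.e. identity by
  descent traced to that founder.

:func:`enumerate_transmissions` replaces the random draws with every possible
transmission outcome (4^k for k non-founders) and produces exact versions of
the same tallies; it is the ground truth the Monte Carlo engine is tested
against on small pedigrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, FounderGroupSet, founder_groups

#: Replicate count used in the published analysis workflow.
DEFAULT_REPLICATES = 50_000


@dataclass(frozen=True)
class GeneDropResult:
    """Sufficient tallies from a gene-drop run.

    ``copies[i, f]`` counts allele copies individual i inherited from founder
    f across replicates (2R per individual in total); ``ibd[i, f]`` counts
    replicates in which i's two alleles are the identical copy from f;
    ``hom[i, g]`` counts replicates in which both of i's alleles originate in
    group g. ``exact`` marks enumeration results, where R is the number of
    enumerated outcomes rather than random replicates.
    """

    ids: list[str]
    founder_ids: list[str]
    groups: FounderGroupSet
    R: int
    seed: int | None
    copies: np.ndarray
    ibd: np.ndarray
    hom: np.ndarray
    exact: bool = False

    def __post_init__(self) -> None:
        if not np.all(self.copies.sum(axis=1) == 2 * self.R):
            raise AssertionError("allele-copy tallies do not sum to 2R")

    @property
    def group_labels(self) -> list[str]:
        return self.groups.labels

    def inbreeding_estimates(self) -> pd.Series:
        """F_P estimate per individual: fraction of replicates with IBD alleles."""
        return pd.Series(
            self.ibd.sum(axis=1) / self.R, index=self.ids, name="F_P_genedrop"
        )


def _propagate(
    pedigree: Pedigree,
    picks: "callable",
    R: int,
) -> tuple[np.ndarray, list[str]]:
    """Transmit alleles down the pedigree.

    ``picks(parent_role_index)`` yields, for each successive non-founder
    meiosis, an integer array of shape (R,) in {0, 1} selecting which of the
    parent's two alleles is transmitted. Returns the (n, R, 2) int32 array of
    allele ids (founder k holds alleles 2k and 2k+1) and the founder list.
    """
    ids = pedigree.ids
    idx = pedigree.index
    founders = pedigree.founders
    founder_no = {f: k for k, f in enumerate(founders)}
    alleles = np.empty((len(ids), R, 2), dtype=np.int32)
    rows = np.arange(R)
    for i in ids:
        k = idx[i]
        sire, dam = pedigree.parents(i)
        if sire is None:
            f = founder_no[i]
            alleles[k, :, 0] = 2 * f
            alleles[k, :, 1] = 2 * f + 1
        else:
            alleles[k, :, 0] = alleles[idx[sire], rows, picks()]
            alleles[k, :, 1] = alleles[idx[dam], rows, picks()]
    return alleles, founders


def _tally(
    pedigree: Pedigree,
    alleles: np.ndarray,
    founders: list[str],
    groups: FounderGroupSet,
    R: int,
    seed: int | None,
    exact: bool,
) -> GeneDropResult:
    n, F = len(pedigree), len(founders)
    labels = groups.labels
    gidx = np.empty(F, dtype=np.int64)
    for k, f in enumerate(founders):
        gidx[k] = labels.index(groups.group_of(f))
    origin = alleles >> 1  # founder index of each allele copy
    copies = np.zeros((n, F), dtype=np.int64)
    ibd = np.zeros((n, F), dtype=np.int64)
    hom = np.zeros((n, len(labels)), dtype=np.int64)
    for k in range(n):
        copies[k] = np.bincount(origin[k].ravel(), minlength=F)
        same_copy = alleles[k, :, 0] == alleles[k, :, 1]
        if same_copy.any():
            ibd[k] = np.bincount(origin[k, same_copy, 0], minlength=F)
        ga = gidx[origin[k]]
        same_group = ga[:, 0] == ga[:, 1]
        hom[k] = np.bincount(ga[same_group, 0], minlength=len(labels))
    return GeneDropResult(
        ids=pedigree.ids,
        founder_ids=founders,
        groups=groups,
        R=R,
        seed=seed,
        copies=copies,
        ibd=ibd,
        hom=hom,
        exact=exact,
    )


def run_genedrop(
    pedigree: Pedigree,
    R: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    groups: FounderGroupSet | None = None,
) -> GeneDropResult:
    """Monte Carlo gene drop with R replicates.

    Reproducible bit-for-bit given (seed, R, pedigree order): transmission
    draws are consumed in topological order from a single seeded generator.
    """
    if R < 1:
        raise ValueError("replicate count R must be >= 1")
    if groups is None:
        groups = founder_groups(pedigree)
    rng = np.random.default_rng(seed)
    alleles, founders = _propagate(
        pedigree, lambda: rng.integers(0, 2, size=R, dtype=np.int8), R
    )
    return _tally(pedigree, alleles, founders, groups, R, seed, exact=False)


def count_meioses(pedigree: Pedigree) -> int:
    """Number of parent-to-offspring transmissions (2 per non-founder)."""
    return 2 * (len(pedigree) - len(pedigree.founders))


def enumerate_transmissions(
    pedigree: Pedigree,
    groups: FounderGroupSet | None = None,
    max_meioses: int = 20,
) -> GeneDropResult:
    """Exact tallies from exhaustive enumeration of all 2^k meiosis outcomes.

    Every downstream estimator (ancestry, homozygous-group probability,
    founder-attributed IBD, F_P) applied to the result is exact, with the
    outcome count playing the role of R. Feasible only for small pedigrees;
    refuses pedigrees with more than ``max_meioses`` meioses (2^20 outcomes).
    """
    k = count_meioses(pedigree)
    if k > max_meioses:
        raise ValueError(
            f"pedigree has {k} meioses; enumeration capped at {max_meioses}"
        )
    if groups is None:
        groups = founder_groups(pedigree)
    total = 2**k
    outcome = np.arange(total, dtype=np.int64)
    bit = iter(range(k))

    def picks() -> np.ndarray:
        return ((outcome >> next(bit)) & 1).astype(np.int8)

    alleles, founders = _propagate(pedigree, picks, total)
    return _tally(pedigree, alleles, founders, groups, total, None, exact=True)


def ancestry_proportions(result: GeneDropResult) -> "AncestryMatrix":
    """Individual x founder-group ancestry proportions from gene-drop tallies.

    Rows sum to 1 exactly (integer tally identity). Standard errors are the
    binomial SE of each proportion on 2R draws (zero for exact results).
    """
    labels = result.group_labels
    F = len(result.founder_ids)
    group_cols = np.zeros((F, len(labels)), dtype=np.int64)
    for k, f in enumerate(result.founder_ids):
        group_cols[k, labels.index(result.groups.group_of(f))] = 1
    counts = result.copies @ group_cols
    prop = counts / (2 * result.R)
    if result.exact:
        se = np.zeros_like(prop)
    else:
        se = np.sqrt(prop * (1 - prop) / (2 * result.R))
    return AncestryMatrix(
        proportions=pd.DataFrame(prop, index=result.ids, columns=labels),
        se=pd.DataFrame(se, index=result.ids, columns=labels),
        source="enumeration" if result.exact else "genedrop",
    )


@dataclass(frozen=True)
class AncestryMatrix:
    """Expected ancestry proportions (individuals x founder groups).

    ``source`` records provenance: "genedrop" (Monte Carlo estimate),
    "enumeration" (exact, small pedigrees), or "exact" (recursion).
    """

    proportions: pd.DataFrame
    se: pd.DataFrame | None = None
    source: str = "genedrop"

    @property
    def nontranslocated_label(self) -> str:
        from .pedigree import NONTRANSLOCATED

        return NONTRANSLOCATED


def translocation_ancestry(matrix: AncestryMatrix) -> pd.Series:
    """Proportion of each individual's genome inherited from translocated
    founders: the complement of the nontranslocated ancestry column."""
    label = matrix.nontranslocated_label
    if label not in matrix.proportions.columns:
        raise ValueError(f"ancestry matrix has no {label!r} column")
    return (1.0 - matrix.proportions[label]).rename("translocation_ancestry")


def prob_homozygous_group(result: GeneDropResult, group: str) -> pd.Series:
    """Per-individual probability that both alleles originate in ``group``.

    Proportion of replicates in which both inherited allele copies trace to
    founders of the group. Because allele origins are correlated through the
    pedigree, this is generally NOT the squared group-ancestry proportion.
    """
    labels = result.group_labels
    if group not in labels:
        raise KeyError(group)
    col = labels.index(group)
    return pd.Series(
        result.hom[:, col] / result.R, index=result.ids, name=f"P_hom[{group}]"
    )


@dataclass(frozen=True)
class InbreedingAttribution:
    """Founder x year matrix of founder-attributed IBD probability.

    Entry (f, t) is the probability that a randomly chosen individual of year
    t's population carries two identical allele copies from founder f at a
    random locus. Summed over founders it equals the population's mean F_P
    (within Monte Carlo error for simulated tallies).
    """

    values: pd.DataFrame
    se: pd.DataFrame | None
    population_sizes: pd.Series


def founder_inbreeding_attribution(
    result: GeneDropResult, census: "CensusTable"
) -> InbreedingAttribution:
    """Attribute each census year's pedigree inbreeding to founders.

    entry(f, t) = mean over replicates of (number of year-t individuals whose
    two alleles are the identical copy from f) / N_t. Empty census years are
    emitted as missing.
    """
    idx = {i: k for k, i in enumerate(result.ids)}
    years = census.years
    F = len(result.founder_ids)
    values = pd.DataFrame(np.nan, index=result.founder_ids, columns=years)
    se = pd.DataFrame(np.nan, index=result.founder_ids, columns=years)
    sizes = pd.Series(0, index=years, dtype=int, name="N")
    for year, sub in census.frame.groupby("year"):
        members = sub["id"].tolist()
        missing = [m for m in members if m not in idx]
        if missing:
            raise ValueError(f"census year {year}: not in pedigree: {missing[:3]}")
        rows = [idx[m] for m in members]
        n_t = len(rows)
        sizes.loc[year] = n_t
        counts = result.ibd[rows, :]  # (n_t, F) replicate tallies
        p = counts / result.R
        values[year] = p.mean(axis=0)
        if result.exact:
            se[year] = 0.0
        else:
            # SE of the mean of per-individual binomial proportions.
            se[year] = np.sqrt((p * (1 - p) / result.R).sum(axis=0)) / n_t
    return InbreedingAttribution(values=values, se=se, population_sizes=sizes)
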