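"""Pedigree data model, validation, and ordering.

A :class:`Pedigree` is a directed acyclic parent--offspring structure with
per-individual metadata (sex, origin, donor population, years). Pedigree
*founders* are individuals without recorded parents: the residents present at
the start of monitoring, occasional natural migrants, and translocated birds.
Founders are partitioned into labeled *founder groups* (one group per
translocation donor population plus a pooled "nontranslocated" group), the
unit at which ancestry and genetic contributions are reported.

Half-founders (exactly one recorded parent) are completed with a synthetic
unknown founder so that every individual carries 0 or 2 parents, the contract
required by the relationship-matrix recursion and by gene-drop transmission.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"
SEXES = frozenset({MALE, FEMALE, UNKNOWN})

LOCAL = "local"
TRANSLOCATED = "translocated"
NATURAL_MIGRANT = "natural_migrant"
ORIGINS = frozenset({LOCAL, TRANSLOCATED, NATURAL_MIGRANT})

#: Label of the pooled founder group holding original residents and migrants.
NONTRANSLOCATED = "nontranslocated"

#: Prefix marking synthetic unknown parents created for half-founders.
SYNTHETIC_PREFIX = "SYN-"


class PedigreeError(ValueError):
    """Structural or metadata error in a pedigree."""


@dataclass(frozen=True)
class IndividualRecord:
    """One row of a pedigree table.

    ``donor_population`` and ``translocation_year`` are required iff
    ``origin == "translocated"``; translocated individuals carry no recorded
    parents (they enter the pedigree as founders).
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN
    origin: str = LOCAL
    donor_population: str | None = None
    translocation_year: int | None = None
    birth_year: int | None = None
    last_year: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be a non-empty string")
        if self.sex not in SEXES:
            raise PedigreeError(f"{self.id}: unknown sex {self.sex!r}")
        if self.origin not in ORIGINS:
            raise PedigreeError(f"{self.id}: unknown origin {self.origin!r}")
        if self.sire_id is not None and self.sire_id == self.dam_id:
            raise PedigreeError(f"{self.id}: sire and dam are both {self.sire_id!r}")
        if self.origin == TRANSLOCATED:
            if self.donor_population is None:
                raise PedigreeError(f"{self.id}: translocated but no donor_population")
            if self.translocation_year is None:
                raise PedigreeError(f"{self.id}: translocated but no translocation_year")
            if self.sire_id is not None or self.dam_id is not None:
                raise PedigreeError(
                    f"{self.id}: translocated individuals cannot have recorded parents"
                )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def is_synthetic(self) -> bool:
        return self.id.startswith(SYNTHETIC_PREFIX)


@dataclass(frozen=True)
class TranslocationCohort:
    """Individuals released at a single translocation event (one year, one donor)."""

    year: int
    donor_population: str
    member_ids: frozenset[str]

    @property
    def label(self) -> str:
        return f"{self.year} {self.donor_population}"

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class FounderGroupSet:
    """Partition of pedigree founders into labeled groups.

    Exactly one label (``nontranslocated_label``) pools the original
    residents and natural migrants; every other label is a donor population.
    """

    groups: Mapping[str, frozenset[str]]
    nontranslocated_label: str = NONTRANSLOCATED

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise PedigreeError(
                    f"founder groups are not disjoint: {sorted(overlap)[:3]} "
                    f"appear in more than one group (second: {label!r})"
                )
            seen |= set(members)
        if self.nontranslocated_label not in self.groups:
            raise PedigreeError(
                f"no {self.nontranslocated_label!r} group in founder group set"
            )

    @property
    def labels(self) -> list[str]:
        """Group labels, donor populations sorted first, nontranslocated last."""
        donors = sorted(l for l in self.groups if l != self.nontranslocated_label)
        return donors + [self.nontranslocated_label]

    @property
    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out |= set(members)
        return frozenset(out)

    def group_of(self, individual_id: str) -> str:
        for label, members in self.groups.items():
            if individual_id in members:
                return label
        raise KeyError(individual_id)


@dataclass
class BuildReport:
    """Summary of pedigree construction and validation."""

    n_records: int = 0
    n_founders: int = 0
    n_half_founders_completed: int = 0
    n_generations: int = 0
    warnings: list[str] = field(default_factory=list)


class Pedigree:
    """Validated pedigree with a fixed topological order.

    Construct via :func:`build_pedigree`, never directly. After construction
    every individual has exactly 0 or 2 parents, every referenced parent
    exists, and ``ids`` lists individuals with all parents before offspring
    (ties broken by id sort).
    """

    def __init__(
        self,
        records: dict[str, IndividualRecord],
        order: list[str],
        report: BuildReport,
    ) -> None:
        self._records = records
        self._order = order
        self.report = report
        self.index = {i: k for k, i in enumerate(order)}
        self._depth: dict[str, int] = {}
        for i in order:
            rec = records[i]
            if rec.is_founder:
                self._depth[i] = 0
            else:
                self._depth[i] = 1 + max(
                    self._depth[rec.sire_id], self._depth[rec.dam_id]
                )
        report.n_generations = (max(self._depth.values()) + 1) if order else 0

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._records

    @property
    def ids(self) -> list[str]:
        """All ids in topological order."""
        return list(self._order)

    @property
    def founders(self) -> list[str]:
        return [i for i in self._order if self._records[i].is_founder]

    def record(self, individual_id: str) -> IndividualRecord:
        return self._records[individual_id]

    def parents(self, individual_id: str) -> tuple[str | None, str | None]:
        rec = self._records[individual_id]
        return rec.sire_id, rec.dam_id

    def depth(self, individual_id: str) -> int:
        """0 for founders, else 1 + max parental depth."""
        return self._depth[individual_id]

    def is_founder(self, individual_id: str) -> bool:
        return self._records[individual_id].is_founder

    def to_frame(self) -> pd.DataFrame:
        """Serialize to the canonical tabular schema (topological row order)."""
        rows = []
        for i in self._order:
            r = self._records[i]
            rows.append(
                {
                    "id": r.id,
                    "sire": r.sire_id,
                    "dam": r.dam_id,
                    "sex": r.sex,
                    "origin": r.origin,
                    "donor_population": r.donor_population,
                    "translocation_year": r.translocation_year,
                    "birth_year": r.birth_year,
                    "last_year": r.last_year,
                }
            )
        frame = pd.DataFrame(
            rows,
            columns=[
                "id", "sire", "dam", "sex", "origin", "donor_population",
                "translocation_year", "birth_year", "last_year",
            ],
        )
        for col in ("translocation_year", "birth_year", "last_year"):
            frame[col] = frame[col].astype("Int64")  # keep integers despite NA
        return frame


def _find_cycle(records: dict[str, IndividualRecord], stuck: set[str]) -> list[str]:
    """Return one parent-chain cycle among ids that could not be ordered."""
    start = sorted(stuck)[0]
    seen: dict[str, int] = {}
    chain: list[str] = []
    cur = start
    while cur not in seen:
        seen[cur] = len(chain)
        chain.append(cur)
        rec = records[cur]
        nxt = [p for p in (rec.sire_id, rec.dam_id) if p in stuck]
        if not nxt:  # pragma: no cover - stuck set always has in-cycle parents
            break
        cur = sorted(nxt)[0]
    return chain[seen.get(cur, 0):] + [cur]


def build_pedigree(records: Iterable[IndividualRecord]) -> Pedigree:
    """Validate records and build a :class:`Pedigree`.

    Raises :class:`PedigreeError` on duplicate ids, references to absent
    parents, or cycles (an individual that is its own ancestor). Half-founders
    are completed with a synthetic unknown parent assigned to the
    nontranslocated pool; the count is reported in ``Pedigree.report``.
    """
    report = BuildReport()
    by_id: dict[str, IndividualRecord] = {}
    for rec in records:
        if rec.id in by_id:
            raise PedigreeError(f"duplicate individual id {rec.id!r}")
        by_id[rec.id] = rec
    report.n_records = len(by_id)

    # Complete half-founders with synthetic unknown parents.
    for rec in list(by_id.values()):
        if (rec.sire_id is None) != (rec.dam_id is None):
            missing_role = "sire" if rec.sire_id is None else "dam"
            syn_id = f"{SYNTHETIC_PREFIX}{missing_role}-of-{rec.id}"
            if syn_id in by_id:
                raise PedigreeError(f"synthetic parent id collision: {syn_id!r}")
            by_id[syn_id] = IndividualRecord(
                id=syn_id,
                sex=MALE if missing_role == "sire" else FEMALE,
                origin=LOCAL,
            )
            by_id[rec.id] = replace(rec, **{f"{missing_role}_id": syn_id})
            report.n_half_founders_completed += 1

    # Referential integrity and sex-role consistency.
    for rec in by_id.values():
        for role, parent_id in (("sire", rec.sire_id), ("dam", rec.dam_id)):
            if parent_id is None:
                continue
            if parent_id not in by_id:
                raise PedigreeError(
                    f"{rec.id}: {role} {parent_id!r} has no pedigree record"
                )
            expected = MALE if role == "sire" else FEMALE
            psex = by_id[parent_id].sex
            if psex != UNKNOWN and psex != expected:
                msg = f"{rec.id}: {role} {parent_id} has recorded sex {psex}"
                report.warnings.append(msg)
                warnings.warn(msg, stacklevel=2)

    # Kahn's algorithm; ready ids drawn smallest-first for determinism.
    children: dict[str, list[str]] = {i: [] for i in by_id}
    pending: dict[str, int] = {}
    for rec in by_id.values():
        n_parents = sum(p is not None for p in (rec.sire_id, rec.dam_id))
        pending[rec.id] = n_parents
        for p in (rec.sire_id, rec.dam_id):
            if p is not None:
                children[p].append(rec.id)
    ready = [i for i, n in pending.items() if n == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        i = heapq.heappop(ready)
        order.append(i)
        for c in children[i]:
            pending[c] -= 1
            if pending[c] == 0:
                heapq.heappush(ready, c)
    if len(order) < len(by_id):
        stuck = {i for i, n in pending.items() if n > 0}
        cycle = _find_cycle(by_id, stuck)
        raise PedigreeError(
            "pedigree contains a cycle (individual is its own ancestor): "
            + " -> ".join(cycle)
        )

    report.n_founders = sum(1 for r in by_id.values() if r.is_founder)
    return Pedigree(by_id, order, report)


def topological_order(pedigree: Pedigree) -> list[str]:
    """Ids ordered so every parent precedes all of its offspring.

    Deterministic: among individuals whose parents are already placed, the
    smallest id comes first.
    """
    return pedigree.ids


def founder_groups(
    pedigree: Pedigree, separate_migrants: bool = False
) -> FounderGroupSet:
    """Partition founders into donor populations plus the nontranslocated pool.

    Local founders and natural migrants are pooled as ``nontranslocated``
    unless ``separate_migrants`` promotes migrants to their own group.
    Raises if a non-founder carries a donor label (metadata inconsistency).
    """
    groups: dict[str, set[str]] = {NONTRANSLOCATED: set()}
    if separate_migrants:
        groups[NATURAL_MIGRANT] = set()
    for i in pedigree.ids:
        rec = pedigree.record(i)
        if not rec.is_founder:
            if rec.donor_population is not None:
                raise PedigreeError(
                    f"{i}: non-founder carries donor label {rec.donor_population!r}"
                )
            continue
        if rec.origin == TRANSLOCATED:
            groups.setdefault(rec.donor_population, set()).add(i)
        elif rec.origin == NATURAL_MIGRANT and separate_migrants:
            groups[NATURAL_MIGRANT].add(i)
        else:
            groups[NONTRANSLOCATED].add(i)
    return FounderGroupSet({k: frozenset(v) for k, v in groups.items()})


def translocation_cohorts(pedigree: Pedigree) -> list[TranslocationCohort]:
    """Group translocated founders into cohorts by (year, donor population)."""
    members: dict[tuple[int, str], set[str]] = {}
    for i in pedigree.ids:
        rec = pedigree.record(i)
        if rec.origin == TRANSLOCATED:
            key = (rec.translocation_year, rec.donor_population)
            members.setdefault(key, set()).add(i)
    return [
        TranslocationCohort(year=y, donor_population=d, member_ids=frozenset(m))
        for (y, d), m in sorted(members.items())
    ]
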