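"""Individual-based simulator of a monitored cooperative-breeder population.

Emulates the study system the analysis modules expect: annual clusters each
holding at most one monogamous breeding pair plus up to four helpers,
sex-differential annual survival, fall translocation cohorts of subadults
from labeled donor populations with imperfect establishment, occasional
natural migrants, and zero-inflated reproduction. The annual cycle is

    survive -> fill breeding vacancies -> nest & fledge -> census ->
    juvenile dispersal -> fall releases,

so released birds can first appear in the census of the year *after* their
release, matching the establishment definition used by the demography
module. Translocation ancestry may affect survival (additive on the logit
scale) and fecundity (multiplicative on the log mean), giving known ground
truth for effect-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import CensusTable, NestRecord
from .pedigree import (
    FEMALE,
    LOCAL,
    MALE,
    NATURAL_MIGRANT,
    TRANSLOCATED,
    IndividualRecord,
    Pedigree,
    TranslocationCohort,
    build_pedigree,
)

#: Study-shaped release schedule: 11 events, sizes 1-10 (54 birds total),
#: six donor labels, spanning 19 calendar years.
DEFAULT_SCHEDULE: tuple[tuple[int, str, int], ...] = (
    (1998, "ANF", 10),
    (1999, "ANF", 6),
    (2001, "FTB", 2),
    (2003, "FTB", 4),
    (2005, "OSC", 6),
    (2008, "ANF", 8),
    (2009, "CBJTC", 4),
    (2010, "FTS", 6),
    (2012, "OHA", 1),
    (2015, "FTS", 4),
    (2016, "FTS", 3),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults mirror the monitored system's shape: 29 monitoring years,
    releases per :data:`DEFAULT_SCHEDULE`, establishment probability 0.7,
    male annual survival above female. ``ancestry_survival_logit`` is the
    additive logit-scale survival effect of full translocation ancestry;
    ``ancestry_fecundity_log`` the log-scale effect on nest mean fledglings.
    """

    start_year: int = 1994
    years: int = 29
    n_clusters: int = 40
    initial_occupied: int = 20
    initial_helpers_mean: float = 0.8
    survival_female: float = 0.71
    survival_male: float = 0.80
    ancestry_survival_logit: float = 0.0
    ancestry_fecundity_log: float = 0.0
    establishment_prob: float = 0.7
    mean_fledglings: float = 1.6
    zero_nest_prob: float = 0.25
    helper_retention: float = 0.4
    max_helpers: int = 4
    migrant_prob: float = 0.02
    translocations: tuple[tuple[int, str, int], ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "survival_female", "survival_male", "establishment_prob",
            "zero_nest_prob", "helper_retention", "migrant_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.years < 2:
            raise ValueError("need at least 2 monitoring years")
        for year, donor, size in self.translocations:
            if size < 1:
                raise ValueError(f"cohort size {size} < 1 ({year} {donor})")

    @property
    def last_year(self) -> int:
        return self.start_year + self.years - 1


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic data."""

    individuals: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulationResult:
    pedigree: Pedigree
    census: CensusTable
    nests: list[NestRecord]
    cohorts: list[TranslocationCohort]
    truth: TruthTable
    extinct_year: int | None = None


@dataclass
class _Bird:
    id: str
    sex: str
    birth_year: int | None
    origin: str = LOCAL
    donor: str | None = None
    translocation_year: int | None = None
    sire: str | None = None
    dam: str | None = None
    ancestry: float = 0.0  # true translocation ancestry
    alive: bool = True
    fledglings: int = 0


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class _Population:
    """Mutable simulation state: clusters, floaters, all birds ever created."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        self.rng = rng
        self.birds: dict[str, _Bird] = {}
        self.clusters: list[dict] = [
            {"male": None, "female": None, "helpers": []}
            for _ in range(cfg.n_clusters)
        ]
        self.floaters: list[str] = []
        self._serial = 0

    def new_id(self, prefix: str) -> str:
        self._serial += 1
        return f"{prefix}{self._serial:04d}"

    def add(self, bird: _Bird) -> _Bird:
        self.birds[bird.id] = bird
        return bird

    def age(self, bird_id: str, year: int) -> int:
        by = self.birds[bird_id].birth_year
        return 99 if by is None else year - by

    def survival_prob(self, bird: _Bird) -> float:
        base = (
            self.cfg.survival_male if bird.sex == MALE else self.cfg.survival_female
        )
        if base <= 0.0 or base >= 1.0:  # degenerate limits: logit undefined
            return base
        return _expit(_logit(base) + self.cfg.ancestry_survival_logit * bird.ancestry)

    def living(self) -> list[str]:
        ids = []
        for c in self.clusters:
            ids.extend(i for i in (c["male"], c["female"]) if i is not None)
            ids.extend(c["helpers"])
        ids.extend(self.floaters)
        return ids


def _initialize(pop: _Population) -> None:
    cfg, rng = pop.cfg, pop.rng
    for c in pop.clusters[: cfg.initial_occupied]:
        for sex, slot in ((MALE, "male"), (FEMALE, "female")):
            bird = pop.add(
                _Bird(
                    id=pop.new_id("F"),
                    sex=sex,
                    birth_year=cfg.start_year - int(rng.integers(1, 5)),
                )
            )
            c[slot] = bird.id
        for _ in range(min(cfg.max_helpers, rng.poisson(cfg.initial_helpers_mean))):
            sex = MALE if rng.random() < 0.5 else FEMALE
            helper = pop.add(
                _Bird(
                    id=pop.new_id("F"),
                    sex=sex,
                    birth_year=cfg.start_year - int(rng.integers(1, 3)),
                )
            )
            c["helpers"].append(helper.id)


def _apply_mortality(pop: _Population, year: int) -> None:
    rng = pop.rng
    dead: set[str] = set()
    for i in pop.living():
        bird = pop.birds[i]
        if bird.translocation_year == year - 1:
            # Establishment already decided at release: birds that joined the
            # population are guaranteed their first post-release census.
            continue
        if rng.random() >= pop.survival_prob(bird):
            bird.alive = False
            dead.add(i)
    for c in pop.clusters:
        for slot in ("male", "female"):
            if c[slot] in dead:
                c[slot] = None
        c["helpers"] = [h for h in c["helpers"] if h not in dead]
    pop.floaters = [f for f in pop.floaters if f not in dead]


def _fill_vacancies(pop: _Population, year: int) -> None:
    """Fill breeder vacancies from same-cluster helpers (oldest first), then
    floaters (oldest first); then let floater pairs colonize empty clusters."""

    def oldest(ids: list[str], sex: str) -> str | None:
        adults = [
            i for i in ids
            if pop.birds[i].sex == sex and pop.age(i, year) >= 1
        ]
        if not adults:
            return None
        return max(adults, key=lambda i: (pop.age(i, year), i))

    for c in pop.clusters:
        occupied = c["male"] is not None or c["female"] is not None or c["helpers"]
        if not occupied:
            continue
        for sex, slot in ((MALE, "male"), (FEMALE, "female")):
            if c[slot] is not None:
                continue
            candidate = oldest(c["helpers"], sex)
            if candidate is not None:
                c["helpers"].remove(candidate)
            else:
                candidate = oldest(pop.floaters, sex)
                if candidate is not None:
                    pop.floaters.remove(candidate)
            c[slot] = candidate
    for c in pop.clusters:
        if c["male"] is None and c["female"] is None and not c["helpers"]:
            m = oldest(pop.floaters, MALE)
            f = oldest(pop.floaters, FEMALE)
            if m is None or f is None:
                break
            pop.floaters.remove(m)
            pop.floaters.remove(f)
            c["male"], c["female"] = m, f


def _nesting(pop: _Population, year: int) -> tuple[list[NestRecord], list[str]]:
    cfg, rng = pop.cfg, pop.rng
    nests: list[NestRecord] = []
    juveniles: list[str] = []
    for k, c in enumerate(pop.clusters):
        if c["male"] is None or c["female"] is None:
            continue
        sire, dam = pop.birds[c["male"]], pop.birds[c["female"]]
        pair_ancestry = 0.5 * (sire.ancestry + dam.ancestry)
        if rng.random() < cfg.zero_nest_prob:
            n_fledged = 0
        else:
            mean = cfg.mean_fledglings * math.exp(
                cfg.ancestry_fecundity_log * pair_ancestry
            )
            n_fledged = int(rng.poisson(mean))
        fledgling_ids = []
        for _ in range(n_fledged):
            chick = pop.add(
                _Bird(
                    id=pop.new_id("L"),
                    sex=MALE if rng.random() < 0.5 else FEMALE,
                    birth_year=year,
                    sire=sire.id,
                    dam=dam.id,
                    ancestry=pair_ancestry,
                )
            )
            fledgling_ids.append(chick.id)
            juveniles.append(chick.id)
        sire.fledglings += n_fledged
        dam.fledglings += n_fledged
        nests.append(
            NestRecord(
                year=year,
                cluster=f"C{k:02d}",
                breeder_male=sire.id,
                breeder_female=dam.id,
                fledgling_ids=tuple(fledgling_ids),
            )
        )
    return nests, juveniles


def _census(pop: _Population, year: int, juveniles: list[str]) -> list[dict]:
    rows = []
    juvenile_set = set(juveniles)
    for k, c in enumerate(pop.clusters):
        cluster_id = f"C{k:02d}"
        for slot in ("male", "female"):
            if c[slot] is not None:
                rows.append(
                    {"year": year, "id": c[slot], "cluster": cluster_id,
                     "role": "breeder"}
                )
        for h in c["helpers"]:
            rows.append(
                {"year": year, "id": h, "cluster": cluster_id, "role": "helper"}
            )
    for j in juveniles:
        bird = pop.birds[j]
        natal = next(
            (f"C{k:02d}" for k, c in enumerate(pop.clusters)
             if c["male"] == bird.sire or c["female"] == bird.dam),
            "floaters",
        )
        rows.append({"year": year, "id": j, "cluster": natal, "role": "juvenile"})
    for f in pop.floaters:
        if f in juvenile_set:
            continue
        rows.append({"year": year, "id": f, "cluster": "floaters", "role": "floater"})
    return rows


def _disperse_juveniles(pop: _Population, juveniles: list[str]) -> None:
    cfg, rng = pop.cfg, pop.rng
    for j in juveniles:
        bird = pop.birds[j]
        natal = next(
            (c for c in pop.clusters if c["male"] == bird.sire or c["female"] == bird.dam),
            None,
        )
        if (
            natal is not None
            and len(natal["helpers"]) < cfg.max_helpers
            and rng.random() < cfg.helper_retention
        ):
            natal["helpers"].append(j)
        else:
            pop.floaters.append(j)


def _release_cohort(
    pop: _Population, year: int, donor: str, size: int
) -> TranslocationCohort:
    cfg, rng = pop.cfg, pop.rng
    member_ids = []
    for k in range(size):
        # Pairs released together; odd cohorts carry an extra female (the
        # single-female release strategy).
        sex = MALE if k % 2 == 1 else FEMALE
        bird = pop.add(
            _Bird(
                id=f"T-{donor}-{year}-{pop.new_id('')}",
                sex=sex,
                birth_year=year,
                origin=TRANSLOCATED,
                donor=donor,
                translocation_year=year,
                ancestry=1.0,
            )
        )
        member_ids.append(bird.id)
        if rng.random() < cfg.establishment_prob:
            pop.floaters.append(bird.id)
        else:
            bird.alive = False
    return TranslocationCohort(
        year=year, donor_population=donor, member_ids=frozenset(member_ids)
    )


def simulate_population(cfg: SimulationConfig) -> SimulationResult:
    """Run the annual-cycle simulation and emit analysis-ready artifacts.

    Outputs pass the validators of the pedigree and census modules; every
    fledgling's pedigree parents equal its nest's breeders. Deterministic
    given ``cfg`` (including ``cfg.seed``). If the population goes extinct,
    the remaining census years are empty and ``extinct_year`` records the
    first empty year.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = _Population(cfg, rng)
    _initialize(pop)
    census_rows: list[dict] = []
    nests: list[NestRecord] = []
    cohorts: list[TranslocationCohort] = []
    schedule: dict[int, list[tuple[str, int]]] = {}
    for year, donor, size in cfg.translocations:
        schedule.setdefault(year, []).append((donor, size))
    extinct_year: int | None = None

    for year in range(cfg.start_year, cfg.last_year + 1):
        if year > cfg.start_year:
            _apply_mortality(pop, year)
        if cfg.migrant_prob and rng.random() < cfg.migrant_prob:
            migrant = pop.add(
                _Bird(
                    id=pop.new_id("M"),
                    sex=MALE if rng.random() < 0.5 else FEMALE,
                    birth_year=None,
                    origin=NATURAL_MIGRANT,
                )
            )
            pop.floaters.append(migrant.id)
        _fill_vacancies(pop, year)
        year_nests, juveniles = _nesting(pop, year)
        nests.extend(year_nests)
        census_rows.extend(_census(pop, year, juveniles))
        _disperse_juveniles(pop, juveniles)
        for donor, size in schedule.get(year, []):
            cohorts.append(_release_cohort(pop, year, donor, size))
        if extinct_year is None and not pop.living():
            extinct_year = year + 1 if year < cfg.last_year else None

    census = CensusTable(pd.DataFrame(
        census_rows, columns=["year", "id", "cluster", "role"]
    ))
    last_seen = census.frame.groupby("id")["year"].max().to_dict()
    first_seen = census.frame.groupby("id")["year"].min().to_dict()
    records = [
        IndividualRecord(
            id=b.id,
            sire_id=b.sire,
            dam_id=b.dam,
            sex=b.sex,
            origin=b.origin,
            donor_population=b.donor,
            translocation_year=b.translocation_year,
            birth_year=b.birth_year,
            last_year=last_seen.get(b.id),
        )
        for b in pop.birds.values()
    ]
    pedigree = build_pedigree(records)
    truth_frame = pd.DataFrame(
        [
            {
                "id": b.id,
                "sex": b.sex,
                "origin": b.origin,
                "donor_population": b.donor,
                "ancestry": b.ancestry,
                "first_year": first_seen.get(b.id),
                "last_year": last_seen.get(b.id),
                "lifetime_fledglings": b.fledglings,
                "established": b.id in first_seen,
            }
            for b in pop.birds.values()
        ]
    ).set_index("id")
    return SimulationResult(
        pedigree=pedigree,
        census=census,
        nests=nests,
        cohorts=cohorts,
        truth=TruthTable(individuals=truth_frame, config=cfg),
        extinct_year=extinct_year,
    )


def naive_survival_by_ancestry(
    truth: TruthTable, census: CensusTable, high_threshold: float = 0.5
) -> dict[str, float]:
    """Naive annual survival (census-presence based, no detection model) for
    zero-ancestry vs high-ancestry (>= threshold) individuals.

    For each individual-year with a following census year, survival = present
    again next year. Returns per-class rates and their difference
    (high - zero); NaN where a class has no exposure years.
    """
    years = census.years
    if len(years) < 2:
        raise ValueError("need >= 2 census years")
    by_year = {
        y: set(census.frame.loc[census.frame["year"] == y, "id"]) for y in years
    }
    ancestry = truth.individuals["ancestry"]
    survived = {"zero": 0, "high": 0}
    exposed = {"zero": 0, "high": 0}
    for y, y_next in zip(years[:-1], years[1:]):
        for i in by_year[y]:
            a = ancestry.loc[i]
            if a == 0.0:
                cls = "zero"
            elif a >= high_threshold:
                cls = "high"
            else:
                continue
            exposed[cls] += 1
            survived[cls] += i in by_year[y_next]
    rates = {
        cls: (survived[cls] / exposed[cls]) if exposed[cls] else math.nan
        for cls in ("zero", "high")
    }
    return {
        "survival_zero": rates["zero"],
        "survival_high": rates["high"],
        "difference": rates["high"] - rates["zero"],
        "exposure_zero": exposed["zero"],
        "exposure_high": exposed["high"],
    }


def recovery_summary(
    truth: TruthTable,
    census: CensusTable,
    ancestry_estimates: pd.Series | None = None,
) -> dict[str, float]:
    """Effect-direction and bias report for a simulated population.

    Reports the naive annual-survival difference between high- and
    zero-translocation-ancestry individuals, the lifetime-fledgling
    difference between the same classes, whether the signs match the
    configured effects, and (when gene-drop or recursion ancestry estimates
    are supplied) the maximum absolute ancestry estimation error vs truth.
    """
    cfg = truth.config
    surv = naive_survival_by_ancestry(truth, census)
    ind = truth.individuals
    high = ind.loc[ind["ancestry"] >= 0.5, "lifetime_fledglings"]
    zero = ind.loc[ind["ancestry"] == 0.0, "lifetime_fledglings"]
    fled_diff = (
        float(high.mean() - zero.mean()) if len(high) and len(zero) else math.nan
    )
    out = dict(surv)
    out["fledgling_difference"] = fled_diff
    out["survival_sign_matches"] = float(
        np.sign(out["difference"]) == np.sign(cfg.ancestry_survival_logit)
        if cfg.ancestry_survival_logit != 0
        else math.nan
    )
    if ancestry_estimates is not None:
        joint = pd.concat(
            [ancestry_estimates.rename("est"), ind["ancestry"]], axis=1
        ).dropna()
        out["ancestry_max_abs_error"] = float(
            (joint["est"] - joint["ancestry"]).abs().max()
        )
    return out


def random_pedigree(
    n_founders: int,
    n_nonfounders: int,
    seed: int | None = None,
    translocated_fraction: float = 0.0,
) -> Pedigree:
    """Small random valid pedigree for property tests and oracles.

    Founders get alternating sexes (at least one of each); each non-founder
    draws its sire uniformly from existing males and its dam from existing
    females, so the structure is acyclic by construction and inbred loops
    arise naturally. ``translocated_fraction`` of founders are labeled as a
    single-donor release cohort.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders (one per sex)")
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    males, females = [], []
    for k in range(n_founders):
        sex = MALE if k % 2 == 0 else FEMALE
        translocated = rng.random() < translocated_fraction
        records.append(
            IndividualRecord(
                id=f"F{k:03d}",
                sex=sex,
                origin=TRANSLOCATED if translocated else LOCAL,
                donor_population="DON" if translocated else None,
                translocation_year=2000 if translocated else None,
            )
        )
        (males if sex == MALE else females).append(f"F{k:03d}")
    for k in range(n_nonfounders):
        sire = males[int(rng.integers(len(males)))]
        dam = females[int(rng.integers(len(females)))]
        sex = MALE if rng.random() < 0.5 else FEMALE
        i = f"X{k:03d}"
        records.append(
            IndividualRecord(id=i, sire_id=sire, dam_id=dam, sex=sex)
        )
        (males if sex == MALE else females).append(i)
    return build_pedigree(records)
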