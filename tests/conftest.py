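import pandas as pd
import pytest

from pedkit.pedigree import IndividualRecord, build_pedigree


def rec(id, sire=None, dam=None, sex="unknown", **kw):
    return IndividualRecord(id=id, sire_id=sire, dam_id=dam, sex=sex, **kw)


def transloc(id, donor, year=2000, sex="unknown"):
    return IndividualRecord(
        id=id, sex=sex, origin="translocated", donor_population=donor,
        translocation_year=year,
    )


@pytest.fixture
def ped5():
    """Two founders from donors X and Y, two full sibs, one full-sib mating."""
    return build_pedigree([
        transloc("A", "X", sex="male"),
        transloc("B", "Y", sex="female"),
        rec("C", "A", "B", "male"),
        rec("D", "A", "B", "female"),
        rec("E", "C", "D"),
    ])


@pytest.fixture
def halfsib():
    """Half sibs through shared sire A mated together: F_E = 1/8."""
    return build_pedigree([
        rec("A", sex="male"),
        rec("B", sex="female"),
        rec("B2", sex="female"),
        rec("C", "A", "B", "male"),
        rec("D", "A", "B2", "female"),
        rec("E", "C", "D"),
    ])


@pytest.fixture
def parent_offspring():
    """Sire mated to his own daughter: F_E = 1/4."""
    return build_pedigree([
        rec("A", sex="male"),
        rec("B", sex="female"),
        rec("C", "A", "B", "female"),
        rec("E", "A", "C"),
    ])


def census_of(assignments):
    """Build a census frame from {year: [(id, cluster, role), ...]}."""
    rows = [
        {"year": year, "id": i, "cluster": cluster, "role": role}
        for year, members in assignments.items()
        for (i, cluster, role) in members
    ]
    return pd.DataFrame(rows, columns=["year", "id", "cluster", "role"])
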