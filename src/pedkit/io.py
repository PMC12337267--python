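"""Readers and writers for the tabular interchange formats.

Pedigree, census, nest, and cohort tables are plain TSV/CSV with headers
(delimiter chosen by file extension on write, sniffed on read). Empty
fields, ``NA``, ``na``, and ``NaN`` read as missing; missing values write as
empty fields. Numeric output keeps full precision. A LINKAGE/PLINK-style
``.fam`` export of the pedigree is provided for interoperability with
standard pedigree tooling.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .demography import CensusTable, NestRecord
from .pedigree import IndividualRecord, Pedigree, MALE, FEMALE

NA_TOKENS = {"", "NA", "na", "NaN", "nan"}

PEDIGREE_COLUMNS = [
    "id", "sire", "dam", "sex", "origin", "donor_population",
    "translocation_year", "birth_year", "last_year",
]
CENSUS_COLUMNS = ["year", "id", "cluster", "role"]
NEST_COLUMNS = ["year", "cluster", "male", "female", "fledglings"]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: str | Path, columns: list[str], required: set[str]) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(
        path, sep=None, engine="python", dtype=str, keep_default_na=False
    )
    unknown = set(frame.columns) - set(columns)
    if unknown:
        raise SchemaError(
            f"{path.name}: unknown column(s) {sorted(unknown)}; "
            f"expected schema: {columns}"
        )
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {sorted(missing)}; "
            f"expected schema: {columns}"
        )
    return frame


def _opt(value: str | None) -> str | None:
    if value is None or value in NA_TOKENS:
        return None
    return value


def _opt_int(value: str | None, path: Path, row: int, column: str) -> int | None:
    value = _opt(value)
    if value is None:
        return None
    try:
        return int(value)
    except ValueError:
        raise SchemaError(
            f"{path.name} row {row}: unparseable {column} {value!r}"
        ) from None


def read_pedigree(path: str | Path) -> list[IndividualRecord]:
    """Read a pedigree table into typed records (row numbers in errors)."""
    path = Path(path)
    frame = _read_table(path, PEDIGREE_COLUMNS, {"id", "sire", "dam", "sex", "origin"})
    records = []
    for k, row in enumerate(frame.itertuples(index=False), start=2):
        get = lambda col: getattr(row, col, None)
        records.append(
            IndividualRecord(
                id=str(row.id),
                sire_id=_opt(row.sire),
                dam_id=_opt(row.dam),
                sex=_opt(row.sex) or "unknown",
                origin=_opt(row.origin) or "local",
                donor_population=_opt(get("donor_population")),
                translocation_year=_opt_int(
                    get("translocation_year"), path, k, "translocation_year"
                ),
                birth_year=_opt_int(get("birth_year"), path, k, "birth_year"),
                last_year=_opt_int(get("last_year"), path, k, "last_year"),
            )
        )
    return records


def write_pedigree(pedigree: Pedigree, path: str | Path) -> Path:
    path = Path(path)
    pedigree.to_frame().to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_census(path: str | Path) -> CensusTable:
    path = Path(path)
    frame = _read_table(path, CENSUS_COLUMNS, set(CENSUS_COLUMNS))
    try:
        frame["year"] = frame["year"].astype(int)
    except ValueError as exc:
        raise SchemaError(f"{path.name}: unparseable year: {exc}") from None
    return CensusTable(frame)


def write_census(census: CensusTable, path: str | Path) -> Path:
    path = Path(path)
    census.frame.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_nests(path: str | Path) -> list[NestRecord]:
    """Read nest records; ``fledglings`` is a comma-separated id list."""
    path = Path(path)
    frame = _read_table(path, NEST_COLUMNS, set(NEST_COLUMNS))
    nests = []
    for k, row in enumerate(frame.itertuples(index=False), start=2):
        fledglings = _opt(row.fledglings)
        nests.append(
            NestRecord(
                year=_opt_int(row.year, path, k, "year"),
                cluster=str(row.cluster),
                breeder_male=str(row.male),
                breeder_female=str(row.female),
                fledgling_ids=tuple(fledglings.split(",")) if fledglings else (),
            )
        )
    return nests


def write_nests(nests: list[NestRecord], path: str | Path) -> Path:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(NEST_COLUMNS)
        for nest in nests:
            writer.writerow(
                [
                    nest.year, nest.cluster, nest.breeder_male,
                    nest.breeder_female, ",".join(nest.fledgling_ids),
                ]
            )
    return path


def write_fam(pedigree: Pedigree, path: str | Path, family_id: str = "POP1") -> Path:
    """LINKAGE/PLINK .fam export: FID IID sire dam sex phenotype.

    Missing parents are 0; sex codes 1=male, 2=female, 0=unknown;
    phenotype fixed at -9 (missing).
    """
    sex_code = {MALE: 1, FEMALE: 2}
    path = Path(path)
    with open(path, "w") as fh:
        for i in pedigree.ids:
            rec = pedigree.record(i)
            fh.write(
                f"{family_id} {i} {rec.sire_id or 0} {rec.dam_id or 0} "
                f"{sex_code.get(rec.sex, 0)} -9\n"
            )
    return path


def write_matrix_long(
    frame: pd.DataFrame,
    path: str | Path,
    index_name: str,
    column_name: str,
    value_name: str = "value",
    se: pd.DataFrame | None = None,
) -> Path:
    """Write a row x column matrix as long-format TSV, optionally with a
    per-entry standard-error column."""
    path = Path(path)
    long = frame.rename_axis(index=index_name, columns=column_name).stack(
        future_stack=True
    ).rename(value_name).reset_index()
    if se is not None:
        long["se"] = se.stack(future_stack=True).to_numpy()
    long.to_csv(path, sep=_sep_for(path), index=False)
    return path


def write_matrix_wide(frame: pd.DataFrame, path: str | Path, index_name: str) -> Path:
    path = Path(path)
    frame.rename_axis(index=index_name).to_csv(path, sep=_sep_for(path))
    return path
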