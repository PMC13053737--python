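"""Twin-cohort data model: long-format person-occasion tables.

The canonical on-disk representation is a single delimited text file with one
row per person-occasion.  Person-level columns (pair structure, zygosity, sex,
SES codes) are repeated on every row of a person; visit-level columns carry the
age at measurement and the functional biomarkers.  Missing values are empty
fields -- no numeric sentinels.

In memory a cohort is split into a ``persons`` table (one row per person) and a
``visits`` table (one row per measurement occasion), which mirrors how the
mixed-model design matrices are assembled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortTable",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "complete_pairs",
    "PERSON_COLUMNS",
    "VISIT_COLUMNS",
]

#: Canonical person-level columns (constant within person).
PERSON_COLUMNS = [
    "person_id",
    "pair_id",
    "zygosity",
    "sex",
    "birth_year",
    "study_label",
    "isced",
    "isei",
    "parental_sei",
    "fs1",
    "fs2",
    "fs3",
    "fs4",
]

#: Canonical visit-level columns.
VISIT_COLUMNS = [
    "person_id",
    "age_years",
    "grip",
    "pef",
    "height_m",
    "gait",
    "vision_self",
    "hearing_self",
]

MANDATORY_COLUMNS = ["person_id", "pair_id", "zygosity", "sex", "age_years"]

_STRING_COLUMNS = {"person_id", "pair_id", "zygosity", "sex", "study_label"}


class SchemaError(ValueError):
    """A required column is absent or the schema mapping is unusable."""


class ValidationError(ValueError):
    """The data violate a cohort invariant (pair structure, ages, duplicates)."""


@dataclass
class CohortTable:
    """A twin cohort: one persons table, one visits table.

    Invariants (checked by :meth:`validate`):

    * every visit's ``person_id`` exists in ``persons``;
    * a ``pair_id`` groups at most two persons, who share zygosity;
    * MZ pairs are same-sex;
    * ``age_years`` is strictly increasing within person (no duplicate ages).
    """

    persons: pd.DataFrame
    visits: pd.DataFrame
    extra_person_cols: list[str] = field(default_factory=list)
    extra_visit_cols: list[str] = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_pairs(self) -> int:
        return self.persons["pair_id"].nunique()

    def validate(self) -> "CohortTable":
        p, v = self.persons, self.visits
        if p["person_id"].duplicated().any():
            dups = p.loc[p["person_id"].duplicated(), "person_id"].tolist()
            raise ValidationError(f"duplicate person_id(s): {dups[:5]}")
        known = set(p["person_id"])
        orphans = set(v["person_id"]) - known
        if orphans:
            raise ValidationError(f"visits reference unknown person_id(s): {sorted(orphans)[:5]}")
        sizes = p.groupby("pair_id")["person_id"].size()
        too_big = sizes[sizes > 2]
        if len(too_big):
            raise ValidationError(f"pair_id with more than 2 members: {too_big.index.tolist()[:5]}")
        zyg_n = p.groupby("pair_id")["zygosity"].nunique()
        bad = zyg_n[zyg_n > 1]
        if len(bad):
            raise ValidationError(f"pair(s) with discordant zygosity: {bad.index.tolist()[:5]}")
        mz = p[p["zygosity"] == "MZ"]
        sex_n = mz.groupby("pair_id")["sex"].nunique()
        bad = sex_n[sex_n > 1]
        if len(bad):
            raise ValidationError(f"MZ pair(s) of discordant sex: {bad.index.tolist()[:5]}")
        dup = v.duplicated(subset=["person_id", "age_years"])
        if dup.any():
            rows = v.loc[dup, ["person_id", "age_years"]].head(5).to_dict("records")
            raise ValidationError(f"duplicate (person_id, age_years): {rows}")
        return self

    def analysis_frame(self) -> pd.DataFrame:
        """Visits joined with person-level columns, sorted by (pair, person, age).

        Adds ``sex_male`` (1 for men, 0 for women) for design construction.
        """
        frame = self.visits.merge(self.persons, on="person_id", how="left")
        frame = frame.sort_values(["pair_id", "person_id", "age_years"], kind="mergesort")
        frame["sex_male"] = (frame["sex"] == "male").astype(float)
        return frame.reset_index(drop=True)


def _visit_cols(columns: list[str]) -> list[str]:
    return [c for c in columns if c in VISIT_COLUMNS and c != "person_id"]


def _split_long(long: pd.DataFrame) -> CohortTable:
    """Split a long person-occasion frame into persons/visits tables.

    Known columns go where the canon says; unknown columns are person-level
    when constant within every person (missing included), visit-level otherwise.
    """
    person_cols, visit_cols = [], []
    for c in long.columns:
        if c in PERSON_COLUMNS:
            person_cols.append(c)
        elif c in VISIT_COLUMNS:
            if c != "person_id":
                visit_cols.append(c)
        else:
            per = long.groupby("person_id", sort=False)[c].nunique(dropna=False)
            (person_cols if (per <= 1).all() else visit_cols).append(c)
    persons = (
        long[person_cols].drop_duplicates(subset="person_id").sort_values("person_id", kind="mergesort").reset_index(drop=True)
    )
    visits = (
        long[["person_id"] + visit_cols]
        .sort_values(["person_id", "age_years"], kind="mergesort")
        .reset_index(drop=True)
    )
    extra_p = [c for c in person_cols if c not in PERSON_COLUMNS]
    extra_v = [c for c in visit_cols if c not in VISIT_COLUMNS]
    return CohortTable(persons, visits, extra_p, extra_v)


def load_schema(path) -> dict:
    """Load a YAML column-mapping config ({rename: {file_col: canonical}, delimiter})."""
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, dict):
        raise SchemaError("schema config must be a mapping")
    return schema


def read_cohort(path, schema: dict | None = None) -> CohortTable:
    """Read and validate a long-format cohort file.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row; comma default, tab accepted via
        ``schema['delimiter']``.
    schema : dict, optional
        ``{"rename": {file_column: canonical_name}, "delimiter": ","}``.

    Raises
    ------
    SchemaError
        if a mandatory column is missing after renaming.
    ValidationError
        on type-coercion failures (reported with row numbers) or invariant
        violations (duplicate occasions, malformed pairs).
    """
    schema = schema or {}
    sep = schema.get("delimiter", ",")
    long = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    rename = schema.get("rename") or {}
    long = long.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in long.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    bad_rows = []
    for c in long.columns:
        if c in _STRING_COLUMNS:
            continue
        raw = long[c]
        num = pd.to_numeric(raw, errors="coerce")
        failed = raw.notna() & num.isna()
        if failed.any():
            bad_rows.extend((int(i) + 2, c, raw[i]) for i in raw.index[failed][:5])
        long[c] = num
    if bad_rows:
        msg = "; ".join(f"line {ln}: column {col!r} value {val!r}" for ln, col, val in bad_rows)
        raise ValidationError(f"type coercion failed: {msg}")

    cohort = _split_long(long)
    # person-level columns must be constant within person
    for c in cohort.persons.columns:
        if c == "person_id" or c not in PERSON_COLUMNS:
            continue
        per = long.groupby("person_id", sort=False)[c].nunique(dropna=False)
        if (per > 1).any():
            bad = per.index[per > 1].tolist()[:5]
            raise ValidationError(f"person-level column {c!r} varies within person(s): {bad}")
    return cohort.validate()


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a cohort as a single long-format delimited file.

    Missing cells become empty fields.  ``read_cohort(write_cohort(c))`` is the
    identity on valid cohorts (up to canonical row/column ordering).
    """
    if cohort.n_persons == 0:
        cols = list(cohort.persons.columns) + [c for c in cohort.visits.columns if c != "person_id"]
        pd.DataFrame(columns=cols).to_csv(path, sep=sep, index=False)
        return
    long = cohort.visits.merge(cohort.persons, on="person_id", how="left")
    person_cols = [c for c in cohort.persons.columns]
    visit_cols = [c for c in cohort.visits.columns if c != "person_id"]
    long = long[person_cols + visit_cols]
    long = long.sort_values(["person_id", "age_years"], kind="mergesort")
    long.to_csv(path, sep=sep, index=False)


def complete_pairs(cohort: CohortTable, require: str | None = None) -> CohortTable:
    """Restrict to complete twin pairs, optionally complete on one variable.

    Keeps only pairs with exactly two members; when ``require`` names a
    person-level variable, both members must be non-missing on it.  Singletons
    are always dropped (they enter phenotypic models but not co-twin models).
    """
    p = cohort.persons
    ok = p
    if require is not None:
        if require not in p.columns:
            raise KeyError(f"unknown person-level variable {require!r}")
        ok = p[p[require].notna()]
    sizes = ok.groupby("pair_id")["person_id"].size()
    keep_pairs = set(sizes.index[sizes == 2])
    persons = p[p["pair_id"].isin(keep_pairs) & p["person_id"].isin(ok["person_id"])]
    persons = persons.reset_index(drop=True)
    visits = cohort.visits[cohort.visits["person_id"].isin(persons["person_id"])].reset_index(drop=True)
    return CohortTable(persons, visits, cohort.extra_person_cols, cohort.extra_visit_cols)


def cohort_to_string(cohort: CohortTable, sep: str = ",") -> str:
    buf = io.StringIO()
    write_cohort(cohort, buf, sep=sep)
    return buf.getvalue()
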