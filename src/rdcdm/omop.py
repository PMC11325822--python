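"""Minimal OMOP CDM v5.4-shaped relational target backed by sqlite3.

Only the column subset needed by the two ETL routes is modelled; primary and
foreign keys are enforced eagerly at insert time so that the mandated
core-before-genotype/phenotype ordering becomes a testable contract.
"""

from __future__ import annotations

import csv
import sqlite3
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import StoreIntegrityError

__all__ = ["OMOPStore", "init_store", "OMOP_TABLES"]

_DDL: dict[str, str] = {
    "person": """
        CREATE TABLE person (
            person_id INTEGER PRIMARY KEY,
            gender_concept_id INTEGER NOT NULL,
            year_of_birth INTEGER,
            month_of_birth INTEGER,
            day_of_birth INTEGER,
            race_concept_id INTEGER NOT NULL DEFAULT 0,
            ethnicity_concept_id INTEGER NOT NULL DEFAULT 0,
            person_source_value TEXT,
            gender_source_value TEXT,
            race_source_value TEXT,
            ethnicity_source_value TEXT
        )""",
    "visit_occurrence": """
        CREATE TABLE visit_occurrence (
            visit_occurrence_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_concept_id INTEGER NOT NULL DEFAULT 0,
            visit_start_date TEXT,
            visit_end_date TEXT,
            visit_source_value TEXT
        )""",
    "condition_occurrence": """
        CREATE TABLE condition_occurrence (
            condition_occurrence_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_occurrence_id INTEGER REFERENCES visit_occurrence(visit_occurrence_id),
            condition_concept_id INTEGER NOT NULL DEFAULT 0,
            condition_start_date TEXT,
            condition_source_value TEXT
        )""",
    "procedure_occurrence": """
        CREATE TABLE procedure_occurrence (
            procedure_occurrence_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_occurrence_id INTEGER REFERENCES visit_occurrence(visit_occurrence_id),
            procedure_concept_id INTEGER NOT NULL DEFAULT 0,
            procedure_date TEXT,
            procedure_source_value TEXT
        )""",
    "measurement": """
        CREATE TABLE measurement (
            measurement_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_occurrence_id INTEGER REFERENCES visit_occurrence(visit_occurrence_id),
            measurement_concept_id INTEGER NOT NULL DEFAULT 0,
            measurement_date TEXT,
            value_as_number REAL,
            value_as_concept_id INTEGER,
            unit_source_value TEXT,
            measurement_source_value TEXT
        )""",
    "observation": """
        CREATE TABLE observation (
            observation_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_occurrence_id INTEGER REFERENCES visit_occurrence(visit_occurrence_id),
            observation_concept_id INTEGER NOT NULL DEFAULT 0,
            observation_date TEXT,
            value_as_number REAL,
            value_as_concept_id INTEGER,
            observation_source_value TEXT
        )""",
    "drug_exposure": """
        CREATE TABLE drug_exposure (
            drug_exposure_id INTEGER PRIMARY KEY,
            person_id INTEGER NOT NULL REFERENCES person(person_id),
            visit_occurrence_id INTEGER REFERENCES visit_occurrence(visit_occurrence_id),
            drug_concept_id INTEGER NOT NULL DEFAULT 0,
            drug_exposure_start_date TEXT,
            drug_source_value TEXT
        )""",
    "source_to_concept_map": """
        CREATE TABLE source_to_concept_map (
            source_code TEXT NOT NULL,
            source_concept_id INTEGER NOT NULL DEFAULT 0,
            source_vocabulary_id TEXT NOT NULL,
            source_code_description TEXT,
            target_concept_id INTEGER NOT NULL,
            target_vocabulary_id TEXT,
            valid_start_date TEXT,
            valid_end_date TEXT,
            invalid_reason TEXT,
            PRIMARY KEY (source_code, source_vocabulary_id)
        )""",
}

OMOP_TABLES: tuple[str, ...] = tuple(_DDL)

_PK_SORT: dict[str, str] = {
    "person": "person_id",
    "visit_occurrence": "visit_occurrence_id",
    "condition_occurrence": "condition_occurrence_id",
    "procedure_occurrence": "procedure_occurrence_id",
    "measurement": "measurement_id",
    "observation": "observation_id",
    "drug_exposure": "drug_exposure_id",
    "source_to_concept_map": "source_vocabulary_id, source_code",
}


class OMOPStore:
    """Thin wrapper around a sqlite3 connection holding the OMOP tables."""

    def __init__(self, conn: sqlite3.Connection) -> None:
        self.conn = conn
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- schema ------------------------------------------------------------

    def create_tables(self) -> None:
        for ddl in _DDL.values():
            self.conn.execute(ddl)
        self.conn.commit()

    def columns(self, table: str) -> tuple[str, ...]:
        self._check_table(table)
        cur = self.conn.execute(f"PRAGMA table_info({table})")
        return tuple(row[1] for row in cur.fetchall())

    @staticmethod
    def _check_table(table: str) -> None:
        if table not in _DDL:
            raise ValueError(f"unknown OMOP table: {table!r}")

    # -- rows --------------------------------------------------------------

    def insert_rows(self, table: str, rows: Sequence[Mapping[str, object]]) -> int:
        """Insert dict rows; FK/PK violations raise :class:`StoreIntegrityError`."""
        self._check_table(table)
        if not rows:
            return 0
        cols = sorted({c for row in rows for c in row})
        unknown = set(cols) - set(self.columns(table))
        if unknown:
            raise ValueError(f"unknown columns for {table}: {sorted(unknown)}")
        sql = (f"INSERT INTO {table} ({', '.join(cols)}) "
               f"VALUES ({', '.join(':' + c for c in cols)})")
        try:
            with self.conn:
                for row in rows:
                    payload = {c: row.get(c) for c in cols}
                    try:
                        self.conn.execute(sql, payload)
                    except sqlite3.IntegrityError as exc:
                        raise StoreIntegrityError(
                            f"{table}: {exc} (row={payload})") from exc
        except StoreIntegrityError:
            raise
        return len(rows)

    def count_rows(self, table: str, predicate: str | None = None,
                   params: Sequence[object] = ()) -> int:
        self._check_table(table)
        sql = f"SELECT COUNT(*) FROM {table}"
        if predicate:
            sql += f" WHERE {predicate}"
        return int(self.conn.execute(sql, params).fetchone()[0])

    def fetch_rows(self, table: str, predicate: str | None = None,
                   params: Sequence[object] = ()) -> list[dict[str, object]]:
        self._check_table(table)
        sql = f"SELECT * FROM {table}"
        if predicate:
            sql += f" WHERE {predicate}"
        sql += f" ORDER BY {_PK_SORT[table]}"
        cur = self.conn.execute(sql, params)
        names = [d[0] for d in cur.description]
        return [dict(zip(names, row)) for row in cur.fetchall()]

    def next_id(self, table: str) -> int:
        pk = _PK_SORT[table].split(",")[0].strip()
        if table == "source_to_concept_map":
            raise ValueError("source_to_concept_map has no integer surrogate key")
        row = self.conn.execute(f"SELECT COALESCE(MAX({pk}), 0) FROM {table}").fetchone()
        return int(row[0]) + 1

    # -- export ------------------------------------------------------------

    def export(self, directory: str | Path) -> list[Path]:
        """One CSV per table, rows in PK order; byte-stable for identical stores."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for table in OMOP_TABLES:
            path = directory / f"{table}.csv"
            cols = self.columns(table)
            cur = self.conn.execute(
                f"SELECT {', '.join(cols)} FROM {table} ORDER BY {_PK_SORT[table]}")
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh, lineterminator="\n")
                writer.writerow(cols)
                for row in cur:
                    writer.writerow(["" if v is None else
                                     (repr(v) if isinstance(v, float) else str(v))
                                     for v in row])
            written.append(path)
        return written

    def close(self) -> None:
        self.conn.close()


def init_store(path_or_memory: str | Path = ":memory:",
               overwrite: bool = False) -> OMOPStore:
    """Create a fresh store with all eight OMOP tables, empty.

    A file-backed store refuses to clobber an existing file unless
    ``overwrite=True``.
    """
    if str(path_or_memory) != ":memory:":
        path = Path(path_or_memory)
        if path.exists():
            if not overwrite:
                raise FileExistsError(
                    f"store already exists at {path}; pass overwrite=True")
            path.unlink()
        path.parent.mkdir(parents=True, exist_ok=True)
    conn = sqlite3.connect(str(path_or_memory))
    store = OMOPStore(conn)
    store.create_tables()
    return store
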