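"""Embedded relational store for the integrated data model.

Holds the deduplicated ZOTU reference set (zero-radius semantics: exact
string equality on uppercased sequences), the ``contains`` provenance
relation linking each reference sequence to every sample/run it was
observed in, per-run process parameter records, taxon assignments, and
the literature/study/sample/experiment/run hierarchy.

Backed by SQLite; the engine sits behind this one class so it could be
swapped without touching callers.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .curation import CuratedSample
from .pipeline.denoise import ZotuRecord
from .pipeline.taxonomy import TaxonAssignment


class MarkerConflictError(ValueError):
    """Same sequence submitted under a conflicting marker annotation."""


@dataclass
class UpdateReport:
    inserted_refs: int = 0
    reused_refs: int = 0
    contains_added: int = 0


@dataclass
class IngestReport:
    studies: int = 0
    samples: int = 0
    experiments: int = 0
    runs: int = 0
    articles: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)


@dataclass
class SraExperiment:
    srx: str
    platform: str
    sample: str  # SRS; a sample accession is always required
    design_description: str = ""
    primers: Optional[tuple[str, str]] = None


@dataclass
class SraHierarchy:
    study: str  # SRP
    experiments: list[SraExperiment] = field(default_factory=list)
    runs: list[tuple[str, str]] = field(default_factory=list)  # (srr, srx)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS article (
    doi TEXT PRIMARY KEY, pmid TEXT, title TEXT
);
CREATE TABLE IF NOT EXISTS study (srp TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS source (
    doi TEXT, srp TEXT, PRIMARY KEY (doi, srp)
);
CREATE TABLE IF NOT EXISTS sample (
    srs TEXT PRIMARY KEY,
    collection_date_iso TEXT, country TEXT, geoname_id INTEGER,
    continent TEXT, latitude REAL, longitude REAL, coord_source TEXT,
    biome_label TEXT, biome_envo TEXT,
    date_raw TEXT, country_raw TEXT, lat_lon_raw TEXT,
    habitat_raw TEXT, material_raw TEXT
);
CREATE TABLE IF NOT EXISTS experiment (
    srx TEXT PRIMARY KEY, srp TEXT, srs TEXT NOT NULL,
    platform TEXT, design TEXT
);
CREATE TABLE IF NOT EXISTS run (srr TEXT PRIMARY KEY, srx TEXT);
CREATE TABLE IF NOT EXISTS reference_sequence (
    ref_id INTEGER PRIMARY KEY AUTOINCREMENT,
    sequence TEXT UNIQUE NOT NULL,
    marker TEXT NOT NULL,
    length INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS contains (
    ref_id INTEGER NOT NULL, srs TEXT NOT NULL, srr TEXT NOT NULL,
    abundance INTEGER NOT NULL,
    PRIMARY KEY (ref_id, srr)
);
CREATE TABLE IF NOT EXISTS process (
    srr TEXT PRIMARY KEY, params_json TEXT, version TEXT
);
CREATE TABLE IF NOT EXISTS assign_taxa (
    ref_id INTEGER PRIMARY KEY,
    lineage TEXT, best_hit_name TEXT, identity REAL
);
"""

TABLES = (
    "article",
    "study",
    "source",
    "sample",
    "experiment",
    "run",
    "reference_sequence",
    "contains",
    "process",
    "assign_taxa",
)


class ZotuStore:
    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- incremental reference update ------------------------------------

    def update_store(
        self,
        sample_zotus: Iterable[
            tuple[str, str, Sequence[tuple[ZotuRecord, Optional[TaxonAssignment]]]]
        ],
    ) -> UpdateReport:
        """Incorporate per-run ZOTU sets into the reference store.

        A ZOTU sequence not seen before becomes a new reference row plus
        a ``contains`` row; a known sequence only gains a ``contains``
        row.  Replaying a (reference, run) observation adds nothing, so
        the update is idempotent per run.
        """
        report = UpdateReport()
        cur = self.conn.cursor()
        for srs, srr, zotu_assignments in sample_zotus:
            seen_in_run: set[str] = set()
            for zotu, assignment in zotu_assignments:
                seq = zotu.sequence.upper()
                if seq in seen_in_run:
                    raise ValueError(
                        f"duplicate sequence within run {srr}: zero-radius input "
                        "must be unique per run"
                    )
                seen_in_run.add(seq)
                row = cur.execute(
                    "SELECT ref_id, marker FROM reference_sequence WHERE sequence = ?",
                    (seq,),
                ).fetchone()
                if row is None:
                    cur.execute(
                        "INSERT INTO reference_sequence (sequence, marker, length) "
                        "VALUES (?, ?, ?)",
                        (seq, zotu.marker, len(seq)),
                    )
                    ref_id = cur.lastrowid
                    if assignment is not None:
                        self._insert_assignment(cur, ref_id, assignment)
                    cur.execute(
                        "INSERT INTO contains (ref_id, srs, srr, abundance) "
                        "VALUES (?, ?, ?, ?)",
                        (ref_id, srs, srr, zotu.abundance),
                    )
                    report.inserted_refs += 1
                    report.contains_added += 1
                else:
                    ref_id, marker = row
                    if marker != zotu.marker:
                        raise MarkerConflictError(
                            f"sequence already stored with marker {marker}, "
                            f"submitted as {zotu.marker}"
                        )
                    cur.execute(
                        "INSERT OR IGNORE INTO contains (ref_id, srs, srr, abundance) "
                        "VALUES (?, ?, ?, ?)",
                        (ref_id, srs, srr, zotu.abundance),
                    )
                    if cur.rowcount == 1:
                        report.reused_refs += 1
                        report.contains_added += 1
        self.conn.commit()
        return report

    @staticmethod
    def _insert_assignment(
        cur: sqlite3.Cursor, ref_id: int, assignment: TaxonAssignment
    ) -> None:
        if not (70.0 <= assignment.identity <= 100.0):
            raise ValueError(
                f"stored assignments must have identity in [70, 100], "
                f"got {assignment.identity}"
            )
        cur.execute(
            "INSERT OR REPLACE INTO assign_taxa (ref_id, lineage, best_hit_name, identity) "
            "VALUES (?, ?, ?, ?)",
            (ref_id, assignment.lineage.to_string(), assignment.best_hit_name, assignment.identity),
        )

    def record_process(self, srr: str, process_record: dict) -> None:
        version = str(process_record.get("pipeline_version", ""))
        self.conn.execute(
            "INSERT OR REPLACE INTO process (srr, params_json, version) VALUES (?, ?, ?)",
            (srr, json.dumps(process_record, sort_keys=True), version),
        )
        self.conn.commit()

    # -- metadata ingest ---------------------------------------------------

    def import_curated(
        self,
        curated_samples: Sequence[CuratedSample],
        hierarchy: SraHierarchy,
        publication_links: Sequence[tuple[str, Optional[str], str]] = (),
        # (doi, pmid, title) articles linked to the study
    ) -> IngestReport:
        """Populate literature/study/location components with closure checks.

        Experiments without a sample accession and runs referencing a
        missing experiment are rejected per record and reported; nothing
        is loaded partially or silently.
        """
        report = IngestReport()
        cur = self.conn.cursor()
        cur.execute("INSERT OR IGNORE INTO study (srp) VALUES (?)", (hierarchy.study,))
        report.studies += 1

        for doi, pmid, title in publication_links:
            cur.execute(
                "INSERT OR REPLACE INTO article (doi, pmid, title) VALUES (?, ?, ?)",
                (doi, pmid, title),
            )
            cur.execute(
                "INSERT OR IGNORE INTO source (doi, srp) VALUES (?, ?)",
                (doi, hierarchy.study),
            )
            report.articles += 1

        for sample in curated_samples:
            cur.execute(
                "INSERT OR REPLACE INTO sample VALUES "
                "(?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    sample.srs,
                    sample.collection_date_iso,
                    sample.country,
                    sample.geoname_id,
                    sample.continent,
                    sample.latitude,
                    sample.longitude,
                    sample.coord_source.value,
                    sample.biome_term[0] if sample.biome_term else None,
                    sample.biome_term[1] if sample.biome_term else None,
                    sample.provenance.get("collection_date_iso"),
                    sample.provenance.get("country"),
                    sample.provenance.get("latitude"),
                    sample.provenance.get("biome_term"),
                    sample.provenance.get("material"),
                ),
            )
            report.samples += 1

        accepted_srx: set[str] = set()
        for exp in hierarchy.experiments:
            if not exp.sample:
                report.rejected.append((exp.srx, "experiment lacks a sample accession"))
                continue
            cur.execute(
                "INSERT OR REPLACE INTO experiment (srx, srp, srs, platform, design) "
                "VALUES (?, ?, ?, ?, ?)",
                (exp.srx, hierarchy.study, exp.sample, exp.platform, exp.design_description),
            )
            accepted_srx.add(exp.srx)
            report.experiments += 1

        for srr, srx in hierarchy.runs:
            if srx not in accepted_srx:
                report.rejected.append((srr, f"run references missing experiment {srx}"))
                continue
            cur.execute("INSERT OR REPLACE INTO run (srr, srx) VALUES (?, ?)", (srr, srx))
            report.runs += 1

        self.conn.commit()
        return report

    # -- access ------------------------------------------------------------

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLES:
            raise ValueError(f"unknown table {name!r}")
        return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)

    def n_references(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM reference_sequence").fetchone()[0]

    def n_contains(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM contains").fetchone()[0]

    def reference_sequences(self) -> set[str]:
        rows = self.conn.execute("SELECT sequence FROM reference_sequence").fetchall()
        return {r[0] for r in rows}

    # -- CSV round trip ----------------------------------------------------

    def export_csv(self, out_dir: Union[str, Path]) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in TABLES:
            self.table(name).to_csv(out_dir / f"{name}.csv", index=False)

    @classmethod
    def import_csv(
        cls, in_dir: Union[str, Path], path: Union[str, Path] = ":memory:"
    ) -> "ZotuStore":
        store = cls(path)
        in_dir = Path(in_dir)
        for name in TABLES:
            csv_path = in_dir / f"{name}.csv"
            if not csv_path.exists():
                continue
            df = pd.read_csv(csv_path)
            if len(df):
                df.to_sql(name, store.conn, if_exists="append", index=False)
        store.conn.commit()
        return store

    def snapshot(self) -> dict[str, list[tuple]]:
        """Field-by-field content of every table, for equality checks."""
        out = {}
        for name in TABLES:
            df = self.table(name)
            # empty string and absent are equivalent through a CSV cycle
            records = [
                tuple(None if (pd.isna(v) or v == "") else v for v in row)
                for row in df.itertuples(index=False, name=None)
            ]
            out[name] = sorted(records, key=repr)
        return out
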