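"""Identifiable tag-data store: directory ingest into a searchable
per-image document collection.

Documents are keyed by SOPInstanceUID and upserted, so re-loading a
directory is idempotent. The backend is pluggable behind a minimal
put/get/scan contract; the default is an embedded single-file SQLite
collection so no server is needed. Duplicate instance UIDs arriving with
different content are overwritten last-write-wins, with an audit record.
"""

from __future__ import annotations

import datetime as dt
import json
import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional

from .model import (
    LoadRejectError,
    NotDicomError,
    TagDocument,
    read_instance,
    tags_to_document,
)


@dataclass
class LoadReport:
    """Outcome of one directory load batch."""

    batch: str
    files_seen: int = 0
    loaded: int = 0
    updated: int = 0
    rejected: int = 0
    reject_reasons: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        assert self.files_seen == self.loaded + self.updated + self.rejected


class SqliteDocumentBackend:
    """Embedded document collection in one SQLite file."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS documents ("
            " id TEXT PRIMARY KEY, body TEXT NOT NULL)"
        )
        self.conn.execute(
            "CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)"
        )
        self.conn.commit()

    def put(self, doc: TagDocument) -> bool:
        """Insert or replace; returns True when the id was new."""
        cur = self.conn.execute("SELECT 1 FROM documents WHERE id=?", (doc.id,))
        existed = cur.fetchone() is not None
        self.conn.execute(
            "INSERT OR REPLACE INTO documents (id, body) VALUES (?, ?)",
            (doc.id, doc.to_json()),
        )
        return not existed

    def get(self, doc_id: str) -> Optional[TagDocument]:
        cur = self.conn.execute("SELECT body FROM documents WHERE id=?", (doc_id,))
        row = cur.fetchone()
        return TagDocument.from_json(row[0]) if row else None

    def scan(self) -> Iterator[TagDocument]:
        cur = self.conn.execute("SELECT body FROM documents ORDER BY id")
        for (body,) in cur:
            yield TagDocument.from_json(body)

    def __len__(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM documents").fetchone()[0]

    def next_batch_seq(self) -> int:
        cur = self.conn.execute("SELECT value FROM meta WHERE key='batch_seq'")
        row = cur.fetchone()
        seq = int(row[0]) + 1 if row else 1
        self.conn.execute(
            "INSERT OR REPLACE INTO meta (key, value) VALUES ('batch_seq', ?)",
            (str(seq),),
        )
        return seq

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()


class TagStore:
    """The searchable store of full, identifiable tag metadata."""

    def __init__(self, path: Path | str, backend=None):
        self.path = Path(path)
        self.backend = backend or SqliteDocumentBackend(self.path)
        self.audit_path = self.path.with_suffix(self.path.suffix + ".audit.jsonl")

    # -- ingest --

    def _new_batch_id(self) -> str:
        # lexically sortable: millisecond timestamp + per-store sequence
        ms = int(time.time() * 1000)
        seq = self.backend.next_batch_seq()
        return f"{ms:013d}-{seq:06d}"

    def load_directory(self, root: Path | str) -> LoadReport:
        """Ingest every readable DICOM file under ``root``.

        Unreadable or structurally invalid files are logged and skipped,
        never fatal to the batch. Re-loading the same tree updates existing
        documents in place (keyed on SOPInstanceUID).
        """
        root = Path(root)
        if not root.is_dir():
            raise FileNotFoundError(f"archive root {root} does not exist")
        report = LoadReport(batch=self._new_batch_id())
        stamp = dt.datetime.now(dt.timezone.utc).isoformat()
        for path in sorted(p for p in root.rglob("*") if p.is_file()):
            if path.name.startswith(".") or path.suffix in (".jsonl", ".yaml", ".json"):
                continue
            report.files_seen += 1
            try:
                tree = read_instance(path, root)
            except (NotDicomError, LoadRejectError) as exc:
                report.rejected += 1
                report.reject_reasons[str(path.relative_to(root))] = str(exc)
                self._audit("reject", path=str(path), reason=str(exc))
                continue
            doc = tags_to_document(tree)
            doc.load_timestamp = stamp
            doc.load_batch = report.batch
            existing = self.backend.get(doc.id)
            if existing is not None and existing.body != doc.body:
                self._audit("overwrite", id=doc.id, batch=report.batch)
            if self.backend.put(doc):
                report.loaded += 1
            else:
                report.updated += 1
        self.backend.commit()
        report.validate()
        return report

    # -- query --

    def query_documents(
        self, predicate: Callable[[TagDocument], bool]
    ) -> list[TagDocument]:
        """Exact filter evaluation over the whole collection."""
        if not callable(predicate):
            raise TypeError("predicate must be callable on TagDocument")
        return [d for d in self.backend.scan() if predicate(d)]

    def get(self, doc_id: str) -> Optional[TagDocument]:
        return self.backend.get(doc_id)

    def scan(self) -> Iterator[TagDocument]:
        return self.backend.scan()

    def __len__(self) -> int:
        return len(self.backend)

    def store_stats(self) -> dict:
        """Counts by modality and by study year; totals equal store size."""
        by_modality: dict[str, int] = {}
        by_year: dict[str, int] = {}
        total = 0
        for doc in self.backend.scan():
            total += 1
            mod = doc.tag("Modality") or "unknown"
            by_modality[mod] = by_modality.get(mod, 0) + 1
            date = doc.tag("StudyDate") or ""
            year = date[:4] if len(date) >= 4 else "unknown"
            by_year[year] = by_year.get(year, 0) + 1
        return {"total": total, "by_modality": by_modality, "by_year": by_year}

    def _audit(self, event: str, **fields) -> None:
        rec = {"event": event, "ts": time.time(), **fields}
        with open(self.audit_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")

    def close(self) -> None:
        self.backend.close()


def tag_equals(keyword: str, value) -> Callable[[TagDocument], bool]:
    """Convenience predicate: top-level tag (by keyword) equals ``value``."""
    return lambda doc: doc.tag(keyword) == value
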