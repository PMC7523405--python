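"""Keyed pseudonymisation: CHI -> EUPI mapping and per-project patient IDs.

The EUPI (encrypted universal patient identifier) is a keyed one-way digest
of the CHI: deterministic, so any two datasets pseudonymised with the same
key and mapping version can be joined on it, but not invertible, so the
de-identified zone never learns the CHI. One person can hold several CHIs
(duplicate registrations); :meth:`MappingTable.reconcile` folds a group of
CHIs onto a single canonical EUPI in a new, append-only table version.

Project-local patient IDs are a second keyed derivation so that two research
projects cannot link their extracts to each other.

No inverse operation exists anywhere in this module; that absence is the
one-way contract.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import sqlite3

import yaml
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

EUPI_LENGTH = 16       # hex characters kept from the keyed digest
PROJECT_ID_LENGTH = 12


class PseudonymError(ValueError):
    pass


def _check_chi(chi: str) -> None:
    if not (isinstance(chi, str) and len(chi) == 10 and chi.isdigit()):
        raise PseudonymError(f"CHI must be 10 decimal digits, got {chi!r}")


def map_chi_to_eupi(chi: str, key: bytes | str) -> str:
    """Keyed one-way pseudonym: HMAC-SHA256 truncated to 16 hex characters.

    Deterministic in (chi, key); different keys give unrelated pseudonyms.
    """
    _check_chi(chi)
    if not key:
        raise PseudonymError("pseudonymisation key is missing")
    if isinstance(key, str):
        key = key.encode()
    digest = hmac.new(key, chi.encode(), hashlib.sha256).hexdigest()
    return digest[:EUPI_LENGTH]


def eupi_to_project_id(eupi: str, project: str, salt: bytes | str) -> str:
    """Per-project patient ID, unlinkable across projects with distinct salts."""
    if not project:
        raise PseudonymError("project id is required")
    if not salt:
        raise PseudonymError("project salt is missing")
    if isinstance(salt, str):
        salt = salt.encode()
    digest = hmac.new(salt, f"{project}:{eupi}".encode(), hashlib.sha256).hexdigest()
    return digest[:PROJECT_ID_LENGTH]


@dataclass
class MappingVersion:
    version: int
    # chi -> canonical chi whose EUPI the person carries
    canonical: dict[str, str] = field(default_factory=dict)


class MappingTable:
    """Versioned CHI -> (EUPI, master person) table.

    Mappings are computed on demand from the key and cached per version.
    Versions are append-only: a reconcile produces a new version; earlier
    versions remain queryable so a historical extract can be reproduced.
    """

    def __init__(self, key: bytes | str):
        if not key:
            raise PseudonymError("pseudonymisation key is missing")
        self._key = key.encode() if isinstance(key, str) else key
        self._versions: list[MappingVersion] = [MappingVersion(version=1)]
        self._cache: dict[tuple[int, str], str] = {}

    @property
    def version(self) -> int:
        return self._versions[-1].version

    def _canonical(self, chi: str, version: MappingVersion) -> str:
        return version.canonical.get(chi, chi)

    def lookup(self, chi: str, version: Optional[int] = None) -> str:
        """EUPI for a CHI under the given (default: latest) table version."""
        _check_chi(chi)
        v = self._versions[-1] if version is None else self._versions[version - 1]
        cache_key = (v.version, chi)
        if cache_key not in self._cache:
            self._cache[cache_key] = map_chi_to_eupi(self._canonical(chi, v), self._key)
        return self._cache[cache_key]

    def reconcile(self, groups: Iterable[Iterable[str]]) -> int:
        """Fold each group of CHIs onto its first (canonical) member.

        Groups must be disjoint. Returns the new version number; prior
        versions are retained unchanged. An empty group set still bumps the
        version (a monthly refresh with nothing to merge).
        """
        groups = [list(g) for g in groups]
        seen: set[str] = set()
        for g in groups:
            for chi in g:
                _check_chi(chi)
                if chi in seen:
                    raise PseudonymError(f"CHI {chi} appears in more than one group")
                seen.add(chi)
        new = MappingVersion(
            version=self.version + 1,
            canonical=dict(self._versions[-1].canonical),
        )
        for g in groups:
            if not g:
                continue
            canonical = new.canonical.get(g[0], g[0])
            for chi in g:
                new.canonical[chi] = canonical
        self._versions.append(new)
        return new.version

    # -- persistence in the relational store --

    def save(self, db_path: Path | str) -> None:
        conn = sqlite3.connect(db_path)
        try:
            conn.execute(
                "CREATE TABLE IF NOT EXISTS chi_eupi_map ("
                " version INTEGER, chi TEXT, canonical TEXT,"
                " PRIMARY KEY (version, chi))"
            )
            conn.execute("DELETE FROM chi_eupi_map")
            for v in self._versions:
                for chi, canonical in v.canonical.items():
                    conn.execute(
                        "INSERT INTO chi_eupi_map VALUES (?, ?, ?)",
                        (v.version, chi, canonical),
                    )
                conn.execute(
                    "INSERT OR REPLACE INTO chi_eupi_map VALUES (?, '_version', '')",
                    (v.version,),
                )
            conn.commit()
        finally:
            conn.close()

    @classmethod
    def load(cls, db_path: Path | str, key: bytes | str) -> "MappingTable":
        table = cls(key)
        conn = sqlite3.connect(db_path)
        try:
            rows = conn.execute(
                "SELECT version, chi, canonical FROM chi_eupi_map ORDER BY version"
            ).fetchall()
        finally:
            conn.close()
        versions: dict[int, MappingVersion] = {}
        for version, chi, canonical in rows:
            v = versions.setdefault(version, MappingVersion(version=version))
            if chi != "_version":
                v.canonical[chi] = canonical
        if versions:
            table._versions = [versions[k] for k in sorted(versions)]
        return table


@dataclass
class ProjectIdMap:
    """Registered projects and their salts; EUPI -> project-ID derivation."""

    salts: dict[str, str] = field(default_factory=dict)
    release_counter: dict[str, int] = field(default_factory=dict)

    def register(self, project: str, salt: str) -> None:
        if not salt:
            raise PseudonymError("project salt must be non-empty")
        self.salts[project] = salt
        self.release_counter.setdefault(project, 0)

    def project_id(self, eupi: str, project: str) -> str:
        if project not in self.salts:
            raise PseudonymError(f"unknown project {project!r}")
        return eupi_to_project_id(eupi, project, self.salts[project])

    def bump_release(self, project: str) -> int:
        self.release_counter[project] = self.release_counter.get(project, 0) + 1
        return self.release_counter[project]


def load_keys(config_path: Path | str) -> dict:
    """Read pseudonymisation key and project salts from a config file.

    Keys live in configuration, never on a command line, so they cannot
    leak through shell history or process listings.
    """
    with open(config_path) as fh:
        cfg = json.load(fh) if str(config_path).endswith(".json") else yaml.safe_load(fh)
    if "eupi_key" not in cfg:
        raise PseudonymError("config must define eupi_key")
    return cfg
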