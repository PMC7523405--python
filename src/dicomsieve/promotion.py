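"""Promotion: whitelisted, cleaned, EUPI-keyed inventory tables.

Everything is blacklisted by default; a tag reaches the inventory only if it
is on the promotion whitelist or is a declared derived field. Promotion

* replaces the CHI with its EUPI before any row leaves the identifiable
  zone,
* homogenises DICOM age strings (``075Y`` / ``006M`` / ``002D`` / bare
  numbers) into numeric years,
* computes derived fields: the primary/original flag, repeated-volume
  detection from slice-position multiplicities, and the contrast-bolus
  candidate flag that disambiguates repeat acquisitions with contrast,
* scans free-text description fields and drops the column (not the row)
  when it leaks an identifier,
* writes flattened study/series/image tables with composite indexes suited
  to cohort queries.

Re-running promotion replaces the whole batch, so it is idempotent.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

import yaml

from .corpus import PatientIdentity, chi_dob
from .model import TagDocument
from .pseudonym import MappingTable, PseudonymError
from .scanner import AllowlistEntry, ScanRule, default_allowlist, default_rules, scan_value
from .store import TagStore

#: tolerance (mm) within which two slice positions count as identical;
#: scanner jitter sits well below clinical slice spacing
POSITION_TOLERANCE_MM = 0.01

DIRECT_IDENTIFIER_KEYWORDS = frozenset(
    {
        "PatientName",
        "PatientID",
        "PatientBirthDate",
        "OtherPatientIDs",
        "OtherPatientNames",
        "PatientAddress",
        "PatientTelephoneNumbers",
        "PatientMotherBirthName",
        "ReferringPhysicianName",
        "InstitutionAddress",
        "PersonName",
    }
)

DEFAULT_WHITELIST = [
    "SOPInstanceUID",
    "SeriesInstanceUID",
    "StudyInstanceUID",
    "Modality",
    "ImageType",
    "StudyDate",          # coarsened to year-month before storage
    "PatientAge",         # normalised to numeric years
    "PatientSex",
    "BodyPartExamined",
    "SliceThickness",
    "Manufacturer",
    "ManufacturerModelName",
    "SeriesDescription",  # scanned; dropped per-row on any finding
    "StudyDescription",   # scanned; dropped per-row on any finding
]

#: inventory column -> provenance: "key", "derived", or the whitelisted tag
COLUMN_SOURCES: dict[str, str] = {
    "eupi": "key",
    "study_uid": "StudyInstanceUID",
    "series_uid": "SeriesInstanceUID",
    "sop_uid": "SOPInstanceUID",
    "modality": "Modality",
    "study_year": "StudyDate",
    "study_year_month": "StudyDate",
    "age_years": "PatientAge",
    "age_missing": "derived",
    "age_derived": "derived",
    "sex": "PatientSex",
    "body_part": "BodyPartExamined",
    "image_type": "ImageType",
    "is_primary_original": "derived",
    "is_repeated_volume": "derived",
    "n_acquisitions": "derived",
    "contrast_bolus_candidate": "derived",
    "slice_thickness": "SliceThickness",
    "manufacturer": "Manufacturer",
    "manufacturer_model": "ManufacturerModelName",
    "series_description": "SeriesDescription",
    "study_description": "StudyDescription",
    "relative_path": "key",   # identifiable-zone locator, image level only
    "n_images": "derived",
    "n_series": "derived",
    "modalities": "Modality",
}


class PromotionError(RuntimeError):
    pass


@dataclass
class PromotionConfig:
    """Versioned promotion policy: whitelist, filters, derived-field toggles."""

    version: int = 1
    whitelist: list[str] = field(default_factory=lambda: list(DEFAULT_WHITELIST))
    collapse: str = "series"          # level mirrored to the de-identified zone
    primary_original_only: bool = True
    compute_repeated_volume: bool = True
    derive_age_from_birth_year: bool = True
    scan_descriptions: bool = True

    def validate(self) -> None:
        bad = set(self.whitelist) & DIRECT_IDENTIFIER_KEYWORDS
        if bad:
            raise PromotionError(
                f"whitelist must not contain direct identifiers: {sorted(bad)}"
            )
        if self.collapse not in ("image", "series", "study"):
            raise PromotionError(f"unknown collapse level {self.collapse!r}")

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PromotionConfig":
        with open(path) as fh:
            cfg = cls(**(yaml.safe_load(fh) or {}))
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# field homogenisation


_AGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([YMWDymwd]?)\s*$")
_AGE_DIVISOR = {"Y": 1.0, "": 1.0, "M": 12.0, "W": 365.25 / 7.0, "D": 365.25}


def parse_age_string(s: Any) -> Optional[float]:
    """Normalise a DICOM age string to years.

    ``075Y`` -> 75.0, ``006M`` -> 0.5, ``002D`` -> 2/365.25; a bare number
    is read as years (the common sloppy encoding). Weeks (``W``) are part
    of the age-string VR and convert via 7-day weeks. Anything unparseable
    returns ``None`` (flagged missing) — never an exception mid-batch.
    """
    if s is None:
        return None
    m = _AGE_RE.match(str(s))
    if not m:
        return None
    value, unit = float(m.group(1)), m.group(2).upper()
    years = value / _AGE_DIVISOR[unit]
    return years if years >= 0 else None


def is_primary_original(image_type: Any) -> bool:
    """True iff the multivalued ImageType contains both ORIGINAL and PRIMARY.

    A missing or malformed tag is conservatively not primary/original.
    """
    if image_type is None:
        return False
    values = (
        [str(v).upper() for v in image_type]
        if isinstance(image_type, (list, tuple))
        else str(image_type).upper().split("\\")
    )
    return "ORIGINAL" in values and "PRIMARY" in values


def detect_repeated_volume(
    slice_positions: Iterable, tolerance: float = POSITION_TOLERANCE_MM
) -> tuple[bool, int]:
    """Spot series in which the same volume was acquired repeatedly.

    Positions (scalars or 3-vectors) identical within ``tolerance`` are the
    same location; the acquisition count is the maximum multiplicity of any
    location, and the series is repeated when that count is at least 2.
    """
    counts: dict[tuple, int] = {}
    n = 0
    for pos in slice_positions:
        n += 1
        if isinstance(pos, (list, tuple)):
            key = tuple(round(float(p) / tolerance) for p in pos)
        else:
            key = (round(float(pos) / tolerance),)
        counts[key] = counts.get(key, 0) + 1
    if n == 0:
        return (False, 0)
    n_acq = max(counts.values())
    return (n_acq >= 2, n_acq)


def flag_contrast_bolus(is_repeated: bool, contrast_tags_present: bool) -> bool:
    """Contrast-bolus candidate: a repeated volume acquired with contrast."""
    return bool(is_repeated) and bool(contrast_tags_present)


# ---------------------------------------------------------------------------
# inventory schema

_IMAGE_COLS = [
    "eupi", "study_uid", "series_uid", "sop_uid", "modality", "study_year",
    "study_year_month", "age_years", "age_missing", "age_derived", "sex",
    "body_part", "image_type", "is_primary_original", "is_repeated_volume",
    "n_acquisitions", "contrast_bolus_candidate", "slice_thickness",
    "manufacturer", "manufacturer_model", "series_description",
    "study_description", "relative_path",
]
_SERIES_COLS = [
    "eupi", "study_uid", "series_uid", "modality", "study_year",
    "study_year_month", "age_years", "sex", "body_part", "image_type",
    "is_primary_original", "is_repeated_volume", "n_acquisitions",
    "contrast_bolus_candidate", "manufacturer", "manufacturer_model",
    "series_description", "study_description", "n_images",
]
_STUDY_COLS = [
    "eupi", "study_uid", "modalities", "study_year", "study_year_month",
    "age_years", "sex", "study_description", "n_series", "n_images",
]

DDL = [
    "CREATE TABLE IF NOT EXISTS image ({} , PRIMARY KEY (sop_uid))".format(
        ", ".join(f"{c} " for c in _IMAGE_COLS)
    ),
    "CREATE TABLE IF NOT EXISTS series ({} , PRIMARY KEY (series_uid))".format(
        ", ".join(f"{c} " for c in _SERIES_COLS)
    ),
    "CREATE TABLE IF NOT EXISTS study ({} , PRIMARY KEY (study_uid))".format(
        ", ".join(f"{c} " for c in _STUDY_COLS)
    ),
    "CREATE INDEX IF NOT EXISTS ix_image_cohort ON image"
    " (eupi, image_type, study_description)",
    "CREATE INDEX IF NOT EXISTS ix_series_cohort ON series"
    " (eupi, modality, study_year)",
]

INVENTORY_COLUMNS = {
    "image": list(_IMAGE_COLS),
    "series": list(_SERIES_COLS),
    "study": list(_STUDY_COLS),
}


class Inventory:
    """Thin query surface over the flattened inventory database."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        for stmt in DDL:
            self.conn.execute(stmt)
        self.conn.commit()

    def rows(self, level: str, where: str = "1=1", params: tuple = ()) -> list[dict]:
        if level not in INVENTORY_COLUMNS:
            raise PromotionError(f"unknown inventory level {level!r}")
        cur = self.conn.execute(f"SELECT * FROM {level} WHERE {where}", params)
        return [dict(r) for r in cur.fetchall()]

    def count(self, level: str) -> int:
        return self.conn.execute(f"SELECT COUNT(*) FROM {level}").fetchone()[0]

    def close(self) -> None:
        self.conn.close()


@dataclass
class PromotionReport:
    images_seen: int = 0
    promoted_images: int = 0
    series_rows: int = 0
    study_rows: int = 0
    skipped: dict[str, int] = field(default_factory=dict)
    descriptions_dropped: int = 0

    def skip(self, reason: str) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + 1


def check_column_closure(config: PromotionConfig) -> None:
    """Machine check: every inventory column traces to the whitelist,
    a derived field, or a key. Runs on every promotion."""
    allowed = set(config.whitelist) | {"key", "derived"}
    for level, cols in INVENTORY_COLUMNS.items():
        for col in cols:
            source = COLUMN_SOURCES.get(col)
            if source is None or source not in allowed:
                raise PromotionError(
                    f"column {level}.{col} has no whitelisted source ({source!r})"
                )


def _doc_identity(doc: TagDocument) -> Optional[PatientIdentity]:
    """Reconstruct the patient's identity from the identifiable document,
    for cross-reference scanning of free-text fields."""
    name = doc.tag("PatientName") or ""
    chi = doc.tag("PatientID") or ""
    parts = str(name).split("^")
    family = parts[0] if parts else ""
    given = parts[1] if len(parts) > 1 else ""
    dob = chi_dob(str(chi))
    if dob is None or not family:
        return None
    try:
        extra = doc.tag("OtherPatientIDs")
        extra_list = (
            [str(e) for e in extra]
            if isinstance(extra, list)
            else [str(extra)]
            if extra
            else []
        )
        return PatientIdentity(
            chi=str(chi),
            family_name=family,
            given_name=given,
            dob=dob,
            sex=str(doc.tag("PatientSex") or "O"),
            extra_chis=extra_list,
        )
    except Exception:  # malformed identity: scan without crossref
        return None


def _slice_position(doc: TagDocument) -> Optional[Any]:
    pos = doc.tag("ImagePositionPatient")
    if isinstance(pos, list) and len(pos) == 3:
        try:
            return [float(p) for p in pos]
        except (TypeError, ValueError):
            pass
    loc = doc.tag("SliceLocation")
    try:
        return float(loc)
    except (TypeError, ValueError):
        return None


def promote(
    store: TagStore,
    config: PromotionConfig,
    mapping: MappingTable,
    inventory_path: Path | str,
    rules: Optional[list[ScanRule]] = None,
    allowlist: Optional[list[AllowlistEntry]] = None,
) -> PromotionReport:
    """Build the inventory tables from the identifiable tag store.

    Aborts before writing anything if the pseudonymisation mapping is
    unavailable; rows are written replace-by-batch so repeated runs leave
    identical tables.
    """
    config.validate()
    check_column_closure(config)
    if mapping is None:
        raise PseudonymError("mapping table required before any row is written")
    rules = default_rules() if rules is None else rules
    allowlist = default_allowlist() if allowlist is None else allowlist

    report = PromotionReport()
    docs = list(store.scan())

    # physical slice-position multiset per series, from all instances
    series_positions: dict[str, list] = {}
    for doc in docs:
        pos = _slice_position(doc)
        if pos is not None:
            series_positions.setdefault(str(doc.tag("SeriesInstanceUID")), []).append(pos)

    inv = Inventory(inventory_path)
    conn = inv.conn
    try:
        conn.execute("BEGIN")
        for level in INVENTORY_COLUMNS:
            conn.execute(f"DELETE FROM {level}")

        image_rows: list[dict] = []
        for doc in docs:
            report.images_seen += 1
            row = _promote_one(
                doc, config, mapping, series_positions, rules, allowlist, report
            )
            if row is not None:
                image_rows.append(row)
                report.promoted_images += 1

        for row in image_rows:
            conn.execute(
                "INSERT OR REPLACE INTO image ({}) VALUES ({})".format(
                    ", ".join(_IMAGE_COLS), ", ".join("?" for _ in _IMAGE_COLS)
                ),
                [row[c] for c in _IMAGE_COLS],
            )
        report.series_rows = _collapse_series(conn, image_rows)
        report.study_rows = _collapse_study(conn, image_rows)
        conn.commit()
    except Exception:
        conn.rollback()
        raise
    finally:
        inv.close()
    return report


def _promote_one(
    doc: TagDocument,
    config: PromotionConfig,
    mapping: MappingTable,
    series_positions: dict[str, list],
    rules: list[ScanRule],
    allowlist: list[AllowlistEntry],
    report: PromotionReport,
) -> Optional[dict]:
    image_type = doc.tag("ImageType")
    primary = is_primary_original(image_type)
    if config.primary_original_only and not primary:
        report.skip("not-primary-original")
        return None
    chi = str(doc.tag("PatientID") or "")
    if len(chi) != 10 or not chi.isdigit():
        report.skip("missing-or-malformed-chi")
        return None
    eupi = mapping.lookup(chi)

    study_date = str(doc.tag("StudyDate") or "")
    year = int(study_date[:4]) if len(study_date) == 8 and study_date.isdigit() else None
    year_month = (
        f"{study_date[:4]}-{study_date[4:6]}" if year is not None else None
    )

    age_years = parse_age_string(doc.tag("PatientAge"))
    age_missing, age_derived = 0, 0
    if age_years is None:
        age_missing = 1
        if config.derive_age_from_birth_year and year is not None:
            birth = str(doc.tag("PatientBirthDate") or "")
            if len(birth) == 8 and birth.isdigit():
                age_years = float(year - int(birth[:4]))
                age_missing, age_derived = 0, 1

    series_uid = str(doc.tag("SeriesInstanceUID"))
    positions = series_positions.get(series_uid, [])
    if config.compute_repeated_volume and positions:
        repeated, n_acq = detect_repeated_volume(positions)
    else:
        repeated, n_acq = False, 1 if positions else 0
    contrast_present = doc.tag("ContrastBolusAgent") is not None
    contrast_candidate = flag_contrast_bolus(repeated, contrast_present)

    identity = _doc_identity(doc)

    def scanned(keyword: str) -> Optional[str]:
        value = doc.tag(keyword)
        if value is None:
            return None
        if config.scan_descriptions:
            result = scan_value(
                value, rules, identity=identity, allowlist=allowlist, location=keyword
            )
            if result.findings:
                report.descriptions_dropped += 1
                return None
        return str(value)

    def _float(v) -> Optional[float]:
        try:
            return float(v)
        except (TypeError, ValueError):
            return None

    return {
        "eupi": eupi,
        "study_uid": str(doc.tag("StudyInstanceUID")),
        "series_uid": series_uid,
        "sop_uid": doc.id,
        "modality": doc.tag("Modality"),
        "study_year": year,
        "study_year_month": year_month,
        "age_years": age_years,
        "age_missing": age_missing,
        "age_derived": age_derived,
        "sex": doc.tag("PatientSex"),
        "body_part": doc.tag("BodyPartExamined"),
        "image_type": "\\".join(image_type) if isinstance(image_type, list) else image_type,
        "is_primary_original": int(primary),
        "is_repeated_volume": int(repeated),
        "n_acquisitions": n_acq,
        "contrast_bolus_candidate": int(contrast_candidate),
        "slice_thickness": _float(doc.tag("SliceThickness")),
        "manufacturer": doc.tag("Manufacturer"),
        "manufacturer_model": doc.tag("ManufacturerModelName"),
        "series_description": scanned("SeriesDescription"),
        "study_description": scanned("StudyDescription"),
        "relative_path": doc.relative_path,
    }


def _collapse_series(conn: sqlite3.Connection, image_rows: list[dict]) -> int:
    groups: dict[str, list[dict]] = {}
    for row in image_rows:
        groups.setdefault(row["series_uid"], []).append(row)
    for series_uid, rows in sorted(groups.items()):
        first = rows[0]
        rec = {c: first.get(c) for c in _SERIES_COLS}
        rec["n_images"] = len(rows)
        conn.execute(
            "INSERT OR REPLACE INTO series ({}) VALUES ({})".format(
                ", ".join(_SERIES_COLS), ", ".join("?" for _ in _SERIES_COLS)
            ),
            [rec[c] for c in _SERIES_COLS],
        )
    return len(groups)


def _collapse_study(conn: sqlite3.Connection, image_rows: list[dict]) -> int:
    groups: dict[str, list[dict]] = {}
    for row in image_rows:
        groups.setdefault(row["study_uid"], []).append(row)
    for study_uid, rows in sorted(groups.items()):
        first = rows[0]
        modalities = "\\".join(sorted({r["modality"] for r in rows if r["modality"]}))
        rec = {
            "eupi": first["eupi"],
            "study_uid": study_uid,
            "modalities": modalities,
            "study_year": first["study_year"],
            "study_year_month": first["study_year_month"],
            "age_years": first["age_years"],
            "sex": first["sex"],
            "study_description": first["study_description"],
            "n_series": len({r["series_uid"] for r in rows}),
            "n_images": len(rows),
        }
        conn.execute(
            "INSERT OR REPLACE INTO study ({}) VALUES ({})".format(
                ", ".join(_STUDY_COLS), ", ".join("?" for _ in _STUDY_COLS)
            ),
            [rec[c] for c in _STUDY_COLS],
        )
    return len(groups)
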