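"""Cohort building and the end-to-end extraction pipeline.

A cohort is a filter over the inventory at study, series or image level,
optionally intersected with an external EUPI list (the "cohort generated
from another dataset" case). Extraction resolves the cohort to archive
files, anonymises tags, redacts pixels, and passes every candidate through
the identifiable-data validation gate before release: any finding — or any
scanner failure — quarantines the file instead of releasing it.

Per-file work is dispatched through a queue contract (publish/consume,
at-least-once delivery, idempotent handlers), realised in process by
default; the final state is invariant to the worker count.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .anonymiser import AnonymisationError, AnonymisationProfile, UidMap, anonymise_tags, redact_pixels
from .corpus import CorpusManifest, CorpusSpec, generate_corpus
from .model import TagTree, read_instance, tags_to_document, write_instance
from .promotion import (
    INVENTORY_COLUMNS,
    Inventory,
    PromotionConfig,
    promote,
    _doc_identity,
)
from .pseudonym import MappingTable, ProjectIdMap
from .scanner import (
    AllowlistEntry,
    ScanRule,
    ScannerError,
    TemplateTextDetector,
    TextDetector,
    default_allowlist,
    default_rules,
    scan_document,
    scan_pixels,
    scan_value,
)
from .store import TagStore


class ExtractionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# cohorts

_SQL_KEYWORDS = {
    "and", "or", "not", "null", "is", "in", "like", "between", "case",
    "when", "then", "else", "end", "cast", "as", "integer", "real", "text",
}
_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


@dataclass
class CohortDefinition:
    """A research project's image selection."""

    project: str
    level: str                      # study | series | image
    filter: str                     # SQL boolean expression over inventory columns
    external_eupis: Optional[list[str]] = None

    def validate(self) -> None:
        if self.level not in INVENTORY_COLUMNS:
            raise ExtractionError(f"unknown cohort level {self.level!r}")
        columns = set(INVENTORY_COLUMNS[self.level])
        stripped = re.sub(r"'[^']*'", " ", self.filter)  # drop string literals
        for token in _IDENT_RE.findall(stripped):
            if token.lower() in _SQL_KEYWORDS:
                continue
            if token not in columns:
                raise ExtractionError(
                    f"filter references unknown column {token!r} at level {self.level}"
                )

    def cohort_id(self) -> str:
        payload = json.dumps(
            [self.project, self.level, self.filter, sorted(self.external_eupis or [])]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CohortResult:
    cohort_id: str
    definition: CohortDefinition
    uids: list[str]
    eupis: list[str]


def build_cohort(defn: CohortDefinition, inventory: Inventory) -> CohortResult:
    """Exact filter evaluation, persisted for reproducible re-release."""
    defn.validate()
    uid_col = {"study": "study_uid", "series": "series_uid", "image": "sop_uid"}[
        defn.level
    ]
    rows = inventory.rows(defn.level, where=defn.filter)
    if defn.external_eupis is not None:
        wanted = set(defn.external_eupis)
        rows = [r for r in rows if r["eupi"] in wanted]
    rows.sort(key=lambda r: r[uid_col])
    result = CohortResult(
        cohort_id=defn.cohort_id(),
        definition=defn,
        uids=[r[uid_col] for r in rows],
        eupis=[r["eupi"] for r in rows],
    )
    conn = inventory.conn
    conn.execute(
        "CREATE TABLE IF NOT EXISTS cohort ("
        " cohort_id TEXT, project TEXT, level TEXT, uid TEXT, eupi TEXT,"
        " PRIMARY KEY (cohort_id, uid))"
    )
    conn.execute("DELETE FROM cohort WHERE cohort_id=?", (result.cohort_id,))
    for uid, eupi in zip(result.uids, result.eupis):
        conn.execute(
            "INSERT OR REPLACE INTO cohort VALUES (?, ?, ?, ?, ?)",
            (result.cohort_id, defn.project, defn.level, uid, eupi),
        )
    conn.commit()
    return result


# ---------------------------------------------------------------------------
# queue contract


class InProcessQueue:
    """Minimal at-least-once queue realised in process.

    ``consume_all`` partitions pending messages across ``workers`` virtual
    consumers; because handlers must be idempotent, the final state equals
    a single-consumer run. ``redeliver_every`` re-delivers every n-th
    message once, exercising the at-least-once contract.
    """

    def __init__(self) -> None:
        self._messages: list[dict] = []

    def publish(self, message: dict) -> None:
        self._messages.append(message)

    def consume_all(
        self,
        handler: Callable[[dict], None],
        workers: int = 1,
        redeliver_every: Optional[int] = None,
    ) -> int:
        if workers < 1:
            raise ExtractionError("workers must be >= 1")
        lanes = [self._messages[w::workers] for w in range(workers)]
        delivered = 0
        # round-robin across lanes approximates concurrent consumers
        for i in range(max((len(l) for l in lanes), default=0)):
            for lane in lanes:
                if i < len(lane):
                    handler(lane[i])
                    delivered += 1
                    if redeliver_every and delivered % redeliver_every == 0:
                        handler(lane[i])
        self._messages.clear()
        return delivered


# ---------------------------------------------------------------------------
# extraction jobs


@dataclass
class ExtractReport:
    job_id: str
    requested: int = 0
    released: int = 0
    rejected_identifiable: int = 0
    rejected_missing: int = 0
    failed: int = 0
    outcomes: dict[str, str] = field(default_factory=dict)  # sop_uid -> outcome
    released_files: dict[str, str] = field(default_factory=dict)  # sop -> path

    def reconciles(self) -> bool:
        return self.requested == (
            self.released + self.rejected_identifiable + self.rejected_missing + self.failed
        )


@dataclass
class ExtractionJob:
    cohort: CohortResult
    profile: AnonymisationProfile
    archive_root: Path
    extract_root: Path
    quarantine_root: Path
    project_salt: str
    detector: TextDetector = field(default_factory=TemplateTextDetector)
    rules: list[ScanRule] = field(default_factory=default_rules)
    allowlist: list[AllowlistEntry] = field(default_factory=default_allowlist)
    workers: int = 1

    @property
    def job_id(self) -> str:
        return f"{self.cohort.definition.project}-{self.cohort.cohort_id}"


def _resolve_images(cohort: CohortResult, inventory: Inventory) -> list[dict]:
    level = cohort.definition.level
    if not cohort.uids:
        return []
    placeholders = ", ".join("?" for _ in cohort.uids)
    col = {"study": "study_uid", "series": "series_uid", "image": "sop_uid"}[level]
    rows = inventory.rows("image", where=f"{col} IN ({placeholders})", params=tuple(cohort.uids))
    rows.sort(key=lambda r: r["sop_uid"])
    return rows


def extract(
    job: ExtractionJob,
    inventory: Inventory,
    audit: Optional["AuditLog"] = None,
    redeliver_every: Optional[int] = None,
) -> ExtractReport:
    """Run one extraction job end to end.

    Per-file failures never abort the job; the report reconciles exactly:
    requested = released + quarantined + missing + failed. The released
    tree layout is ``extract_root/project/<study>/<series>/<sop>.dcm`` in
    remapped UIDs, plus a researcher metadata table (TSV) restricted to the
    profile whitelist and project identifiers.
    """
    archive_root = Path(job.archive_root)
    if not archive_root.is_dir():
        raise ExtractionError(f"archive root {archive_root} missing")
    job.profile.validate()
    project = job.cohort.definition.project
    uid_map = UidMap(project, job.profile.uid_salt)
    id_map = ProjectIdMap()
    id_map.register(project, job.project_salt)

    rows = _resolve_images(job.cohort, inventory)
    report = ExtractReport(job_id=job.job_id, requested=len(rows))
    release_dir = Path(job.extract_root) / project
    quarantine_dir = Path(job.quarantine_root) / project
    metadata_rows: dict[str, dict] = {}

    def handle(msg: dict) -> None:
        sop = msg["sop_uid"]
        if sop in report.outcomes and report.outcomes[sop] != "pending":
            return  # at-least-once redelivery: already done
        outcome = _extract_one(
            msg, job, uid_map, id_map, archive_root, release_dir, quarantine_dir,
            metadata_rows,
        )
        report.outcomes[sop] = outcome["status"]
        if audit is not None:
            audit.record("extract-file", job=job.job_id, sop=sop, **outcome)

    queue = InProcessQueue()
    for row in rows:
        queue.publish(row)
    queue.consume_all(handle, workers=job.workers, redeliver_every=redeliver_every)

    for sop, status in report.outcomes.items():
        if status == "released":
            report.released += 1
        elif status == "quarantined":
            report.rejected_identifiable += 1
        elif status == "missing":
            report.rejected_missing += 1
        else:
            report.failed += 1
    for sop, row in metadata_rows.items():
        if report.outcomes.get(sop) == "released":
            report.released_files[sop] = row["_path"]

    _write_metadata_table(release_dir, metadata_rows, report)
    if audit is not None:
        audit.record(
            "extract-job", job=job.job_id, requested=report.requested,
            released=report.released, quarantined=report.rejected_identifiable,
            missing=report.rejected_missing, failed=report.failed,
        )
    assert report.reconciles()
    return report


def _extract_one(
    row: dict,
    job: ExtractionJob,
    uid_map: UidMap,
    id_map: ProjectIdMap,
    archive_root: Path,
    release_dir: Path,
    quarantine_dir: Path,
    metadata_rows: dict[str, dict],
) -> dict:
    sop = row["sop_uid"]
    src = archive_root / row["relative_path"]
    if not src.is_file():
        return {"status": "missing"}
    project = job.cohort.definition.project
    try:
        tree = read_instance(src, archive_root)
        identity = _doc_identity(tags_to_document(tree))
        project_pid = id_map.project_id(row["eupi"], project)
        candidate = anonymise_tags(tree, job.profile, uid_map, project_pid)
        # free-text fields that leak are dropped, not the whole file —
        # mirroring the promotion stage's column-drop policy
        for keyword in ("StudyDescription", "SeriesDescription"):
            if keyword in candidate.dataset:
                scrubbed = scan_value(
                    str(candidate.dataset[keyword].value), job.rules,
                    identity=identity, allowlist=job.allowlist, location=keyword,
                )
                if scrubbed.findings:
                    del candidate.dataset[keyword]
        candidate = redact_pixels(candidate, job.profile.redaction_rules)

        # defence-in-depth validation gate: tags, then pixels, fail closed
        doc_result = scan_document(
            tags_to_document(candidate), job.rules, identity=identity,
            allowlist=job.allowlist,
        )
        pixels = candidate.pixels
        pix_result = scan_pixels(
            pixels, job.detector, job.rules, identity=identity,
            allowlist=job.allowlist, context=sop,
        ) if pixels is not None else None
        findings = doc_result.findings + (pix_result.findings if pix_result else [])
        if findings:
            _quarantine(quarantine_dir, sop, candidate, findings)
            return {
                "status": "quarantined",
                "findings": [f.rule_id for f in findings],
            }

        new_sop = uid_map.remap(sop)
        rel = Path(uid_map.remap(row["study_uid"])) / uid_map.remap(
            row["series_uid"]
        ) / f"{new_sop}.dcm"
        out_path = release_dir / rel
        write_instance(candidate, out_path)
        metadata_rows[sop] = _metadata_row(row, job.profile, project_pid, uid_map, rel)
        return {"status": "released", "path": str(rel)}
    except ScannerError as exc:
        _quarantine(quarantine_dir, sop, None, [], error=str(exc))
        return {"status": "quarantined", "error": str(exc)}
    except (AnonymisationError, OSError, ValueError) as exc:
        return {"status": "failed", "error": str(exc)}


def _metadata_row(
    row: dict,
    profile: AnonymisationProfile,
    project_pid: str,
    uid_map: UidMap,
    rel: Path,
) -> dict:
    # columns limited to profile whitelist analogues + project identifiers
    whitelisted = {
        "Modality": "modality",
        "StudyDate": "study_year_month",
        "PatientAge": "age_years",
        "PatientSex": "sex",
        "BodyPartExamined": "body_part",
        "SeriesDescription": "series_description",
        "StudyDescription": "study_description",
    }
    out = {
        "project_patient_id": project_pid,
        "study_uid": uid_map.remap(row["study_uid"]),
        "series_uid": uid_map.remap(row["series_uid"]),
        "sop_uid": uid_map.remap(row["sop_uid"]),
    }
    for keyword, col in whitelisted.items():
        if keyword in profile.whitelist:
            out[col] = row.get(col)
    out["_path"] = str(rel)
    return out


def _write_metadata_table(
    release_dir: Path, metadata_rows: dict[str, dict], report: ExtractReport
) -> None:
    release_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        metadata_rows[sop]
        for sop in sorted(metadata_rows)
        if report.outcomes.get(sop) == "released"
    ]
    columns = [c for c in (rows[0] if rows else {"project_patient_id": 1}) if c != "_path"]
    rows.sort(key=lambda r: (r["project_patient_id"], r["study_uid"], r["sop_uid"]))
    with open(release_dir / "metadata.tsv", "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write(
                "\t".join("" if r.get(c) is None else str(r.get(c)) for c in columns)
                + "\n"
            )
    with open(release_dir / "release_manifest.json", "w") as fh:
        json.dump(
            {
                "job_id": report.job_id,
                "released": report.released,
                "files": {
                    uid_mapped: path
                    for uid_mapped, path in sorted(
                        (metadata_rows[s]["sop_uid"], report.released_files[s])
                        for s in report.released_files
                    )
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def _quarantine(
    quarantine_dir: Path,
    sop: str,
    candidate: Optional[TagTree],
    findings: list,
    error: Optional[str] = None,
) -> None:
    quarantine_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "sop_uid": sop,
        "error": error,
        "findings": [
            {
                "location": f.location,
                "matched_text": f.matched_text,
                "rule_id": f.rule_id,
                "severity": f.severity,
            }
            for f in findings
        ],
    }
    with open(quarantine_dir / f"{sop}.findings.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
    if candidate is not None:
        write_instance(candidate, quarantine_dir / f"{sop}.dcm")


# ---------------------------------------------------------------------------
# audit + pipeline


class AuditLog:
    """Append-only JSON-lines record of every state transition."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, event: str, **fields) -> None:
        rec = {"event": event, "ts": dt.datetime.now(dt.timezone.utc).isoformat(), **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, default=str) + "\n")


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, rooted at ``work_dir``."""

    work_dir: Path
    spec: CorpusSpec = field(default_factory=CorpusSpec)
    eupi_key: str = "demo-eupi-key"
    project: str = "demo-project"
    project_salt: str = "demo-salt"
    cohort_level: str = "series"
    cohort_filter: str = "modality = 'CT'"
    profile: Optional[AnonymisationProfile] = None
    promotion: PromotionConfig = field(default_factory=PromotionConfig)
    workers: int = 1
    reconcile_multi_chi: bool = True

    def __post_init__(self) -> None:
        self.work_dir = Path(self.work_dir)
        if self.profile is None:
            self.profile = AnonymisationProfile(project=self.project)

    @property
    def archive_root(self) -> Path:
        return self.work_dir / "archive"

    @property
    def store_path(self) -> Path:
        return self.work_dir / "tagstore.sqlite"

    @property
    def inventory_path(self) -> Path:
        return self.work_dir / "inventory.sqlite"

    @property
    def extract_root(self) -> Path:
        return self.work_dir / "extract"

    @property
    def quarantine_root(self) -> Path:
        return self.work_dir / "quarantine"

    @property
    def state_path(self) -> Path:
        return self.work_dir / "pipeline_state.json"


def run_pipeline(
    config: PipelineConfig,
    detector: Optional[TextDetector] = None,
    resume: bool = True,
) -> dict:
    """generate -> load -> reconcile -> promote -> cohort -> extract.

    Stage completion is checkpointed to ``pipeline_state.json``; a re-run
    (after a crash or otherwise) skips completed stages and, because every
    stage is idempotent, converges on the same final state as an
    uninterrupted run.
    """
    config.work_dir.mkdir(parents=True, exist_ok=True)
    audit = AuditLog(config.work_dir / "audit.jsonl")
    state = {}
    if resume and config.state_path.is_file():
        state = json.loads(config.state_path.read_text())

    def checkpoint(stage: str, payload: dict) -> None:
        state[stage] = payload
        config.state_path.write_text(json.dumps(state, indent=2, default=str))
        audit.record("stage-complete", stage=stage, **{
            k: v for k, v in payload.items() if isinstance(v, (int, str, float))
        })

    report: dict = {}

    if "generate" not in state:
        manifest = generate_corpus(config.spec, config.archive_root)
        manifest.save(config.work_dir / "manifest")
        checkpoint("generate", {"n_files": len(manifest.files)})
    manifest = CorpusManifest.load(config.work_dir / "manifest")
    report["generate"] = {"n_files": len(manifest.files)}

    store = TagStore(config.store_path)
    if "load" not in state:
        load_report = store.load_directory(config.archive_root)
        checkpoint(
            "load",
            {
                "files_seen": load_report.files_seen,
                "loaded": load_report.loaded,
                "updated": load_report.updated,
                "rejected": load_report.rejected,
            },
        )
    report["load"] = state["load"]

    mapping = MappingTable(config.eupi_key)
    if config.reconcile_multi_chi:
        groups = [g for g in manifest.master_persons if len(g) > 1]
        mapping.reconcile(groups)
    mapping.save(config.inventory_path)

    if "promote" not in state:
        promo_report = promote(store, config.promotion, mapping, config.inventory_path)
        checkpoint(
            "promote",
            {
                "images_seen": promo_report.images_seen,
                "promoted_images": promo_report.promoted_images,
                "series_rows": promo_report.series_rows,
                "study_rows": promo_report.study_rows,
                "descriptions_dropped": promo_report.descriptions_dropped,
            },
        )
    report["promote"] = state["promote"]

    inventory = Inventory(config.inventory_path)
    defn = CohortDefinition(
        project=config.project, level=config.cohort_level, filter=config.cohort_filter
    )
    cohort = build_cohort(defn, inventory)
    report["cohort"] = {"cohort_id": cohort.cohort_id, "n_uids": len(cohort.uids)}

    job = ExtractionJob(
        cohort=cohort,
        profile=config.profile,
        archive_root=config.archive_root,
        extract_root=config.extract_root,
        quarantine_root=config.quarantine_root,
        project_salt=config.project_salt,
        detector=detector or TemplateTextDetector(),
        workers=config.workers,
    )
    extract_report = extract(job, inventory, audit=audit)
    checkpoint(
        "extract",
        {
            "requested": extract_report.requested,
            "released": extract_report.released,
            "quarantined": extract_report.rejected_identifiable,
            "missing": extract_report.rejected_missing,
            "failed": extract_report.failed,
        },
    )
    report["extract"] = state["extract"]
    store.close()
    inventory.close()
    return report
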