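"""Cohorts, the extraction gate, queue semantics and the full pipeline."""

import hashlib
import json
from pathlib import Path

import pytest

from dicomsieve import (
    AnonymisationProfile,
    CohortDefinition,
    CorpusSpec,
    GroundTruthDetector,
    InProcessQueue,
    RedactionRule,
    build_cohort,
    extract,
    parse_age_string,
    read_instance,
)
from dicomsieve.extraction import ExtractionError, ExtractionJob, PipelineConfig, run_pipeline
from dicomsieve.promotion import is_primary_original


def _oracle_series(manifest, predicate):
    """Brute-force series-level filter evaluation straight off the manifest."""
    out = set()
    for series_uid, recs in manifest.series_records().items():
        rec = recs[0]
        if not is_primary_original(rec.image_type):
            continue
        if predicate(rec):
            out.add(series_uid)
    return out


def test_cohort_filter_matches_manifest_oracle(inventory, corpus):
    _, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(
        project="p1",
        level="series",
        filter="modality = 'CT' AND age_years >= 40 AND age_years <= 80",
    )
    result = build_cohort(defn, inv)
    expected = _oracle_series(
        manifest,
        lambda r: r.modality == "CT"
        and 40 <= _age_from_string(r.age_string) <= 80,
    )
    assert set(result.uids) == expected


def _age_from_string(s: str) -> float:
    # independent conversion for the oracle: suffix divisor table
    unit = s[-1] if s[-1] in "YMWD" else ""
    digits = s[:-1] if unit else s
    div = {"Y": 1, "": 1, "M": 12, "W": 365.25 / 7, "D": 365.25}[unit]
    return float(digits) / div


def test_unsatisfiable_filter_gives_empty_cohort(inventory):
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="age_years < 0")
    assert build_cohort(defn, inv).uids == []


def test_unknown_column_rejected(inventory):
    inv, _ = inventory
    with pytest.raises(ExtractionError):
        build_cohort(
            CohortDefinition(project="p1", level="series", filter="shoe_size > 9"), inv
        )


def test_external_eupi_list_restricts_cohort(inventory, corpus, mapping):
    _, manifest = corpus
    inv, _ = inventory
    target = manifest.patients[0]
    eupi = mapping.lookup(target.chi)
    defn = CohortDefinition(
        project="p1", level="series", filter="1=1", external_eupis=[eupi]
    )
    result = build_cohort(defn, inv)
    assert result.uids
    chis = set(target.all_chis)
    expected = _oracle_series(manifest, lambda r: r.chi in chis)
    assert set(result.uids) == expected


def _job(cohort, root, out, detector, rules=(), workers=1, project_salt="salt-1"):
    return ExtractionJob(
        cohort=cohort,
        profile=AnonymisationProfile(
            project=cohort.definition.project, redaction_rules=list(rules)
        ),
        archive_root=root,
        extract_root=Path(out) / "release",
        quarantine_root=Path(out) / "quarantine",
        project_salt=project_salt,
        detector=detector,
        workers=workers,
    )


def test_clean_ct_cohort_releases_everything(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="modality = 'CT'")
    cohort = build_cohort(defn, inv)
    job = _job(cohort, root, tmp_path, GroundTruthDetector(manifest))
    report = extract(job, inv)
    assert report.reconciles()
    assert report.rejected_identifiable == 0
    assert report.released == report.requested > 0
    released = list((tmp_path / "release").rglob("*.dcm"))
    assert len(released) == report.released
    meta = (tmp_path / "release" / "p1" / "metadata.tsv").read_text().splitlines()
    assert len(meta) - 1 == report.released


def test_burned_series_without_rule_is_quarantined(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(
        project="p1", level="series", filter="modality = 'US' OR modality = 'MR'"
    )
    cohort = build_cohort(defn, inv)
    job = _job(cohort, root, tmp_path, GroundTruthDetector(manifest))
    report = extract(job, inv)
    burned_sops = {
        r.sop_uid
        for r in manifest.files
        if r.burned_text is not None and is_primary_original(r.image_type)
    }
    cohort_sops = set(report.outcomes)
    assert burned_sops & cohort_sops, "cohort should include burned images"
    for sop in burned_sops & cohort_sops:
        assert report.outcomes[sop] == "quarantined"
        assert (tmp_path / "quarantine" / "p1" / f"{sop}.findings.json").is_file()
    assert report.reconciles()
    # nothing quarantined ever reaches the release tree
    released_names = {p.stem for p in (tmp_path / "release").rglob("*.dcm")}
    assert not {s for s in burned_sops} & released_names


def test_covering_redaction_rule_releases_burned_series(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="modality = 'US'")
    cohort = build_cohort(defn, inv)
    rule = RedactionRule("US", ".*", ".*", ((0, 0, 256, 40),))
    job = _job(cohort, root, tmp_path, GroundTruthDetector(manifest), rules=[rule])
    report = extract(job, inv)
    assert report.requested > 0
    assert report.rejected_identifiable == 0
    assert report.released == report.requested


def _release_digest(out_dir: Path) -> dict:
    return {
        str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out_dir.rglob("*"))
        if p.is_file()
    }


def test_re_extraction_is_byte_identical(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="modality = 'CT'")
    cohort = build_cohort(defn, inv)
    digests = []
    for run in ("one", "two"):
        out = tmp_path / run
        job = _job(cohort, root, out, GroundTruthDetector(manifest))
        report = extract(job, inv)
        digests.append((_release_digest(out / "release"), report.released))
    assert digests[0] == digests[1]


def test_worker_count_invariance(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="1=1")
    cohort = build_cohort(defn, inv)
    results = {}
    for workers in (1, 4):
        out = tmp_path / f"w{workers}"
        job = _job(cohort, root, out, GroundTruthDetector(manifest), workers=workers)
        report = extract(job, inv)
        results[workers] = (_release_digest(out / "release"), dict(report.outcomes))
    assert results[1] == results[4]


def test_at_least_once_redelivery_is_harmless(tmp_path, inventory, corpus):
    root, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="modality = 'CT'")
    cohort = build_cohort(defn, inv)
    out1, out2 = tmp_path / "plain", tmp_path / "redelivered"
    r1 = extract(_job(cohort, root, out1, GroundTruthDetector(manifest)), inv)
    r2 = extract(
        _job(cohort, root, out2, GroundTruthDetector(manifest)),
        inv,
        redeliver_every=2,
    )
    assert r1.outcomes == r2.outcomes
    assert _release_digest(out1 / "release") == _release_digest(out2 / "release")


def test_queue_requires_positive_workers():
    q = InProcessQueue()
    q.publish({"x": 1})
    with pytest.raises(ExtractionError):
        q.consume_all(lambda m: None, workers=0)


def test_missing_archive_root_aborts(tmp_path, inventory, corpus):
    _, manifest = corpus
    inv, _ = inventory
    defn = CohortDefinition(project="p1", level="series", filter="modality = 'CT'")
    cohort = build_cohort(defn, inv)
    job = _job(cohort, tmp_path / "nowhere", tmp_path, GroundTruthDetector(manifest))
    with pytest.raises(ExtractionError):
        extract(job, inv)


# -- end-to-end pipeline ----------------------------------------------------


def test_pipeline_completes_on_small_corpus(tmp_path):
    cfg = PipelineConfig(
        work_dir=tmp_path / "run",
        spec=CorpusSpec(n_patients=2, seed=9),
        cohort_filter="1=1",
    )
    report = run_pipeline(cfg)
    ex = report["extract"]
    assert ex["requested"] == ex["released"] + ex["quarantined"] + ex["missing"] + ex["failed"]
    assert (tmp_path / "run" / "audit.jsonl").is_file()
    assert report["load"]["rejected"] == 0


def test_pipeline_resume_after_crash_matches_uninterrupted(tmp_path):
    spec = CorpusSpec(n_patients=2, seed=9)
    clean_cfg = PipelineConfig(
        work_dir=tmp_path / "clean", spec=spec, cohort_filter="1=1"
    )
    clean = run_pipeline(clean_cfg)

    crash_cfg = PipelineConfig(
        work_dir=tmp_path / "crash", spec=spec, cohort_filter="1=1"
    )
    bad_profile = AnonymisationProfile(project="demo-project", date_policy="year-month")
    bad_profile.date_policy = "bogus"  # fails validation at the extract stage
    crash_cfg.profile = bad_profile
    with pytest.raises(Exception):
        run_pipeline(crash_cfg)
    state = json.loads((tmp_path / "crash" / "pipeline_state.json").read_text())
    assert "promote" in state and "extract" not in state  # crashed mid-run

    crash_cfg.profile = AnonymisationProfile(project="demo-project")
    resumed = run_pipeline(crash_cfg, resume=True)
    assert resumed["extract"] == clean["extract"]
    assert resumed["promote"] == clean["promote"]
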