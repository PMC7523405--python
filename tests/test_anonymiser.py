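"""Anonymiser: whitelist retention, UID remapping, coarsening, redaction."""

import numpy as np
import pytest
from pydicom.dataset import Dataset

from dicomsieve import (
    AnonymisationError,
    AnonymisationProfile,
    GroundTruthDetector,
    RedactionRule,
    TagTree,
    UidMap,
    anonymise_tags,
    convert_format,
    default_rules,
    example_us_redaction_rule,
    read_instance,
    redact_pixels,
    scan_pixels,
    write_instance,
)
from dicomsieve.anonymiser import DEID_MARKER_TAGS, STRUCTURAL_REQUIRED


@pytest.fixture()
def profile() -> AnonymisationProfile:
    return AnonymisationProfile(project="proj-a")


def _ultrasound(rows=768, cols=1024, manufacturer="Manufacturer X", model="Model Y"):
    ds = Dataset()
    ds.SOPInstanceUID = "1.2.3.1"
    ds.SeriesInstanceUID = "1.2.3.2"
    ds.StudyInstanceUID = "1.2.3.3"
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.6.1"
    ds.Modality = "US"
    ds.Manufacturer = manufacturer
    ds.ManufacturerModelName = model
    ds.InstanceNumber = 1
    pixels = (np.arange(rows * cols, dtype=np.uint8) % 199).reshape(rows, cols)
    ds.Rows, ds.Columns = rows, cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()
    return TagTree(dataset=ds)


def test_output_tags_within_whitelist_and_structural(corpus, profile):
    root, manifest = corpus
    rec = manifest.files[0]
    tree = read_instance(root / rec.relative_path, root)
    assert tree.leaf_count() > 20
    uid_map = UidMap("proj-a", "salt")
    out = anonymise_tags(tree, profile, uid_map, "PID001")
    allowed = set(profile.whitelist) | set(STRUCTURAL_REQUIRED) | set(DEID_MARKER_TAGS)
    for elem in out.dataset:
        if elem.keyword == "PixelData":
            continue
        assert not elem.tag.is_private
        assert elem.keyword in allowed, elem.keyword
    assert "PatientName" not in out.dataset
    assert out.dataset.PatientID == "PID001"
    assert out.dataset.PatientIdentityRemoved == "YES"


def test_no_planted_identifier_survives_tag_anonymisation(corpus, profile):
    root, manifest = corpus
    uid_map = UidMap("proj-a", "salt")
    # description-leak files keep their leak in the whitelisted description
    # tag by design; the validation gate quarantines those downstream
    clean = [
        r
        for r in manifest.files
        if not any("(0008,10" in p.tag_path for p in r.planted)
    ][:10]
    assert clean
    for rec in clean:
        tree = read_instance(root / rec.relative_path, root)
        out = anonymise_tags(tree, profile, uid_map, "PID001")
        identifiers = manifest.identity_for_chi(rec.chi).identifier_strings()
        blob = " \\ ".join(str(v) for _, v in out.leaves()).upper()
        leaked = [s for s in identifiers if s.upper() in blob]
        assert not leaked, (rec.relative_path, leaked)


def test_anonymisation_is_deterministic(corpus, profile, tmp_path):
    root, manifest = corpus
    tree1 = read_instance(root / manifest.files[0].relative_path, root)
    tree2 = read_instance(root / manifest.files[0].relative_path, root)
    a = anonymise_tags(tree1, profile, UidMap("proj-a", "salt"), "PID001")
    b = anonymise_tags(tree2, profile, UidMap("proj-a", "salt"), "PID001")
    write_instance(a, tmp_path / "a.dcm")
    write_instance(b, tmp_path / "b.dcm")
    assert (tmp_path / "a.dcm").read_bytes() == (tmp_path / "b.dcm").read_bytes()


def test_projects_get_unlinkable_uids_and_patient_ids(corpus, profile):
    root, manifest = corpus
    tree = read_instance(root / manifest.files[0].relative_path, root)
    tree2 = read_instance(root / manifest.files[0].relative_path, root)
    a = anonymise_tags(tree, profile, UidMap("proj-a", "salt"), "PID-A")
    b = anonymise_tags(
        tree2, AnonymisationProfile(project="proj-b"), UidMap("proj-b", "salt"), "PID-B"
    )
    assert a.sop_uid != b.sop_uid
    assert a.study_uid != b.study_uid
    assert a.dataset.PatientID != b.dataset.PatientID


def test_uid_hierarchy_preserved_within_project(corpus, profile):
    """Two instances of one series keep a common remapped series UID."""
    root, manifest = corpus
    series = next(recs for recs in manifest.series_records().values() if len(recs) > 1)
    uid_map = UidMap("proj-a", "salt")
    outs = [
        anonymise_tags(
            read_instance(root / r.relative_path, root), profile, uid_map, "PID"
        )
        for r in series[:2]
    ]
    assert outs[0].series_uid == outs[1].series_uid
    assert outs[0].study_uid == outs[1].study_uid
    assert outs[0].sop_uid != outs[1].sop_uid
    for uid in (outs[0].sop_uid, outs[0].series_uid, outs[0].study_uid):
        assert len(uid) <= 64
        assert all(part.isdigit() for part in uid.split("."))


def test_date_coarsening_policies(corpus):
    root, manifest = corpus
    rec = manifest.files[0]
    tree = read_instance(root / rec.relative_path, root)
    ym = anonymise_tags(
        tree,
        AnonymisationProfile(project="p", date_policy="year-month"),
        UidMap("p", "s"),
        "PID",
    )
    assert str(ym.dataset.StudyDate) == rec.study_date[:6] + "01"
    tree2 = read_instance(root / rec.relative_path, root)
    y = anonymise_tags(
        tree2,
        AnonymisationProfile(project="p", date_policy="year-only"),
        UidMap("p", "s"),
        "PID",
    )
    assert str(y.dataset.StudyDate) == rec.study_date[:4] + "0101"


def test_age_banding_policy(corpus):
    root, manifest = corpus
    rec = next(r for r in manifest.files if r.age_string.endswith("Y"))
    tree = read_instance(root / rec.relative_path, root)
    out = anonymise_tags(
        tree,
        AnonymisationProfile(project="p", age_policy="banded:5"),
        UidMap("p", "s"),
        "PID",
    )
    banded = int(str(out.dataset.PatientAge)[:3])
    assert banded % 5 == 0
    assert banded <= int(rec.age_string[:3]) < banded + 5


def test_missing_structural_tag_rejects_file(profile):
    ds = Dataset()
    ds.SOPInstanceUID = "1.2.3.1"
    ds.SeriesInstanceUID = "1.2.3.2"
    ds.StudyInstanceUID = "1.2.3.3"
    ds.Modality = "CT"  # no SOPClassUID, no pixel module
    with pytest.raises(AnonymisationError):
        anonymise_tags(TagTree(dataset=ds), profile, UidMap("p", "s"), "PID")


def test_marker_guards_idempotence(corpus, profile):
    root, manifest = corpus
    tree = read_instance(root / manifest.files[0].relative_path, root)
    uid_map = UidMap("proj-a", "salt")
    once = anonymise_tags(tree, profile, uid_map, "PID001")
    again = anonymise_tags(once, profile, uid_map, "PID001")
    # identical up to UID re-remapping
    a = {p.render(): str(v) for p, v in once.leaves() if not p.render().startswith("(0008,0018)")}
    b = {p.render(): str(v) for p, v in again.leaves() if not p.render().startswith("(0008,0018)")}
    skip = {"(0008,0018)", "(0020,000d)", "(0020,000e)"}
    assert {k: v for k, v in a.items() if k not in skip} == {
        k: v for k, v in b.items() if k not in skip
    }


# -- pixel redaction --------------------------------------------------------


def test_redaction_rule_fills_exactly_the_rectangle():
    tree = _ultrasound()
    before = tree.pixels.copy()
    out = redact_pixels(tree, [example_us_redaction_rule()])
    px = out.pixels
    assert (px[0:200, 0:1000] == 0).all()
    assert (px[200:, :] == before[200:, :]).all()
    assert (px[:, 1000:] == before[:, 1000:]).all()


def test_non_matching_modality_unchanged():
    ct = _ultrasound()
    ct.dataset.Modality = "CT"
    before = ct.dataset.PixelData
    out = redact_pixels(ct, [example_us_redaction_rule()])
    assert out.dataset.PixelData == before


def test_non_matching_model_unchanged():
    us = _ultrasound(model="Other Model")
    before = us.dataset.PixelData
    out = redact_pixels(us, [example_us_redaction_rule()])
    assert out.dataset.PixelData == before


def test_oversized_rectangle_clipped(caplog):
    us = _ultrasound(rows=100, cols=100)
    rule = RedactionRule("US", ".*", ".*", ((0, 0, 1000, 200),))
    out = redact_pixels(us, [rule])
    assert (out.pixels == 0).all()


def test_redaction_followed_by_scan_is_clean(corpus):
    root, manifest = corpus
    rec = next(r for r in manifest.files if r.burned_text is not None)
    tree = read_instance(root / rec.relative_path, root)
    x0, y0, x1, y1 = rec.burned_text.region
    rule = RedactionRule(rec.modality, ".*", ".*", ((x0, y0, x1, y1),))
    out = redact_pixels(tree, [rule])
    result = scan_pixels(
        out.pixels, GroundTruthDetector(manifest), default_rules(), context=rec.sop_uid
    )
    assert result.findings == []


def test_convert_format_identity_and_rejection(tmp_path, corpus):
    root, manifest = corpus
    tree = read_instance(root / manifest.files[0].relative_path, root)
    path = convert_format(tree, tmp_path / "out.dcm", target="dicom")
    assert read_instance(path, tmp_path).tags_equal(tree)
    with pytest.raises(AnonymisationError):
        convert_format(tree, tmp_path / "x.nii", target="nifti")
    with pytest.raises(AnonymisationError):
        convert_format(tree, tmp_path / "x.bin", target="mystery")
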