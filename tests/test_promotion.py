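"""Promotion: homogenisation, derived fields, whitelist closure, idempotency."""

import sqlite3
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from dicomsieve import (
    Inventory,
    PromotionConfig,
    detect_repeated_volume,
    flag_contrast_bolus,
    is_primary_original,
    parse_age_string,
    promote,
)
from dicomsieve.promotion import PromotionError, check_column_closure


@pytest.mark.parametrize(
    "text, expected",
    [
        ("075Y", 75.0),
        ("006M", 0.5),
        ("002D", 2 / 365.25),
        ("004W", 28 / 365.25),
        ("073", 73.0),          # bare number read as years
        (" 12 Y ", 12.0),
        ("banana", None),
        ("", None),
        (None, None),
    ],
)
def test_age_string_normalisation(text, expected):
    got = parse_age_string(text)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "image_type, expected",
    [
        ("ORIGINAL\\PRIMARY\\AXIAL", True),
        (["ORIGINAL", "PRIMARY", "AXIAL"], True),
        ("DERIVED\\SECONDARY", False),
        (["ORIGINAL"], False),
        (None, False),  # conservative default for missing tag
    ],
)
def test_primary_original_flag(image_type, expected):
    assert is_primary_original(image_type) is expected


@pytest.mark.parametrize(
    "positions, expected",
    [
        ([0, 1, 2, 0, 1, 2], (True, 2)),
        ([0, 1, 2], (False, 1)),
        ([0, 0, 0], (True, 3)),
        ([[0, 0, 5], [0, 0, 10], [0, 0, 5.0049]], (True, 2)),  # within tolerance
        ([[0, 0, 5], [0, 0, 5.5]], (False, 1)),
    ],
)
def test_repeated_volume_examples(positions, expected):
    assert detect_repeated_volume(positions) == expected


@settings(max_examples=150, deadline=None)
@given(st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=40))
def test_repeated_volume_matches_multiplicity_oracle(zs):
    is_rep, n = detect_repeated_volume(zs)
    oracle = max(Counter(zs).values())
    assert n == oracle
    assert is_rep is (oracle >= 2)


@pytest.mark.parametrize(
    "repeated, contrast, expected",
    [(True, True, True), (True, False, False), (False, True, False), (False, False, False)],
)
def test_contrast_bolus_flag(repeated, contrast, expected):
    assert flag_contrast_bolus(repeated, contrast) is expected


def test_whitelist_rejects_direct_identifiers():
    cfg = PromotionConfig(whitelist=["Modality", "PatientName"])
    with pytest.raises(PromotionError):
        cfg.validate()


def test_column_closure_machine_check():
    check_column_closure(PromotionConfig())  # default config closes
    with pytest.raises(PromotionError):
        check_column_closure(PromotionConfig(whitelist=["Modality"]))


def test_promotion_counts_match_manifest_filter_oracle(inventory, corpus):
    _, manifest = corpus
    inv, report = inventory
    primary = [r for r in manifest.files if is_primary_original(r.image_type)]
    assert report.promoted_images == len(primary)
    assert inv.count("image") == len(primary)
    assert inv.count("series") == len({r.series_uid for r in primary})
    assert inv.count("study") == len({r.study_uid for r in primary})
    assert report.skipped.get("not-primary-original", 0) == len(manifest.files) - len(
        primary
    )


def test_no_inventory_value_equals_a_planted_identifier(inventory, corpus):
    """The cohort-building surface never carries an identifier: checked
    cell by cell against the complete manifest identity set."""
    _, manifest = corpus
    inv, _ = inventory
    identifiers = {s.upper() for s in manifest.all_identifier_strings()}
    for level in ("image", "series", "study"):
        for row in inv.rows(level):
            for col, value in row.items():
                if col == "relative_path" or col.endswith("uid"):
                    continue  # identifiable-zone locator / opaque keys
                assert str(value).upper() not in identifiers, (level, col, value)
                if "description" in col and value is not None:
                    assert not any(i in str(value).upper() for i in identifiers)


def test_eupi_replaces_chi_everywhere(inventory, corpus):
    _, manifest = corpus
    inv, _ = inventory
    chis = {c for p in manifest.patients for c in p.all_chis}
    eupis = {row["eupi"] for row in inv.rows("image")}
    assert not eupis & chis
    assert all(len(e) == 16 for e in eupis)


def test_repeated_volume_and_contrast_columns_match_manifest(inventory, corpus):
    _, manifest = corpus
    inv, _ = inventory
    truth = {
        recs[0].series_uid: (
            recs[0].is_repeated_volume,
            recs[0].is_repeated_volume and recs[0].contrast_used,
        )
        for recs in manifest.series_records().values()
    }
    for row in inv.rows("series"):
        want_rep, want_contrast = truth[row["series_uid"]]
        assert bool(row["is_repeated_volume"]) == want_rep
        assert bool(row["contrast_bolus_candidate"]) == want_contrast


def test_collapse_conserves_image_counts(inventory):
    inv, _ = inventory
    per_series = {r["series_uid"]: r["n_images"] for r in inv.rows("series")}
    image_rows = inv.rows("image")
    by_series = Counter(r["series_uid"] for r in image_rows)
    assert per_series == dict(by_series)
    per_study = {r["study_uid"]: r["n_images"] for r in inv.rows("study")}
    by_study = Counter(r["study_uid"] for r in image_rows)
    assert per_study == dict(by_study)


def test_age_column_close_to_truth(inventory, corpus):
    _, manifest = corpus
    inv, _ = inventory
    truth = {r.sop_uid: r.age_years_truth for r in manifest.files}
    rows = inv.rows("image", "age_missing = 0")
    assert rows
    for row in rows:
        # written age strings are floor-quantised, so allow a year+a bit
        assert abs(row["age_years"] - truth[row["sop_uid"]]) < 1.1


def test_leaky_descriptions_dropped_column_not_row(inventory, corpus):
    _, manifest = corpus
    inv, report = inventory
    leaky = {
        r.sop_uid
        for r in manifest.files
        if any(p.tag_path == "(0008,1030)" for p in r.planted)
        and is_primary_original(r.image_type)
    }
    assert leaky, "corpus should contain leaked descriptions"
    assert report.descriptions_dropped > 0
    for row in inv.rows("image"):
        if row["sop_uid"] in leaky:
            assert row["study_description"] is None
            assert row["modality"] is not None  # the rest of the row survives


def test_promote_twice_yields_identical_tables(tmp_path, loaded_store, mapping):
    store, _ = loaded_store

    def snapshot(path):
        conn = sqlite3.connect(path)
        try:
            return {
                level: conn.execute(
                    f"SELECT * FROM {level} ORDER BY 2"
                ).fetchall()
                for level in ("image", "series", "study")
            }
        finally:
            conn.close()

    path = tmp_path / "inv.sqlite"
    promote(store, PromotionConfig(), mapping, path)
    first = snapshot(path)
    promote(store, PromotionConfig(), mapping, path)
    assert snapshot(path) == first


def test_promote_without_mapping_writes_nothing(tmp_path, loaded_store):
    from dicomsieve import PseudonymError

    store, _ = loaded_store
    path = tmp_path / "inv.sqlite"
    with pytest.raises(PseudonymError):
        promote(store, PromotionConfig(), None, path)
    assert not path.exists() or Inventory(path).count("image") == 0
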