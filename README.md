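# dicomsieve

A desk-scale pipeline for turning an archive of identifiable clinical DICOM
images into de-identified, linkage-ready research extracts — the data flow
used by imaging safe havens / trusted research environments (TREs):

```
identifiable zone                          de-identified zone
─────────────────────────────────────────  ─────────────────────────
DICOM archive ─► tag store (full tags) ─►  inventory tables (EUPI-keyed,
                     │                     whitelisted, flattened)
                     │                          │ cohort filters
                     ▼                          ▼
              anonymiser + pixel redaction ─► validation gate ─► release
                                                   │ any finding
                                                   ▼
                                               quarantine
```

It is written for research coordinators and data engineers who need the
whole chain testable: a built-in synthetic corpus generator plants known
identifiers (names, CHI numbers, burned-in pixel text) and records every
one in a ground-truth manifest, so "nothing leaked" is a measurable
property, not an aspiration.

## The core ideas

* **Blacklist by default.** Every tag is withheld unless promoted: the
  inventory and the released files carry only a whitelist (UIDs, Modality,
  ImageType, coarsened StudyDate, normalised PatientAge, PatientSex,
  BodyPartExamined, scanner make/model, scanned description fields) plus
  declared derived fields. A machine check verifies on every promotion run
  that each populated column traces to the whitelist, a derived field or a
  key.
* **Keyed pseudonymisation.** The patient identifier (CHI, which embeds the
  birth date) is replaced by an EUPI — `HMAC-SHA256(key, CHI)` truncated to
  16 hex characters: deterministic, so datasets pseudonymised with the same
  key join exactly; one-way, so the de-identified zone cannot recover the
  CHI. Duplicate registrations (one person, several CHIs) are folded by a
  versioned, append-only reconcile. Per-project patient IDs are a second
  keyed derivation, so two projects cannot link their extracts.
* **Cleaning and derived fields.** DICOM age strings `075Y` / `006M` /
  `002D` (or bare numbers) are homogenised to numeric years (÷1, ÷12,
  ÷365.25). Repeated-volume series are detected from slice-position
  multiplicities (a series is a repeat acquisition when some position
  occurs ≥2 times within 0.01 mm); combined with contrast tags this flags
  contrast-bolus candidates.
* **Rule-driven redaction and a fail-closed gate.** Pixel redaction rules
  have the classic scripted form — *if Modality is US and Manufacturer
  matches X and model matches Y, blank the rectangle (0 0 1000 200)* —
  with rectangles `(x_min, y_min, x_max, y_max)`, origin top-left,
  exclusive far edges. After anonymisation every candidate is scanned
  (tags and pixel text) against pattern rules, the patient's own identity
  and an allowlist of known false positives ("Princess Royal" is a
  hospital, not a name); any finding, or any scanner failure, quarantines
  the file instead of releasing it.

## Worked example

`examples/06_cohort_and_extract.py` runs the whole pipeline on a 6-patient
synthetic corpus and prints:

```
 generate: {'n_files': 99}
     load: {'files_seen': 99, 'loaded': 99, 'updated': 0, 'rejected': 0}
  promote: {'images_seen': 99, 'promoted_images': 90, 'series_rows': 15,
            'study_rows': 10, 'descriptions_dropped': 16}
   cohort: {'cohort_id': '5c52096db439', 'n_uids': 8}
  extract: {'requested': 50, 'released': 50, 'quarantined': 0,
            'missing': 0, 'failed': 0}
```

Reading: all 99 generated files loaded into the tag store; 90 were
primary/original images and became EUPI-keyed inventory rows (16 free-text
description fields were dropped because they leaked a name — the column is
dropped, never the row); the CT/US series filter selected 8 series (50
images), and with a covering ultrasound redaction rule every candidate
passed the validation gate and was released. The report always reconciles:
`requested = released + quarantined + missing + failed`.

The other examples exercise one capability each: corpus generation and its
manifest (01), tag-store ingest and querying (02), pseudonymisation,
reconcile and promotion (03), identifier scanning with allowlists and
pixel-text detection (04), and single-file anonymisation with UID remapping
and redaction (05). A thin CLI (`dicomsieve generate|load|promote|cohort|
extract|scan`) wraps the same library calls; keys and salts live in a
config file, never on the command line.

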