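# Methods

## What the pipeline models

The package reproduces, at desk scale, the data-management pattern used by
imaging safe havens: originals are kept unaltered in an identifiable zone;
all tag metadata is extracted verbatim into a searchable per-image document
store (de-identification analysts must be able to see what the identifiers
*are* in order to remove them); a vetted, cleaned subset is promoted into
flattened relational inventory tables keyed by a pseudonym; cohorts are
SQL filters over those tables; and extraction re-anonymises the original
files per project, behind a validation gate. Anonymisation is deliberately
repeated per release rather than done once on ingest: the originals remain
available for better anonymisation later, at the cost of repeated work.

## Synthetic corpus

`CorpusSpec` declares every distribution; the defaults are the study
conditions used throughout the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 20 (24 in the reference corpus) | persons in the archive |
| `studies_per_patient` | 1–3 | uniform range |
| `series_per_study` | 1–2 | uniform range |
| `modality_mix` | CT .4, MR .3, US .2, CR .1 | weights |
| `slices_per_series` | 3–8 | unique slice positions per series |
| `burn_text_fraction` | 0.5 | US/MR series receiving burned-in text |
| `repeated_volume_fraction` | 0.3 | CT series acquired k∈{2,3} times |
| `contrast_fraction` | 0.5 | repeated series with contrast tags (half that rate for non-repeated CT) |
| `age_encoding_mix` | Y .7, M .1, D .05, bare .15 | how PatientAge is written |
| `typo_rate` | 0.05 | single-character transpositions in descriptions |
| `multi_chi_fraction` | 0.15 | patients registered under 1–2 extra CHIs |
| `desc_leak_fraction` | 0.2 | studies whose descriptions carry the surname |
| `derived_fraction` | 0.15 | series marked DERIVED\SECONDARY |
| `image_size` | 256×256 | phantom dimensions |

The synthetic CHI is ten decimal digits: DDMMYY of the birth date plus a
four-digit serial. It reproduces the one property that matters here — the
identifier itself encodes a birth date — and deliberately claims no
check-digit logic of any real national scheme. Two-digit years are decoded
preferring the century that gives an age under 115 years.

Pixel data are geometric phantoms (gradient plus disc) whose values stay
strictly below the dtype maximum; burned-in text is rendered at the dtype
maximum with a built-in 5×7 bitmap font at 2× scale. That separation makes
rendering byte-deterministic and lets the template detector find text by
exact glyph matching. What the corpus does **not** emulate: real anatomy,
compressed transfer syntaxes, non-ASCII character sets, fonts other than
its own, and free-text fields longer or messier than its description
vocabulary. Passing tests therefore demonstrate the *mechanics* of
detection and redaction, not OCR performance on clinical ultrasound.

Every planted identifier (tag path and value), every burn region and the
true person-level grouping of CHIs is recorded in a manifest
(JSON-lines + YAML) that round-trips losslessly; all system-level claims
are measured against it.

## Text detectors

The scanner takes any object satisfying the `TextDetector` contract
(`pixels -> [(region, text)]`; a constant-filled region yields nothing).
Two implementations ship:

* `TemplateTextDetector` — finds pixels at the burn value, takes their
  bounding box, and decodes the text by exact matching against the font's
  glyph bitmaps, searching small alignment offsets because glyphs may have
  leading blank rows/columns. It is a genuinely functional detector for
  this corpus (no access to the manifest) and is the pipeline default.
* `GroundTruthDetector` — reads burn regions from the manifest and reports
  them only while the region still carries non-constant pixels. Used where
  the check must be independent of the detector under test.

An OCR-backed detector would slot into the same contract; none is bundled.

## Scanner rules and allowlist

Default rules: a 10-digit CHI-like pattern (digit-boundary guarded, so
longer runs do not fire), a date-like pattern `(19|20)\d{6}` applied only
to non-date-typed values, a UK postcode pattern, and an identity
cross-reference (the scanned patient's name parts with word boundaries;
CHIs and birth-date string as substrings, case-insensitive). Allowlist
entries suppress exact matches in a given context and always leave an
audit record. Adding a rule can only grow the finding set; adding an
allowlist entry can only shrink it (monotonicity is property-tested).
Pixel text additionally yields a minimum-severity `text-present` finding
regardless of content, because burned-in text is disallowed by default.
The rule inventory is intentionally minimal and extensible via YAML; the
mechanism, not the list, is the deliverable.

## Promotion choices

* Default filter keeps only `ORIGINAL`+`PRIMARY` images; a missing
  ImageType is conservatively not primary/original.
* Age normalisation: `Y`÷1, `M`÷12, `W`÷(365.25/7), `D`÷365.25; a bare
  number is read as years (the common sloppy encoding); anything else is
  flagged missing, never an exception mid-batch. When PatientAge is absent
  the age is derived from birth year vs study year and flagged as derived.
* Repeated-volume tolerance is 0.01 mm: scanner jitter sits well below
  clinical slice spacing, and positions are compared on a rounded grid.
* Dates are kept at year-month in the inventory (the most permissive level
  later restricted per project).
* Leaking free-text fields are dropped per column, never per row, both at
  promotion and again at extraction.
* Re-promotion replaces the whole batch inside one transaction, making it
  idempotent; the mapping table must exist before any row is written.

## Anonymisation choices

* Replacement UIDs are `2.25.<decimal of a 120-bit keyed hash>` of
  (project, original UID): ≤ 64 characters, numeric components,
  hierarchy-preserving within a project, unlinkable across projects.
* Date policies: year-only, year-month (default), or a per-patient
  constant day shift for projects needing interval fidelity. Age policies:
  exact or banded (`banded:5` floors to 5-year bands; sub-year ages band
  to 000Y).
* Redaction fill is modality-appropriate background — 0 for US/CR, the
  minimum stored value for CT/MR — preserving window/level usability.
  Out-of-bounds rectangles are clipped with a logged warning.
* `PatientIdentityRemoved=YES` plus a method description are written and
  double as the idempotence marker: re-anonymising a marked file is a
  no-op apart from UID re-remapping.
* Format conversion supports DICOM only; converting to other containers is
  not treated as a de-identification method and fails loudly.

## Extraction and orchestration

Cohort filters are SQL boolean expressions validated to reference only
inventory columns (string literals stripped before identifier checking);
cohorts are persisted under a content-derived ID for reproducible
re-release, and an external EUPI list (a cohort built from another
dataset) restricts the result. Per-file work flows through a queue
contract — publish/consume, at-least-once delivery, idempotent handlers —
realised in process; the final state is invariant to worker count, and a
broker adapter would slot in at the same interface. Quarantined candidates
stay in the identifiable zone with their findings report. The researcher
metadata table (TSV) carries only profile-whitelisted columns plus project
identifiers, sorted for byte-stable re-release. Pipeline stages checkpoint
to a state file; a re-run after a crash skips completed stages and, because
each stage is idempotent, converges on the uninterrupted result.

## Problem sizes

The shared test corpus is 10 patients (~75 images); the reference corpus
used by the end-to-end guarantees and the acceptance script is 24 patients
(~600 images, seed-dependent), chosen to exercise every modality, both
multi-CHI reconciliation and description leaks, and several hundred
released files, while a full suite run stays under a minute of compute.

## Known limitations

Name matching is exact substring with word boundaries — no fuzzy matching,
so a typo'd surname ("Brian" for a brain scan is the classic inverse case)
evades the cross-reference; only uncompressed little-endian single-frame
greyscale images are handled; the document store and queue are embedded
stand-ins behind contracts rather than networked services; facial
re-identification defacing and NLP-based free-text de-identification are
out of scope.
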