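"""Anonymise one instance: whitelist tags, remap UIDs, redact pixels.

Output files carry only whitelisted + structural tags, a project-local
patient ID, deterministically remapped UIDs (hierarchy preserved within a
project, unlinkable across projects) and, for matching modality/scanner
rules, constant-filled pixel rectangles.
"""

import tempfile
from pathlib import Path

from dicomsieve import (
    AnonymisationProfile, CorpusSpec, RedactionRule, UidMap, anonymise_tags,
    generate_corpus, read_instance, redact_pixels,
)

work = Path(tempfile.mkdtemp(prefix="anon-example-"))
manifest = generate_corpus(CorpusSpec(n_patients=2, seed=3), work)
rec = next((r for r in manifest.files if r.burned_text), manifest.files[0])
tree = read_instance(work / rec.relative_path, work)
print(f"original: {tree.leaf_count()} tags, "
      f"PatientName={tree.dataset.PatientName}, PatientID={tree.dataset.PatientID}")

profile = AnonymisationProfile(
    project="proj-a",
    redaction_rules=[RedactionRule(rec.modality, ".*", ".*", ((0, 0, 256, 40),))],
)
out = anonymise_tags(tree, profile, UidMap("proj-a", "salt"), "PID-0001")
out = redact_pixels(out, profile.redaction_rules)
print(f"anonymised: {out.leaf_count()} tags, PatientID={out.dataset.PatientID}, "
      f"PatientName present: {'PatientName' in out.dataset}")
print(f"  SOP UID {tree.sop_uid}\n   -> {out.sop_uid}")
print(f"  StudyDate {tree.dataset.StudyDate} -> {out.dataset.StudyDate} (year-month)")
if rec.burned_text:
    x0, y0, x1, y1 = rec.burned_text.region
    print(f"  burned region now constant: "
          f"{bool((out.pixels[y0:y1, x0:x1] == out.pixels[y0, x0]).all())}")
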