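"""Hunt for identifiable data in tag values and pixel text.

The rules engine combines generic patterns (CHI-like numbers, date-like
strings, postcodes) with a cross-reference against the scanned patient's
own identity, and suppresses known false positives through an allowlist
— each suppression leaves an audit record.
"""

import datetime as dt

import numpy as np

from dicomsieve import (
    PatientIdentity, TemplateTextDetector, burn_text, default_allowlist,
    default_rules, scan_pixels, scan_value,
)

jones = PatientIdentity(chi="0102801234", family_name="JONES",
                        given_name="MARGARET", dob=dt.date(1980, 2, 1), sex="F")
rules, allowlist = default_rules(), default_allowlist()

r = scan_value("Referred by Dr for Mrs Jones", rules, identity=jones)
print("cross-reference finding:", r.findings[0])

r = scan_value("Seen at Princess Royal", rules + [
    # a naive name pattern that would flag the hospital
    type(rules[0])("name-like", "pattern", "PRINCESS ROYAL", "medium")],
    allowlist=allowlist)
print(f"\nallowlist: {len(r.findings)} findings, "
      f"{len(r.suppressions)} suppression ({r.suppressions[0]['rationale']})")

img = np.zeros((64, 300), dtype=np.uint8)
img, region = burn_text(img, "JONES 0102801234", (4, 4))
r = scan_pixels(img, TemplateTextDetector(), rules, identity=jones)
print(f"\nburned-in text at {region}:")
for f in r.findings:
    print(f"  [{f.severity}] rule={f.rule_id} matched {f.matched_text!r}")
# any readable pixel text is flagged, and its content is scanned like a tag.
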