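"""Per-file anonymisation: whitelist tag retention, UID remapping,
date/age coarsening and rule-driven pixel redaction.

The output of :func:`anonymise_tags` contains only whitelisted tags plus a
small structural set a viewer needs (pixel-module attributes, SOP class,
the de-identification marker tags). Every UID is remapped through a
project-scoped keyed hash, so the study/series/instance hierarchy is
preserved within a project but unlinkable across projects.

Redaction rules follow the classic scripted form: *if Modality is US and
Manufacturer matches X and model matches Y then blank out the rectangle
(x0 y0 x1 y1)*. Rectangles are (x_min, y_min, x_max, y_max) in pixel
coordinates with origin top-left and exclusive far edges; rectangles
extending beyond the image are clipped with a warning. The fill value is
modality-appropriate background: 0 for US/CR, the minimum stored value for
CT/MR, preserving window/level usability.
"""

from __future__ import annotations

import hashlib
import hmac
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
import yaml
from pydicom.dataset import Dataset

from .model import TagTree, write_instance
from .promotion import DIRECT_IDENTIFIER_KEYWORDS

log = logging.getLogger(__name__)

#: tags any release-ready file must carry, beyond the whitelist
STRUCTURAL_REQUIRED = [
    "SOPClassUID",
    "SOPInstanceUID",
    "SeriesInstanceUID",
    "StudyInstanceUID",
    "Modality",
    "PatientID",
    "Rows",
    "Columns",
    "BitsAllocated",
    "BitsStored",
    "HighBit",
    "PixelRepresentation",
    "SamplesPerPixel",
    "PhotometricInterpretation",
    "InstanceNumber",
]

#: written by the anonymiser itself; doubles as the idempotence marker
DEID_MARKER_TAGS = {
    "PatientIdentityRemoved": "YES",
    "DeidentificationMethod": "dicomsieve whitelist retention + rule-driven pixel redaction",
}

DEFAULT_ANON_WHITELIST = [
    "Modality",
    "ImageType",
    "StudyDate",
    "PatientAge",
    "PatientSex",
    "BodyPartExamined",
    "SliceThickness",
    "SliceLocation",
    "Manufacturer",
    "ManufacturerModelName",
    "SeriesDescription",
    "StudyDescription",
]


class AnonymisationError(RuntimeError):
    """Per-file rejection: the instance cannot be made release-ready."""


@dataclass(frozen=True)
class RedactionRule:
    modality: str
    manufacturer_pattern: str
    model_pattern: str
    rectangles: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        re.compile(self.manufacturer_pattern)
        re.compile(self.model_pattern)
        for x0, y0, x1, y1 in self.rectangles:
            if x0 < 0 or y0 < 0 or x1 < x0 or y1 < y0:
                raise ValueError(f"bad rectangle ({x0},{y0},{x1},{y1})")

    def matches(self, tree: TagTree) -> bool:
        ds = tree.dataset
        if str(getattr(ds, "Modality", "")) != self.modality:
            return False
        if not re.search(
            self.manufacturer_pattern, str(getattr(ds, "Manufacturer", "")), re.I
        ):
            return False
        return bool(
            re.search(
                self.model_pattern, str(getattr(ds, "ManufacturerModelName", "")), re.I
            )
        )


@dataclass
class AnonymisationProfile:
    """Per-project release policy."""

    project: str
    whitelist: list[str] = field(default_factory=lambda: list(DEFAULT_ANON_WHITELIST))
    date_policy: str = "year-month"   # year-only | year-month | shift-by-patient-offset
    age_policy: str = "exact"         # exact | banded:<width>
    redaction_rules: list[RedactionRule] = field(default_factory=list)
    structural_required: list[str] = field(
        default_factory=lambda: list(STRUCTURAL_REQUIRED)
    )
    uid_salt: str = "dicomsieve"

    def validate(self) -> None:
        bad = set(self.whitelist) & DIRECT_IDENTIFIER_KEYWORDS
        if bad:
            raise AnonymisationError(
                f"profile whitelist contains direct identifiers: {sorted(bad)}"
            )
        if self.date_policy not in ("year-only", "year-month", "shift-by-patient-offset"):
            raise AnonymisationError(f"unknown date policy {self.date_policy!r}")
        if self.age_policy != "exact" and not re.fullmatch(
            r"banded:\d+", self.age_policy
        ):
            raise AnonymisationError(f"unknown age policy {self.age_policy!r}")

    def to_yaml(self, path: Path | str) -> None:
        data = {
            "project": self.project,
            "whitelist": list(self.whitelist),
            "date_policy": self.date_policy,
            "age_policy": self.age_policy,
            "uid_salt": self.uid_salt,
            "structural_required": list(self.structural_required),
            "redaction_rules": [
                {
                    "modality": r.modality,
                    "manufacturer_pattern": r.manufacturer_pattern,
                    "model_pattern": r.model_pattern,
                    "rectangles": [list(rect) for rect in r.rectangles],
                }
                for r in self.redaction_rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "AnonymisationProfile":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        rules = [
            RedactionRule(
                modality=r["modality"],
                manufacturer_pattern=r["manufacturer_pattern"],
                model_pattern=r["model_pattern"],
                rectangles=tuple(tuple(rect) for rect in r["rectangles"]),
            )
            for r in data.pop("redaction_rules", [])
        ]
        profile = cls(redaction_rules=rules, **data)
        profile.validate()
        return profile


class UidMap:
    """Deterministic project-scoped UID replacement.

    Replacement UIDs are ``2.25.<decimal of a 120-bit keyed hash>`` —
    registered-root style, <= 64 characters, numeric dot-separated — and a
    function of (salt, project, original UID) only, so the study/series/
    instance hierarchy survives remapping within a project while two
    projects get unrelated UIDs.
    """

    def __init__(self, project: str, salt: str):
        self.project = project
        self.salt = salt.encode()
        self._cache: dict[str, str] = {}

    def remap(self, uid: str) -> str:
        uid = str(uid)
        if uid not in self._cache:
            digest = hmac.new(
                self.salt, f"{self.project}:{uid}".encode(), hashlib.sha256
            ).digest()
            value = int.from_bytes(digest[:15], "big")  # 120 bits
            self._cache[uid] = f"2.25.{value}"
        return self._cache[uid]


def _coarsen_date(value: str, policy: str, patient_offset_days: int = 0) -> str:
    s = str(value)
    if len(s) != 8 or not s.isdigit():
        return ""
    if policy == "year-only":
        return s[:4] + "0101"
    if policy == "year-month":
        return s[:6] + "01"
    # shift-by-patient-offset keeps interval fidelity per patient
    import datetime as dt

    d = dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])) + dt.timedelta(
        days=patient_offset_days
    )
    return d.strftime("%Y%m%d")


def _coarsen_age(value: str, policy: str) -> str:
    if policy == "exact":
        return str(value)
    width = int(policy.split(":")[1])
    m = re.match(r"^\s*(\d+)\s*([YMWDymwd]?)\s*$", str(value))
    if not m:
        return ""
    n, unit = int(m.group(1)), (m.group(2) or "Y").upper()
    if unit != "Y":  # sub-year ages band to the lowest band
        return f"000Y"
    return f"{(n // width) * width:03d}Y"


def anonymise_tags(
    tree: TagTree,
    profile: AnonymisationProfile,
    uid_map: UidMap,
    project_patient_id: str,
    patient_offset_days: int = 0,
) -> TagTree:
    """Produce a release-candidate tree: whitelist ∪ structural tags only.

    PatientID becomes the project-local patient id, PatientName is absent,
    all UID-valued tags are remapped, dates and ages follow the profile
    policies, and private tags never survive (the whitelist is keyword
    based). A file already carrying the de-identification marker passes
    through untouched except for UID remapping. Missing structural tags
    reject the file.
    """
    profile.validate()
    src = tree.dataset
    already = str(getattr(src, "PatientIdentityRemoved", "")) == "YES"

    keep = set(profile.whitelist) | set(profile.structural_required)
    out = Dataset()
    for elem in src:
        if elem.tag.group == 0x0002 or elem.tag.is_private:
            continue
        keyword = elem.keyword or ""
        if keyword == "PixelData":
            out.PixelData = elem.value
            continue
        if keyword not in keep and keyword not in DEID_MARKER_TAGS:
            continue
        if elem.VR == "UI" and keyword.endswith("UID") and keyword != "SOPClassUID":
            out.add_new(elem.tag, elem.VR, uid_map.remap(str(elem.value)))
        elif already:
            # marker present: the file is already de-identified, so only
            # UID remapping applies; coarsening is not repeated
            out.add(elem)
        elif elem.VR == "DA":
            out.add_new(
                elem.tag,
                elem.VR,
                _coarsen_date(elem.value, profile.date_policy, patient_offset_days),
            )
        elif keyword == "PatientAge":
            out.add_new(elem.tag, elem.VR, _coarsen_age(elem.value, profile.age_policy))
        else:
            out.add(elem)

    out.PatientID = project_patient_id
    for keyword, value in DEID_MARKER_TAGS.items():
        setattr(out, keyword, value)

    missing = [
        k
        for k in profile.structural_required
        if k not in out or getattr(out, k, None) in (None, "")
    ]
    if missing:
        raise AnonymisationError(f"missing structural tags: {missing}")
    return TagTree(
        dataset=out,
        transfer_syntax=tree.transfer_syntax,
        relative_path=tree.relative_path,
    )


def redact_pixels(tree: TagTree, rules: list[RedactionRule]) -> TagTree:
    """Apply every matching rule's rectangles to the pixel matrix.

    Non-matching images are returned unchanged (same object); matching
    images get a new pixel buffer with constant fill inside the rectangles
    and untouched bytes elsewhere.
    """
    matching = [r for r in rules if r.matches(tree)]
    if not matching:
        return tree
    pixels = tree.pixels
    if pixels is None:
        raise AnonymisationError("redaction rule matched an image without pixel data")
    modality = str(getattr(tree.dataset, "Modality", ""))
    fill = 0 if modality in ("US", "CR") else int(pixels.min())
    out = pixels.copy()
    rows, cols = out.shape
    for rule in matching:
        for x0, y0, x1, y1 in rule.rectangles:
            cx1, cy1 = min(x1, cols), min(y1, rows)
            if cx1 < x1 or cy1 < y1:
                log.warning(
                    "redaction rectangle (%d,%d,%d,%d) clipped to %dx%d image",
                    x0, y0, x1, y1, cols, rows,
                )
            out[y0:cy1, x0:cx1] = fill
    tree.set_pixels(out)
    return tree


def convert_format(tree: TagTree, path: Path | str, target: str = "dicom") -> Path:
    """Write the instance in the requested container format.

    Only ``dicom`` is supported: format conversion (e.g. NIFTI) is not a
    de-identification method here, and requests for other targets fail
    loudly rather than silently degrading.
    """
    if target != "dicom":
        raise AnonymisationError(
            f"unsupported output format {target!r}; only 'dicom' is available"
        )
    path = Path(path)
    write_instance(tree, path)
    return path


def example_us_redaction_rule() -> RedactionRule:
    """The classic scripted redaction rule: if Modality is US and the
    manufacturer is X and the model is Y, blank the rectangle (0 0 1000 200)."""
    return RedactionRule(
        modality="US",
        manufacturer_pattern="^MANUFACTURER X$",
        model_pattern="^MODEL Y$",
        rectangles=((0, 0, 1000, 200),),
    )
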