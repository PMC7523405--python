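"""Rules engine that hunts for identifiable data in tag values and pixels.

Three rule kinds:

* ``pattern`` — a regular expression (10-digit CHI-like numbers, 8-digit
  date-like strings in free text, UK postcodes);
* ``identity-crossref`` — the scanned patient's own name parts and CHIs,
  matched case-insensitively (word boundaries for names, plain substring
  for digit strings);
* implicit ``text-present`` — any text detected in pixel data is reported
  at minimum severity even if it matches no identifier rule, because
  burned-in text is disallowed by default.

Known false positives (hospital names such as "Princess Royal" that look
like person names) are suppressed through an allowlist; every suppression
is recorded so the audit trail shows what was waved through and why.

The scanner is used twice: at promotion, to keep free-text columns out of
the inventory when they leak, and as the pre-release validation gate, where
any finding — or any detector failure — blocks the file (fail-closed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Optional, Protocol

import numpy as np
import yaml

from .corpus import BurnedText, CorpusManifest, PatientIdentity, burn_value
from .model import TagDocument

SEVERITY_ORDER = {"info": 0, "low": 1, "medium": 2, "high": 3}

# VRs whose values are dates/times by definition; the date-like pattern rule
# only applies to free text, not to these.
_DATE_VRS = {"DA", "DT", "TM"}


class ScannerError(RuntimeError):
    """Detector or rule failure; callers must treat the file as unreleasable."""


@dataclass(frozen=True)
class ScanRule:
    id: str
    kind: str                      # pattern | identity-crossref | date-like
    pattern: Optional[str] = None  # regex for pattern/date-like rules
    severity: str = "high"

    def __post_init__(self) -> None:
        if self.kind in ("pattern", "date-like"):
            re.compile(self.pattern or "")
        if self.severity not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity {self.severity!r}")


@dataclass(frozen=True)
class AllowlistEntry:
    text: str
    context: str = "any"  # tag-path glob-ish pattern or "any"
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("allowlist text must be non-empty")

    def matches(self, matched_text: str, location: str) -> bool:
        if matched_text.upper() != self.text.upper():
            return False
        if self.context == "any":
            return True
        return re.fullmatch(self.context, location) is not None


@dataclass(frozen=True)
class Finding:
    location: str        # tag path, or "pixels[x0,y0,x1,y1]"
    matched_text: str
    rule_id: str
    severity: str = "high"


@dataclass
class ScanResult:
    findings: list[Finding] = field(default_factory=list)
    suppressions: list[dict] = field(default_factory=list)

    def extend(self, other: "ScanResult") -> None:
        self.findings.extend(other.findings)
        self.suppressions.extend(other.suppressions)


def default_rules() -> list[ScanRule]:
    return [
        ScanRule("chi-like", "pattern", r"(?<!\d)\d{10}(?!\d)", "high"),
        ScanRule("date-like", "date-like", r"(?<!\d)(19|20)\d{6}(?!\d)", "medium"),
        ScanRule(
            "uk-postcode",
            "pattern",
            r"\b[A-Z]{1,2}\d{1,2}[A-Z]?\s*\d[A-Z]{2}\b",
            "medium",
        ),
        ScanRule("identity-crossref", "identity-crossref", None, "high"),
    ]


def default_allowlist() -> list[AllowlistEntry]:
    return [
        AllowlistEntry(
            "PRINCESS ROYAL",
            context="any",
            rationale="hospital, not a person name",
        ),
    ]


# ---------------------------------------------------------------------------
# value scanning


def _identity_terms(identity: PatientIdentity) -> list[tuple[str, bool]]:
    """(term, needs_word_boundary) pairs for one patient."""
    terms: list[tuple[str, bool]] = [
        (identity.family_name, True),
        (identity.given_name, True),
    ]
    terms += [(chi, False) for chi in identity.all_chis]
    terms.append((identity.dob.strftime("%Y%m%d"), False))
    return terms


def scan_value(
    text: Any,
    rules: list[ScanRule],
    identity: Optional[PatientIdentity] = None,
    allowlist: Optional[list[AllowlistEntry]] = None,
    location: str = "value",
    is_date_vr: bool = False,
) -> ScanResult:
    """Scan one value against every rule; total (never raises on odd input)."""
    result = ScanResult()
    if text is None:
        return result
    s = str(text)
    allowlist = allowlist or []

    def emit(matched: str, rule: ScanRule) -> None:
        for entry in allowlist:
            if entry.matches(matched, location):
                result.suppressions.append(
                    {
                        "location": location,
                        "matched_text": matched,
                        "rule_id": rule.id,
                        "allowlist_text": entry.text,
                        "rationale": entry.rationale,
                    }
                )
                return
        result.findings.append(Finding(location, matched, rule.id, rule.severity))

    for rule in rules:
        if rule.kind == "pattern":
            for m in re.finditer(rule.pattern, s, flags=re.IGNORECASE):
                emit(m.group(0), rule)
        elif rule.kind == "date-like":
            if is_date_vr:
                continue  # date-typed tags are dates by definition
            for m in re.finditer(rule.pattern, s):
                emit(m.group(0), rule)
        elif rule.kind == "identity-crossref":
            if identity is None:
                continue
            for term, word_boundary in _identity_terms(identity):
                if word_boundary:
                    pat = r"(?<![A-Za-z])" + re.escape(term) + r"(?![A-Za-z])"
                else:
                    pat = re.escape(term)
                for m in re.finditer(pat, s, flags=re.IGNORECASE):
                    emit(m.group(0), rule)
    return result


# ---------------------------------------------------------------------------
# document scanning


def scan_document(
    doc: TagDocument,
    rules: list[ScanRule],
    identity: Optional[PatientIdentity] = None,
    allowlist: Optional[list[AllowlistEntry]] = None,
) -> ScanResult:
    """Union of :func:`scan_value` over every leaf, at any nesting depth."""
    result = ScanResult()
    for path, value in doc.leaves():
        vr = _leaf_vr(doc, path)
        values = value if isinstance(value, list) else [value]
        for v in values:
            result.extend(
                scan_value(
                    v,
                    rules,
                    identity=identity,
                    allowlist=allowlist,
                    location=path,
                    is_date_vr=vr in _DATE_VRS,
                )
            )
    return result


def _leaf_vr(doc: TagDocument, path: str) -> Optional[str]:
    node: dict = doc.body
    steps = path.split("/")
    for step in steps[:-1]:
        key, idx = step.split("[")
        node = node[key]["items"][int(idx.rstrip("]"))]
    entry = node.get(steps[-1])
    return entry.get("vr") if entry else None


# ---------------------------------------------------------------------------
# pixel scanning


class TextDetector(Protocol):
    """Contract: pixel matrix -> list of (region, text).

    Implementations must return nothing for a region previously filled with
    a constant value (redacted text is gone). ``context`` carries the
    original SOPInstanceUID when the caller knows it.
    """

    def detect(
        self, pixels: np.ndarray, context: Optional[str] = None
    ) -> list[tuple[tuple[int, int, int, int], str]]: ...


class GroundTruthDetector:
    """Manifest-backed detector for deterministic, dependency-free testing.

    Knows where text was burned from the corpus ground truth; reports it
    only while the region still carries non-constant (unredacted) pixels,
    which preserves the constant-fill invariant of the detector contract.
    """

    def __init__(self, manifest: CorpusManifest):
        self._by_sop: dict[str, BurnedText] = {
            rec.sop_uid: rec.burned_text
            for rec in manifest.files
            if rec.burned_text is not None
        }

    def detect(
        self, pixels: np.ndarray, context: Optional[str] = None
    ) -> list[tuple[tuple[int, int, int, int], str]]:
        if context is None or context not in self._by_sop:
            return []
        burned = self._by_sop[context]
        x0, y0, x1, y1 = burned.region
        patch = pixels[y0:y1, x0:x1]
        if patch.size == 0 or patch.min() == patch.max():
            return []  # constant fill: nothing readable remains
        return [(tuple(burned.region), burned.text)]


class TemplateTextDetector:
    """Glyph-template detector for text rendered with the built-in font.

    Finds pixels at the burn value (the dtype maximum, which phantoms never
    reach naturally), takes their bounding box, and decodes the text by
    exact matching against the font's glyph bitmaps. A genuinely functional
    detector for this corpus — unlike the ground-truth detector it has no
    access to the manifest — though it only reads text in the corpus font.
    """

    def __init__(self, scale: int = 2):
        self.scale = scale

    def detect(
        self, pixels: np.ndarray, context: Optional[str] = None
    ) -> list[tuple[tuple[int, int, int, int], str]]:
        from ._font import GLYPH_HEIGHT, GLYPH_SPACING, GLYPH_WIDTH, glyph_mask, _GLYPHS

        hot = pixels == burn_value(pixels.dtype)
        if not hot.any():
            return []
        ys, xs = np.nonzero(hot)
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        region = (x0, y0, x1, y1)
        # The hot bounding box may start mid-glyph (leading blank columns or
        # rows); try small alignment offsets and keep the decode in which
        # the most cells match a glyph bitmap exactly.
        s = self.scale
        best_text, best_score = "", -1
        for bx in range(GLYPH_WIDTH):
            for by in range(GLYPH_HEIGHT):
                text, score = self._decode(hot, x0 - bx * s, y0 - by * s, x1)
                if score > best_score:
                    best_text, best_score = text, score
        return [(region, best_text.strip())]

    def _decode(self, hot: np.ndarray, x_start: int, y_start: int, x1: int):
        from ._font import GLYPH_HEIGHT, GLYPH_SPACING, GLYPH_WIDTH, glyph_mask, _GLYPHS

        s = self.scale
        cell = (GLYPH_WIDTH + GLYPH_SPACING) * s
        if x_start < 0 or y_start < 0:
            return "", -1
        chars: list[str] = []
        score = 0
        x = x_start
        while x < x1:
            patch = hot[y_start : y_start + GLYPH_HEIGHT * s, x : x + GLYPH_WIDTH * s]
            down = patch[::s, ::s]
            if down.shape != (GLYPH_HEIGHT, GLYPH_WIDTH):
                pad = np.zeros((GLYPH_HEIGHT, GLYPH_WIDTH), dtype=bool)
                pad[: down.shape[0], : down.shape[1]] = down
                down = pad
            best = "\x00"
            for ch in _GLYPHS:
                if np.array_equal(down, glyph_mask(ch)):
                    best = ch
                    break
            if best != "\x00":
                score += 1
            chars.append(best if best != "\x00" else " ")
            x += cell
        return "".join(chars), score


def scan_pixels(
    pixels: np.ndarray,
    detector: TextDetector,
    rules: list[ScanRule],
    identity: Optional[PatientIdentity] = None,
    allowlist: Optional[list[AllowlistEntry]] = None,
    context: Optional[str] = None,
) -> ScanResult:
    """Detect burned-in text and scan it like any other value.

    Any detected text yields at least an ``info``-severity ``text-present``
    finding: burned-in text is disallowed by default regardless of content.
    Detector failures raise :class:`ScannerError`; callers quarantine the
    file (fail-closed).
    """
    try:
        detections = detector.detect(pixels, context=context)
    except Exception as exc:  # noqa: BLE001 - contract: fail closed
        raise ScannerError(f"text detector failed: {exc}") from exc
    result = ScanResult()
    for region, text in detections:
        location = f"pixels[{region[0]},{region[1]},{region[2]},{region[3]}]"
        result.findings.append(Finding(location, text, "text-present", "info"))
        result.extend(
            scan_value(
                text, rules, identity=identity, allowlist=allowlist, location=location
            )
        )
    return result


# ---------------------------------------------------------------------------
# YAML (de)serialisation of rules and allowlists


def load_rules(path) -> list[ScanRule]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    return [ScanRule(**d) for d in data]


def save_rules(rules: list[ScanRule], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {"id": r.id, "kind": r.kind, "pattern": r.pattern, "severity": r.severity}
                for r in rules
            ],
            fh,
        )


def load_allowlist(path) -> list[AllowlistEntry]:
    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    return [AllowlistEntry(**d) for d in data]
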