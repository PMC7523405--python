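"""Tag-tree data model: reading, writing and documenting DICOM instances.

A :class:`TagTree` wraps one instance's full tag set (pydicom dataset),
pixel matrix and archive-relative path. :func:`tags_to_document` flattens it
into a JSON-serialisable :class:`TagDocument` — the unit persisted by the
tag store — preserving sequence nesting but never pixel data.

Tag paths use a canonical text form: ``(0008,0060)`` at top level,
``(0040,0275)[0]/(0008,0050)`` inside sequence items.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.tag import Tag
from pydicom.uid import ExplicitVRLittleEndian

from .corpus import UID_ROOT

PIXEL_DATA_TAG = Tag(0x7FE0, 0x0010)
REQUIRED_UIDS = ("SOPInstanceUID", "SeriesInstanceUID", "StudyInstanceUID")


class NotDicomError(ValueError):
    """The file is not a readable Part-10 DICOM file."""


class LoadRejectError(ValueError):
    """The file parsed as DICOM but fails a structural requirement."""


# ---------------------------------------------------------------------------
# tag paths

_STEP_RE = re.compile(r"^\(([0-9a-fA-F]{4}),([0-9a-fA-F]{4})\)(?:\[(\d+)\])?$")


@dataclass(frozen=True)
class TagPath:
    """Location of one tag, possibly nested in sequence items.

    ``steps`` is a tuple of ``(tag, item_index)`` pairs; every step except
    the last descends into the given item of a sequence, the last step has
    ``item_index is None``.
    """

    steps: tuple[tuple[int, Optional[int]], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("TagPath must have at least one step")
        for tag, item in self.steps[:-1]:
            if item is None:
                raise ValueError("non-final steps need an item index")
        if self.steps[-1][1] is not None:
            raise ValueError("final step must not carry an item index")

    def render(self) -> str:
        parts = []
        for tag, item in self.steps:
            t = Tag(tag)
            s = f"({t.group:04x},{t.element:04x})"
            if item is not None:
                s += f"[{item}]"
            parts.append(s)
        return "/".join(parts)

    @classmethod
    def parse(cls, text: str) -> "TagPath":
        steps: list[tuple[int, Optional[int]]] = []
        for part in text.split("/"):
            m = _STEP_RE.match(part.strip())
            if not m:
                raise ValueError(f"malformed tag path step {part!r}")
            group, elem, item = m.groups()
            steps.append(
                (int(group, 16) << 16 | int(elem, 16), int(item) if item else None)
            )
        return cls(tuple(steps))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def tag_key(tag: Tag | int) -> str:
    t = Tag(tag)
    return f"({t.group:04x},{t.element:04x})"


# ---------------------------------------------------------------------------
# tag tree


@dataclass
class TagTree:
    """One DICOM instance: full tag set, optional pixels, provenance."""

    dataset: Dataset
    transfer_syntax: str = str(ExplicitVRLittleEndian)
    relative_path: Optional[str] = None

    @property
    def sop_uid(self) -> str:
        return str(self.dataset.SOPInstanceUID)

    @property
    def series_uid(self) -> str:
        return str(self.dataset.SeriesInstanceUID)

    @property
    def study_uid(self) -> str:
        return str(self.dataset.StudyInstanceUID)

    @property
    def pixels(self) -> Optional[np.ndarray]:
        if PIXEL_DATA_TAG not in self.dataset:
            return None
        if not getattr(
            getattr(self.dataset, "file_meta", None), "TransferSyntaxUID", None
        ):
            meta = FileMetaDataset()
            meta.TransferSyntaxUID = self.transfer_syntax
            self.dataset.file_meta = meta
        return self.dataset.pixel_array

    def set_pixels(self, pixels: np.ndarray) -> None:
        self.dataset.PixelData = np.ascontiguousarray(pixels).tobytes()
        self.dataset.Rows, self.dataset.Columns = pixels.shape

    def leaves(self) -> Iterator[tuple[TagPath, Any]]:
        """All non-sequence, non-pixel tag values with their paths."""
        yield from _walk_leaves(self.dataset, ())

    def leaf_count(self) -> int:
        return sum(1 for _ in self.leaves())

    def get(self, path: TagPath | str) -> Any:
        if isinstance(path, str):
            path = TagPath.parse(path)
        node: Any = self.dataset
        for tag, item in path.steps:
            elem = node[Tag(tag)]
            node = elem.value[item] if item is not None else elem.value
        return node

    def tags_equal(self, other: "TagTree") -> bool:
        mine = {p.render(): _jsonable(v) for p, v in self.leaves()}
        theirs = {p.render(): _jsonable(v) for p, v in other.leaves()}
        return mine == theirs


def _walk_leaves(
    ds: Dataset, prefix: tuple[tuple[int, Optional[int]], ...]
) -> Iterator[tuple[TagPath, Any]]:
    for elem in ds:
        if elem.tag == PIXEL_DATA_TAG or elem.tag.group == 0x0002:
            continue
        if elem.VR == "SQ":
            for i, item in enumerate(elem.value):
                yield from _walk_leaves(item, prefix + ((int(elem.tag), i),))
        else:
            yield TagPath(prefix + ((int(elem.tag), None),)), elem.value


# ---------------------------------------------------------------------------
# file I/O


def read_instance(path: Path | str, root: Path | str) -> TagTree:
    """Read one Part-10 file into a tag tree.

    ``relative_path`` is recorded relative to the archive ``root`` so the
    extraction stage can locate the original later. Raises
    :class:`NotDicomError` for non-DICOM input and :class:`LoadRejectError`
    when any of the study/series/instance UIDs is missing.
    """
    path, root = Path(path), Path(root)
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, EOFError) as exc:
        raise NotDicomError(f"{path}: {exc}") from exc
    missing = [k for k in REQUIRED_UIDS if not getattr(ds, k, None)]
    if missing:
        raise LoadRejectError(f"{path}: missing required UIDs {missing}")
    ts = str(getattr(ds.file_meta, "TransferSyntaxUID", ExplicitVRLittleEndian))
    return TagTree(
        dataset=ds,
        transfer_syntax=ts,
        relative_path=str(path.relative_to(root)),
    )


def write_instance(tree: TagTree, path: Path | str) -> None:
    """Write a standard-conformant explicit-VR little-endian Part-10 file.

    Writing is byte-deterministic: file meta carries no timestamps and the
    implementation identifiers are fixed, so two writes of equal trees
    produce identical bytes.
    """
    ds = tree.dataset
    for k in REQUIRED_UIDS:
        if not getattr(ds, k, None):
            raise LoadRejectError(f"cannot write instance missing {k}")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = getattr(
        ds, "SOPClassUID", "1.2.840.10008.5.1.4.1.1.7"
    )
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = pydicom.uid.UID(f"{UID_ROOT}.1")
    meta.ImplementationVersionName = "DICOMSIEVE01"
    ds.file_meta = meta
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# documents


@dataclass
class TagDocument:
    """Searchable per-image document: full nested tag map, no pixels."""

    id: str  # SOPInstanceUID
    body: dict[str, Any]
    relative_path: Optional[str] = None
    load_timestamp: Optional[str] = None
    load_batch: Optional[str] = None

    def leaves(self) -> Iterator[tuple[str, Any]]:
        yield from _doc_leaves(self.body, "")

    def leaf_count(self) -> int:
        return sum(1 for _ in self.leaves())

    def get(self, path: str, default: Any = None) -> Any:
        for p, v in self.leaves():
            if p == path:
                return v
        return default

    def tag(self, keyword: str, default: Any = None) -> Any:
        """Top-level lookup by DICOM keyword (e.g. ``'Modality'``)."""
        try:
            key = tag_key(pydicom.datadict.tag_for_keyword(keyword))
        except (TypeError, ValueError):
            return default
        entry = self.body.get(key)
        return entry["value"] if entry and "value" in entry else default

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "relative_path": self.relative_path,
                "load_timestamp": self.load_timestamp,
                "load_batch": self.load_batch,
                "body": self.body,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TagDocument":
        d = json.loads(text)
        return cls(
            id=d["id"],
            body=d["body"],
            relative_path=d.get("relative_path"),
            load_timestamp=d.get("load_timestamp"),
            load_batch=d.get("load_batch"),
        )


def _doc_leaves(body: dict[str, Any], prefix: str) -> Iterator[tuple[str, Any]]:
    for key, entry in body.items():
        if "items" in entry:
            for i, item in enumerate(entry["items"]):
                yield from _doc_leaves(item, f"{prefix}{key}[{i}]/")
        else:
            yield f"{prefix}{key}", entry.get("value")


def _jsonable(value: Any) -> Any:
    if value is None or isinstance(value, (int, float, str, bool)):
        return value
    if isinstance(value, bytes):
        return value.hex()
    if isinstance(value, (list, pydicom.multival.MultiValue)):
        return [_jsonable(v) for v in value]
    return str(value)


def _body_from_dataset(ds: Dataset) -> dict[str, Any]:
    body: dict[str, Any] = {}
    for elem in ds:
        if elem.tag == PIXEL_DATA_TAG or elem.tag.group == 0x0002:
            continue
        key = tag_key(elem.tag)
        name = pydicom.datadict.keyword_for_tag(elem.tag) or None
        if elem.VR == "SQ":
            body[key] = {
                "vr": "SQ",
                "name": name,
                "items": [_body_from_dataset(item) for item in elem.value],
            }
        else:
            body[key] = {"vr": str(elem.VR), "name": name, "value": _jsonable(elem.value)}
    return body


def tags_to_document(tree: TagTree) -> TagDocument:
    """Flatten a tag tree into its persistable document.

    Structure-preserving (sequences keep their nesting) and total on valid
    trees; pixel data and file-meta tags are excluded by construction.
    """
    return TagDocument(
        id=tree.sop_uid,
        body=_body_from_dataset(tree.dataset),
        relative_path=tree.relative_path,
    )
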