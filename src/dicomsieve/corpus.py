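"""Synthetic identifiable DICOM corpus with a ground-truth manifest.

Generates a heterogeneous multi-patient archive (CT/MR/US/CR) in which every
identifier — patient names and CHIs in tags, text burned into pixel data,
names leaked into free-text descriptions — is planted deliberately and
recorded in a manifest. The manifest is the oracle against which every
downstream stage (loading, promotion, anonymisation, extraction) is tested:
a released artifact is clean exactly when scanning it with the manifest's
full identity set finds nothing.

The CHI grammar used here is synthetic: ten decimal digits whose first six
encode the date of birth as DDMMYY and whose last four are a serial number.
It mimics the real identifier's property of embedding the birth date but
claims no check-digit logic.
"""

from __future__ import annotations

import datetime as dt
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from ._font import render_mask

UID_ROOT = "1.2.826.0.1.3680043.10.1098"


def reference_corpus_spec(seed: int = 20) -> "CorpusSpec":
    """Study-condition corpus: ~600 images over 24 patients, all four
    modalities, with burned-in text on roughly half of US/MR series,
    repeated-volume CT, multi-CHI patients and description leaks."""
    return CorpusSpec(n_patients=24, studies_per_patient=(2, 3), seed=seed)

SURNAMES = [
    "JONES", "MACDONALD", "CAMPBELL", "STEWART", "FRASER", "MURRAY",
    "DOUGLAS", "CAMERON", "GRAHAM", "WALLACE", "BRODIE", "LENNOX",
]
FORENAMES = [
    "MARGARET", "EWAN", "FIONA", "ALISTAIR", "MORAG", "HAMISH",
    "ISLA", "DOUGAL", "SENGA", "RUARIDH", "AILSA", "GREGOR",
]
# Hospital / place names, including allowlist-style false positives such as
# "PRINCESS ROYAL" which pattern scanners tend to flag as a person name.
HOSPITALS = [
    "PRINCESS ROYAL", "NINEWELLS", "WESTERN GENERAL", "ROYAL INFIRMARY",
]
STUDY_DESCRIPTIONS = {
    "CT": ["CT HEAD PLAIN", "CT THORAX ABDO", "CT ANGIOGRAM", "CT KUB"],
    "MR": ["MR BRAIN SCAN", "MR LUMBAR SPINE", "MR KNEE", "MR PELVIS"],
    "US": ["US ABDOMEN", "US CAROTID DOPPLER", "US THYROID", "US RENAL"],
    "CR": ["XR CHEST PA", "XR LEFT WRIST", "XR PELVIS AP", "XR FOOT"],
}
BODY_PARTS = {
    "CT": ["HEAD", "CHEST", "ABDOMEN", "PELVIS"],
    "MR": ["BRAIN", "LSPINE", "KNEE", "PELVIS"],
    "US": ["ABDOMEN", "NECK", "KIDNEY", "NECK"],
    "CR": ["CHEST", "WRIST", "PELVIS", "FOOT"],
}
MANUFACTURERS = [
    ("ACME IMAGING", "SCANMASTER 9000"),
    ("ZENITH MEDICAL", "ULTRAVIEW X"),
    ("ORION DIAGNOSTICS", "CLARITY 5"),
]

BURN_SCALE = 2  # glyph pixel scale used for burned-in text


class CorpusError(ValueError):
    """Invalid corpus specification or generation parameters."""


# ---------------------------------------------------------------------------
# identities


def make_chi(dob: dt.date, serial: int) -> str:
    """Build a synthetic CHI: DDMMYY of the birth date + 4-digit serial.

    Deterministic; rejects dates outside 1900..today and serials outside
    0..9999.
    """
    if not isinstance(dob, dt.date):
        raise CorpusError(f"dob must be a date, got {type(dob).__name__}")
    if not (dt.date(1900, 1, 1) <= dob <= dt.date.today()):
        raise CorpusError(f"dob {dob} outside supported range 1900..present")
    if not (0 <= serial <= 9999):
        raise CorpusError(f"serial {serial} outside 0..9999")
    return f"{dob.day:02d}{dob.month:02d}{dob.year % 100:02d}{serial:04d}"


def chi_dob(chi: str) -> Optional[dt.date]:
    """Decode the DDMMYY prefix of a synthetic CHI.

    The two-digit year is ambiguous; the century giving a plausible age
    (under 115 years) wins, preferring the later candidate.
    """
    if len(chi) != 10 or not chi.isdigit():
        return None
    day, month, yy = int(chi[:2]), int(chi[2:4]), int(chi[4:6])
    today = dt.date.today()
    candidates = []
    for century in (2000, 1900):
        try:
            d = dt.date(century + yy, month, day)
        except ValueError:
            continue
        if d <= today:
            candidates.append(d)
    for d in candidates:
        if (today - d).days < 115 * 365.25:
            return d
    return candidates[0] if candidates else None


@dataclass
class PatientIdentity:
    """One synthetic person: primary CHI, name, and optional duplicate CHIs.

    ``extra_chis`` model the duplicate-registration problem: the same person
    registered under several identifiers, reconciled only later.
    """

    chi: str
    family_name: str
    given_name: str
    dob: dt.date
    sex: str
    extra_chis: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.chi) != 10 or not self.chi.isdigit():
            raise CorpusError(f"CHI {self.chi!r} is not 10 decimal digits")
        if self.chi[:6] != self.dob.strftime("%d%m%y"):
            raise CorpusError(f"CHI {self.chi!r} does not encode dob {self.dob}")
        if self.sex not in ("M", "F", "O"):
            raise CorpusError(f"sex must be M/F/O, got {self.sex!r}")
        all_chis = [self.chi, *self.extra_chis]
        if len(set(all_chis)) != len(all_chis):
            raise CorpusError("extra_chis must differ from chi and each other")

    @property
    def all_chis(self) -> list[str]:
        return [self.chi, *self.extra_chis]

    def identifier_strings(self) -> set[str]:
        """Every string that identifies this person (for leak scanning)."""
        return {
            self.family_name,
            self.given_name,
            f"{self.family_name}^{self.given_name}",
            self.dob.strftime("%Y%m%d"),
            *self.all_chis,
        }


# ---------------------------------------------------------------------------
# specification


def _as_range(v) -> tuple[int, int]:
    if isinstance(v, int):
        return (v, v)
    lo, hi = int(v[0]), int(v[1])
    return (lo, hi)


@dataclass
class CorpusSpec:
    """Declared distributions for the synthetic archive.

    Defaults describe a small but heterogeneous hospital snapshot: mostly CT
    and MR, a fifth ultrasound (the modality prone to burned-in text), short
    multi-slice series, occasional repeated-acquisition CT volumes, mixed
    age-string encodings and a low typo rate in free-text descriptions.
    """

    n_patients: int = 20
    studies_per_patient: int | tuple[int, int] = (1, 3)
    series_per_study: int | tuple[int, int] = (1, 2)
    modality_mix: dict[str, float] = field(
        default_factory=lambda: {"CT": 0.4, "MR": 0.3, "US": 0.2, "CR": 0.1}
    )
    slices_per_series: tuple[int, int] = (3, 8)
    burn_text_fraction: float = 0.5
    repeated_volume_fraction: float = 0.3
    contrast_fraction: float = 0.5
    age_encoding_mix: dict[str, float] = field(
        default_factory=lambda: {"Y": 0.7, "M": 0.1, "D": 0.05, "bare": 0.15}
    )
    typo_rate: float = 0.05
    multi_chi_fraction: float = 0.15
    desc_leak_fraction: float = 0.2
    derived_fraction: float = 0.15
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise CorpusError("n_patients must be >= 0")
        for name in ("burn_text_fraction", "repeated_volume_fraction",
                     "contrast_fraction", "typo_rate", "multi_chi_fraction",
                     "desc_leak_fraction", "derived_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CorpusError(f"{name}={v} outside [0, 1]")
        for name in ("modality_mix", "age_encoding_mix"):
            weights = getattr(self, name)
            if not weights or any(w < 0 for w in weights.values()):
                raise CorpusError(f"{name} must have non-negative weights")
            if abs(sum(weights.values()) - 1.0) > 1e-6:
                raise CorpusError(f"{name} weights must sum to 1")
        unknown = set(self.modality_mix) - {"CT", "MR", "US", "CR"}
        if unknown:
            raise CorpusError(f"unsupported modalities: {sorted(unknown)}")
        for name in ("studies_per_patient", "series_per_study", "slices_per_series"):
            lo, hi = _as_range(getattr(self, name))
            if lo < 1 or hi < lo:
                raise CorpusError(f"{name} range ({lo}, {hi}) is empty")


# ---------------------------------------------------------------------------
# manifest


@dataclass
class PlantedIdentifier:
    tag_path: str   # canonical tag-path text form
    text: str
    kind: str       # name | chi | dob


@dataclass
class BurnedText:
    text: str
    region: tuple[int, int, int, int]  # x0, y0, x1, y1 (exclusive)


@dataclass
class FileRecord:
    relative_path: str
    sop_uid: str
    series_uid: str
    study_uid: str
    chi: str                      # CHI the file was registered under
    modality: str
    study_date: str               # DICOM form YYYYMMDD
    image_type: list[str]
    planted: list[PlantedIdentifier]
    burned_text: Optional[BurnedText]
    age_string: str
    age_years_truth: float
    slice_position: float
    is_repeated_volume: bool
    n_acquisitions: int
    contrast_used: bool
    study_description: str


@dataclass
class CorpusManifest:
    """Ground truth for one generated archive.

    ``master_persons`` groups all CHIs belonging to one person, so linkage
    and reconcile behaviour can be checked against truth.
    """

    spec_seed: int
    files: list[FileRecord] = field(default_factory=list)
    patients: list[PatientIdentity] = field(default_factory=list)
    master_persons: list[list[str]] = field(default_factory=list)

    def identity_for_chi(self, chi: str) -> PatientIdentity:
        for p in self.patients:
            if chi in p.all_chis:
                return p
        raise KeyError(chi)

    def all_identifier_strings(self) -> set[str]:
        out: set[str] = set()
        for p in self.patients:
            out |= p.identifier_strings()
        return out

    def series_records(self) -> dict[str, list[FileRecord]]:
        out: dict[str, list[FileRecord]] = {}
        for rec in self.files:
            out.setdefault(rec.series_uid, []).append(rec)
        return out

    # -- persistence (JSON-lines records + YAML summary) --

    def save(self, directory: Path | str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.jsonl", "w") as fh:
            for rec in self.files:
                fh.write(json.dumps(asdict(rec), default=str) + "\n")
        head = {
            "spec_seed": self.spec_seed,
            "n_files": len(self.files),
            "patients": [
                {
                    "chi": p.chi,
                    "family_name": p.family_name,
                    "given_name": p.given_name,
                    "dob": p.dob.isoformat(),
                    "sex": p.sex,
                    "extra_chis": list(p.extra_chis),
                }
                for p in self.patients
            ],
            "master_persons": self.master_persons,
        }
        with open(directory / "manifest.yaml", "w") as fh:
            yaml.safe_dump(head, fh, sort_keys=True)

    @classmethod
    def load(cls, directory: Path | str) -> "CorpusManifest":
        directory = Path(directory)
        with open(directory / "manifest.yaml") as fh:
            head = yaml.safe_load(fh)
        patients = [
            PatientIdentity(
                chi=p["chi"],
                family_name=p["family_name"],
                given_name=p["given_name"],
                dob=dt.date.fromisoformat(p["dob"]),
                sex=p["sex"],
                extra_chis=list(p["extra_chis"]),
            )
            for p in head["patients"]
        ]
        files: list[FileRecord] = []
        with open(directory / "manifest.jsonl") as fh:
            for line in fh:
                d = json.loads(line)
                d["planted"] = [PlantedIdentifier(**p) for p in d["planted"]]
                if d["burned_text"] is not None:
                    bt = d["burned_text"]
                    d["burned_text"] = BurnedText(bt["text"], tuple(bt["region"]))
                d["image_type"] = list(d["image_type"])
                files.append(FileRecord(**d))
        return cls(
            spec_seed=head["spec_seed"],
            files=files,
            patients=patients,
            master_persons=[list(g) for g in head["master_persons"]],
        )


# ---------------------------------------------------------------------------
# pixel phantoms and burned-in text


def _phantom(rng: random.Random, shape: tuple[int, int], modality: str) -> np.ndarray:
    """Geometric phantom: gradient background plus an off-centre disc.

    Values stay strictly below the dtype maximum so the burn value (dtype
    max) never occurs naturally.
    """
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    if modality in ("CT", "MR"):
        dtype, cap = np.uint16, 3000
    else:
        dtype, cap = np.uint8, 200
    base = (xx + yy) * cap // (2 * max(rows + cols - 2, 1))
    cy = rng.randrange(rows // 4, 3 * rows // 4)
    cx = rng.randrange(cols // 4, 3 * cols // 4)
    r = min(rows, cols) // 5
    disc = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r * r
    img = base.astype(np.int64)
    img[disc] += cap // 2
    return np.minimum(img, cap).astype(dtype)


def burn_value(dtype: np.dtype) -> int:
    return int(np.iinfo(dtype).max)


def burn_text(
    pixels: np.ndarray,
    text: str,
    origin: tuple[int, int],
    scale: int = BURN_SCALE,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Render ``text`` into a copy of ``pixels`` at ``origin`` = (x, y).

    Glyphs are drawn at the dtype's maximum value with the fixed bitmap
    font. Returns the burned image and the tight bounding region
    (x0, y0, x1, y1), exclusive on the far edges. Empty text returns the
    image unchanged and a zero-area region at the origin. Text that would
    not fit inside the image raises :class:`CorpusError`.
    """
    ox, oy = int(origin[0]), int(origin[1])
    if not text:
        return pixels.copy(), (ox, oy, ox, oy)
    mask = render_mask(text)
    mask = np.kron(mask, np.ones((scale, scale), dtype=bool))
    h, w = mask.shape
    rows, cols = pixels.shape
    if ox < 0 or oy < 0 or ox + w > cols or oy + h > rows:
        raise CorpusError(
            f"text {text!r} ({w}x{h}px) does not fit at origin ({ox},{oy}) "
            f"in a {cols}x{rows} image"
        )
    out = pixels.copy()
    region_view = out[oy : oy + h, ox : ox + w]
    region_view[mask] = burn_value(out.dtype)
    ys, xs = np.nonzero(mask)
    x0, x1 = ox + int(xs.min()), ox + int(xs.max()) + 1
    y0, y1 = oy + int(ys.min()), oy + int(ys.max()) + 1
    return out, (x0, y0, x1, y1)


# ---------------------------------------------------------------------------
# generation


def _uid(rng: random.Random) -> str:
    return f"{UID_ROOT}.{rng.randrange(10**4)}.{rng.randrange(10**10)}"


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _typo(rng: random.Random, text: str) -> str:
    """Single-character transposition, the classic free-text data-quality flaw."""
    if len(text) < 4:
        return text
    i = rng.randrange(1, len(text) - 2)
    return text[:i] + text[i + 1] + text[i] + text[i + 2 :]


def _age_string(rng: random.Random, encoding: str, age_days: int) -> str:
    years = age_days // 365
    months = age_days // 30
    days = age_days
    if encoding == "M" and months <= 999:
        return f"{months:03d}M"
    if encoding == "D" and days <= 999:
        return f"{days:03d}D"
    if encoding == "bare":
        return f"{years:03d}"
    return f"{min(years, 999):03d}Y"


def _make_identity(rng: random.Random, used_chis: set[str], multi_chi: bool) -> PatientIdentity:
    dob = dt.date(1930, 1, 1) + dt.timedelta(days=rng.randrange(0, 365 * 75))
    while True:
        chi = make_chi(dob, rng.randrange(0, 10000))
        if chi not in used_chis:
            used_chis.add(chi)
            break
    extra: list[str] = []
    if multi_chi:
        for _ in range(rng.choice([1, 1, 2])):
            while True:
                c = make_chi(dob, rng.randrange(0, 10000))
                if c not in used_chis:
                    used_chis.add(c)
                    extra.append(c)
                    break
    return PatientIdentity(
        chi=chi,
        family_name=rng.choice(SURNAMES),
        given_name=rng.choice(FORENAMES),
        dob=dob,
        sex=rng.choice("MF"),
        extra_chis=extra,
    )


def _base_dataset(identity: PatientIdentity, chi_used: str) -> tuple[Dataset, list[PlantedIdentifier]]:
    ds = Dataset()
    ds.PatientName = f"{identity.family_name}^{identity.given_name}"
    ds.PatientID = chi_used
    ds.PatientBirthDate = identity.dob.strftime("%Y%m%d")
    ds.PatientSex = identity.sex
    planted = [
        PlantedIdentifier("(0010,0010)", str(ds.PatientName), "name"),
        PlantedIdentifier("(0010,0020)", chi_used, "chi"),
        PlantedIdentifier("(0010,0030)", ds.PatientBirthDate, "dob"),
    ]
    others = [c for c in identity.all_chis if c != chi_used]
    if others:
        ds.OtherPatientIDs = others if len(others) > 1 else others[0]
        planted.append(
            PlantedIdentifier("(0010,1000)", "\\".join(others), "chi")
        )
    return ds, planted


def generate_corpus(spec: CorpusSpec, out_dir: Path | str) -> CorpusManifest:
    """Write the synthetic archive under ``out_dir`` and return its manifest.

    Layout: ``<chi>/<study_uid>/<series_uid>/<sop_uid>.dcm``. The same spec
    (including seed) regenerates an identical manifest and identical tag
    content; only filesystem timestamps differ between runs.
    """
    spec.validate()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CorpusError(f"output directory not writable: {exc}") from exc

    rng = random.Random(spec.seed)
    manifest = CorpusManifest(spec_seed=spec.seed)
    used_chis: set[str] = set()

    for _ in range(spec.n_patients):
        identity = _make_identity(
            rng, used_chis, rng.random() < spec.multi_chi_fraction
        )
        manifest.patients.append(identity)
        manifest.master_persons.append(identity.all_chis)
        lo, hi = _as_range(spec.studies_per_patient)
        for _ in range(rng.randint(lo, hi)):
            _generate_study(rng, spec, identity, out_dir, manifest)
    return manifest


def _generate_study(
    rng: random.Random,
    spec: CorpusSpec,
    identity: PatientIdentity,
    out_dir: Path,
    manifest: CorpusManifest,
) -> None:
    chi_used = rng.choice(identity.all_chis)
    study_uid = _uid(rng)
    study_date = dt.date(2015, 1, 1) + dt.timedelta(days=rng.randrange(0, 365 * 4))
    if study_date <= identity.dob:  # infants registered late; clamp
        study_date = identity.dob + dt.timedelta(days=rng.randrange(30, 365))
    age_days = (study_date - identity.dob).days
    age_encoding = _weighted_choice(rng, spec.age_encoding_mix)
    age_string = _age_string(rng, age_encoding, age_days)
    modality = _weighted_choice(rng, spec.modality_mix)
    description = rng.choice(STUDY_DESCRIPTIONS[modality])
    if rng.random() < spec.typo_rate:
        description = _typo(rng, description)
    desc_leak = rng.random() < spec.desc_leak_fraction
    if desc_leak:
        description = f"{description} REFERRED FOR {identity.family_name}"
    manufacturer, model = rng.choice(MANUFACTURERS)
    hospital = rng.choice(HOSPITALS)

    n_series = rng.randint(*_as_range(spec.series_per_study))
    for series_index in range(n_series):
        series_uid = _uid(rng)
        n_unique = rng.randint(*_as_range(spec.slices_per_series))
        repeated = modality == "CT" and rng.random() < spec.repeated_volume_fraction
        k = rng.choice([2, 3]) if repeated else 1
        if repeated:
            contrast = rng.random() < spec.contrast_fraction
        else:
            contrast = modality == "CT" and rng.random() < spec.contrast_fraction / 2
        derived = rng.random() < spec.derived_fraction
        image_type = (
            ["DERIVED", "SECONDARY"] if derived else ["ORIGINAL", "PRIMARY", "AXIAL"]
        )
        burn = modality in ("US", "MR") and rng.random() < spec.burn_text_fraction
        burn_text_value = (
            rng.choice(
                [
                    f"{identity.family_name} {chi_used}",
                    f"{identity.given_name} {identity.family_name}",
                    chi_used,
                ]
            )
            if burn
            else None
        )
        positions = [round(i * 5.0, 2) for i in range(n_unique)] * k
        for slice_index, z in enumerate(positions):
            ds, planted = _base_dataset(identity, chi_used)
            sop_uid = _uid(rng)
            ds.SOPInstanceUID = sop_uid
            ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture
            ds.SeriesInstanceUID = series_uid
            ds.StudyInstanceUID = study_uid
            ds.Modality = modality
            ds.StudyDate = study_date.strftime("%Y%m%d")
            ds.SeriesDate = ds.StudyDate
            ds.StudyDescription = description
            ds.SeriesDescription = f"{description} SER{series_index + 1}"
            ds.PatientAge = age_string
            ds.BodyPartExamined = BODY_PARTS[modality][
                STUDY_DESCRIPTIONS[modality].index(
                    description.split(" REFERRED")[0]
                )
                if description.split(" REFERRED")[0] in STUDY_DESCRIPTIONS[modality]
                else 0
            ]
            ds.ImageType = image_type
            ds.InstanceNumber = slice_index + 1
            ds.Manufacturer = manufacturer
            ds.ManufacturerModelName = model
            ds.InstitutionName = hospital
            ds.SliceThickness = "5.0"
            ds.SliceLocation = f"{z:g}"
            ds.ImagePositionPatient = ["0", "0", f"{z:g}"]
            if contrast:
                ds.ContrastBolusAgent = "IOHEXOL 300"
                ds.ContrastBolusRoute = "IV"
            # a referring-physician tag carrying the patient's clinician is
            # safe, but occasionally clinical staff type the *patient* name
            if desc_leak:
                # the leaked surname sits in both description fields
                planted.append(
                    PlantedIdentifier("(0008,1030)", identity.family_name, "name")
                )
                planted.append(
                    PlantedIdentifier("(0008,103e)", identity.family_name, "name")
                )
            # private tag exercising the preserve-then-blacklist contract
            block = ds.private_block(0x00E1, "dicomsieve-synthetic", create=True)
            block.add_new(0x01, "LO", f"station {rng.randrange(100)}")

            pixels = _phantom(rng, spec.image_size, modality)
            burned: Optional[BurnedText] = None
            if burn_text_value is not None:
                px, region = burn_text(pixels, burn_text_value, (8, 8))
                pixels = px
                burned = BurnedText(burn_text_value, region)
            ds.Rows, ds.Columns = pixels.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = pixels.dtype.itemsize * 8
            ds.BitsStored = ds.BitsAllocated
            ds.HighBit = ds.BitsStored - 1
            ds.PixelRepresentation = 0
            ds.PixelData = pixels.tobytes()

            rel = f"{chi_used}/{study_uid}/{series_uid}/{sop_uid}.dcm"
            _write_part10(ds, out_dir / rel)
            manifest.files.append(
                FileRecord(
                    relative_path=rel,
                    sop_uid=sop_uid,
                    series_uid=series_uid,
                    study_uid=study_uid,
                    chi=chi_used,
                    modality=modality,
                    study_date=study_date.strftime("%Y%m%d"),
                    image_type=list(image_type),
                    planted=planted,
                    burned_text=burned,
                    age_string=age_string,
                    age_years_truth=age_days / 365.25,
                    slice_position=z,
                    is_repeated_volume=repeated,
                    n_acquisitions=k,
                    contrast_used=contrast,
                    study_description=description,
                )
            )


def _write_part10(ds: Dataset, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = pydicom.uid.UID(f"{UID_ROOT}.1")
    meta.ImplementationVersionName = "DICOMSIEVE01"
    ds.file_meta = meta
    ds.save_as(path, enforce_file_format=True)
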