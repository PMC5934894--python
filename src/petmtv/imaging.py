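"""Core data structures and standard-format I/O.

SUV volumes and label masks travel as NIfTI; cohort tables as CSV.
Physical bookkeeping convention: voxel index ``i`` maps to physical
coordinate ``origin + i * spacing`` (mm), and one voxel occupies
``prod(spacing) / 1000`` ml.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "SUVImage",
    "Segmentation",
    "PatientRecord",
    "FormatError",
    "AlignmentError",
    "CohortParseError",
    "read_suv_image",
    "write_suv_image",
    "read_mask",
    "write_mask",
    "activity_to_suv",
    "read_cohort_table",
    "write_cohort_table",
    "VALID_STAGES",
    "VALID_PROTOCOLS",
]

VALID_STAGES = ("I", "IIA", "IIB", "IIIA", "IIIB", "IV")
VALID_PROTOCOLS = ("C1", "C2")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected format."""


class AlignmentError(ValueError):
    """Raised when an image and a mask do not share one grid."""


class CohortParseError(ValueError):
    """Raised on malformed cohort/response CSV rows."""


@dataclass(frozen=True)
class SUVImage:
    """A 3D grid of body-weight normalized SUV values.

    Parameters
    ----------
    voxels
        3D float array of SUV values; all finite and non-negative.
    spacing
        Per-axis voxel edge length in mm; strictly positive.
    origin
        Physical coordinate (mm) of voxel index (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise FormatError(f"expected a 3D volume, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise FormatError("SUV grid contains non-finite values")
        if np.any(vox < 0):
            raise FormatError("SUV grid contains negative values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be 3 positive components, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in ml (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        """Physical coordinate (mm) of a voxel index."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass(frozen=True)
class Segmentation:
    """Integer label grid aligned to an :class:`SUVImage`.

    Label 0 is background; labels >= 1 identify lesions. Per-lesion
    volumes (ml) and the total metabolic tumor volume are derived from
    voxel counts, so ``total_mtv == sum(lesion_volumes.values())`` by
    construction.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    lesion_volumes: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise FormatError(f"label grid must be 3D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.all(lab == np.round(lab)):
                raise FormatError("label grid must be integer-valued")
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise FormatError("negative labels are not allowed")
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        vol = float(np.prod(spacing)) / 1000.0
        ids, counts = np.unique(lab[lab > 0], return_counts=True)
        volumes = {int(i): float(c) * vol for i, c in zip(ids, counts)}
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "lesion_volumes", volumes)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_volumes)

    @property
    def total_mtv(self) -> float:
        """Total metabolic tumor volume in ml."""
        return float(sum(self.lesion_volumes.values()))

    @property
    def binary_mask(self) -> np.ndarray:
        return self.labels > 0

    def check_aligned(self, image: SUVImage, tol: float = 1e-6) -> None:
        if self.labels.shape != image.shape:
            raise AlignmentError(
                f"mask shape {self.labels.shape} != image shape {image.shape}"
            )
        if not np.allclose(self.spacing, image.spacing, atol=tol):
            raise AlignmentError(
                f"mask spacing {self.spacing} != image spacing {image.spacing}"
            )


_STAGE_NUMERAL = {"I": "I", "IIA": "II", "IIB": "II", "IIIA": "III", "IIIB": "III", "IV": "IV"}


@dataclass
class PatientRecord:
    """Clinical covariates for one patient.

    ``tg_tl`` (treatment group/level 1-3) and ``response`` ("IR"/"AR")
    stay unset until rule evaluation or simulation fills them in.
    """

    id: str
    stage: str
    esr_elevated: bool
    bulk_present: bool
    extranodal: bool
    b_symptoms: bool
    protocol: str
    tg_tl: Optional[int] = None
    response: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise CohortParseError(f"unknown stage {self.stage!r} (expected one of {VALID_STAGES})")
        if self.protocol not in VALID_PROTOCOLS:
            raise CohortParseError(
                f"unknown protocol {self.protocol!r} (expected one of {VALID_PROTOCOLS})"
            )
        if self.tg_tl is not None and self.tg_tl not in (1, 2, 3):
            raise CohortParseError(f"tg_tl must be 1, 2 or 3, got {self.tg_tl}")
        if self.response is not None and self.response not in ("IR", "AR"):
            raise CohortParseError(f"response must be 'IR' or 'AR', got {self.response!r}")

    @property
    def stage_numeral(self) -> str:
        """A/B-agnostic stage: I, II, III or IV."""
        return _STAGE_NUMERAL[self.stage]

    @property
    def stage_group(self) -> str:
        """Low (I/II) versus high (III/IV) stage group."""
        return "I/II" if self.stage_numeral in ("I", "II") else "III/IV"


# ---------------------------------------------------------------------------
# NIfTI I/O


def _spacing_from_img(img: nib.spatialimages.SpatialImage) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_suv_image(path: str | Path) -> SUVImage:
    """Read a NIfTI SUV volume; spacing is taken from the affine/header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got {data.ndim}D")
    spacing = _spacing_from_img(img)
    if any(s <= 0 for s in spacing):
        raise FormatError(f"{path}: non-positive voxel spacing {spacing}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return SUVImage(voxels=data, spacing=spacing, origin=origin)


def write_suv_image(image: SUVImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.voxels.astype(np.float32), image.affine()), str(path))


def read_mask(path: str | Path, image: Optional[SUVImage] = None) -> Segmentation:
    """Read an integer label mask; optionally validate alignment to ``image``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D mask, got {data.ndim}D")
    seg = Segmentation(labels=np.rint(data).astype(np.int32), spacing=_spacing_from_img(img))
    if image is not None:
        seg.check_aligned(image)
    return seg


def write_mask(seg: Segmentation, path: str | Path, image: Optional[SUVImage] = None) -> None:
    aff = image.affine() if image is not None else np.diag(list(seg.spacing) + [1.0])
    nib.save(nib.Nifti1Image(seg.labels.astype(np.uint16), aff), str(path))


def activity_to_suv(
    concentration: np.ndarray,
    injected_activity_mbq: float,
    body_weight_kg: float,
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SUVImage:
    """Convert an activity-concentration grid (Bq/ml) to SUV.

    SUV = concentration [Bq/ml] * body weight [g] / injected activity [Bq],
    elementwise; dimensionless for water-equivalent tissue density.
    """
    if injected_activity_mbq <= 0:
        raise ValueError(f"injected activity must be > 0 MBq, got {injected_activity_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be > 0 kg, got {body_weight_kg}")
    conc = np.asarray(concentration, dtype=float)
    suv = conc * (body_weight_kg * 1000.0) / (injected_activity_mbq * 1e6)
    return SUVImage(voxels=suv, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# Cohort CSV I/O

COHORT_COLUMNS = [
    "id",
    "stage",
    "esr_elevated",
    "bulk_present",
    "extranodal",
    "b_symptoms",
    "protocol",
    "tg_tl",
    "response",
]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(token: str, row: int, column: str) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise CohortParseError(f"row {row}, column {column!r}: cannot parse boolean {token!r}")


def read_cohort_table(path: str | Path) -> list[PatientRecord]:
    """Read patient records from a comma-separated UTF-8 table.

    The header row is mandatory; unset optional fields (``tg_tl``,
    ``response``) are preserved as unset when the cell is empty.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return records
        missing = [c for c in COHORT_COLUMNS[:7] if c not in reader.fieldnames]
        if missing:
            raise CohortParseError(f"{path}: missing required columns {missing}")
        for i, row in enumerate(reader, start=1):
            stage = row["stage"].strip()
            if stage not in VALID_STAGES:
                raise CohortParseError(
                    f"row {i}, column 'stage': unknown stage token {stage!r}"
                )
            protocol = row["protocol"].strip()
            if protocol not in VALID_PROTOCOLS:
                raise CohortParseError(
                    f"row {i}, column 'protocol': unknown protocol token {protocol!r}"
                )
            tg_tl_cell = (row.get("tg_tl") or "").strip()
            response_cell = (row.get("response") or "").strip()
            records.append(
                PatientRecord(
                    id=row["id"].strip(),
                    stage=stage,
                    esr_elevated=_parse_bool(row["esr_elevated"], i, "esr_elevated"),
                    bulk_present=_parse_bool(row["bulk_present"], i, "bulk_present"),
                    extranodal=_parse_bool(row["extranodal"], i, "extranodal"),
                    b_symptoms=_parse_bool(row["b_symptoms"], i, "b_symptoms"),
                    protocol=protocol,
                    tg_tl=int(tg_tl_cell) if tg_tl_cell else None,
                    response=response_cell or None,
                )
            )
    return records


def write_cohort_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.stage,
                    str(r.esr_elevated).lower(),
                    str(r.bulk_present).lower(),
                    str(r.extranodal).lower(),
                    str(r.b_symptoms).lower(),
                    r.protocol,
                    "" if r.tg_tl is None else r.tg_tl,
                    "" if r.response is None else r.response,
                ]
            )
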