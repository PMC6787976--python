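"""Volumetric image I/O and the lobe-label convention.

CT volumes are exchanged as NIfTI (``.nii``/``.nii.gz``) with voxel spacing
taken from the header zooms. Lobe label maps share the grid of their
companion CT volume and use a fixed integer convention:

======  =====================================================
label   region
======  =====================================================
0       background (everything outside the lung)
1       RU — right upper lobe, with the right middle lobe
        merged in (the minor fissure is often undetectable,
        so the two are analysed as one region)
2       RL — right lower lobe
3       LL — left lower lobe
4       LU — left upper lobe
======  =====================================================

Subject manifests are CSV tables pointing at the four image files per
subject plus the demographic / pulmonary-function columns used for GAP
scoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LungState",
    "Group",
    "Sex",
    "LOBE_LABELS",
    "LOBE_NAMES",
    "CtVolume",
    "LobeLabelMap",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "region_volume_liters",
    "read_manifest",
]


class LungState(str, enum.Enum):
    """Breath-hold state of a CT acquisition."""

    EXPANDED = "expanded"  # full inspiration
    CONTRACTED = "contracted"  # full expiration


class Group(str, enum.Enum):
    HEALTHY = "healthy"
    IPF = "ipf"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


#: Canonical lobe label integers (background excluded).
LOBE_LABELS: Mapping[str, int] = {"RU": 1, "RL": 2, "LL": 3, "LU": 4}
#: Lobe names in canonical order.
LOBE_NAMES: tuple[str, ...] = ("RU", "RL", "LL", "LU")

_BACKGROUND = 0
_VALID_LABELS = frozenset({_BACKGROUND, *LOBE_LABELS.values()})


@dataclass
class CtVolume:
    """A 3D grid of Hounsfield-unit values with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array of HU values (air ≈ −1000, water ≈ 0).
    spacing
        Per-axis voxel edge length in millimetres.
    subject_id
        Identifier of the scanned subject.
    state
        Breath-hold state (:class:`LungState`).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    subject_id: str = ""
    state: LungState = LungState.EXPANDED

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"non-3D volume: got {self.voxels.ndim} dimensions")
        if min(self.voxels.shape) < 1:
            raise ValueError("volume must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("HU values must be finite")
        self.state = LungState(self.state)

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class LobeLabelMap:
    """Integer lobe assignment on the grid of a companion :class:`CtVolume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            arr = np.asarray(self.labels)
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("label map must be integer-valued")
            self.labels = rounded.astype(np.int32)
        found = set(np.unique(self.labels).tolist())
        unknown = found - _VALID_LABELS
        if unknown:
            raise ValueError(f"unknown lobe label(s) {sorted(unknown)}; expected subset of {sorted(_VALID_LABELS)}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    def mask(self, lobe: str | int) -> np.ndarray:
        """Boolean mask of one lobe, by name ("RU", ...) or label integer."""
        label = LOBE_LABELS[lobe] if isinstance(lobe, str) else int(lobe)
        return self.labels == label

    def lung_mask(self) -> np.ndarray:
        """Boolean mask of all labelled (non-background) voxels."""
        return self.labels != _BACKGROUND

    def voxel_counts(self) -> dict[str, int]:
        """Voxel count per lobe, in canonical lobe order."""
        return {name: int(np.count_nonzero(self.labels == lab)) for name, lab in LOBE_LABELS.items()}


@dataclass
class SubjectRecord:
    """One study subject: demographics, PFT values and paired scans.

    ``dlco_pct`` may be ``None`` when diffusing capacity could not be
    measured; GAP scoring has a dedicated branch for that case.
    """

    subject_id: str
    group: Group
    sex: Sex
    age: float
    fvc_pct: float
    dlco_pct: float | None = None
    expanded: tuple[CtVolume, LobeLabelMap] | None = None
    contracted: tuple[CtVolume, LobeLabelMap] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sex = Sex(self.sex)
        if self.age <= 0:
            raise ValueError("age must be positive")


def read_volume(path: str | Path, state: LungState | str, subject_id: str = "") -> CtVolume:
    """Read a 3D CT volume from a NIfTI file.

    HU values are returned unmodified (after application of the NIfTI
    scl_slope/scl_inter scaling, which nibabel performs when loading
    floating-point data); spacing comes from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"non-3D image in {path}: shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid spacing metadata in {path}: {zooms}")
    return CtVolume(voxels=data, spacing=tuple(float(z) for z in zooms), subject_id=subject_id, state=LungState(state))


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a :class:`CtVolume` to NIfTI, encoding spacing in the affine."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(Path(path)))


def read_label_map(path: str | Path, companion: CtVolume) -> LobeLabelMap:
    """Read a lobe label map and validate it against its companion volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.shape != companion.shape:
        raise ValueError(f"label map shape {data.shape} does not match companion volume {companion.shape}")
    return LobeLabelMap(labels=data, spacing=companion.spacing)


def write_label_map(label_map: LobeLabelMap, path: str | Path) -> None:
    affine = np.diag([*label_map.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(label_map.labels, dtype=np.int16), affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(Path(path)))


def region_volume_liters(mask_voxel_count: int, spacing: tuple[float, float, float]) -> float:
    """Convert a voxel count to a physical volume in litres.

    One litre is 10⁶ mm³, so the result is
    ``count × prod(spacing in mm) × 1e-6``.
    """
    if mask_voxel_count < 0:
        raise ValueError("voxel count must be non-negative")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return float(mask_voxel_count) * float(np.prod(spacing)) * 1e-6


_MANIFEST_COLUMNS = ("subject_id", "group", "sex", "age", "fvc_pct", "dlco_pct")


def read_manifest(path: str | Path, load_images: bool = True) -> list[SubjectRecord]:
    """Read a subject manifest CSV and (optionally) the images it references.

    Expected columns: ``subject_id, group, sex, age, fvc_pct, dlco_pct,
    expanded_image, expanded_labels, contracted_image, contracted_labels``.
    Image paths are resolved relative to the manifest's directory. An empty
    ``dlco_pct`` cell means DLCO could not be measured.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    records: list[SubjectRecord] = []
    for row in table.itertuples(index=False):
        dlco = getattr(row, "dlco_pct")
        dlco = None if pd.isna(dlco) else float(dlco)
        rec = SubjectRecord(
            subject_id=str(row.subject_id),
            group=Group(str(row.group)),
            sex=Sex(str(row.sex)),
            age=float(row.age),
            fvc_pct=float(row.fvc_pct),
            dlco_pct=dlco,
        )
        if load_images:
            base = path.parent
            for state, img_col, lab_col in (
                (LungState.EXPANDED, "expanded_image", "expanded_labels"),
                (LungState.CONTRACTED, "contracted_image", "contracted_labels"),
            ):
                vol = read_volume(base / str(getattr(row, img_col)), state, subject_id=rec.subject_id)
                labels = read_label_map(base / str(getattr(row, lab_col)), vol)
                setattr(rec, state.value, (vol, labels))
        records.append(rec)
    return records
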