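"""Label-volume I/O and grid normalization.

Reads co-registered 3D segmentation label volumes (NIfTI or NRRD), splits
them into named binary structures (tumor, the five peripancreatic vessels,
optionally pancreas), and resamples everything onto an isotropic voxel grid
so that downstream features expressed in voxels coincide with millimetres.

Arrays are held in (z, y, x) order throughout the package: the slice axis
first, the two in-plane axes last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

#: Canonical vocabulary of the five major peripancreatic vessels:
#: celiac artery, common hepatic artery, superior mesenteric artery,
#: portal vein, superior mesenteric vein.
VESSEL_NAMES = ("CA", "CHA", "SMA", "PV", "SMV")

ARTERIES = frozenset({"CA", "CHA", "SMA"})
VEINS = frozenset({"PV", "SMV"})

#: Fixed column order of the 14 anatomically designed tumor-vessel features.
ANATOMICAL_COLUMNS = (
    "R_min", "R_max", "R_mean", "R_range", "R_std",
    "theta_encase_deg",
    "D_min", "D_max", "D_mean", "D_range", "D_std", "D_ratio",
    "C_area", "C_length",
)

#: Tumor morphology columns appended to the same feature table.
MORPHOLOGY_COLUMNS = (
    "T_surface", "T_volume", "T_sphere", "T_compact",
    "T_maxD", "T_majorAxis", "T_mediumAxis", "T_minorAxis", "T_flat",
)


class FormatError(ValueError):
    """The file exists but cannot be read as a label volume."""


class MissingStructureError(KeyError):
    """A required label code is absent from the volume."""


class GridError(ValueError):
    """Member volumes do not share a common grid."""


@dataclass
class LabelVolume:
    """A 3D integer label grid with physical voxel spacing.

    ``voxels`` is indexed (z, y, x); ``spacing`` gives millimetres per voxel
    along the same axes.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("label volume must be a non-empty 3D array")
        if self.voxels.min() < 0:
            raise ValueError("label codes must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class StructureSet:
    """Named binary structures on one shared grid.

    ``vessels`` maps names from :data:`VESSEL_NAMES` to binary volumes;
    ``missing`` records requested structures that were absent from the file.
    """

    tumor: np.ndarray
    vessels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    pancreas: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    missing: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        shape = self.tumor.shape
        for name, vol in self.vessels.items():
            if name not in VESSEL_NAMES:
                raise ValueError(f"unknown vessel name {name!r}")
            if vol.shape != shape:
                raise GridError(f"vessel {name} shape {vol.shape} != tumor {shape}")
        for vol in (self.pancreas, self.intensity):
            if vol is not None and vol.shape != shape:
                raise GridError("member volume shape mismatch")
        if self.tumor.sum() == 0 and "tumor" not in self.missing:
            raise ValueError("tumor mask is empty")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tumor.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0], rtol=1e-6))


def _load_array(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Return (voxels in zyx order, spacing in zyx order) from NIfTI or NRRD."""
    suffixes = "".join(path.suffixes)
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
            zooms = img.header.get_zooms()[:3]
            # nibabel arrays are (x, y, z); normalize to (z, y, x)
            return np.ascontiguousarray(data.transpose(2, 1, 0)), tuple(zooms[::-1])
        if suffixes.endswith((".nrrd", ".nhdr")):
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img)  # already (z, y, x)
            return data, tuple(img.GetSpacing()[::-1])
    except Exception as exc:  # noqa: BLE001 - normalized to one error type
        raise FormatError(f"cannot read {path}: {exc}") from exc
    raise FormatError(f"unsupported volume format: {path}")


def read_label_volume(
    path: str | Path,
    label_map: Mapping[int, str],
    optional: Sequence[str] = (),
    intensity_path: str | Path | None = None,
) -> StructureSet:
    """Read a label volume and split it into a :class:`StructureSet`.

    Parameters
    ----------
    path:
        NIfTI (``.nii``/``.nii.gz``) or NRRD file holding integer labels.
    label_map:
        Mapping of label code to structure name. Names must be ``tumor``,
        ``pancreas`` or one of :data:`VESSEL_NAMES`.
    optional:
        Structure names allowed to be absent; they are flagged in
        ``StructureSet.missing`` rather than raising.
    intensity_path:
        Optional scalar volume (same grid) for first-order texture.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    data, spacing = _load_array(path)

    present = set(np.unique(data).tolist())
    structures: dict[str, np.ndarray] = {}
    missing: set[str] = set()
    for code, name in label_map.items():
        code = int(code)
        if code in present:
            structures[name] = data == code
        elif name in optional:
            missing.add(name)
        else:
            raise MissingStructureError(
                f"label code {code} ({name}) absent from {path.name}"
            )

    intensity = None
    if intensity_path is not None:
        intensity, ispacing = _load_array(Path(intensity_path))
        if intensity.shape != data.shape:
            raise GridError("intensity volume grid differs from label volume")

    tumor = structures.pop("tumor", None)
    if tumor is None:
        tumor = np.zeros(data.shape, dtype=bool)
        missing.add("tumor")
    pancreas = structures.pop("pancreas", None)
    vessels = {k: v for k, v in structures.items() if k in VESSEL_NAMES}
    return StructureSet(
        tumor=tumor, vessels=vessels, spacing=spacing,
        pancreas=pancreas, intensity=intensity, missing=missing,
    )


def load_label_map(path: str | Path) -> dict[int, str]:
    """Load a JSON label map ``{"1": "tumor", "2": "PV", ...}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_label_volume(
    volume: np.ndarray, spacing: Sequence[float], path: str | Path
) -> None:
    """Write a (z, y, x) integer volume as NIfTI or NRRD."""
    path = Path(path)
    arr = np.asarray(volume)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(spacing)[::-1] + [1.0])
        img = nib.Nifti1Image(
            np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.int16), affine
        )
        img.header.set_zooms(tuple(spacing)[::-1])
        nib.save(img, str(path))
    elif suffixes.endswith((".nrrd", ".nhdr")):
        img = sitk.GetImageFromArray(arr.astype(np.int16))
        img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported volume format: {path}")


def _resample_binary(vol: np.ndarray, zoom: Sequence[float]) -> np.ndarray:
    # grid_mode treats voxels as cells, which keeps integer-factor
    # resampling volume-conserving
    return ndimage.zoom(
        vol.astype(np.uint8), zoom, order=0,
        grid_mode=True, mode="grid-constant",
    ).astype(bool)


def resample_isotropic(s: StructureSet, target: float = 1.0) -> StructureSet:
    """Resample every member volume to cubic voxels of side ``target`` mm.

    Labels are interpolated nearest-neighbour (order 0), so no new label can
    appear; an already-isotropic set at the target spacing is returned as-is.
    """
    if target <= 0:
        raise ValueError("target spacing must be > 0")
    if s.is_isotropic and np.isclose(s.spacing[0], target, rtol=1e-6):
        return s
    zoom = [sp / target for sp in s.spacing]
    vessels = {k: _resample_binary(v, zoom) for k, v in s.vessels.items()}
    tumor = _resample_binary(s.tumor, zoom)
    pancreas = _resample_binary(s.pancreas, zoom) if s.pancreas is not None else None
    intensity = (
        ndimage.zoom(s.intensity.astype(float), zoom, order=1,
                     grid_mode=True, mode="grid-constant")
        if s.intensity is not None else None
    )
    return StructureSet(
        tumor=tumor, vessels=vessels, spacing=(target,) * 3,
        pancreas=pancreas, intensity=intensity, missing=set(s.missing),
    )


def require_isotropic(s: StructureSet) -> None:
    """Assert the grid contract all feature modules rely on."""
    if not s.is_isotropic:
        raise GridError(
            f"anisotropic grid {s.spacing}; call resample_isotropic first"
        )


def write_feature_table(rows: Sequence, path: str | Path) -> int:
    """Write per-(case, vessel) feature records to CSV.

    ``rows`` may be mappings or objects exposing ``to_row() -> dict``.
    Missing values are written as empty cells (never 0). Returns the number
    of data rows written.
    """
    dicts = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in rows]
    lead = ["case_id", "vessel", "missing"]
    known = lead + list(ANATOMICAL_COLUMNS) + list(MORPHOLOGY_COLUMNS)
    seen: list[str] = [c for c in known if any(c in d for d in dicts)]
    for d in dicts:
        for k in d:
            if k not in seen:
                seen.append(k)
    df = pd.DataFrame(dicts, columns=seen)
    df.to_csv(path, index=False, na_rep="")
    return len(df)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
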