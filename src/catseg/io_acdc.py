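"""NIfTI input/output for short-axis cardiac MR volumes and label maps.

The internal label convention follows the ACDC standard throughout the
package: 0 = background, 1 = right-ventricular blood pool (RV),
2 = left-ventricular myocardium (Myo), 3 = left-ventricular blood pool (LV).
Data from sources using other conventions is remapped at the boundary with
:func:`remap_labels`.

Arrays are indexed 0-based in (row, column, slice) order with half-open
ranges; any affine carried by a file is passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

ACDC_LABELS = {0: "background", 1: "RV", 2: "Myo", 3: "LV"}
VALID_LABELS = frozenset(ACDC_LABELS)


@dataclass
class CardiacVolume:
    """A 3D short-axis intensity volume.

    Attributes
    ----------
    data : (rows, cols, slices) float array, arbitrary intensity units.
    spacing : voxel size in mm per axis.
    phase : cardiac phase tag, ``"ED"`` or ``"ES"`` (or ``None``).
    patient_id : patient identifier (or ``None``).
    affine : optional 4x4 voxel-to-world matrix, carried through untouched.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    phase: str | None = None
    patient_id: str | None = None
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}-D payload")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """An integer segmentation aligned to a volume (ACDC convention)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label map must be 3D, got {data.ndim}-D payload")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise ValueError("label map values must be integers")
            data = data.astype(np.int16)
        self.data = data
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def values(self) -> set[int]:
        return set(int(v) for v in np.unique(self.data))

    def validate(self) -> "LabelMap":
        """Raise unless all values follow the ACDC convention {0,1,2,3}."""
        extra = self.values() - VALID_LABELS
        if extra:
            raise ValueError(f"invalid label value(s) {sorted(extra)}; expected subset of {sorted(VALID_LABELS)}")
        return self


def _affine_from_spacing(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path, phase: str | None = None, patient_id: str | None = None) -> CardiacVolume:
    """Read a NIfTI intensity volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CardiacVolume(data, spacing, phase=phase, patient_id=patient_id,
                         affine=np.asarray(img.affine))


def read_labelmap(path, strict: bool = True) -> LabelMap:
    """Read a NIfTI label map; ``strict`` enforces the ACDC convention."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    lm = LabelMap(data, spacing, affine=np.asarray(img.affine))
    return lm.validate() if strict else lm


def write_volume(volume: CardiacVolume, path) -> None:
    aff = volume.affine if volume.affine is not None else _affine_from_spacing(volume.spacing)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), aff)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_labelmap(labels: LabelMap, path, spacing=None) -> None:
    """Write a label map as uint8 NIfTI; rejects values outside {0,1,2,3}."""
    labels.validate()
    spacing = tuple(spacing) if spacing is not None else labels.spacing
    aff = labels.affine if labels.affine is not None else _affine_from_spacing(spacing)
    img = nib.Nifti1Image(labels.data.astype(np.uint8), aff)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def remap_labels(labels: LabelMap, mapping: Mapping[int, int]) -> LabelMap:
    """Voxelwise label substitution; the mapping must cover every value present."""
    present = labels.values()
    missing = sorted(present - set(int(k) for k in mapping))
    if missing:
        raise ValueError(f"mapping does not cover label value(s) {missing}")
    out = np.zeros_like(labels.data)
    for old, new in mapping.items():
        out[labels.data == old] = new
    return LabelMap(out, labels.spacing, affine=labels.affine)


def normalize_intensity(volume: CardiacVolume) -> CardiacVolume:
    """Per-volume z-score: output mean 0 and unit SD.

    Volume-level (not per-slice) statistics are used so the 3D segmenter
    sees no inter-slice seams. Constant volumes are rejected.
    """
    data = volume.data.astype(np.float32)
    sd = float(data.std())
    if sd < 1e-8:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    out = (data - float(data.mean())) / sd
    return CardiacVolume(out, volume.spacing, phase=volume.phase,
                         patient_id=volume.patient_id, affine=volume.affine)


def block_downsample_inplane(arr: np.ndarray, factor: int) -> np.ndarray:
    """In-plane block-mean downsampling of a (rows, cols, slices) array;
    rows and cols must be divisible by ``factor``."""
    if factor == 1:
        return arr
    r, c, s = arr.shape
    if r % factor or c % factor:
        raise ValueError(f"in-plane shape {r}x{c} not divisible by {factor}")
    return arr.reshape(r // factor, factor, c // factor, factor, s).mean(axis=(1, 3))


def stride_downsample_inplane(arr: np.ndarray, factor: int) -> np.ndarray:
    """In-plane subsampling (every ``factor``-th voxel) — used for labels."""
    return arr if factor == 1 else arr[::factor, ::factor]


def repeat_upsample_inplane(arr: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour in-plane upsampling, the inverse of stride
    subsampling for piecewise-constant label maps."""
    if factor == 1:
        return arr
    return np.repeat(np.repeat(arr, factor, axis=0), factor, axis=1)


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
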