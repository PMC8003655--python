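"""Volume containers, VOI label merging, normalization and resampling.

Conventions used throughout the package:

* a 4-channel volume is a float32 array of shape ``(4, X, Y, Z)`` with
  channel order T1, T2, FLAIR, GdT1; the last axis is the slice (z)
  direction;
* voxel indices are 0-based and bounding boxes are half-open;
* sub-region label codes follow the BraTS convention (1 = necrotic
  core, 2 = edema, 4 = enhancing tumor, 0 = background); the whole-tumor
  VOI is their union;
* Z-score normalization is computed over the in-brain support (voxels
  nonzero in any channel) with the population (n) standard deviation,
  and is applied after crop/resize so the model always sees unit-variance
  input regardless of interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume4Ch",
    "VoiMask",
    "CHANNELS",
    "merge_voi",
    "zscore_normalize",
    "support_mask",
    "bounding_box",
    "crop_resize",
    "read_case",
    "write_case",
]

CHANNELS = ("T1", "T2", "FLAIR", "GdT1")


@dataclass
class Volume4Ch:
    """A 4-channel 3D intensity volume with voxel-spacing metadata (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[0] != 4:
            raise ValueError(
                f"expected 4 channels (shape (4, X, Y, Z)), got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoiMask:
    """A binary 3D mask aligned to a :class:`Volume4Ch`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    identifier: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


def merge_voi(labels: np.ndarray, spacing=(1.0, 1.0, 1.0), identifier: str = "") -> VoiMask:
    """Merge sub-region labels into the whole-tumor VOI.

    Every nonzero label code (necrotic core, edema, enhancing tumor, or
    any other positive code) becomes 1; background stays 0.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"labels must be 3D, got shape {labels.shape}")
    if np.issubdtype(labels.dtype, np.signedinteger) and labels.min() < 0:
        raise ValueError(f"negative label code {labels.min()} is not allowed")
    return VoiMask((labels != 0).astype(np.uint8), spacing=spacing, identifier=identifier)


def support_mask(vol: Volume4Ch) -> np.ndarray:
    """In-brain support: voxels nonzero in any channel."""
    return np.any(vol.data != 0, axis=0)


def zscore_normalize(vol: Volume4Ch, region: np.ndarray | None = None) -> Volume4Ch:
    """Per-channel Z-score normalization over the in-brain support.

    Each channel is centered and scaled so that the mean over the support
    region is 0 and the population standard deviation is 1; voxels outside
    the support are set to 0. Raises if a channel has (near-)zero variance
    over the support.
    """
    sup = support_mask(vol) if region is None else np.asarray(region).astype(bool)
    if sup.shape != vol.shape:
        raise ValueError("support region shape does not match volume")
    n = int(sup.sum())
    if n < 2:
        raise ValueError("support region must contain at least 2 voxels")
    out = np.zeros_like(vol.data, dtype=np.float32)
    for c in range(4):
        vals = vol.data[c][sup].astype(np.float64)
        mu = vals.mean()
        sd = vals.std()  # population (ddof=0)
        if sd < 1e-12:
            raise ValueError(f"channel {CHANNELS[c]} has zero variance over the support region")
        out[c][sup] = ((vol.data[c][sup] - mu) / sd).astype(np.float32)
    return Volume4Ch(out, spacing=vol.spacing, identifier=vol.identifier)


def bounding_box(mask: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Tight half-open bounding box of the nonzero voxels of a 3D mask."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("cannot compute bounding box of an empty mask")
    box = []
    for ax in range(3):
        proj = np.any(mask, axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        box.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(box)


def _resample(arr: np.ndarray, box, target_shape, order: int) -> np.ndarray:
    coords = np.meshgrid(
        *[
            b0 + (np.arange(t) + 0.5) * (b1 - b0) / t - 0.5
            for (b0, b1), t in zip(box, target_shape)
        ],
        indexing="ij",
    )
    return map_coordinates(arr.astype(np.float32), np.array(coords), order=order, mode="nearest")


def crop_resize(obj, target_shape, mode: str = "image", box=None):
    """Crop to a bounding box and resample to ``target_shape``.

    Images (``mode='image'``) default to the tight bounding box of their
    in-brain support and are resampled with trilinear interpolation;
    masks (``mode='mask'``) must be given the box computed from their
    paired image and are resampled nearest-neighbor, staying binary.
    Spacing metadata is rescaled by box-size / target-size.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    if mode not in ("image", "mask"):
        raise ValueError("mode must be 'image' or 'mask'")

    if mode == "image":
        if not isinstance(obj, Volume4Ch):
            raise TypeError("mode='image' expects a Volume4Ch")
        if box is None:
            sup = support_mask(obj)
            if not sup.any():
                raise ValueError("empty support and no explicit box given")
            box = bounding_box(sup)
        full = all(b == (0, s) for b, s in zip(box, obj.shape))
        if full and tuple(obj.shape) == target_shape:
            return Volume4Ch(obj.data.copy(), spacing=obj.spacing, identifier=obj.identifier)
        data = np.stack([_resample(ch, box, target_shape, order=1) for ch in obj.data])
        spacing = tuple(
            s * (b1 - b0) / t for s, (b0, b1), t in zip(obj.spacing, box, target_shape)
        )
        return Volume4Ch(data, spacing=spacing, identifier=obj.identifier)

    if not isinstance(obj, VoiMask):
        raise TypeError("mode='mask' expects a VoiMask")
    if box is None:
        raise ValueError("mask resampling requires the box computed from the paired image")
    full = all(b == (0, s) for b, s in zip(box, obj.shape))
    if full and tuple(obj.shape) == target_shape:
        return VoiMask(obj.data.copy(), spacing=obj.spacing, identifier=obj.identifier)
    data = _resample(obj.data, box, target_shape, order=0).astype(np.uint8)
    spacing = tuple(s * (b1 - b0) / t for s, (b0, b1), t in zip(obj.spacing, box, target_shape))
    return VoiMask(data, spacing=spacing, identifier=obj.identifier)


# ---------------------------------------------------------------- NIfTI I/O


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_case(image_path, label_path, vol: Volume4Ch, labels: np.ndarray) -> None:
    """Write a case as NIfTI: 4D image (channels last) + 3D integer labels."""
    labels = np.asarray(labels)
    if labels.shape != vol.shape:
        raise ValueError(f"label shape {labels.shape} does not match image shape {vol.shape}")
    aff = _affine(vol.spacing)
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.transpose(1, 2, 3, 0)).astype(np.float32), aff)
    lab = nib.Nifti1Image(labels.astype(np.int16), aff)
    nib.save(img, str(image_path))
    nib.save(lab, str(label_path))


def read_case(image_path, label_path) -> tuple[Volume4Ch, np.ndarray]:
    """Read a 4-channel NIfTI image and its multi-label mask."""
    image_path, label_path = Path(image_path), Path(label_path)
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[3] != 4:
        raise ValueError(
            f"{image_path.name}: expected a 4D image with 4 channels, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume4Ch(
        np.ascontiguousarray(data.transpose(3, 0, 1, 2)).astype(np.float32),
        spacing=spacing,
        identifier=image_path.name.split(".")[0],
    )
    lab = nib.load(str(label_path))
    labels = np.asanyarray(lab.dataobj).astype(np.int16)
    if labels.shape != vol.shape:
        raise ValueError(
            f"label shape {labels.shape} does not match image shape {vol.shape}"
        )
    return vol, labels
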