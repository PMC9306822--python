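"""Voxel-volume data model and I/O.

A :class:`VoxelVolume` is a 3D grayscale grid (8-bit-equivalent intensities
stored as floats in [0, 255]) on a regular Cartesian lattice with physical
voxel spacing in mm.  A :class:`SegmentMask` is a boolean labelling of one
organ on the same lattice.

Coordinate convention: voxel indices are 0-based and the physical *center*
of voxel ``(i, j, k)`` is ``origin + (index + 0.5) * spacing``, i.e. ``origin``
is the corner of the first voxel.  NIfTI and NRRD headers store the center of
the first voxel, so readers/writers shift by half a voxel accordingly.

Supported formats
-----------------
* NIfTI ``.nii`` / ``.nii.gz`` (via nibabel) — compressed standard format
* NRRD ``.nrrd`` (via SimpleITK) — uncompressed research format, keeps
  free-form key/value metadata
* raw fallback: ``.npy`` array plus a plain-text JSON sidecar
  (``<stem>.meta.json``) holding ``spacing_mm``, ``origin_mm`` and, for
  masks, ``organ_label``
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import AlignmentError, VolumeFormatError

ORGAN_LABELS = ("heart", "lung_right", "lung_left", "kidney_right", "kidney_left")

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_NRRD_SUFFIXES = (".nrrd", ".nhdr")
_RAW_SUFFIX = ".npy"


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 entries, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VoxelVolume:
    """3D grayscale volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities; finite, within [0, 255].
    spacing
        Per-axis voxel edge length in mm, all > 0.
    origin
        Physical coordinate (mm) of the corner of voxel (0, 0, 0).
    meta
        Free-form acquisition metadata (e.g. nominal volume angle).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing entries must be > 0, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")
        if not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of a single voxel in mm³ (product of spacings)."""
        return float(np.prod(self.spacing))

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical center coordinates of the voxel grid (mm)."""
        return tuple(
            self.origin[a] + (np.arange(self.data.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )


@dataclass
class SegmentMask:
    """Boolean voxel labelling of a single organ, aligned to a VoxelVolume."""

    data: np.ndarray
    organ_label: str | None = None
    ref_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.ref_shape is None:
            self.ref_shape = self.data.shape
        else:
            self.ref_shape = tuple(int(s) for s in self.ref_shape)
            if self.data.shape != self.ref_shape:
                raise AlignmentError(
                    f"mask shape {self.data.shape} does not match declared "
                    f"reference shape {self.ref_shape}"
                )
        if self.organ_label is not None and self.organ_label not in ORGAN_LABELS:
            # custom labels allowed but the study organs are the canonical set
            pass

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def check_aligned(self, vol: VoxelVolume) -> None:
        if self.data.shape != vol.data.shape:
            raise AlignmentError(
                f"mask shape {self.data.shape} does not match volume shape {vol.data.shape}"
            )


# ---------------------------------------------------------------------------
# format dispatch


def _kind(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_NRRD_SUFFIXES):
        return "nrrd"
    if name.endswith(_RAW_SUFFIX):
        return "raw"
    raise VolumeFormatError(f"unsupported volume format for {path}")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name[: -len(_RAW_SUFFIX)] + ".meta.json")


def _clamp_loaded(data: np.ndarray, path: Path) -> np.ndarray:
    if data.min() < 0 or data.max() > 255:
        warnings.warn(
            f"intensities in {path} outside [0, 255]; clamping", stacklevel=3
        )
        data = np.clip(data, 0.0, 255.0)
    return data


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a grayscale volume from NIfTI, NRRD or raw .npy + sidecar.

    Spacing is taken from the file header (or sidecar) and is required;
    intensities outside [0, 255] are clamped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such volume file: {path}")
    kind = _kind(path)
    try:
        if kind == "nifti":
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj).astype(float)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            center0 = img.affine[:3, 3].astype(float)
            meta = {}
            descrip = img.header["descrip"].item()
            if descrip:
                meta["descrip"] = descrip.decode(errors="replace")
        elif kind == "nrrd":
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(float)
            spacing = tuple(float(s) for s in img.GetSpacing())
            center0 = np.asarray(img.GetOrigin(), dtype=float)
            meta = {k: img.GetMetaData(k) for k in img.GetMetaDataKeys()}
        else:
            data = np.load(path).astype(float)
            side = _sidecar(path)
            if not side.exists():
                raise VolumeFormatError(
                    f"missing sidecar {side} (spacing is required for mm³ volumetry)"
                )
            info = json.loads(side.read_text())
            if "spacing_mm" not in info:
                raise VolumeFormatError(f"sidecar {side} lacks required key 'spacing_mm'")
            spacing = _as_triple(info["spacing_mm"], "spacing_mm")
            origin = _as_triple(info.get("origin_mm", (0.0, 0.0, 0.0)), "origin_mm")
            meta = dict(info.get("meta", {}))
            if "organ_label" in info:
                meta["organ_label"] = info["organ_label"]
            if any(s <= 0 for s in spacing):
                raise VolumeFormatError(f"non-positive spacing in {side}: {spacing}")
            data = _clamp_loaded(data, path)
            return VoxelVolume(data, spacing, origin, meta)
    except (VolumeFormatError, AlignmentError):
        raise
    except Exception as exc:  # unreadable / malformed file
        raise VolumeFormatError(f"cannot read volume file {path}: {exc}") from exc
    if any(s <= 0 for s in spacing):
        raise VolumeFormatError(f"non-positive spacing in header of {path}: {spacing}")
    origin = tuple(float(c) - 0.5 * s for c, s in zip(center0, spacing))
    data = _clamp_loaded(data, path)
    return VoxelVolume(data, spacing, origin, meta)


def _write_array(arr: np.ndarray, vol_like: VoxelVolume, path: Path, extra_meta: dict) -> Path:
    kind = _kind(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    spacing = vol_like.spacing
    center0 = tuple(o + 0.5 * s for o, s in zip(vol_like.origin, spacing))
    if kind == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = center0
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(spacing)
        descrip = extra_meta.get("descrip") or vol_like.meta.get("descrip", "")
        if descrip:
            img.header["descrip"] = str(descrip)[:79].encode()
        nib.save(img, str(path))
    elif kind == "nrrd":
        img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
        img.SetSpacing(spacing)
        img.SetOrigin(center0)
        for key, val in {**vol_like.meta, **extra_meta}.items():
            img.SetMetaData(str(key), str(val))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        np.save(path, arr)
        info = {
            "spacing_mm": list(spacing),
            "origin_mm": list(vol_like.origin),
            "meta": {k: v for k, v in vol_like.meta.items()},
        }
        info.update(extra_meta)
        _sidecar(path).write_text(json.dumps(info, indent=1))
    return path


def write_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume; lossless for integer-valued grids (round-trips exactly)."""
    path = Path(path)
    data = vol.data
    if np.all(data == np.round(data)) and data.min() >= 0 and data.max() <= 255:
        arr = data.astype(np.uint8) if _kind(path) != "raw" else data
    else:
        arr = data.astype(np.float32)
    return _write_array(np.asarray(arr), vol, path, {})


def write_mask(mask: SegmentMask, path: str | Path,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
               origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Path:
    """Write a mask as a 0/1 payload; organ_label is kept in metadata/sidecar."""
    path = Path(path)
    extra = {}
    if mask.organ_label:
        extra["organ_label"] = mask.organ_label
        extra["descrip"] = f"organ={mask.organ_label}"
    carrier = VoxelVolume.__new__(VoxelVolume)  # geometry carrier, no intensity grid
    carrier.spacing = _as_triple(spacing, "spacing")
    carrier.origin = _as_triple(origin, "origin")
    carrier.meta = {}
    return _write_array(mask.data.astype(np.uint8), carrier, path, extra)


def read_mask(path: str | Path, ref: VoxelVolume | tuple[int, int, int] | None = None) -> SegmentMask:
    """Read a mask; if ``ref`` is given, enforce shape alignment."""
    vol = read_volume(path)
    label = None
    if "organ_label" in vol.meta:
        label = vol.meta["organ_label"]
    elif "descrip" in vol.meta and str(vol.meta["descrip"]).startswith("organ="):
        label = str(vol.meta["descrip"]).split("=", 1)[1]
    data = vol.data > 0.5
    ref_shape = None
    if ref is not None:
        ref_shape = ref.data.shape if isinstance(ref, VoxelVolume) else tuple(ref)
        if data.shape != tuple(ref_shape):
            raise AlignmentError(
                f"mask {path} has shape {data.shape}, companion volume has {tuple(ref_shape)}"
            )
    return SegmentMask(data, organ_label=label, ref_shape=ref_shape)
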