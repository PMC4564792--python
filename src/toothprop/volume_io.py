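"""Reading and writing CT volumes and per-tooth label volumes.

Arrays are indexed ``data[x, y, z]`` with ``z`` the axial slice index, so
``data[:, :, k]`` is axial slice ``k``.  Spacing and origin are in
millimetres.  Intensities are treated as already calibrated Hounsfield-like
units; no rescale slope/intercept handling is done, so values round-trip
bit-exactly.

Supported formats
-----------------
* NIfTI-1 ``.nii`` / ``.nii.gz`` (via nibabel),
* NRRD ``.nrrd`` (via SimpleITK),
* headerless raw dumps ``.raw`` with a JSON sidecar
  ``{"shape": [nx, ny, nz], "dtype": "int16", "spacing": [dx, dy, dz],
  "origin": [x0, y0, z0]}``; the raw stream is x-fastest (Fortran order
  for the ``(x, y, z)`` array), the layout CT scanners typically dump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import ConfigError

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]


def _validate_geometry(data: np.ndarray, spacing, origin) -> tuple[tuple, tuple]:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim} dimensions")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"every dimension must be >= 1, got shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or len(origin) != 3:
        raise ValueError("spacing and origin must have three components")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be > 0, got {spacing}")
    return spacing, origin


@dataclass
class VolumeImage:
    """A 3D scalar grid in Hounsfield-like units with voxel geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _validate_geometry(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def axial_slice(self, z: int) -> np.ndarray:
        """The 2D (x, y) array of axial slice ``z``."""
        return self.data[:, :, z]


@dataclass
class LabelVolume:
    """Integer per-tooth label grid: 0 = background, k >= 1 = tooth k."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must be integer-valued, got dtype {self.data.dtype}")
        self.spacing, self.origin = _validate_geometry(self.data, self.spacing, self.origin)
        if self.data.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def labels(self) -> list[int]:
        """Sorted nonzero label ids present in the volume."""
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != 0]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label


# ---------------------------------------------------------------------------
# format dispatch


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D image, got {data.ndim}D")
    affine = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in affine[:3, 3])
    return data, spacing, origin


def _write_nifti(data: np.ndarray, spacing, origin, path: Path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _read_nrrd(path: Path):
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected 3D image, got {img.GetDimension()}D")
    # SimpleITK arrays come back (z, y, x); our convention is (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _write_nrrd(data: np.ndarray, spacing, origin, path: Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))


def _read_raw(path: Path):
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigError(f"raw volume {path} is missing its JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        shape = tuple(int(n) for n in meta["shape"])
        dtype = np.dtype(meta["dtype"])
        spacing = tuple(meta["spacing"])
    except KeyError as exc:
        raise ConfigError(f"sidecar {sidecar} lacks required key {exc}") from exc
    origin = tuple(meta.get("origin", (0.0, 0.0, 0.0)))
    if len(shape) != 3:
        raise ValueError(f"{sidecar}: shape must be 3D, got {shape}")
    flat = np.fromfile(path, dtype=dtype)
    if flat.size != int(np.prod(shape)):
        raise ValueError(
            f"{path}: file holds {flat.size} voxels, sidecar shape {shape} "
            f"needs {int(np.prod(shape))}"
        )
    return flat.reshape(shape, order="F"), spacing, origin


def _write_raw(data: np.ndarray, spacing, origin, path: Path) -> None:
    data.flatten(order="F").tofile(path)
    meta = {
        "shape": list(data.shape),
        "dtype": data.dtype.name,
        "spacing": list(spacing),
        "origin": list(origin),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


_READERS = {".nii": _read_nifti, ".nii.gz": _read_nifti, ".nrrd": _read_nrrd, ".raw": _read_raw}
_WRITERS = {".nii": _write_nifti, ".nii.gz": _write_nifti, ".nrrd": _write_nrrd, ".raw": _write_raw}


def _read_any(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = _suffix(path)
    if ext not in _READERS:
        raise ConfigError(f"unsupported volume format {ext!r} ({path})")
    return _READERS[ext](path)


def _write_any(data: np.ndarray, spacing, origin, path) -> None:
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"target directory {path.parent} does not exist")
    ext = _suffix(path)
    if ext not in _WRITERS:
        raise ConfigError(f"unsupported volume format {ext!r} ({path})")
    _WRITERS[ext](data, spacing, origin, path)


# ---------------------------------------------------------------------------
# public API


def read_volume(path) -> VolumeImage:
    """Read a CT volume; raw 16-bit values are passed through unmodified."""
    data, spacing, origin = _read_any(path)
    return VolumeImage(data, spacing, origin)


def write_volume(vol: VolumeImage, path) -> None:
    """Write ``vol`` so that :func:`read_volume` recovers it bit-identically."""
    _write_any(vol.data, vol.spacing, vol.origin, path)


def read_labels(path) -> LabelVolume:
    """Read a label volume; non-integer voxel data is a :class:`TypeError`."""
    data, spacing, origin = _read_any(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise TypeError(f"{path}: label volume must be integer-valued, got {data.dtype}")
    return LabelVolume(data, spacing, origin)


def write_labels(lab: LabelVolume, path) -> None:
    _write_any(lab.data, lab.spacing, lab.origin, path)
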