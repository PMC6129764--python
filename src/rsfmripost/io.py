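"""NIfTI volume I/O and 4D <-> masked 2D time-series conversion.

The whole package works on two in-memory containers:

* :class:`Volume4D` — a 4D image grid (X, Y, Z, T) with its affine and TR.
  A 3D image is a Volume4D with T = 1.
* :class:`TimeSeriesMatrix` — the frames-by-voxels matrix obtained by masking
  a volume; the unit all metric code operates on.

Voxel linear order is fixed package-wide: column-major over the spatial grid
(X fastest, then Y, then Z).  Column ``j`` of a TimeSeriesMatrix is the full
time series of the in-mask voxel with the j-th smallest linear index.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume4D",
    "BrainMask",
    "TimeSeriesMatrix",
    "read_volume",
    "write_volume",
    "volume_to_matrix",
    "matrix_to_volume",
    "smooth_volume",
    "GridMismatchError",
]

#: tolerance (mm per affine element) when deciding two grids match
AFFINE_TOL = 1e-4


class GridMismatchError(ValueError):
    """Raised when two images do not share a voxel grid (shape + affine)."""


@dataclass
class Volume4D:
    """A 4D image: ``data`` is (X, Y, Z, T), ``tr`` in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float = 1.0
    descrip: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (norms of the affine columns)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class BrainMask:
    """Binary 3D mask on the same grid as the volumes it is applied to."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim == 4 and self.data.shape[3] == 1:
            self.data = self.data[..., 0]
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def linear_indices(self) -> np.ndarray:
        """Strictly increasing linear indices (X fastest) of true voxels."""
        return np.flatnonzero(self.data.ravel(order="F"))

    @classmethod
    def from_volume(cls, vol: Volume4D, threshold: float = 0.0) -> "BrainMask":
        return cls(vol.data[..., 0] > threshold, vol.affine)


@dataclass
class TimeSeriesMatrix:
    """Frames x voxels matrix plus the map back to the source grid.

    ``values[t, j]`` is the intensity at frame ``t`` of the voxel whose
    column-major linear index is ``voxel_index[j]``.
    """

    values: np.ndarray
    voxel_index: np.ndarray
    tr: float
    source_shape: tuple[int, int, int]
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (frames x voxels)")
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.voxel_index.ndim != 1 or len(self.voxel_index) != self.values.shape[1]:
            raise ValueError("voxel_index length must equal the voxel count")
        if np.any(np.diff(self.voxel_index) <= 0):
            raise ValueError("voxel_index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def grid_coordinates(self) -> np.ndarray:
        """(V, 3) integer grid coordinates of each column's voxel."""
        return np.column_stack(
            np.unravel_index(self.voxel_index, self.source_shape, order="F")
        )


def check_grid_match(
    affine_a: np.ndarray,
    shape_a: tuple[int, ...],
    affine_b: np.ndarray,
    shape_b: tuple[int, ...],
) -> None:
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise GridMismatchError(f"shape mismatch: {shape_a[:3]} vs {shape_b[:3]}")
    if np.max(np.abs(np.asarray(affine_a) - np.asarray(affine_b))) > AFFINE_TOL:
        raise GridMismatchError("affines differ by more than tolerance")


def read_volume(path: str | os.PathLike, tr: float | None = None) -> Volume4D:
    """Read a NIfTI-1 image (plain or gzipped) as a :class:`Volume4D`.

    TR is taken from the header time step unless ``tr`` overrides it (a
    warning is logged when both are present and disagree).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises various errors for bad files
        raise ValueError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path!r}: expected a 3D or 4D image, got ndim={data.ndim}")
    header_tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else 0.0
    if tr is not None:
        if header_tr > 0 and abs(header_tr - tr) > 1e-6:
            warnings.warn(
                f"TR override {tr} s disagrees with header time step {header_tr} s; "
                "using the override"
            )
        use_tr = tr
    else:
        use_tr = header_tr if header_tr > 0 else 1.0
    descrip = ""
    if hasattr(img.header, "get"):
        try:
            descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode("ascii", "ignore")
        except Exception:
            descrip = ""
    return Volume4D(data, img.affine, tr=use_tr, descrip=descrip)


def write_volume(vol: Volume4D, path: str | os.PathLike, gzip: bool | None = None) -> str:
    """Write a volume as NIfTI-1; T = 1 volumes are written as 3D images.

    ``gzip=True`` forces a ``.nii.gz`` suffix; by default the suffix of
    ``path`` decides.
    """
    path = os.fspath(path)
    if gzip is True and not path.endswith(".gz"):
        path = path + ".gz" if path.endswith(".nii") else path + ".nii.gz"
    elif gzip is False and path.endswith(".gz"):
        path = path[: -len(".gz")]
    parent = os.path.dirname(path)
    if parent:
        os.makedirs(parent, exist_ok=True)
    data = vol.data[..., 0] if vol.n_frames == 1 else vol.data
    img = nib.Nifti1Image(data, vol.affine)
    if data.ndim == 4:
        img.header.set_zooms((*vol.voxel_sizes(), float(vol.tr)))
    if vol.descrip:
        img.header["descrip"] = vol.descrip.encode()[:79]
    nib.save(img, path)
    return path


def volume_to_matrix(vol: Volume4D, mask: BrainMask) -> TimeSeriesMatrix:
    """Mask a 4D volume into a frames x voxels matrix.

    Columns follow the fixed voxel linear order (X fastest); the voxel with
    the smallest linear index becomes column 0.
    """
    check_grid_match(vol.affine, vol.shape3d, mask.affine, mask.data.shape)
    idx = mask.linear_indices()
    flat = vol.data.reshape((-1, vol.n_frames), order="F")
    return TimeSeriesMatrix(
        flat[idx].T.copy(), idx, tr=vol.tr, source_shape=vol.shape3d, affine=vol.affine
    )


def matrix_to_volume(
    mat: TimeSeriesMatrix,
    mask: BrainMask,
    template: Volume4D | None = None,
    fill: float = 0.0,
) -> Volume4D:
    """Scatter a matrix back onto the 3D grid; out-of-mask voxels get ``fill``."""
    idx = mask.linear_indices()
    if len(idx) != mat.n_voxels or not np.array_equal(idx, mat.voxel_index):
        raise ValueError("matrix voxel_index inconsistent with mask")
    shape = mat.source_shape
    flat = np.full((int(np.prod(shape)), mat.n_frames), fill, dtype=np.float64)
    flat[idx] = mat.values.T
    data = flat.reshape((*shape, mat.n_frames), order="F")
    affine = template.affine if template is not None else (
        mat.affine if mat.affine is not None else mask.affine
    )
    return Volume4D(data, affine, tr=mat.tr)


def smooth_volume(vol: Volume4D, fwhm: float | tuple[float, float, float]) -> Volume4D:
    """Separable spatial Gaussian smoothing, FWHM given in mm per axis."""
    fwhm_arr = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,)).copy()
    if np.any(fwhm_arr < 0):
        raise ValueError("fwhm must be non-negative")
    # FWHM = 2 sqrt(2 ln 2) sigma; sigma in voxel units
    sigma = fwhm_arr / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vol.voxel_sizes()
    out = np.empty_like(vol.data)
    for t in range(vol.n_frames):
        out[..., t] = ndimage.gaussian_filter(vol.data[..., t], sigma=sigma)
    return Volume4D(out, vol.affine, tr=vol.tr, descrip=vol.descrip)
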