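"""Quality control: head-motion summaries and temporal SNR masking.

Motion summaries follow the realignment-trace conventions: translations in
mm, rotations in radians (converted to degrees for reporting).  Framewise
displacement (FD) sums the absolute frame-to-frame changes of all six
parameters with rotations converted to arc length on a sphere of the given
head radius (50 mm by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import BrainMask, Volume4D, volume_to_matrix

__all__ = [
    "MotionSummary",
    "TsnrResult",
    "framewise_displacement",
    "motion_summary",
    "tsnr",
    "read_motion_params",
    "write_motion_params",
]

DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass
class MotionSummary:
    max_abs_translation: float   # mm
    max_abs_rotation: float      # degrees
    mean_rms_displacement: float  # mm, mean over frames of sqrt(x^2+y^2+z^2)
    max_displacement: float      # mm
    n_micro_displacements: int   # inter-frame rms-displacement changes > threshold
    mean_abs_euler_angle: float  # degrees
    mean_fd: float               # mm
    n_fd_above: int
    fd_threshold: float          # mm

    def to_row(self) -> dict:
        return asdict(self)


@dataclass
class TsnrResult:
    map: np.ndarray          # 3D TSNR values (0 outside input mask)
    mask: BrainMask | None   # voxels surviving the threshold
    threshold: float
    level: str               # "subject" | "group"


def read_motion_params(path, rotation_unit: str = "radians") -> np.ndarray:
    """Read a whitespace-delimited T x 6 realignment parameter file."""
    values = np.loadtxt(path, ndmin=2)
    if values.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {values.shape[1]}")
    if rotation_unit == "degrees":
        values = values.copy()
        values[:, 3:] = np.deg2rad(values[:, 3:])
    elif rotation_unit != "radians":
        raise ValueError("rotation_unit must be 'radians' or 'degrees'")
    return values


def write_motion_params(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values), fmt="%.10g")


def framewise_displacement(
    motion: np.ndarray, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """FD(t) = sum of |delta| over the 6 parameters; rotations scaled to mm.

    Rotational deltas (radians) are converted to displacement on a sphere of
    ``head_radius`` mm.  FD(0) is defined as 0.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames for framewise displacement")
    delta = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = delta[:, :3].sum(axis=1) + head_radius * delta[:, 3:].sum(axis=1)
    return fd


def _euler_angle(rot: np.ndarray) -> np.ndarray:
    """Composite rotation angle per frame from (pitch, yaw, roll) radians."""
    p, y, r = rot[:, 0], rot[:, 1], rot[:, 2]
    arg = (np.cos(p) * np.cos(y) + np.cos(p) * np.cos(r) + np.cos(y) * np.cos(r)
           + np.sin(p) * np.sin(y) * np.sin(r) - 1.0) / 2.0
    return np.arccos(np.clip(arg, -1.0, 1.0))


def motion_summary(
    motion: np.ndarray,
    fd_threshold: float = 0.5,
    micro_threshold: float = 0.1,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
) -> MotionSummary:
    """All head-motion exclusion criteria from one realignment trace."""
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    trans, rot = motion[:, :3], motion[:, 3:]
    rms = np.sqrt((trans**2).sum(axis=1))
    d_rms = np.abs(np.diff(rms))
    fd = framewise_displacement(motion, head_radius=head_radius)
    return MotionSummary(
        max_abs_translation=float(np.max(np.abs(trans))),
        max_abs_rotation=float(np.rad2deg(np.max(np.abs(rot)))),
        mean_rms_displacement=float(rms.mean()),
        max_displacement=float(rms.max()),
        n_micro_displacements=int(np.sum(d_rms > micro_threshold)),
        mean_abs_euler_angle=float(np.rad2deg(np.mean(_euler_angle(rot)))),
        mean_fd=float(fd.mean()),
        n_fd_above=int(np.sum(fd > fd_threshold)),
        fd_threshold=float(fd_threshold),
    )


def summaries_to_csv(rows: dict[str, MotionSummary], path) -> pd.DataFrame:
    """One QC row per subject, columns = MotionSummary fields."""
    df = pd.DataFrame({k: v.to_row() for k, v in rows.items()}).T
    df.index.name = "subject"
    df.to_csv(path)
    return df


def tsnr(
    vol: Volume4D,
    mask: BrainMask,
    threshold: float = 30.0,
    group_maps: list[np.ndarray] | None = None,
) -> TsnrResult:
    """Temporal SNR per voxel: series mean / standard deviation (N-1).

    Zero-variance voxels get TSNR 0 and never survive the threshold.  With
    ``group_maps`` (a list of subject TSNR maps), the group-level mask
    thresholds the across-subject mean map instead.
    """
    if vol.n_frames < 2:
        raise ValueError("need at least 2 frames for TSNR")
    mat = volume_to_matrix(vol, mask)
    mean = mat.values.mean(axis=0)
    sd = mat.values.std(axis=0, ddof=1)
    snr = np.zeros_like(mean)
    nz = sd > 0
    snr[nz] = mean[nz] / sd[nz]
    snr_map = np.zeros(vol.shape3d, order="F")
    snr_map.ravel(order="F")[mat.voxel_index] = snr
    if group_maps is not None:
        level = "group"
        stack = np.stack(list(group_maps) + [snr_map])
        basis = stack.mean(axis=0)
    else:
        level = "subject"
        basis = snr_map
    surv = (basis > threshold) & mask.data
    if not surv.any():
        warnings.warn("no voxels survive the TSNR threshold; mask is empty")
        out_mask = None
    else:
        out_mask = BrainMask(surv, mask.affine)
    return TsnrResult(map=snr_map, mask=out_mask, threshold=float(threshold),
                      level=level)
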