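"""Nuisance regression, motion scrubbing, and ideal band-pass filtering.

The denoising model is the standard multiple regression of each voxel's
time series on a design of slow trends, tissue mean signals (white matter,
CSF, optionally the global signal), and the six realignment parameters,
together with their squares, backward first derivatives, and one-frame
lagged copies (the 24-parameter motion expansion).  The residual of that
fit is the denoised series.

Frame censoring ("scrubbing") is decided before the regression from the
framewise displacement: betas are estimated on the kept frames only, but
residuals are produced for every frame so that the subsequent FFT-based
filter sees an unbroken series; censored frames should be dropped again at
metric time.

The band-pass filter is an ideal (square-wave) frequency-domain filter.  To
suppress wrap-around artifacts each series is extended to length 2T by
appending its time-reverse before the transform; DFT bins with
low <= f <= high (computed on the extended length) are retained, everything
else is zeroed, and the first T samples of the inverse transform are
returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeriesMatrix

__all__ = [
    "TissueSignals",
    "NuisanceDesign",
    "CensorPlan",
    "build_design",
    "make_censor_plan",
    "scrub",
    "regress_nuisance",
    "bandpass",
]


@dataclass
class TissueSignals:
    """Mean tissue time series: white matter, CSF, optional global signal."""

    wm: np.ndarray
    csf: np.ndarray
    gs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm, dtype=np.float64).ravel()
        self.csf = np.asarray(self.csf, dtype=np.float64).ravel()
        if self.gs is not None:
            self.gs = np.asarray(self.gs, dtype=np.float64).ravel()
            if len(self.gs) != len(self.wm):
                raise ValueError("tissue series lengths differ")
        if len(self.wm) != len(self.csf):
            raise ValueError("tissue series lengths differ")


@dataclass
class NuisanceDesign:
    matrix: np.ndarray
    labels: list[str]
    options: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CensorPlan:
    """Partition of frames into kept and removed, driven by FD."""

    fd: np.ndarray
    threshold: float
    kept: np.ndarray
    removed: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.fd)


def _derivative(col: np.ndarray) -> np.ndarray:
    """Backward difference with zero padding at frame 0."""
    out = np.zeros_like(col)
    out[1:] = np.diff(col)
    return out


def _lag(col: np.ndarray) -> np.ndarray:
    """Shift by one frame with zero padding at frame 0."""
    out = np.zeros_like(col)
    out[1:] = col[:-1]
    return out


def build_design(
    tissue: TissueSignals | None,
    motion: np.ndarray | None,
    trends: bool = True,
    use_gs: bool = False,
    squares: bool = True,
    derivatives: bool = True,
    lags: bool = True,
    n_frames: int | None = None,
    rotation_unit: str = "radians",
) -> NuisanceDesign:
    """Assemble the nuisance design matrix.

    Base columns are the tissue means (WM, CSF, + GS when ``use_gs``) and
    the six motion parameters.  Per base column the enabled variant blocks
    add the backward derivative and the one-frame lag, and ``squares`` adds
    the elementwise square of every base/variant column.  An intercept is
    always present; ``trends`` adds linear + quadratic trend columns.

    With all blocks on and GS: 1 + 2 + 3*6 + 6*6 = 57 columns; GS off: 49.
    """
    if rotation_unit not in ("radians", "degrees"):
        raise ValueError("rotation_unit must be 'radians' or 'degrees'")
    if tissue is not None:
        T = len(tissue.wm)
    elif motion is not None:
        T = len(motion)
    elif n_frames is not None:
        T = n_frames
    else:
        raise ValueError("need tissue, motion, or n_frames to fix the length")

    cols: list[np.ndarray] = [np.ones(T)]
    labels: list[str] = ["intercept"]
    if trends:
        lin = np.linspace(-1.0, 1.0, T)
        cols += [lin, lin**2]
        labels += ["trend_linear", "trend_quadratic"]

    bases: list[tuple[str, np.ndarray]] = []
    if tissue is not None:
        if len(tissue.wm) != T or len(tissue.csf) != T:
            raise ValueError("tissue series length mismatch")
        bases += [("wm", tissue.wm), ("csf", tissue.csf)]
        if use_gs:
            if tissue.gs is None:
                raise ValueError("use_gs=True but no global signal supplied")
            bases.append(("gs", tissue.gs))
    if motion is not None:
        motion = np.asarray(motion, dtype=np.float64)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError("motion must be T x 6")
        if motion.shape[0] != T:
            raise ValueError("motion length mismatch with tissue series")
        if not np.all(np.isfinite(motion)):
            raise ValueError("non-finite motion parameters")
        mot = motion.copy()
        if rotation_unit == "degrees":
            mot[:, 3:] = np.deg2rad(mot[:, 3:])
        for k, name in enumerate(["tx", "ty", "tz", "pitch", "yaw", "roll"]):
            bases.append((name, mot[:, k]))

    if not bases:
        warnings.warn("all nuisance blocks are off; design is intercept/trends only")

    for name, base in bases:
        variants = [(name, base)]
        if derivatives:
            variants.append((f"{name}_deriv", _derivative(base)))
        if lags:
            variants.append((f"{name}_lag", _lag(base)))
        for vname, vcol in variants:
            cols.append(vcol)
            labels.append(vname)
            if squares:
                cols.append(vcol**2)
                labels.append(f"{vname}_sq")

    matrix = np.column_stack(cols)
    if not np.all(np.isfinite(matrix)):
        bad = [labels[j] for j in np.where(~np.isfinite(matrix).all(axis=0))[0]]
        raise ValueError(f"non-finite values in design columns: {bad}")
    options = dict(
        trends=trends, use_gs=use_gs, squares=squares,
        derivatives=derivatives, lags=lags,
    )
    return NuisanceDesign(matrix, labels, options)


def make_censor_plan(fd: np.ndarray, threshold: float) -> CensorPlan:
    """Mark frames whose framewise displacement exceeds ``threshold`` mm."""
    fd = np.asarray(fd, dtype=np.float64).ravel()
    removed = np.flatnonzero(fd > threshold)
    kept = np.flatnonzero(fd <= threshold)
    return CensorPlan(fd=fd, threshold=float(threshold), kept=kept, removed=removed)


def scrub(
    mat: TimeSeriesMatrix,
    plan: CensorPlan,
    min_fraction: float = 0.5,
) -> tuple[TimeSeriesMatrix, CensorPlan]:
    """Drop censored frames; errors when fewer than ``min_fraction``*T remain."""
    if plan.n_frames != mat.n_frames:
        raise ValueError("censor plan length does not match the matrix")
    if len(plan.kept) < min_fraction * mat.n_frames:
        raise ValueError(
            f"too few frames retained after scrubbing "
            f"({len(plan.kept)}/{mat.n_frames} < {min_fraction:.0%})"
        )
    out = TimeSeriesMatrix(
        mat.values[plan.kept], mat.voxel_index, tr=mat.tr,
        source_shape=mat.source_shape, affine=mat.affine,
    )
    return out, plan


def regress_nuisance(
    mat: TimeSeriesMatrix,
    design: NuisanceDesign,
    plan: CensorPlan | None = None,
) -> TimeSeriesMatrix:
    """Residualize every voxel series against the design.

    Betas are fit by least squares on the kept frames (all frames when no
    plan is given); fitted values are subtracted at every frame so the
    output is a full-length residual series.  Rank-deficient designs fall
    back to the pseudoinverse with a warning.
    """
    if design.n_frames != mat.n_frames:
        raise ValueError("design rows do not match the matrix frames")
    Y = mat.values
    if not np.all(np.isfinite(Y)):
        bad = np.where(~np.isfinite(Y).all(axis=0))[0]
        raise ValueError(f"non-finite values in voxel columns {bad[:10].tolist()}")
    X = design.matrix
    keep = plan.kept if plan is not None else np.arange(mat.n_frames)
    Xk = X[keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{X.shape[1]}); using pseudoinverse"
        )
    beta = np.linalg.pinv(Xk) @ Y[keep]
    resid = Y - X @ beta
    return TimeSeriesMatrix(
        resid, mat.voxel_index, tr=mat.tr,
        source_shape=mat.source_shape, affine=mat.affine,
    )


def bandpass(
    mat: TimeSeriesMatrix | np.ndarray,
    low: float,
    high: float,
    tr: float | None = None,
) -> TimeSeriesMatrix | np.ndarray:
    """Ideal band-pass via FFT on the mirror-extended series.

    A DFT bin of the length-2T extension is kept iff low <= f <= high; the
    Nyquist bin is therefore kept exactly when ``high`` equals the Nyquist
    frequency 1/(2*TR).
    """
    if isinstance(mat, TimeSeriesMatrix):
        values, use_tr = mat.values, mat.tr
    else:
        values = np.atleast_2d(np.asarray(mat, dtype=np.float64))
        if tr is None:
            raise ValueError("tr required for a bare array")
        use_tr = tr
    nyquist = 1.0 / (2.0 * use_tr)
    if not (0.0 <= low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band [{low}, {high}] Hz outside [0, Nyquist={nyquist:.4g}] Hz"
        )
    T = values.shape[0]
    ext = np.concatenate([values, values[::-1]], axis=0)  # mirrored extension
    F = np.fft.rfft(ext, axis=0)
    freqs = np.fft.rfftfreq(2 * T, d=use_tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    F[~keep] = 0.0
    filtered = np.fft.irfft(F, n=2 * T, axis=0)[:T]
    if isinstance(mat, TimeSeriesMatrix):
        return TimeSeriesMatrix(
            filtered, mat.voxel_index, tr=mat.tr,
            source_shape=mat.source_shape, affine=mat.affine,
        )
    return filtered
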