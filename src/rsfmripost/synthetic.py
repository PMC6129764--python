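"""Synthetic phantoms, motion traces, and atlases with known ground truth.

Every downstream stage of the package can be exercised on these fixtures:
band-limited sinusoids plus noise in labeled blobs stand in for BOLD
fluctuations, a seeded random walk with injected steps stands in for a
realignment trace, and region-grown blobs stand in for an ROI atlas.
Waveforms are deliberately simple (no hemodynamic convolution, no
physiological noise spectra) — the point is recoverable ground truth, not
biophysical realism.

All generators take an explicit integer seed; the same seed always yields
bit-identical output and no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BrainMask, Volume4D

__all__ = [
    "Waveform",
    "sinusoid",
    "drift",
    "white_noise",
    "PhantomSpec",
    "generate_phantom",
    "generate_motion",
    "generate_atlas",
]


@dataclass
class Waveform:
    """One additive signal component: sinusoid, polynomial drift, or noise."""

    kind: str  # "sinusoid" | "drift" | "noise"
    freq: float = 0.0       # Hz, sinusoid only
    amplitude: float = 1.0
    phase: float = 0.0      # radians, sinusoid only
    order: int = 1          # drift only: polynomial order
    sd: float = 1.0         # noise only: per-sample standard deviation

    def sample(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "sinusoid":
            return self.amplitude * np.sin(2.0 * np.pi * self.freq * t + self.phase)
        if self.kind == "drift":
            x = np.linspace(-1.0, 1.0, len(t))
            return self.amplitude * x**self.order
        if self.kind == "noise":
            return self.sd * rng.standard_normal(len(t))
        raise ValueError(f"unknown waveform kind {self.kind!r}")


def sinusoid(freq: float, amplitude: float = 1.0, phase: float = 0.0) -> Waveform:
    return Waveform("sinusoid", freq=freq, amplitude=amplitude, phase=phase)


def drift(order: int = 1, amplitude: float = 1.0) -> Waveform:
    return Waveform("drift", order=order, amplitude=amplitude)


def white_noise(sd: float) -> Waveform:
    return Waveform("noise", sd=sd)


@dataclass
class PhantomSpec:
    """Recipe for a 4D phantom.

    ``components`` is a list of ``(region, waveform)`` pairs where region is
    either the string ``"global"`` or a boolean 3D array selecting the voxels
    that receive the waveform.  Noise components draw fresh samples per voxel;
    deterministic components are shared by all voxels of their region.
    """

    dims: tuple[int, int, int] = (10, 10, 10)
    n_frames: int = 100
    tr: float = 2.0
    components: list = field(default_factory=list)
    baseline: float = 100.0
    seed: int = 0
    voxel_size: float = 3.0  # mm, isotropic


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def generate_phantom(spec: PhantomSpec) -> Volume4D:
    """Render a :class:`PhantomSpec` to a 4D volume; fully seed-determined."""
    nyquist = 1.0 / (2.0 * spec.tr)
    for _, wf in spec.components:
        if wf.kind == "sinusoid" and wf.freq >= nyquist:
            raise ValueError(
                f"sinusoid frequency {wf.freq} Hz at or above Nyquist {nyquist} Hz"
            )
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.tr
    data = np.full((*spec.dims, spec.n_frames), spec.baseline, dtype=np.float64)
    for region, wf in spec.components:
        if isinstance(region, str) and region == "global":
            sel = np.ones(spec.dims, dtype=bool)
        else:
            sel = np.asarray(region, dtype=bool)
            if sel.shape != tuple(spec.dims):
                raise ValueError("component region shape does not match dims")
        if wf.kind == "noise":
            # independent noise per in-region voxel
            n_vox = int(sel.sum())
            data[sel] += wf.sd * rng.standard_normal((n_vox, spec.n_frames))
        else:
            data[sel] += wf.sample(t, rng)
    return Volume4D(data, _affine(spec.voxel_size), tr=spec.tr)


def generate_motion(
    n_frames: int,
    events: list[tuple[int, int, float]] | None = None,
    drift_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A T x 6 realignment trace: seeded random walk plus step events.

    ``events`` are ``(frame, axis, delta)``: from ``frame`` onward the given
    parameter is offset by ``delta`` (mm for axes 0-2, radians for 3-5).
    """
    events = events or []
    rng = np.random.default_rng(seed)
    if drift_sd > 0:
        steps = drift_sd * rng.standard_normal((n_frames, 6))
        steps[0] = 0.0
        values = np.cumsum(steps, axis=0)
    else:
        values = np.zeros((n_frames, 6))
    for frame, axis, delta in events:
        if not 0 <= frame < n_frames:
            raise ValueError(f"event frame {frame} out of range")
        if not 0 <= axis < 6:
            raise ValueError(f"axis {axis} outside the 6 motion parameters")
        values[frame:, axis] += delta
    return values


def generate_atlas(
    dims: tuple[int, int, int],
    n_rois: int,
    min_size: int = 8,
    seed: int = 0,
    voxel_size: float = 3.0,
):
    """Disjoint connected blobs labeled 1..n_rois, each >= min_size voxels.

    Blobs grow by face-connected accretion from random seed voxels, which
    guarantees connectivity; packing that cannot fit raises an error.
    """
    from .fc import LabelTable, ROIAtlas

    dims = tuple(dims)
    total = int(np.prod(dims))
    if n_rois * min_size > total:
        raise ValueError("cannot pack n_rois * min_size voxels into the grid")
    rng = np.random.default_rng(seed)
    labels = np.zeros(dims, dtype=np.int32)
    offsets = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for roi in range(1, n_rois + 1):
        for _attempt in range(200):
            free = np.argwhere(labels == 0)
            start = free[rng.integers(len(free))]
            grown = _grow_blob(labels, start, min_size, offsets, rng, dims)
            if grown is not None:
                for vox in grown:
                    labels[tuple(vox)] = roi
                break
        else:
            raise ValueError(f"could not place ROI {roi}: infeasible packing")
    table = LabelTable.from_records(
        [(i, f"roi{i:03d}") for i in range(1, n_rois + 1)]
    )
    return ROIAtlas(labels, _affine(voxel_size), table)


def _grow_blob(labels, start, size, offsets, rng, dims):
    """Face-connected accretion from ``start``; None if growth stalls."""
    member = {tuple(start)}
    frontier = [tuple(start)]
    while len(member) < size:
        candidates = []
        for vox in frontier:
            for off in offsets:
                nb = tuple(np.asarray(vox) + off)
                if all(0 <= nb[k] < dims[k] for k in range(3)):
                    if labels[nb] == 0 and nb not in member:
                        candidates.append(nb)
        if not candidates:
            return None
        pick = candidates[rng.integers(len(candidates))]
        member.add(pick)
        frontier.append(pick)
    return [np.asarray(v) for v in member]


def blob_mask(dims: tuple[int, int, int], corner: tuple[int, int, int],
              size: tuple[int, int, int]) -> np.ndarray:
    """Axis-aligned rectangular region selector (test-fixture convenience)."""
    sel = np.zeros(dims, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    sel[sl] = True
    return sel


def full_mask(dims: tuple[int, int, int], voxel_size: float = 3.0) -> BrainMask:
    """A mask covering the whole grid, on the phantom affine."""
    return BrainMask(np.ones(dims, dtype=bool), _affine(voxel_size))
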