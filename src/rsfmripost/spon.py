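"""Voxel-wise spontaneous-activity metrics.

Implemented metrics
-------------------
* **AM** — mean absolute deviation and corrected standard deviation of the
  mean-subtracted series; a crude fluctuation-strength measure.
* **ALFF / fALFF** — (fractional) amplitude of low-frequency fluctuation:
  the mean square-root power-spectral-density amplitude in a band, and its
  fraction of the full positive-frequency amplitude.
* **ReHo** — regional homogeneity, Kendall's coefficient of concordance W
  between a voxel's series and its 6/18/26 neighbors' series.
* **FCD** — functional connectivity density: global (count of
  supra-threshold correlations), local (size of the spatially connected
  supra-threshold region grown from the seed), and long-range
  (global minus local).  The binarized voxel-by-voxel connectivity is held
  bit-packed, 1 bit per pair — 1/32 the bytes of a dense float32 store.
* **FCS** — functional connectivity strength: mean supra-threshold
  Fisher-z connectivity per voxel.

Plus the two map intensity normalizations (divide by in-mask mean; in-mask
z-score) usually applied before group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import BrainMask, TimeSeriesMatrix

__all__ = [
    "MetricMap",
    "NeighborScheme",
    "PackedAdjacency",
    "normalize_map",
    "amplitude",
    "alff_falff",
    "reho",
    "kendall_w",
    "fcd",
    "fcs",
    "fisher_z",
]

# spatial offsets by connectivity class
_OFFSETS_FACE = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
]
_OFFSETS_EDGE = _OFFSETS_FACE + [
    (a, b, 0) for a in (-1, 1) for b in (-1, 1)
] + [
    (a, 0, b) for a in (-1, 1) for b in (-1, 1)
] + [
    (0, a, b) for a in (-1, 1) for b in (-1, 1)
]
_OFFSETS_VERTEX = [
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


@dataclass
class NeighborScheme:
    """Spatial neighborhood: face (6), edge (18), or vertex (26) connected."""

    kind: str = "vertex"

    def __post_init__(self) -> None:
        if self.kind not in ("face", "edge", "vertex"):
            raise ValueError("kind must be 'face', 'edge' or 'vertex'")

    @property
    def offsets(self) -> list[tuple[int, int, int]]:
        return {"face": _OFFSETS_FACE, "edge": _OFFSETS_EDGE,
                "vertex": _OFFSETS_VERTEX}[self.kind]

    @property
    def k_total(self) -> int:
        """Neighborhood size including the seed voxel: 7, 19 or 27."""
        return len(self.offsets) + 1


@dataclass
class MetricMap:
    """A 3D per-voxel metric with the mask it was computed on."""

    values: np.ndarray
    mask: BrainMask
    name: str = ""
    params: dict = field(default_factory=dict)

    def in_mask(self) -> np.ndarray:
        """In-mask values in the package voxel linear order."""
        return self.values.ravel(order="F")[self.mask.linear_indices()]


def _to_map(vec: np.ndarray, mat: TimeSeriesMatrix, mask: BrainMask,
            name: str, params: dict | None = None, fill: float = 0.0) -> MetricMap:
    # F-order so ravel(order="F") is a writable view
    out = np.full(mat.source_shape, fill, dtype=np.float64, order="F")
    out.ravel(order="F")[mat.voxel_index] = vec
    return MetricMap(out, mask, name=name, params=params or {})


def normalize_map(map_: MetricMap, mask: BrainMask | None = None,
                  mode: str = "zscore") -> MetricMap:
    """Intensity-normalize a metric map within the mask.

    ``mean`` divides by the in-mask mean (output in-mask mean = 1);
    ``zscore`` subtracts the in-mask mean and divides by the in-mask sd.
    """
    mask = mask or map_.mask
    idx = mask.linear_indices()
    flat = map_.values.ravel(order="F")
    vals = flat[idx]
    out = np.zeros(map_.values.shape, dtype=np.float64, order="F")
    if mode == "mean":
        mu = vals.mean()
        if abs(mu) < 1e-300:
            raise ValueError("in-mask mean is zero; cannot mean-normalize")
        out.ravel(order="F")[idx] = vals / mu
    elif mode == "zscore":
        sd = vals.std()
        if sd == 0:
            raise ValueError("in-mask sd is zero; cannot z-score")
        out.ravel(order="F")[idx] = (vals - vals.mean()) / sd
    else:
        raise ValueError("mode must be 'mean' or 'zscore'")
    params = dict(map_.params, normalization=mode)
    return MetricMap(out, mask, name=f"{map_.name}_{mode}norm", params=params)


def amplitude(mat: TimeSeriesMatrix, mask: BrainMask) -> tuple[MetricMap, MetricMap]:
    """Temporal fluctuation amplitude of each voxel's mean-subtracted series.

    Returns (AM_mean, AM_std): the mean absolute deviation (1/N) sum |x - xbar|
    and the corrected (N-1) sample standard deviation.
    """
    if mat.n_frames < 2:
        raise ValueError("need at least 2 frames")
    centered = mat.values - mat.values.mean(axis=0)
    am_mean = np.abs(centered).mean(axis=0)
    am_std = mat.values.std(axis=0, ddof=1)
    return (
        _to_map(am_mean, mat, mask, "am_mean"),
        _to_map(am_std, mat, mask, "am_std"),
    )


def alff_falff(mat: TimeSeriesMatrix, mask: BrainMask,
               band: tuple[float, float] = (0.01, 0.08)
               ) -> tuple[MetricMap, MetricMap]:
    """ALFF and fALFF of each (unfiltered) voxel series.

    Per voxel the one-sided DFT amplitude is sqrt((1/L) |F|^2) per bin.
    ALFF averages it over the bins with low <= f <= high; fALFF is the ratio
    of the in-band amplitude sum to the sum over all bins 0 < f <= Nyquist.
    Voxels with no spectral power at all get fALFF 0.
    """
    low, high = band
    L = mat.n_frames
    freqs = np.fft.rfftfreq(L, d=mat.tr)
    nonzero = freqs > 0  # DC never counts toward either amplitude sum
    in_band = (freqs >= low - 1e-12) & (freqs <= high + 1e-12) & nonzero
    if not in_band.any():
        raise ValueError(
            f"no DFT bins inside ({low}, {high}] Hz at resolution "
            f"{freqs[1] if len(freqs) > 1 else 0:.4g} Hz (T={L}, TR={mat.tr})"
        )
    F = np.fft.rfft(mat.values, axis=0)
    amp = np.sqrt(np.abs(F) ** 2 / L)
    alff = amp[in_band].mean(axis=0)
    denom = amp[nonzero].sum(axis=0)
    falff = np.zeros_like(alff)
    ok = denom > 0
    falff[ok] = amp[in_band][:, ok].sum(axis=0) / denom[ok]
    params = {"band": (low, high)}
    return (
        _to_map(alff, mat, mask, "alff", params),
        _to_map(falff, mat, mask, "falff", params),
    )


def _neighbor_columns(mat: TimeSeriesMatrix, scheme: NeighborScheme) -> np.ndarray:
    """(V, k) matrix of neighbor column ids, -1 where missing/out of mask."""
    shape = mat.source_shape
    col_of = np.full(shape, -1, dtype=np.int64)
    coords = mat.grid_coordinates()
    col_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(mat.n_voxels)
    offsets = scheme.offsets
    out = np.full((mat.n_voxels, len(offsets)), -1, dtype=np.int64)
    for j, (dx, dy, dz) in enumerate(offsets):
        nb = coords + np.array([dx, dy, dz])
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        out[ok, j] = col_of[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
    return out


def reho(mat: TimeSeriesMatrix, mask: BrainMask,
         scheme: NeighborScheme | str = "vertex") -> MetricMap:
    """Regional homogeneity: Kendall's W of each voxel with its neighbors.

    W = (sum_i R_i^2 - n Rbar^2) / ((1/12) K^2 (n^3 - n)) where R_i is the
    sum over the K member series of their within-series temporal ranks at
    frame i.  Ranks use midranks for ties; at the mask boundary K shrinks to
    the members actually inside the mask.  A fully constant neighborhood
    yields W = 0 (with a warning).
    """
    if isinstance(scheme, str):
        scheme = NeighborScheme(scheme)
    n = mat.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    ranks = rankdata(mat.values, axis=0)  # midranks per series
    nbr = _neighbor_columns(mat, scheme)
    V = mat.n_voxels
    rank_sum = ranks.copy()              # seed contributes first
    K = np.ones(V, dtype=np.int64)
    for j in range(nbr.shape[1]):
        cols = nbr[:, j]
        ok = cols >= 0
        rank_sum[:, ok] += ranks[:, cols[ok]]
        K[ok] += 1
    r_bar = rank_sum.mean(axis=0)
    numer = (rank_sum**2).sum(axis=0) - n * r_bar**2
    denom = (K.astype(np.float64) ** 2) * (n**3 - n) / 12.0
    w = numer / denom
    constant = mat.values.std(axis=0) == 0
    if constant.any():
        # a constant seed with constant members gives numer == 0 already,
        # but flag fully constant neighborhoods explicitly
        all_const = constant.copy()
        for j in range(nbr.shape[1]):
            cols = nbr[:, j]
            ok = cols >= 0
            all_const[ok] &= constant[cols[ok]]
        if all_const.any():
            warnings.warn(f"{int(all_const.sum())} fully constant "
                          "neighborhoods; W set to 0")
            w[all_const] = 0.0
    w = np.clip(w, 0.0, 1.0)
    return _to_map(w, mat, mask, "reho",
                   {"neighbors": scheme.kind, "k_total": scheme.k_total})


def kendall_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance of K series (frames x K).

    Same statistic the ReHo map computes per neighborhood; exposed for
    direct use on an explicit set of series.  Midranks for ties, no
    tie-correction term.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series must be frames x K")
    n, K = series.shape
    if n < 2 or K < 2:
        raise ValueError("need at least 2 frames and 2 series")
    ranks = rankdata(series, axis=0)
    r_sum = ranks.sum(axis=1)
    numer = (r_sum**2).sum() - n * r_sum.mean() ** 2
    denom = K**2 * (n**3 - n) / 12.0
    return float(np.clip(numer / denom, 0.0, 1.0))


class PackedAdjacency:
    """Binarized symmetric connectivity stored 1 bit per pair.

    Row ``i`` holds the bits of ``adj[i, :]`` packed 8 per byte, so the
    whole store takes V * ceil(V/8) bytes — 1/32 of a dense float32 matrix.
    """

    def __init__(self, packed: np.ndarray, n: int):
        self.packed = packed
        self.n = n

    @classmethod
    def from_bool(cls, adj: np.ndarray) -> "PackedAdjacency":
        adj = np.asarray(adj, dtype=bool)
        return cls(np.packbits(adj, axis=1), adj.shape[0])

    def row(self, i: int) -> np.ndarray:
        return np.unpackbits(self.packed[i], count=self.n).astype(bool)

    def row_counts(self) -> np.ndarray:
        """Per-row set-bit counts without unpacking the whole matrix."""
        return np.unpackbits(self.packed, axis=1, count=self.n).sum(axis=1)

    @property
    def nbytes(self) -> int:
        return self.packed.nbytes


def _correlation_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-by-voxel Pearson correlation; zero-variance columns flagged."""
    sd = values.std(axis=0)
    degenerate = sd == 0
    centered = values - values.mean(axis=0)
    safe_sd = np.where(degenerate, 1.0, sd)
    z = centered / safe_sd
    corr = (z.T @ z) / values.shape[0]
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 0.0)
    return corr, degenerate


def _region_grow(seed: int, eligible: np.ndarray, nbr: np.ndarray) -> int:
    """Voxels reachable from the seed through spatially adjacent eligible
    voxels (seed excluded from the count)."""
    visited = np.zeros(len(eligible), dtype=bool)
    visited[seed] = True
    stack = [seed]
    count = 0
    while stack:
        v = stack.pop()
        for c in nbr[v]:
            if c >= 0 and not visited[c] and eligible[c]:
                visited[c] = True
                count += 1
                stack.append(c)
    return count


def fcd(mat: TimeSeriesMatrix, mask: BrainMask, r_threshold: float = 0.6,
        scheme: NeighborScheme | str = "vertex", packed: bool = True
        ) -> tuple[MetricMap, MetricMap, MetricMap]:
    """Local, global, and long-range functional connectivity density.

    For each seed voxel: gFCD counts the voxels whose Pearson correlation
    with the seed exceeds ``r_threshold``; lFCD is the size of the region
    grown from the seed by repeatedly adding voxels spatially adjacent (per
    ``scheme``) to a current member whose correlation *with the seed*
    exceeds the threshold; lrFCD = gFCD - lFCD.  The seed itself is never
    counted.

    ``packed=True`` (default) holds the binarized connectivity bit-packed;
    the dense-float path (``packed=False``) is a reference that must return
    identical maps.
    """
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must be in (0, 1)")
    if isinstance(scheme, str):
        scheme = NeighborScheme(scheme)
    if mat.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    corr, degenerate = _correlation_matrix(mat.values)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance voxels; "
                      "their FCD metrics are 0")
    nbr = _neighbor_columns(mat, scheme)
    V = mat.n_voxels
    lfcd = np.zeros(V)
    if packed:
        store = PackedAdjacency.from_bool(corr > r_threshold)
        gfcd = store.row_counts().astype(np.float64)
        for seed in range(V):
            eligible = store.row(seed)
            lfcd[seed] = _region_grow(seed, eligible, nbr)
    else:
        adj = corr > r_threshold
        gfcd = adj.sum(axis=1).astype(np.float64)
        for seed in range(V):
            lfcd[seed] = _region_grow(seed, adj[seed], nbr)
    lrfcd = gfcd - lfcd
    params = {"r_threshold": r_threshold, "neighbors": scheme.kind}
    return (
        _to_map(lfcd, mat, mask, "lfcd", params),
        _to_map(gfcd, mat, mask, "gfcd", params),
        _to_map(lrfcd, mat, mask, "lrfcd", params),
    )


def fisher_z(r, clip: float = 1e-7):
    """Variance-stabilizing transform z = 0.5 ln((1+r)/(1-r)).

    |r| = 1 is clipped to 1 - ``clip`` before the transform (with a
    warning) so downstream statistics stay finite; |r| > 1 is an error.
    """
    r = np.asarray(r, dtype=np.float64)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| = 1 clipped before Fisher-z transform")
    r = np.clip(r, -1.0 + clip, 1.0 - clip)
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    return float(z[0]) if scalar else z


def fcs(mat: TimeSeriesMatrix, mask: BrainMask, threshold: float = 0.25
        ) -> MetricMap:
    """Functional connectivity strength per voxel.

    Correlations with all other voxels are Fisher-z transformed; FCS is the
    sum of z-values exceeding ``threshold`` (Fisher-z scale), divided by the
    number of possible partners V - 1.
    """
    if mat.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    corr, degenerate = _correlation_matrix(mat.values)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance voxels; FCS 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = fisher_z(corr)
    np.fill_diagonal(z, 0.0)
    above = z > threshold
    out = np.where(above, z, 0.0).sum(axis=1) / (mat.n_voxels - 1)
    out[degenerate] = 0.0
    return _to_map(out, mat, mask, "fcs", {"threshold": threshold})
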