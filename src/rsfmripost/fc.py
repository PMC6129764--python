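"""ROI construction, ROI signal extraction, and ROI-wise connectivity.

ROIs live in an :class:`ROIAtlas` — a 3D volume of positive integer labels
(0 = background) plus a :class:`LabelTable` CSV companion.  Connectivity is
Pearson correlation between ROI mean time series, optionally partial (each
pair conditioned on all other ROIs' means) and Fisher-z transformed.

Conventions fixed here and relied on elsewhere: connectivity diagonals are
stored as 0 (keeps thresholding and graph code self-loop free), and matrix
rows/columns follow the label-table order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BrainMask, TimeSeriesMatrix, Volume4D, check_grid_match
from .spon import fisher_z

__all__ = [
    "LabelTable",
    "ROIAtlas",
    "ConnectivityMatrix",
    "draw_rois",
    "merge_rois",
    "extract_rois",
    "roi_timeseries",
    "roi_connectivity",
    "roi_centers",
    "extract_table",
    "fisher_z",
]


@dataclass
class LabelTable:
    """CSV-backed table of (index, label[, x, y, z, color, module]) rows."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "index" not in self.frame.columns or "label" not in self.frame.columns:
            raise ValueError("label table needs 'index' and 'label' columns")
        idx = self.frame["index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("label indices must be unique")
        if np.any(idx <= 0):
            raise ValueError("label indices must be positive integers")

    @classmethod
    def from_records(cls, records: list[tuple]) -> "LabelTable":
        cols = ["index", "label", "x", "y", "z", "color", "module"]
        width = len(records[0])
        return cls(pd.DataFrame(records, columns=cols[:width]))

    @classmethod
    def read_csv(cls, path) -> "LabelTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def indices(self) -> np.ndarray:
        return self.frame["index"].to_numpy(dtype=np.int64)

    @property
    def labels(self) -> list[str]:
        return self.frame["label"].astype(str).tolist()

    def coordinates(self) -> np.ndarray:
        return self.frame[["x", "y", "z"]].to_numpy(dtype=np.float64)


@dataclass
class ROIAtlas:
    """Positive-integer-labeled 3D volume with its label table."""

    labels: np.ndarray
    affine: np.ndarray
    table: LabelTable

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim == 4 and self.labels.shape[3] == 1:
            self.labels = self.labels[..., 0]
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if np.any(self.labels < 0):
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table.indices.tolist())
        if not present <= known:
            raise ValueError(f"labels missing from table: {sorted(present - known)}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table.indices

    def roi_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI (or voxel x voxel) connectivity, zero diagonal."""

    values: np.ndarray
    node_labels: list[str]
    kind: str = "pearson"  # pearson | partial | fisher_z

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        finite = np.isfinite(self.values)
        sym_err = np.nanmax(np.abs(self.values - self.values.T)) if finite.all() else 0
        if finite.all() and sym_err > 1e-8:
            raise ValueError(f"matrix asymmetric by {sym_err:.3g}")
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, columns=self.node_labels).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, kind: str = "pearson") -> "ConnectivityMatrix":
        df = pd.read_csv(path)
        return cls(df.to_numpy(dtype=np.float64), list(df.columns), kind=kind)

    def upper_triangle(self) -> np.ndarray:
        """Row-major i < j flattening, the package-wide edge vector order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


def _world_coords_of_grid(shape, affine) -> np.ndarray:
    """(prod(shape), 3) voxel-center world coordinates, F-order linear index."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([
        ii.ravel(order="F"), jj.ravel(order="F"), kk.ravel(order="F"),
        np.ones(ii.size),
    ])
    return (vox @ affine.T)[:, :3]


def draw_rois(
    table: LabelTable,
    reference: Volume4D,
    shape: str = "sphere",
    size: float = 6.0,
    inclusive_mask: BrainMask | None = None,
) -> ROIAtlas:
    """Draw spheres or cubes around the table's mm coordinates.

    ``size`` is the radius (sphere) or half-width (cube) in mm.  Sphere
    membership: voxel-center distance <= radius; cube: every |axis offset|
    <= half-width.  Voxels claimed by several ROIs go to the nearer center,
    ties to the lower index.  ROIs that end up empty keep their table row
    but trigger a warning.
    """
    if shape not in ("sphere", "cube"):
        raise ValueError("shape must be 'sphere' or 'cube'")
    grid_shape = reference.shape3d
    world = _world_coords_of_grid(grid_shape, reference.affine)
    centers = table.coordinates()
    ids = table.indices
    best_dist = np.full(world.shape[0], np.inf)
    labels_flat = np.zeros(world.shape[0], dtype=np.int32)
    # iterate ROIs in table order: with strict '<' on distance, earlier
    # (lower-index) ROIs win exact ties
    order = np.argsort(ids, kind="stable")
    for k in order:
        offset = world - centers[k]
        dist = np.sqrt((offset**2).sum(axis=1))
        if shape == "sphere":
            member = dist <= size + 1e-9
        else:
            member = np.all(np.abs(offset) <= size + 1e-9, axis=1)
        if size == 0:
            member = np.zeros_like(member)
            member[np.argmin(dist)] = True
        claim = member & (dist < best_dist)
        labels_flat[claim] = ids[k]
        best_dist[claim] = dist[claim]
    labels = labels_flat.reshape(grid_shape, order="F")
    if inclusive_mask is not None:
        check_grid_match(reference.affine, grid_shape,
                         inclusive_mask.affine, inclusive_mask.data.shape)
        labels = np.where(inclusive_mask.data, labels, 0)
    for roi_id in ids:
        if not np.any(labels == roi_id):
            warnings.warn(f"ROI {roi_id} contains no voxels")
    return ROIAtlas(labels, reference.affine, table)


def merge_rois(masks: list[BrainMask], names: list[str] | None = None) -> ROIAtlas:
    """Merge disjoint binary masks into one atlas labeled 1..k in input order."""
    if not masks:
        raise ValueError("no masks to merge")
    base = masks[0]
    labels = np.zeros(base.data.shape, dtype=np.int32)
    count = np.zeros(base.data.shape, dtype=np.int32)
    for k, m in enumerate(masks, start=1):
        check_grid_match(base.affine, base.data.shape, m.affine, m.data.shape)
        count += m.data.astype(np.int32)
        labels[m.data] = k
    overlap = int(np.sum(count > 1))
    if overlap:
        raise ValueError(f"masks overlap in {overlap} voxels; refusing to merge")
    names = names or [f"roi{k:03d}" for k in range(1, len(masks) + 1)]
    table = LabelTable.from_records(list(zip(range(1, len(masks) + 1), names)))
    return ROIAtlas(labels, base.affine, table)


def extract_rois(atlas: ROIAtlas, ids: list[int], as_atlas: bool = False):
    """Union mask (or relabeled sub-atlas) of the requested ROI ids."""
    known = set(atlas.roi_ids.tolist())
    missing = [i for i in ids if i not in known]
    if missing:
        raise ValueError(f"atlas has no ROI id(s) {missing}")
    if as_atlas:
        keep = np.isin(atlas.labels, ids)
        sub = np.where(keep, atlas.labels, 0)
        rows = atlas.table.frame[atlas.table.frame["index"].isin(ids)]
        return ROIAtlas(sub, atlas.affine, LabelTable(rows.reset_index(drop=True)))
    union = np.isin(atlas.labels, ids)
    return BrainMask(union, atlas.affine)


def roi_timeseries(
    mat: TimeSeriesMatrix, atlas: ROIAtlas, mask: BrainMask | None = None
) -> pd.DataFrame:
    """ROI x frame matrix of unweighted mean in-mask member series.

    ROIs with no in-mask voxels get an all-NaN row and a warning.
    """
    labels_flat = atlas.labels.ravel(order="F")[mat.voxel_index]
    rows = {}
    for roi_id, name in zip(atlas.roi_ids, atlas.table.labels):
        member = labels_flat == roi_id
        if not member.any():
            warnings.warn(f"ROI {roi_id} ({name}) has no in-mask voxels")
            rows[name] = np.full(mat.n_frames, np.nan)
        else:
            rows[name] = mat.values[:, member].mean(axis=1)
    return pd.DataFrame(rows).T


def roi_connectivity(
    roi_ts: pd.DataFrame | np.ndarray,
    partial: bool = False,
    with_fisher_z: bool = True,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix | None]:
    """Pearson (or partial) correlation between ROI series + Fisher-z twin.

    ``roi_ts`` is ROIs x frames.  Partial correlation of a pair regresses
    each member on the mean series of all *other* ROIs (plus intercept) and
    correlates the residuals; it requires more frames than ROIs.  Rows with
    zero variance (or missing data) yield NaN entries and a warning.
    """
    if isinstance(roi_ts, pd.DataFrame):
        names = [str(i) for i in roi_ts.index]
        data = roi_ts.to_numpy(dtype=np.float64)
    else:
        data = np.asarray(roi_ts, dtype=np.float64)
        names = [f"roi{k + 1:03d}" for k in range(data.shape[0])]
    n_roi, n_frames = data.shape
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    bad = ~np.isfinite(data).all(axis=1) | (np.nanstd(data, axis=1) == 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} ROI series are constant or missing; "
                      "their connectivity is NaN")
    if partial:
        if n_frames <= n_roi:
            raise ValueError("partial correlation needs more frames than ROIs")
        values = np.zeros((n_roi, n_roi))
        good = ~bad
        for i in range(n_roi):
            for j in range(i + 1, n_roi):
                if bad[i] or bad[j]:
                    values[i, j] = values[j, i] = np.nan
                    continue
                others = good.copy()
                others[[i, j]] = False
                X = np.column_stack([np.ones(n_frames), data[others].T])
                proj = X @ np.linalg.pinv(X)
                ri = data[i] - proj @ data[i]
                rj = data[j] - proj @ data[j]
                denom = np.linalg.norm(ri) * np.linalg.norm(rj)
                values[i, j] = values[j, i] = (ri @ rj) / denom if denom else np.nan
        kind = "partial"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values = np.corrcoef(data)
        values[bad, :] = np.nan
        values[:, bad] = np.nan
        kind = "pearson"
    cm = ConnectivityMatrix(values, names, kind=kind)
    if not with_fisher_z:
        return cm, None
    z = cm.values.copy()
    off = ~np.eye(n_roi, dtype=bool) & np.isfinite(z)
    z[off] = fisher_z(z[off])
    return cm, ConnectivityMatrix(z, names, kind="fisher_z")


def roi_centers(atlas: ROIAtlas) -> LabelTable:
    """Equal-weight center of mass of each ROI, in world mm."""
    world = _world_coords_of_grid(atlas.labels.shape, atlas.affine)
    labels_flat = atlas.labels.ravel(order="F")
    records = []
    for roi_id, name in zip(atlas.roi_ids, atlas.table.labels):
        member = labels_flat == roi_id
        if not member.any():
            warnings.warn(f"ROI {roi_id} is empty; coordinates missing")
            records.append((int(roi_id), name, np.nan, np.nan, np.nan))
        else:
            cx, cy, cz = world[member].mean(axis=0)
            records.append((int(roi_id), name, cx, cy, cz))
    return LabelTable.from_records(records)


def extract_table(
    inputs: list,
    selector,
    subject_names: list[str] | None = None,
) -> pd.DataFrame:
    """Arrange extracted signals as subjects (rows) x signals (columns).

    ``inputs`` are 3D maps (arrays/MetricMaps) or square 2D matrices.  The
    selector is a :class:`BrainMask` (per-voxel columns), an
    :class:`ROIAtlas` (per-ROI mean columns), or the string
    ``"upper_triangle"`` for 2D matrices (row-major i < j order).
    """
    from .spon import MetricMap

    rows, columns = [], None
    for k, item in enumerate(inputs):
        arr = item.values if isinstance(item, (MetricMap, ConnectivityMatrix)) else np.asarray(item)
        if isinstance(selector, str) and selector == "upper_triangle":
            if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
                raise ValueError(f"input {k} is not a square matrix")
            n = arr.shape[0]
            iu = np.triu_indices(n, k=1)
            row = arr[iu]
            cols = [f"e{i}_{j}" for i, j in zip(*iu)]
        elif isinstance(selector, ROIAtlas):
            if arr.shape != selector.labels.shape:
                raise ValueError(f"input {k} shape {arr.shape} does not match atlas")
            row = np.array([
                arr[selector.labels == rid].mean() if np.any(selector.labels == rid)
                else np.nan
                for rid in selector.roi_ids
            ])
            cols = selector.table.labels
        elif isinstance(selector, BrainMask):
            if arr.shape != selector.data.shape:
                raise ValueError(f"input {k} shape {arr.shape} does not match mask")
            idx = selector.linear_indices()
            row = arr.ravel(order="F")[idx]
            cols = [f"v{int(i)}" for i in idx]
        else:
            raise TypeError("selector must be BrainMask, ROIAtlas or 'upper_triangle'")
        if columns is None:
            columns = cols
        elif cols != columns:
            raise ValueError(f"input {k} yields inconsistent columns")
        rows.append(row)
    index = subject_names or [f"subject{k + 1:03d}" for k in range(len(rows))]
    return pd.DataFrame(np.asarray(rows), index=index, columns=columns)
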