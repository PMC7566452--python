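"""qsm_lite: cylinder-model tree volume, trunk/branch split and surface area.

A deliberately simple quantitative-structure-model estimator with the same
input/output contract as the established TreeQSM family: from a single
tree's point cloud it produces a list of connected cylinders, total / trunk
/ branch volume, lateral surface area, and (via an ensemble over structure
parameters) a mean and standard deviation of total volume.

Algorithm
---------
1.  Build a symmetric k-nearest-neighbour graph over the points and check
    connectivity.
2.  Compute graph-geodesic distance from a base source set (all points
    within a small height band above the lowest point) with Dijkstra.
3.  Bin points into geodesic shells of width ``patch_size``; split each
    shell into connected clusters (segments); parent each segment to the
    previous-shell cluster it is most connected to.
4.  The trunk is the root-to-tip path following maximum cumulative point
    count; everything else is branch.
5.  Fit one cylinder per segment: axis from the segment chain, centre from
    a least-squares circle in the plane normal to the axis, radius from the
    geometric fit (fallback: mean point-to-axis distance on degenerate
    arcs).  Adjacent segments of a limb share an axial boundary at the
    midpoint of their overlapping extents so chain cylinders tile the stem.

Volume is sum(pi r^2 L); surface is lateral only, sum(2 pi r L) — no end
caps, which would double-count at joints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .exceptions import DisconnectedCloudError, EnsembleError, InsufficientPointsError
from .io import TreeCloud
from .stem import FitDegenerateError, fit_circle

log = logging.getLogger("tlstree")

__all__ = [
    "Cylinder",
    "QSMModel",
    "QSMEnsemble",
    "Skeleton",
    "build_skeleton",
    "fit_cylinders",
    "qsm_single",
    "qsm_ensemble",
]


@dataclass(frozen=True)
class Cylinder:
    start: np.ndarray  # (3,)
    axis: np.ndarray  # unit (3,)
    length: float
    radius: float
    parent_id: int | None
    is_trunk: bool

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length

    @property
    def lateral_area(self) -> float:
        return 2.0 * math.pi * self.radius * self.length


@dataclass
class QSMModel:
    cylinders: list[Cylinder]
    total_volume_m3: float = 0.0
    trunk_volume_m3: float = 0.0
    branch_volume_m3: float = 0.0
    surface_area_m2: float = 0.0

    @classmethod
    def from_cylinders(cls, cylinders: list[Cylinder]) -> "QSMModel":
        trunk = sum(c.volume for c in cylinders if c.is_trunk)
        branch = sum(c.volume for c in cylinders if not c.is_trunk)
        return cls(
            cylinders=cylinders,
            total_volume_m3=trunk + branch,
            trunk_volume_m3=trunk,
            branch_volume_m3=branch,
            surface_area_m2=sum(c.lateral_area for c in cylinders),
        )


@dataclass
class QSMEnsemble:
    runs: list[QSMModel]
    volume_mean_m3: float
    volume_sd_m3: float
    n_failed: int = 0

    @classmethod
    def from_runs(cls, runs: list[QSMModel], n_failed: int = 0) -> "QSMEnsemble":
        vols = np.array([r.total_volume_m3 for r in runs])
        sd = float(vols.std(ddof=1)) if len(vols) > 1 else 0.0
        return cls(runs=runs, volume_mean_m3=float(vols.mean()), volume_sd_m3=sd,
                   n_failed=n_failed)


@dataclass
class _Segment:
    idx: np.ndarray  # point indices
    shell: int
    centroid: np.ndarray
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    cum_points: int = 0
    on_trunk: bool = False
    continuation: int | None = None  # child that continues this limb


@dataclass
class Skeleton:
    segments: list[_Segment]
    root: int
    patch_size: float
    points: np.ndarray


def _knn_graph(points: np.ndarray, k: int):
    tree = cKDTree(points)
    dist, idx = tree.query(points, k=k + 1, workers=-1)
    n = len(points)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    g = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    g = g.maximum(g.T)  # symmetrise
    median_nn = float(np.median(dist[:, 1]))
    return g, median_nn


def build_skeleton(cloud: TreeCloud, patch_size_m: float, k: int = 10) -> Skeleton:
    """Geodesic-shell segment graph of a connected tree cloud."""
    points = cloud.points
    if len(points) < 50:
        raise InsufficientPointsError(f"{len(points)} points is too few for a skeleton")
    g, median_nn = _knn_graph(points, k)
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        raise DisconnectedCloudError(n_comp, 1.0 - counts.max() / len(points))

    z = points[:, 2]
    base_band = max(2.5 * median_nn, 0.05)
    sources = np.flatnonzero(z <= z.min() + base_band)
    d = dijkstra(g, directed=False, indices=sources, min_only=True)

    shell_of = np.floor(d / patch_size_m).astype(int)
    segments: list[_Segment] = []
    seg_of_point = np.full(len(points), -1, dtype=int)
    for s in range(int(shell_of.max()) + 1):
        pts_in = np.flatnonzero(shell_of == s)
        if len(pts_in) == 0:
            continue
        sub = g[pts_in][:, pts_in]
        nc, lab = connected_components(sub, directed=False)
        for c in range(nc):
            idx = pts_in[lab == c]
            seg_id = len(segments)
            segments.append(
                _Segment(idx=idx, shell=s, centroid=points[idx].mean(axis=0))
            )
            seg_of_point[idx] = seg_id

    # parents: the previous-shell segment with the most graph edges into us
    indptr, indices = g.indptr, g.indices
    root = int(seg_of_point[int(np.argmin(d))])
    for sid, seg in enumerate(segments):
        if sid == root:
            continue
        nbr = np.unique(indices[np.concatenate([np.arange(indptr[i], indptr[i + 1]) for i in seg.idx])])
        nbr_segs = seg_of_point[nbr]
        prev = nbr_segs[[segments[t].shell == seg.shell - 1 for t in nbr_segs]]
        if len(prev):
            vals, cnt = np.unique(prev, return_counts=True)
            seg.parent = int(vals[np.argmax(cnt)])
        else:
            earlier = [t for t in range(len(segments)) if segments[t].shell < seg.shell]
            if earlier:
                cents = np.array([segments[t].centroid for t in earlier])
                seg.parent = int(earlier[int(np.argmin(np.linalg.norm(cents - seg.centroid, axis=1)))])
            else:
                seg.parent = root  # stray base cluster
    for sid, seg in enumerate(segments):
        if seg.parent is not None:
            segments[seg.parent].children.append(sid)

    # cumulative point counts, deepest shells first
    order = sorted(range(len(segments)), key=lambda t: segments[t].shell, reverse=True)
    for sid in order:
        seg = segments[sid]
        seg.cum_points = len(seg.idx) + sum(segments[c].cum_points for c in seg.children)

    # continuation child (max cumulative count; ties: more own points, lower id)
    for seg in segments:
        if seg.children:
            seg.continuation = min(
                seg.children,
                key=lambda c: (-segments[c].cum_points, -len(segments[c].idx), c),
            )

    # trunk = path of continuations from the root
    sid = root
    while sid is not None:
        segments[sid].on_trunk = True
        sid = segments[sid].continuation

    return Skeleton(segments=segments, root=root, patch_size=patch_size_m, points=points)


def _orthobasis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def fit_cylinders(skeleton: Skeleton, cloud: TreeCloud | None = None) -> QSMModel:
    """One least-squares cylinder per skeleton segment.

    Segments with fewer than 10 points inherit the parent radius (logged);
    a whole-tree failure is never raised from a single bad segment.
    """
    points = skeleton.points
    segs = skeleton.segments
    radii: dict[int, float] = {}
    cylinders: list[Cylinder] = []
    # segments are created shell-by-shell, so a parent precedes its children
    # except for stray base clusters re-parented to the root; the branch-root
    # extension below simply skips a not-yet-fitted parent
    cyl_by_seg: list[Cylinder | None] = []

    for sid, seg in enumerate(segs):
        # axis from the segment chain
        if seg.parent is not None:
            axis = seg.centroid - segs[seg.parent].centroid
        elif seg.continuation is not None:
            axis = segs[seg.continuation].centroid - seg.centroid
        else:
            p = points[seg.idx] - seg.centroid
            _, _, vt = np.linalg.svd(p, full_matrices=False)
            axis = vt[0]
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            axis = axis / norm
        if axis[2] < 0 and seg.parent is None:
            axis = -axis
        u, v = _orthobasis(axis)

        own = points[seg.idx]
        rel = own - seg.centroid
        t = rel @ axis
        w = np.column_stack([rel @ u, rel @ v])
        anchor = seg.centroid.copy()

        radius = None
        if len(own) >= 10:
            extent = float(np.ptp(w, axis=0).max())
            try:
                fit = fit_circle(w, min_points=5)
                # reject wild fits from short arcs
                if fit.radius <= 2.5 * max(extent, 1e-6) and \
                        math.hypot(*fit.center) <= 2.0 * max(extent, 1e-6):
                    radius = fit.radius
                    anchor = anchor + fit.center[0] * u + fit.center[1] * v
            except (FitDegenerateError, InsufficientPointsError):
                pass
            if radius is None:
                radius = float(np.mean(np.hypot(w[:, 0], w[:, 1])))
        else:
            if seg.parent is not None and seg.parent in radii:
                radius = radii[seg.parent]
                log.debug("segment %d: %d points, inheriting parent radius", sid, len(own))
            else:
                radius = float(np.mean(np.hypot(w[:, 0], w[:, 1]))) if len(own) else 0.0
        if radius <= 0:
            radius = radii.get(seg.parent, 1e-3) if seg.parent is not None else 1e-3
        radii[sid] = radius

        # axial extent: share boundaries with the limb's neighbours at midpoints
        lo, hi = float(t.min()), float(t.max())
        if seg.parent is not None and segs[seg.parent].continuation == sid:
            tp = (points[segs[seg.parent].idx] - anchor) @ axis
            lo = 0.5 * (lo + float(tp.max()))
        elif seg.parent is not None and seg.parent < len(cyl_by_seg) \
                and cyl_by_seg[seg.parent] is not None:
            # branch root: its first shell merges into the parent limb, so
            # extend back to the parent cylinder's surface
            par = cyl_by_seg[seg.parent]
            p0 = anchor + lo * axis
            rel0 = p0 - par.start
            gap = float(np.linalg.norm(rel0 - (rel0 @ par.axis) * par.axis)) - par.radius
            if 0.0 < gap < 2.0 * skeleton.patch_size:
                lo -= gap
        if seg.continuation is not None:
            tc = (points[segs[seg.continuation].idx] - anchor) @ axis
            hi = 0.5 * (hi + float(tc.min()))
        length = hi - lo
        if length <= 0:
            length = max(float(t.max() - t.min()), 1e-6)
            lo = float(t.min())

        cyl = Cylinder(
            start=anchor + lo * axis,
            axis=axis,
            length=length,
            radius=radius,
            parent_id=seg.parent,
            is_trunk=seg.on_trunk,
        )
        cylinders.append(cyl)
        cyl_by_seg.append(cyl)
    return QSMModel.from_cylinders(cylinders)


def qsm_single(cloud: TreeCloud, patch_size_m: float = 0.5, k: int = 10) -> QSMModel:
    """Convenience: skeleton + cylinder fit in one call."""
    return fit_cylinders(build_skeleton(cloud, patch_size_m, k=k))


def qsm_ensemble(
    cloud: TreeCloud,
    patch_sizes: tuple[float, ...] = (0.3, 0.5, 0.8),
    runs_per_size: int = 3,
    seed: int = 0,
    subsample: float = 0.95,
) -> QSMEnsemble:
    """Ensemble of cylinder models over patch sizes and seeded point jitter.

    Each run re-draws a ``subsample`` fraction of the points and a k-NN
    neighbourhood size, so the run-to-run spread captures the structural
    sensitivity of the fit; the ensemble SD is the per-tree volume
    uncertainty used downstream.  Partial failures are logged and excluded;
    an ensemble with zero successful runs raises.
    """
    n_runs = len(patch_sizes) * runs_per_size
    if n_runs < 2:
        raise EnsembleError("need at least 2 runs")
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x71736D])
    child_seeds = ss.spawn(n_runs)
    runs: list[QSMModel] = []
    failures = 0
    i = 0
    for patch in patch_sizes:
        for _ in range(runs_per_size):
            rng = np.random.default_rng(child_seeds[i])
            i += 1
            m = max(int(round(subsample * len(cloud))), 50)
            keep = rng.choice(len(cloud), size=m, replace=False)
            sub = TreeCloud(cloud.tree_id, cloud.points[np.sort(keep)], cloud.source)
            k = int(rng.choice([8, 10, 12]))
            try:
                runs.append(qsm_single(sub, patch_size_m=patch, k=k))
            except Exception as exc:
                failures += 1
                log.warning("%s: QSM run failed (patch=%.2f, k=%d): %s",
                            cloud.tree_id, patch, k, exc)
    if not runs:
        raise EnsembleError(f"all {n_runs} QSM runs failed for {cloud.tree_id}")
    return QSMEnsemble.from_runs(runs, n_failed=failures)
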