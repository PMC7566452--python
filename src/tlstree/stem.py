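"""Stem geometry: H, DBH, fDBH and DTB from a single tree's point cloud.

Definitions follow standard TLS forestry practice:

* a 20 cm slab at 1.2-1.4 m above the *lowest point* of the cloud is
  collapsed onto a plane; a geometric least-squares circle gives DBH and its
  fit RMSE;
* the same slab's concave hull (alpha shape, circumradius < 1/alpha) gives
  the non-circular cross-section area, and fDBH is the diameter of the
  circle of equivalent area, ``fDBH = 2*sqrt(area/pi)``;
* DTB (diameter at top of buttress) is a circle fit to the 4.0-4.5 m slab,
  above basal flare;
* H is simply ``z_max - z_min``.

The circle fit uses a Taubin-style algebraic fit to initialise a geometric
(orthogonal-distance) least-squares refinement, so the reported RMSE is the
root mean square of the radial residuals ``d_i - r``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.optimize import least_squares
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .exceptions import (
    DegenerateAlphaError,
    EmptyInputError,
    FitDegenerateError,
    InsufficientPointsError,
)
from .io import PipelineConfig, TreeCloud

log = logging.getLogger("tlstree")

MIN_SECTION_POINTS = 20

__all__ = [
    "CrossSection",
    "CircleFit",
    "AlphaShapeFit",
    "StemMetrics",
    "extract_section",
    "fit_circle",
    "fit_alpha_shape",
    "measure_tree",
]


@dataclass(frozen=True)
class CrossSection:
    """A half-open slab [z_lo, z_hi) above the lowest point, collapsed to 2D."""

    z_lo: float
    z_hi: float
    points2d: np.ndarray  # (N, 2)


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rmse: float
    n_points: int

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class AlphaShapeFit:
    boundary: np.ndarray  # (M, 2) exterior vertices of the kept component
    area: float
    fdbh: float
    rmse: float


@dataclass
class StemMetrics:
    """Per-tree stem dimensions with per-quantity fit RMSEs.

    A quantity whose extraction failed is ``None`` and the reason is recorded
    in ``notes``; the other quantities are still populated.
    """

    tree_id: str
    height_m: float
    dbh_m: float | None = None
    dbh_rmse_m: float | None = None
    fdbh_m: float | None = None
    fdbh_rmse_m: float | None = None
    dtb_m: float | None = None
    dtb_rmse_m: float | None = None
    notes: dict = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.notes is None:
            self.notes = {}

    def as_dict(self) -> dict:
        return dict(
            tree_id=self.tree_id, H_m=self.height_m,
            DBH_m=self.dbh_m, DBH_rmse_m=self.dbh_rmse_m,
            fDBH_m=self.fdbh_m, fDBH_rmse_m=self.fdbh_rmse_m,
            DTB_m=self.dtb_m, DTB_rmse_m=self.dtb_rmse_m,
        )


def extract_section(cloud: TreeCloud, z_lo: float, z_hi: float) -> CrossSection:
    """Slab [z_lo, z_hi) measured from the cloud's lowest point, z dropped."""
    if len(cloud) == 0:
        raise EmptyInputError("empty cloud")
    z = cloud.points[:, 2] - cloud.z_min
    mask = (z >= z_lo) & (z < z_hi)
    n = int(mask.sum())
    if n < MIN_SECTION_POINTS:
        raise InsufficientPointsError(
            f"{cloud.tree_id}: {n} points in slab [{z_lo}, {z_hi}) "
            f"(need >= {MIN_SECTION_POINTS})"
        )
    return CrossSection(z_lo=z_lo, z_hi=z_hi, points2d=cloud.points[mask, :2].copy())


def _taubin(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Taubin algebraic circle fit (SVD form); returns (cx, cy, r)."""
    xm, ym = x.mean(), y.mean()
    X, Y = x - xm, y - ym
    Z = X * X + Y * Y
    zmean = Z.mean()
    if zmean <= 0:
        raise FitDegenerateError("all points coincide")
    Z0 = (Z - zmean) / (2.0 * math.sqrt(zmean))
    A = np.column_stack([Z0, X, Y])
    _, _, vt = np.linalg.svd(A, full_matrices=False)
    a = vt[-1]
    a0 = a[0] / (2.0 * math.sqrt(zmean))
    a = np.array([a0, a[1], a[2], -zmean * a0])
    if abs(a[0]) < 1e-14:
        raise FitDegenerateError("points are collinear")
    cx = -a[1] / (2 * a[0])
    cy = -a[2] / (2 * a[0])
    r2 = cx * cx + cy * cy - a[3] / a[0]
    if r2 <= 0:
        raise FitDegenerateError("algebraic fit produced non-positive radius")
    return cx + xm, cy + ym, math.sqrt(r2)


def fit_circle(section: CrossSection | np.ndarray, min_points: int = MIN_SECTION_POINTS) -> CircleFit:
    """Geometric least-squares circle: minimises sum((d_i - r)^2).

    Taubin's algebraic fit initialises a Levenberg-Marquardt refinement of
    (cx, cy, r); the RMSE is sqrt(mean((d_i - r)^2)) of the final fit.
    """
    pts = section.points2d if isinstance(section, CrossSection) else np.asarray(section, float)
    if len(pts) < min_points:
        raise InsufficientPointsError(f"{len(pts)} points (need >= {min_points})")
    x, y = pts[:, 0], pts[:, 1]
    # collinearity check: perpendicular spread of the best-fit line
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[-1] < 1e-12 * max(sv[0], 1.0):
        raise FitDegenerateError("points are collinear")
    cx, cy, r = _taubin(x, y)

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, x0=[cx, cy, r], method="lm")
    cx, cy, r = sol.x
    if r <= 0:
        raise FitDegenerateError("non-positive fitted radius")
    rmse = float(np.sqrt(np.mean(resid(sol.x) ** 2)))
    return CircleFit(center=(float(cx), float(cy)), radius=float(r), rmse=rmse, n_points=len(pts))


def _alpha_complex(pts: np.ndarray, alpha: float) -> tuple[Delaunay, np.ndarray]:
    """Delaunay triangulation and mask of simplices with circumradius < 1/alpha."""
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise FitDegenerateError(f"triangulation failed: {exc}") from None
    p = pts[tri.simplices]  # (m, 3, 2)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    s = (a + b + c) / 2.0
    area2 = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    area = np.sqrt(area2)
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
    return tri, circum_r < (1.0 / alpha)


def fit_alpha_shape(
    section: CrossSection | np.ndarray,
    alpha: float = 4.0,
    min_area_fraction: float = 0.2,
    rmse_band_m: float = 0.05,
) -> AlphaShapeFit:
    """Concave hull (alpha shape) of a cross-section and the derived fDBH.

    Follows the alpha-shape convention of the Python ``alphashape`` toolbox
    v1.0.1: keep Delaunay triangles with circumradius < 1/alpha (alpha in
    m^-1, larger = tighter), take the region enclosed by the complex
    boundary.  A TLS bark section is a hollow ring of points, so interior
    holes of the complex are filled; with several disjoint components the
    largest by (filled) area is kept — fragments below ``min_area_fraction``
    of the convex-hull area raise a degenerate-alpha error instead of being
    silently patched.

    The fit RMSE is the root-mean-square distance to the boundary polyline
    over input points within ``rmse_band_m`` of it (a documented convention;
    see the methods note).
    """
    pts = section.points2d if isinstance(section, CrossSection) else np.asarray(section, float)
    if alpha <= 0:
        raise DegenerateAlphaError("alpha must be > 0")
    if len(pts) < MIN_SECTION_POINTS:
        raise InsufficientPointsError(f"{len(pts)} points (need >= {MIN_SECTION_POINTS})")
    pts = np.unique(pts, axis=0)
    tri, keep = _alpha_complex(pts, alpha)
    if not keep.any():
        raise DegenerateAlphaError(f"no triangle has circumradius < 1/alpha = {1/alpha:.3g} m")
    polys = shapely.polygons(pts[tri.simplices[keep]])
    merged = unary_union(polys)
    parts = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    filled = [Polygon(p.exterior) for p in parts if p.geom_type == "Polygon"]
    if not filled:
        raise DegenerateAlphaError("alpha complex has no areal component")
    best = max(filled, key=lambda p: p.area)
    hull_area = float(shapely.convex_hull(shapely.multipoints(pts)).area)
    if hull_area > 0 and best.area < min_area_fraction * hull_area:
        raise DegenerateAlphaError(
            f"largest component covers {best.area / hull_area:.1%} of the convex hull "
            f"(alpha = {alpha} too tight for this section)"
        )
    area = float(best.area)
    fdbh = 2.0 * math.sqrt(area / math.pi)
    ring = best.exterior
    dists = shapely.distance(shapely.points(pts), ring)
    near = dists <= rmse_band_m
    rmse = float(np.sqrt(np.mean(dists[near] ** 2))) if near.any() else float(np.sqrt(np.mean(dists**2)))
    return AlphaShapeFit(
        boundary=np.asarray(ring.coords), area=area, fdbh=fdbh, rmse=rmse
    )


def measure_tree(cloud: TreeCloud, cfg: PipelineConfig | None = None) -> StemMetrics:
    """H, DBH, fDBH, DTB (each with its fit RMSE) for one tree.

    A quantity whose slab or fit fails is reported missing (with the reason
    in ``metrics.notes``); the remaining quantities are still returned.
    """
    cfg = cfg or PipelineConfig()
    if len(cloud) == 0:
        raise EmptyInputError("empty cloud")
    m = StemMetrics(tree_id=cloud.tree_id, height_m=cloud.z_max - cloud.z_min)

    section = None
    try:
        section = extract_section(cloud, *cfg.slice_dbh)
        fit = fit_circle(section)
        m.dbh_m, m.dbh_rmse_m = fit.diameter, fit.rmse
    except Exception as exc:  # per-quantity isolation is the contract
        m.notes["DBH"] = str(exc)
        log.warning("%s: DBH failed: %s", cloud.tree_id, exc)

    try:
        if section is None:
            section = extract_section(cloud, *cfg.slice_dbh)
        ashape = fit_alpha_shape(section, alpha=cfg.alpha)
        m.fdbh_m, m.fdbh_rmse_m = ashape.fdbh, ashape.rmse
    except Exception as exc:
        m.notes["fDBH"] = str(exc)
        log.warning("%s: fDBH failed: %s", cloud.tree_id, exc)

    try:
        dtb_section = extract_section(cloud, *cfg.slice_dtb)
        fit = fit_circle(dtb_section)
        m.dtb_m, m.dtb_rmse_m = fit.diameter, fit.rmse
    except Exception as exc:
        m.notes["DTB"] = str(exc)
        log.warning("%s: DTB failed: %s", cloud.tree_id, exc)

    return m
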