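"""Point-cloud and tabular I/O plus pipeline configuration.

Formats:

* ASCII XYZ — one ``x y z [label]`` row per line, meters, float64 round-trip.
* PLY — binary little-endian, vertex properties ``x y z`` (float64) and an
  optional ``uint32 tree`` label column.  ASCII PLY is accepted on read.

The per-tree container is :class:`TreeCloud`; labelled plot clouds are split
into per-tree clouds by :func:`split_plot`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError, EmptyInputError, ParseError

log = logging.getLogger("tlstree")

__all__ = [
    "TreeCloud",
    "PipelineConfig",
    "read_cloud",
    "write_cloud",
    "split_plot",
]


@dataclass
class TreeCloud:
    """One tree's 3D points (meters), with an identifier and provenance."""

    tree_id: str
    points: np.ndarray  # (N, 3) float64
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParseError("points must be an (N, 3) array")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def z_min(self) -> float:
        return float(self.points[:, 2].min())

    @property
    def z_max(self) -> float:
        return float(self.points[:, 2].max())


@dataclass
class PipelineConfig:
    """Tunable parameters of the measurement pipeline.

    Slabs are (z_lo, z_hi) in meters above the lowest point of each cloud;
    ``alpha`` follows the circumradius < 1/alpha convention (m^-1), so larger
    alpha means a tighter concave hull.
    """

    slice_dbh: tuple[float, float] = (1.2, 1.4)
    slice_dtb: tuple[float, float] = (4.0, 4.5)
    alpha: float = 4.0
    wood_density_kg_m3: float = 380.0
    qsm_patch_sizes: tuple[float, ...] = (0.3, 0.5, 0.8)
    qsm_runs_per_size: int = 3
    monte_carlo_n: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("slice_dbh", "slice_dtb"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name}: need z_lo < z_hi, got ({lo}, {hi})")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if self.wood_density_kg_m3 <= 0:
            raise ConfigError("wood_density_kg_m3 must be > 0")
        if self.monte_carlo_n < 100:
            raise ConfigError("monte_carlo_n must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("slice_dbh", "slice_dtb", "qsm_patch_sizes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers


def _check_finite(pts: np.ndarray, lines: np.ndarray | None = None) -> None:
    bad = ~np.isfinite(pts).all(axis=1)
    if bad.any():
        i = int(np.argmax(bad))
        line = int(lines[i]) if lines is not None else i + 1
        raise ParseError("non-finite coordinate", line=line)


def _read_xyz(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    rows, labels = [], []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if ncol is None:
                ncol = len(parts)
                if ncol not in (3, 4):
                    raise ParseError(f"expected 3 or 4 columns, got {ncol}", line=lineno)
            if len(parts) != ncol:
                raise ParseError(f"expected {ncol} columns, got {len(parts)}", line=lineno)
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError("unparseable coordinate", line=lineno) from None
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                raise ParseError("non-finite coordinate", line=lineno)
            rows.append((x, y, z))
            if ncol == 4:
                try:
                    labels.append(int(parts[3]))
                except ValueError:
                    raise ParseError("unparseable label", line=lineno) from None
    if not rows:
        raise EmptyInputError(f"{path}: no points")
    pts = np.asarray(rows, dtype=np.float64)
    lab = np.asarray(labels, dtype=np.uint32) if labels else None
    return pts, lab


_PLY_DTYPES = {
    "double": "<f8", "float64": "<f8", "float": "<f4", "float32": "<f4",
    "uint": "<u4", "uint32": "<u4", "int": "<i4", "int32": "<i4",
    "uchar": "u1", "uint8": "u1",
}


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError("not a PLY file", line=1)
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise ParseError("unexpected end of PLY header", line=lineno)
            tok = line.decode("ascii", "replace").split()
            if not tok:
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                if tok[1] != "vertex":
                    raise ParseError(f"unsupported PLY element {tok[1]!r}", line=lineno)
                n_vertex = int(tok[2])
            elif tok[0] == "property":
                if tok[1] not in _PLY_DTYPES:
                    raise ParseError(f"unsupported PLY property type {tok[1]!r}", line=lineno)
                props.append((tok[2], _PLY_DTYPES[tok[1]]))
            elif tok[0] == "end_header":
                break
        if fmt not in ("binary_little_endian", "ascii") or n_vertex is None:
            raise ParseError(f"unsupported PLY format {fmt!r}")
        names = [p[0] for p in props]
        for need in ("x", "y", "z"):
            if need not in names:
                raise ParseError(f"PLY missing vertex property {need!r}")
        dtype = np.dtype(props)
        if fmt == "binary_little_endian":
            data = np.fromfile(fh, dtype=dtype, count=n_vertex)
        else:
            data = np.loadtxt(fh, dtype=np.float64, max_rows=n_vertex, ndmin=2)
            data = np.core.records.fromarrays(data.T, dtype=np.dtype(
                [(n, "<f8") if d.startswith("<f") else (n, "<u4") for n, d in props]))
        if len(data) != n_vertex:
            raise ParseError(f"expected {n_vertex} vertices, read {len(data)}")
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    lab = None
    for cand in ("tree", "label", "tree_id"):
        if cand in names:
            lab = np.asarray(data[cand], dtype=np.uint32)
            break
    return pts, lab


def read_cloud(path: str | Path, fmt: str | None = None, tree_id: str | None = None) -> TreeCloud:
    """Read a point cloud (``xyz`` or ``ply``), inferring the format from the suffix.

    Coordinates are returned unchanged (no recentring).  A label column, if
    present, is attached as ``cloud.labels``.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz" or fmt == "txt":
        pts, lab = _read_xyz(path)
    elif fmt == "ply":
        pts, lab = _read_ply(path)
    else:
        raise ParseError(f"unknown point-cloud format {fmt!r}")
    if len(pts) == 0:
        raise EmptyInputError(f"{path}: empty cloud")
    _check_finite(pts)
    cloud = TreeCloud(tree_id=tree_id or path.stem, points=pts, source=str(path))
    cloud.labels = lab  # type: ignore[attr-defined]
    log.info(
        "read %s: %d points, bbox x[%.2f, %.2f] y[%.2f, %.2f] z[%.2f, %.2f]",
        path, len(pts), *pts[:, 0].take([pts[:, 0].argmin(), pts[:, 0].argmax()]),
        *pts[:, 1].take([pts[:, 1].argmin(), pts[:, 1].argmax()]),
        *pts[:, 2].take([pts[:, 2].argmin(), pts[:, 2].argmax()]),
    )
    return cloud


def write_cloud(
    path: str | Path,
    points: np.ndarray,
    labels: np.ndarray | None = None,
    fmt: str | None = None,
) -> None:
    """Write points (and optional uint32 labels) as XYZ text or binary PLY."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    points = np.asarray(points, dtype=np.float64)
    if fmt in ("xyz", "txt"):
        with open(path, "w") as fh:
            if labels is None:
                for x, y, z in points.tolist():
                    fh.write(f"{x!r} {y!r} {z!r}\n")
            else:
                for (x, y, z), l in zip(points.tolist(), labels):
                    fh.write(f"{x!r} {y!r} {z!r} {int(l)}\n")
    elif fmt == "ply":
        props = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
        if labels is not None:
            props.append(("tree", "<u4"))
        rec = np.empty(len(points), dtype=np.dtype(props))
        rec["x"], rec["y"], rec["z"] = points[:, 0], points[:, 1], points[:, 2]
        if labels is not None:
            rec["tree"] = np.asarray(labels, dtype=np.uint32)
        header = ["ply", "format binary_little_endian 1.0",
                  f"element vertex {len(points)}",
                  "property double x", "property double y", "property double z"]
        if labels is not None:
            header.append("property uint32 tree")
        header.append("end_header")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            rec.tofile(fh)
    else:
        raise ParseError(f"unknown point-cloud format {fmt!r}")


def split_plot(points: np.ndarray, labels: np.ndarray, manifest=None) -> list[TreeCloud]:
    """Split a labelled plot cloud into per-tree clouds.

    Conserves the total point count exactly; tree ids come from the manifest
    when given (matched on its ``tree_id`` column order = label value),
    otherwise from the label values themselves.
    """
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    if len(points) != len(labels):
        raise ParseError("points and labels differ in length")
    if len(points) == 0:
        raise EmptyInputError("empty plot cloud")
    uniq = np.unique(labels)
    id_of = {}
    if manifest is not None:
        ids = list(manifest["tree_id"])
        for lab in uniq:
            if int(lab) >= len(ids):
                raise ConfigError(f"label {int(lab)} not in manifest")
            id_of[int(lab)] = str(ids[int(lab)])
    clouds = []
    for lab in uniq:
        mask = labels == lab
        clouds.append(
            TreeCloud(
                tree_id=id_of.get(int(lab), str(int(lab))),
                points=points[mask],
                source="split_plot",
            )
        )
    assert sum(len(c) for c in clouds) == len(points)
    return clouds
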