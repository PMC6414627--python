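"""Readers and writers for the on-disk formats used by the pipeline.

Formats
-------
``.asc``
    Plain-text polyline export: one ``x y z`` coordinate triple per line
    (whitespace- or comma-separated), in millimetres, point order meaningful.
    Blank lines and lines starting with ``#`` are skipped.  Whether the
    original digitization software wrote headers or other delimiters is not
    documented anywhere; this permissive dialect is a deliberate guess.
``.obj``
    Wavefront OBJ; only ``v x y z`` vertex records are consumed.  The pipeline
    needs mesh vertices (for caliper length), never topology, so faces,
    normals and texture coordinates are skipped.
semilandmark CSV
    One row per specimen: ``specimen_id, group, sex, curve_length_mm,
    x01, y01, z01, ..., x{k}, y{k}, z{k}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContentError, ParseError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class Polyline3D:
    """Ordered dense 3D digitization of one anterior-crest curve (mm)."""

    points: np.ndarray  # (n, 3) float64
    source_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ContentError(
                f"polyline must be an (n, 3) array, got shape {self.points.shape}"
            )
        if len(self.points) < 2:
            raise ContentError(
                f"polyline needs at least 2 points, got {len(self.points)}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ContentError("polyline contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_duplicate_consecutive(self) -> int:
        """Count of consecutive duplicate points (permitted on read, flagged)."""
        return int(np.sum(np.all(np.diff(self.points, axis=0) == 0.0, axis=1)))


@dataclass
class PointCloud:
    """Unordered mesh vertices (mm), used for caliper length measurement."""

    vertices: np.ndarray  # (n, 3) float64
    source_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ContentError(
                f"point cloud must be an (n, 3) array, got shape {self.vertices.shape}"
            )
        if len(self.vertices) < 2:
            raise ContentError("point cloud needs at least 2 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ContentError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class SemilandmarkTable:
    """Per-specimen semilandmark configurations plus grouping metadata.

    ``coords`` has shape (n_specimens, k, 3); rows align with the metadata
    sequences.  ``k`` is fixed per table (20 in the standard configuration).
    """

    specimen_ids: list[str]
    groups: list[str]
    sexes: list[str]
    curve_lengths_mm: np.ndarray  # (n,)
    coords: np.ndarray  # (n, k, 3)
    group_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.curve_lengths_mm = np.asarray(self.curve_lengths_mm, dtype=float)
        n = len(self.specimen_ids)
        if not (len(self.groups) == len(self.sexes) == len(self.curve_lengths_mm)
                == self.coords.shape[0] == n):
            raise SchemaError("metadata and coordinate row counts disagree")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SchemaError(
                f"coords must be (n, k, 3), got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError("semilandmark table contains non-finite coordinates")
        if not self.group_levels:
            # preserve first-appearance (chronological) order, not sorted order
            self.group_levels = list(dict.fromkeys(self.groups))

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def read_asc_polyline(path: str | Path) -> Polyline3D:
    """Read a plain-text ``.asc`` polyline (one x y z triple per line).

    Point order is preserved exactly.  Raises :class:`ParseError` naming the
    line number on the first malformed line, :class:`ContentError` when fewer
    than two points remain.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                xyz = (float(parts[0]), float(parts[1]), float(parts[2]))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if not all(np.isfinite(xyz)):
                raise ParseError(f"{path.name}:{lineno}: non-finite coordinate")
            rows.append(xyz)
    if len(rows) < 2:
        raise ContentError(f"{path.name}: polyline has {len(rows)} points, need >= 2")
    poly = Polyline3D(np.array(rows, dtype=float), source_id=path.stem)
    if poly.n_duplicate_consecutive:
        logger.warning(
            "%s: %d consecutive duplicate points", path.name, poly.n_duplicate_consecutive
        )
    logger.debug("%s: read %d points", path.name, len(poly))
    return poly


def write_asc_polyline(polyline: Polyline3D, path: str | Path) -> None:
    """Write a polyline as plain-text x y z lines at full float precision."""
    path = Path(path)
    with open(path, "w") as fh:
        if polyline.source_id:
            fh.write(f"# {polyline.source_id}\n")
        for x, y, z in polyline.points:
            fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_obj_vertices(path: str | Path) -> PointCloud:
    """Read vertex records from a Wavefront OBJ file.

    Only ``v x y z`` records are consumed; faces, normals, texture
    coordinates and any other records are skipped (counted at debug level).
    """
    path = Path(path)
    vertices: list[tuple[float, float, float]] = []
    skipped = 0
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) < 4:
                    raise ParseError(
                        f"{path.name}:{lineno}: vertex record with < 3 coordinates"
                    )
                try:
                    # OBJ allows an optional w (and vertex colors); take x y z
                    vertices.append(
                        (float(parts[1]), float(parts[2]), float(parts[3]))
                    )
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            else:
                skipped += 1
    if not vertices:
        raise ContentError(f"{path.name}: no vertex records found")
    logger.debug("%s: %d vertices, %d non-vertex records skipped",
                 path.name, len(vertices), skipped)
    return PointCloud(np.array(vertices, dtype=float), source_id=path.stem)


def _coordinate_columns(k: int) -> list[str]:
    cols = []
    for j in range(1, k + 1):
        cols.extend([f"x{j:02d}", f"y{j:02d}", f"z{j:02d}"])
    return cols


_META_COLUMNS = ["specimen_id", "group", "sex", "curve_length_mm"]


def write_semilandmark_table(table: SemilandmarkTable, path: str | Path) -> None:
    """Write a semilandmark table as CSV in canonical column order."""
    k = table.k
    df = pd.DataFrame({
        "specimen_id": table.specimen_ids,
        "group": table.groups,
        "sex": table.sexes,
        "curve_length_mm": table.curve_lengths_mm,
    })
    flat = table.coords.reshape(table.n, 3 * k)
    for i, col in enumerate(_coordinate_columns(k)):
        df[col] = flat[:, i]
    df.to_csv(path, index=False, float_format="%.17g")


def read_semilandmark_table(path: str | Path, k: int | None = None) -> SemilandmarkTable:
    """Read a semilandmark CSV; columns may appear in any order.

    ``k`` is inferred from the coordinate columns present when not given.
    Raises :class:`SchemaError` listing the offending fields on missing
    columns, non-numeric coordinates, or missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str, "group": str, "sex": str},
                     float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    if k is None:
        xcols = sorted(c for c in df.columns if len(c) == 3 and c[0] == "x"
                       and c[1:].isdigit())
        k = len(xcols)
    coord_cols = _coordinate_columns(k)
    missing = [c for c in coord_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing coordinate columns {missing}")
    block = df[coord_cols]
    bad = [c for c in coord_cols
           if not np.issubdtype(block[c].dtype, np.number) or block[c].isna().any()]
    bad += [c for c in ("curve_length_mm",) if df[c].isna().any()]
    if bad:
        raise SchemaError(f"{path.name}: non-numeric or missing values in {bad}")
    coords = block.to_numpy(dtype=float).reshape(len(df), k, 3)
    return SemilandmarkTable(
        specimen_ids=df["specimen_id"].astype(str).tolist(),
        groups=df["group"].astype(str).tolist(),
        sexes=df["sex"].astype(str).tolist(),
        curve_lengths_mm=df["curve_length_mm"].to_numpy(dtype=float),
        coords=coords,
    )


def table_from_curves(
    curves: Sequence["object"],
    groups: Sequence[str],
    sexes: Sequence[str],
) -> SemilandmarkTable:
    """Assemble a :class:`SemilandmarkTable` from resampled curves + metadata."""
    coords = np.stack([c.coords for c in curves])
    return SemilandmarkTable(
        specimen_ids=[c.specimen_id for c in curves],
        groups=list(groups),
        sexes=list(sexes),
        curve_lengths_mm=np.array([c.length_mm for c in curves]),
        coords=coords,
    )
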