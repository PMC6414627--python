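"""Arc-length resampling of dense polylines into equidistant semilandmarks.

A digitized crest curve arrives as a dense ordered polyline (typically
1,800-2,000 points).  ``resample_equidistant`` subdivides it into ``k``
points (default 20) equally spaced in arc length along the piecewise-linear
curve, with the two anatomically anchored endpoints preserved exactly.  At
digitization densities of ~1,900 points the chordal error of the
piecewise-linear parameterization is negligible, so no spline smoothing is
applied; this also makes the operator exactly idempotent on its own output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .curve_io import PointCloud, Polyline3D
from .errors import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Standard semilandmark count per curve.
DEFAULT_K = 20


@dataclass
class SemilandmarkCurve:
    """Fixed-count equidistant semilandmark representation of one curve.

    ``coords`` are the k ordered 3D semilandmarks (mm); ``length_mm`` is the
    arc length of the source polyline, carried along as the size variable for
    allometry (distinct from centroid size, which superimposition removes).
    """

    coords: np.ndarray  # (k, 3)
    length_mm: float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def k(self) -> int:
        return len(self.coords)


def arc_length(polyline: Polyline3D | np.ndarray) -> float:
    """Total length of a polyline: sum of consecutive Euclidean segments."""
    pts = polyline.points if isinstance(polyline, Polyline3D) else np.asarray(polyline)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(seg.sum())


def _dedupe_consecutive(pts: np.ndarray) -> np.ndarray:
    """Collapse consecutive duplicate points before arc-length parameterization."""
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    return pts[keep]


def resample_equidistant(
    polyline: Polyline3D | np.ndarray,
    k: int = DEFAULT_K,
    specimen_id: str | None = None,
) -> SemilandmarkCurve:
    """Resample a polyline into ``k`` semilandmarks equidistant in arc length.

    Semilandmark ``j`` (j = 0..k-1) lies on the piecewise-linear curve at
    arc-length fraction j/(k-1), found by linear interpolation within the
    containing segment.  The first and last points (the two anatomical
    anchors) are preserved exactly.
    """
    if k < 3:
        raise InvalidParameterError(f"k must be >= 3, got {k}")
    if isinstance(polyline, Polyline3D):
        pts = polyline.points
        sid = polyline.source_id if specimen_id is None else specimen_id
    else:
        pts = np.asarray(polyline, dtype=float)
        sid = specimen_id or ""
    pts = _dedupe_consecutive(pts)
    if len(pts) < 2:
        raise DegenerateInputError("polyline degenerates to a single point")
    if len(pts) < 2 * k:
        logger.warning(
            "polyline %s has only %d distinct points for k=%d semilandmarks",
            sid, len(pts), k,
        )

    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise DegenerateInputError("polyline has zero arc length")

    targets = np.linspace(0.0, total, k)
    coords = np.empty((k, 3))
    # interpolate each coordinate along cumulative arc length
    for d in range(3):
        coords[:, d] = np.interp(targets, cum, pts[:, d])
    coords[0] = pts[0]
    coords[-1] = pts[-1]
    return SemilandmarkCurve(coords=coords, length_mm=float(total), specimen_id=sid)


def max_caliper_length(cloud: PointCloud | np.ndarray) -> float:
    """Maximum Euclidean distance between any two vertices (point-set diameter).

    This implements the osteometric "book"/caliper measurement as the exact
    diameter of the vertex set; for an elongated bone the diameter direction
    coincides with the long axis.  Computed over convex-hull vertices for
    efficiency, falling back to the brute-force pairwise maximum when the
    hull is degenerate (coplanar or collinear clouds).
    """
    v = cloud.vertices if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if v.ndim != 2 or v.shape[1] != 3 or len(v) < 2:
        raise DegenerateInputError("need at least 2 vertices in an (n, 3) array")
    if len(v) > 50:
        try:
            v = v[ConvexHull(v).vertices]
        except QhullError:
            pass  # degenerate geometry: brute force below
    return float(pdist(v).max())
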