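"""Group mean shapes, difference fields, anatomical frames and score ellipses.

A difference field describes, semilandmark by semilandmark, the displacement
needed to relocate one (reference) mean configuration onto another (target):
a 3D vector per point plus its magnitude (rendered downstream as spheres
whose diameters reflect magnitude, with arrows for direction).  Vectors are
also projected onto two anatomical planes: the "medial view" plane (anterior-
posterior x proximo-distal), which exposes A-P bowing, and the "anterior
view" plane (medio-lateral x proximo-distal), which exposes the M-L sigmoid.

The anatomical frame is estimated from a mean curve itself: the proximo-
distal axis runs from the first to the last semilandmark (the two anatomical
anchors), the anterior axis is the direction in which the curve midpoint
bows away from the chord, and the medio-lateral axis completes a right-
handed triad.  The frame of the pooled-sample consensus is shared across all
group comparisons so that fields are commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import ContractError, DegenerateInputError, InvalidParameterError

#: Default coverage probability for group score-space ellipses.
DEFAULT_ELLIPSE_LEVEL = 0.70


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal triad (proximo-distal, anterior-posterior,
    medio-lateral) plus origin, all derived from a mean curve."""

    pd_axis: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        triad = np.column_stack([self.pd_axis, self.ap_axis, self.ml_axis])
        if not np.allclose(triad.T @ triad, np.eye(3), atol=1e-9):
            raise ContractError("frame axes are not orthonormal")


@dataclass
class DifferenceField:
    """Per-semilandmark displacement field between two mean shapes."""

    reference_label: str
    target_label: str
    vectors: np.ndarray  # (k, 3): target mean - reference mean
    magnitudes: np.ndarray  # (k,)
    frame: AnatomicalFrame
    ap_projection: np.ndarray  # (k, 2): (ap, pd) components, "medial view"
    ml_projection: np.ndarray  # (k, 2): (ml, pd) components, "anterior view"


@dataclass
class EllipseSpec:
    """Covariance ellipse of a 2D score cloud at a given coverage level."""

    center: np.ndarray  # (2,)
    semi_axes: np.ndarray  # (2,), major first
    orientation: float  # radians, major axis vs. first score axis
    level: float


def group_mean(sample, members) -> np.ndarray:
    """Coordinate-wise mean shape over a member index set of an aligned sample.

    ``sample`` may be an :class:`~crestcurve.superimposition.AlignedSample`
    or a raw (n, k, 3) array.
    """
    shapes = getattr(sample, "shapes", sample)
    members = np.asarray(members)
    if members.size == 0:
        raise InvalidParameterError("member set is empty")
    return np.asarray(shapes)[members].mean(axis=0)


def _arc_midpoint(curve: np.ndarray) -> np.ndarray:
    """Point at half arc length along a piecewise-linear curve."""
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    out = np.empty(3)
    for d in range(3):
        out[d] = np.interp(half, cum, curve[:, d])
    return out


def anatomical_frame(mean_shape: np.ndarray) -> AnatomicalFrame:
    """Estimate the anatomical frame of a mean curve.

    pd_axis: unit vector from the first to the last semilandmark.
    ap_axis: unit component, orthogonal to pd_axis, of the displacement of
    the curve's arc-length midpoint from the chord midpoint (the bow
    direction defines "anterior").  ml_axis = pd x ap.  Deterministic; a
    collinear curve with no bow has an ambiguous anterior direction and
    raises :class:`DegenerateInputError` (supply an explicit frame instead).
    """
    curve = np.asarray(mean_shape, float)
    chord = curve[-1] - curve[0]
    chord_len = np.linalg.norm(chord)
    if chord_len <= 1e-12:
        raise DegenerateInputError("curve endpoints coincide; frame undefined")
    pd_axis = chord / chord_len
    bow = _arc_midpoint(curve) - (curve[0] + curve[-1]) / 2.0
    bow -= (bow @ pd_axis) * pd_axis
    bow_len = np.linalg.norm(bow)
    if bow_len <= 1e-9 * chord_len:
        raise DegenerateInputError(
            "curve has no anterior bow; supply an explicit AnatomicalFrame"
        )
    ap_axis = bow / bow_len
    ml_axis = np.cross(pd_axis, ap_axis)
    return AnatomicalFrame(
        pd_axis=pd_axis, ap_axis=ap_axis, ml_axis=ml_axis, origin=curve[0].copy()
    )


def difference_field(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    frame: AnatomicalFrame,
    reference_label: str = "reference",
    target_label: str = "target",
) -> DifferenceField:
    """Displacement field relocating ``mean_a`` onto ``mean_b`` (b - a)."""
    a = np.asarray(mean_a, float)
    b = np.asarray(mean_b, float)
    if a.shape != b.shape:
        raise ContractError(f"mean shapes differ in k: {a.shape} vs {b.shape}")
    vectors = b - a
    magnitudes = np.linalg.norm(vectors, axis=1)
    ap_projection = np.column_stack([vectors @ frame.ap_axis, vectors @ frame.pd_axis])
    ml_projection = np.column_stack([vectors @ frame.ml_axis, vectors @ frame.pd_axis])
    return DifferenceField(
        reference_label=reference_label,
        target_label=target_label,
        vectors=vectors,
        magnitudes=magnitudes,
        frame=frame,
        ap_projection=ap_projection,
        ml_projection=ml_projection,
    )


def curvature_amplitudes(
    curve: np.ndarray, frame: AnatomicalFrame | None = None
) -> tuple[float, float]:
    """Recover the anterior bow and medio-lateral sigmoid amplitudes of a curve.

    Residuals of the curve points from the chord line are projected onto the
    anatomical axes; the bow amplitude is the maximum anterior component,
    the sigmoid amplitude the maximum absolute medio-lateral component.
    With the frame estimated from the curve itself this inverts the
    generator's parametric family up to digitization noise, which is what
    makes generator parameters recoverable from digitized data.
    """
    pts = np.asarray(curve, float)
    if frame is None:
        frame = anatomical_frame(pts)
    rel = pts - pts[0]
    resid = rel - np.outer(rel @ frame.pd_axis, frame.pd_axis)
    ap_profile = resid @ frame.ap_axis
    ml_profile = resid @ frame.ml_axis
    if len(pts) >= 200:
        # dense digitizations: a moving average suppresses the upward bias a
        # max over thousands of noisy points would otherwise introduce
        w = max(3, len(pts) // 40)
        kernel = np.ones(w) / w
        ap_profile = np.convolve(ap_profile, kernel, mode="valid")
        ml_profile = np.convolve(ml_profile, kernel, mode="valid")
    ap_amp = float(np.max(ap_profile))
    ml_amp = float(np.max(np.abs(ml_profile)))
    return ap_amp, ml_amp


def confidence_ellipse(
    scores_2d: np.ndarray, level: float = DEFAULT_ELLIPSE_LEVEL
) -> EllipseSpec:
    """Covariance ellipse of a group's 2D PC scores at the given coverage.

    The ellipse is the set {x : (x-m)' S^{-1} (x-m) = q} with S the sample
    covariance and q the chi-square quantile with 2 degrees of freedom at
    ``level``; for Gaussian scores it covers ``level`` of the distribution.
    """
    if not 0.0 < level < 1.0:
        raise InvalidParameterError(f"level must be in (0, 1), got {level}")
    pts = np.asarray(scores_2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise InvalidParameterError("need an (n >= 3, 2) score array")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-15 * max(evals[-1], 1.0):
        import logging
        logging.getLogger(__name__).warning("degenerate score covariance; ellipse flat")
        evals = np.clip(evals, 0.0, None)
    q = chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]  # major axis first
    semi_axes = np.sqrt(evals[order] * q)
    major = evecs[:, order[0]]
    return EllipseSpec(
        center=center,
        semi_axes=semi_axes,
        orientation=float(np.arctan2(major[1], major[0])),
        level=level,
    )
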