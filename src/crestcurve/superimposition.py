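"""Generalized Procrustes superimposition with tangent-sliding semilandmarks.

Shape is extracted from each semilandmark configuration by removing
position (centering), scale (unit centroid size) and orientation (rotation
to an evolving consensus, least squares).  Interior semilandmarks are then
allowed to slide along their local tangent direction — the unit vector
between the two adjacent semilandmarks — so as to minimize Procrustes
distance to the consensus; the first and last semilandmarks, which sit on
anatomical landmarks, never slide.  Sliding alternates with
re-superimposition until the total Procrustes sum of squares stabilizes.

Procrustes-distance sliding is used rather than bending-energy sliding.
Rotations are constrained to be proper (determinant +1): the sample contains
only left tibiae, so reflections are never legitimate.

After convergence the whole sample is rotated into a canonical anatomical
pose (anterior bow along +x, proximo-distal axis along -z) so that results
do not depend on the arbitrary coordinate frames the input polylines were
digitized in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractError, DegenerateInputError, InsufficientSampleError
from .resampling import SemilandmarkCurve

logger = logging.getLogger(__name__)


@dataclass
class SimilarityTransform:
    """Similarity map ``x -> scale * x @ rotation + translation`` (no reflection)."""

    rotation: np.ndarray  # (3, 3), det +1
    scale: float
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation + self.translation


@dataclass
class AlignedSample:
    """Procrustes-aligned (and optionally slid) shape coordinates.

    ``shapes`` are centered, unit-centroid-size, optimally rotated
    configurations; ``consensus`` is their coordinate-wise mean rescaled to
    unit centroid size.  ``centroid_sizes`` and ``curve_lengths`` keep the
    size information (mm) that superimposition strips out.  ``iterations``
    logs every alignment/sliding step with its total Procrustes sum of
    squares, which must be non-increasing.
    """

    shapes: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3)
    centroid_sizes: np.ndarray  # (n,)
    curve_lengths: np.ndarray  # (n,)
    specimen_ids: list[str] = field(default_factory=list)
    iterations: list[dict] = field(default_factory=list)
    n_skipped_slides: int = 0

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def total_ss(self) -> float:
        return float(np.sum((self.shapes - self.consensus) ** 2))


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def centroid_size(x: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    return float(np.linalg.norm(_center(np.asarray(x, float))))


def _normalize(x: np.ndarray) -> tuple[np.ndarray, float]:
    c = _center(x)
    cs = np.linalg.norm(c)
    if cs <= 0.0:
        raise DegenerateInputError("configuration has zero centroid size")
    return c / cs, float(cs)


def _optimal_rotations(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Batch proper rotations R_i minimizing ||shapes_i @ R_i - target||."""
    m = np.einsum("nki,kj->nij", shapes, target)  # X_i^T C, stacked
    u, _, vt = np.linalg.svd(m)
    det = np.linalg.det(np.einsum("nij,njk->nik", u, vt))
    u = u.copy()
    u[:, :, 2] *= np.sign(det)[:, None]
    return np.einsum("nij,njk->nik", u, vt)


def _rotate_all(shapes: np.ndarray, target: np.ndarray) -> np.ndarray:
    return np.einsum("nkj,nji->nki", shapes, _optimal_rotations(shapes, target))


def _gpa_core(
    configs: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[dict], np.ndarray]:
    """Rotation-only GPA of pre-centered unit-size shapes.

    Returns (aligned shapes, consensus, iteration log, centroid sizes).
    """
    n = configs.shape[0]
    shapes = np.empty_like(configs, dtype=float)
    sizes = np.empty(n)
    for i, cfg in enumerate(configs):
        shapes[i], sizes[i] = _normalize(np.asarray(cfg, float))

    consensus = shapes[0].copy()
    log: list[dict] = []
    ss_prev = np.inf
    for it in range(max_iter):
        shapes = _rotate_all(shapes, consensus)
        mean = shapes.mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm <= 0.0:
            raise DegenerateInputError("degenerate consensus (zero norm)")
        consensus = mean / norm
        ss = float(np.sum((shapes - consensus) ** 2))
        log.append({"stage": "gpa", "iteration": it, "total_ss": ss})
        if ss_prev - ss <= tol * max(ss_prev if np.isfinite(ss_prev) else ss, 1e-12):
            break
        ss_prev = ss
    else:
        logger.warning("GPA did not converge in %d iterations (ss trace: %s)",
                       max_iter, [rec["total_ss"] for rec in log[-3:]])
    # final re-rotation so every shape is optimally posed on the final consensus
    shapes = _rotate_all(shapes, consensus)
    return shapes, consensus, log, sizes


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray | None:
    """Rotation taking the consensus into the canonical anatomical pose.

    Anterior (bow) axis to +x, proximo-distal axis to -z.  Returns None when
    the pose is ambiguous (collinear consensus with no bow).
    """
    from .mean_shapes import anatomical_frame  # deferred: avoids import cycle

    try:
        frame = anatomical_frame(consensus)
    except DegenerateInputError:
        return None
    m = np.column_stack([frame.ap_axis, frame.ml_axis, frame.pd_axis])
    t = np.column_stack([(1.0, 0.0, 0.0), (0.0, -1.0, 0.0), (0.0, 0.0, -1.0)])
    return t @ m.T


def _canonicalize(shapes: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = _canonical_rotation(consensus)
    if r is None:
        logger.debug("canonical pose ambiguous (no bow); leaving GPA orientation")
        return shapes, consensus
    return shapes @ r.T, consensus @ r.T


def _as_config_array(curves: Sequence[SemilandmarkCurve] | np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(curves, np.ndarray):
        arr = np.asarray(curves, float)
        return arr, np.full(arr.shape[0], np.nan), [""] * arr.shape[0]
    arr = np.stack([c.coords for c in curves]).astype(float)
    lengths = np.array([c.length_mm for c in curves], float)
    ids = [c.specimen_id for c in curves]
    return arr, lengths, ids


def gpa(
    curves: Sequence[SemilandmarkCurve] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    canonicalize: bool = True,
) -> AlignedSample:
    """Generalized Procrustes alignment of semilandmark curves.

    Iteratively rotates every centered, unit-size configuration onto the
    evolving consensus (mean shape, rescaled to unit centroid size) until the
    relative change of the total Procrustes sum of squares falls below
    ``tol`` or ``max_iter`` is reached.
    """
    configs, lengths, ids = _as_config_array(curves)
    if configs.shape[0] < 2:
        raise InsufficientSampleError("GPA needs at least 2 configurations")
    shapes, consensus, log, sizes = _gpa_core(configs, tol=tol, max_iter=max_iter)
    if canonicalize:
        shapes, consensus = _canonicalize(shapes, consensus)
    return AlignedSample(
        shapes=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        curve_lengths=lengths,
        specimen_ids=ids,
        iterations=log,
    )


def slide_pass(shapes: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, int]:
    """One sliding pass: project each interior semilandmark toward the consensus
    along its tangent.

    The tangent at interior point i is the unit vector between its neighbours,
    t_i = unit(p_{i+1} - p_{i-1}); the point moves by the projection of
    (consensus_i - p_i) onto t_i.  Endpoints (0 and k-1) never move.  Points
    whose neighbours coincide (zero tangent) are skipped and counted.
    """
    slid = shapes.copy()
    tangents = shapes[:, 2:, :] - shapes[:, :-2, :]  # (n, k-2, 3)
    norms = np.linalg.norm(tangents, axis=2)
    ok = norms > 1e-12
    n_skipped = int(np.size(ok) - np.count_nonzero(ok))
    unit = np.zeros_like(tangents)
    unit[ok] = tangents[ok] / norms[ok][:, None]
    resid = consensus[None, 1:-1, :] - shapes[:, 1:-1, :]
    amount = np.einsum("nkd,nkd->nk", resid, unit)
    slid[:, 1:-1, :] += amount[:, :, None] * unit
    return slid, n_skipped


def slide_semilandmarks(
    sample: AlignedSample,
    tol: float = 1e-8,
    max_passes: int = 10,
    canonicalize: bool = True,
) -> AlignedSample:
    """Slide interior semilandmarks by Procrustes-distance minimization.

    Each pass slides every interior semilandmark along its tangent toward the
    consensus, then re-superimposes the slid configurations with a fresh GPA
    and updates the consensus.  Passes repeat until the relative decrease of
    the total Procrustes sum of squares falls below ``tol``, the objective
    stops improving, or ``max_passes`` is reached.  The logged objective is
    non-increasing by construction (a pass that fails to improve is reverted).
    """
    if sample.k < 3:
        raise DegenerateInputError("sliding needs k >= 3 semilandmarks")
    shapes = sample.shapes.copy()
    consensus = sample.consensus.copy()
    log = list(sample.iterations)
    skipped_total = sample.n_skipped_slides
    ss_prev = float(np.sum((shapes - consensus) ** 2))
    for p in range(max_passes):
        slid, n_skip = slide_pass(shapes, consensus)
        skipped_total += n_skip
        if n_skip:
            logger.warning("sliding pass %d: %d points skipped (zero tangent)", p, n_skip)
        new_shapes, new_consensus, _, _ = _gpa_core(slid)
        ss = float(np.sum((new_shapes - new_consensus) ** 2))
        if ss > ss_prev:
            logger.debug("sliding pass %d would increase SS (%.3e > %.3e); stopping",
                         p, ss, ss_prev)
            break
        log.append({"stage": "slide", "pass": p, "total_ss": ss})
        shapes, consensus = new_shapes, new_consensus
        if ss_prev - ss <= tol * max(ss_prev, 1e-12):
            break
        ss_prev = ss
    if canonicalize:
        shapes, consensus = _canonicalize(shapes, consensus)
    return AlignedSample(
        shapes=shapes,
        consensus=consensus,
        centroid_sizes=sample.centroid_sizes.copy(),
        curve_lengths=sample.curve_lengths.copy(),
        specimen_ids=list(sample.specimen_ids),
        iterations=log,
        n_skipped_slides=skipped_total,
    )


def gpa_with_sliding(
    curves: Sequence[SemilandmarkCurve] | np.ndarray,
    slide: bool = True,
    tol: float = 1e-8,
    max_passes: int = 10,
) -> AlignedSample:
    """Convenience: GPA followed (optionally) by tangent sliding."""
    sample = gpa(curves, canonicalize=not slide)
    if slide:
        sample = slide_semilandmarks(sample, tol=tol, max_passes=max_passes)
    return sample


def _pair_rotation(a_unit: np.ndarray, b_unit: np.ndarray) -> tuple[np.ndarray, float]:
    """Proper rotation R minimizing ||b_unit @ R - a_unit||; returns (R, trace term)."""
    m = b_unit.T @ a_unit
    u, s, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= d
    u = u.copy()
    u[:, 2] *= d
    return u @ vt, float(s.sum())


def full_procrustes_align_pair(
    a: SemilandmarkCurve | np.ndarray, b: SemilandmarkCurve | np.ndarray
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity superimposition of ``b`` onto ``a``.

    Returns the similarity transform (translation, proper rotation, scale)
    minimizing the summed squared distances of the transformed ``b`` onto
    ``a``, together with the Procrustes distance: the residual
    root-sum-of-squares between the unit-centroid-size, centered shapes after
    optimal rotation.
    """
    pa = a.coords if isinstance(a, SemilandmarkCurve) else np.asarray(a, float)
    pb = b.coords if isinstance(b, SemilandmarkCurve) else np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ContractError(f"configurations differ in shape: {pa.shape} vs {pb.shape}")
    a_unit, cs_a = _normalize(pa)
    b_unit, cs_b = _normalize(pb)
    rot, trace = _pair_rotation(a_unit, b_unit)
    distance = float(np.sqrt(max(0.0, 2.0 - 2.0 * trace)))
    # similarity map acting on raw b coordinates: scale relative to raw sizes
    scale = trace * cs_a / cs_b
    translation = pa.mean(axis=0) - scale * pb.mean(axis=0) @ rot
    return SimilarityTransform(rotation=rot, scale=scale, translation=translation), distance


def procrustes_distance(a: np.ndarray, b: np.ndarray, atol: float = 1e-6) -> float:
    """Procrustes distance between two centered, unit-size configurations.

    Root summed squared difference after optimal proper rotation; symmetric,
    zero iff the shapes coincide up to rotation.  Inputs violating the
    centering/unit-size contract raise :class:`ContractError`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ContractError(f"configurations differ in shape: {a.shape} vs {b.shape}")
    for name, x in (("a", a), ("b", b)):
        if np.abs(x.mean(axis=0)).max() > atol:
            raise ContractError(f"shape {name} is not centered")
        if abs(np.linalg.norm(x) - 1.0) > atol:
            raise ContractError(f"shape {name} does not have unit centroid size")
    _, trace = _pair_rotation(a, b)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * trace)))
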