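"""Minimal static plots: score scatter with group ellipses, vector fields.

These are convenience renderings of the exported data (the CSV/JSON exports
are the primary interface); matplotlib is imported lazily so the analysis
pipeline carries no hard plotting dependency at import time.
"""

from __future__ import annotations

import numpy as np

from .mean_shapes import DifferenceField, EllipseSpec, confidence_ellipse


def plot_scores_with_ellipses(scores_2d, groups, level: float = 0.70, ax=None,
                              min_group_n: int = 3):
    """PC1-PC2 scatter colored by group, with coverage ellipses per group."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores_2d = np.asarray(scores_2d, float)
    groups = np.asarray(list(groups))
    for lab in dict.fromkeys(groups):
        sel = groups == lab
        pts = scores_2d[sel]
        sc = ax.scatter(pts[:, 0], pts[:, 1], s=12, label=str(lab), alpha=0.7)
        if sel.sum() >= min_group_n:
            e: EllipseSpec = confidence_ellipse(pts, level=level)
            ax.add_patch(Ellipse(
                e.center, 2 * e.semi_axes[0], 2 * e.semi_axes[1],
                angle=np.degrees(e.orientation), fill=False,
                edgecolor=sc.get_facecolor()[0], linewidth=1.2,
            ))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    ax.set_title(f"shape scores with {int(level * 100)}% ellipses")
    return ax


def plot_difference_field(field: DifferenceField, plane: str = "ap",
                          reference_curve=None, scale: float = 1.0, ax=None):
    """2D vector plot of a mean-shape difference field in one anatomical plane.

    ``plane``: "ap" (medial view: anterior-posterior vs proximo-distal) or
    "ml" (anterior view: medio-lateral vs proximo-distal).  Sphere areas are
    proportional to displacement magnitude; arrows show direction.
    """
    import matplotlib.pyplot as plt

    if plane not in ("ap", "ml"):
        raise ValueError(f"plane must be 'ap' or 'ml', got {plane!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 7))
    proj = field.ap_projection if plane == "ap" else field.ml_projection
    if reference_curve is not None:
        ref = np.asarray(reference_curve, float)
        axis = field.frame.ap_axis if plane == "ap" else field.frame.ml_axis
        base = np.column_stack([ref @ axis, ref @ field.frame.pd_axis])
    else:
        base = np.column_stack([np.zeros(len(proj)),
                                -np.arange(len(proj), dtype=float)])
    mag = field.magnitudes
    size = 2000.0 * mag / max(mag.max(), 1e-12)
    ax.plot(base[:, 0], base[:, 1], "-", color="0.8", zorder=1)
    ax.scatter(base[:, 0], base[:, 1], s=size, alpha=0.4, zorder=2)
    ax.quiver(base[:, 0], base[:, 1], proj[:, 0] * scale, proj[:, 1] * scale,
              angles="xy", scale_units="xy", scale=1.0, width=0.01, zorder=3)
    ax.set_aspect("equal")
    view = "medial view (A-P)" if plane == "ap" else "anterior view (M-L)"
    ax.set_title(f"{field.reference_label} → {field.target_label}\n{view}",
                 fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
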