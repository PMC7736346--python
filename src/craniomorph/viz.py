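"""Morphospace plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .ordination import GroupEllipse, OrdinationResult


def plot_morphospace(result: OrdinationResult, ax=None,
                     components: tuple[int, int] = (0, 1),
                     centroid_sizes: np.ndarray | None = None,
                     ellipses: list[GroupEllipse] | None = None,
                     hulls: bool = True):
    """Scatter of two ordination components, one colour per group.

    Point area scales with centroid size when given; convex hulls and/or
    90% ellipses outline each group's occupation of the morphospace.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy.spatial import ConvexHull, QhullError

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    i, j = components
    xy = result.scores[:, [i, j]]
    labels = result.labels if result.labels is not None else np.array(["all"] * len(xy))
    sizes = None
    if centroid_sizes is not None:
        cs = np.asarray(centroid_sizes, float)
        sizes = 20 + 80 * (cs - cs.min()) / max(np.ptp(cs), 1e-12)
    for g in dict.fromkeys(labels):
        m = labels == g
        sc = ax.scatter(xy[m, 0], xy[m, 1], label=str(g),
                        s=sizes[m] if sizes is not None else 30, alpha=0.8)
        color = sc.get_facecolor()[0]
        if hulls and m.sum() >= 3:
            try:
                hull = ConvexHull(xy[m])
                pts = xy[m][np.append(hull.vertices, hull.vertices[0])]
                ax.plot(pts[:, 0], pts[:, 1], color=color, lw=0.8, alpha=0.6)
            except QhullError:
                pass
    for ell in ellipses or []:
        angle = np.degrees(np.arctan2(ell.axes[1, 0], ell.axes[0, 0]))
        ax.add_patch(Ellipse(ell.center, 2 * ell.radii[0], 2 * ell.radii[1],
                             angle=angle, fill=False, ls=":", lw=1.0))
    frac = result.variance_fractions
    ax.set_xlabel(f"{result.kind.upper()} {i + 1} ({frac[i] * 100:.1f}%)")
    ax.set_ylabel(f"{result.kind.upper()} {j + 1} ({frac[j] * 100:.1f}%)")
    ax.legend(fontsize=8)
    return ax
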