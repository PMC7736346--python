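"""Generalized Procrustes Analysis, symmetrization and Procrustes distances.

Conventions: superimposition removes translation, scale (unit centroid
size) and orientation; rotations are proper (determinant +1, no
reflections), so bilateral asymmetry survives alignment and can be removed
explicitly by :func:`symmetrize`.  Pairwise shape distance is the partial
Procrustes distance between unit-size configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import Dataset
from .scheme import LandmarkScheme


class AlignmentError(ValueError):
    pass


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared distances of points to their centroid."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    dev = coords - coords.mean(axis=0)
    cs = float(np.sqrt((dev ** 2).sum()))
    if cs == 0.0:
        raise AlignmentError("all points coincident: centroid size is zero")
    return cs


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    dev = coords - coords.mean(axis=0)
    cs = np.sqrt((dev ** 2).sum())
    if cs == 0:
        raise AlignmentError("degenerate configuration (zero centroid size)")
    return dev / cs, float(cs)


def optimal_rotation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising ||x R - y||_F for centered x, y."""
    u, _, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def opa_transform(x: np.ndarray, y: np.ndarray, scale: bool = True
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Ordinary Procrustes fit of x onto y: returns (s, R, t) with
    ``s * x @ R + t`` the least-squares superimposition of x on y."""
    xm, ym = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - xm, y - ym
    u, sv, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    if scale:
        num = sv[0] + sv[1] + d * sv[2]
        s = float(num / (xc ** 2).sum())
    else:
        s = 1.0
    t = ym - s * xm @ rot
    return s, rot, t


@dataclass
class AlignedDataset:
    """Procrustes shape coordinates plus the sizes removed by alignment."""
    shapes: np.ndarray            # (n, k, 3), unit centroid size
    centroid_sizes: np.ndarray    # (n,), mm
    consensus: np.ndarray         # (k, 3): arithmetic mean of aligned shapes
    labels: np.ndarray            # group per specimen
    specimen_ids: list[str]
    sexes: Optional[np.ndarray] = None
    convergence_log: list[float] = field(default_factory=list)
    tangent_projected: bool = False

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    def residuals(self) -> np.ndarray:
        """Procrustes residuals, flattened to (n, 3k)."""
        n = self.shapes.shape[0]
        return (self.shapes - self.consensus).reshape(n, -1)

    def flat(self) -> np.ndarray:
        return self.shapes.reshape(self.n, -1)


def gpa(data, labels: Optional[Sequence[str]] = None,
        specimen_ids: Optional[Sequence[str]] = None,
        sexes: Optional[Sequence[str]] = None,
        tol: float = 1e-10, max_iter: int = 100,
        tangent: bool = True, canonical: bool = True) -> AlignedDataset:
    """Generalized Procrustes Analysis of complete configurations.

    Accepts a complete :class:`~craniomorph.dataset.Dataset` or an
    (n, k, 3) array.  Each configuration is centered, scaled to unit
    centroid size and rotated onto the running consensus (initialised from
    the first specimen, so the result is deterministic); the consensus is
    the arithmetic mean of the aligned shapes.  With ``canonical=True`` the
    converged solution is rotated into the consensus's principal-axis frame
    (with a deterministic sign convention), making the output invariant to
    rigid motion and scaling of any input, including the one used to
    initialise the consensus.  With ``tangent=True`` the aligned shapes are
    orthogonally projected onto the tangent plane at the consensus before
    being returned.
    """
    if isinstance(data, Dataset):
        ids = data.specimen_ids
        labels = data.groups
        sexes = np.array([r.sex for r in data])
        incomplete = [r.specimen_id for r in data if not r.is_complete]
        if incomplete:
            raise AlignmentError(f"missing landmarks in {incomplete}; impute first")
        arr = data.coords_array()
    else:
        arr = np.asarray(data, float)
        ids = list(specimen_ids) if specimen_ids is not None else [
            f"spec{i}" for i in range(arr.shape[0])]
        labels = np.asarray(labels) if labels is not None else np.array(["all"] * arr.shape[0])
        sexes = np.asarray(sexes) if sexes is not None else None
    n = arr.shape[0]
    if n < 1:
        raise AlignmentError("empty dataset")

    shapes = np.empty_like(arr)
    sizes = np.empty(n)
    for i in range(n):
        rank = np.linalg.matrix_rank(arr[i] - arr[i].mean(axis=0), tol=1e-9)
        if rank < 2:
            raise AlignmentError(f"{ids[i]}: degenerate (rank {rank}) configuration")
        shapes[i], sizes[i] = _center_scale(arr[i])

    consensus = shapes[0].copy()
    log: list[float] = []
    for _ in range(max_iter):
        for i in range(n):
            shapes[i] = shapes[i] @ optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        log.append(delta)
        if delta < tol:
            break

    if canonical:
        rot = _principal_frame(consensus)
        shapes = shapes @ rot
        consensus = consensus @ rot

    if tangent and n > 1:
        c = consensus.reshape(-1)
        cn = c / np.linalg.norm(c)
        flat = shapes.reshape(n, -1)
        # orthogonal projection onto the tangent plane at the consensus
        flat = flat - np.outer(flat @ cn - np.linalg.norm(c), cn)
        shapes = flat.reshape(n, -1, 3)
        consensus = shapes.mean(axis=0)

    return AlignedDataset(shapes=shapes, centroid_sizes=sizes,
                          consensus=consensus, labels=np.asarray(labels),
                          specimen_ids=list(ids), sexes=sexes,
                          convergence_log=log, tangent_projected=tangent)


def _principal_frame(consensus: np.ndarray) -> np.ndarray:
    """Rotation into the consensus's principal axes, deterministic signs."""
    _, vec = np.linalg.eigh(consensus.T @ consensus)
    vec = vec[:, ::-1]  # descending variance
    for j in range(3):
        lead = np.argmax(np.abs(consensus[:, :] @ vec[:, j]))
        if (consensus @ vec[:, j])[lead] < 0:
            vec[:, j] = -vec[:, j]
    if np.linalg.det(vec) < 0:
        vec[:, 2] = -vec[:, 2]
    return vec


def gpa_mean(arr: np.ndarray, tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Procrustes mean shape of an (n, k, 3) stack, unit centroid size."""
    aligned = gpa(arr, tol=tol, max_iter=max_iter, tangent=False)
    m, _ = _center_scale(aligned.consensus)
    return m


def symmetrize(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Symmetrized configuration for object symmetry.

    The configuration is reflected, left/right labels are swapped, the
    relabelled reflection is rigidly fitted back onto the original
    (rotation + translation, no scaling between the two copies) and the two
    are averaged.  The result is exactly symmetric about its own midplane
    and the operation is idempotent.
    """
    if scheme.n_pairs == 0:
        raise ValueError("scheme has no bilateral pairs; nothing to symmetrize")
    coords = np.asarray(coords, float)
    if np.isnan(coords).any():
        raise ValueError("symmetrize requires a complete configuration")
    centroid = coords.mean(axis=0)
    x = coords - centroid
    refl = x * np.array([-1.0, 1.0, 1.0])
    y = refl[scheme.relabel_permutation()]
    rot = optimal_rotation(y, x)
    return (x + y @ rot) / 2.0 + centroid


def symmetrize_dataset(dataset: Dataset) -> Dataset:
    recs = []
    for r in dataset:
        out = r.copy()
        out.coords = symmetrize(r.coords, dataset.scheme)
        recs.append(out)
    return Dataset(dataset.scheme, recs)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, b is rotated onto
    a, and the root summed squared coordinate difference is returned.
    Symmetric in its arguments.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched point counts: {a.shape} vs {b.shape}")
    xa, _ = _center_scale(a)
    xb, _ = _center_scale(b)
    xb = xb @ optimal_rotation(xb, xa)
    return float(np.sqrt(((xa - xb) ** 2).sum()))


def screen_outliers(aligned: AlignedDataset, scope: str = "whole-sample",
                    iqr_factor: float = 1.5):
    """Flag specimens unusually far from their scope mean shape.

    ``scope`` is ``whole-sample`` or ``per-group``.  Distance is the
    partial Procrustes distance to the scope mean; the flag threshold is
    Q3 + ``iqr_factor`` x IQR of the scope's distances.
    Returns a list of ``(specimen_id, group, distance, threshold,
    is_outlier)`` tuples in specimen order.
    """
    import pandas as pd

    if scope not in ("whole-sample", "per-group"):
        raise ValueError(scope)
    rows = []
    if scope == "whole-sample":
        groups = {None: np.arange(aligned.n)}
    else:
        groups = {g: np.flatnonzero(aligned.labels == g)
                  for g in dict.fromkeys(aligned.labels)}
    for g, idx in groups.items():
        if idx.size < 3:
            raise ValueError(f"scope {g or 'whole-sample'} has fewer than 3 specimens")
        mean = aligned.shapes[idx].mean(axis=0)
        d = np.array([procrustes_distance(aligned.shapes[i], mean) for i in idx])
        q1, q3 = np.percentile(d, [25, 75])
        thr = q3 + iqr_factor * (q3 - q1)
        for i, di in zip(idx, d):
            rows.append((aligned.specimen_ids[i], aligned.labels[i],
                         float(di), float(thr), bool(di > thr)))
    order = {sid: j for j, sid in enumerate(aligned.specimen_ids)}
    rows.sort(key=lambda r: order[r[0]])
    return pd.DataFrame(rows, columns=["specimen_id", "group", "distance",
                                       "threshold", "is_outlier"])
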