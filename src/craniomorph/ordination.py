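"""Ordination of Procrustes shape coordinates.

PCA of the Procrustes residuals (via SVD of the centered residual matrix —
the specimen count is far below the 3k coordinate count, so the
decomposition must tolerate rank deficiency), between-group PCA (bgPCA),
and its leave-one-out cross-validated variant.  bgPCA projects every
specimen onto the principal axes of the group means; with few groups it can
manufacture apparent separation, which the cross-validation removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import chi2

from .superimpose import AlignedDataset


@dataclass
class GroupEllipse:
    group: str
    center: np.ndarray       # (2,)
    axes: np.ndarray         # (2, 2) unit axis directions (columns)
    radii: np.ndarray        # (2,) semi-axis lengths
    level: float


@dataclass
class OrdinationResult:
    scores: np.ndarray               # (n, m)
    axes: np.ndarray                 # (p, m), orthonormal columns
    eigenvalues: np.ndarray          # (m,)
    variance_fractions: np.ndarray   # (m,), shares of total variance
    kind: str                        # pca | bgpca | bgpca_cv
    labels: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None        # mean removed before projection
    retained_fraction: float = 1.0
    group_centers: dict = field(default_factory=dict)
    ellipses: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(aligned: AlignedDataset | np.ndarray) -> OrdinationResult:
    """PCA of Procrustes residuals (shapes minus consensus)."""
    if isinstance(aligned, AlignedDataset):
        resid = aligned.residuals()
        labels = aligned.labels
    else:
        resid = np.asarray(aligned, float)
        labels = None
    n = resid.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs n >= 3 specimens, got {n}")
    centered = resid - resid.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    m = min(n - 1, centered.shape[1])
    u, s, vt = u[:, :m], s[:m], vt[:m]
    eig = s ** 2 / (n - 1)
    total = eig.sum()
    return OrdinationResult(
        scores=u * s, axes=vt.T, eigenvalues=eig,
        variance_fractions=eig / total if total > 0 else eig,
        kind="pca", labels=labels, center=resid.mean(axis=0))


def retain_components(result: OrdinationResult, k: int) -> OrdinationResult:
    """Truncate an ordination to its first k components."""
    if not 1 <= k <= result.n_components:
        raise ValueError(f"k={k} outside 1..{result.n_components}")
    return replace(result,
                   scores=result.scores[:, :k], axes=result.axes[:, :k],
                   eigenvalues=result.eigenvalues[:k],
                   variance_fractions=result.variance_fractions[:k],
                   retained_fraction=float(result.variance_fractions[:k].sum()
                                           * result.retained_fraction))


def _group_means(scores: np.ndarray, labels: np.ndarray):
    groups = list(dict.fromkeys(labels))
    means = np.stack([scores[labels == g].mean(axis=0) for g in groups])
    sizes = np.array([(labels == g).sum() for g in groups])
    return groups, means, sizes


def _bg_axes(scores: np.ndarray, labels: np.ndarray, weighted: bool):
    groups, means, sizes = _group_means(scores, labels)
    w = sizes / sizes.sum() if weighted else np.full(len(groups), 1.0 / len(groups))
    grand = w @ means
    dev = means - grand
    between = (dev * w[:, None]).T @ dev
    eigval, eigvec = np.linalg.eigh(between)
    order = np.argsort(eigval)[::-1][:max(len(groups) - 1, 1)]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > max(eigval[0], 0) * 1e-12
    return groups, grand, eigval[keep], eigvec[:, keep]


def bgpca(scores: np.ndarray, labels, weighted: bool = True) -> OrdinationResult:
    """Between-group PCA: principal axes of the (size-weighted) group means.

    All specimens are projected onto the between-group axes; variance
    fractions are shares of the between-group variance.  At most
    (n_groups - 1) axes exist.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(set(labels)) < 2:
        raise ValueError("bgPCA needs at least 2 groups")
    groups, grand, eigval, axes = _bg_axes(scores, labels, weighted)
    proj = (scores - grand) @ axes
    centers = {g: proj[labels == g].mean(axis=0) for g in groups}
    return OrdinationResult(
        scores=proj, axes=axes, eigenvalues=eigval,
        variance_fractions=eigval / eigval.sum(), kind="bgpca",
        labels=labels, center=grand, group_centers=centers)


def bgpca_cv(scores: np.ndarray, labels, weighted: bool = True) -> OrdinationResult:
    """Leave-one-out cross-validated bgPCA.

    Each specimen is projected onto between-group axes recomputed without
    it; per-fold axes are sign-aligned to the full-data axes so the
    assembled scores live in one consistent frame.  Removes the spurious
    self-inclusion separation of plain bgPCA.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    singletons = [g for g in set(labels) if (labels == g).sum() < 2]
    if singletons:
        raise ValueError(f"cross-validation impossible: group(s) of size 1: {sorted(singletons)}")
    full = bgpca(scores, labels, weighted)
    m = full.n_components
    n = scores.shape[0]
    cv = np.zeros((n, m))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        _, grand, _, axes = _bg_axes(scores[mask], labels[mask], weighted)
        mask[i] = True
        mm = min(m, axes.shape[1])
        signs = np.sign(np.einsum("pm,pm->m", axes[:, :mm], full.axes[:, :mm]))
        signs[signs == 0] = 1.0
        cv[i, :mm] = (scores[i] - grand) @ (axes[:, :mm] * signs)
    centers = {g: cv[labels == g].mean(axis=0) for g in full.group_centers}
    return replace(full, scores=cv, kind="bgpca_cv", group_centers=centers)


def confidence_ellipse(scores_2d: np.ndarray, labels, level: float = 0.90
                       ) -> list[GroupEllipse]:
    """Per-group confidence ellipses from the 2x2 score covariance.

    Semi-axes are sqrt(eigenvalue x chi2_2 quantile at ``level``); at
    level 0 the ellipse degenerates to the group mean point.
    """
    scores_2d = np.asarray(scores_2d, float)
    if scores_2d.shape[1] != 2:
        raise ValueError("confidence_ellipse expects 2-column scores")
    labels = np.asarray(labels)
    out = []
    for g in dict.fromkeys(labels):
        pts = scores_2d[labels == g]
        if pts.shape[0] < 3:
            raise ValueError(f"group {g}: fewer than 3 members")
        cov = np.cov(pts, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        eigval = np.clip(eigval, 0, None)[::-1]
        eigvec = eigvec[:, ::-1]
        q = chi2.ppf(level, df=2) if level > 0 else 0.0
        out.append(GroupEllipse(group=str(g), center=pts.mean(axis=0),
                                axes=eigvec, radii=np.sqrt(eigval * q),
                                level=level))
    return out
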