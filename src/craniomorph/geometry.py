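"""Thin-plate splines and midsagittal mirroring for missing-landmark estimation.

Missing cranial landmarks are filled in two stages, mirroring first:

1. a bilateral point whose antimere is present is reflected across the
   specimen's least-squares midsagittal plane;
2. anything mirroring cannot fill (midline points, pairs missing on both
   sides) is interpolated by a 3D thin-plate spline warped from a sample
   average configuration onto the specimen's present landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .dataset import Dataset, SpecimenRecord
from .scheme import LandmarkScheme


class SingularTPSError(ValueError):
    """TPS system is singular (coincident or coplanar control points)."""


class CannotMirrorError(ValueError):
    """Too few usable midline landmarks to estimate a midsagittal plane."""


@dataclass
class ThinPlateSpline:
    """Exact 3D thin-plate-spline interpolant between two point sets.

    Uses the volumetric kernel U(r) = r.  The affine part is a 3x3 matrix
    plus translation; ``nonaffine_weights`` satisfy the usual side
    conditions (zero column sums, orthogonal to the source coordinates),
    which makes the bending energy well defined.
    """
    source: np.ndarray            # (k, 3)
    target: np.ndarray            # (k, 3)
    nonaffine_weights: np.ndarray  # (k, 3)
    affine_matrix: np.ndarray     # (3, 3)
    translation: np.ndarray       # (3,)
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the interpolant at (m, 3) query points."""
        points = np.atleast_2d(np.asarray(points, float))
        kern = cdist(points, self.source)  # U(r) = r
        return (points @ self.affine_matrix + self.translation
                + kern @ self.nonaffine_weights)


def fit_tps(source: np.ndarray, target: np.ndarray) -> ThinPlateSpline:
    """Fit the exact TPS mapping source control points onto target points.

    Raises :class:`SingularTPSError` for coincident or coplanar controls
    (fewer than 4 points in general position leave the affine part
    unidentified), naming the offending indices where possible.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    k = source.shape[0]
    if source.shape != target.shape or source.shape[1] != 3:
        raise ValueError("source and target must both be (k, 3)")
    if k < 4:
        raise SingularTPSError(f"need >= 4 control points, got {k}")
    dists = cdist(source, source)
    dup = np.argwhere((dists < 1e-12) & ~np.eye(k, dtype=bool))
    if dup.size:
        raise SingularTPSError(
            f"coincident source control points at indices {sorted({tuple(sorted(p)) for p in dup})[:5]}")
    # coplanarity: centered source must have rank 3
    centered = source - source.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-10 * max(sv[0], 1.0):
        raise SingularTPSError("control points are coplanar; affine part unidentified")

    kmat = dists  # U(r) = r
    pmat = np.hstack([np.ones((k, 1)), source])
    lmat = np.zeros((k + 4, k + 4))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = pmat
    lmat[k:, :k] = pmat.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    try:
        sol = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded above
        raise SingularTPSError(str(e)) from e
    weights, affine = sol[:k], sol[k:]
    # with U(r) = r the quadratic form w' K w is <= 0 on the side-condition
    # subspace; the bending energy is its magnitude
    be = -float(np.einsum("id,ij,jd->", weights, kmat, weights))
    return ThinPlateSpline(source=source, target=target,
                           nonaffine_weights=weights,
                           affine_matrix=affine[1:], translation=affine[0],
                           bending_energy=max(be, 0.0))


@dataclass(frozen=True)
class MidsagittalPlane:
    point: np.ndarray        # (3,)
    unit_normal: np.ndarray  # (3,)

    def reflect(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        d = (points - self.point) @ self.unit_normal
        return points - 2.0 * d[:, None] * self.unit_normal


def estimate_midplane(record: SpecimenRecord,
                      scheme: LandmarkScheme) -> MidsagittalPlane:
    """Least-squares plane through the specimen's present midline landmarks."""
    mid = record.coords[scheme.midline_indices]
    mid = mid[~np.isnan(mid).any(axis=1)]
    if mid.shape[0] < 3:
        raise CannotMirrorError(
            f"{record.specimen_id}: only {mid.shape[0]} midline landmarks present")
    centroid = mid.mean(axis=0)
    u, s, vt = np.linalg.svd(mid - centroid)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise CannotMirrorError(f"{record.specimen_id}: midline landmarks are collinear")
    return MidsagittalPlane(point=centroid, unit_normal=vt[2])


def mirror_impute(record: SpecimenRecord, scheme: LandmarkScheme,
                  plane: MidsagittalPlane | None = None) -> SpecimenRecord:
    """Fill missing bilateral landmarks by reflecting their present antimeres.

    Points that cannot be mirrored (midline, or both antimeres missing) are
    left missing for the TPS stage.  Returns a new record; ``imputed`` marks
    the mirrored points.
    """
    if plane is None:
        plane = estimate_midplane(record, scheme)
    out = record.copy()
    missing = out.missing_mask
    anti = scheme.antimere
    imputed = np.zeros(len(scheme), dtype=bool) if out.imputed is None else out.imputed
    for i in np.flatnonzero(missing):
        j = anti[i]
        if j != i and not missing[j]:
            out.coords[i] = plane.reflect(out.coords[j])[0]
            imputed[i] = True
    out.imputed = imputed
    return out


def tps_impute(dataset: Dataset, reference: np.ndarray | None = None,
               max_missing: float = 0.5, tol: float = 1e-6,
               max_iter: int = 10, align: bool = True) -> Dataset:
    """Estimate remaining missing landmarks by TPS from a sample average.

    The reference is the Procrustes mean shape of the complete specimens
    (or a supplied (k, 3) configuration).  Each incomplete specimen is
    similarity-aligned to the reference on its present points, the TPS
    mapping reference -> specimen (restricted to present points) is
    evaluated at the reference's positions of the missing points, and the
    estimates are mapped back to the specimen's own space.  The reference
    is then refreshed from the completed sample and the procedure iterated
    to a fixed point (Procrustes mean-shape change < ``tol``).
    """
    from .superimpose import gpa_mean, opa_transform, procrustes_distance

    incomplete = [r for r in dataset if not r.is_complete]
    if not incomplete:
        return dataset
    for r in incomplete:
        if r.missing_fraction > max_missing:
            raise ValueError(
                f"{r.specimen_id}: {r.missing_fraction:.0%} landmarks missing "
                f"exceeds the configured maximum {max_missing:.0%}")
    if reference is None:
        complete = [r.coords for r in dataset if r.is_complete]
        if not complete:
            raise ValueError("no complete specimens to initialise the reference")
        reference = gpa_mean(np.stack(complete))

    records = {r.specimen_id: r.copy() for r in dataset}
    for _ in range(max_iter):
        for rec in incomplete:
            out = records[rec.specimen_id]
            missing = rec.missing_mask  # original pattern: re-estimated each pass
            present = ~missing
            src, spec = reference[present], rec.coords[present]
            if align:
                # similarity-align the specimen onto the reference space
                s, rot, t = opa_transform(spec, src, scale=True)
                spec_al = s * spec @ rot + t
                warp = fit_tps(src, spec_al)
                est = warp(reference[missing])
                out.coords[missing] = (est - t) @ rot.T / s
            else:
                warp = fit_tps(src, rec.coords[present])
                out.coords[missing] = warp(reference[missing])
            imputed = np.zeros(len(dataset.scheme), bool) if rec.imputed is None else rec.imputed.copy()
            imputed |= missing
            out.imputed = imputed
        new_ref = gpa_mean(np.stack([records[r.specimen_id].coords for r in dataset]))
        delta = procrustes_distance(reference, new_ref)
        reference = new_ref
        if delta < tol:
            break
    return Dataset(dataset.scheme, [records[r.specimen_id] for r in dataset])


def impute_missing(dataset: Dataset, max_missing: float = 0.5,
                   tol: float = 1e-6, max_iter: int = 10) -> Dataset:
    """Full two-stage imputation: mirroring, then TPS for the remainder."""
    records = []
    for r in dataset:
        if r.is_complete:
            records.append(r.copy())
            continue
        try:
            records.append(mirror_impute(r, dataset.scheme))
        except CannotMirrorError:
            records.append(r.copy())
    mirrored = Dataset(dataset.scheme, records)
    return tps_impute(mirrored, max_missing=max_missing, tol=tol, max_iter=max_iter)
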