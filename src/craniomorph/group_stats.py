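"""Group distance matrices, permutation tests and allometry screening.

Three distances between group centroids are supported:

* ``procrustes`` — partial Procrustes distance between group mean shapes,
  computed from aligned (n, k, 3) coordinates;
* ``euclidean`` — Euclidean distance between group mean score vectors on a
  stated number of leading PCs;
* ``mahalanobis`` — distance between group centroids standardised by the
  pooled within-group covariance.  With far more coordinates than
  specimens the pooled covariance is rank deficient, so it is inverted by
  Moore-Penrose pseudo-inverse on the subspace spanned by the data; the
  flag travels in the result metadata.

P-values come from pairwise permutation tests: the two groups' specimens
are pooled, labels reshuffled, the distance recomputed, and
p = (#{permuted >= observed} + 1) / (rounds + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .superimpose import optimal_rotation

METRICS = ("mahalanobis", "procrustes", "euclidean")


@dataclass
class DistanceTable:
    groups: list[str]
    distances: np.ndarray            # symmetric, zero diagonal
    metric: str
    p_values: Optional[np.ndarray] = None
    n_permutations: int = 0
    seed: Optional[int] = None
    notes: str = ""

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.groups, columns=self.groups)

    def p_frame(self) -> Optional[pd.DataFrame]:
        if self.p_values is None:
            return None
        return pd.DataFrame(self.p_values, index=self.groups, columns=self.groups)


def _as_2d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, float)
    return data.reshape(data.shape[0], -1) if data.ndim == 3 else data


def _procrustes_mean_distance(shapes: np.ndarray, sel_a: np.ndarray,
                              sel_b: np.ndarray) -> float:
    """Partial Procrustes distance between the mean shapes of two index sets."""
    ma = shapes[sel_a].mean(axis=0)
    mb = shapes[sel_b].mean(axis=0)
    ma = ma - ma.mean(axis=0)
    mb = mb - mb.mean(axis=0)
    ma /= np.sqrt((ma ** 2).sum())
    mb /= np.sqrt((mb ** 2).sum())
    mb = mb @ optimal_rotation(mb, ma)
    return float(np.sqrt(((ma - mb) ** 2).sum()))


def _mahalanobis_pair(x: np.ndarray, is_b: np.ndarray) -> float:
    """Mahalanobis distance between two groups, pooled pairwise covariance."""
    xa, xb = x[~is_b], x[is_b]
    da = xa - xa.mean(axis=0)
    db = xb - xb.mean(axis=0)
    pooled = (da.T @ da + db.T @ db) / (len(x) - 2)
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    sol = np.linalg.pinv(pooled, rcond=1e-10) @ diff
    return float(np.sqrt(max(diff @ sol, 0.0)))


def _pair_reduce(x: np.ndarray) -> np.ndarray:
    """Rotate pooled data of one pair onto its spanned subspace.

    Mahalanobis/Euclidean distances computed with a pseudo-inverse are
    invariant under this orthonormal reduction, and it makes the 10,000
    permutation rounds affordable.
    """
    c = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(c, full_matrices=False)
    keep = s > s[0] * 1e-10 if s.size and s[0] > 0 else slice(0)
    return u[:, keep] * s[keep]


def group_distance(data: np.ndarray, labels, metric: str,
                   pc_count: Optional[int] = None,
                   groups: Optional[Sequence[str]] = None) -> DistanceTable:
    """Pairwise distances between group centroids under the chosen metric.

    ``data`` is (n, k, 3) aligned coordinates for ``procrustes`` and
    ``mahalanobis``, or an (n, m) score matrix; ``euclidean`` requires
    ``pc_count`` (columns retained).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    labels = np.asarray(labels)
    order = list(groups) if groups is not None else list(dict.fromkeys(labels))
    for g in order:
        if (labels == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    g_count = len(order)
    dist = np.zeros((g_count, g_count))
    notes = ""
    if metric == "euclidean":
        if pc_count is None:
            raise ValueError("euclidean distance requires pc_count")
        x = _as_2d(data)[:, :pc_count]
        means = {g: x[labels == g].mean(axis=0) for g in order}
        for (i, a), (j, b) in combinations(enumerate(order), 2):
            dist[i, j] = dist[j, i] = np.linalg.norm(means[a] - means[b])
    elif metric == "procrustes":
        shapes = np.asarray(data, float)
        if shapes.ndim != 3:
            raise ValueError("procrustes metric needs (n, k, 3) aligned coordinates")
        for (i, a), (j, b) in combinations(enumerate(order), 2):
            dist[i, j] = dist[j, i] = _procrustes_mean_distance(
                shapes, labels == a, labels == b)
    else:  # mahalanobis, pooled within-group covariance across all groups
        x = _as_2d(data)
        n = x.shape[0]
        if n - g_count < x.shape[1]:
            notes = "rank-deficient pooled covariance: Moore-Penrose pseudo-inverse"
        resid = np.vstack([x[labels == g] - x[labels == g].mean(axis=0) for g in order])
        pooled = resid.T @ resid / (n - g_count)
        prec = np.linalg.pinv(pooled, rcond=1e-10)
        means = {g: x[labels == g].mean(axis=0) for g in order}
        for (i, a), (j, b) in combinations(enumerate(order), 2):
            d = means[a] - means[b]
            dist[i, j] = dist[j, i] = np.sqrt(max(d @ prec @ d, 0.0))
    return DistanceTable(groups=[str(g) for g in order], distances=dist,
                         metric=metric, notes=notes)


def permutation_test(data: np.ndarray, labels, metric: str,
                     n_rounds: int = 10000, seed: int = 0,
                     pc_count: Optional[int] = None,
                     groups: Optional[Sequence[str]] = None) -> DistanceTable:
    """Pairwise permutation tests of group centroid distances.

    For each group pair the pooled specimens' labels are reshuffled
    ``n_rounds`` times and the distance recomputed;
    p = (#{permuted >= observed} + 1) / (n_rounds + 1), never zero.
    Per-pair RNG streams are spawned from ``seed`` in pair order, so
    results are reproducible bit-for-bit and independent of which other
    pairs are present.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    table = group_distance(data, labels, metric, pc_count=pc_count, groups=groups)
    labels = np.asarray(labels)
    order = table.groups
    pvals = np.ones((len(order), len(order)))
    shapes3d = np.asarray(data, float) if metric == "procrustes" else None
    x2d = None
    if metric != "procrustes":
        x2d = _as_2d(data)
        if metric == "euclidean":
            x2d = x2d[:, :pc_count]
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(order) * (len(order) - 1) // 2)
    for pair_idx, ((i, a), (j, b)) in enumerate(combinations(enumerate(order), 2)):
        sel = (labels == a) | (labels == b)
        idx = np.flatnonzero(sel)
        nb = int((labels[idx] == b).sum())
        rng = np.random.default_rng(streams[pair_idx])
        if metric == "procrustes":
            pooled = shapes3d[idx]
            observed = _procrustes_mean_distance(
                pooled, labels[idx] == a, labels[idx] == b)

            def stat(is_b, pooled=pooled):
                return _procrustes_mean_distance(pooled, ~is_b, is_b)
        else:
            pooled = _pair_reduce(x2d[idx])
            if metric == "euclidean":
                def stat(is_b, pooled=pooled):
                    return float(np.linalg.norm(
                        pooled[~is_b].mean(axis=0) - pooled[is_b].mean(axis=0)))
            else:
                def stat(is_b, pooled=pooled):
                    return _mahalanobis_pair(pooled, is_b)
            observed = stat(labels[idx] == b)
        count = 0
        base = np.zeros(idx.size, dtype=bool)
        base[:nb] = True
        for _ in range(n_rounds):
            perm = rng.permutation(base)
            if stat(perm) >= observed - 1e-12:
                count += 1
        p = (count + 1) / (n_rounds + 1)
        pvals[i, j] = pvals[j, i] = p
        # keep the pairwise-pooled observed value for consistency with its p
        table.distances[i, j] = table.distances[j, i] = observed
    table.p_values = pvals
    table.n_permutations = n_rounds
    table.seed = seed
    return table


def exact_permutation_p(x_a: np.ndarray, x_b: np.ndarray, metric: str = "euclidean"
                        ) -> float:
    """Exact permutation p by full enumeration of label splits (tiny n only)."""
    pooled = np.vstack([_as_2d(x_a), _as_2d(x_b)])
    n, nb = pooled.shape[0], len(x_b)
    is_b0 = np.zeros(n, dtype=bool)
    is_b0[len(x_a):] = True
    if metric == "euclidean":
        def stat(m):
            return float(np.linalg.norm(pooled[~m].mean(axis=0) - pooled[m].mean(axis=0)))
    else:
        def stat(m):
            return _mahalanobis_pair(pooled, m)
    observed = stat(is_b0)
    count = total = 0
    for comb in combinations(range(n), nb):
        m = np.zeros(n, dtype=bool)
        m[list(comb)] = True
        total += 1
        if stat(m) >= observed - 1e-12:
            count += 1
    return count / total


@dataclass
class AllometryFit:
    component: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    sex_stratum: str = "pooled"


def allometry_scan(scores: np.ndarray, centroid_sizes: np.ndarray,
                   sex_labels=None, strata: bool = False,
                   alpha: float = 0.05) -> list[AllometryFit]:
    """OLS of each shape component against log centroid size.

    One fit per retained component (and per sex stratum when ``strata``);
    ``p_value`` is the two-sided slope test.  The convenience
    :func:`no_significant_allometry` summarises the scan.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    sizes = np.asarray(centroid_sizes, float)
    if np.any(sizes <= 0):
        raise ValueError("centroid sizes must be positive")
    if np.ptp(sizes) == 0:
        raise ValueError("constant size vector: allometric slope undefined")
    logsize = np.log(sizes)
    strata_sets: list[tuple[str, np.ndarray]] = [("pooled", np.ones(len(sizes), bool))]
    if strata:
        if sex_labels is None:
            raise ValueError("strata=True requires sex labels")
        sex = np.asarray(sex_labels)
        base = np.where(np.isin(sex, ["M", "M?"]), "M",
                        np.where(np.isin(sex, ["F", "F?"]), "F", "unknown"))
        for s in ("M", "F"):
            m = base == s
            if m.sum() >= 3:
                strata_sets.append((s, m))
    fits = []
    for stratum, mask in strata_sets:
        design = sm.add_constant(logsize[mask])
        for c in range(scores.shape[1]):
            res = sm.OLS(scores[mask, c], design).fit()
            fits.append(AllometryFit(
                component=c + 1, slope=float(res.params[1]),
                intercept=float(res.params[0]),
                r_squared=float(res.rsquared),
                p_value=float(res.pvalues[1]), sex_stratum=stratum))
    return fits


def no_significant_allometry(fits: list[AllometryFit], alpha: float = 0.05) -> bool:
    """True when no component shows a significant size effect."""
    return all(f.p_value >= alpha for f in fits)


def mean_shape_deviation(mean_a: np.ndarray, mean_b: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-landmark deviation field b - a and its magnitudes.

    Both means must already live in the common superimposition space.
    Returns ``(vectors (k, 3), magnitudes (k,))``.
    """
    a = np.asarray(mean_a, float)
    b = np.asarray(mean_b, float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched schemes: {a.shape} vs {b.shape}")
    vec = b - a
    return vec, np.linalg.norm(vec, axis=1)
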