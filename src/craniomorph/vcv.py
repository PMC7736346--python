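"""Within-group variance comparison via covariance matrices on retained PCs.

Two groups' covariance matrices S_a, S_b are compared through the relative
eigenvalues (eigenvalues of S_b^{-1} S_a):

* a maximum-likelihood proportionality test — under H0: S_a = c S_b all
  relative eigenvalues are equal, and the likelihood-ratio statistic
  measures the dispersion of their logs,
  T = n_eff (k log(mean lambda) - sum log lambda),
  compared to chi-square with k(k+1)/2 - 1 degrees of freedom, where
  n_eff = nu_a nu_b / (nu_a + nu_b) combines the two sample sizes
  (nu = n - 1);
* the ratio of generalized variances det(S_a)/det(S_b), equal to the
  product of the relative eigenvalues: an overall "how much more variable"
  factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.stats import chi2


def group_covariances(scores: np.ndarray, labels, ddof: int = 1,
                      groups: Optional[Sequence[str]] = None
                      ) -> dict[str, tuple[np.ndarray, int]]:
    """Per-group sample covariance of score vectors: group -> (S, n).

    ``ddof=1`` gives the unbiased estimator; ``ddof=0`` the ML variant.
    Warns when a group has too few specimens for a full-rank k x k matrix.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    k = scores.shape[1]
    out: dict[str, tuple[np.ndarray, int]] = {}
    for g in (groups if groups is not None else dict.fromkeys(labels)):
        x = scores[labels == g]
        n = x.shape[0]
        if n < 2:
            raise ValueError(f"group {g!r} has {n} specimen(s); covariance undefined")
        if n < k + 1:
            warnings.warn(f"group {g}: n={n} < k+1={k + 1}, covariance is rank deficient",
                          stacklevel=2)
        d = x - x.mean(axis=0)
        out[str(g)] = (d.T @ d / (n - ddof), n)
    return out


def relative_eigenvalues(s_a: np.ndarray, s_b: np.ndarray) -> np.ndarray:
    """Eigenvalues of S_b^{-1} S_a, descending. Requires invertible S_b."""
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    if s_a.shape != s_b.shape or s_a.shape[0] != s_a.shape[1]:
        raise ValueError("covariance matrices must be square and same shape")
    rank = np.linalg.matrix_rank(s_b)
    if rank < s_b.shape[0]:
        raise np.linalg.LinAlgError(
            f"reference covariance is singular (rank {rank} of {s_b.shape[0]})")
    vals = eigh(s_a, s_b, eigvals_only=True)
    return vals[::-1]


@dataclass
class CovarianceComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    dim: int
    relative_eigenvalues: np.ndarray
    prop_statistic: float
    prop_df: int
    prop_p: float
    gv_ratio: float


def generalized_variance_ratio(s_a: np.ndarray, s_b: np.ndarray) -> float:
    """det(S_a) / det(S_b)."""
    s_a = np.asarray(s_a, float)
    s_b = np.asarray(s_b, float)
    if s_a.shape != s_b.shape or s_a.ndim != 2 or s_a.shape[0] != s_a.shape[1]:
        raise ValueError("inputs must be square matrices of equal size")
    return float(np.linalg.det(s_a) / np.linalg.det(s_b))


def proportionality_test(s_a: np.ndarray, s_b: np.ndarray, n_a: int, n_b: int,
                         group_a: str = "a", group_b: str = "b"
                         ) -> CovarianceComparison:
    """ML test of proportionality between two covariance matrices.

    The statistic is zero exactly when S_a is a scalar multiple of S_b and
    grows with the dispersion of the log relative eigenvalues; the p-value
    uses the chi-square reference with k(k+1)/2 - 1 degrees of freedom.
    """
    lam = relative_eigenvalues(s_a, s_b)
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError("non-positive relative eigenvalues: "
                                    "singular covariance input")
    k = lam.size
    nu_a, nu_b = n_a - 1, n_b - 1
    if nu_a < 1 or nu_b < 1:
        raise ValueError("each group needs n >= 2")
    n_eff = nu_a * nu_b / (nu_a + nu_b)
    stat = float(n_eff * (k * np.log(lam.mean()) - np.log(lam).sum()))
    stat = max(stat, 0.0)  # Jensen guarantees >= 0 up to roundoff
    df = k * (k + 1) // 2 - 1
    p = float(chi2.sf(stat, df))
    return CovarianceComparison(
        group_a=group_a, group_b=group_b, n_a=n_a, n_b=n_b, dim=k,
        relative_eigenvalues=lam, prop_statistic=stat, prop_df=df,
        prop_p=p, gv_ratio=float(np.prod(lam)))


@dataclass
class VarianceComparisonTable:
    """All pairwise covariance comparisons among groups.

    ``prop_p`` holds proportionality-test p-values (upper block of the
    published layout), ``ratios`` the generalized-variance ratios
    row-over-column (lower block); ``significant`` flags p < alpha.
    """
    groups: list[str]
    sizes: dict[str, int]
    comparisons: dict[tuple[str, str], CovarianceComparison]
    alpha: float = 0.05

    def prop_p_frame(self) -> pd.DataFrame:
        return self._frame(lambda c: c.prop_p, symmetric=True)

    def ratio_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(np.nan, index=self.groups, columns=self.groups)
        for (a, b), c in self.comparisons.items():
            out.loc[a, b] = c.gv_ratio
            out.loc[b, a] = 1.0 / c.gv_ratio
        return out

    def significant_frame(self) -> pd.DataFrame:
        return self._frame(lambda c: c.prop_p < self.alpha, symmetric=True)

    def _frame(self, fn, symmetric: bool) -> pd.DataFrame:
        out = pd.DataFrame(np.nan, index=self.groups, columns=self.groups)
        for (a, b), c in self.comparisons.items():
            out.loc[a, b] = fn(c)
            if symmetric:
                out.loc[b, a] = fn(c)
        return out


def variance_comparison_table(scores: np.ndarray, labels,
                              specimen_ids: Optional[Sequence[str]] = None,
                              exclude: Sequence[str] = (),
                              groups: Optional[Sequence[str]] = None,
                              ddof: int = 1, alpha: float = 0.05
                              ) -> VarianceComparisonTable:
    """Pairwise proportionality tests and generalized-variance ratios.

    ``exclude`` drops specimens by id before computing the group
    covariances (the published analysis was re-run without one outlier);
    an exclusion that empties a group is an error.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    labels = np.asarray(labels)
    order = [str(g) for g in (groups if groups is not None else dict.fromkeys(labels))]
    if len(order) < 2:
        raise ValueError("need at least 2 groups")
    keep = np.ones(scores.shape[0], dtype=bool)
    if exclude:
        if specimen_ids is None:
            raise ValueError("exclude requires specimen_ids")
        ids = np.asarray(list(specimen_ids))
        unknown = set(exclude) - set(ids)
        if unknown:
            raise ValueError(f"exclusions name unknown specimens: {sorted(unknown)}")
        keep = ~np.isin(ids, list(exclude))
    scores, labels = scores[keep], labels[keep]
    for g in order:
        if (labels == g).sum() == 0:
            raise ValueError(f"exclusions emptied group {g!r}")
    covs = group_covariances(scores, labels, ddof=ddof, groups=order)
    comparisons = {}
    for a, b in combinations(order, 2):
        sa, na = covs[a]
        sb, nb = covs[b]
        comparisons[(a, b)] = proportionality_test(sa, sb, na, nb, a, b)
    return VarianceComparisonTable(groups=order,
                                   sizes={g: covs[g][1] for g in order},
                                   comparisons=comparisons, alpha=alpha)
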