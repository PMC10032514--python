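"""Mardia's multivariate normality test and PCA with variance reporting.

Mardia's test summarises departure from multivariate normality with two
statistics computed from Mahalanobis forms under the maximum-likelihood
(1/n) covariance S:

    b1p = (1/n^2) sum_ij [ (x_i - xbar)' S^-1 (x_j - xbar) ]^3    (skewness)
    b2p = (1/n)   sum_i  [ (x_i - xbar)' S^-1 (x_i - xbar) ]^2    (kurtosis)

Under normality n*b1p/6 is asymptotically chi-square with p(p+1)(p+2)/6
degrees of freedom, and (b2p - p(p+2)) / sqrt(8 p (p+2) / n) is standard
normal.  Both statistics are invariant under invertible affine transforms of
the data.  With far more features than samples the covariance is singular;
callers are then expected to reduce to PCA scores first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SingularCovarianceError, ValidationError

__all__ = ["MardiaResult", "PcaResult", "mardia_test", "pca"]


@dataclass(frozen=True)
class MardiaResult:
    b1p: float
    b2p: float
    skew_stat: float
    skew_df: int
    kurt_stat: float
    p_skew: float
    p_kurt: float

    @property
    def normal_at(self):
        """Convenience: alpha -> True when neither statistic rejects."""
        return lambda alpha=0.05: self.p_skew >= alpha and self.p_kurt >= alpha


def mardia_test(x) -> MardiaResult:
    """Mardia's multivariate skewness/kurtosis test on samples x features."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("x must be 2-D (samples x features)")
    n, p = x.shape
    if n < p + 2:
        raise SingularCovarianceError(
            f"n={n} samples for p={p} features: covariance is singular; "
            "reduce the data to PCA scores first"
        )
    xc = x - x.mean(axis=0)
    s = xc.T @ xc / n  # maximum-likelihood covariance
    try:
        s_inv = np.linalg.inv(s)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "singular covariance; reduce the data to PCA scores first"
        ) from exc
    if np.linalg.cond(s) > 1e12:
        raise SingularCovarianceError(
            "near-singular covariance; reduce the data to PCA scores first"
        )
    d = xc @ s_inv @ xc.T  # d[i, j] = centered Mahalanobis cross product
    b1p = float((d**3).mean())
    b2p = float((np.diag(d) ** 2).mean())
    skew_df = p * (p + 1) * (p + 2) // 6
    skew_stat = n * b1p / 6.0
    kurt_stat = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    return MardiaResult(
        b1p=b1p,
        b2p=b2p,
        skew_stat=float(skew_stat),
        skew_df=skew_df,
        kurt_stat=float(kurt_stat),
        p_skew=float(stats.chi2.sf(skew_stat, skew_df)),
        p_kurt=float(2.0 * stats.norm.sf(abs(kurt_stat))),
    )


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_pct: np.ndarray  # per-component % of total variance

    def __post_init__(self) -> None:
        if np.any(np.diff(self.explained_pct) > 1e-9):
            raise ValidationError("explained_pct must be nonincreasing")
        if self.explained_pct.sum() > 100 + 1e-9:
            raise ValidationError("explained variance exceeds 100%")


def pca(x, n_components: int) -> PcaResult:
    """Mean-centred PCA via SVD; no unit-variance scaling.

    ``explained_pct`` is each component's percentage of the data's total
    variance (so it sums to <= 100 over the retained components).
    """
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}"
        )
    fit = PCA(n_components=n_components, svd_solver="full").fit(x)
    return PcaResult(
        scores=fit.transform(x),
        loadings=fit.components_.T,
        explained_pct=100.0 * fit.explained_variance_ratio_,
    )
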