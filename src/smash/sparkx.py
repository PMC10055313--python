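"""Re-implementation of the SPARK-X projection-covariance test.

SPARK-X tests each gene against the linear-projection kernel
D = Z(ZᵀZ)⁻¹Zᵀ built from the (possibly element-wise transformed,
column-centered) coordinate matrix Z.  The statistic is the same trace form
as SMASH, T = yᵀDy/(N·yᵀy); its asymptotic null is a weighted mixture of
χ²₁ laws whose weights are products of the ordered eigenvalues of E_k (a
single 1) and of D (r ones, r = rank).  With an exact projection all weights
are equal, so N²·T — which equals N·R², the scaled coefficient of
determination of y on the projected space — follows χ²_r and the p-value is
a plain chi-square upper tail evaluated from the N×r factor, never from an
N×N matrix.  p-values across the identity + 5 Gaussian-transform +
5 cosine-transform projections (11 tests) are combined with the Cauchy rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._exceptions import ValidationError
from .io import PreparedExpression, SpatialDataset, prepare_expression
from .kernels import KernelMatrix, projection_battery
from .multiple_testing import benjamini_yekutieli

CAUCHY_CLIP = 1e-15


@dataclass
class SparkxResult:
    gene_id: str
    per_transform_p: np.ndarray
    combined_p: float
    adjusted_p: float = np.nan
    degenerate: bool = False


def _mixture_pvalue(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Upper tail of Σ wᵢ χ²₁ at x via a moment-matched gamma (fallback for
    numerically unequal projection weights)."""
    mean = weights.sum()
    var = 2.0 * (weights**2).sum()
    shape = mean**2 / var
    scale = var / mean
    return stats.gamma.sf(x, a=shape, scale=scale)


def sparkx_single(
    residual: np.ndarray, sum_sq: float, D: KernelMatrix
) -> tuple[float, float]:
    """Statistic and p-value for one gene against one projection kernel."""
    if D.factor is None or D.spec.family != "projection":
        raise ValidationError("sparkx_single requires a projection kernel")
    if D.rank is None or D.rank < 1:
        raise ValidationError("projection kernel has rank 0")
    if sum_sq <= 0:
        return 0.0, 1.0
    residual = np.asarray(residual, dtype=float)
    N = residual.shape[0]
    q = float(D.quad_form(residual[None, :])[0])
    T = q / (N * sum_sq)
    x = N * q / sum_sq  # = N²·T = N·R²
    if np.allclose(D.weights, 1.0, atol=1e-8):
        p = float(stats.chi2.sf(x, df=D.rank))
    else:
        p = float(_mixture_pvalue(np.array([x]), D.weights)[0])
    return T, p


def cauchy_combine(ps: Sequence[float]) -> float:
    """Cauchy p-value combination: robust to dependence among the tests."""
    p = np.asarray(ps, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty p-value vector")
    p = np.clip(p, CAUCHY_CLIP, 1.0 - CAUCHY_CLIP)
    stat = np.mean(np.tan((0.5 - p) * np.pi))
    return float(np.clip(0.5 - np.arctan(stat) / np.pi, 0.0, 1.0))


def sparkx_pvalue_matrix(
    prep: PreparedExpression, battery: Sequence[KernelMatrix]
) -> np.ndarray:
    """(K × R) chi-square p-values, vectorized over genes per projection."""
    Y = prep.residuals
    K, N = Y.shape
    safe_ss = np.where(prep.degenerate_mask, 1.0, prep.sum_sq)
    pvals = np.ones((K, len(battery)))
    for r, D in enumerate(battery):
        if D.factor is None:
            raise ValidationError("SPARK-X battery must contain projection kernels")
        proj = Y @ D.factor
        q = np.einsum("kr,kr->k", proj * D.weights, proj)
        x = N * q / safe_ss
        if np.allclose(D.weights, 1.0, atol=1e-8):
            pvals[:, r] = stats.chi2.sf(x, df=D.rank)
        else:
            pvals[:, r] = _mixture_pvalue(x, D.weights)
    pvals[prep.degenerate_mask] = 1.0
    return pvals


def run_sparkx(
    prep: PreparedExpression,
    coords: np.ndarray,
    n_transform: int = 5,
) -> list[SparkxResult]:
    """SPARK-X over the default 11-projection battery with Cauchy combination."""
    battery = projection_battery(coords, n_transform)
    pvals = sparkx_pvalue_matrix(prep, battery)
    gene_ids = (
        prep.gene_ids
        if prep.gene_ids is not None
        else np.array([f"gene_{i}" for i in range(prep.n_genes)], dtype=object)
    )
    results = []
    for k in range(prep.n_genes):
        combined = 1.0 if prep.degenerate_mask[k] else cauchy_combine(pvals[k])
        results.append(
            SparkxResult(
                gene_id=str(gene_ids[k]),
                per_transform_p=pvals[k],
                combined_p=combined,
                degenerate=bool(prep.degenerate_mask[k]),
            )
        )
    return results


def results_table(results: Sequence[SparkxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "combined_p_sparkx": [r.combined_p for r in results],
            "adjusted_p_sparkx": [r.adjusted_p for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


class SPARKX(BaseEstimator):
    """SPARK-X projection-covariance test in scikit-learn estimator form.

    ``X`` is the spots × genes expression matrix, ``y`` the N×d coordinates.
    Fitted attributes mirror :class:`~smash.core.SMASH`:
    ``pvalues_`` (Cauchy-combined), ``adjusted_pvalues_`` (BY),
    ``transform_pvalues_`` (per-projection), ``degenerate_``.
    """

    def __init__(
        self,
        n_transform: int = 5,
        transform_choice: str = "none",
        alpha: float = 0.05,
    ) -> None:
        self.n_transform = n_transform
        self.transform_choice = transform_choice
        self.alpha = alpha

    def fit(self, X, y, covariates: Optional[np.ndarray] = None) -> "SPARKX":
        X = check_array(X, dtype=float)
        coords = check_array(y, dtype=float)
        if coords.shape[0] != X.shape[0]:
            raise ValidationError("coordinates must have one row per spot")
        ds = SpatialDataset(
            expression=X.T,
            coords=coords,
            gene_ids=np.array([f"gene_{j}" for j in range(X.shape[1])], dtype=object),
            spot_ids=np.array([f"spot_{i}" for i in range(X.shape[0])], dtype=object),
            covariates=covariates,
        )
        prep = prepare_expression(ds, transform=self.transform_choice)
        battery = projection_battery(coords, self.n_transform)
        pvals = sparkx_pvalue_matrix(prep, battery)
        combined = np.array([cauchy_combine(row) for row in pvals])
        combined[prep.degenerate_mask] = 1.0
        self.transform_pvalues_ = pvals
        self.pvalues_ = combined
        self.adjusted_pvalues_ = benjamini_yekutieli(combined)
        self.degenerate_ = prep.degenerate_mask
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, alpha: Optional[float] = None) -> np.ndarray:
        check_is_fitted(self, "adjusted_pvalues_")
        a = self.alpha if alpha is None else alpha
        return self.adjusted_pvalues_ < a

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "adjusted_pvalues_")
        X = check_array(X, dtype=float)
        return X[:, self.get_support()]

    def fit_transform(self, X, y, **fit_params) -> np.ndarray:
        return self.fit(X, y, **fit_params).transform(X)
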