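"""The SMASH kernel-covariance test for spatially variable genes.

For gene k with mean-zero (covariate-residualized) expression y over N spots
and a spatial kernel matrix H(S), the statistic is

    T = tr(E_k H(S)) / N = yᵀ H y / (N · yᵀy),

where E_k = y(yᵀy)⁻¹yᵀ is the rank-one normalized expression covariance
(tr E_k = tr E_k² = 1).  Under the null of no spatial association T follows a
weighted mixture of χ²₁ laws; evaluating that mixture exactly would need the
eigenvalues of H (O(N³)), so the null is approximated by a gamma distribution
matched to the first two moments

    E(T) = tr(H̃)/N²,     V(T) = 2·tr(H̃²)/N⁴,

computed on the doubly centered kernel H̃ = CHC (y is mean-zero, so
yᵀHy = yᵀH̃y, and the centered moments match the permutation null).  Per-kernel
p-values across a battery of R kernels are combined with the Bonferroni-style
minimum-p rule min(1, R·min p), which is slightly conservative; a Cauchy
combination is available as an alternative.

The whole pipeline is wrapped in the scikit-learn style estimator
:class:`SMASH` (fit on a spots × genes matrix with the coordinates as ``y``).
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
from .kernels import KernelMatrix, default_battery
from .multiple_testing import benjamini_yekutieli

P_FLOOR = 1e-300


@dataclass
class GeneTestResult:
    """Per-gene SMASH output: per-kernel statistics/p-values and combined p."""

    gene_id: str
    per_kernel_stat: np.ndarray
    per_kernel_p: np.ndarray
    combined_p: float
    adjusted_p: float = np.nan
    degenerate: bool = False


def smash_statistic(residual: np.ndarray, sum_sq: float, H: KernelMatrix) -> float:
    """T = yᵀHy/(N·yᵀy) for one mean-zero residual vector."""
    residual = np.asarray(residual, dtype=float)
    if sum_sq <= 0:
        raise ValidationError("sum_sq must be positive (degenerate gene)")
    N = residual.shape[0]
    return float(H.quad_form(residual[None, :])[0] / (N * sum_sq))


def gamma_pvalue(
    T: np.ndarray | float,
    trace_centered: float,
    trace_sq_centered: float,
    N: int,
) -> np.ndarray | float:
    """Upper-tail gamma p-value for the trace statistic (vectorized in T).

    Moment matching: shape θ₁ = E(T)²/V(T), scale θ₂ = V(T)/E(T).  Returns 1
    when the kernel's centered mean is non-positive (no usable signal
    direction).  p-values are floored at 1e−300 to keep −log10 p finite.
    """
    T_arr = np.asarray(T, dtype=float)
    if not (np.isfinite(T_arr).all() and np.isfinite([trace_centered, trace_sq_centered]).all()):
        raise ValidationError("non-finite inputs to gamma_pvalue")
    if trace_sq_centered <= 0:
        raise ValidationError("trace_sq_centered must be positive")
    ET = trace_centered / N**2
    VT = 2.0 * trace_sq_centered / N**4
    if ET <= 0:
        out = np.ones_like(T_arr)
        return float(out) if np.isscalar(T) else out
    shape = ET**2 / VT
    scale = VT / ET
    p = stats.gamma.sf(T_arr, a=shape, scale=scale)
    p = np.clip(p, P_FLOOR, 1.0)
    return float(p) if np.isscalar(T) else p


def combine_min_p(per_kernel_p: Sequence[float]) -> float:
    """Bonferroni-calibrated minimum-p combination: min(1, R·min p)."""
    p = np.asarray(per_kernel_p, dtype=float)
    if p.size == 0:
        raise ValidationError("cannot combine an empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return float(min(1.0, p.size * p.min()))


def _battery_pvalues(
    prep: PreparedExpression,
    kernel_battery: Sequence[KernelMatrix],
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(K × R) statistics and gamma p-values; kernels outer, genes vectorized.

    One kernel is resident at a time; per kernel the cost is one K×N by N×N
    product, O(N²K) over the battery for the dense families.
    """
    if len(kernel_battery) == 0:
        raise ValidationError("kernel battery is empty")
    Y = prep.residuals
    K, N = Y.shape
    safe_ss = np.where(prep.degenerate_mask, 1.0, prep.sum_sq)
    stats_mat = np.zeros((K, len(kernel_battery)))
    pvals = np.ones((K, len(kernel_battery)))
    for r, km in enumerate(kernel_battery):
        if km.n_spots != N:
            raise ValidationError(
                f"kernel {r} has {km.n_spots} spots, expression has {N}"
            )
        T = km.quad_form(Y) / (N * safe_ss)
        T[prep.degenerate_mask] = 0.0
        tc = km.trace_centered if center else km.trace_raw
        tsc = km.trace_sq_centered if center else km.trace_sq_raw
        stats_mat[:, r] = T
        pvals[:, r] = gamma_pvalue(T, tc, tsc, N)
    pvals[prep.degenerate_mask] = 1.0
    return stats_mat, pvals


def run_smash(
    prep: PreparedExpression,
    kernel_battery: Sequence[KernelMatrix],
    combine: str = "minp",
    center: bool = True,
) -> list[GeneTestResult]:
    """Run the SMASH battery on prepared expression; one result per gene."""
    from .sparkx import cauchy_combine  # local import avoids a cycle

    stats_mat, pvals = _battery_pvalues(prep, kernel_battery, center=center)
    gene_ids = (
        prep.gene_ids
        if prep.gene_ids is not None
        else np.array([f"gene_{i}" for i in range(prep.n_genes)], dtype=object)
    )
    results = []
    for k in range(prep.n_genes):
        if prep.degenerate_mask[k]:
            combined = 1.0
        elif combine == "minp":
            combined = combine_min_p(pvals[k])
        elif combine == "cauchy":
            combined = cauchy_combine(pvals[k])
        else:
            raise ValidationError(f"unknown combination rule: {combine!r}")
        results.append(
            GeneTestResult(
                gene_id=str(gene_ids[k]),
                per_kernel_stat=stats_mat[k],
                per_kernel_p=pvals[k],
                combined_p=combined,
                degenerate=bool(prep.degenerate_mask[k]),
            )
        )
    return results


def rank_results(results: Sequence[GeneTestResult]) -> list[GeneTestResult]:
    """Deterministic ranking: combined p ↑, then max per-kernel stat ↓, then id."""
    return sorted(
        results,
        key=lambda r: (r.combined_p, -float(np.max(r.per_kernel_stat)), r.gene_id),
    )


def results_table(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        best = int(np.argmin(r.per_kernel_p))
        rows.append(
            {
                "gene_id": r.gene_id,
                "combined_p_smash": r.combined_p,
                "adjusted_p_smash": r.adjusted_p,
                "best_kernel_index": best,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


class SMASH(BaseEstimator):
    """Non-parametric kernel-covariance test for spatially variable genes.

    Follows the scikit-learn feature-selection convention: ``X`` is the
    spots × genes expression matrix, ``y`` the N×d spot coordinates.  After
    ``fit``, each gene (column) carries a combined p-value; ``transform``
    keeps the columns called spatially variable at ``alpha`` after
    Benjamini–Yekutieli adjustment.

    Parameters
    ----------
    n_lengthscales, n_periods : int
        Sizes of the data-driven Gaussian/cosine parameter grids.
    include_projection : bool
        Whether to add the 11 linear-projection kernels to the battery.
    combine : {"minp", "cauchy"}
        Rule for combining the per-kernel p-values.
    center_kernel : bool
        Compute the gamma moments on the doubly-centered kernel (default).
    transform_choice : {"none", "log1p_libnorm"}
        Expression preprocessing before residualization.
    alpha : float
        FDR level used by ``get_support``/``transform``.
    subsample_cap : int
        Spot subsample cap for the data-driven parameter grids.
    random_state : int
        Seed for the grid subsampling.

    Attributes
    ----------
    pvalues_ : (n_genes,) combined p-values.
    adjusted_pvalues_ : (n_genes,) BY-adjusted p-values.
    statistics_ : (n_genes, R) per-kernel trace statistics.
    kernel_pvalues_ : (n_genes, R) per-kernel gamma p-values.
    kernel_specs_ : list of KernelSpec for the battery used.
    degenerate_ : (n_genes,) boolean mask of numerically constant genes.
    """

    def __init__(
        self,
        n_lengthscales: int = 10,
        n_periods: int = 10,
        include_projection: bool = True,
        combine: str = "minp",
        center_kernel: bool = True,
        transform_choice: str = "none",
        alpha: float = 0.05,
        subsample_cap: int = 1000,
        random_state: int = 0,
    ) -> None:
        self.n_lengthscales = n_lengthscales
        self.n_periods = n_periods
        self.include_projection = include_projection
        self.combine = combine
        self.center_kernel = center_kernel
        self.transform_choice = transform_choice
        self.alpha = alpha
        self.subsample_cap = subsample_cap
        self.random_state = random_state

    def _prepare(self, X, y, covariates) -> tuple[PreparedExpression, np.ndarray]:
        X = check_array(X, dtype=float)
        coords = check_array(y, dtype=float)
        if coords.shape[0] != X.shape[0]:
            raise ValidationError(
                "coordinates must have one row per spot (row of X)"
            )
        ds = SpatialDataset(
            expression=X.T,
            coords=coords,
            gene_ids=np.array([f"gene_{j}" for j in range(X.shape[1])], dtype=object),
            spot_ids=np.array([f"spot_{i}" for i in range(X.shape[0])], dtype=object),
            covariates=covariates,
        )
        return prepare_expression(ds, transform=self.transform_choice), coords

    def _battery(self, coords: np.ndarray) -> list[KernelMatrix]:
        return default_battery(
            coords,
            n_lengthscales=self.n_lengthscales,
            n_periods=self.n_periods,
            include_projection=self.include_projection,
            subsample_cap=self.subsample_cap,
            seed=self.random_state,
        )

    def fit(self, X, y, covariates: Optional[np.ndarray] = None) -> "SMASH":
        prep, coords = self._prepare(X, y, covariates)
        battery = self._battery(coords)
        stats_mat, pvals = _battery_pvalues(prep, battery, center=self.center_kernel)
        from .sparkx import cauchy_combine

        if self.combine == "minp":
            combined = np.minimum(1.0, pvals.shape[1] * pvals.min(axis=1))
        elif self.combine == "cauchy":
            combined = np.array([cauchy_combine(row) for row in pvals])
        else:
            raise ValidationError(f"unknown combination rule: {self.combine!r}")
        combined[prep.degenerate_mask] = 1.0
        self.statistics_ = stats_mat
        self.kernel_pvalues_ = pvals
        self.pvalues_ = combined
        self.adjusted_pvalues_ = benjamini_yekutieli(combined)
        self.kernel_specs_ = [km.spec for km in battery]
        self.degenerate_ = prep.degenerate_mask
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X[0])
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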