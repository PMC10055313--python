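"""Spatial kernel (covariance) matrices and their trace summaries.

Three kernel families over spot coordinates are supported:

* ``gaussian`` — H_ij = exp(−‖s_i − s_j‖² / (2 l²)), lengthscale l;
* ``cosine`` — H_ij = cos(2π ‖s_i − s_j‖ / p), period p;
* ``projection`` — the linear-kernel matrix D = Z(ZᵀZ)⁻¹Zᵀ, where Z is the
  column-centered coordinate matrix or an element-wise Gaussian/cosine
  transformation of it.  D is the orthogonal projection onto the (transformed)
  coordinate space and is stored through its N×r orthonormal factor, never as
  a dense N×N matrix.

The trace summaries tr(H̃) and tr(H̃²) of the doubly-centered kernel
H̃ = C H C (C = I − 11ᵀ/N) feed the moment-matched gamma null; both are
computed in O(N²) without extra N×N allocations beyond one working copy.
Raw (uncentered) summaries are kept alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._exceptions import ValidationError

GRAM_RANK_TOL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Identity of one kernel: family plus its parameter(s).

    For the projection family, ``transform`` names the element-wise map
    applied to the coordinates before projecting (identity, gaussian_transform
    with scale σ, or cosine_transform with period p)."""

    family: str  # gaussian | cosine | projection
    parameter: Optional[float] = None  # lengthscale l / period p
    transform: str = "identity"  # projection family only
    transform_parameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "cosine", "projection"):
            raise ValidationError(f"unknown kernel family: {self.family!r}")
        if self.family in ("gaussian", "cosine"):
            if self.parameter is None or self.parameter <= 0:
                raise ValidationError(f"{self.family} kernel needs a positive parameter")
        if self.transform not in ("identity", "gaussian_transform", "cosine_transform"):
            raise ValidationError(f"unknown transform: {self.transform!r}")
        if self.transform != "identity" and (
            self.transform_parameter is None or self.transform_parameter <= 0
        ):
            raise ValidationError("transform needs a positive parameter")

    def label(self) -> str:
        if self.family == "projection":
            if self.transform == "identity":
                return "projection"
            return f"projection:{self.transform}={self.transform_parameter:.4g}"
        return f"{self.family}={self.parameter:.4g}"


class KernelMatrix:
    """One realized kernel on a fixed set of spots.

    Dense families store H (N×N); the projection family stores only the
    orthonormal factor Q with H = QQᵀ.  ``quad_form`` evaluates yᵀHy for a
    batch of row vectors, which is all the tests need.
    """

    def __init__(
        self,
        spec: KernelSpec,
        H: Optional[np.ndarray] = None,
        factor: Optional[np.ndarray] = None,
        weights: Optional[np.ndarray] = None,
    ) -> None:
        self.spec = spec
        self._H = H
        self.factor = factor
        if factor is not None:
            r = factor.shape[1]
            self.rank = r
            self.weights = np.ones(r) if weights is None else weights
            # centered coordinate columns ⇒ Q ⊥ 1 ⇒ CHC = H = QQᵀ
            self.trace_centered = float(self.weights.sum())
            self.trace_sq_centered = float((self.weights**2).sum())
            self.trace_raw = self.trace_centered
            self.trace_sq_raw = self.trace_sq_centered
            self.n_spots = factor.shape[0]
        else:
            assert H is not None
            if not np.allclose(H, H.T, atol=1e-10):
                raise ValidationError("kernel matrix must be symmetric")
            self.rank = None
            self.weights = None
            self.n_spots = H.shape[0]
            self.trace_raw = float(np.trace(H))
            self.trace_sq_raw = float(np.einsum("ij,ij->", H, H))
            self.trace_centered, self.trace_sq_centered = center_summaries(H)

    def dense(self) -> np.ndarray:
        if self._H is not None:
            return self._H
        return self.factor @ self.factor.T

    def quad_form(self, Y: np.ndarray) -> np.ndarray:
        """yᵀ H y for each row y of Y, vectorized over rows."""
        Y = np.atleast_2d(Y)
        if Y.shape[1] != self.n_spots:
            raise ValidationError(
                f"expression has {Y.shape[1]} spots, kernel has {self.n_spots}"
            )
        if self.factor is not None:
            proj = Y @ self.factor
            return np.einsum("kr,kr->k", proj * self.weights, proj)
        return np.einsum("kn,kn->k", Y @ self._H, Y)


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise ValidationError("coords must be 2-D")
    if not np.isfinite(coords).all():
        raise ValidationError("coordinates contain non-finite values")
    return squareform(pdist(coords))


def gaussian_kernel(coords: np.ndarray, lengthscale: float) -> KernelMatrix:
    """Gaussian (squared-exponential) kernel with lengthscale ``l``."""
    if lengthscale <= 0:
        raise ValidationError("lengthscale must be positive")
    D = _pairwise_distances(coords)
    H = np.exp(-(D**2) / (2.0 * lengthscale**2))
    return KernelMatrix(KernelSpec("gaussian", float(lengthscale)), H=H)


def cosine_kernel(coords: np.ndarray, period: float) -> KernelMatrix:
    """Cosine kernel cos(2π‖s_i − s_j‖/p) with period ``p``."""
    if period <= 0:
        raise ValidationError("period must be positive")
    D = _pairwise_distances(coords)
    H = np.cos(2.0 * np.pi * D / period)
    return KernelMatrix(KernelSpec("cosine", float(period)), H=H)


def projection_kernel(
    coords: np.ndarray,
    transform: str = "identity",
    parameter: Optional[float] = None,
) -> KernelMatrix:
    """Projection (linear) kernel D = Z(ZᵀZ)⁻¹Zᵀ on transformed coordinates.

    The element-wise transform is applied per coordinate, the result is
    column-centered, and the orthonormal basis of its column space is found
    by SVD of the N×d matrix (never an N×N eigenproblem).  Eigenvalues of the
    d×d Gram below GRAM_RANK_TOL × largest are treated as rank deficiency.
    """
    Z = np.asarray(coords, dtype=float)
    if not np.isfinite(Z).all():
        raise ValidationError("coordinates contain non-finite values")
    if transform == "identity":
        pass
    elif transform == "gaussian_transform":
        if parameter is None or parameter <= 0:
            raise ValidationError("gaussian_transform needs a positive scale")
        Z = np.exp(-(Z**2) / (2.0 * parameter**2))
    elif transform == "cosine_transform":
        if parameter is None or parameter <= 0:
            raise ValidationError("cosine_transform needs a positive period")
        Z = np.cos(2.0 * np.pi * Z / parameter)
    else:
        raise ValidationError(f"unknown transform: {transform!r}")
    Zc = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValidationError("transformed coordinates have zero variance")
    keep = s > GRAM_RANK_TOL**0.5 * s[0]  # singular values; Gram eigenvalues are s²
    if not keep.any():
        raise ValidationError("transformed coordinates have zero variance")
    Q = U[:, keep]
    spec = KernelSpec(
        "projection",
        transform=transform,
        transform_parameter=None if parameter is None else float(parameter),
    )
    return KernelMatrix(spec, factor=Q)


def center_summaries(H: np.ndarray) -> tuple[float, float]:
    """tr(H̃) and tr(H̃²) for the doubly centered H̃ = C H C, in O(N²)."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValidationError("H must be square")
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValidationError("H must be symmetric")
    N = H.shape[0]
    row_mean = H.mean(axis=0)
    grand_mean = row_mean.mean()
    trace_centered = float(np.trace(H) - N * grand_mean)
    Ht = H - row_mean[None, :]
    Ht -= row_mean[:, None]
    Ht += grand_mean
    trace_sq_centered = float(np.einsum("ij,ij->", Ht, Ht))
    return trace_centered, max(trace_sq_centered, 0.0)


def data_driven_grid(
    coords: np.ndarray,
    n_values: int = 10,
    family: str = "gaussian",
    subsample_cap: int = 1000,
    seed: int = 0,
) -> list[KernelSpec]:
    """Data-driven lengthscale/period grid from the pairwise-distance range.

    Parameters are equally log-spaced between the 1st and 99th percentiles of
    the nonzero pairwise Euclidean distances of a seeded subsample of at most
    ``subsample_cap`` spots, so grid cost is bounded regardless of N.
    """
    if n_values < 1:
        raise ValidationError("n_values must be ≥ 1")
    if family not in ("gaussian", "cosine"):
        raise ValidationError("grid family must be gaussian or cosine")
    coords = np.asarray(coords, dtype=float)
    N = coords.shape[0]
    rng = np.random.default_rng(seed)
    if N > subsample_cap:
        idx = rng.choice(N, size=subsample_cap, replace=False)
        coords = coords[idx]
    dists = pdist(coords)
    dists = dists[dists > 0]
    if dists.size == 0:
        raise ValidationError("all pairwise distances are zero (coincident spots)")
    lo, hi = np.percentile(dists, [1.0, 99.0])
    lo = max(lo, np.finfo(float).tiny)
    hi = max(hi, lo)
    values = np.geomspace(lo, hi, n_values) if n_values > 1 else np.array(
        [np.sqrt(lo * hi)]
    )
    return [KernelSpec(family, float(v)) for v in values]


def transform_parameter_grid(coords: np.ndarray, n_values: int = 5) -> np.ndarray:
    """Scale/period parameters for the projection-kernel transforms.

    Taken as evenly spaced quantiles ({0.1, 0.3, ...} for the default 5) of
    the absolute centered coordinate values pooled over axes.
    """
    coords = np.asarray(coords, dtype=float)
    pooled = np.abs(coords - coords.mean(axis=0)).ravel()
    qs = (np.arange(n_values) + 0.5) / n_values
    vals = np.quantile(pooled, qs)
    return np.maximum(vals, 1e-8)


def projection_battery(coords: np.ndarray, n_transform: int = 5) -> list[KernelMatrix]:
    """Identity + Gaussian-transform + cosine-transform projection kernels
    (the SPARK-X battery; 11 kernels with the default ``n_transform=5``)."""
    params = transform_parameter_grid(coords, n_transform)
    battery = [projection_kernel(coords)]
    battery += [projection_kernel(coords, "gaussian_transform", p) for p in params]
    battery += [projection_kernel(coords, "cosine_transform", p) for p in params]
    return battery


def default_battery(
    coords: np.ndarray,
    n_lengthscales: int = 10,
    n_periods: int = 10,
    include_projection: bool = True,
    n_transform: int = 5,
    subsample_cap: int = 1000,
    seed: int = 0,
) -> list[KernelMatrix]:
    """The full SMASH battery: Gaussian grid + cosine grid + projections (R=31)."""
    battery: list[KernelMatrix] = []
    for spec in data_driven_grid(coords, n_lengthscales, "gaussian", subsample_cap, seed):
        battery.append(gaussian_kernel(coords, spec.parameter))
    for spec in data_driven_grid(coords, n_periods, "cosine", subsample_cap, seed):
        battery.append(cosine_kernel(coords, spec.parameter))
    if include_projection:
        battery += projection_battery(coords, n_transform)
    return battery
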