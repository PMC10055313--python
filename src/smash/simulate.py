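"""Synthetic spatial transcriptomics generators with known ground truth.

Two generative regimes cover the study conditions used throughout the
package's evaluation:

* **Count patterns** (:func:`simulate_setup1`): spot locations from a
  homogeneous Poisson point process on the unit square (uniform conditioned
  on N); 20% of spots form a spatial pattern (streak — a band of the largest
  x-coordinates; hotspot — a disc of spots nearest the center); per-gene
  negative-binomial counts whose mean is elevated by a fold-change on the
  pattern (reverse variants elevate the background instead).  fold = 1 is
  the null: no spatial structure.

* **Gaussian-process fields** (:func:`simulate_gp`): uniform locations;
  each gene drawn i.i.d. from N(0, h·K + (1−h)·I) where K is a Gaussian or
  cosine kernel on the locations.  Total variance is fixed at τ² + σ² = 1
  with spatial share τ² = h, so h is the effect size and h = 0 the null.
  The cosine kernel need not be positive semidefinite on 2-D Euclidean
  distances, so negative eigenvalues of K are clipped to zero before
  factorizing.

All generators are pure functions of their config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._exceptions import ValidationError
from .io import SpatialDataset
from .kernels import cosine_kernel, gaussian_kernel

PATTERNS = ("streak", "reverse_streak", "hotspot", "reverse_hotspot")


@dataclass(frozen=True)
class Setup1Config:
    """Negative-binomial pattern simulation (counts)."""

    N: int = 1000
    K: int = 500
    pattern: str = "streak"
    fold: float = 3.0
    pattern_fraction: float = 0.2
    background_mean: float = 0.5
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern: {self.pattern!r}")
        if self.fold < 1:
            raise ValidationError("fold must be ≥ 1 (1 = null)")
        if not 0 < self.pattern_fraction < 1:
            raise ValidationError("pattern_fraction must lie in (0, 1)")
        if self.background_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("background_mean and dispersion must be positive")


@dataclass(frozen=True)
class GPConfig:
    """Gaussian-process (multivariate-normal) simulation."""

    N: int = 1000
    K: int = 1000
    kernel_family: str = "gaussian"
    kernel_parameter: float = 0.2
    h: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_family not in ("gaussian", "cosine"):
            raise ValidationError("kernel_family must be gaussian or cosine")
        if not 0 <= self.h < 1:
            raise ValidationError("h must lie in [0, 1)")
        if self.kernel_parameter <= 0:
            raise ValidationError("kernel_parameter must be positive")


@dataclass
class SimulatedDataset:
    """A generated dataset plus the per-gene truth labels for power curves."""

    dataset: SpatialDataset
    truth: np.ndarray  # True where the gene carries spatial signal
    config: object
    pattern_mask: Optional[np.ndarray] = None  # setup-1 on-pattern spots


def _ids(K: int, N: int) -> tuple[np.ndarray, np.ndarray]:
    genes = np.array([f"gene_{i:05d}" for i in range(K)], dtype=object)
    spots = np.array([f"spot_{i:05d}" for i in range(N)], dtype=object)
    return genes, spots


def _pattern_mask(coords: np.ndarray, pattern: str, n_pattern: int) -> np.ndarray:
    """Exactly n_pattern spots flagged; streak = largest-x band, hotspot =
    nearest-to-center disc (reverse variants share the geometry)."""
    N = coords.shape[0]
    if pattern in ("streak", "reverse_streak"):
        order = np.argsort(coords[:, 0])[::-1]
    else:
        dist = np.linalg.norm(coords - 0.5, axis=1)
        order = np.argsort(dist)
    mask = np.zeros(N, dtype=bool)
    mask[order[:n_pattern]] = True
    return mask


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float, size) -> np.ndarray:
    # mean/dispersion parameterization: var = μ + μ²/θ
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def simulate_setup1(cfg: Setup1Config) -> SimulatedDataset:
    """Negative-binomial counts with one of four mean-shift spatial patterns."""
    rng = np.random.default_rng(cfg.seed)
    coords = rng.uniform(0.0, 1.0, size=(cfg.N, 2))
    n_pattern = int(round(cfg.pattern_fraction * cfg.N))
    if n_pattern < 1:
        raise ValidationError("pattern_fraction·N rounds to zero spots")
    mask = _pattern_mask(coords, cfg.pattern, n_pattern)
    mean = np.full(cfg.N, cfg.background_mean)
    if cfg.pattern.startswith("reverse"):
        mean[~mask] = cfg.background_mean * cfg.fold
    else:
        mean[mask] = cfg.background_mean * cfg.fold
    counts = _nb_draw(rng, mean[None, :], cfg.dispersion, size=(cfg.K, cfg.N))
    genes, spots = _ids(cfg.K, cfg.N)
    ds = SpatialDataset(counts, coords, genes, spots)
    truth = np.full(cfg.K, cfg.fold != 1.0)
    return SimulatedDataset(ds, truth, cfg, pattern_mask=mask)


def simulate_gp(cfg: GPConfig) -> SimulatedDataset:
    """Multivariate-normal expression with covariance h·K + (1−h)·I."""
    rng = np.random.default_rng(cfg.seed)
    coords = rng.uniform(0.0, 1.0, size=(cfg.N, 2))
    if cfg.h > 0:
        if cfg.kernel_family == "gaussian":
            Ksp = gaussian_kernel(coords, cfg.kernel_parameter).dense()
        else:
            Ksp = cosine_kernel(coords, cfg.kernel_parameter).dense()
        if not np.isfinite(Ksp).all():
            raise ValidationError("kernel matrix contains non-finite values")
        evals, evecs = np.linalg.eigh(Ksp)
        evals = np.clip(evals, 0.0, None)
        # clipping inflates the diagonal (cosine kernels are indefinite in
        # 2-D); rescale so the spatial component keeps unit marginal variance
        # and τ² + σ² = 1 holds for the generated genes
        evals /= evals.sum() / cfg.N
        A = evecs * np.sqrt(evals)  # A Aᵀ = clipped, diag-normalized K
        Y = np.sqrt(cfg.h) * (rng.standard_normal((cfg.K, cfg.N)) @ A.T)
        Y += np.sqrt(1.0 - cfg.h) * rng.standard_normal((cfg.K, cfg.N))
    else:
        Y = rng.standard_normal((cfg.K, cfg.N))
    genes, spots = _ids(cfg.K, cfg.N)
    ds = SpatialDataset(Y, coords, genes, spots)
    truth = np.full(cfg.K, cfg.h > 0)
    return SimulatedDataset(ds, truth, cfg)


DEFAULT_KERNEL_PARAMS = {"2": (0.05, 0.1, 0.2, 0.4), "3": (0.5, 1.0, 2.0, 4.0)}


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_battery(
    setup: int,
    N_grid: list[int],
    effect_grid: list[float],
    K: int,
    replicates: int = 5,
    seed: int = 0,
    pattern: str = "streak",
    kernel_parameters: Optional[list[float]] = None,
) -> list[SimulatedDataset]:
    """Cross-product of N × effect (× kernel parameter) × replicate datasets.

    ``effect_grid`` holds fold-changes for setup 1 and effect sizes h for
    setups 2–3.  Setup 2 uses Gaussian kernels (default lengthscales
    0.05–0.4), setup 3 cosine kernels (default periods 0.5–4, anchoring the
    short-period regime where projection tests lose power).
    """
    if setup not in (1, 2, 3):
        raise ValidationError("setup must be 1, 2 or 3")
    if not N_grid or not effect_grid:
        raise ValidationError("grids must be nonempty")
    if setup == 1:
        params: list[Optional[float]] = [None]
    else:
        params = list(
            kernel_parameters
            if kernel_parameters is not None
            else DEFAULT_KERNEL_PARAMS[str(setup)]
        )
    out: list[SimulatedDataset] = []
    index = 0
    for N in N_grid:
        for effect in effect_grid:
            for param in params:
                for _ in range(replicates):
                    s = _child_seed(seed, index)
                    index += 1
                    if setup == 1:
                        cfg1 = Setup1Config(
                            N=N, K=K, pattern=pattern, fold=effect, seed=s
                        )
                        out.append(simulate_setup1(cfg1))
                    else:
                        cfg2 = GPConfig(
                            N=N,
                            K=K,
                            kernel_family="gaussian" if setup == 2 else "cosine",
                            kernel_parameter=float(param),
                            h=effect,
                            seed=s,
                        )
                        out.append(simulate_gp(cfg2))
    return out
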