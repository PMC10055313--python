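"""Power/type-I evaluation, permutation-null calibration and enrichment.

Power is computed exactly as in simulation benchmarking practice: the
fraction of signal genes with raw combined p ≤ α at the nominal level
(α = 0.05 by default), averaged over replicate datasets; cells with no signal
genes (fold = 1 / h = 0) report the same fraction among null genes as the
type-I error.  FDR-adjusted p-values are deliberately not used here — the
adjustment is for real-data gene calling, not for operating characteristics.

The permutation null follows the empirical-calibration recipe: permute the
spot coordinates (expression fixed) B times, re-run the tests, pool the raw
combined p-values, and compare them with uniform quantiles on a QQ plot.

Enrichment of spatially restricted cell-type markers near the top of the
ranked SVG list is scored with the classic unweighted GSEA running-sum
statistic: +1/|G| on set members, −1/(n−|G|) otherwise, ES = max(0, max
running sum).
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, Sequence, Set

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .io import SpatialDataset, prepare_expression
from .kernels import default_battery
from .core import run_smash, rank_results
from .simulate import GPConfig, SimulatedDataset
from .sparkx import run_sparkx

METHODS = ("smash", "sparkx")


def combined_pvalues(
    ds: SpatialDataset,
    method: str,
    grid_seed: int = 0,
    transform: str = "none",
) -> np.ndarray:
    """Raw combined p-values of one method on a dataset (helper used by both
    the power evaluation and the permutation null)."""
    prep = prepare_expression(ds, transform=transform)
    if method == "smash":
        battery = default_battery(ds.coords, seed=grid_seed)
        results = run_smash(prep, battery)
    elif method == "sparkx":
        results = run_sparkx(prep, ds.coords)
    else:
        raise ValidationError(f"unknown method: {method!r}")
    return np.array([r.combined_p for r in results])


def _cell_key(sim: SimulatedDataset) -> tuple:
    cfg = sim.config
    if isinstance(cfg, GPConfig):
        setup = 2 if cfg.kernel_family == "gaussian" else 3
        return (setup, cfg.N, cfg.h, cfg.kernel_parameter)
    return (1, cfg.N, cfg.fold, None)


def evaluate_power(
    datasets: Sequence[SimulatedDataset],
    methods: Iterable[str] = METHODS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate-averaged rejection rates at nominal ``alpha`` per grid cell.

    Returns a tidy table with columns setup, N, effect, kernel_parameter,
    method, metric ("power" or "type_i_error"), rate, replicates.
    """
    methods = list(methods)
    if not datasets:
        raise ValidationError("no datasets to evaluate")
    cells: Dict[tuple, Dict[str, list]] = {}
    for sim in datasets:
        if sim.truth is None:
            raise ValidationError("datasets must carry truth labels")
        key = _cell_key(sim)
        rates = cells.setdefault(key, {m: [] for m in methods})
        seed = getattr(sim.config, "seed", 0)
        signal = sim.truth.astype(bool)
        if not signal.any() and not (~signal).any():
            raise ValidationError("dataset has neither signal nor null genes")
        for m in methods:
            ps = combined_pvalues(sim.dataset, m, grid_seed=seed)
            mask = signal if signal.any() else ~signal
            rates[m].append(float(np.mean(ps[mask] <= alpha)))
    rows = []
    for (setup, N, effect, param), per_method in sorted(
        cells.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3] or 0)
    ):
        null_effect = 1.0 if setup == 1 else 0.0  # fold = 1 / h = 0
        metric = "type_i_error" if effect == null_effect else "power"
        for m, vals in per_method.items():
            rows.append(
                {
                    "setup": setup,
                    "N": N,
                    "effect": effect,
                    "kernel_parameter": param,
                    "method": m,
                    "metric": metric,
                    "rate": float(np.mean(vals)),
                    "replicates": len(vals),
                }
            )
    return pd.DataFrame(rows)


def empirical_null(
    ds: SpatialDataset,
    methods: Iterable[str] = METHODS,
    B: int = 5,
    seed: int = 0,
) -> Dict[str, pd.DataFrame]:
    """Location-permutation empirical null p-values, QQ-ready.

    For each of B seeded permutations of the coordinate rows (expression
    held fixed) the tests are re-run on all genes and the raw combined
    p-values pooled.  Returns, per method, a DataFrame with sorted empirical
    p-values and matching uniform theoretical quantiles.
    """
    if B < 1:
        raise ValidationError("B must be ≥ 1")
    methods = list(methods)
    rng = np.random.default_rng(seed)
    pooled: Dict[str, list] = {m: [] for m in methods}
    for b in range(B):
        perm = rng.permutation(ds.n_spots)
        ds_perm = SpatialDataset(
            ds.expression,
            ds.coords[perm],
            ds.gene_ids,
            ds.spot_ids,
            ds.covariates,
            ds.labels,
        )
        for m in methods:
            pooled[m].append(combined_pvalues(ds_perm, m, grid_seed=seed + b))
    out = {}
    for m in methods:
        ps = np.sort(np.concatenate(pooled[m]))
        n = ps.size
        out[m] = pd.DataFrame(
            {"empirical_p": ps, "uniform_quantile": (np.arange(1, n + 1) - 0.5) / n}
        )
    return out


def enrichment_score(ranked_genes: Sequence[str], gene_set: Set[str]) -> float:
    """Unweighted GSEA enrichment score of ``gene_set`` in a ranked list."""
    if len(gene_set) == 0:
        raise ValidationError("gene set is empty")
    ranked = list(ranked_genes)
    gene_set = set(gene_set)
    if not gene_set.issubset(ranked):
        raise ValidationError("gene_set must be a subset of the ranked genes")
    n, g = len(ranked), len(gene_set)
    if n == g:
        return 1.0
    hit, miss = 1.0 / g, 1.0 / (n - g)
    running = 0.0
    best = 0.0
    for gene in ranked:
        running += hit if gene in gene_set else -miss
        best = max(best, running)
    return best


def marker_sets(ds: SpatialDataset, top_n: int = 50) -> Dict[str, list]:
    """Top-``top_n`` marker genes per label category by fold change.

    Fold change for type m = (mean expression in m + ε)/(mean elsewhere + ε),
    ε = 1e−8; ties broken by gene id.  Categories with < 2 spots are skipped
    with a warning.
    """
    import warnings

    if ds.labels is None:
        raise ValidationError("dataset has no labels")
    labels = np.asarray(ds.labels)
    cats = pd.unique(labels)
    if len(cats) < 2:
        raise ValidationError("need at least 2 label categories")
    eps = 1e-8
    out: Dict[str, list] = {}
    for cat in cats:
        mask = labels == cat
        if mask.sum() < 2:
            warnings.warn(f"label category {cat!r} has < 2 spots; skipped")
            continue
        mean_in = ds.expression[:, mask].mean(axis=1)
        mean_out = ds.expression[:, ~mask].mean(axis=1)
        fold = (mean_in + eps) / (mean_out + eps)
        order = sorted(range(ds.n_genes), key=lambda i: (-fold[i], str(ds.gene_ids[i])))
        out[str(cat)] = [str(ds.gene_ids[i]) for i in order[:top_n]]
    return out


def ranked_gene_list(results: Sequence) -> list:
    """Gene ids from most to least significant (deterministic tie-breaks)."""
    if results and hasattr(results[0], "per_kernel_stat"):
        return [r.gene_id for r in rank_results(results)]
    return [
        r.gene_id
        for r in sorted(results, key=lambda r: (r.combined_p, r.gene_id))
    ]


def overlap_summary(calls_by_method: Dict[str, Set[str]]) -> Dict[frozenset, int]:
    """Venn-partition counts of the SVG sets of ≥ 2 methods.

    The key of each entry is the frozenset of methods whose sets (and only
    whose sets) contain the genes counted; counts sum to |union|.
    """
    if len(calls_by_method) < 2:
        raise ValidationError("need at least 2 methods")
    names = list(calls_by_method)
    universe = set().union(*calls_by_method.values())
    out: Dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set(universe)
            for m in subset:
                inside &= calls_by_method[m]
            for m in names:
                if m not in subset:
                    inside -= calls_by_method[m]
            out[frozenset(subset)] = len(inside)
    return out
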