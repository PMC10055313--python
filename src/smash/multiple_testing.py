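"""FDR adjustment and SVG calling.

Per-gene combined p-values from a kernel battery are dependent in an
arbitrary way, so the Benjamini–Yekutieli procedure (valid under any
dependence) is used rather than Benjamini–Hochberg.  Degenerate genes enter
the adjustment with p = 1: they were tested, so they count toward K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._exceptions import ValidationError


@dataclass
class AdjustedCalls:
    gene_id: str
    combined_p: float
    adjusted_p: float
    is_svg: bool
    alpha: float


def benjamini_yekutieli(ps: np.ndarray) -> np.ndarray:
    """BY-adjusted p-values, returned in input order.

    adjusted_(i) = min over j ≥ i of min(1, c(K)·K·p_(j)/j) with
    c(K) = Σ 1/m — the step-up rule with the harmonic-sum penalty.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.ndim != 1 or ps.size == 0:
        raise ValidationError("ps must be a nonempty 1-D vector")
    if ((ps < 0) | (ps > 1)).any() or not np.isfinite(ps).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(ps, method="fdr_by")[1]


def call_svgs(results: Sequence, alpha: float = 0.05) -> list[AdjustedCalls]:
    """Adjust combined p-values of all tested genes and call SVGs at ``alpha``.

    ``results`` is any sequence of objects with ``gene_id`` and ``combined_p``
    attributes (SMASH or SPARK-X results).  A gene is called when its adjusted
    p is strictly below alpha.
    """
    if len(results) == 0:
        raise ValidationError("no results to adjust")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    ps = np.array([r.combined_p for r in results], dtype=float)
    adj = benjamini_yekutieli(ps)
    calls = []
    for r, p, a in zip(results, ps, adj):
        r.adjusted_p = float(a)
        calls.append(
            AdjustedCalls(
                gene_id=r.gene_id,
                combined_p=float(p),
                adjusted_p=float(a),
                is_svg=bool(a < alpha),
                alpha=alpha,
            )
        )
    return calls
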