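"""Reading, filtering and preparing spatial expression data.

The central container is :class:`SpatialDataset`: a genes × spots expression
matrix together with the spot coordinates and optional per-spot covariates
and cell-type/layer labels.  Expression can be read from a dense CSV/TSV
(first column gene id, header row spot ids) or from a 10x-style MatrixMarket
triplet (``matrix.mtx`` plus one-column gene and barcode sidecar files).

Before testing, each gene vector is residualized on an intercept (and any
covariates) by least squares — the tests operate on mean-zero residuals, so
results are invariant to the location and scale of the raw expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.linalg

from ._exceptions import EmptyResultError, FormatError, ValidationError

logger = logging.getLogger(__name__)

_COORD_NAMES = ("x", "y", "z")


@dataclass
class SpatialDataset:
    """Expression matrix with spatial coordinates and optional annotations.

    Parameters
    ----------
    expression : ndarray of shape (n_genes, n_spots)
        Expression values — counts or normalized values for measured data;
        simulated Gaussian fields may be real-valued.
    coords : ndarray of shape (n_spots, d)
        Spatial coordinates, d = 2 or 3, arbitrary units.
    gene_ids, spot_ids : sequences of unique strings.
    covariates : optional (n_spots, q) array of per-spot covariates.
    labels : optional length-n_spots categorical vector (cell type / layer).
    """

    expression: np.ndarray
    coords: np.ndarray
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    covariates: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        if self.expression.ndim != 2:
            raise ValidationError("expression must be a 2-D genes × spots matrix")
        K, N = self.expression.shape
        if self.coords.ndim != 2 or self.coords.shape[0] != N:
            raise ValidationError(
                f"coords must have one row per spot ({N}), got shape {self.coords.shape}"
            )
        d = self.coords.shape[1]
        if d not in (2, 3):
            raise ValidationError(f"coordinates must be 2- or 3-dimensional, got d={d}")
        if N < d + 2:
            raise ValidationError(f"need at least d+2={d + 2} spots, got {N}")
        if not np.isfinite(self.expression).all():
            raise ValidationError("expression contains non-finite values")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coordinates contain non-finite values")
        if len(self.gene_ids) != K or len(set(self.gene_ids)) != K:
            raise ValidationError("gene_ids must be unique and match expression rows")
        if len(self.spot_ids) != N or len(set(self.spot_ids)) != N:
            raise ValidationError("spot_ids must be unique and match expression columns")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != N:
                raise ValidationError("covariates must have one row per spot")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != N:
                raise ValidationError("labels must have one entry per spot")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_spots(self) -> int:
        return self.expression.shape[1]

    @property
    def n_dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class PreparedExpression:
    """Covariate-residualized, mean-centered expression ready for testing.

    ``residuals`` holds one mean-zero row per gene; ``sum_sq`` the residual
    sum of squares yᵀy; ``degenerate_mask`` flags genes whose residual is
    numerically zero (constant genes, or genes fully explained by the
    covariates) — these receive p = 1 downstream rather than being dropped.
    """

    residuals: np.ndarray
    sum_sq: np.ndarray
    degenerate_mask: np.ndarray
    gene_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_genes(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_spots(self) -> int:
        return self.residuals.shape[1]


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise FormatError(f"could not parse {path}: {exc}") from exc


def _read_dense_expression(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no spot columns found")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values") from exc
    return mat, df.index.to_numpy(dtype=object), df.columns.to_numpy(dtype=object)


def _find_sidecar(mtx_path: Path, candidates: tuple[str, ...]) -> Path:
    for name in candidates:
        p = mtx_path.parent / name
        if p.exists():
            return p
    raise FormatError(
        f"missing sidecar next to {mtx_path}: looked for {', '.join(candidates)}"
    )


def _read_mtx_expression(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    genes_path = _find_sidecar(path, ("genes.tsv", "features.tsv", "genes.txt"))
    barcodes_path = _find_sidecar(path, ("barcodes.tsv", "barcodes.txt"))
    mat = spio.mmread(path)
    mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].to_numpy(object)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].to_numpy(object)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{path}: matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return mat, genes, barcodes


def _coordinate_frame(path: Path, coord_columns: Optional[list[str]]) -> pd.DataFrame:
    df = _read_table(path)
    id_col = df.columns[0]
    if coord_columns is None:
        coord_columns = [c for c in _COORD_NAMES if c in df.columns]
        if len(coord_columns) < 2:
            # fall back to positional: id column first, then the axes
            coord_columns = list(df.columns[1:4])
    if not 2 <= len(coord_columns) <= 3:
        raise FormatError(
            f"{path}: expected 2 or 3 coordinate columns, got {coord_columns}"
        )
    out = df[[id_col] + list(coord_columns)].copy()
    out.columns = ["spot_id"] + list(coord_columns)
    if out["spot_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate spot ids in coordinate table")
    coords = out[coord_columns]
    if not coords.map(np.isreal).all().all():
        raise ValidationError(f"{path}: non-numeric coordinates")
    try:
        out[coord_columns] = coords.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric coordinates") from exc
    return out


def read_dataset(
    expression_path: str | Path,
    coords_path: str | Path,
    covariates_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    format: str = "dense_csv",
    coord_columns: Optional[list[str]] = None,
) -> SpatialDataset:
    """Read expression + coordinates (+ covariates, labels) into a dataset.

    Spots are aligned across all tables by spot id (inner join); the spot
    order of the coordinate table is kept.  The number of spots dropped by
    the join is logged.
    """
    expression_path = Path(expression_path)
    coords_path = Path(coords_path)
    if format == "dense_csv":
        mat, genes, spots = _read_dense_expression(expression_path)
    elif format == "mtx":
        mat, genes, spots = _read_mtx_expression(expression_path)
    else:
        raise ValidationError(f"unknown expression format: {format!r}")
    if len(set(spots)) != len(spots):
        raise ValidationError(f"{expression_path}: duplicate spot ids")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"{expression_path}: duplicate gene ids")

    cf = _coordinate_frame(coords_path, coord_columns)
    col_index = {s: j for j, s in enumerate(spots)}
    keep = cf["spot_id"].map(lambda s: col_index.get(s, -1)).to_numpy()
    kept = keep >= 0
    dropped_coords = int((~kept).sum())
    dropped_expr = len(spots) - int(kept.sum())
    if dropped_coords or dropped_expr:
        logger.info(
            "inner join on spot ids dropped %d coordinate rows and %d expression columns",
            dropped_coords,
            dropped_expr,
        )
    cf = cf.loc[kept]
    order = keep[kept]
    spot_ids = cf["spot_id"].to_numpy(object)
    coords = cf.iloc[:, 1:].to_numpy(float)
    expression = mat[:, order]

    covariates = labels = None
    if covariates_path is not None:
        cov = _read_table(Path(covariates_path)).set_index(
            _read_table(Path(covariates_path)).columns[0]
        )
        try:
            covariates = cov.loc[spot_ids].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValidationError(f"{covariates_path}: missing spot ids {exc}") from exc
    if labels_path is not None:
        lab = _read_table(Path(labels_path))
        lab = lab.set_index(lab.columns[0])
        try:
            labels = lab.loc[spot_ids].iloc[:, 0].to_numpy(object)
        except KeyError as exc:
            raise ValidationError(f"{labels_path}: missing spot ids {exc}") from exc

    return SpatialDataset(expression, coords, genes, spot_ids, covariates, labels)


def write_dataset(ds: SpatialDataset, expression_path: str | Path, coords_path: str | Path) -> None:
    """Write a dataset as dense expression CSV + coordinate CSV (round-trippable)."""
    pd.DataFrame(ds.expression, index=ds.gene_ids, columns=ds.spot_ids).to_csv(
        expression_path, index_label="gene_id"
    )
    cols = list(_COORD_NAMES[: ds.n_dim])
    cf = pd.DataFrame(ds.coords, columns=cols)
    cf.insert(0, "spot_id", ds.spot_ids)
    cf.to_csv(coords_path, index=False)


def filter_genes(ds: SpatialDataset, min_expressed_fraction: float = 0.01) -> SpatialDataset:
    """Keep genes expressed (value > 0) in strictly more than the given
    fraction of spots.  The common choice for sequencing-based platforms is
    0.01, i.e. "expressed in more than 1% of the spots"."""
    if not 0 <= min_expressed_fraction < 1:
        raise ValidationError("min_expressed_fraction must lie in [0, 1)")
    frac = (ds.expression > 0).sum(axis=1) / ds.n_spots
    keep = frac > min_expressed_fraction
    if not keep.any():
        raise EmptyResultError(
            f"no gene is expressed in more than {min_expressed_fraction:.1%} of spots"
        )
    return replace(
        ds,
        expression=ds.expression[keep],
        gene_ids=ds.gene_ids[keep],
    )


def _design_matrix(ds: SpatialDataset) -> np.ndarray:
    N = ds.n_spots
    if ds.covariates is None:
        return np.ones((N, 1))
    X = np.column_stack([np.ones(N), ds.covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(piv[rank:])
        names = ["intercept"] + [f"covariate_{j}" for j in range(ds.covariates.shape[1])]
        raise ValidationError(
            "covariate matrix (with intercept) is rank deficient; "
            f"collinear columns: {[names[j] for j in bad]}"
        )
    return X


DEGENERACY_TOL = 1e-12


def prepare_expression(ds: SpatialDataset, transform: str = "none") -> PreparedExpression:
    """Residualize each gene on an intercept (and covariates, if present).

    ``transform="log1p_libnorm"`` first normalizes each spot's library to the
    median library size and applies log(1 + x).  Default is to test raw
    values; the tests are non-parametric and scale/location invariant.
    """
    Y = ds.expression
    if transform == "log1p_libnorm":
        lib = Y.sum(axis=0)
        med = np.median(lib[lib > 0]) if (lib > 0).any() else 1.0
        scale = np.where(lib > 0, med / np.where(lib > 0, lib, 1.0), 1.0)
        Y = np.log1p(Y * scale)
    elif transform != "none":
        raise ValidationError(f"unknown transform: {transform!r}")

    X = _design_matrix(ds)
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    sum_sq = np.einsum("kn,kn->k", resid, resid)
    degenerate = sum_sq < DEGENERACY_TOL * ds.n_spots
    resid = np.where(degenerate[:, None], 0.0, resid)
    sum_sq = np.where(degenerate, 0.0, sum_sq)
    return PreparedExpression(resid, sum_sq, degenerate, gene_ids=np.asarray(ds.gene_ids))
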