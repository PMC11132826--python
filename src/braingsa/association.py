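"""Map-gene association: Pearson correlation profiles with per-gene p-values.

A brain map is correlated with every background gene's regional expression
profile.  Two-sided p-values come from the t transform
t = r * sqrt(n - 2) / sqrt(1 - r^2).  A leave-one-region-out variant averages
the N leave-one-parcel-out correlations per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BrainMap, ExpressionMatrix

__all__ = [
    "CorrelationProfile",
    "correlate",
    "correlate_loro",
    "correlation_matrix",
    "pearson_pvalues",
    "mean_pairwise_correlation",
]

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-gene Pearson correlations (and p-values) of one brain map."""

    gene_ids: tuple
    r: np.ndarray
    p: np.ndarray
    n_parcels_used: int
    estimator: str = "pearson"

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if not (len(self.gene_ids) == r.size == p.size):
            raise ValueError("gene_ids, r and p must have equal lengths")
        if not np.all(np.isfinite(r)):
            raise ValueError("correlations must be finite")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.gene_ids)})

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_indices(self, genes) -> np.ndarray:
        from .core import MissingGeneError

        idx = self.__dict__["_index"]
        try:
            return np.array([idx[g] for g in genes], dtype=np.intp)
        except KeyError as e:
            raise MissingGeneError(f"gene {e.args[0]!r} not in profile") from e


def _standardize_rows(x: np.ndarray):
    """Rows z-scored by population sd; flat rows become all-zero (flag returned)."""
    z = x - x.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    flat = sd == 0
    sd = np.where(flat, 1.0, sd)
    return z / sd[:, None], flat


def correlation_matrix(gene_values: np.ndarray, map_values: np.ndarray) -> np.ndarray:
    """Pearson correlations of each gene row with each map column.

    ``gene_values`` is (G, N); ``map_values`` is (N,) or (N, M).  Flat gene
    rows or flat maps correlate 0.  Returns (G,) or (G, M).
    """
    gz, _ = _standardize_rows(np.asarray(gene_values, dtype=float))
    mv = np.asarray(map_values, dtype=float)
    squeeze = mv.ndim == 1
    if squeeze:
        mv = mv[:, None]
    mz, _ = _standardize_rows(mv.T)
    r = (gz @ mz.T) / gene_values.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    return r[:, 0] if squeeze else r


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson r at sample size n via the t transform.

    p is clipped into (0, 1]; |r| = 1 maps to the smallest positive float.
    """
    r = np.asarray(r, dtype=float)
    df = n - 2
    if df < 1:
        raise ValueError("need at least 3 observations for a p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
        t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, _TINY, 1.0)


def _check_geometry(brain_map: BrainMap, expr: ExpressionMatrix):
    if brain_map.geometry != expr.geometry:
        raise ValueError("map and expression matrix use different geometries")


def correlate(brain_map: BrainMap, expr: ExpressionMatrix) -> CorrelationProfile:
    """Correlate a brain map with every background gene profile."""
    _check_geometry(brain_map, expr)
    if brain_map.values.std() == 0:
        raise ValueError("cannot correlate a zero-variance map")
    gz, flat = _standardize_rows(expr.values)
    if flat.any():
        logger.warning(
            "%d zero-variance gene profiles recorded as r=0, p=1", int(flat.sum())
        )
    n = expr.geometry.n_parcels
    r = correlation_matrix(expr.values, brain_map.values)
    p = pearson_pvalues(r, n)
    p[flat] = 1.0
    return CorrelationProfile(expr.gene_ids, r, p, n_parcels_used=n)


def correlate_loro(brain_map: BrainMap, expr: ExpressionMatrix) -> CorrelationProfile:
    """Leave-one-region-out correlation profile.

    For each gene, the Pearson correlation is recomputed N times with one
    parcel left out and the N estimates are averaged.  p-values are derived
    from the averaged r at sample size N-1 (a pragmatic convention, recorded
    in ``estimator``).
    """
    _check_geometry(brain_map, expr)
    n = expr.geometry.n_parcels
    if n < 4:
        raise ValueError("leave-one-region-out needs at least 4 parcels")
    if brain_map.values.std() == 0:
        raise ValueError("cannot correlate a zero-variance map")
    acc = np.zeros(expr.n_genes)
    keep = np.ones(n, dtype=bool)
    for left_out in range(n):
        keep[left_out] = False
        acc += correlation_matrix(expr.values[:, keep], brain_map.values[keep])
        keep[left_out] = True
    r = acc / n
    flat = expr.values.std(axis=1) == 0
    p = pearson_pvalues(np.clip(r, -1, 1), n - 1)
    p[flat] = 1.0
    r[flat] = 0.0
    return CorrelationProfile(
        expr.gene_ids, r, p, n_parcels_used=n - 1, estimator="pearson-loro"
    )


def mean_pairwise_correlation(values: np.ndarray) -> float:
    """Mean of the off-diagonal pairwise Pearson correlations between rows.

    Zero-variance rows are excluded (with a logged warning).  Needs at least
    two non-flat rows.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(axis=1)
    if np.any(sd == 0):
        logger.warning("excluding %d zero-variance profiles from co-expression",
                       int((sd == 0).sum()))
        v = v[sd > 0]
    k = v.shape[0]
    if k < 2:
        raise ValueError("need at least two non-degenerate profiles")
    z, _ = _standardize_rows(v)
    c = (z @ z.T) / v.shape[1]
    return float((c.sum() - np.trace(c)) / (k * (k - 1)))
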