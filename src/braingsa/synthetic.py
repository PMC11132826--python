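"""Synthetic data generators.

Produces region geometries, regional expression matrices with controllable
co-expression and bimodality structure, and random / co-expression-targeted
gene sets, so the full analysis is testable without atlas data.

The expression model is a latent-factor model: each gene's regional profile
is a weighted sum of a small number of smooth spatial components (low-order
polynomial functions of the centroid coordinates) plus independent Gaussian
noise.  ``loading_scale`` controls how strongly genes load on the shared
components and therefore the typical within-set co-expression; a
``bimodal_fraction`` of genes load +1 or -1 (split evenly) on one designated
component, so that a brain map aligned with that component correlates
strongly positively with half of those genes and strongly negatively with
the other half -- a bimodal background-correlation histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import (
    BrainMap,
    ExpressionMatrix,
    GeneSet,
    RegionGeometry,
    SearchFailureError,
)

__all__ = [
    "SyntheticSpec",
    "generate_geometry",
    "generate_expression",
    "sample_gene_sets",
    "sample_coexpressed_set",
    "component_map",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression generator.

    Attributes
    ----------
    n_genes, n_parcels
        Background pool size and parcellation size.
    n_latent
        Number of shared smooth spatial components (>= 1).
    loading_scale
        Scale of the Gaussian component loadings; 0 gives independent genes.
    noise_sd
        Standard deviation of the per-gene independent noise (> 0).
    bimodal_fraction
        Fraction of genes loading +/-1 (evenly split) on the designated
        component, inducing bimodal background correlations for maps aligned
        with it.
    brain_specific_fraction
        Fraction of genes labelled brain-specific (top of a seeded per-gene
        tissue-specificity score).
    seed
        Master seed; every generated matrix is a pure function of (spec, seed).
    """

    n_genes: int
    n_parcels: int
    n_latent: int = 3
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    bimodal_fraction: float = 0.0
    brain_specific_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_parcels < 3:
            raise ValueError("n_genes must be >= 1 and n_parcels >= 3")
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.loading_scale < 0:
            raise ValueError("loading_scale must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.bimodal_fraction <= 1.0:
            raise ValueError("bimodal_fraction must be in [0, 1]")
        if not 0.0 <= self.brain_specific_fraction <= 1.0:
            raise ValueError("brain_specific_fraction must be in [0, 1]")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, approximately even lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def generate_geometry(n_parcels: int, seed: int = 0,
                      pair_half_angle: float = 0.07,
                      jitter: float = 0.02) -> RegionGeometry:
    """Parcel centroids on the unit sphere: a paired-site lattice + seeded jitter.

    Evenly spread Fibonacci-lattice sites are each split into a close pair of
    parcels (tangentially offset by ``pair_half_angle`` radians), echoing the
    strongly non-uniform centroid spacing of real parcellations (adjacent
    sub-regions sit far closer than the typical inter-regional distance).
    This heterogeneity matters: it gives the inverse-distance weights a heavy
    tail, so random maps span a wide enough range of Moran's I for the
    subsampling simulator to hit positive autocorrelation targets.  A small
    seeded jitter breaks residual symmetry; all centroids are unit-norm and
    pairwise distinct.
    """
    if n_parcels < 3:
        raise ValueError("n_parcels must be at least 3")
    rng = np.random.default_rng(seed)
    n_sites = (n_parcels + 1) // 2
    sites = _fibonacci_sphere(n_sites)
    ref = np.array([0.513, 0.642, 0.570])  # fixed oblique axis, avoids poles
    tang = np.cross(sites, ref)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    cos_a, sin_a = math.cos(pair_half_angle), math.sin(pair_half_angle)
    pts = []
    for i in range(n_sites):
        for s in (+1.0, -1.0):
            if len(pts) < n_parcels:
                pts.append(cos_a * sites[i] + s * sin_a * tang[i])
    pts = np.array(pts) + jitter * rng.standard_normal((n_parcels, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    ids = [f"P{i + 1:03d}" for i in range(n_parcels)]
    return RegionGeometry(ids, pts)


def _spatial_components(geometry: RegionGeometry, n_latent: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth spatial fields: random linear + quadratic forms of (x, y, z).

    Returns an (n_latent, n_parcels) matrix, each row standardised to zero
    mean and unit variance across parcels.
    """
    xyz = geometry.centroids
    # design: [x, y, z, x^2, y^2, z^2, xy, xz, yz]
    design = np.column_stack([
        xyz,
        xyz ** 2,
        xyz[:, 0] * xyz[:, 1],
        xyz[:, 0] * xyz[:, 2],
        xyz[:, 1] * xyz[:, 2],
    ])
    coeff = rng.standard_normal((n_latent, design.shape[1]))
    comp = coeff @ design.T
    comp -= comp.mean(axis=1, keepdims=True)
    sd = comp.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return comp / sd


def generate_expression(spec: SyntheticSpec, geometry: RegionGeometry) -> ExpressionMatrix:
    """Generate a latent-factor expression matrix on ``geometry``.

    Gene profiles are ``loadings @ components + noise``.  Loadings are
    Gaussian with sd ``loading_scale``; a ``bimodal_fraction`` of genes
    instead load exactly +/-loading_scale (evenly split) on component 0 and
    zero elsewhere.  A ``brain_specific_fraction`` of genes is labelled
    brain-specific via a seeded per-gene specificity score.
    """
    if spec.n_parcels != geometry.n_parcels:
        raise ValueError("spec.n_parcels does not match geometry.n_parcels")
    rng = np.random.default_rng(spec.seed)
    comp = _spatial_components(geometry, spec.n_latent, rng)

    g = spec.n_genes
    loadings = spec.loading_scale * rng.standard_normal((g, spec.n_latent))
    n_bimodal = int(round(spec.bimodal_fraction * g))
    bimodal_component: Optional[int] = None
    if n_bimodal > 0:
        bimodal_component = 0
        which = rng.choice(g, size=n_bimodal, replace=False)
        signs = np.ones(n_bimodal)
        signs[n_bimodal // 2:] = -1.0
        loadings[which] = 0.0
        loadings[which, 0] = signs * spec.loading_scale

    values = loadings @ comp + spec.noise_sd * rng.standard_normal((g, geometry.n_parcels))

    specificity = rng.random(g)
    n_specific = int(round(spec.brain_specific_fraction * g))
    gene_ids = [f"G{i + 1:06d}" for i in range(g)]
    brain_specific = None
    if n_specific > 0:
        top = np.argsort(-specificity, kind="stable")[:n_specific]
        brain_specific = [gene_ids[i] for i in top]

    return ExpressionMatrix(
        gene_ids,
        values,
        geometry,
        brain_specific=brain_specific,
        components=comp,
        bimodal_component=bimodal_component,
    )


def component_map(expr: ExpressionMatrix, component: Optional[int] = None,
                  noise_sd: float = 0.0, seed: int = 0,
                  name: Optional[str] = None) -> BrainMap:
    """Brain map aligned with one latent component of a synthetic matrix.

    By default uses the designated bimodality-inducing component.  Optional
    Gaussian noise (sd relative to the unit-variance component) degrades the
    alignment.
    """
    if expr.components is None:
        raise ValueError("expression matrix carries no latent components")
    if component is None:
        if expr.bimodal_component is None:
            raise ValueError("no designated bimodal component; pass `component`")
        component = expr.bimodal_component
    vals = np.array(expr.components[component], dtype=float)
    if noise_sd > 0:
        vals = vals + noise_sd * np.random.default_rng(seed).standard_normal(vals.size)
    return BrainMap(vals, expr.geometry, name=name or f"component_{component}")


def sample_gene_sets(
    expr: ExpressionMatrix,
    sizes: Sequence[int],
    repeats: int,
    seed: int = 0,
) -> List[GeneSet]:
    """Random gene sets: |sizes| x repeats sets drawn uniformly without replacement.

    Set names encode size and repeat index (``set_s{size}_r{repeat}``).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for s in sizes:
        if not 1 <= s < expr.n_genes:
            raise ValueError(f"set size {s} must be in [1, n_genes)")
    rng = np.random.default_rng(seed)
    ids = np.array(expr.gene_ids)
    out = []
    for rep in range(repeats):
        for s in sizes:
            members = ids[rng.choice(expr.n_genes, size=s, replace=False)]
            out.append(GeneSet(f"set_s{s}_r{rep + 1:02d}", members))
    return out


def _gene_correlation_matrix(expr: ExpressionMatrix) -> np.ndarray:
    z = expr.values - expr.values.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = np.inf  # flat genes correlate 0 with everything
    z /= sd[:, None]
    return (z @ z.T) / expr.geometry.n_parcels


def grow_set_toward_target(
    gene_corr: np.ndarray,
    size: int,
    target: float,
    rng: np.random.Generator,
    n_candidates: int = 64,
    pool: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Greedy growth of a gene set whose mean pairwise correlation tracks ``target``.

    Starts from one random gene and repeatedly adds, from a random candidate
    batch, the gene that keeps the running mean pairwise correlation closest
    to the target.  Returns member indices.
    """
    n = gene_corr.shape[0]
    pool = np.arange(n) if pool is None else np.asarray(pool)
    in_set = np.zeros(n, dtype=bool)
    first = int(rng.choice(pool))
    members = [first]
    in_set[first] = True
    corr_to_members = gene_corr[first].copy()
    pair_sum = 0.0
    for t in range(1, size):
        cand = pool[~in_set[pool]]
        if cand.size > n_candidates:
            cand = rng.choice(cand, size=n_candidates, replace=False)
        new_mean = (pair_sum + corr_to_members[cand]) / (t * (t + 1) / 2)
        g = int(cand[np.argmin(np.abs(new_mean - target))])
        members.append(g)
        in_set[g] = True
        pair_sum += corr_to_members[g]
        corr_to_members += gene_corr[g]
    return np.array(members, dtype=np.intp)


def sample_coexpressed_set(
    expr: ExpressionMatrix,
    size: int,
    target_coexpression: float,
    tolerance: float,
    seed: int = 0,
    max_attempts: int = 50,
    gene_corr: Optional[np.ndarray] = None,
    name: Optional[str] = None,
) -> GeneSet:
    """Sample a gene set whose mean pairwise correlation hits a target.

    Rejection sampling with greedy guided proposals; fails with a
    SearchFailureError (carrying the best value found) after ``max_attempts``.
    ``gene_corr`` can pass a precomputed gene-gene correlation matrix.
    """
    if not -1.0 < target_coexpression < 1.0:
        raise ValueError("target_coexpression must be in (-1, 1)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if not 2 <= size < expr.n_genes:
        raise ValueError("size must be in [2, n_genes)")
    if gene_corr is None:
        gene_corr = _gene_correlation_matrix(expr)
    rng = np.random.default_rng(seed)
    n_pairs = size * (size - 1) / 2
    best_val, best_members = np.inf, None
    for _ in range(max_attempts):
        members = grow_set_toward_target(gene_corr, size, target_coexpression, rng)
        sub = gene_corr[np.ix_(members, members)]
        mean_corr = (sub.sum() - size) / (2 * n_pairs)
        if abs(mean_corr - target_coexpression) <= tolerance:
            ids = [expr.gene_ids[i] for i in members]
            return GeneSet(name or f"coexpr_{target_coexpression:+.2f}_s{size}", ids)
        if abs(mean_corr - target_coexpression) < abs(best_val - target_coexpression):
            best_val, best_members = mean_corr, members
    raise SearchFailureError(
        f"could not reach co-expression {target_coexpression} +/- {tolerance} "
        f"in {max_attempts} attempts; best achieved {best_val:.4f}",
        best_value=float(best_val),
    )
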