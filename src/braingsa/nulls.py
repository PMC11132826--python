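"""Permutation null models and permutation p-values.

Five null families:

* ``competitive`` — gene labels resampled: each permutation draws a random
  same-sized subset of the background genes and evaluates the statistics on
  the fixed empirical correlation profile.
* ``self_contained`` — brain map spun: each permutation recomputes the full
  correlation profile against a spatially rotated map; the gene set itself
  is fixed, so within-set co-expression is preserved across iterations.
* ``coexpr_matched`` — competitive, but drawn subsets must match the
  empirical set's mean pairwise co-expression within a tolerance.
* ``brain_specific`` — competitive with the resampling pool restricted to
  the brain-specific gene subset.
* ``combined`` — one spin AND one gene-label resampling per iteration.

Permutation p-values use the add-one convention: upper-tail
(1 + #{null >= emp}) / (1 + B) for sign-insensitive statistics and the
doubled smaller tail for sign-sensitive ones.

Reproducibility: every gene-resampling permutation draws from its own rng
seeded by (master seed, sampling-group, permutation index).  All
resampling-based families share the sampling-group code, so e.g. a
brain-specific null with the full pool, or a matched null with infinite
tolerance, reproduces the competitive draws exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .association import (
    CorrelationProfile,
    correlation_matrix,
    mean_pairwise_correlation,
    pearson_pvalues,
)
from .core import BrainMap, ExpressionMatrix, GeneSet, MatchedSamplingError
from .setstats import (
    SIGN_SENSITIVE,
    STATISTICS,
    StatisticValue,
    batch_members_stats,
    batch_profile_stats,
)
from .spatial import SpinSet
from .synthetic import grow_set_toward_target

__all__ = [
    "NullEnsemble",
    "TestResult",
    "FAMILIES",
    "competitive_nulls",
    "self_contained_nulls",
    "coexpr_matched_nulls",
    "brain_specific_nulls",
    "combined_nulls",
    "permutation_p",
    "draw_memberships",
    "draw_matched_memberships",
]

FAMILIES = ["competitive", "self_contained", "coexpr_matched", "brain_specific", "combined"]

_RESAMPLE_GROUP = 101  # shared by all gene-resampling families (see module docstring)


@dataclass(frozen=True)
class NullEnsemble:
    """Per-statistic vectors of null statistic values from one null family."""

    family: str
    n_perm: int
    values: Dict[str, np.ndarray]
    seed: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown null family {self.family!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")
        for name, v in self.values.items():
            if np.asarray(v).shape != (self.n_perm,):
                raise ValueError(f"null vector for {name!r} must have length n_perm")


@dataclass(frozen=True)
class TestResult:
    """One permutation test outcome at significance level alpha."""

    gene_set: str
    brain_map: str
    statistic: str
    family: str
    empirical: float
    p_value: float
    alpha: float
    significant: bool

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")
        if self.significant != (self.p_value < self.alpha):
            raise ValueError("significant flag inconsistent with p_value and alpha")


def _perm_rng(seed: int, perm_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, _RESAMPLE_GROUP, perm_index])


def draw_memberships(
    n_pool: int, set_size: int, n_perm: int, seed: int,
    pool: Optional[np.ndarray] = None,
) -> np.ndarray:
    """(n_perm, set_size) random member indices, one rng per permutation.

    ``pool`` restricts the draw to a subset of gene indices.  The draws
    depend only on (seed, permutation index, pool, set size), never on the
    brain map, so they can be cached and shared across maps.
    """
    if pool is None:
        pool = np.arange(n_pool)
    if set_size > pool.size:
        raise ValueError("set size exceeds the sampling pool")
    out = np.empty((n_perm, set_size), dtype=np.intp)
    for b in range(n_perm):
        rng = _perm_rng(seed, b)
        out[b] = rng.choice(pool, size=set_size, replace=False)
    return out


def _ensemble_from_members(
    family: str,
    profile: CorrelationProfile,
    idx: np.ndarray,
    statistics: Sequence[str],
    alpha: float,
    seed: int,
    meta: Optional[dict] = None,
) -> NullEnsemble:
    vals = batch_members_stats(profile.r, profile.p, idx, statistics, alpha=alpha)
    return NullEnsemble(family, idx.shape[0], vals, seed, meta=meta or {})


def competitive_nulls(
    profile: CorrelationProfile,
    gene_set: GeneSet,
    n_perm: int,
    seed: int,
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
) -> NullEnsemble:
    """Gene-label-resampling nulls on a fixed correlation profile.

    Per the competitive convention, Sig Number reuses the empirical per-gene
    p-values of the resampled labels.
    """
    if gene_set.size >= profile.n_genes:
        raise ValueError("gene set must be smaller than the background")
    profile.gene_indices(gene_set.members)  # validate membership
    idx = draw_memberships(profile.n_genes, gene_set.size, n_perm, seed)
    return _ensemble_from_members("competitive", profile, idx, statistics, alpha, seed)


def brain_specific_nulls(
    expr: ExpressionMatrix,
    profile: CorrelationProfile,
    gene_set: GeneSet,
    n_perm: int,
    seed: int,
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
) -> NullEnsemble:
    """Competitive nulls restricted to the brain-specific gene pool."""
    pool = expr.brain_specific_indices()
    if pool.size < gene_set.size:
        raise ValueError(
            f"brain-specific pool ({pool.size}) smaller than the gene set ({gene_set.size})"
        )
    idx = draw_memberships(profile.n_genes, gene_set.size, n_perm, seed, pool=pool)
    return _ensemble_from_members("brain_specific", profile, idx, statistics, alpha, seed)


def draw_matched_memberships(
    gene_corr: np.ndarray,
    set_size: int,
    target: float,
    tolerance: float,
    n_perm: int,
    seed: int,
    max_attempts: int = 60,
) -> tuple:
    """Member indices for co-expression-matched nulls.

    Each permutation first tries one uniform proposal (so an infinite
    tolerance reproduces the competitive draws) and then guided greedy
    proposals grown toward the target co-expression; any accepted set
    satisfies |coexpr - target| <= tolerance.  Returns (idx, acceptance_rate).
    Raises MatchedSamplingError when a permutation exhausts its budget.
    """
    n = gene_corr.shape[0]
    n_pairs = set_size * (set_size - 1) / 2.0
    idx = np.empty((n_perm, set_size), dtype=np.intp)
    attempts_total = 0
    for b in range(n_perm):
        rng = _perm_rng(seed, b)
        accepted = False
        for attempt in range(max_attempts):
            attempts_total += 1
            if attempt == 0:
                members = rng.choice(n, size=set_size, replace=False)
            else:
                members = grow_set_toward_target(gene_corr, set_size, target, rng)
            sub = gene_corr[np.ix_(members, members)]
            coexpr = (sub.sum() - set_size) / (2.0 * n_pairs)
            if abs(coexpr - target) <= tolerance:
                idx[b] = members
                accepted = True
                break
        if not accepted:
            rate = b / attempts_total if attempts_total else 0.0
            raise MatchedSamplingError(
                f"matched sampling exhausted {max_attempts} attempts at permutation "
                f"{b}; acceptance rate so far {rate:.3f}",
                acceptance_rate=rate,
            )
    return idx, (n_perm / attempts_total if attempts_total else 1.0)


def coexpr_matched_nulls(
    expr: ExpressionMatrix,
    profile: CorrelationProfile,
    gene_set: GeneSet,
    tolerance: float,
    n_perm: int,
    seed: int,
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
    gene_corr: Optional[np.ndarray] = None,
    max_attempts: int = 60,
) -> NullEnsemble:
    """Competitive nulls whose drawn sets match the empirical co-expression."""
    if gene_set.size >= profile.n_genes:
        raise ValueError("gene set must be smaller than the background")
    if gene_corr is None:
        from .synthetic import _gene_correlation_matrix

        gene_corr = _gene_correlation_matrix(expr)
    members = expr.gene_indices(gene_set.members)
    target = mean_pairwise_correlation(expr.values[members])
    idx, rate = draw_matched_memberships(
        gene_corr, gene_set.size, target, tolerance, n_perm, seed, max_attempts
    )
    return _ensemble_from_members(
        "coexpr_matched", profile, idx, statistics, alpha, seed,
        meta={"target_coexpression": target, "acceptance_rate": rate},
    )


def spun_correlations(
    brain_map: BrainMap, expr: ExpressionMatrix, spins: SpinSet
) -> np.ndarray:
    """(G, n_spins) correlations of every gene with every spun map."""
    if spins.n_parcels != expr.geometry.n_parcels:
        raise ValueError("spin set built on a different geometry")
    if brain_map.geometry != expr.geometry:
        raise ValueError("map and expression matrix use different geometries")
    spun = brain_map.values[spins.permutations]  # (n_spins, N)
    return correlation_matrix(expr.values, spun.T)


def self_contained_nulls(
    brain_map: BrainMap,
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    spins: SpinSet,
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
) -> NullEnsemble:
    """Spin nulls: the full profile is recomputed for each spun map while the
    gene set membership stays fixed."""
    member_idx = expr.gene_indices(gene_set.members)
    r_null = spun_correlations(brain_map, expr, spins)
    vals = batch_profile_stats(
        r_null, member_idx, statistics, alpha=alpha,
        n_parcels=expr.geometry.n_parcels,
    )
    return NullEnsemble("self_contained", spins.n_spins, vals, spins.seed)


def combined_nulls(
    brain_map: BrainMap,
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    spins: SpinSet,
    seed: int,
    statistics: Sequence[str] = STATISTICS,
    alpha: float = 0.05,
) -> NullEnsemble:
    """Hybrid nulls: each iteration spins the map AND resamples gene labels."""
    n_perm = spins.n_spins
    idx = draw_memberships(expr.n_genes, gene_set.size, n_perm, seed)
    r_null = spun_correlations(brain_map, expr, spins)  # (G, n_perm)
    p_null = None
    if "signumber" in statistics:
        p_null = pearson_pvalues(r_null, expr.geometry.n_parcels)
    vals: Dict[str, np.ndarray] = {}
    # iteration b uses spin b's profile with membership draw b
    for name in statistics:
        per_iter = np.empty(n_perm)
        for b in range(n_perm):
            prof_r = r_null[:, b]
            prof_p = p_null[:, b] if p_null is not None else None
            per_iter[b] = batch_members_stats(
                prof_r, prof_p, idx[b: b + 1], [name], alpha=alpha
            )[name][0]
        vals[name] = per_iter
    return NullEnsemble("combined", n_perm, vals, seed)


def permutation_p(
    empirical: StatisticValue,
    ensemble: NullEnsemble,
    alpha: float = 0.05,
    gene_set: str = "",
    brain_map: str = "",
    tail: Optional[str] = None,
) -> TestResult:
    """Permutation p-value with the add-one convention.

    Sign-insensitive statistics use the one-sided upper tail; sign-sensitive
    ones double the smaller tail (override with ``tail`` in
    {"upper", "lower", "two-sided"}).
    """
    if empirical.name not in ensemble.values:
        raise ValueError(f"statistic {empirical.name!r} absent from the ensemble")
    null = np.asarray(ensemble.values[empirical.name], dtype=float)
    b = null.size
    p_upper = (1.0 + np.sum(null >= empirical.value)) / (1.0 + b)
    p_lower = (1.0 + np.sum(null <= empirical.value)) / (1.0 + b)
    if tail is None:
        tail = "two-sided" if empirical.name in SIGN_SENSITIVE else "upper"
    if tail == "upper":
        p = p_upper
    elif tail == "lower":
        p = p_lower
    elif tail == "two-sided":
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        raise ValueError("tail must be 'upper', 'lower' or 'two-sided'")
    p = float(p)
    return TestResult(
        gene_set=gene_set,
        brain_map=brain_map,
        statistic=empirical.name,
        family=ensemble.family,
        empirical=float(empirical.value),
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
    )


def batch_permutation_p(
    empirical: np.ndarray, null: np.ndarray, sign_sensitive: bool
) -> np.ndarray:
    """Vectorised permutation p-values: empirical (M,), null (B,) or (M, B)."""
    emp = np.atleast_1d(np.asarray(empirical, dtype=float))
    null = np.asarray(null, dtype=float)
    if null.ndim == 1:
        ge = np.sum(null[None, :] >= emp[:, None], axis=1)
        le = np.sum(null[None, :] <= emp[:, None], axis=1)
        b = null.size
    else:
        ge = np.sum(null >= emp[:, None], axis=1)
        le = np.sum(null <= emp[:, None], axis=1)
        b = null.shape[1]
    p_upper = (1.0 + ge) / (1.0 + b)
    p_lower = (1.0 + le) / (1.0 + b)
    if sign_sensitive:
        return np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    return p_upper
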