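"""Spatial autocorrelation and spatial permutations.

Implements global Moran's I with inverse-centroid-distance weights, its null
expectation E(I) = -1/(N-1), a subsampling simulator that draws random maps
with a prescribed Moran's I, and spherical "spin" permutations that shuffle
parcels while preserving the spatial structure of a map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import special_ortho_group

from .core import (
    BrainMap,
    DegenerateGeometryError,
    InsufficientPoolError,
    RegionGeometry,
    UndefinedStatisticError,
)

__all__ = [
    "WeightMatrix",
    "SpinSet",
    "build_weights",
    "moran_i",
    "moran_i_many",
    "expected_moran",
    "simulate_maps",
    "generate_spins",
    "nearest_assignment",
    "apply_spin",
]


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric non-negative spatial weights with zero diagonal.

    ``total`` is W = sum_ij w_ij over all ordered pairs.
    """

    weights: np.ndarray
    total: float

    def __init__(self, weights):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = float(w.sum())
        if total <= 0:
            raise ValueError("total weight must be positive")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "total", total)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SpinSet:
    """A batch of parcel-index permutations from spherical rotations.

    ``permutations[s, i]`` is the source parcel whose value lands on parcel
    ``i`` in spin ``s``; every row is a bijection on {0..N-1}.
    """

    permutations: np.ndarray
    seed: int

    def __init__(self, permutations, seed: int = 0):
        perms = np.asarray(permutations, dtype=np.intp)
        if perms.ndim != 2:
            raise ValueError("permutations must be (n_spins, n_parcels)")
        n = perms.shape[1]
        ref = np.arange(n)
        if not np.all(np.sort(perms, axis=1) == ref):
            raise ValueError("each spin must be a bijection on parcel indices")
        perms = perms.copy()
        perms.setflags(write=False)
        object.__setattr__(self, "permutations", perms)
        object.__setattr__(self, "seed", int(seed))

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.permutations.shape[1]


def build_weights(geometry: RegionGeometry) -> WeightMatrix:
    """Inverse-Euclidean-distance weights between parcel centroids."""
    d = geometry.distance_matrix()
    off = ~np.eye(geometry.n_parcels, dtype=bool)
    if np.any(d[off] <= 0):
        raise DegenerateGeometryError("coincident centroids give infinite weights")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    return WeightMatrix(w)


def moran_i(brain_map: BrainMap, weights: WeightMatrix) -> float:
    """Global Moran's I of a brain map.

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    """
    x = brain_map.values
    n = x.size
    if weights.n != n:
        raise ValueError("weight matrix size does not match the map")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatisticError("Moran's I is undefined for a constant map")
    num = float(z @ weights.weights @ z)
    return (n / weights.total) * num / denom


def moran_i_many(values: np.ndarray, weights: WeightMatrix) -> np.ndarray:
    """Moran's I for each row of a (n_maps, N) value matrix (vectorised)."""
    v = np.asarray(values, dtype=float)
    z = v - v.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", z, z)
    if np.any(denom == 0):
        raise UndefinedStatisticError("Moran's I is undefined for a constant map")
    num = np.einsum("ij,ij->i", z @ weights.weights, z)
    return (weights.n / weights.total) * num / denom


def expected_moran(n_parcels: int) -> float:
    """Null expectation of Moran's I: -1/(N-1)."""
    if n_parcels < 2:
        raise ValueError("n_parcels must be at least 2")
    return -1.0 / (n_parcels - 1)


def simulate_maps(
    geometry: RegionGeometry,
    target_moran: float,
    n_maps: int,
    pool_size: int = 100_000,
    target_sd: float = 0.001,
    seed: int = 0,
) -> List[BrainMap]:
    """Subsample random uniform maps to a prescribed Moran's I.

    Draws ``pool_size`` maps with each parcel value independent uniform(-1, 1),
    computes Moran's I for each, and returns the ``n_maps`` maps nearest the
    target.  The selection must be centred on the target (|mean - target| <=
    target_sd) with standard deviation <= target_sd, otherwise an
    InsufficientPoolError reports how many pool members fell inside the
    acceptance window.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be positive")
    if pool_size < n_maps:
        raise ValueError("pool_size must be at least n_maps")
    rng = np.random.default_rng(seed)
    weights = build_weights(geometry)
    pool = rng.uniform(-1.0, 1.0, size=(pool_size, geometry.n_parcels))
    i_vals = moran_i_many(pool, weights)
    order = np.argsort(np.abs(i_vals - target_moran), kind="stable")
    chosen = order[:n_maps]
    sel = i_vals[chosen]
    if abs(sel.mean() - target_moran) > target_sd or (n_maps > 1 and sel.std(ddof=0) > target_sd):
        n_ok = int(np.sum(np.abs(i_vals - target_moran) <= target_sd))
        raise InsufficientPoolError(
            f"only {n_ok} of {pool_size} pool maps fall within +/-{target_sd} of "
            f"Moran's I target {target_moran}; need {n_maps}",
            n_qualified=n_ok,
        )
    width = len(str(n_maps))
    return [
        BrainMap(pool[j], geometry, name=f"map_{k + 1:0{width}d}", moran_i=float(i_vals[j]))
        for k, j in enumerate(chosen)
    ]


def nearest_assignment(
    original: np.ndarray, rotated: np.ndarray, order: Sequence[int]
) -> np.ndarray:
    """Greedy one-to-one assignment of rotated centroids to original parcels.

    Processing original parcels in ``order``, each takes its nearest unused
    rotated centroid (ties broken by lower parcel index).  Returns the
    permutation pi with pi[i] = assigned source parcel for position i.
    """
    d = np.linalg.norm(original[:, None, :] - rotated[None, :, :], axis=2)
    n = d.shape[0]
    perm = np.empty(n, dtype=np.intp)
    available = np.ones(n, dtype=bool)
    for i in order:
        row = np.where(available, d[i], np.inf)
        j = int(np.argmin(row))  # argmin takes the lowest index on ties
        perm[i] = j
        available[j] = False
    return perm


def generate_spins(geometry: RegionGeometry, n_spins: int, seed: int = 0) -> SpinSet:
    """Spherical spin permutations of the parcellation.

    Each spin applies a Haar-uniform 3-D rotation (det +1) to the centroids
    and reassigns rotated to original parcels by greedy unique nearest
    neighbour, visiting parcels in random order.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be positive")
    rng = np.random.default_rng(seed)
    cen = geometry.centroids
    perms = np.empty((n_spins, geometry.n_parcels), dtype=np.intp)
    for s in range(n_spins):
        rot = special_ortho_group.rvs(3, random_state=rng)
        rotated = cen @ rot.T
        order = rng.permutation(geometry.n_parcels)
        perms[s] = nearest_assignment(cen, rotated, order)
    return SpinSet(perms, seed=seed)


def apply_spin(values: np.ndarray, permutation: np.ndarray) -> np.ndarray:
    """Spun map values: position i receives the value of parcel permutation[i]."""
    return np.asarray(values)[np.asarray(permutation, dtype=np.intp)]
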