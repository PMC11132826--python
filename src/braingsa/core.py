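"""Core domain types shared across the package.

The analysis operates on four kinds of objects: a parcellation geometry
(region centroids), a regional expression matrix (genes x parcels), named
gene sets, and brain maps (one phenotype value per parcel).  All containers
are lightweight frozen dataclasses wrapping numpy arrays; validation of the
structural invariants happens at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "RegionGeometry",
    "ExpressionMatrix",
    "GeneSet",
    "BrainMap",
    "BrainGSAError",
    "DegenerateGeometryError",
    "UndefinedStatisticError",
    "InsufficientPoolError",
    "MissingGeneError",
    "MatchedSamplingError",
    "SearchFailureError",
    "IncompleteDesignError",
]


class BrainGSAError(Exception):
    """Base class for package-specific errors."""


class DegenerateGeometryError(BrainGSAError, ValueError):
    """Raised when parcel centroids coincide (zero pairwise distance)."""


class UndefinedStatisticError(BrainGSAError, ValueError):
    """Raised when a statistic is undefined (e.g. Moran's I of a flat map)."""


class InsufficientPoolError(BrainGSAError, RuntimeError):
    """Raised when the subsampling pool cannot supply enough qualifying maps."""

    def __init__(self, msg: str, n_qualified: int = 0):
        super().__init__(msg)
        self.n_qualified = n_qualified


class MissingGeneError(BrainGSAError, KeyError):
    """Raised when a gene-set member is absent from the background pool."""


class MatchedSamplingError(BrainGSAError, RuntimeError):
    """Raised when matched rejection sampling exhausts its attempt budget."""

    def __init__(self, msg: str, acceptance_rate: float = 0.0):
        super().__init__(msg)
        self.acceptance_rate = acceptance_rate


class SearchFailureError(BrainGSAError, RuntimeError):
    """Raised when a co-expression target cannot be met; carries the best value."""

    def __init__(self, msg: str, best_value: float = float("nan")):
        super().__init__(msg)
        self.best_value = best_value


class IncompleteDesignError(BrainGSAError, ValueError):
    """Raised when a Psig aggregation receives an incomplete set x map grid."""

    def __init__(self, msg: str, missing: Sequence = ()):
        super().__init__(msg)
        self.missing = list(missing)


def _as_float_array(x, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"expected a {ndim}-d array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RegionGeometry:
    """Parcellation geometry: labelled parcels with 3-D centroid coordinates.

    Parameters
    ----------
    parcel_ids
        Ordered, unique parcel labels.
    centroids
        (n_parcels, 3) centroid coordinates in arbitrary length units.
    """

    parcel_ids: tuple
    centroids: np.ndarray

    def __init__(self, parcel_ids: Sequence[str], centroids):
        object.__setattr__(self, "parcel_ids", tuple(str(p) for p in parcel_ids))
        cen = _as_float_array(centroids, 2)
        if cen.shape[1] != 3:
            raise ValueError("centroids must be (n_parcels, 3)")
        cen = cen.copy()
        cen.setflags(write=False)
        object.__setattr__(self, "centroids", cen)
        if len(self.parcel_ids) != cen.shape[0]:
            raise ValueError("parcel_ids and centroids disagree in length")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("duplicate parcel_ids")
        if self.n_parcels < 3:
            raise ValueError("a geometry needs at least 3 parcels")
        d = pdist(cen)
        if d.size and d.min() <= 0:
            raise DegenerateGeometryError("coincident parcel centroids")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances, (N, N) with zero diagonal."""
        return squareform(pdist(self.centroids))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionGeometry)
            and self.parcel_ids == other.parcel_ids
            and np.array_equal(self.centroids, other.centroids)
        )

    def __hash__(self):
        return hash((self.parcel_ids, self.centroids.tobytes()))


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers (the 'prior gene set')."""

    name: str
    members: tuple

    def __init__(self, name: str, members: Sequence[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", tuple(str(m) for m in members))
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {name!r} has duplicate members")
        if self.size < 1:
            raise ValueError("a gene set needs at least one member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Regional expression: genes x parcels, with optional brain-specific labels.

    ``components`` / ``bimodal_component`` are provenance extras populated by
    the synthetic generator: the latent spatial components underlying the
    matrix and the index of the component pair that induces a bimodal
    background-correlation distribution.  Real-data matrices leave them None.
    """

    gene_ids: tuple
    values: np.ndarray
    geometry: RegionGeometry
    brain_specific: Optional[frozenset] = None
    components: Optional[np.ndarray] = field(default=None, compare=False)
    bimodal_component: Optional[int] = field(default=None, compare=False)

    def __init__(
        self,
        gene_ids: Sequence[str],
        values,
        geometry: RegionGeometry,
        brain_specific: Optional[Sequence[str]] = None,
        components: Optional[np.ndarray] = None,
        bimodal_component: Optional[int] = None,
    ):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in gene_ids))
        vals = _as_float_array(values, 2).copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "geometry", geometry)
        bs = frozenset(str(g) for g in brain_specific) if brain_specific is not None else None
        object.__setattr__(self, "brain_specific", bs)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "bimodal_component", bimodal_component)

        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if vals.shape[0] != len(self.gene_ids):
            raise ValueError("row count must equal number of gene_ids")
        if vals.shape[1] != geometry.n_parcels:
            raise ValueError("column count must equal geometry.n_parcels")
        if bs is not None and not bs <= set(self.gene_ids):
            raise ValueError("brain_specific labels must be a subset of gene_ids")
        object.__setattr__(
            self, "_index", {g: i for i, g in enumerate(self.gene_ids)}
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``; raises MissingGeneError on unknown ids."""
        idx = self.__dict__["_index"]
        try:
            return np.array([idx[g] for g in genes], dtype=np.intp)
        except KeyError as e:
            raise MissingGeneError(f"gene {e.args[0]!r} not in background pool") from e

    def brain_specific_indices(self) -> np.ndarray:
        if not self.brain_specific:
            raise ValueError("expression matrix carries no brain-specific labels")
        return self.gene_indices(sorted(self.brain_specific))


@dataclass(frozen=True)
class BrainMap:
    """One phenotype value per parcel, tied to a RegionGeometry."""

    values: np.ndarray
    geometry: RegionGeometry
    name: str = "map"
    moran_i: Optional[float] = field(default=None, compare=False)

    def __init__(self, values, geometry: RegionGeometry, name: str = "map",
                 moran_i: Optional[float] = None):
        vals = _as_float_array(values, 1).copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "geometry", geometry)
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "moran_i", moran_i)
        if vals.shape[0] != geometry.n_parcels:
            raise ValueError("map length must equal geometry.n_parcels")
        if not np.all(np.isfinite(vals)):
            raise ValueError("map values must be finite")
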