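"""Plain-text file interfaces.

Tab-delimited tables throughout: expression (gene_id + one column per
parcel), geometry (parcel_id, x, y, z), brain maps (parcel_id + one column
per map), spin sets (integer matrix), long-format result tables; gene sets
use the GMT format (name, description, tab-separated members).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import BrainMap, ExpressionMatrix, GeneSet, RegionGeometry
from .spatial import SpinSet

__all__ = [
    "read_geometry", "write_geometry",
    "read_expression", "write_expression",
    "read_brain_maps", "write_brain_maps",
    "read_gmt", "write_gmt",
    "read_spins", "write_spins",
]

PathLike = Union[str, Path]


def write_geometry(geometry: RegionGeometry, path: PathLike) -> None:
    df = pd.DataFrame(geometry.centroids, columns=["x", "y", "z"])
    df.insert(0, "parcel_id", geometry.parcel_ids)
    df.to_csv(path, sep="\t", index=False)


def read_geometry(path: PathLike) -> RegionGeometry:
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"geometry file {path} must have columns {sorted(required)}")
    return RegionGeometry(df["parcel_id"].astype(str), df[["x", "y", "z"]].to_numpy())


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    df = pd.DataFrame(expr.values, columns=expr.geometry.parcel_ids)
    df.insert(0, "gene_id", expr.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def read_expression(
    path: PathLike,
    geometry: RegionGeometry,
    brain_specific: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValueError(f"expression file {path}: first column must be 'gene_id'")
    parcels = tuple(df.columns[1:])
    if parcels != geometry.parcel_ids:
        raise ValueError(
            f"expression file {path}: parcel columns do not match the geometry"
        )
    return ExpressionMatrix(
        df["gene_id"].astype(str),
        df.iloc[:, 1:].to_numpy(dtype=float),
        geometry,
        brain_specific=brain_specific,
    )


def write_brain_maps(maps: Sequence[BrainMap], path: PathLike) -> None:
    geometry = maps[0].geometry
    data: Dict[str, np.ndarray] = {"parcel_id": np.array(geometry.parcel_ids)}
    for m in maps:
        if m.geometry != geometry:
            raise ValueError("all maps in one file must share a geometry")
        data[m.name] = m.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_brain_maps(path: PathLike, geometry: RegionGeometry) -> List[BrainMap]:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "parcel_id":
        raise ValueError(f"map file {path}: first column must be 'parcel_id'")
    if tuple(df["parcel_id"].astype(str)) != geometry.parcel_ids:
        raise ValueError(f"map file {path}: parcel_id column does not match the geometry")
    return [
        BrainMap(df[c].to_numpy(dtype=float), geometry, name=str(c))
        for c in df.columns[1:]
    ]


def write_gmt(gene_sets: Sequence[GeneSet], path: PathLike,
              descriptions: Optional[Dict[str, str]] = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = descriptions.get(gs.name, "na")
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


def read_gmt(path: PathLike) -> List[GeneSet]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT lines need name, description and >= 1 member"
                )
            out.append(GeneSet(fields[0], fields[2:]))
    return out


def write_spins(spins: SpinSet, path: PathLike) -> None:
    np.savetxt(path, spins.permutations, fmt="%d", delimiter="\t",
               header=f"seed={spins.seed}")


def read_spins(path: PathLike) -> SpinSet:
    seed = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "seed=" in first:
            seed = int(first.split("seed=")[1].strip())
    perms = np.loadtxt(path, dtype=np.intp, delimiter="\t", comments="#")
    return SpinSet(np.atleast_2d(perms), seed=seed)
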