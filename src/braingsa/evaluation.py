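"""Aggregation and bias diagnostics.

Psig-G is, per gene set, the fraction of brain maps it significantly
correlates with; Psig-B is, per brain map, the fraction of gene sets that
significantly correlate with it.  On a complete grid their grand averages
coincide exactly.  Bias diagnostics regress Psig on within-set
co-expression (the competitive-null confounder) or on the bimodality of the
background correlations (the self-contained-null confounder, measured by
Hartigan's dip or by the distance between positive and negative modes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import gaussian_kde

from .core import ExpressionMatrix, GeneSet, IncompleteDesignError
from .association import mean_pairwise_correlation
from .dip import dip as _dip

__all__ = [
    "PsigTable",
    "BiasRegression",
    "psig_g",
    "psig_b",
    "coexpression",
    "dip_statistic",
    "mode_distance",
    "regress_bias",
]

RESULT_COLUMNS = ["gene_set", "brain_map", "statistic", "family",
                  "empirical", "p_value", "significant"]


@dataclass(frozen=True)
class PsigTable:
    """Probability-of-significance per unit x statistic x null family.

    ``entries`` has one row per (unit, statistic, family) with the Psig in
    [0, 1]; ``summary`` holds mean and standard error per statistic x family,
    with SE defined as standard deviation / n_units (the convention used for
    reporting Psig spread).
    """

    axis: str
    entries: pd.DataFrame
    n_units: int
    summary: pd.DataFrame = field(compare=False, default=None)

    def grand_mean(self, statistic: str, family: str) -> float:
        sel = self.entries[
            (self.entries.statistic == statistic) & (self.entries.family == family)
        ]
        return float(sel.psig.mean())


@dataclass(frozen=True)
class BiasRegression:
    """OLS summary of a Psig-vs-predictor bias model."""

    predictor: str
    response: str
    estimate: float
    t_statistic: float
    r_squared: float
    n: int
    terms: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n < 3:
            raise ValueError("bias regression needs n >= 3")


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([r.__dict__ for r in results])
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results lack columns {missing}")
    return df


def _psig(results, unit_col: str, other_col: str, axis: str) -> PsigTable:
    df = _results_frame(results)
    n_other = df[other_col].nunique()
    counts = df.groupby(["statistic", "family", unit_col], observed=True)[other_col].nunique()
    bad = counts[counts != n_other]
    if len(bad):
        raise IncompleteDesignError(
            f"incomplete {unit_col} x {other_col} grid; first offenders: "
            f"{bad.head(5).to_dict()}",
            missing=list(bad.index[:20]),
        )
    entries = (
        df.groupby(["statistic", "family", unit_col], observed=True)["significant"]
        .mean()
        .rename("psig")
        .reset_index()
        .rename(columns={unit_col: "unit"})
    )
    n_units = df[unit_col].nunique()
    summary = (
        entries.groupby(["statistic", "family"], observed=True)["psig"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )
    summary["se"] = summary.pop("sd") / n_units
    return PsigTable(axis=axis, entries=entries, n_units=n_units, summary=summary)


def psig_g(results) -> PsigTable:
    """Psig per gene set: fraction of brain maps flagged significant."""
    return _psig(results, "gene_set", "brain_map", axis="gene_set")


def psig_b(results) -> PsigTable:
    """Psig per brain map: fraction of gene sets flagged significant."""
    return _psig(results, "brain_map", "gene_set", axis="brain_map")


def coexpression(expr: ExpressionMatrix, gene_set: GeneSet) -> float:
    """Mean pairwise Pearson correlation among the member expression profiles."""
    if gene_set.size < 2:
        raise ValueError("co-expression needs at least two member genes")
    idx = expr.gene_indices(gene_set.members)
    return mean_pairwise_correlation(expr.values[idx])


def dip_statistic(values: Iterable[float]) -> float:
    """Hartigan's dip of a sample (deviation from the closest unimodal CDF)."""
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < 4:
        raise ValueError("dip needs at least 4 values")
    return _dip(vals)


def mode_distance(values: Iterable[float], grid_size: int = 512) -> float:
    """Distance between the highest positive-abscissa and negative-abscissa
    density peaks (Gaussian KDE, Silverman bandwidth); 0 if either side has
    no interior peak."""
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < 10:
        raise ValueError("mode_distance needs at least 10 values")
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    dens = kde(grid)
    interior = np.zeros(grid_size, dtype=bool)
    interior[1:-1] = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])

    def side_peak(mask):
        cand = np.flatnonzero(interior & mask)
        if cand.size == 0:
            return None
        return grid[cand[np.argmax(dens[cand])]]

    pos = side_peak(grid > 0)
    neg = side_peak(grid < 0)
    if pos is None or neg is None:
        return 0.0
    return float(abs(pos - neg))


def regress_bias(
    response: Union[np.ndarray, pd.Series],
    predictors: Union[np.ndarray, pd.Series, pd.DataFrame],
    interaction: bool = False,
    response_name: str = "psig",
) -> BiasRegression:
    """OLS of Psig on the predictor(s).

    With ``interaction=True`` the predictors must provide ``size`` and
    ``coexpression`` columns; the model is
    ``psig ~ size + coexpression + size:coexpression`` and the reported term
    is the interaction.  Otherwise a single predictor is used.  Plain
    heteroskedasticity-naive OLS throughout.
    """
    y = np.asarray(response, dtype=float)
    if interaction:
        x = pd.DataFrame(predictors)
        if not {"size", "coexpression"} <= set(x.columns):
            raise ValueError("interaction model needs 'size' and 'coexpression'")
        design = pd.DataFrame({
            "size": x["size"].to_numpy(dtype=float),
            "coexpression": x["coexpression"].to_numpy(dtype=float),
        })
        design["size:coexpression"] = design["size"] * design["coexpression"]
        term = "size:coexpression"
        pred_name = "size×coexpression"
    else:
        if isinstance(predictors, pd.DataFrame):
            if predictors.shape[1] != 1:
                raise ValueError("pass a single predictor unless interaction=True")
            pred_name = str(predictors.columns[0])
            design = predictors.astype(float)
        else:
            arr = np.asarray(predictors, dtype=float)
            pred_name = getattr(predictors, "name", None) or "predictor"
            design = pd.DataFrame({pred_name: arr})
        term = design.columns[0]
    if len(y) < 3:
        raise ValueError("bias regression needs n >= 3")
    if np.any(design.std(axis=0, ddof=0) == 0):
        raise ValueError("zero-variance predictor")
    model = sm.OLS(y, sm.add_constant(design)).fit()

    def _clean(v):  # constant responses yield nan t / R^2; report 0 instead
        return float(v) if np.isfinite(v) else 0.0

    return BiasRegression(
        predictor=pred_name,
        response=response_name,
        estimate=float(model.params[term]),
        t_statistic=_clean(model.tvalues[term]),
        r_squared=min(max(_clean(model.rsquared), 0.0), 1.0),
        n=int(len(y)),
        terms={k: (float(model.params[k]), _clean(model.tvalues[k]))
               for k in model.params.index},
    )
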