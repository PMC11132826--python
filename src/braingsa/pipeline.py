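"""End-to-end orchestration: generate -> simulate -> test -> evaluate.

`run_grid` evaluates every (gene set x brain map x statistic x null family)
cell and returns a long-format result table; it shares permutation draws
where the null construction permits it (spins are reused across gene sets;
gene-resampling draws depend only on the seed, pool and set size, so they
are cached per gene set across maps).  `run_pipeline` wraps a full run from
a RunConfig: inputs (files or synthetic specs), the grid, Psig tables, bias
regressions, figures and a manifest, all reproducible from the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlate
from .core import BrainMap, ExpressionMatrix
from .evaluation import (
    RESULT_COLUMNS,
    coexpression,
    dip_statistic,
    psig_b,
    psig_g,
    regress_bias,
)
from .nulls import (
    FAMILIES,
    batch_permutation_p,
    combined_nulls,
    draw_matched_memberships,
    draw_memberships,
    spun_correlations,
)
from .setstats import (
    SIGN_SENSITIVE,
    STATISTICS,
    batch_members_stats,
    batch_profile_stats,
    evaluate_statistics,
    members_rank_context,
    profile_rank_context,
)
from .spatial import SpinSet, generate_spins, simulate_maps
from .synthetic import (
    SyntheticSpec,
    _gene_correlation_matrix,
    generate_expression,
    generate_geometry,
    sample_gene_sets,
)
from . import io as bio

logger = logging.getLogger(__name__)


def run_grid(
    expr: ExpressionMatrix,
    maps: Sequence[BrainMap],
    gene_sets: Sequence[GeneSet],
    statistics: Sequence[str] = STATISTICS,
    families: Sequence[str] = ("competitive", "self_contained"),
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    spins: Optional[SpinSet] = None,
    matched_tolerance: float = 0.1,
    matched_max_attempts: int = 60,
) -> pd.DataFrame:
    """Evaluate the full test grid; returns a long-format result table."""
    statistics = list(statistics)
    families = list(families)
    for s in statistics:
        if s not in STATISTICS:
            raise ValueError(f"unknown statistic {s!r}; choose from {STATISTICS}")
    for f in families:
        if f not in FAMILIES:
            raise ValueError(f"unknown null family {f!r}; choose from {FAMILIES}")

    geometry = expr.geometry
    needs_spins = {"self_contained", "combined"} & set(families)
    if needs_spins and spins is None:
        spins = generate_spins(geometry, n_perm, seed=seed)
    if spins is not None and spins.n_spins < n_perm:
        raise ValueError("spin set smaller than n_perm")

    member_idx = {gs.name: expr.gene_indices(gs.members) for gs in gene_sets}

    # gene-resampling draws are map-independent: cache them per set (by size
    # for the plain pools, per set for the matched family)
    resample_idx: Dict[int, np.ndarray] = {}
    bs_idx: Dict[int, np.ndarray] = {}
    matched_idx: Dict[str, np.ndarray] = {}
    if "competitive" in families or "combined" in families:
        for gs in gene_sets:
            if gs.size not in resample_idx:
                resample_idx[gs.size] = draw_memberships(
                    expr.n_genes, gs.size, n_perm, seed
                )
    if "brain_specific" in families:
        pool = expr.brain_specific_indices()
        for gs in gene_sets:
            if gs.size not in bs_idx:
                bs_idx[gs.size] = draw_memberships(
                    expr.n_genes, gs.size, n_perm, seed, pool=pool
                )
    if "coexpr_matched" in families:
        gene_corr = _gene_correlation_matrix(expr)
        for gs in gene_sets:
            target = coexpression(expr, gs)
            matched_idx[gs.name], rate = draw_matched_memberships(
                gene_corr, gs.size, target, matched_tolerance, n_perm, seed,
                max_attempts=matched_max_attempts,
            )
            if rate < 0.2:
                logger.warning("matched sampling for %s: acceptance rate %.3f",
                               gs.name, rate)

    needs_ks = {"ks", "weighted_ks"} & set(statistics)
    rows = []
    for bm in maps:
        profile = correlate(bm, expr)
        ctx_members = members_rank_context(profile.r)
        emp = {
            gs.name: evaluate_statistics(profile, gs, statistics, alpha=alpha)
            for gs in gene_sets
        }
        r_null = p_null = ctx_profile = None
        if needs_spins:
            r_null = spun_correlations(bm, expr, spins)[:, :n_perm]
            if "signumber" in statistics:
                from .association import pearson_pvalues

                p_null = pearson_pvalues(r_null, geometry.n_parcels)
            if needs_ks:
                ctx_profile = profile_rank_context(r_null)

        for family in families:
            for gs in gene_sets:
                if family == "competitive":
                    nulls = batch_members_stats(
                        profile.r, profile.p, resample_idx[gs.size], statistics,
                        alpha=alpha, context=ctx_members,
                    )
                elif family == "brain_specific":
                    nulls = batch_members_stats(
                        profile.r, profile.p, bs_idx[gs.size], statistics,
                        alpha=alpha, context=ctx_members,
                    )
                elif family == "coexpr_matched":
                    nulls = batch_members_stats(
                        profile.r, profile.p, matched_idx[gs.name], statistics,
                        alpha=alpha, context=ctx_members,
                    )
                elif family == "self_contained":
                    nulls = batch_profile_stats(
                        r_null, member_idx[gs.name], statistics, alpha=alpha,
                        n_parcels=geometry.n_parcels, p=p_null,
                        context=ctx_profile,
                    )
                elif family == "combined":
                    nulls = combined_nulls(
                        bm, expr, gs, spins, seed, statistics, alpha=alpha
                    ).values
                for stat in statistics:
                    ev = emp[gs.name][stat].value
                    p = float(batch_permutation_p(
                        np.array([ev]), nulls[stat], stat in SIGN_SENSITIVE
                    )[0])
                    rows.append((gs.name, bm.name, stat, family, ev, p, p < alpha))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.insert(6, "alpha", alpha)
    return df


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Inputs are either file paths (expression/geometry/gene_sets/maps) or
    synthetic-generation parameters; file inputs win when both are present.
    """

    output_dir: str = "braingsa_run"
    master_seed: int = 0
    statistics: List[str] = field(default_factory=lambda: list(STATISTICS))
    families: List[str] = field(default_factory=lambda: ["competitive", "self_contained"])
    n_perm: int = 5000
    alpha: float = 0.05
    target_moran: float = 0.03
    n_maps: int = 100
    map_pool_size: int = 50_000
    matched_tolerance: float = 0.1
    # file inputs
    expression: Optional[str] = None
    geometry: Optional[str] = None
    gene_sets: Optional[str] = None
    maps: Optional[str] = None
    # synthetic generation
    n_genes: int = 2000
    n_parcels: int = 34
    n_latent: int = 3
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    bimodal_fraction: float = 0.0
    set_sizes: List[int] = field(default_factory=lambda: list(range(20, 201, 20)))
    set_repeats: int = 2

    def __post_init__(self):
        unknown = set(self.statistics) - set(STATISTICS)
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown null families {sorted(unknown)}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _load_or_generate(config: RunConfig):
    seed = config.master_seed
    if config.geometry:
        geometry = bio.read_geometry(config.geometry)
    else:
        geometry = generate_geometry(config.n_parcels, seed=seed)
    if config.expression:
        expr = bio.read_expression(config.expression, geometry)
    else:
        spec = SyntheticSpec(
            n_genes=config.n_genes,
            n_parcels=geometry.n_parcels,
            n_latent=config.n_latent,
            loading_scale=config.loading_scale,
            noise_sd=config.noise_sd,
            bimodal_fraction=config.bimodal_fraction,
            seed=seed,
        )
        expr = generate_expression(spec, geometry)
    if config.gene_sets:
        gene_sets = bio.read_gmt(config.gene_sets)
    else:
        gene_sets = sample_gene_sets(
            expr, config.set_sizes, config.set_repeats, seed=seed + 1
        )
    if config.maps:
        maps = bio.read_brain_maps(config.maps, geometry)
    else:
        maps = simulate_maps(
            geometry, config.target_moran, config.n_maps,
            pool_size=config.map_pool_size, seed=seed + 2,
        )
    return geometry, expr, gene_sets, maps


def _bias_table(expr, gene_sets, maps, results) -> pd.DataFrame:
    """Co-expression -> Psig-G and dip -> Psig-B regressions per statistic x family."""
    coexpr = {gs.name: coexpression(expr, gs) for gs in gene_sets if gs.size >= 2}
    dips = {}
    for bm in maps:
        r = correlate(bm, expr).r
        dips[bm.name] = dip_statistic(r)
    pg = psig_g(results)
    pb = psig_b(results)
    rows = []
    for table, pred_map, pred_name, resp in (
        (pg, coexpr, "coexpression", "psig_g"),
        (pb, dips, "dip", "psig_b"),
    ):
        for (stat, family), sub in table.entries.groupby(["statistic", "family"],
                                                         observed=True):
            sub = sub[sub.unit.isin(pred_map)]
            x = sub.unit.map(pred_map).to_numpy()
            y = sub.psig.to_numpy()
            if len(y) < 3 or np.std(x) == 0:
                continue
            reg = regress_bias(y, pd.DataFrame({pred_name: x}), response_name=resp)
            rows.append((resp, pred_name, stat, family, reg.estimate,
                         reg.t_statistic, reg.r_squared, reg.n))
    return pd.DataFrame(rows, columns=[
        "response", "predictor", "statistic", "family",
        "estimate", "t_statistic", "r_squared", "n",
    ])


def _figures(outdir: Path, results, pg, pb, bias):
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    for table, label in ((pg, "psig_g"), (pb, "psig_b")):
        fig, ax = plt.subplots(figsize=(8, 4))
        summary = table.summary
        xticks = np.arange(len(summary))
        ax.bar(xticks, summary["mean"], yerr=summary["se"], capsize=2)
        ax.axhline(0.05, ls="--", c="grey")
        ax.set_xticks(xticks)
        ax.set_xticklabels(
            [f"{s}\n{f}" for s, f in zip(summary.statistic, summary.family)],
            fontsize=6, rotation=45,
        )
        ax.set_ylabel(f"mean {label}")
        fig.tight_layout()
        fig.savefig(outdir / f"{label}_summary.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Writes inputs, the result table, Psig tables, bias regressions, summary
    figures and a manifest.  Re-running with the same config reproduces every
    numeric output.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    geometry, expr, gene_sets, maps = _load_or_generate(config)
    bio.write_geometry(geometry, outdir / "geometry.tsv")
    bio.write_expression(expr, outdir / "expression.tsv")
    bio.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    bio.write_brain_maps(maps, outdir / "maps.tsv")

    results = run_grid(
        expr, maps, gene_sets,
        statistics=config.statistics,
        families=config.families,
        n_perm=config.n_perm,
        seed=config.master_seed,
        alpha=config.alpha,
        matched_tolerance=config.matched_tolerance,
    )
    results.to_csv(outdir / "results.tsv", sep="\t", index=False)

    pg = psig_g(results)
    pb = psig_b(results)
    pg.entries.to_csv(outdir / "psig_g.tsv", sep="\t", index=False)
    pg.summary.to_csv(outdir / "psig_g_summary.tsv", sep="\t", index=False)
    pb.entries.to_csv(outdir / "psig_b.tsv", sep="\t", index=False)
    pb.summary.to_csv(outdir / "psig_b_summary.tsv", sep="\t", index=False)

    bias = _bias_table(expr, gene_sets, maps, results)
    bias.to_csv(outdir / "bias_regressions.tsv", sep="\t", index=False)
    _figures(outdir, results, pg, pb, bias)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_gene_sets": len(gene_sets),
        "n_maps": len(maps),
        "n_genes": expr.n_genes,
        "grand_mean_psig_g": {
            f"{row.statistic}|{row.family}": float(row["mean"])
            for _, row in pg.summary.iterrows()
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
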