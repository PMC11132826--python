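"""Gene-set test statistics.

Eight summary statistics of the within-set correlations: Mean, Meanabs,
Meansqr, Maxmean, Median, Sig Number (count of BH-significant member
correlations), KS and Weighted KS (running-sum enrichment scores over the
ranked background).  Mean, Median, KS and Weighted KS are sign-sensitive
(negating every correlation negates them); the other four are not.

Scalar functions operate on a (CorrelationProfile, GeneSet) pair and are the
reference implementation; `batch_members_stats` / `batch_profile_stats`
evaluate the same statistics vectorised across permutations (resampled
memberships on a fixed profile, or fixed membership on per-permutation
profiles) and are checked against the scalar path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np

from .association import CorrelationProfile, pearson_pvalues
from .core import GeneSet

__all__ = [
    "StatisticValue",
    "STATISTICS",
    "SIGN_SENSITIVE",
    "stat_mean",
    "stat_meanabs",
    "stat_meansqr",
    "stat_maxmean",
    "stat_median",
    "stat_signumber",
    "stat_ks",
    "evaluate_statistics",
    "bh_adjust",
    "batch_members_stats",
    "batch_profile_stats",
]

SIGN_SENSITIVE = frozenset({"mean", "median", "ks", "weighted_ks"})

STATISTICS: List[str] = [
    "mean", "meanabs", "meansqr", "maxmean",
    "median", "signumber", "ks", "weighted_ks",
]


@dataclass(frozen=True)
class StatisticValue:
    name: str
    value: float
    sign_sensitive: bool

    def __post_init__(self):
        if self.sign_sensitive != (self.name in SIGN_SENSITIVE):
            raise ValueError(f"inconsistent sign_sensitive flag for {self.name!r}")


def _value(name: str, value: float) -> StatisticValue:
    return StatisticValue(name, float(value), name in SIGN_SENSITIVE)


def _member_r(profile: CorrelationProfile, gene_set: GeneSet) -> np.ndarray:
    return profile.r[profile.gene_indices(gene_set.members)]


def stat_mean(profile, gene_set) -> StatisticValue:
    """Mean of the member correlations."""
    return _value("mean", _member_r(profile, gene_set).mean())


def stat_meanabs(profile, gene_set) -> StatisticValue:
    """Mean absolute member correlation."""
    return _value("meanabs", np.abs(_member_r(profile, gene_set)).mean())


def stat_meansqr(profile, gene_set) -> StatisticValue:
    """Mean squared member correlation."""
    return _value("meansqr", (_member_r(profile, gene_set) ** 2).mean())


def stat_median(profile, gene_set) -> StatisticValue:
    """Median member correlation."""
    return _value("median", np.median(_member_r(profile, gene_set)))


def stat_maxmean(profile, gene_set) -> StatisticValue:
    """max(mean of positive member r, |mean of negative member r|).

    Each side averages over its own count (0 if the side is empty).
    """
    r = _member_r(profile, gene_set)
    pos = r[r > 0]
    neg = r[r < 0]
    s_pos = pos.mean() if pos.size else 0.0
    s_neg = -neg.mean() if neg.size else 0.0
    return _value("maxmean", max(s_pos, s_neg))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, within one family)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def stat_signumber(profile, gene_set, alpha: float = 0.05) -> StatisticValue:
    """Count of member correlations significant after BH correction.

    The BH family is the member p-values only; significance is corrected
    p < alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = profile.p[profile.gene_indices(gene_set.members)]
    return _value("signumber", int((bh_adjust(p) < alpha).sum()))


def _ranking(profile: CorrelationProfile) -> np.ndarray:
    """Background order: r descending, ties broken by gene identifier."""
    ids = np.array(profile.gene_ids)
    return np.lexsort((ids, -profile.r))


def stat_ks(profile, gene_set, weighted: bool = False,
            variant: str = "gsea") -> StatisticValue:
    """Running-sum enrichment score over the ranked background.

    Genes are ranked by r descending; walking the ranking, the cumulative
    sum rises at members and falls at non-members, and the statistic is the
    signed cumulative sum at the position of maximum absolute deviation
    (earliest position on ties).

    The default normalised walk (``variant="gsea"``) increments by
    w_g / sum(member w) at members (w_g = 1 unweighted, |r_g| weighted) and
    decrements by 1/(G-k) at non-members, so the walk ends at zero and the
    score is invariant to the overall correlation magnitude.
    ``variant="literal"`` uses raw +/-w_g steps instead; its walk ends at the
    set-size drift sum(member w) - sum(non-member w), which dominates the
    extreme deviation for small sets, so it is kept only as a variant.
    """
    if variant not in ("literal", "gsea"):
        raise ValueError("variant must be 'literal' or 'gsea'")
    member_idx = profile.gene_indices(gene_set.members)
    g = profile.n_genes
    if member_idx.size >= g:
        raise ValueError("gene set must be a strict subset of the background")
    is_member = np.zeros(g, dtype=bool)
    is_member[member_idx] = True
    order = _ranking(profile)
    ranked_member = is_member[order]
    if weighted:
        w = np.abs(profile.r[order])
    else:
        w = np.ones(g)
    if variant == "gsea":
        inc = np.where(ranked_member, w, 0.0)
        inc_total = inc.sum()
        steps = np.where(
            ranked_member,
            inc / (inc_total if inc_total > 0 else 1.0),
            -1.0 / (g - member_idx.size),
        )
    else:
        steps = np.where(ranked_member, w, -w)
    cum = np.cumsum(steps)
    j = int(np.argmax(np.abs(cum)))  # argmax returns the earliest maximum
    name = "weighted_ks" if weighted else "ks"
    return _value(name, cum[j])


_SCALAR_FUNCS = {
    "mean": stat_mean,
    "meanabs": stat_meanabs,
    "meansqr": stat_meansqr,
    "maxmean": stat_maxmean,
    "median": stat_median,
    "signumber": stat_signumber,
    "ks": lambda pr, gs: stat_ks(pr, gs, weighted=False),
    "weighted_ks": lambda pr, gs: stat_ks(pr, gs, weighted=True),
}


def evaluate_statistics(profile, gene_set, statistics: Iterable[str] = STATISTICS,
                        alpha: float = 0.05) -> Dict[str, StatisticValue]:
    """Evaluate the requested statistics on one (profile, gene set) pair."""
    out = {}
    for name in statistics:
        if name not in _SCALAR_FUNCS:
            raise ValueError(f"unknown statistic {name!r}; choose from {STATISTICS}")
        if name == "signumber":
            out[name] = stat_signumber(profile, gene_set, alpha=alpha)
        else:
            out[name] = _SCALAR_FUNCS[name](profile, gene_set)
    return out


# ---------------------------------------------------------------------------
# Batched evaluation
#
# The running-sum statistics are evaluated without materialising the full
# walk: between member positions the cumulative sum is strictly monotone, so
# its extreme absolute deviation is attained either at a member position, just
# before the next member, or at the end of the ranking.  Evaluating those
# 2k + 1 candidate points per permutation reduces the cost from O(G) to O(k)
# per permutation and makes large grids tractable.
# ---------------------------------------------------------------------------


def _ks_pick_candidates(c_member, c_before, c_end, ranks, g) -> np.ndarray:
    """Signed extreme deviation from the 2k+1 candidate points per row.

    Candidate positions are the member positions (counts ranks+1), the
    positions just before each member (counts ranks), and the end of the
    ranking; ties in |cum| resolve to the earliest position, matching the
    scalar walk.
    """
    b = ranks.shape[0]
    j_member = ranks + 1.0
    j_before = ranks.astype(float)
    c = np.concatenate([c_member, c_before, c_end[:, None]], axis=1)
    j = np.concatenate([j_member, j_before, np.full((b, 1), float(g))], axis=1)
    absc = np.abs(c)
    absc[j == 0] = -1.0  # the walk has no deviation before the first gene
    best = absc.max(axis=1)
    pos = np.where(absc == best[:, None], j, np.inf).argmin(axis=1)
    return c[np.arange(b), pos]


def _ks_candidates(ranks, g, variant, p_cum=None, a_at=None, a_before=None,
                   a_end=None) -> np.ndarray:
    """Candidate values for the running sum given sorted member ranks.

    ``ranks`` is (B, k) 0-based ascending member ranks.  For weighted walks
    ``p_cum`` passes cumulative member weights in rank order; the literal
    weighted walk additionally needs the all-gene weight prefix sums at the
    member positions (``a_at``), just before them (``a_before``) and at the
    end (``a_end``).  Unweighted walks imply all prefix sums from the ranks.
    """
    b, k = ranks.shape
    t = np.arange(1, k + 1, dtype=float)
    if variant == "gsea":
        if p_cum is None:
            frac = t / k
            frac_prev = (t - 1.0) / k
        else:
            total = p_cum[:, -1:].copy()
            total[total == 0] = 1.0
            frac = p_cum / total
            frac_prev = np.concatenate([np.zeros((b, 1)), frac[:, :-1]], axis=1)
        dec = 1.0 / (g - k)
        c_member = frac - (ranks + 1.0 - t) * dec
        c_before = frac_prev - (ranks - (t - 1.0)) * dec
        c_end = np.zeros(b)
    elif variant == "literal":
        if p_cum is None:  # P_t = t, A_j = j
            c_member = 2.0 * t - (ranks + 1.0)
            c_before = 2.0 * (t - 1.0) - ranks
            c_end = np.full(b, 2.0 * k - g)
        else:
            p_shift = np.concatenate([np.zeros((b, 1)), p_cum[:, :-1]], axis=1)
            c_member = 2.0 * p_cum - a_at
            c_before = 2.0 * p_shift - a_before
            c_end = 2.0 * p_cum[:, -1] - a_end
    else:
        raise ValueError("variant must be 'literal' or 'gsea'")
    return _ks_pick_candidates(c_member, c_before, c_end, ranks, g)


def members_rank_context(r: np.ndarray, ranking: Optional[np.ndarray] = None) -> dict:
    """Shared ranking context for resampling-style batches on one profile."""
    if ranking is None:
        ranking = np.argsort(-r, kind="stable")
    g = r.size
    rank_of = np.empty(g, dtype=np.intp)
    rank_of[ranking] = np.arange(g)
    w = np.abs(r)[ranking]
    return {"ranking": ranking, "rank_of": rank_of, "acum": np.cumsum(w)}


def profile_rank_context(r: np.ndarray) -> dict:
    """Shared per-permutation ranking context for (G, B) profile batches."""
    order = np.argsort(-r, axis=0, kind="stable")
    g = r.shape[0]
    rank_of = np.empty_like(order)
    np.put_along_axis(rank_of, order, np.arange(g)[:, None], axis=0)
    w = np.abs(np.take_along_axis(r, order, axis=0))
    return {"order": order, "rank_of": rank_of, "acum": np.cumsum(w, axis=0)}


def _ks_members_batch(r, idx, weighted, ctx, variant) -> np.ndarray:
    g = r.size
    ranks = np.sort(ctx["rank_of"][idx], axis=1)
    if not weighted:
        return _ks_candidates(ranks, g, variant)
    acum = ctx["acum"]
    w_at = np.abs(r)[ctx["ranking"]][ranks]
    p_cum = np.cumsum(w_at, axis=1)
    a_at = acum[ranks]
    a_before = np.where(ranks > 0, acum[np.maximum(ranks - 1, 0)], 0.0)
    return _ks_candidates(ranks, g, variant, p_cum, a_at, a_before, acum[g - 1])


def _ks_profile_batch(r, member_idx, weighted, ctx, variant) -> np.ndarray:
    g = r.shape[0]
    ranks = np.sort(ctx["rank_of"][member_idx, :], axis=0).T  # (B, k)
    if not weighted:
        return _ks_candidates(ranks, g, variant)
    acum = ctx["acum"]  # (G, B)
    a_at = np.take_along_axis(acum, ranks.T, axis=0).T
    a_before = np.where(
        ranks > 0,
        np.take_along_axis(acum, np.maximum(ranks.T - 1, 0), axis=0).T,
        0.0,
    )
    # member weights in rank order, recovered as prefix-sum differences
    p_cum = np.cumsum(a_at - a_before, axis=1)
    a_end = acum[g - 1, :]
    return _ks_candidates(ranks, g, variant, p_cum, a_at, a_before, a_end)

def _bh_count_rows(p: np.ndarray, alpha: float) -> np.ndarray:
    """Per-row count of BH-significant p-values; p is (n_perm, k)."""
    k = p.shape[1]
    ps = np.sort(p, axis=1)
    q = ps * k / np.arange(1, k + 1)
    qmin = np.minimum.accumulate(q[:, ::-1], axis=1)[:, ::-1]
    return (np.minimum(qmin, 1.0) < alpha).sum(axis=1)


def _maxmean_rows(r: np.ndarray) -> np.ndarray:
    pos = r > 0
    neg = r < 0
    npos = pos.sum(axis=1)
    nneg = neg.sum(axis=1)
    s_pos = np.where(pos, r, 0.0).sum(axis=1) / np.maximum(npos, 1)
    s_neg = -np.where(neg, r, 0.0).sum(axis=1) / np.maximum(nneg, 1)
    s_pos[npos == 0] = 0.0
    s_neg[nneg == 0] = 0.0
    return np.maximum(s_pos, s_neg)


def batch_members_stats(
    r: np.ndarray,
    p: Optional[np.ndarray],
    idx: np.ndarray,
    statistics: Iterable[str],
    alpha: float = 0.05,
    ranking: Optional[np.ndarray] = None,
    context: Optional[dict] = None,
    ks_variant: str = "gsea",
) -> Dict[str, np.ndarray]:
    """Statistics for many memberships on one fixed profile.

    ``r``/``p`` are the fixed per-gene correlations and p-values; ``idx`` is
    (n_perm, k) member indices.  ``ranking``/``context`` may pass a
    precomputed descending-r order (ties by gene position) or a full
    ``members_rank_context``.  Returns name -> (n_perm,) vectors.
    """
    statistics = list(statistics)
    rp = r[idx]
    out: Dict[str, np.ndarray] = {}
    for name in statistics:
        if name == "mean":
            out[name] = rp.mean(axis=1)
        elif name == "meanabs":
            out[name] = np.abs(rp).mean(axis=1)
        elif name == "meansqr":
            out[name] = (rp ** 2).mean(axis=1)
        elif name == "median":
            out[name] = np.median(rp, axis=1)
        elif name == "maxmean":
            out[name] = _maxmean_rows(rp)
        elif name == "signumber":
            if p is None:
                raise ValueError("signumber needs per-gene p-values")
            out[name] = _bh_count_rows(p[idx], alpha).astype(float)
        elif name in ("ks", "weighted_ks"):
            if context is None:
                context = members_rank_context(r, ranking)
            out[name] = _ks_members_batch(r, idx, name == "weighted_ks",
                                          context, ks_variant)
        else:
            raise ValueError(f"unknown statistic {name!r}")
    return out


def batch_profile_stats(
    r: np.ndarray,
    member_idx: np.ndarray,
    statistics: Iterable[str],
    alpha: float = 0.05,
    n_parcels: Optional[int] = None,
    p: Optional[np.ndarray] = None,
    context: Optional[dict] = None,
    ks_variant: str = "gsea",
) -> Dict[str, np.ndarray]:
    """Statistics for one fixed membership on many profiles.

    ``r`` is (G, n_perm) per-permutation correlations; ``member_idx`` the
    fixed member rows.  For signumber, p-values are recomputed from ``r`` at
    ``n_parcels`` unless ``p`` is given.  ``context`` may pass a precomputed
    ``profile_rank_context`` shared across gene sets.  Returns
    name -> (n_perm,) vectors.
    """
    statistics = list(statistics)
    sub = r[member_idx]  # (k, n_perm)
    out: Dict[str, np.ndarray] = {}
    for name in statistics:
        if name == "mean":
            out[name] = sub.mean(axis=0)
        elif name == "meanabs":
            out[name] = np.abs(sub).mean(axis=0)
        elif name == "meansqr":
            out[name] = (sub ** 2).mean(axis=0)
        elif name == "median":
            out[name] = np.median(sub, axis=0)
        elif name == "maxmean":
            out[name] = _maxmean_rows(sub.T)
        elif name == "signumber":
            if p is None:
                if n_parcels is None:
                    raise ValueError("signumber needs n_parcels or p-values")
                p = pearson_pvalues(r, n_parcels)
            out[name] = _bh_count_rows(p[member_idx].T, alpha).astype(float)
        elif name in ("ks", "weighted_ks"):
            if context is None:
                context = profile_rank_context(r)
            out[name] = _ks_profile_batch(r, member_idx, name == "weighted_ks",
                                          context, ks_variant)
        else:
            raise ValueError(f"unknown statistic {name!r}")
    return out
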