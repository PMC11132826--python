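"""Independent brute-force oracles used only by the test suite.

Every oracle encodes the defining computation directly (plain loops, an LP
over the definition, or a library routine not used by the implementation)
and stays independent of the code paths it checks.
"""

import numpy as np
from scipy.optimize import linprog


def moran_oracle(x, centroids):
    """Moran's I by literal double loop over the formula."""
    x = np.asarray(x, float)
    n = len(x)
    xbar = x.mean()
    num = 0.0
    wsum = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = 1.0 / np.linalg.norm(np.asarray(centroids[i]) - np.asarray(centroids[j]))
            wsum += w
            num += w * (x[i] - xbar) * (x[j] - xbar)
    den = ((x - xbar) ** 2).sum()
    return (n / wsum) * num / den


def mean_oracle(r):
    return sum(r) / len(r)


def meanabs_oracle(r):
    return sum(abs(v) for v in r) / len(r)


def meansqr_oracle(r):
    return sum(v * v for v in r) / len(r)


def median_oracle(r):
    s = sorted(r)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


def maxmean_oracle(r):
    pos = [v for v in r if v > 0]
    neg = [-v for v in r if v < 0]
    s_pos = sum(pos) / len(pos) if pos else 0.0
    s_neg = sum(neg) / len(neg) if neg else 0.0
    return max(s_pos, s_neg)


def bh_oracle(p):
    """Benjamini-Hochberg adjusted p-values by the textbook definition:
    adj_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for pos, i in enumerate(order):
        adj[i] = min(
            min(p[order[q]] * m / (q + 1) for q in range(pos, m)), 1.0
        )
    return adj


def signumber_oracle(p, alpha=0.05):
    return sum(1 for a in bh_oracle(p) if a < alpha)


def ks_oracle(r, member_flags, gene_ids, weighted, variant="gsea"):
    """Running-sum walk by explicit loop; ranking r desc, ties by gene id.

    variant="gsea": member steps w/sum(member w), non-member steps -1/(G-k);
    variant="literal": raw +/-w steps.
    """
    order = sorted(range(len(r)), key=lambda i: (-r[i], gene_ids[i]))
    k = sum(member_flags)
    g = len(r)
    inc_total = sum(
        (abs(r[i]) if weighted else 1.0) for i in range(g) if member_flags[i]
    )
    cum, best, best_abs = 0.0, None, -1.0
    for i in order:
        w = abs(r[i]) if weighted else 1.0
        if variant == "gsea":
            step = w / (inc_total or 1.0) if member_flags[i] else -1.0 / (g - k)
        else:
            step = w if member_flags[i] else -w
        cum += step
        if abs(cum) > best_abs:
            best_abs = abs(cum)
            best = cum
    return best


def ks_values_equivalent(a, b, rel=1e-6, tie_tol=1e-9):
    """Running-sum values agree, allowing opposite signs only on an exact
    tie between the positive and negative extremes (summation-order noise
    can break such ties either way)."""
    if a * b >= 0:
        return abs(a - b) <= rel * max(1.0, abs(b))
    return abs(abs(a) - abs(b)) <= tie_tol


def dip_lp_oracle(values):
    """min over unimodal CDFs G of sup|F_n - G| via LPs over the definition.

    G is piecewise linear between the sorted data points, convex before the
    mode and concave after; for the mode in segment f two LPs cover an atom
    at the segment's right knot (convex piece reaching it) or left knot
    (concave piece starting there); fully convex / fully concave cases cover
    modes beyond the data range.  Assumes distinct values.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    dlt = np.diff(x)
    assert np.all(dlt > 0)
    T = -1

    def solve(rows, rhs, n_extra):
        c = np.zeros(n + n_extra + 1)
        c[-1] = 1.0
        bounds = [(0.0, 1.0)] * (n + n_extra) + [(0.0, None)]
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds,
                      method="highs")
        return res.fun if res.status == 0 else np.inf

    def base(n_extra, skip_left=None, skip_right=None):
        rows, rhs = [], []

        def add(pairs, t_coef, b):
            row = np.zeros(n + n_extra + 1)
            for col, v in pairs:
                row[col] = v
            row[T] = t_coef
            rows.append(row)
            rhs.append(b)

        for i in range(n):
            if i != skip_right:
                add([(i, 1.0)], -1.0, (i + 1) / n)
                add([(i, -1.0)], -1.0, -(i + 1) / n)
            if i != skip_left:
                add([(i, 1.0)], -1.0, i / n)
                add([(i, -1.0)], -1.0, -i / n)
        for i in range(n - 1):
            add([(i, 1.0), (i + 1, -1.0)], 0.0, 0.0)
        return rows, rhs, add

    def slope_pair(add, i, sign):
        coefs = [(i, -1.0 / dlt[i]), (i + 1, 1.0 / dlt[i] + 1.0 / dlt[i + 1]),
                 (i + 2, -1.0 / dlt[i + 1])]
        if sign > 0:
            add(coefs, 0.0, 0.0)
        else:
            add([(c0, -v) for c0, v in coefs], 0.0, 0.0)

    best = np.inf
    for sign in (+1, -1):
        rows, rhs, add = base(0)
        for i in range(n - 2):
            slope_pair(add, i, sign)
        best = min(best, solve(rows, rhs, 0))

    E = n
    for f in range(n - 1):
        # atom at the right knot of segment f
        rows, rhs, add = base(1, skip_left=f + 1)
        add([(E, 1.0)], -1.0, (f + 1) / n)
        add([(E, -1.0)], -1.0, -(f + 1) / n)
        add([(f, 1.0), (E, -1.0)], 0.0, 0.0)
        add([(E, 1.0), (f + 1, -1.0)], 0.0, 0.0)
        if f >= 1:
            add([(f - 1, -1.0 / dlt[f - 1]), (f, 1.0 / dlt[f - 1] + 1.0 / dlt[f]),
                 (E, -1.0 / dlt[f])], 0.0, 0.0)
        for i in range(n - 2):
            if i + 1 <= f - 1:
                slope_pair(add, i, +1)
            if i >= f + 1:
                slope_pair(add, i, -1)
        best = min(best, solve(rows, rhs, 1))

        # atom at the left knot of segment f
        rows, rhs, add = base(1, skip_right=f)
        add([(E, 1.0)], -1.0, (f + 1) / n)
        add([(E, -1.0)], -1.0, -(f + 1) / n)
        add([(f, 1.0), (E, -1.0)], 0.0, 0.0)
        add([(E, 1.0), (f + 1, -1.0)], 0.0, 0.0)
        if f + 1 <= n - 2:
            add([(E, 1.0 / dlt[f]), (f + 1, -1.0 / dlt[f] - 1.0 / dlt[f + 1]),
                 (f + 2, 1.0 / dlt[f + 1])], 0.0, 0.0)
        for i in range(n - 2):
            if i + 1 <= f - 1:
                slope_pair(add, i, +1)
            if i >= f + 1:
                slope_pair(add, i, -1)
        best = min(best, solve(rows, rhs, 1))

    return best


def loro_oracle(map_values, gene_values):
    """Leave-one-out averaged Pearson correlation by explicit loop."""
    from scipy.stats import pearsonr

    n = len(map_values)
    acc = 0.0
    for left in range(n):
        keep = [i for i in range(n) if i != left]
        acc += pearsonr(np.asarray(map_values)[keep],
                        np.asarray(gene_values)[keep]).statistic
    return acc / n
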