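"""Hartigan & Hartigan dip statistic of unimodality.

The dip of an empirical distribution is the smallest sup-norm distance
between its CDF and any unimodal (convex-then-concave) CDF.  This module
implements the classical greatest-convex-minorant / least-concave-majorant
algorithm: the modal interval [low, high] is iteratively refined; within it
the maximum gap between the GCM and LCM fits is tracked, and outside it the
one-sided deviations of the empirical CDF from the convex minorant (left)
and concave majorant (right) bound the dip.  Distances are accumulated in
units of counts and halved at the end; the smallest attainable value is
1/(2n).

The test suite validates this implementation against an independent
linear-programming oracle that minimises sup|F_n - G| over piecewise-linear
unimodal CDFs directly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip"]


def _gcm_predecessors(x: np.ndarray) -> np.ndarray:
    """mn[j]: previous touch point of the greatest convex minorant at j."""
    n = x.size
    mn = np.zeros(n, dtype=np.intp)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    return mn


def _lcm_successors(x: np.ndarray) -> np.ndarray:
    """mj[k]: next touch point of the least concave majorant at k."""
    n = x.size
    mj = np.zeros(n, dtype=np.intp)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk
    return mj


def dip(values) -> float:
    """Dip statistic of a sample (always >= 1/(2n) for non-degenerate data).

    Returns 0.0 for samples of size < 2 or with all values equal.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if not np.all(np.isfinite(x)):
        raise ValueError("dip requires finite values")

    mn = _gcm_predecessors(x)
    mj = _lcm_successors(x)

    low, high = 0, n - 1
    best = 1.0  # in count units; yields the 1/(2n) floor

    while True:
        # GCM touch points from high down to low, LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])

        l_gcm = len(gcm)
        l_lcm = len(lcm)
        ig = l_gcm - 1
        ih = l_lcm - 1
        ix = l_gcm - 2
        iv = 1
        # Largest distance between the GCM and LCM curves inside [low, high].
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next change point comes from the LCM: distance of LCM
                    # point to the GCM chord
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # next change point comes from the GCM: distance of GCM
                    # point to the LCM chord
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < best:
            break

        # One-sided dip of the empirical CDF against the convex minorant
        # (left of the modal interval) ...
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                max_t = max(max_t, t.max())
            dip_l = max(dip_l, max_t)

        # ... and against the concave majorant (right of the modal interval).
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                jj = np.arange(jb, je + 1)
                t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                max_t = max(max_t, t.max())
            dip_u = max(dip_u, max_t)

        best = max(best, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high

    return best / (2 * n)
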