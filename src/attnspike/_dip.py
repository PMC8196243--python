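"""Hartigan & Hartigan dip statistic for unimodality.

Implements the iterative greatest-convex-minorant / least-concave-majorant
algorithm (Hartigan 1985, algorithm AS 217).  The dip is the maximum
difference, over all x, between the empirical distribution function and the
closest unimodal distribution function; large values indicate multimodality.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(values: np.ndarray) -> float:
    """Dip statistic of a 1-D sample.

    Parameters
    ----------
    values : array-like
        Sample values; need not be sorted. NaNs are rejected.

    Returns
    -------
    float
        The dip statistic in [0, 0.25]. Degenerate samples (n < 2 or all
        values identical) return 0.0.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if np.any(np.isnan(x)):
        raise ValueError("dip_statistic: input contains NaN")
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    dip = 1.0  # in units of counts; divided by 2n at the end

    # Touch points of the greatest convex minorant: mn[j] is the previous
    # vertex when walking left from j along the GCM of the ecdf.
    mn = np.zeros(n, dtype=np.intp)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # Touch points of the least concave majorant, walking right.
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

    while True:
        # GCM change points from high down to low; LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        ix = l_gcm - 2
        ig = l_gcm - 1

        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)
        iv = 1
        ih = l_lcm - 1

        # Largest vertical separation d between the GCM and LCM fits.
        if l_gcm == 2 and l_lcm == 2:
            d = 1.0
        else:
            d = 0.0
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / (
                        x[gcmix] - x[gcmi1]
                    )
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (x[lcmiv] - x[lcmiv1]) - (
                        gcmix - lcmiv1 - 1
                    )
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

        if d < dip:
            break

        # Max deviation of the ecdf below the GCM segments outside the modal
        # interval, and above the LCM segments on the other side.
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb = gcm[j + 1]
            je = gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb = lcm[j]
            je = lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew

        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)
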