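"""Numba kernels for pairwise-complete biweight midcorrelation.

The biweight midcorrelation down-weights observations by their distance
from the median in MAD units: u = (x - med) / (9 * MAD), w = (1 - u^2)^2
for |u| < 1 else 0, and correlates the weighted deviations.  When a
vector's MAD is zero the pair falls back to Pearson; pairs with fewer
than 4 complete observations yield NaN.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_PAIR_OBS = 4


@njit(cache=True)
def _pair_bicor(xi, xj):
    n = xi.size
    mi = np.median(xi)
    mj = np.median(xj)
    madi = np.median(np.abs(xi - mi))
    madj = np.median(np.abs(xj - mj))
    if madi == 0.0 or madj == 0.0:
        # Pearson fallback
        mx = xi.mean()
        my = xj.mean()
        sxy = 0.0
        sxx = 0.0
        syy = 0.0
        for s in range(n):
            dx = xi[s] - mx
            dy = xj[s] - my
            sxy += dx * dy
            sxx += dx * dx
            syy += dy * dy
        if sxx == 0.0 or syy == 0.0:
            return np.nan, True
        return sxy / np.sqrt(sxx * syy), True
    sxy = 0.0
    sxx = 0.0
    syy = 0.0
    for s in range(n):
        ui = (xi[s] - mi) / (9.0 * madi)
        uj = (xj[s] - mj) / (9.0 * madj)
        wi = (1.0 - ui * ui) ** 2 if abs(ui) < 1.0 else 0.0
        wj = (1.0 - uj * uj) ** 2 if abs(uj) < 1.0 else 0.0
        a = (xi[s] - mi) * wi
        b = (xj[s] - mj) * wj
        sxy += a * b
        sxx += a * a
        syy += b * b
    if sxx == 0.0 or syy == 0.0:
        return np.nan, True
    r = sxy / np.sqrt(sxx * syy)
    if r > 1.0:
        r = 1.0
    elif r < -1.0:
        r = -1.0
    return r, False


@njit(cache=True)
def bicor_matrix_kernel(X, M):
    """All-pairs bicor of the rows of X; M marks observed entries.

    Returns the correlation matrix and a count of pairs that needed the
    Pearson fallback or had too few complete observations (NaN result).
    """
    p, n = X.shape
    out = np.empty((p, p))
    n_fallback = 0
    for i in range(p):
        out[i, i] = 1.0
        for j in range(i + 1, p):
            cnt = 0
            for s in range(n):
                if M[i, s] and M[j, s]:
                    cnt += 1
            if cnt < MIN_PAIR_OBS:
                out[i, j] = np.nan
                out[j, i] = np.nan
                n_fallback += 1
                continue
            xi = np.empty(cnt)
            xj = np.empty(cnt)
            c = 0
            for s in range(n):
                if M[i, s] and M[j, s]:
                    xi[c] = X[i, s]
                    xj[c] = X[j, s]
                    c += 1
            r, fb = _pair_bicor(xi, xj)
            if fb:
                n_fallback += 1
            out[i, j] = r
            out[j, i] = r
    return out, n_fallback


@njit(cache=True)
def bicor_cross_kernel(X, MX, Y, MY):
    """Bicor of every row of X against every row of Y (pairwise complete)."""
    p, n = X.shape
    k = Y.shape[0]
    out = np.empty((p, k))
    for i in range(p):
        for j in range(k):
            cnt = 0
            for s in range(n):
                if MX[i, s] and MY[j, s]:
                    cnt += 1
            if cnt < MIN_PAIR_OBS:
                out[i, j] = np.nan
                continue
            xi = np.empty(cnt)
            xj = np.empty(cnt)
            c = 0
            for s in range(n):
                if MX[i, s] and MY[j, s]:
                    xi[c] = X[i, s]
                    xj[c] = Y[j, s]
                    c += 1
            r, _ = _pair_bicor(xi, xj)
            out[i, j] = r
    return out
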