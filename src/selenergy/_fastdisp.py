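"""Compiled kernel for the batched dispersion-F computation.

For each of ``m`` two-group label vectors the kernel runs a Weiszfeld
iteration per group to the spatial median, then forms the one-way ANOVA F of
the distances from each sample to its own group median.  Medians may be
warm-started, which the greedy selection loop exploits (candidate subsets
differ from the accepted subset by one column).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def permdisp_kernel(X, masks0, n1, n2, tol, max_iter, med0, med1, warm):
    m, n = masks0.shape
    s = X.shape[1]
    f = np.empty(m)
    for r in range(m):
        if not warm:
            for c in range(s):
                acc0 = 0.0
                acc1 = 0.0
                for i in range(n):
                    if masks0[r, i]:
                        acc0 += X[i, c]
                    else:
                        acc1 += X[i, c]
                med0[r, c] = acc0 / n1
                med1[r, c] = acc1 / n2
        new0 = np.empty(s)
        new1 = np.empty(s)
        for _ in range(max_iter):
            shift = 0.0
            for g in range(2):
                med = med0[r] if g == 0 else med1[r]
                new = new0 if g == 0 else new1
                wsum = 0.0
                for c in range(s):
                    new[c] = 0.0
                for i in range(n):
                    if (masks0[r, i] and g == 0) or ((not masks0[r, i]) and g == 1):
                        d2 = 0.0
                        for c in range(s):
                            diff = X[i, c] - med[c]
                            d2 += diff * diff
                        d = np.sqrt(d2)
                        if d < 1e-12:
                            d = 1e-12
                        w = 1.0 / d
                        wsum += w
                        for c in range(s):
                            new[c] += w * X[i, c]
                for c in range(s):
                    new[c] /= wsum
                    delta = abs(new[c] - med[c])
                    if delta > shift:
                        shift = delta
                    med[c] = new[c]
            if shift < tol:
                break
        # residual ANOVA F
        sum0 = 0.0
        sum1 = 0.0
        for i in range(n):
            med = med0[r] if masks0[r, i] else med1[r]
            d2 = 0.0
            for c in range(s):
                diff = X[i, c] - med[c]
                d2 += diff * diff
            d = np.sqrt(d2)
            if masks0[r, i]:
                sum0 += d
            else:
                sum1 += d
        mean0 = sum0 / n1
        mean1 = sum1 / n2
        grand = (sum0 + sum1) / n
        ssb = n1 * (mean0 - grand) ** 2 + n2 * (mean1 - grand) ** 2
        ssw = 0.0
        for i in range(n):
            if masks0[r, i]:
                med = med0[r]
                mg = mean0
            else:
                med = med1[r]
                mg = mean1
            d2 = 0.0
            for c in range(s):
                diff = X[i, c] - med[c]
                d2 += diff * diff
            resid = np.sqrt(d2) - mg
            ssw += resid * resid
        if ssw > 0.0:
            f[r] = ssb / (ssw / (n - 2))
        elif ssb > 0.0:
            f[r] = np.inf
        else:
            f[r] = 0.0
    return f
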