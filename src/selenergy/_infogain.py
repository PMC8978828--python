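"""Supervised MDL (minimum description length) discretization and the
information gain of a binary class variable given a discretized attribute.

Entropies use natural logarithms.  The recursive binary-cut search accepts a
cut only when its gain exceeds the MDL coding cost; when no cut is accepted
anywhere, a median split is used as a fallback so every non-constant attribute
receives a defined (possibly small) gain.

The hot path is compiled with numba when available; a pure-numpy twin with
identical semantics is kept for environments without a working compiler.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _ent(ones: int, total: int) -> float:
    if total <= 0:
        return 0.0
    h = 0.0
    if ones > 0:
        p = ones / total
        h -= p * math.log(p)
    zeros = total - ones
    if zeros > 0:
        p = zeros / total
        h -= p * math.log(p)
    return h


@njit(cache=True)
def _info_gain_sorted(xs: np.ndarray, ys: np.ndarray) -> float:
    n = xs.shape[0]
    cum = np.empty(n + 1, np.int64)
    cum[0] = 0
    for i in range(n):
        cum[i + 1] = cum[i] + ys[i]
    total1 = cum[n]
    h_total = _ent(total1, n)
    if h_total == 0.0 or xs[0] == xs[n - 1]:
        return 0.0

    lo_stack = np.empty(n + 2, np.int64)
    hi_stack = np.empty(n + 2, np.int64)
    top = 0
    lo_stack[0] = 0
    hi_stack[0] = n
    top = 1
    cond = 0.0  # sum over leaf bins of n_bin * H(y | bin)
    n_cuts = 0
    while top > 0:
        top -= 1
        lo = lo_stack[top]
        hi = hi_stack[top]
        m = hi - lo
        ones = cum[hi] - cum[lo]
        h_seg = _ent(ones, m)
        if m < 2 or h_seg == 0.0:
            cond += m * h_seg
            continue
        best_i = -1
        best_we = 1e300
        for i in range(lo, hi - 1):
            if xs[i] < xs[i + 1]:
                nl = i + 1 - lo
                ol = cum[i + 1] - cum[lo]
                nr = m - nl
                orr = ones - ol
                we = (nl * _ent(ol, nl) + nr * _ent(orr, nr)) / m
                if we < best_we:
                    best_we = we
                    best_i = i
        if best_i < 0:
            cond += m * h_seg
            continue
        nl = best_i + 1 - lo
        ol = cum[best_i + 1] - cum[lo]
        nr = m - nl
        orr = ones - ol
        gain = h_seg - best_we
        h_l = _ent(ol, nl)
        h_r = _ent(orr, nr)
        k1 = 2 if 0 < ol < nl else 1
        k2 = 2 if 0 < orr < nr else 1
        delta = math.log(3.0 ** 2 - 2.0) - (2.0 * h_seg - k1 * h_l - k2 * h_r)
        threshold = (math.log(m - 1.0) + delta) / m
        if gain > threshold:
            n_cuts += 1
            lo_stack[top] = lo
            hi_stack[top] = best_i + 1
            top += 1
            lo_stack[top] = best_i + 1
            hi_stack[top] = hi
            top += 1
        else:
            cond += m * h_seg

    if n_cuts == 0:
        # fallback: single median split
        med = 0.5 * (xs[(n - 1) // 2] + xs[n // 2])
        nl = 0
        for i in range(n):
            if xs[i] < med:
                nl += 1
        if nl == 0 or nl == n:
            nl = 0
            for i in range(n):
                if xs[i] <= med:
                    nl += 1
            if nl == 0 or nl == n:
                return 0.0
        ol = cum[nl]
        cond = nl * _ent(ol, nl) + (n - nl) * _ent(total1 - ol, n - nl)

    return h_total - cond / n


@njit(cache=True)
def _info_gain_matrix(zs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    n, p = zs.shape
    out = np.empty(p)
    for j in range(p):
        out[j] = _info_gain_sorted(np.ascontiguousarray(zs[:, j]),
                                   np.ascontiguousarray(ys[:, j]))
    return out


def info_gain_mdl(sorted_values: np.ndarray, sorted_codes: np.ndarray) -> np.ndarray:
    """Per-column MDL information gain.

    Parameters are the value matrix sorted within each column and the 0/1
    class codes rearranged by the same per-column order.
    """
    zs = np.asfortranarray(sorted_values, dtype=np.float64)
    ys = np.asfortranarray(sorted_codes, dtype=np.int64)
    return _info_gain_matrix(zs, ys)


def info_gain_equal_frequency(sorted_values: np.ndarray, sorted_codes: np.ndarray,
                              n_bins: int) -> np.ndarray:
    """Information gain using equal-frequency binning (alternative discretizer)."""
    n, p = sorted_values.shape
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    total1 = sorted_codes.sum(axis=0)
    h_total = _entropy_vec(total1, n)
    cond = np.zeros(p)
    cum = np.vstack([np.zeros(p, dtype=np.int64), np.cumsum(sorted_codes, axis=0)])
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        m = hi - lo
        if m == 0:
            continue
        ones = cum[hi] - cum[lo]
        cond += m * _entropy_vec(ones, m)
    return h_total - cond / n


def _entropy_vec(ones: np.ndarray, total: int) -> np.ndarray:
    ones = np.asarray(ones, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = ones / total
        p0 = 1.0 - p1
        h = -np.where(p1 > 0, p1 * np.log(p1), 0.0) - np.where(p0 > 0, p0 * np.log(p0), 0.0)
    return h
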