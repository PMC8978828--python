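"""Multivariate two-sample association statistics on logratio coordinates.

Implements the energy-partition F ratio (discoF), PERMANOVA F, a dispersion F
based on distances to per-group spatial medians, their raw and
permutation-scaled combination, plus comparator statistics (two-sample energy
statistic, ANOSIM R).  Internal ``*_batch`` helpers evaluate a statistic for
many permuted label vectors at once; the permutation machinery and the greedy
selection loop rely on them for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import _fastdisp
from .compositional import GroupLabels, LogratioFrame

__all__ = [
    "DistanceMatrix",
    "AssociationStatistic",
    "euclidean_distances",
    "disco_f",
    "energy_statistic",
    "permanova_f",
    "permdisp_f",
    "spatial_median",
    "combined_f_raw",
    "scaled_combined_f",
    "dispersion_detected",
    "anosim_r",
]

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    values: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.abs(v - v.T) > _SYM_TOL):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AssociationStatistic:
    kind: str
    value: float
    parts: dict = field(default_factory=dict)
    alpha_exponent: float = 1.0

    def to_dict(self) -> dict:
        """JSON-ready payload: kind, value, parts and settings."""

        def _clean(v):
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (tuple, list)):
                return [_clean(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {"kind": self.kind, "value": float(self.value),
                "parts": _clean(self.parts),
                "alpha_exponent": self.alpha_exponent}


def euclidean_distances(Z: LogratioFrame) -> DistanceMatrix:
    """Inter-sample Euclidean distance matrix of the frame's rows."""
    X = Z.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.maximum(d2, 0.0))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, Z.sample_ids)


def _two_group_codes(y: GroupLabels) -> tuple[np.ndarray, int, int]:
    if y.n_classes != 2:
        raise ValueError("statistic requires exactly 2 groups")
    y.require_min_per_class(2)
    codes = y.codes
    return codes, int((codes == 0).sum()), int((codes == 1).sum())


# ---------------------------------------------------------------------------
# energy / DISCO


def _group_pair_sums(A: np.ndarray, codes: np.ndarray):
    """Sums of A over the within-group and between-group blocks."""
    m0 = codes == 0
    s00 = A[np.ix_(m0, m0)].sum()
    s11 = A[np.ix_(~m0, ~m0)].sum()
    s01 = A[np.ix_(m0, ~m0)].sum()
    return s00, s11, s01


def disco_f(D: DistanceMatrix, y: GroupLabels, alpha: float = 1.0) -> AssociationStatistic:
    """Energy-partition F: between dispersion over within dispersion.

    Total dispersion ``T = (n/2) * mean(d^alpha)`` over all ordered pairs is
    split into within-group ``W = sum_g (n_g/2) * mean_g(d^alpha)`` and
    between ``S = T - W``; the statistic is ``S / (W / (n - 2))``.
    """
    if not (0 < alpha <= 2):
        raise ValueError("alpha must be in (0, 2]")
    codes, n1, n2 = _two_group_codes(y)
    n = n1 + n2
    if n < 4:
        raise ValueError("need at least 4 samples")
    A = D.values if alpha == 1.0 else D.values ** alpha
    s00, s11, s01 = _group_pair_sums(A, codes)
    T = (n / 2.0) * (s00 + s11 + 2 * s01) / n ** 2
    W = s00 / (2.0 * n1) + s11 / (2.0 * n2)
    S = T - W
    value = np.inf if W == 0 else S / (W / (n - 2))
    return AssociationStatistic(
        "discoF", float(value),
        parts={"S": float(S), "W": float(W), "total": float(T)},
        alpha_exponent=alpha,
    )


def energy_statistic(D: DistanceMatrix, y: GroupLabels) -> AssociationStatistic:
    """Two-sample energy statistic
    ``(n1*n2/n) * (2*mean_between - mean_within1 - mean_within2)``."""
    if y.n_classes != 2:
        raise ValueError("statistic requires exactly 2 groups")
    codes = y.codes
    n1 = int((codes == 0).sum())
    n2 = int((codes == 1).sum())
    s00, s11, s01 = _group_pair_sums(D.values, codes)
    value = (n1 * n2 / (n1 + n2)) * (
        2.0 * s01 / (n1 * n2) - s00 / n1 ** 2 - s11 / n2 ** 2
    )
    return AssociationStatistic("energy", float(value))


# ---------------------------------------------------------------------------
# PERMANOVA


def _gower_ss(D2: np.ndarray, codes: np.ndarray, n_groups: int):
    n = D2.shape[0]
    ss_t = D2.sum() / (2.0 * n)
    ss_w = 0.0
    for g in range(n_groups):
        m = codes == g
        ng = int(m.sum())
        ss_w += D2[np.ix_(m, m)].sum() / (2.0 * ng)
    return ss_t, ss_t - ss_w, ss_w


def permanova_f(D: DistanceMatrix, y: GroupLabels) -> AssociationStatistic:
    """Distance-based ANOVA F from the squared-distance partition."""
    y.require_min_per_class(1)
    a = y.n_classes
    n = D.n
    D2 = D.values ** 2
    ss_t, ss_a, ss_w = _gower_ss(D2, y.codes, a)
    parts = {"SS_T": float(ss_t), "SS_A": float(ss_a), "SS_W": float(ss_w),
             "df_between": a - 1, "df_within": n - a, "zero_within": ss_w == 0}
    if ss_w == 0:
        return AssociationStatistic("permanovaF", float("inf"), parts)
    value = (ss_a / (a - 1)) / (ss_w / (n - a))
    return AssociationStatistic("permanovaF", float(value), parts)


def _permanova_f_batch(D2: np.ndarray, masks0: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """Two-group PERMANOVA F for a batch of group-0 indicator rows (m, n)."""
    n = D2.shape[0]
    ss_t = D2.sum() / (2.0 * n)
    A0 = masks0.astype(float)
    A1 = 1.0 - A0
    P0 = A0 @ D2
    q0 = (P0 * A0).sum(axis=1)
    q1 = ((D2.sum(axis=0)[None, :] - P0) * A1).sum(axis=1)
    ss_w = q0 / (2.0 * n1) + q1 / (2.0 * n2)
    ss_a = ss_t - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss_w > 0, ss_a / (ss_w / (n - 2)), np.inf)
    return f


# ---------------------------------------------------------------------------
# spatial medians / dispersion F


def spatial_median(X: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Weiszfeld iteration for the point minimizing summed Euclidean distance."""
    X = np.asarray(X, dtype=float)
    med = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - med, axis=1)
        d = np.maximum(d, 1e-12)
        w = 1.0 / d
        new = (w[:, None] * X).sum(axis=0) / w.sum()
        shift = np.linalg.norm(new - med)
        med = new
        if shift < tol:
            return med
    raise RuntimeError(f"spatial median did not converge in {max_iter} iterations")


def _permdisp_f_batch(X: np.ndarray, masks0: np.ndarray, n1: int, n2: int,
                      tol: float = 1e-5, max_iter: int = 400,
                      chunk: int = 512, med_init=None,
                      return_medians: bool = False):
    """Dispersion F for a batch of group-0 indicator rows (m, n).

    For each label vector, per-group spatial medians are found by a Weiszfeld
    iteration; the statistic is the one-way ANOVA F of each sample's distance
    to its own group median.  ``med_init`` may warm-start the iteration with
    ``(medians0, medians1)`` arrays of shape (m, n_cols); with
    ``return_medians`` the converged medians are returned alongside.
    Dispatches to a compiled kernel when numba is available.
    """
    m_total, n = masks0.shape
    if _fastdisp.HAVE_NUMBA and X.shape[1] > 0:
        Xc = np.ascontiguousarray(X)
        masks = np.ascontiguousarray(masks0)
        s = X.shape[1]
        if med_init is not None:
            med0 = np.ascontiguousarray(med_init[0], dtype=float)
            med1 = np.ascontiguousarray(med_init[1], dtype=float)
            warm = True
        else:
            med0 = np.zeros((m_total, s))
            med1 = np.zeros((m_total, s))
            warm = False
        f = _fastdisp.permdisp_kernel(Xc, masks, n1, n2, tol, max_iter,
                                      med0, med1, warm)
        if return_medians:
            return f, (med0, med1)
        return f
    return _permdisp_f_batch_numpy(X, masks0, n1, n2, tol, max_iter, chunk,
                                   med_init, return_medians)


def _permdisp_f_batch_numpy(X: np.ndarray, masks0: np.ndarray, n1: int, n2: int,
                            tol: float = 1e-5, max_iter: int = 400,
                            chunk: int = 512, med_init=None,
                            return_medians: bool = False):
    m_total, n = masks0.shape
    if X.shape[1] == 0:
        zero = np.zeros(m_total)
        return (zero, None) if return_medians else zero
    if med_init is not None and m_total > chunk:
        chunk = m_total
    out = np.empty(m_total)
    med_out = None
    Xt = X.T
    x_sq = (X ** 2).sum(axis=1)

    def _dist(med: np.ndarray) -> np.ndarray:
        # squared-norm expansion: ||x - m||^2 = ||x||^2 + ||m||^2 - 2 x.m
        d2 = x_sq[None, :] + (med ** 2).sum(axis=1)[:, None] - 2.0 * (med @ Xt)
        return np.sqrt(np.maximum(d2, 0.0))

    for start in range(0, m_total, chunk):
        A0 = masks0[start:start + chunk].astype(float)
        A1 = 1.0 - A0
        m = A0.shape[0]
        if med_init is not None:
            med0 = np.array(med_init[0], dtype=float)
            med1 = np.array(med_init[1], dtype=float)
        else:
            med0 = (A0 @ X) / n1
            med1 = (A1 @ X) / n2
        for _ in range(max_iter):
            w0 = A0 / np.maximum(_dist(med0), 1e-12)
            w1 = A1 / np.maximum(_dist(med1), 1e-12)
            new0 = (w0 @ X) / w0.sum(axis=1, keepdims=True)
            new1 = (w1 @ X) / w1.sum(axis=1, keepdims=True)
            shift = max(np.abs(new0 - med0).max(), np.abs(new1 - med1).max())
            med0, med1 = new0, new1
            if shift < tol:
                break
        d0 = _dist(med0)
        d1 = _dist(med1)
        resid = A0 * d0 + A1 * d1
        mean0 = (A0 * resid).sum(axis=1) / n1
        mean1 = (A1 * resid).sum(axis=1) / n2
        grand = resid.sum(axis=1) / n
        ssb = n1 * (mean0 - grand) ** 2 + n2 * (mean1 - grand) ** 2
        ssw = (A0 * (resid - mean0[:, None]) ** 2).sum(axis=1) \
            + (A1 * (resid - mean1[:, None]) ** 2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ssw > 0, ssb / (ssw / (n - 2)),
                         np.where(ssb > 0, np.inf, 0.0))
        out[start:start + m] = f
        if return_medians:
            med_out = (med0, med1)
    if return_medians:
        return out, med_out
    return out


def permdisp_f(Zp: LogratioFrame, y: GroupLabels) -> AssociationStatistic:
    """Dispersion heterogeneity F: ANOVA on distances to group spatial medians."""
    codes, n1, n2 = _two_group_codes(y)
    X = Zp.values
    med0 = spatial_median(X[codes == 0])
    med1 = spatial_median(X[codes == 1])
    resid = np.where(codes == 0,
                     np.linalg.norm(X - med0, axis=1),
                     np.linalg.norm(X - med1, axis=1))
    n = n1 + n2
    mean0 = resid[codes == 0].mean()
    mean1 = resid[codes == 1].mean()
    grand = resid.mean()
    ss_t = ((resid - grand) ** 2).sum()
    ssb = n1 * (mean0 - grand) ** 2 + n2 * (mean1 - grand) ** 2
    ssw = ((resid[codes == 0] - mean0) ** 2).sum() + ((resid[codes == 1] - mean1) ** 2).sum()
    if ssw == 0:
        value = np.inf if ssb > 0 else 0.0
    else:
        value = ssb / (ssw / (n - 2))
    parts = {"SS_T": float(ss_t), "SS_E": float(ssw), "SS_between": float(ssb),
             "residual_means": (float(mean0), float(mean1))}
    return AssociationStatistic("permdispF", float(value), parts)


# ---------------------------------------------------------------------------
# combined statistics


def combined_f_raw(Zp: LogratioFrame, y: GroupLabels) -> AssociationStatistic:
    """Unscaled combined F: location F plus dispersion F on Euclidean distances."""
    loc = permanova_f(euclidean_distances(Zp), y)
    disp = permdisp_f(Zp, y)
    parts = {"F_location": loc.value, "F_dispersion": disp.value,
             "location_parts": loc.parts, "dispersion_parts": disp.parts}
    return AssociationStatistic("cF_raw", loc.value + disp.value, parts)


def _perm_masks(perm_labels, y: GroupLabels) -> np.ndarray:
    """Stack permuted label vectors into a (m, n) group-0 indicator matrix."""
    if isinstance(perm_labels, np.ndarray) and perm_labels.ndim == 2 \
            and np.issubdtype(perm_labels.dtype, np.integer):
        return perm_labels == 0
    lookup = {c: i for i, c in enumerate(y.classes)}
    rows = []
    for lab in perm_labels:
        rows.append(np.array([lookup[str(v)] for v in np.asarray(lab)]) == 0)
    return np.asarray(rows)


def scaled_combined_f(Zp: LogratioFrame, y: GroupLabels,
                      perm_labels) -> AssociationStatistic:
    """Combined F with each component z-scored against its permutation null.

    ``perm_labels`` is a reusable set of >= 30 permuted label vectors (or an
    (m, n) integer code matrix); the same set should be supplied across calls
    when statistics are to be compared.
    """
    codes, n1, n2 = _two_group_codes(y)
    masks0 = _perm_masks(perm_labels, y)
    m = masks0.shape[0]
    if m < 30:
        raise ValueError("need at least 30 permuted label vectors")
    D2 = _squared_distances(Zp.values)
    f_loc = float(_permanova_f_batch(D2, (codes == 0)[None, :], n1, n2)[0])
    f_disp = float(_permdisp_f_batch(Zp.values, (codes == 0)[None, :], n1, n2)[0])
    null_loc = _permanova_f_batch(D2, masks0, n1, n2)
    null_disp = _permdisp_f_batch(Zp.values, masks0, n1, n2)
    mu_l, sd_l = null_loc.mean(), null_loc.std(ddof=1)
    mu_d, sd_d = null_disp.mean(), null_disp.std(ddof=1)
    if sd_l == 0 or sd_d == 0:
        raise ValueError("degenerate permutation null (zero standard deviation)")
    f_hat_loc = (f_loc - mu_l) / sd_l
    f_hat_disp = (f_disp - mu_d) / sd_d
    parts = {"F_location": f_loc, "F_dispersion": f_disp,
             "F_hat_loc": f_hat_loc, "F_hat_disp": f_hat_disp,
             "null_mean_loc": float(mu_l), "null_sd_loc": float(sd_l),
             "null_mean_disp": float(mu_d), "null_sd_disp": float(sd_d),
             "m": m}
    return AssociationStatistic("cF_scaled", f_hat_loc + f_hat_disp, parts)


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = (X ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def dispersion_detected(Zp: LogratioFrame, y: GroupLabels, k: int = 999,
                        alpha_level: float = 0.05,
                        rng: np.random.Generator | int | None = None) -> bool:
    """Permutation test of the dispersion F; True iff ``p <= alpha_level``.

    ``p = (1 + #{null > observed}) / (k + 1)`` with ``k`` label permutations.
    """
    if k < 99:
        raise ValueError("use at least 99 permutations")
    codes, n1, n2 = _two_group_codes(y)
    rng = np.random.default_rng(rng)
    masks0 = np.empty((k, y.n), dtype=bool)
    for i in range(k):
        masks0[i] = rng.permutation(codes) == 0
    obs = float(_permdisp_f_batch(Zp.values, (codes == 0)[None, :], n1, n2)[0])
    null = _permdisp_f_batch(Zp.values, masks0, n1, n2)
    p = (1.0 + np.sum(null > obs)) / (k + 1.0)
    return bool(p <= alpha_level)


# ---------------------------------------------------------------------------
# ANOSIM


def anosim_r(D: DistanceMatrix, y: GroupLabels) -> AssociationStatistic:
    """Rank-based separation R in [-1, 1]."""
    if y.n_classes < 2:
        raise ValueError("need at least 2 groups")
    n = D.n
    iu = np.triu_indices(n, 1)
    dist = D.values[iu]
    ranks = rankdata(dist)
    same = y.codes[iu[0]] == y.codes[iu[1]]
    m = n * (n - 1) / 2
    r = (ranks[~same].mean() - ranks[same].mean()) / (m / 2.0)
    return AssociationStatistic("anosimR", float(r))
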