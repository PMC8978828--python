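"""Differential-variation scoring of pairwise logratios.

Each logratio column receives five components measuring between-group signal:

1. absolute Welch t-statistic (location, variance-weighted),
2. a mean-difference F ratio with denominator ``var_c1 + var_c2``,
3. the Brown-Forsythe statistic (spread heterogeneity around class medians),
4. the two-sample Kolmogorov-Smirnov sup-distance,
5. information gain of the class labels given the MDL-discretized logratio.

Components are z-standardized across logratios and summed into one score per
ratio.  The final score is invariant to the arbitrary orientation of each
ratio (component 1 uses ``|t|``; the others are sign-symmetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._infogain import info_gain_equal_frequency, info_gain_mdl
from .compositional import GroupLabels, LogratioFrame

__all__ = ["DCVMatrix", "DCVScores", "dcv_component_matrix", "dcv_scores"]

_DENOM_FLOOR = 1e-12

COMPONENT_NAMES = ("welch_t_abs", "mean_diff_f", "brown_forsythe_f",
                   "ks_distance", "information_gain")


@dataclass
class DCVMatrix:
    """p logratios x 5 components, aligned with the source frame's ratios."""

    components: np.ndarray
    ratio_names: list[str]

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[1] != 5:
            raise ValueError("components must be a p x 5 matrix")
        if self.components.shape[0] != len(self.ratio_names):
            raise ValueError("ratio_names length mismatch")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("non-finite component values")


@dataclass
class DCVScores:
    """Aggregated per-ratio scores with the component matrix they came from."""

    scores: np.ndarray
    ratio_names: list[str]
    components: DCVMatrix
    standardized: np.ndarray

    def ranked(self) -> list[tuple[str, float]]:
        """Ratios sorted by descending score, ties broken by ratio name."""
        order = sorted(range(len(self.ratio_names)),
                       key=lambda i: (-self.scores[i], self.ratio_names[i]))
        return [(self.ratio_names[i], float(self.scores[i])) for i in order]


def _sorted_views(values: np.ndarray, codes: np.ndarray):
    idx = np.argsort(values, axis=0, kind="stable")
    zs = np.take_along_axis(values, idx, axis=0)
    ys = codes[idx]
    return zs, ys


def dcv_component_matrix(
    Z: LogratioFrame,
    y: GroupLabels,
    discretization: str | int = "mdl",
    _presorted: tuple[np.ndarray, np.ndarray] | None = None,
) -> DCVMatrix:
    """Compute the 5-component matrix for every logratio column of ``Z``.

    ``discretization`` selects the information-gain binning: ``"mdl"``
    (default) or an integer number of equal-frequency bins.  ``_presorted``
    optionally supplies ``(sorted_values, argsort_index)`` computed once for
    the frame; only label-dependent work is then redone (used by the
    permutation machinery, where the data are fixed and labels vary).
    """
    if y.n_classes != 2:
        raise ValueError("component scoring is defined for exactly 2 classes")
    y.require_min_per_class(2)
    values = Z.values
    if values.shape[0] != y.n:
        raise ValueError("frame and labels disagree on sample count")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite logratio values")

    codes = y.codes
    n1 = int((codes == 0).sum())
    n2 = int((codes == 1).sum())
    n = n1 + n2
    g1 = values[codes == 0]
    g2 = values[codes == 1]

    m1 = g1.mean(axis=0)
    m2 = g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    mbar = values.mean(axis=0)

    # component 1: |Welch t|
    num1 = np.abs(m1 - m2)
    den1 = np.sqrt(np.maximum(v1 / n1 + v2 / n2, 0.0))
    c1 = np.where(num1 == 0, 0.0, num1 / np.maximum(den1, _DENOM_FLOOR))

    # component 2: mean-difference F with var_c1 + var_c2 denominator
    num2 = n1 * (m1 - mbar) ** 2 + n2 * (m2 - mbar) ** 2
    c2 = np.where(num2 == 0, 0.0, num2 / np.maximum(v1 + v2, _DENOM_FLOOR))

    # component 3: Brown-Forsythe on absolute deviations from class medians
    b1 = np.abs(g1 - np.median(g1, axis=0))
    b2 = np.abs(g2 - np.median(g2, axis=0))
    bb1 = b1.mean(axis=0)
    bb2 = b2.mean(axis=0)
    bball = (n1 * bb1 + n2 * bb2) / n
    num3 = n1 * (bb1 - bball) ** 2 + n2 * (bb2 - bball) ** 2
    den3 = (((b1 - bb1) ** 2).sum(axis=0) + ((b2 - bb2) ** 2).sum(axis=0)) / (n - 2)
    c3 = np.where(num3 == 0, 0.0, num3 / np.maximum(den3, _DENOM_FLOOR))

    # components 4 and 5 work on per-column sorted views
    if _presorted is not None:
        zs, idx = _presorted
        ys = codes[idx]
    else:
        zs, ys = _sorted_views(values, codes)

    step = np.where(ys == 0, 1.0 / n1, -1.0 / n2)
    cum = np.cumsum(step, axis=0)
    distinct = np.ones_like(cum, dtype=bool)
    distinct[:-1] = zs[:-1] != zs[1:]
    c4 = np.max(np.abs(np.where(distinct, cum, 0.0)), axis=0)

    if discretization == "mdl":
        c5 = info_gain_mdl(zs, ys)
    elif isinstance(discretization, int) and discretization >= 2:
        c5 = info_gain_equal_frequency(zs, ys, discretization)
    else:
        raise ValueError("discretization must be 'mdl' or an integer >= 2")

    constant = zs[-1] == zs[0]
    components = np.column_stack([c1, c2, c3, c4, c5])
    components[constant] = 0.0
    return DCVMatrix(components, Z.ratio_names)


def dcv_scores(V: DCVMatrix) -> DCVScores:
    """Z-standardize each component column over the p ratios and sum rows.

    Zero-variance columns contribute 0 to every score; with a single ratio the
    standard deviation is undefined and all standardized values are 0.
    """
    comps = V.components
    p = comps.shape[0]
    if p == 1:
        warnings.warn("only one logratio: standardized components set to 0",
                      stacklevel=2)
        std = np.zeros_like(comps)
    else:
        mean = comps.mean(axis=0)
        sd = comps.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            std = np.where(sd > 0, (comps - mean) / sd, 0.0)
    scores = std.sum(axis=1)
    return DCVScores(scores, list(V.ratio_names), V, std)
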