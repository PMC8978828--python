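"""Compositional preprocessing: count validation, prevalence filtering, closure,
multiplicative zero replacement, and pairwise-logratio construction.

All downstream analysis operates on the full frame of pairwise logratios (PLR)
between taxa.  For ``d`` taxa there are ``d*(d-1)/2`` unordered pairs; only one
orientation per pair is kept, following the lower-off-diagonal convention
(numerator = later taxon in column order), i.e. columns are ordered
``t2/t1, t3/t1, ..., td/t1, t3/t2, ..., td/t(d-1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountTable",
    "Composition",
    "LogratioFrame",
    "GroupLabels",
    "prevalence_filter",
    "closure",
    "multiplicative_zero_replacement",
    "pairwise_logratio_frame",
    "ratio_name",
]

_ROW_SUM_TOL = 1e-9


def ratio_name(numerator: str, denominator: str) -> str:
    """Stable display / sort key of a logratio: ``"num/den"``."""
    return f"{numerator}/{denominator}"


@dataclass
class CountTable:
    """A samples x taxa matrix of nonnegative integer counts."""

    counts: np.ndarray
    sample_ids: list[str]
    taxon_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x taxa)")
        n, d = self.counts.shape
        if len(self.sample_ids) != n or len(self.taxon_names) != d:
            raise ValueError("sample_ids / taxon_names lengths do not match counts shape")
        if d < 2:
            raise ValueError("need at least 2 taxa")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if len(set(self.taxon_names)) != d:
            raise ValueError("taxon names must be unique")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be integers")
        row_sums = self.counts.sum(axis=1)
        if np.any(row_sums == 0):
            bad = [s for s, t in zip(self.sample_ids, row_sums) if t == 0]
            raise ValueError(f"samples with all-zero counts: {bad}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class Composition:
    """A samples x taxa matrix whose rows lie on the unit-sum simplex."""

    values: np.ndarray
    taxon_names: list[str]
    sample_ids: list[str] | None = None
    strictly_positive: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.taxon_names) != self.values.shape[1]:
            raise ValueError("taxon_names length does not match values")
        if self.sample_ids is not None and len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match values")
        if np.any(self.values < 0):
            raise ValueError("composition entries must be nonnegative")
        if np.any(np.abs(self.values.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("composition rows must sum to 1 within 1e-9")
        if self.strictly_positive and np.any(self.values <= 0):
            raise ValueError("composition flagged strictly positive contains zeros")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class LogratioFrame:
    """A samples x p matrix of logratio columns with their (num, den) labels."""

    values: np.ndarray
    ratios: list[tuple[str, str]]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.ratios):
            raise ValueError("column count does not match ratio labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_ratios(self) -> int:
        return self.values.shape[1]

    @property
    def ratio_names(self) -> list[str]:
        return [ratio_name(a, b) for a, b in self.ratios]

    def subframe_by_names(self, names: list[str]) -> "LogratioFrame":
        """Order-stable extraction of a subset of columns by ratio name."""
        index = {r: i for i, r in enumerate(self.ratio_names)}
        missing = [nm for nm in names if nm not in index]
        if missing:
            raise KeyError(f"ratios not in frame: {missing}")
        cols = [index[nm] for nm in names]
        return LogratioFrame(
            self.values[:, cols], [self.ratios[i] for i in cols], self.sample_ids
        )


@dataclass
class GroupLabels:
    """Length-n class labels; class order is fixed lexicographically."""

    labels: np.ndarray
    classes: list[str] = field(init=False)
    codes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        self.classes = sorted({str(v) for v in self.labels})
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        lookup = {c: i for i, c in enumerate(self.classes)}
        self.codes = np.array([lookup[str(v)] for v in self.labels], dtype=np.int64)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.codes, minlength=len(self.classes))

    def require_min_per_class(self, minimum: int = 2) -> None:
        sizes = self.class_sizes
        if np.any(sizes < minimum):
            small = [c for c, s in zip(self.classes, sizes) if s < minimum]
            raise ValueError(f"classes with fewer than {minimum} samples: {small}")


def prevalence_filter(table: CountTable, threshold: float = 0.10) -> CountTable:
    """Retain taxa with nonzero counts in at least ``ceil(threshold * n)`` samples.

    Column order is preserved; samples are unchanged.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = table.n_samples
    min_present = math.ceil(threshold * n)
    present = (table.counts >= 1).sum(axis=0)
    keep = present >= min_present
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 taxa present in >= {threshold:.0%} of samples "
            f"(need nonzero counts in >= {min_present} of {n} samples)"
        )
    return CountTable(
        table.counts[:, keep],
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_names, keep) if k],
    )


def closure(table: CountTable | np.ndarray, taxon_names: list[str] | None = None,
            sample_ids: list[str] | None = None) -> Composition:
    """Normalize each row to the unit-sum simplex: ``x_ij = m_ij / sum_k m_ik``."""
    if isinstance(table, CountTable):
        counts = np.asarray(table.counts, dtype=float)
        taxon_names = list(table.taxon_names)
        sample_ids = list(table.sample_ids)
    else:
        counts = np.asarray(table, dtype=float)
        if taxon_names is None:
            taxon_names = [f"t{j + 1}" for j in range(counts.shape[1])]
    row_sums = counts.sum(axis=1)
    if np.any(row_sums <= 0):
        if sample_ids is not None:
            bad = [s for s, t in zip(sample_ids, row_sums) if t <= 0]
        else:
            bad = list(np.nonzero(row_sums <= 0)[0])
        raise ValueError(f"cannot close rows with nonpositive sum: {bad}")
    values = counts / row_sums[:, None]
    return Composition(
        values,
        taxon_names,
        sample_ids,
        strictly_positive=bool(np.all(values > 0)),
    )


def multiplicative_zero_replacement(comp: Composition) -> Composition:
    """Replace zeros with the global smallest nonzero value ``delta``.

    Zeros become ``delta``; nonzero entries ``x`` in a row with ``z`` zeros
    become ``x * (1 - z * delta)``, so each row still sums to 1 exactly.
    A matrix with no zeros is returned unchanged.
    """
    values = comp.values
    zero_mask = values == 0
    if not zero_mask.any():
        return Composition(values.copy(), list(comp.taxon_names), comp.sample_ids,
                           strictly_positive=True)
    delta = values[values > 0].min()
    zeros_per_row = zero_mask.sum(axis=1)
    shrink = 1.0 - zeros_per_row * delta
    if np.any(shrink <= 0):
        bad = np.nonzero(shrink <= 0)[0]
        raise ValueError(
            f"zero replacement would remove all mass in rows {list(bad)} "
            f"(delta={delta:g}, zeros={zeros_per_row[bad].tolist()})"
        )
    out = values * shrink[:, None]
    out[zero_mask] = delta
    return Composition(out, list(comp.taxon_names), comp.sample_ids,
                       strictly_positive=True)


def pairwise_logratio_frame(comp: Composition) -> LogratioFrame:
    """Full frame of pairwise logratios, one orientation per unordered pair.

    Pair ``(j, k)`` with ``j > k`` yields column ``log(r_j) - log(r_k)`` named
    ``taxon_j/taxon_k``; pairs are emitted denominator-major (lower
    off-diagonal reshaped column by column).
    """
    if np.any(comp.values <= 0):
        raise ValueError("logratios require a strictly positive composition "
                         "(apply zero replacement first)")
    logs = np.log(comp.values)
    d = comp.n_taxa
    names = comp.taxon_names
    num_idx: list[int] = []
    den_idx: list[int] = []
    for k in range(d - 1):
        for j in range(k + 1, d):
            num_idx.append(j)
            den_idx.append(k)
    values = logs[:, num_idx] - logs[:, den_idx]
    ratios = [(names[j], names[k]) for j, k in zip(num_idx, den_idx)]
    return LogratioFrame(values, ratios, comp.sample_ids)
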