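"""Monte-Carlo permutation significance for the selected association.

Supports free label shuffles, shuffles restricted to strata, and block
designs where whole blocks of samples (e.g. repeated measures of one host)
exchange their class labels as units.  Each null replicate reruns the entire
selection pipeline on permuted labels with the statistic kind fixed to the
one chosen on the observed labels, so observed and null statistics are the
same functional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .compositional import (Composition, CountTable, GroupLabels, closure,
                            multiplicative_zero_replacement, prevalence_filter)
from .selection import PLRWorkspace, SelectionConfig, SelectionResult, _select

__all__ = ["PermutationScheme", "TestReport", "generate_permutations",
           "sel_energy_perm_test", "permutation_p_value"]


@dataclass
class PermutationScheme:
    mode: str = "free"  # free | within_strata | block
    strata_or_block: np.ndarray | None = None
    k: int = 999
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("free", "within_strata", "block"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode != "free" and self.strata_or_block is None:
            raise ValueError(f"mode {self.mode!r} requires strata_or_block labels")
        if self.strata_or_block is not None:
            self.strata_or_block = np.asarray(self.strata_or_block)


@dataclass
class TestReport:
    F_obs: float
    statistic_kind: str
    null_values: np.ndarray
    p_hat: float
    signature: list[str]
    k: int
    scheme_mode: str
    selection: SelectionResult | None = None
    settings: dict = field(default_factory=dict)
    n_failed: int = 0


def permutation_p_value(f_obs: float, null_values: np.ndarray) -> float:
    """One-sided estimate ``(1 + #{null > observed}) / (k + 1)``; ties count
    toward non-exceedance, and the value is never 0."""
    null_values = np.asarray(null_values, dtype=float)
    k = null_values.shape[0]
    return float((1.0 + np.sum(null_values > f_obs)) / (k + 1.0))


def generate_permutations(y: GroupLabels, scheme: PermutationScheme) -> list[np.ndarray]:
    """Draw ``scheme.k`` permuted label vectors, reproducible under the seed."""
    rng = np.random.default_rng(scheme.seed)
    labels = y.labels
    n = labels.shape[0]
    out: list[np.ndarray] = []
    if scheme.mode == "free":
        for _ in range(scheme.k):
            out.append(labels[rng.permutation(n)])
        return out

    groups = scheme.strata_or_block
    if groups.shape[0] != n:
        raise ValueError("strata/block vector length does not match labels")
    if scheme.mode == "within_strata":
        strata = {}
        for i, s in enumerate(groups):
            strata.setdefault(s, []).append(i)
        index_sets = [np.array(v) for v in strata.values()]
        for _ in range(scheme.k):
            perm = labels.copy()
            for idx in index_sets:
                perm[idx] = labels[idx[rng.permutation(idx.shape[0])]]
            out.append(perm)
        return out

    # block mode: each block carries one class label; blocks swap labels
    block_ids: list = []
    block_members: dict = {}
    for i, b in enumerate(groups):
        if b not in block_members:
            block_members[b] = []
            block_ids.append(b)
        block_members[b].append(i)
    block_label = {}
    for b, members in block_members.items():
        labs = {str(labels[i]) for i in members}
        if len(labs) != 1:
            raise ValueError(f"block {b!r} mixes class labels {sorted(labs)}")
        block_label[b] = labels[members[0]]
    base = np.array([block_label[b] for b in block_ids])
    for _ in range(scheme.k):
        shuffled = base[rng.permutation(len(block_ids))]
        perm = labels.copy()
        for b, lab in zip(block_ids, shuffled):
            perm[block_members[b]] = lab
        out.append(perm)
    return out


def preprocess_counts(M: CountTable, prevalence_threshold: float = 0.10) -> Composition:
    """Standard preprocessing chain: prevalence filter on raw counts, closure,
    multiplicative zero replacement."""
    filtered = prevalence_filter(M, prevalence_threshold)
    return multiplicative_zero_replacement(closure(filtered))


def sel_energy_perm_test(
    M: CountTable | Composition,
    y: GroupLabels,
    scheme: PermutationScheme | None = None,
    cfg: SelectionConfig | None = None,
    prevalence_threshold: float = 0.10,
    permutations: list[np.ndarray] | None = None,
) -> TestReport:
    """Full association test: observed selection, permutation null, p-value.

    ``permutations`` may supply a precomputed label set (e.g. one shared
    across methods in a benchmark); otherwise ``scheme`` generates it.
    """
    cfg = cfg or SelectionConfig()
    scheme = scheme or PermutationScheme()
    if isinstance(M, CountTable):
        comp = preprocess_counts(M, prevalence_threshold)
    else:
        comp = M if M.strictly_positive else multiplicative_zero_replacement(M)

    ws = PLRWorkspace(comp)
    if ws.n_samples != y.n:
        raise ValueError("data and labels disagree on sample count")
    seed_seq = np.random.SeedSequence(cfg.seed)
    disp_seed, scale_seed = seed_seq.spawn(2)
    scaling_seed = int(scale_seed.generate_state(1)[0])

    observed = _select(ws, y, cfg, np.random.default_rng(disp_seed), scaling_seed)

    if permutations is None:
        permutations = generate_permutations(y, scheme)
    null_values: list[float] = []
    n_failed = 0
    sink_rng = np.random.default_rng(0)
    for perm in permutations:
        try:
            res = _select(ws, GroupLabels(perm), cfg, sink_rng, scaling_seed,
                          fixed_kind=observed.statistic_kind, keep_details=False)
            null_values.append(res.statistic_value)
        except Exception as exc:  # pragma: no cover - defensive
            n_failed += 1
            warnings.warn(f"permutation replicate failed and was excluded: {exc}",
                          stacklevel=2)
    null = np.asarray(null_values)
    p_hat = permutation_p_value(observed.statistic_value, null)
    return TestReport(
        F_obs=observed.statistic_value,
        statistic_kind=observed.statistic_kind,
        null_values=null,
        p_hat=p_hat,
        signature=observed.signature,
        k=len(null_values),
        scheme_mode=scheme.mode,
        selection=observed,
        settings={
            "requested_k": len(permutations),
            "seed": cfg.seed,
            "scheme_seed": scheme.seed,
            "alpha_exponent": cfg.alpha_exponent,
            "scaling_m": cfg.scaling_m,
            "dispersion_k": cfg.dispersion_k,
            "prevalence_threshold": prevalence_threshold,
        },
        n_failed=n_failed,
    )
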