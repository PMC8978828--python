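"""Benchmark data generators.

Five synthetic scenarios (Dirichlet compositions, negative-binomial library
sizes with Dirichlet proportions, and additive-logistic-normal compositions
with structured covariance) plus two "experimental-style" generators that fit
a Gaussian to the additive-logratio coordinates of any reference count table
and resample it with controlled mean or covariance shifts.  A parametric
zero-inflated negative binomial sampler provides a default reference table.

Every generator has a true-case variant (classes from different
distributions) and a null-case variant (both classes from the class-1
distribution), and is bit-reproducible under its seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .compositional import (Composition, CountTable, GroupLabels, closure,
                            multiplicative_zero_replacement, prevalence_filter)

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "inverse_alr",
    "alr_transform",
    "nb_library_sizes",
    "simulate_synthetic",
    "experimental_location_shift",
    "experimental_covariance_shift",
    "zinb_sample",
    "default_zinb_reference",
]

SYNTHETIC_SCENARIOS = ("syn1", "syn2", "syn3", "syn4", "syn5")


@dataclass
class ScenarioConfig:
    scenario: str
    d: int = 50
    n1: int = 40
    n2: int = 40
    case: str = "true"
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case not in ("true", "null"):
            raise ValueError("case must be 'true' or 'null'")
        if self.d < 2 or self.n1 < 2 or self.n2 < 2:
            raise ValueError("need d >= 2 and class sizes >= 2")


@dataclass
class SimulatedDataset:
    data: CountTable | Composition
    labels: GroupLabels
    truth: bool
    provenance: dict = field(default_factory=dict)


def _default_taxa(d: int) -> list[str]:
    return [f"t{j + 1}" for j in range(d)]


def _labels(n1: int, n2: int) -> GroupLabels:
    return GroupLabels(np.array(["c1"] * n1 + ["c2"] * n2))


def inverse_alr(S: np.ndarray, taxon_names: list[str] | None = None) -> Composition:
    """Map additive-logratio coordinates back to the simplex.

    A zero column (the reference part) is appended, rows are shifted by their
    maximum before exponentiation (an invariant of the closure that guards
    against overflow), and rows are normalized.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite ALR coordinates")
    full = np.column_stack([S, np.zeros(S.shape[0])])
    full = full - full.max(axis=1, keepdims=True)
    e = np.exp(full)
    values = e / e.sum(axis=1, keepdims=True)
    names = taxon_names or _default_taxa(values.shape[1])
    # extreme coordinates can underflow to exact zeros; flag honestly
    return Composition(values, names,
                       strictly_positive=bool(np.all(values > 0)))


def alr_transform(comp: Composition) -> np.ndarray:
    """Additive-logratio coordinates with the last taxon as reference part."""
    if np.any(comp.values <= 0):
        raise ValueError("ALR requires a strictly positive composition")
    logs = np.log(comp.values)
    return logs[:, :-1] - logs[:, -1:]


def nb_library_sizes(s: float, mu: float, n: int,
                     rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Negative-binomial library sizes with mean ``mu`` and size ``s``
    (variance ``mu + mu^2 / s``)."""
    if s <= 0 or mu <= 0:
        raise ValueError("s and mu must be positive")
    rng = np.random.default_rng(rng)
    return rng.negative_binomial(s, s / (s + mu), size=n)


def _banded_sigma(dim: int) -> np.ndarray:
    sigma = np.eye(dim)
    idx = np.arange(dim - 1)
    sigma[idx, idx + 1] = 0.2
    sigma[idx + 1, idx] = 0.2
    return sigma


def _symmetric_uniform(rng: np.random.Generator, dim: int, high: float) -> np.ndarray:
    u = rng.uniform(0.0, high, size=(dim, dim))
    return 0.5 * (u + u.T)


def _cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite after shift") from exc


def _mvn(rng: np.random.Generator, mean: np.ndarray, chol: np.ndarray,
         size: int) -> np.ndarray:
    z = rng.standard_normal((size, mean.shape[0]))
    return mean + z @ chol.T


def _scenario_dirichlet(cfg: ScenarioConfig, rng: np.random.Generator) -> SimulatedDataset:
    d, n1, n2 = cfg.d, cfg.n1, cfg.n2
    a1 = 3.0
    a2 = 3.0 * math.log(d) / 5.0 if cfg.case == "true" else a1
    x1 = rng.dirichlet(np.full(d, a1), size=n1)
    x2 = rng.dirichlet(np.full(d, a2), size=n2)
    comp = Composition(np.vstack([x1, x2]) / np.vstack([x1, x2]).sum(1, keepdims=True),
                       _default_taxa(d), strictly_positive=True)
    return SimulatedDataset(comp, _labels(n1, n2), cfg.case == "true",
                            {"scenario": "syn1", "alpha1": a1, "alpha2": a2})


def _syn2_alpha(rng: np.random.Generator, d: int, first_low: float,
                first_high: float) -> np.ndarray:
    if d < 11:
        raise ValueError("scenario syn2 requires d >= 11")
    alpha = np.empty(d)
    alpha[0] = rng.uniform(first_low, first_high)
    alpha[1:10] = rng.uniform(500.0, 1500.0, size=9)
    alpha[10:] = rng.uniform(1.0, 5.0, size=d - 10)
    return alpha


def _scenario_sparse_counts(cfg: ScenarioConfig, rng: np.random.Generator) -> SimulatedDataset:
    d, n1, n2 = cfg.d, cfg.n1, cfg.n2
    s = cfg.params.get("nb_size", 1.0)
    mu = cfg.params.get("nb_mean", 1e7)
    alpha1 = _syn2_alpha(rng, d, 3000.0, 5000.0)
    if cfg.case == "true":
        alpha2 = _syn2_alpha(rng, d, 12500.0, 17500.0)
    else:
        alpha2 = alpha1
    rows = []
    for alpha, n in ((alpha1, n1), (alpha2, n2)):
        for _ in range(n):
            while True:
                c = rng.negative_binomial(s, s / (s + mu))
                counts = np.floor(c * rng.dirichlet(alpha) + 0.5).astype(np.int64)
                if counts.sum() > 0:
                    break
            rows.append(counts)
    table = CountTable(np.vstack(rows),
                       [f"s{i + 1}" for i in range(n1 + n2)], _default_taxa(d))
    return SimulatedDataset(table, _labels(n1, n2), cfg.case == "true",
                            {"scenario": "syn2", "nb_size": s, "nb_mean": mu})


def _scenario_logistic_normal(cfg: ScenarioConfig, rng: np.random.Generator) -> SimulatedDataset:
    d, n1, n2 = cfg.d, cfg.n1, cfg.n2
    dim = d - 1
    sigma = _banded_sigma(dim)
    if cfg.scenario == "syn5":
        u_high = 3.0 ** 2
    else:
        u_high = 3.0 ** 2 / d ** 2
    U = _symmetric_uniform(rng, dim, u_high)
    delta = abs(min(np.linalg.eigvalsh(sigma).min(),
                    np.linalg.eigvalsh(sigma + U).min())) + 0.05
    sigma1 = sigma + delta * np.eye(dim)
    sigma2 = sigma + U + delta * np.eye(dim)

    mu1 = np.zeros(dim)
    mu2 = np.zeros(dim)
    if cfg.scenario == "syn3":
        n_shift = math.ceil(0.25 * dim)
        mu2[:n_shift] = 1.0 / math.sqrt(d)
    elif cfg.scenario == "syn4":
        n_shift = int(cfg.params.get("n_shift", 1))
        mu2[:n_shift] = math.log(d) / 3.0
    else:  # syn5
        mu2[:] = 1.0 / math.sqrt(n1 + n2)

    chol1 = _cholesky(sigma1)
    if cfg.case == "true":
        chol2 = _cholesky(sigma2)
        s1 = _mvn(rng, mu1, chol1, n1)
        s2 = _mvn(rng, mu2, chol2, n2)
    else:
        s1 = _mvn(rng, mu1, chol1, n1)
        s2 = _mvn(rng, mu1, chol1, n2)
    comp = inverse_alr(np.vstack([s1, s2]), _default_taxa(d))
    return SimulatedDataset(comp, _labels(n1, n2), cfg.case == "true",
                            {"scenario": cfg.scenario, "delta": float(delta)})


def simulate_synthetic(cfg: ScenarioConfig) -> SimulatedDataset:
    """Dispatch on ``cfg.scenario`` (``syn1`` .. ``syn5``)."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.scenario == "syn1":
        return _scenario_dirichlet(cfg, rng)
    if cfg.scenario == "syn2":
        return _scenario_sparse_counts(cfg, rng)
    if cfg.scenario in ("syn3", "syn4", "syn5"):
        return _scenario_logistic_normal(cfg, rng)
    raise ValueError(f"unknown synthetic scenario {cfg.scenario!r}")


def _reference_gaussian(reference: CountTable, prevalence_threshold: float):
    comp = multiplicative_zero_replacement(
        closure(prevalence_filter(reference, prevalence_threshold)))
    A = alr_transform(comp)
    mu = A.mean(axis=0)
    sigma = np.atleast_2d(np.cov(A, rowvar=False))
    return comp, mu, sigma


def _ordered_by_variance(mu: np.ndarray, sigma: np.ndarray):
    order = np.argsort(np.diag(sigma), kind="stable")
    return mu[order], sigma[np.ix_(order, order)]


def _safe_chol(sigma: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance: adding 1e-8 ridge", stacklevel=2)
        return np.linalg.cholesky(sigma + 1e-8 * np.eye(sigma.shape[0]))


def experimental_location_shift(
    reference: CountTable,
    P_frac: float,
    factor: float = 1.25,
    n1: int = 40,
    n2: int = 40,
    case: str = "true",
    seed: int | None = None,
    prevalence_threshold: float = 0.15,
) -> SimulatedDataset:
    """Gaussian resampling of a reference table with the lowest-variance
    ``ceil(P_frac * (d-1))`` ALR coordinates of the class-2 mean multiplied by
    ``factor``."""
    if not (0 < P_frac <= 1):
        raise ValueError("P_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    comp, mu, sigma = _reference_gaussian(reference, prevalence_threshold)
    mu_r, sigma_r = _ordered_by_variance(mu, sigma)
    chol = _safe_chol(sigma_r)
    dim = mu_r.shape[0]
    n_shift = math.ceil(P_frac * dim)
    mu2 = mu_r.copy()
    if case == "true":
        mu2[:n_shift] = mu2[:n_shift] * factor
    s1 = _mvn(rng, mu_r, chol, n1)
    s2 = _mvn(rng, mu2, chol, n2)
    out = inverse_alr(np.vstack([s1, s2]), _default_taxa(dim + 1))
    return SimulatedDataset(out, _labels(n1, n2), case == "true",
                            {"scenario": "exp_location", "P_frac": P_frac,
                             "factor": factor, "d": dim + 1})


def experimental_covariance_shift(
    reference: CountTable,
    beta: float,
    shift_factor: float = 1.25,
    P_frac: float = 0.10,
    n1: int = 40,
    n2: int = 40,
    case: str = "true",
    seed: int | None = None,
    prevalence_threshold: float = 0.15,
) -> SimulatedDataset:
    """Gaussian resampling with a symmetrized uniform-entry covariance bump
    ``T ~ U[0, beta]`` (plus the positive-definiteness shift) for class 2 and a
    mean shift on the first 10% of coordinates."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    comp, mu, sigma = _reference_gaussian(reference, prevalence_threshold)
    mu1, sigma1 = _ordered_by_variance(mu, sigma)
    dim = mu1.shape[0]
    T = _symmetric_uniform(rng, dim, beta) if beta > 0 else np.zeros((dim, dim))
    delta = abs(min(np.linalg.eigvalsh(sigma1).min(),
                    np.linalg.eigvalsh(sigma1 + T).min())) + 0.05
    sigma_s1 = sigma1 + delta * np.eye(dim)
    sigma_s2 = sigma1 + T + delta * np.eye(dim)
    mu2 = mu1.copy()
    n_shift = math.ceil(P_frac * dim)
    chol1 = _safe_chol(sigma_s1)
    if case == "true":
        mu2[:n_shift] = mu2[:n_shift] * shift_factor
        s1 = _mvn(rng, mu1, chol1, n1)
        s2 = _mvn(rng, mu2, _safe_chol(sigma_s2), n2)
    else:
        s1 = _mvn(rng, mu1, chol1, n1)
        s2 = _mvn(rng, mu1, chol1, n2)
    out = inverse_alr(np.vstack([s1, s2]), _default_taxa(dim + 1))
    return SimulatedDataset(out, _labels(n1, n2), case == "true",
                            {"scenario": "exp_covariance", "beta": beta,
                             "shift_factor": shift_factor, "delta": float(delta),
                             "d": dim + 1,
                             "logdet_s1": float(np.linalg.slogdet(sigma_s1)[1]),
                             "logdet_s2": float(np.linalg.slogdet(sigma_s2)[1])})


def zinb_sample(mean_vector, dispersion_vector, zero_inflation_vector, n: int,
                seed: int | None = None) -> CountTable:
    """Independent per-taxon zero-inflated negative-binomial counts."""
    mu = np.asarray(mean_vector, dtype=float)
    s = np.asarray(dispersion_vector, dtype=float)
    pi = np.asarray(zero_inflation_vector, dtype=float)
    if np.any(mu <= 0) or np.any(s <= 0):
        raise ValueError("means and dispersions must be positive")
    if np.any((pi < 0) | (pi >= 1)):
        raise ValueError("zero-inflation probabilities must be in [0, 1)")
    d = mu.shape[0]
    rng = np.random.default_rng(seed)
    counts = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        for _ in range(100):
            row = rng.negative_binomial(s, s / (s + mu))
            row = np.where(rng.random(d) < pi, 0, row)
            if row.sum() > 0:
                break
        else:
            raise RuntimeError("could not draw a nonzero count row")
        counts[i] = row
    return CountTable(counts, [f"s{i + 1}" for i in range(n)], _default_taxa(d))


def default_zinb_reference(d: int = 60, n: int = 150,
                           seed: int | None = None) -> CountTable:
    """A generic reference count table for the experimental-style scenarios
    when no user table is supplied."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(math.log(80.0), 1.2, size=d))
    s = rng.uniform(0.4, 2.0, size=d)
    pi = rng.uniform(0.0, 0.5, size=d)
    sub_seed = int(rng.integers(0, 2 ** 31 - 1))
    return zinb_sample(mu, s, pi, n, seed=sub_seed)
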