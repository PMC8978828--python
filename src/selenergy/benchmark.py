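"""Detection benchmark over simulated datasets.

For each simulated dataset (a true-case and a null-case variant per draw),
every method decides reject/accept at a significance level using one shared
permutation label set, and results are aggregated into power, type-I error
and the Matthews correlation coefficient per method and condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .compositional import Composition, CountTable, GroupLabels, pairwise_logratio_frame
from .network import SpanningTreeSignature, global_clustering_coefficient
from .permutation import (PermutationScheme, generate_permutations,
                          permutation_p_value, preprocess_counts,
                          sel_energy_perm_test)
from .selection import SelectionConfig, SelectionResult
from .simulate import (ScenarioConfig, SimulatedDataset, default_zinb_reference,
                       experimental_covariance_shift, experimental_location_shift,
                       simulate_synthetic)
from .stats import (_permanova_f_batch, _permdisp_f_batch, energy_statistic,
                    euclidean_distances, scaled_combined_f)

__all__ = ["ConfusionSummary", "mcc", "run_detection_benchmark",
           "feature_selection_metrics", "STANDARD_METHODS"]

STANDARD_METHODS = ("selenergyperm", "permanova", "anosim", "energy", "permdisp2")


@dataclass
class ConfusionSummary:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(c: ConfusionSummary) -> float:
    """Matthews correlation coefficient; 0 when any marginal factor is 0."""
    denom2 = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom2 == 0:
        return 0.0
    return ((c.TP * c.TN) - (c.FP * c.FN)) / math.sqrt(denom2)


def _simulate(scenario: str, d: int, n1: int, n2: int, case: str, seed: int,
              reference: CountTable | None) -> SimulatedDataset:
    if scenario.startswith("syn"):
        return simulate_synthetic(ScenarioConfig(scenario, d=d, n1=n1, n2=n2,
                                                 case=case, seed=seed))
    if reference is None:
        reference = default_zinb_reference(d=d, seed=seed ^ 0x5EED)
    if scenario == "expA":
        return experimental_location_shift(reference, P_frac=0.20, factor=1.25,
                                           n1=n1, n2=n2, case=case, seed=seed)
    if scenario == "expB":
        return experimental_covariance_shift(reference, beta=1.4, n1=n1, n2=n2,
                                             case=case, seed=seed)
    raise ValueError(f"unknown scenario {scenario!r}")


def _to_composition(ds: SimulatedDataset, prevalence_threshold: float) -> Composition:
    if isinstance(ds.data, CountTable):
        return preprocess_counts(ds.data, prevalence_threshold)
    return ds.data


def _standard_rejections(comp: Composition, y: GroupLabels,
                         perms: list[np.ndarray], alpha_level: float,
                         methods: list[str]) -> dict[str, bool]:
    """Reject/accept for each comparator on the full logratio frame."""
    Z = pairwise_logratio_frame(comp)
    D = euclidean_distances(Z)
    codes = y.codes
    n1 = int((codes == 0).sum())
    n2 = y.n - n1
    masks0 = np.stack([
        np.array([str(v) for v in perm]) == y.classes[0] for perm in perms
    ])
    out: dict[str, bool] = {}

    if "permanova" in methods:
        obs = float(_permanova_f_batch(D.values ** 2, (codes == 0)[None, :], n1, n2)[0])
        null = _permanova_f_batch(D.values ** 2, masks0, n1, n2)
        out["permanova"] = permutation_p_value(obs, null) <= alpha_level
    if "energy" in methods:
        obs = energy_statistic(D, y).value
        null = np.array([
            energy_statistic(D, GroupLabels(perm)).value for perm in perms
        ])
        out["energy"] = permutation_p_value(obs, null) <= alpha_level
    if "anosim" in methods:
        n = D.n
        iu = np.triu_indices(n, 1)
        ranks = np.zeros((n, n))
        ranks[iu] = rankdata(D.values[iu])
        ranks = ranks + ranks.T
        m_pairs = n * (n - 1) / 2

        def _r(mask0: np.ndarray) -> float:
            same = mask0[:, None] == mask0[None, :]
            within = ranks[same].sum() / 2 - 0.0
            n_within = (same.sum() - n) / 2
            between = ranks[~same].sum() / 2
            n_between = (~same).sum() / 2
            return (between / n_between - within / n_within) / (m_pairs / 2)

        obs = _r(codes == 0)
        null = np.array([_r(m) for m in masks0])
        out["anosim"] = permutation_p_value(obs, null) <= alpha_level
    if "permdisp2" in methods:
        obs = float(_permdisp_f_batch(Z.values, (codes == 0)[None, :], n1, n2,
                                      chunk=64)[0])
        null = _permdisp_f_batch(Z.values, masks0, n1, n2, chunk=64)
        out["permdisp2"] = permutation_p_value(obs, null) <= alpha_level
    return out


def run_detection_benchmark(
    scenarios: list[str],
    methods: list[str] | None = None,
    n_datasets: int = 25,
    k_perms: int = 99,
    alpha_level: float = 0.05,
    design: str = "balanced",
    seed: int | None = None,
    d: int = 50,
    selection_cfg: SelectionConfig | None = None,
    prevalence_threshold: float = 0.10,
    reference: CountTable | None = None,
) -> pd.DataFrame:
    """Tidy per-method summary (power, type-I error, MCC) over the scenarios.

    All methods share one permutation label set per dataset; datasets on which
    a method fails are excluded from that method's tally with a warning.
    """
    methods = list(methods or STANDARD_METHODS)
    unknown = set(methods) - set(STANDARD_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if design == "balanced":
        n1, n2 = 40, 40
    elif design == "unbalanced":
        n1, n2 = 20, 60
    else:
        raise ValueError("design must be 'balanced' or 'unbalanced'")
    selection_cfg = selection_cfg or SelectionConfig(scaling_m=100, dispersion_k=99)

    master = np.random.SeedSequence(seed)
    rows = []
    for scenario in scenarios:
        confusion = {m: ConfusionSummary() for m in methods}
        failures = {m: 0 for m in methods}
        sep_sizes: list[int] = []
        sep_ccs: list[float] = []
        sep_cfs: list[float] = []
        for i in range(n_datasets):
            ds_seed_true, ds_seed_null, perm_seed, sel_seed = [
                int(s.generate_state(1)[0]) for s in master.spawn(4)]
            for case, ds_seed in (("true", ds_seed_true), ("null", ds_seed_null)):
                ds = _simulate(scenario, d, n1, n2, case, ds_seed, reference)
                comp = _to_composition(ds, prevalence_threshold)
                y = ds.labels
                perms = generate_permutations(
                    y, PermutationScheme(k=k_perms, seed=perm_seed))
                decided: dict[str, bool] = {}
                if "selenergyperm" in methods:
                    try:
                        cfg = SelectionConfig(
                            statistic_mode=selection_cfg.statistic_mode,
                            alpha_exponent=selection_cfg.alpha_exponent,
                            max_features=selection_cfg.max_features,
                            patience=selection_cfg.patience,
                            scaling_m=selection_cfg.scaling_m,
                            dispersion_k=selection_cfg.dispersion_k,
                            dispersion_alpha=selection_cfg.dispersion_alpha,
                            discretization=selection_cfg.discretization,
                            seed=sel_seed,
                        )
                        report = sel_energy_perm_test(comp, y, cfg=cfg,
                                                      permutations=perms)
                        decided["selenergyperm"] = report.p_hat <= alpha_level
                        if case == "true":
                            sep_sizes.append(len(report.signature))
                            sep_ccs.append(global_clustering_coefficient(
                                SpanningTreeSignature(report.selection.signature_edges)))
                    except Exception as exc:
                        failures["selenergyperm"] += 1
                        warnings.warn(f"selenergyperm failed on {scenario} "
                                      f"dataset {i} ({case}): {exc}", stacklevel=2)
                std = [m for m in methods if m != "selenergyperm"]
                if std:
                    try:
                        decided.update(_standard_rejections(
                            comp, y, perms, alpha_level, std))
                    except Exception as exc:
                        for m in std:
                            failures[m] += 1
                        warnings.warn(f"standard methods failed on {scenario} "
                                      f"dataset {i} ({case}): {exc}", stacklevel=2)
                for m, reject in decided.items():
                    c = confusion[m]
                    if case == "true":
                        if reject:
                            c.TP += 1
                        else:
                            c.FN += 1
                    else:
                        if reject:
                            c.FP += 1
                        else:
                            c.TN += 1
        for m in methods:
            c = confusion[m]
            n_true = c.TP + c.FN
            n_null = c.TN + c.FP
            rows.append({
                "scenario": scenario, "method": m, "d": d, "design": design,
                "n_datasets": n_datasets, "k": k_perms,
                "power": c.TP / n_true if n_true else float("nan"),
                "type_I": c.FP / n_null if n_null else float("nan"),
                "mcc": mcc(c),
                "failures": failures[m],
                "mean_signature_size": (float(np.mean(sep_sizes))
                                        if m == "selenergyperm" and sep_sizes
                                        else float("nan")),
                "mean_clustering_coefficient": (float(np.mean(sep_ccs))
                                                if m == "selenergyperm" and sep_ccs
                                                else float("nan")),
            })
    return pd.DataFrame(rows)


def feature_selection_metrics(result: SelectionResult, Zfull, y: GroupLabels,
                              perm_labels) -> tuple[int, float, float]:
    """(signature size, logratio-network clustering coefficient, scaled
    combined F of the signature's subframe)."""
    if not result.signature:
        raise ValueError("empty selection result")
    sig = SpanningTreeSignature(result.signature_edges)
    cc = global_clustering_coefficient(sig)
    sub = Zfull.subframe_by_names(result.signature)
    cf = scaled_combined_f(sub, y, perm_labels).value
    return len(result.signature), cc, cf
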