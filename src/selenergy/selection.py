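"""Greedy forward selection of a minimal logratio signature.

Pipeline: full pairwise-logratio frame -> component scoring -> aggregated
scores -> covering-prefix network -> maximum spanning tree -> greedy forward
selection over the tree's ratios, maximizing an association statistic.  The
statistic is the energy-partition F (discoF) unless between-group dispersion
effects are detected in the tree frame, in which case the permutation-scaled
combined F is maximized instead.

``PLRWorkspace`` caches everything label-independent (the logratio frame, its
per-column sort order, per-column pairwise squared-difference matrices and
the dataset-level scaling permutation set) so that permutation replicates,
which rerun the whole pipeline with shuffled labels, only redo
label-dependent work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compositional import Composition, GroupLabels, LogratioFrame, pairwise_logratio_frame, ratio_name
from .dcv import DCVScores, dcv_component_matrix, dcv_scores
from .network import (SpanningTreeSignature, covering_prefix_network,
                      maximum_spanning_tree, subframe)
from .stats import (_permanova_f_batch, _permdisp_f_batch, dispersion_detected)

__all__ = ["SelectionConfig", "SelectionResult", "PLRWorkspace", "selection_energy"]


@dataclass
class SelectionConfig:
    statistic_mode: str = "auto"  # auto | force_discoF | force_cF
    alpha_exponent: float = 1.0
    max_features: int | None = None
    patience: int = 1
    scaling_m: int = 5000
    dispersion_k: int = 99
    dispersion_alpha: float = 0.05
    discretization: str | int = "mdl"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.statistic_mode not in ("auto", "force_discoF", "force_cF"):
            raise ValueError(f"unknown statistic_mode {self.statistic_mode!r}")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if not (0 < self.alpha_exponent <= 2):
            raise ValueError("alpha_exponent must be in (0, 2]")


@dataclass
class SelectionResult:
    signature: list[str]
    signature_edges: list[tuple[str, str, float]]
    statistic_kind: str
    statistic_value: float
    trajectory: list[float]
    dispersion_flag: bool
    dcv: DCVScores | None = None
    mst: SpanningTreeSignature | None = None

    @property
    def size(self) -> int:
        return len(self.signature)


class PLRWorkspace:
    """Label-independent precomputation for one dataset."""

    def __init__(self, comp_or_frame: Composition | LogratioFrame):
        if isinstance(comp_or_frame, Composition):
            self.frame = pairwise_logratio_frame(comp_or_frame)
        else:
            self.frame = comp_or_frame
        values = self.frame.values
        self.sort_idx = np.argsort(values, axis=0, kind="stable")
        self.sorted_values = np.take_along_axis(values, self.sort_idx, axis=0)
        self._scaling_masks: dict[tuple[int, int], np.ndarray] = {}
        self._ratio_index = {pair: i for i, pair in enumerate(self.frame.ratios)}
        # permutation-null moments of the combined-F components, keyed by
        # (scaling key, frozen set of ratio columns); label-independent, so
        # shared across all permutation replicates of one dataset
        self.cf_null_cache: dict[tuple, tuple[float, float, float, float]] = {}

    @property
    def n_samples(self) -> int:
        return self.frame.n_samples

    def scaling_masks(self, codes: np.ndarray, m: int, seed_entropy: int) -> np.ndarray:
        """Dataset-level permutation set for combined-F scaling, generated once
        per (m, seed) and reused across every candidate subset and replicate."""
        key = (m, seed_entropy)
        if key not in self._scaling_masks:
            rng = np.random.default_rng(np.random.SeedSequence(seed_entropy))
            base = np.sort(codes)
            masks = np.empty((m, codes.shape[0]), dtype=bool)
            for i in range(m):
                masks[i] = rng.permutation(base) == 0
            self._scaling_masks[key] = masks
        return self._scaling_masks[key]


class _DiscoEvaluator:
    """Incremental discoF over growing column subsets of a frame."""

    def __init__(self, X: np.ndarray, codes: np.ndarray, alpha: float):
        n = X.shape[0]
        self.n = n
        self.alpha = alpha
        self.m0 = codes == 0
        self.n1 = int(self.m0.sum())
        self.n2 = n - self.n1
        # per-column squared-difference matrices
        self.sq_cols = np.empty((X.shape[1], n, n))
        for j in range(X.shape[1]):
            diff = X[:, j][:, None] - X[:, j][None, :]
            self.sq_cols[j] = diff * diff
        self.base = np.zeros((n, n))

    def evaluate(self, j: int) -> float:
        A = np.sqrt(self.base + self.sq_cols[j])
        if self.alpha != 1.0:
            A = A ** self.alpha
        m0 = self.m0
        s00 = A[np.ix_(m0, m0)].sum()
        s11 = A[np.ix_(~m0, ~m0)].sum()
        total = A.sum()
        T = (self.n / 2.0) * total / self.n ** 2
        W = s00 / (2.0 * self.n1) + s11 / (2.0 * self.n2)
        S = T - W
        if W == 0:
            return np.inf
        return float(S / (W / (self.n - 2)))

    def accept(self, j: int) -> None:
        self.base = self.base + self.sq_cols[j]


class _ScaledCFEvaluator:
    """Incremental permutation-scaled combined F over growing column subsets.

    Null moments are orientation- and label-independent for a given ratio
    set, so they are memoized in ``null_cache`` (shared via the workspace)
    under the global ratio ids of the candidate set.
    """

    def __init__(self, X: np.ndarray, codes: np.ndarray, masks0: np.ndarray,
                 global_ids: list[int], cache_key: tuple,
                 null_cache: dict):
        self.X = X
        self.codes = codes
        self.obs_mask = (codes == 0)[None, :]
        self.n1 = int((codes == 0).sum())
        self.n2 = X.shape[0] - self.n1
        self.masks0 = masks0
        self.global_ids = global_ids
        self.cache_key = cache_key
        self.null_cache = null_cache
        n = X.shape[0]
        self.sq_cols = np.empty((X.shape[1], n, n))
        for j in range(X.shape[1]):
            diff = X[:, j][:, None] - X[:, j][None, :]
            self.sq_cols[j] = diff * diff
        self.base_d2 = np.zeros((n, n))
        self.selected: list[int] = []
        self.selected_gids: frozenset = frozenset()
        # converged spatial medians of the accepted set, used to warm-start
        # each candidate evaluation (the candidate set adds one column)
        self._A0_null = masks0.astype(float)
        self._A0_obs = self.obs_mask.astype(float)
        self._null_meds: tuple | None = None
        self._obs_meds: tuple | None = None
        self._med_stash: dict = {}

    def _warm(self, meds, A0, j: int, m: int):
        if meds is None:
            return None
        mean0 = (A0 @ self.X[:, j])[:, None] / self.n1
        mean1 = ((1.0 - A0) @ self.X[:, j])[:, None] / self.n2
        return (np.hstack([meds[0], mean0]), np.hstack([meds[1], mean1]))

    def evaluate(self, j: int) -> float:
        D2 = self.base_d2 + self.sq_cols[j]
        cols = self.selected + [j]
        Xc = self.X[:, cols]
        f_loc = float(_permanova_f_batch(D2, self.obs_mask, self.n1, self.n2)[0])
        f_disp_arr, obs_meds = _permdisp_f_batch(
            Xc, self.obs_mask, self.n1, self.n2,
            med_init=self._warm(self._obs_meds, self._A0_obs, j, 1),
            return_medians=True)
        f_disp = float(f_disp_arr[0])
        key = (self.cache_key, self.selected_gids | {self.global_ids[j]})
        moments = self.null_cache.get(key)
        null_meds = None
        if moments is None:
            null_loc = _permanova_f_batch(D2, self.masks0, self.n1, self.n2)
            null_disp, null_meds = _permdisp_f_batch(
                Xc, self.masks0, self.n1, self.n2,
                med_init=self._warm(self._null_meds, self._A0_null,
                                    j, self.masks0.shape[0]),
                return_medians=True)
            moments = (float(null_loc.mean()), float(null_loc.std(ddof=1)),
                       float(null_disp.mean()), float(null_disp.std(ddof=1)))
            self.null_cache[key] = moments
        self._med_stash[j] = (obs_meds, null_meds)
        mu_l, sd_l, mu_d, sd_d = moments
        if sd_l == 0 or sd_d == 0:
            raise ValueError("degenerate permutation null in combined-F scaling")
        return float((f_loc - mu_l) / sd_l + (f_disp - mu_d) / sd_d)

    def accept(self, j: int) -> None:
        self.base_d2 = self.base_d2 + self.sq_cols[j]
        self.selected.append(j)
        self.selected_gids = self.selected_gids | {self.global_ids[j]}
        obs_meds, null_meds = self._med_stash.get(j, (None, None))
        self._obs_meds = obs_meds
        if null_meds is not None:
            self._null_meds = null_meds
        elif self._null_meds is not None:
            # cached moments skipped the null solve: extend with column means
            self._null_meds = self._warm(self._null_meds, self._A0_null, j,
                                         self.masks0.shape[0])
        self._med_stash.clear()


def _select(ws: PLRWorkspace, y: GroupLabels, cfg: SelectionConfig,
            disp_rng: np.random.Generator,
            scaling_seed: int,
            fixed_kind: str | None = None,
            keep_details: bool = True) -> SelectionResult:
    V = dcv_component_matrix(ws.frame, y, cfg.discretization,
                             _presorted=(ws.sorted_values, ws.sort_idx))
    scores = dcv_scores(V)
    net = covering_prefix_network(scores, ratios=ws.frame.ratios)
    mst = maximum_spanning_tree(net)
    Zp = subframe(ws.frame, mst)
    if Zp.n_ratios == 0:
        raise ValueError("empty spanning-tree frame")

    codes = y.codes
    dispersion_flag = False
    if fixed_kind is not None:
        kind = fixed_kind
        dispersion_flag = kind == "cF_scaled"
    elif cfg.statistic_mode == "force_discoF":
        kind = "discoF"
    elif cfg.statistic_mode == "force_cF":
        kind = "cF_scaled"
        dispersion_flag = True
    else:
        dispersion_flag = dispersion_detected(
            Zp, y, k=cfg.dispersion_k, alpha_level=cfg.dispersion_alpha,
            rng=disp_rng)
        kind = "cF_scaled" if dispersion_flag else "discoF"

    if kind == "cF_scaled":
        masks0 = ws.scaling_masks(codes, cfg.scaling_m, scaling_seed)
        global_ids = [ws._ratio_index[(num, den)]
                      if (num, den) in ws._ratio_index
                      else ws._ratio_index[(den, num)]
                      for num, den, _ in mst.edges]
        evaluator = _ScaledCFEvaluator(Zp.values, codes, masks0, global_ids,
                                       (cfg.scaling_m, scaling_seed),
                                       ws.cf_null_cache)
    else:
        evaluator = _DiscoEvaluator(Zp.values, codes, cfg.alpha_exponent)

    names = Zp.ratio_names
    weights = [w for _, _, w in mst.edges]
    order = sorted(range(len(names)), key=lambda i: (-weights[i], names[i]))

    current = [order[0]]
    evaluator_stat = evaluator.evaluate(order[0])
    evaluator.accept(order[0])
    trajectory = [evaluator_stat]
    remaining = order[1:]
    non_improving = 0
    while remaining:
        if cfg.max_features is not None and len(current) >= cfg.max_features:
            break
        best_j, best_stat = None, -np.inf
        for j in remaining:
            stat = evaluator.evaluate(j)
            if stat > best_stat or (stat == best_stat and best_j is not None
                                    and names[j] < names[best_j]):
                best_j, best_stat = j, stat
        if best_stat > trajectory[-1]:
            current.append(best_j)
            evaluator.accept(best_j)
            trajectory.append(best_stat)
            remaining.remove(best_j)
            non_improving = 0
        else:
            # deterministic state: the next scan would repeat identically, so
            # `patience` non-improving scans are exhausted immediately
            non_improving += 1
            if non_improving >= max(cfg.patience, 1):
                break

    edges = [mst.edges[i] for i in current]
    return SelectionResult(
        signature=[ratio_name(num, den) for num, den, _ in edges],
        signature_edges=edges,
        statistic_kind=kind,
        statistic_value=float(trajectory[-1]),
        trajectory=[float(t) for t in trajectory],
        dispersion_flag=bool(dispersion_flag),
        dcv=scores if keep_details else None,
        mst=mst if keep_details else None,
    )


def selection_energy(R: Composition | LogratioFrame, y: GroupLabels,
                     cfg: SelectionConfig | None = None) -> SelectionResult:
    """Run the full selection pipeline on a strictly positive composition (or a
    prebuilt logratio frame) and return the selected signature with its
    association statistic."""
    cfg = cfg or SelectionConfig()
    if y.n_classes != 2:
        raise ValueError("selection requires exactly two classes")
    ws = PLRWorkspace(R)
    if ws.n_samples != y.n:
        raise ValueError("data and labels disagree on sample count")
    seed_seq = np.random.SeedSequence(cfg.seed)
    disp_seed, scale_seed = seed_seq.spawn(2)
    return _select(ws, y, cfg, np.random.default_rng(disp_seed),
                   int(scale_seed.generate_state(1)[0]))
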