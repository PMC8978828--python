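"""Readers and writers for count tables, metadata and result artifacts.

Count tables are delimited text (TSV/CSV decided by extension), samples in
rows by default.  Sample alignment between counts and metadata is always by
sample id, never by row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .compositional import Composition, CountTable, GroupLabels
from .dcv import COMPONENT_NAMES, DCVScores
from .permutation import TestReport
from .selection import SelectionResult

__all__ = [
    "read_count_table", "write_count_table", "write_composition",
    "read_composition", "read_metadata", "align_labels",
    "write_dcv_report", "write_signature", "write_network_edgelist",
    "write_network_graphml", "write_test_report",
]


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_count_table(path: str | Path, orientation: str = "samples") -> CountTable:
    """Load a delimited count table; ``orientation`` names what the rows hold
    (``"samples"`` or ``"taxa"``)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'samples' or 'taxa'")
    return CountTable(df.to_numpy(), [str(i) for i in df.index],
                      [str(c) for c in df.columns])


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.sample_ids,
                      columns=table.taxon_names)
    df.to_csv(path, sep=_sep(path))


def write_composition(comp: Composition, path: str | Path) -> None:
    """Closed (unit-sum) table as delimited text, round-trippable."""
    pd.DataFrame(comp.values,
                 index=comp.sample_ids or [f"s{i + 1}" for i in range(comp.n_samples)],
                 columns=comp.taxon_names).to_csv(path, sep=_sep(path))


def read_composition(path: str | Path) -> Composition:
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    values = df.to_numpy(dtype=float)
    return Composition(values, [str(c) for c in df.columns],
                       [str(i) for i in df.index],
                       strictly_positive=bool((values > 0).all()))


def read_metadata(path: str | Path, sample_col: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if sample_col is None:
        sample_col = df.columns[0]
    if sample_col not in df.columns:
        raise ValueError(f"sample id column {sample_col!r} not in metadata")
    return df.set_index(sample_col)


def align_labels(table: CountTable, meta: pd.DataFrame, label_col: str,
                 group_col: str | None = None):
    """Match metadata rows to the table's samples by id.

    Returns ``(labels, groups)`` where ``groups`` is the optional
    strata/block vector (or None).
    """
    if label_col not in meta.columns:
        raise ValueError(f"label column {label_col!r} not in metadata")
    if group_col is not None and group_col not in meta.columns:
        raise ValueError(f"column {group_col!r} not in metadata")
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    ordered = meta.loc[table.sample_ids]
    labels = GroupLabels(ordered[label_col].to_numpy())
    groups = ordered[group_col].to_numpy() if group_col else None
    return labels, groups


def _sig12(x) -> float:
    return float(f"{float(x):.12g}")


def write_dcv_report(scores: DCVScores, path: str | Path) -> None:
    comps = scores.components.components
    df = pd.DataFrame(comps, columns=list(COMPONENT_NAMES))
    for i, name in enumerate(COMPONENT_NAMES):
        df[f"z_{name}"] = scores.standardized[:, i]
    df.insert(0, "ratio", scores.ratio_names)
    df["score"] = scores.scores
    df = df.sort_values(["score", "ratio"], ascending=[False, True],
                        kind="stable")
    df.to_csv(path, sep="\t", index=False)


def write_signature(result: SelectionResult, path: str | Path) -> None:
    rows = []
    for rank, ((num, den, w), stat) in enumerate(
            zip(result.signature_edges, result.trajectory), start=1):
        rows.append({"rank": rank, "numerator": num, "denominator": den,
                     "dcv_score": _sig12(w), "statistic_after_inclusion": _sig12(stat)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _edges_of(obj) -> list:
    if isinstance(obj, SelectionResult):
        return obj.signature_edges
    return obj.edges  # LogratioNetwork / SpanningTreeSignature


def _signature_graph(obj) -> nx.DiGraph:
    g = nx.DiGraph()
    for num, den, w in _edges_of(obj):
        g.add_edge(num, den, weight=float(w))
    return g


def write_network_edgelist(obj, path: str | Path) -> None:
    """Edge TSV (numerator, denominator, weight) for a selection result,
    logratio network or spanning-tree signature."""
    rows = [{"numerator": num, "denominator": den, "weight": _sig12(w)}
            for num, den, w in _edges_of(obj)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network_graphml(obj, path: str | Path) -> None:
    nx.write_graphml(_signature_graph(obj), path)


def write_test_report(report: TestReport, path: str | Path,
                      null_path: str | Path | None = None) -> None:
    payload = {
        "F_obs": _sig12(report.F_obs),
        "statistic_kind": report.statistic_kind,
        "p_hat": _sig12(report.p_hat),
        "k": report.k,
        "p_floor": _sig12(1.0 / (report.k + 1)),
        "scheme": report.scheme_mode,
        "signature": report.signature,
        "n_failed_replicates": report.n_failed,
        "settings": report.settings,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if null_path is not None:
        pd.DataFrame({"null_statistic": [
            _sig12(v) for v in np.asarray(report.null_values)
        ]}).to_csv(null_path, sep="\t", index=False)
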