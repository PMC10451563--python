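"""Graph-recovery metrics: directed precision/recall/F1 and SHD.

Edges are compared with strict direction.  For precision and recall, a
learned edge whose reverse is in the truth is a false positive (and the
missed truth edge a false negative).  The structural Hamming distance
(SHD) counts the edit operations turning the learned network into the
truth: redundant edges to delete, missing edges to add, and reversed edges
— each reversal costing a single edit:

    SHD = Redu + Miss + Reve.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cbn import CBN

__all__ = ["EvalReport", "compare", "report_table",
           "read_edge_list", "write_edge_list"]


@dataclass
class EvalReport:
    """Directed-edge confusion counts, SHD decomposition, and ratios."""

    tp: int
    fp: int
    fn: int
    redu: int
    miss: int
    reve: int
    precision: float
    recall: float
    f1: float
    shd: int
    degenerate: bool = False  # a 0/0 precision or recall was defined as 0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "redu": self.redu, "miss": self.miss, "reve": self.reve,
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "shd": self.shd,
        }


def _edge_sets(graph: CBN) -> set[tuple[int, int]]:
    return set(graph.arcs())


def compare(learned: CBN, truth: CBN) -> EvalReport:
    """Score a learned network against the ground truth.

    Node sets are reconciled by label; a reversed edge counts as one SHD
    edit but as an error in both precision and recall.
    """
    if sorted(learned.node_labels) != sorted(truth.node_labels):
        raise ValueError("learned and truth networks must share node labels")
    if learned.node_labels != truth.node_labels:
        order = [learned.node_labels.index(lbl) for lbl in truth.node_labels]
        remap = {old: new for new, old in enumerate(order)}
        learned = CBN.from_edges(
            [(remap[u], remap[c]) for u, c in learned.arcs()],
            truth.v, node_labels=truth.node_labels)

    le = _edge_sets(learned)
    tr = _edge_sets(truth)
    tp = len(le & tr)
    fp = len(le - tr)
    fn = len(tr - le)
    reve = sum(1 for (u, c) in le if (c, u) in tr and (u, c) not in tr)
    redu = sum(1 for (u, c) in le
               if (u, c) not in tr and (c, u) not in tr)
    miss = sum(1 for (u, c) in tr
               if (u, c) not in le and (c, u) not in le)

    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvalReport(tp=tp, fp=fp, fn=fn, redu=redu, miss=miss, reve=reve,
                      precision=precision, recall=recall, f1=f1,
                      shd=redu + miss + reve, degenerate=degenerate)


def report_table(reports: Sequence[EvalReport],
                 labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-run Precision/Recall/F1/SHD grid with mean and sd rows."""
    if labels is None:
        labels = [f"run{i + 1}" for i in range(len(reports))]
    rows = [
        {"run": lbl, "precision": r.precision, "recall": r.recall,
         "f1": r.f1, "shd": r.shd}
        for lbl, r in zip(labels, reports)
    ]
    df = pd.DataFrame(rows).set_index("run")
    if len(df):
        summary = pd.DataFrame(
            [df.mean(), df.std(ddof=1) if len(df) > 1 else df.iloc[0] * 0.0],
            index=["mean", "sd"])
        df = pd.concat([df, summary])
    return df


def read_edge_list(path: str | Path,
                   node_labels: Sequence[str] | None = None) -> CBN:
    """Read a directed edge list (parent, child[, weight/count]) into a CBN.

    Accepts two or three tab-separated columns with an optional header.  If
    ``node_labels`` is omitted, the node set is the sorted union of labels
    in the file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: edge list needs at least 2 columns")
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    if first[0] in {"parent", "from", "source"} or first[1] in {"child", "to", "target"}:
        df = df.iloc[1:]
    edges = [(str(a).strip(), str(b).strip())
             for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    if node_labels is None:
        node_labels = sorted({x for e in edges for x in e})
    index = {lbl: i for i, lbl in enumerate(node_labels)}
    missing = [x for e in edges for x in e if x not in index]
    if missing:
        raise ValueError(f"{path.name}: unknown node labels {sorted(set(missing))}")
    return CBN.from_edges([(index[a], index[b]) for a, b in edges],
                          len(node_labels), node_labels=list(node_labels))


def write_edge_list(graph: CBN, path: str | Path,
                    counts: np.ndarray | None = None) -> None:
    """Write arcs as 'parent<TAB>child[<TAB>count]' with a header row."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("parent\tchild\tcount\n" if counts is not None
                 else "parent\tchild\n")
        for u, c in graph.arcs():
            row = f"{graph.node_labels[u]}\t{graph.node_labels[c]}"
            if counts is not None:
                row += f"\t{int(counts[u, c])}"
            fh.write(row + "\n")
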