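"""Ground-truth comparison of module partitions.

Predicted modules are matched to ground-truth communities by solving a
(zero-padded) linear assignment problem that maximizes the total
overlap between matched pairs, then pooled true/false positive and
false negative node counts across the matched pairs give micro
precision, recall and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .treecut import ModulePartition

__all__ = ["ModuleMapping", "EvalReport", "intersection_matrix",
           "map_modules", "micro_f1", "evaluate_against_truth"]


@dataclass
class ModuleMapping:
    """Optimal bijection between (padded) predicted and truth modules."""

    pred_ids: list[int]            # row order; 0 entries are padding
    truth_ids: list[int]           # column order; 0 entries are padding
    S: np.ndarray                  # padded square intersection-count matrix
    assignment: list[tuple[int, int]]  # (row, col) pairs, one per row
    objective: int

    def pairs(self) -> list[tuple[int, int]]:
        """(predicted id, truth id) with 0 for padding on either side."""
        return [(self.pred_ids[r], self.truth_ids[c])
                for r, c in self.assignment]


def _as_modules(partition: ModulePartition | Mapping[str, int]) -> dict[int, set[str]]:
    if isinstance(partition, ModulePartition):
        return partition.modules()
    out: dict[int, set[str]] = {}
    for node, m in partition.items():
        if m > 0:
            out.setdefault(int(m), set()).add(str(node))
    return out


def intersection_matrix(pred: dict[int, set[str]], truth: dict[int, set[str]],
                        universe: set[str]) -> tuple[np.ndarray, list[int], list[int]]:
    """Square zero-padded overlap-count matrix restricted to ``universe``."""
    pred_ids = sorted(pred)
    truth_ids = sorted(truth)
    k = max(len(pred_ids), len(truth_ids))
    S = np.zeros((k, k), dtype=np.int64)
    for i, pi in enumerate(pred_ids):
        a = pred[pi] & universe
        for j, tj in enumerate(truth_ids):
            S[i, j] = len(a & truth[tj])
    rows = pred_ids + [0] * (k - len(pred_ids))
    cols = truth_ids + [0] * (k - len(truth_ids))
    return S, rows, cols


def map_modules(predicted: ModulePartition | Mapping[str, int],
                truth: Mapping[str, int]) -> ModuleMapping:
    """Maximize total matched overlap via the Hungarian algorithm.

    Nodes present in only one partition are excluded from the counts.
    Among equally optimal assignments a deterministic one is returned
    (a vanishing perturbation prefers low module-id pairings).
    """
    pred = _as_modules(predicted)
    tru = _as_modules(dict(truth) if not isinstance(truth, dict) else truth)
    if not pred or not tru:
        raise ValueError("both partitions must contain at least one module")
    pred_nodes = set().union(*pred.values())
    truth_nodes = set().union(*tru.values())
    universe = pred_nodes & truth_nodes
    if not universe:
        raise ValueError("predicted and truth partitions share no nodes")
    S, rows, cols = intersection_matrix(pred, tru, universe)
    k = S.shape[0]
    # lexicographic tie-break: tiny decreasing perturbation favoring
    # low (row, col) pairs, far below the integer resolution of S
    eps = 1.0 / (4.0 * k * k + 4.0)
    bias = np.fromfunction(lambda i, j: eps * (1.0 - (i * k + j) / (k * k)),
                           (k, k))
    r, c = linear_sum_assignment(S + bias, maximize=True)
    assignment = sorted(zip(r.tolist(), c.tolist()))
    objective = int(S[r, c].sum())
    return ModuleMapping(pred_ids=rows, truth_ids=cols, S=S,
                         assignment=assignment, objective=objective)


def micro_f1(predicted: ModulePartition | Mapping[str, int],
             truth: Mapping[str, int],
             mapping: ModuleMapping | None = None
             ) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1) under the optimal mapping.

    For matched pair (P_i, T_j): TP = |P_i & T_j|, FP = |P_i| - TP,
    FN = |T_j| - TP; a module matched to padding contributes TP = 0.
    """
    if mapping is None:
        mapping = map_modules(predicted, truth)
    pred = _as_modules(predicted)
    tru = _as_modules(dict(truth) if not isinstance(truth, dict) else truth)
    pred_nodes = set().union(*pred.values())
    truth_nodes = set().union(*tru.values())
    universe = pred_nodes & truth_nodes
    tp = fp = fn = 0
    for pid, tid in mapping.pairs():
        a = (pred[pid] & universe) if pid else set()
        b = (tru[tid] & universe) if tid else set()
        inter = len(a & b)
        tp += inter
        fp += len(a) - inter
        fn += len(b) - inter
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


@dataclass
class EvalReport:
    mapping: ModuleMapping
    precision: float
    recall: float
    f1: float
    n_predicted_modules: int
    n_truth_modules: int
    counts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "micro_f1": self.f1,
            "n_predicted_modules": self.n_predicted_modules,
            "n_truth_modules": self.n_truth_modules,
            "mapping": self.mapping.pairs(),
            "per_module": self.counts,
        }


def evaluate_against_truth(predicted: ModulePartition | Mapping[str, int],
                           truth: Mapping[str, int]) -> EvalReport:
    """Full report: mapping table, per-module counts, micro P/R/F1."""
    mapping = map_modules(predicted, truth)
    precision, recall, f1 = micro_f1(predicted, truth, mapping)
    pred = _as_modules(predicted)
    tru = _as_modules(dict(truth) if not isinstance(truth, dict) else truth)
    universe = set().union(*pred.values()) & set().union(*tru.values())
    counts = []
    for pid, tid in mapping.pairs():
        a = (pred[pid] & universe) if pid else set()
        b = (tru[tid] & universe) if tid else set()
        inter = len(a & b)
        counts.append({"predicted": pid, "truth": tid, "tp": inter,
                       "fp": len(a) - inter, "fn": len(b) - inter})
    return EvalReport(mapping=mapping, precision=precision, recall=recall,
                      f1=f1, n_predicted_modules=len(pred),
                      n_truth_modules=len(tru), counts=counts)
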