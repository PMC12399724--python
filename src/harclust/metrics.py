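"""Clustering evaluation: NMI, ARI and optimal-mapping cluster accuracy.

NMI uses the geometric-mean normalization and natural logarithms (the
value is base-invariant); ARI is the chance-corrected Rand index;
cluster accuracy is the best fraction correct over one-to-one
cluster-to-class mappings (maximum-weight bipartite matching on the
contingency table).  NMI/ARI are delegated to scikit-learn and verified
against direct-summation oracles in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (adjusted_rand_score,
                             normalized_mutual_info_score)
from sklearn.metrics.cluster import contingency_matrix

REPORT_SCHEMA_VERSION = 1


@dataclass
class ContingencyTable:
    counts: np.ndarray   # [r, c] non-negative ints
    n: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) != self.n:
            raise ValueError("counts must sum to n")


@dataclass
class EvalReport:
    nmi: float
    ari: float
    accuracy: float
    n: int
    k_true: int
    k_pred: int
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _check(true_labels, pred_labels):
    t = np.asarray(true_labels, dtype=int).ravel()
    p = np.asarray(pred_labels, dtype=int).ravel()
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    if len(t) < 1:
        raise ValueError("need at least one point")
    return t, p


def contingency(true_labels, pred_labels) -> ContingencyTable:
    t, p = _check(true_labels, pred_labels)
    counts = contingency_matrix(t, p)
    return ContingencyTable(counts=counts, n=len(t))


def nmi(true_labels, pred_labels) -> float:
    """NMI with geometric-mean normalization.

    1.0 when both partitions are single-cluster and identical in the
    degenerate sense; 0.0 when either partition has zero entropy while
    the other does not.
    """
    t, p = _check(true_labels, pred_labels)
    return float(normalized_mutual_info_score(t, p, average_method="geometric"))


def ari(true_labels, pred_labels) -> float:
    t, p = _check(true_labels, pred_labels)
    return float(adjusted_rand_score(t, p))


def cluster_accuracy(true_labels, pred_labels) -> float:
    """Best accuracy over one-to-one cluster-to-class mappings."""
    t, p = _check(true_labels, pred_labels)
    counts = contingency_matrix(t, p)
    rows, cols = linear_sum_assignment(counts, maximize=True)
    return float(counts[rows, cols].sum() / len(t))


def evaluate(true_labels, pred_labels) -> EvalReport:
    t, p = _check(true_labels, pred_labels)
    return EvalReport(nmi=nmi(t, p), ari=ari(t, p),
                      accuracy=cluster_accuracy(t, p), n=len(t),
                      k_true=len(np.unique(t)), k_pred=len(np.unique(p)))
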