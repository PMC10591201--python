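"""Scoring reconstructions against ground truth.

The evaluation universe is the set of ordered pairs (pre, post) of observed
cells with pre != post: the decoder never sees unobserved cells, so only
observed-pair space is scored.  Recall = TP / (TP + FN) and precision =
TP / (TP + FP); a metric with a zero denominator is undefined and reported
as NaN (missing), never as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GroundTruthNetwork

__all__ = [
    "ConfusionCounts",
    "confusion_matrix",
    "recall",
    "precision",
    "per_cell_metrics",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_true_connections(self) -> int:
        return self.tp + self.fn


def _truth_adjacency(truth: GroundTruthNetwork | np.ndarray, observed=None) -> np.ndarray:
    if isinstance(truth, GroundTruthNetwork):
        obs = truth.observed if observed is None else np.asarray(observed)
        return truth.weights[np.ix_(obs, obs)] != 0
    return np.asarray(truth) != 0


def confusion_matrix(
    estimated: np.ndarray,
    truth: GroundTruthNetwork | np.ndarray,
    observed=None,
) -> ConfusionCounts:
    """Counts over ordered observed pairs j -> i, j != i.

    ``estimated`` is the thresholded (post, pre) adjacency over observed
    cells; ``truth`` is either a GroundTruthNetwork (its observed submatrix
    is used) or a weight/adjacency matrix of the same shape.
    """
    est = np.asarray(estimated, dtype=bool)
    tru = _truth_adjacency(truth, observed)
    if est.shape != tru.shape or est.shape[0] != est.shape[1]:
        raise ValueError(f"shape mismatch: estimate {est.shape} vs truth {tru.shape}")
    off = ~np.eye(est.shape[0], dtype=bool)
    e, t = est[off], tru[off]
    return ConfusionCounts(
        tp=int(np.sum(e & t)),
        fp=int(np.sum(e & ~t)),
        fn=int(np.sum(~e & t)),
        tn=int(np.sum(~e & ~t)),
    )


def recall(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN when there are no true connections."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else float("nan")


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN when nothing was declared connected."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else float("nan")


def per_cell_metrics(
    estimated: np.ndarray,
    truth: GroundTruthNetwork | np.ndarray,
    observed=None,
) -> pd.DataFrame:
    """Recall/precision restricted to each postsynaptic cell's row.

    Returns a DataFrame with one row per observed postsynaptic cell and
    columns tp, fp, fn, tn, recall, precision (NaN where undefined).
    """
    est = np.asarray(estimated, dtype=bool)
    tru = _truth_adjacency(truth, observed)
    if est.shape != tru.shape:
        raise ValueError("shape mismatch between estimate and truth")
    n = est.shape[0]
    rows = []
    for i in range(n):
        keep = np.arange(n) != i
        e, t = est[i, keep], tru[i, keep]
        c = ConfusionCounts(
            tp=int(np.sum(e & t)),
            fp=int(np.sum(e & ~t)),
            fn=int(np.sum(~e & t)),
            tn=int(np.sum(~e & ~t)),
        )
        rows.append(
            {
                "cell": i,
                "tp": c.tp,
                "fp": c.fp,
                "fn": c.fn,
                "tn": c.tn,
                "recall": recall(c),
                "precision": precision(c),
            }
        )
    return pd.DataFrame(rows)
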