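"""d-accuracy: object-level detection scoring of predicted cell centers.

A predicted center counts as a true positive only if it is matched
one-to-one with a ground-truth center at distance <= d. Matching is a
minimum-total-cost assignment (Hungarian algorithm) on the pairwise
Euclidean distance matrix; matched pairs farther than d are discarded.
Per-image F1 scores are aggregated as the median on a 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    d: float
    pairs: List[Tuple[int, int]] = field(default_factory=list)


def _safe_ratio(tp: int, denom: int, other_zero: bool) -> float:
    """tp/denom with the degenerate conventions: 1.0 for 0/0 when the other
    error count is also zero, else 0.0."""
    if denom == 0:
        return 1.0 if other_zero else 0.0
    return tp / denom


def match_detections(pred, gt, d: float = 10.0) -> MatchResult:
    """Score predicted vs. true centers with one-to-one matching at radius d."""
    if d <= 0:
        raise ValueError("d must be > 0")
    p = np.asarray(getattr(pred, "points", pred), dtype=np.float64).reshape(-1, 2)
    g = np.asarray(getattr(gt, "points", gt), dtype=np.float64).reshape(-1, 2)

    pairs: List[Tuple[int, int]] = []
    if len(p) and len(g):
        cost = cdist(p, g)
        rows, cols = linear_sum_assignment(cost)
        pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
                 if cost[r, c] <= d]
    tp = len(pairs)
    fp = len(p) - tp
    fn = len(g) - tp
    precision = _safe_ratio(tp, tp + fp, other_zero=(fn == 0))
    recall = _safe_ratio(tp, tp + fn, other_zero=(fp == 0))
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MatchResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                       f1=f1, d=d, pairs=pairs)


def summarize_images(per_image: Sequence[MatchResult]) -> dict:
    """Median and standard deviation of per-image F1 on the 0-100 scale."""
    if len(per_image) == 0:
        raise ValueError("need at least one MatchResult")
    f1s = np.array([100.0 * r.f1 for r in per_image])
    return {
        "median_f1": float(np.median(f1s)),
        "std_f1": float(np.std(f1s)),
        "n_images": len(per_image),
        "per_image": [
            {"tp": r.tp, "fp": r.fp, "fn": r.fn, "precision": r.precision,
             "recall": r.recall, "f1_pct": 100.0 * r.f1, "d": r.d}
            for r in per_image
        ],
    }
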