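"""Scoring detections against generator ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class DetectionScore:
    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0


def match_detections(
    truth_xy: np.ndarray, detected_xy: np.ndarray, tolerance_um: float = 10.0
) -> DetectionScore:
    """One-to-one match of detected centroids to truth centroids within a
    distance tolerance, by minimum-cost assignment on the candidate pairs.
    """
    truth = np.asarray(truth_xy, dtype=float).reshape(-1, 2)
    det = np.asarray(detected_xy, dtype=float).reshape(-1, 2)
    if len(truth) == 0 or len(det) == 0:
        return DetectionScore(len(truth), len(det), 0)
    # sparse candidate set keeps the assignment small at histology scale
    tree = cKDTree(truth)
    pairs = tree.query_ball_point(det, r=tolerance_um)
    det_idx = [i for i, js in enumerate(pairs) if js]
    if not det_idx:
        return DetectionScore(len(truth), len(det), 0)
    truth_idx = sorted({j for js in pairs for j in js})
    tmap = {j: c for c, j in enumerate(truth_idx)}
    big = 10.0 * tolerance_um
    cost = np.full((len(det_idx), len(truth_idx)), big)
    for r, i in enumerate(det_idx):
        for j in pairs[i]:
            cost[r, tmap[j]] = np.hypot(*(det[i] - truth[j]))
    ri, ci = linear_sum_assignment(cost)
    matched = int(np.sum(cost[ri, ci] <= tolerance_um))
    return DetectionScore(len(truth), len(det), matched)
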