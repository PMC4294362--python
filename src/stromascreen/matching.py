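"""Optimal centroid matching between detections and ground truth.

Used to score the detector against the simulator's ground truth and to
label candidate objects for classifier training.  Matching is one-to-one
(Hungarian assignment on the pairwise distance matrix, pairs farther
than the tolerance forbidden), so a single detection can never consume
two ground-truth objects.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

_FORBIDDEN = 1e9


def match_points(
    predicted: np.ndarray, truth: np.ndarray, tolerance: float
) -> list[tuple[int, int, float]]:
    """One-to-one match of predicted to true points within a distance.

    Parameters are (n, 2) arrays of (row, col) positions.  Returns a list
    of (predicted_index, truth_index, distance) for matched pairs with
    distance <= tolerance.
    """
    predicted = np.asarray(predicted, float).reshape(-1, 2)
    truth = np.asarray(truth, float).reshape(-1, 2)
    if len(predicted) == 0 or len(truth) == 0:
        return []
    diff = predicted[:, None, :] - truth[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    cost = np.where(dist <= tolerance, dist, _FORBIDDEN)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j), float(dist[i, j]))
        for i, j in zip(rows, cols)
        if dist[i, j] <= tolerance
    ]


def detection_scores(
    predicted: np.ndarray, truth: np.ndarray, tolerance: float
) -> dict[str, float]:
    """Precision, recall and F1 of a detection set against ground truth."""
    matches = match_points(predicted, truth, tolerance)
    n_pred = len(np.asarray(predicted, float).reshape(-1, 2))
    n_true = len(np.asarray(truth, float).reshape(-1, 2))
    tp = len(matches)
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "n_predicted": n_pred,
        "n_truth": n_true,
        "n_matched": tp,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }
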