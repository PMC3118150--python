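"""Scoring helpers for comparing pipeline output against planted truth."""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.special import comb


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    n = len(labels_a)
    if n < 2:
        return 1.0
    sum_ij = sum(comb(v, 2) for v in Counter(zip(labels_a, labels_b)).values())
    sum_a = sum(comb(v, 2) for v in Counter(labels_a).values())
    sum_b = sum(comb(v, 2) for v in Counter(labels_b).values())
    expected = sum_a * sum_b / comb(n, 2)
    denom = (sum_a + sum_b) / 2 - expected
    if denom == 0:
        return 1.0
    return float((sum_ij - expected) / denom)


def interval_iou(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def match_intervals(truth: list, predicted: list, min_iou: float = 0.8) -> dict:
    """Greedy best-IoU matching of predicted elements to truth records.

    Both inputs need contig_id/start/end attributes.  Returns recall,
    precision and the matched (truth_index, predicted_index) pairs.
    """
    pairs = []
    for ti, tr in enumerate(truth):
        for pi, pr in enumerate(predicted):
            if tr.contig_id != pr.contig_id:
                continue
            iou = interval_iou((tr.start, tr.end), (pr.start, pr.end))
            if iou >= min_iou:
                pairs.append((iou, ti, pi))
    pairs.sort(reverse=True)
    used_t: set[int] = set()
    used_p: set[int] = set()
    matches = []
    for iou, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi))
    recall = len(matches) / len(truth) if truth else float("nan")
    precision = len(matches) / len(predicted) if predicted else float("nan")
    return {"recall": recall, "precision": precision, "matches": matches,
            "n_truth": len(truth), "n_predicted": len(predicted)}
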