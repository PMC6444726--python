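"""Scoring detected events against generator ground truth."""

from __future__ import annotations

import numpy as np


def _time_overlaps(det, tr, frame_interval: float) -> bool:
    half = np.sqrt(2 * np.log(2)) * tr.sigma_t
    t_lo = (tr.peak_time - half) / frame_interval
    t_hi = (tr.peak_time + half) / frame_interval
    return not (det.t_end < np.floor(t_lo) or det.t_start > np.ceil(t_hi))


def score_detection(detected, truth_events, frame_interval: float,
                    min_overlap: float = 0.5) -> tuple[float, float]:
    """Event-level precision and recall under coverage matching.

    A true event is *recovered* when some detected component covers at least
    ``min_overlap`` of its footprint and overlaps it in time (the true span
    taken as the frames where the Gaussian kernel is at or above half
    maximum); a detected component is *correct* when it so covers at least
    one true event.  Matching is deliberately not one-to-one: connected
    suprathreshold components are never split, so one component may
    legitimately recover several overlapping true events.

    Returns ``(precision, recall)``; with no detections precision is 1 only
    when there is also no truth, and vice versa for recall.
    """
    if not detected and not truth_events:
        return 1.0, 1.0
    covered = [False] * len(truth_events)
    correct = [False] * len(detected)
    for di, det in enumerate(detected):
        for ti, tr in enumerate(truth_events):
            ov = len(det.footprint_2d & tr.footprint) / len(tr.footprint)
            if ov >= min_overlap and _time_overlaps(det, tr, frame_interval):
                covered[ti] = True
                correct[di] = True
    precision = sum(correct) / len(detected) if detected else 0.0
    recall = sum(covered) / len(truth_events) if truth_events else 0.0
    return precision, recall
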