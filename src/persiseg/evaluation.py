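"""Segmentation accuracy scoring."""

from __future__ import annotations

import numpy as np


def iou_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks.

    The ratio of the pixel counts of the intersection and the union;
    defined as 1.0 when both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def mean_iou(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    if not pairs:
        raise ValueError("no mask pairs to score")
    return float(np.mean([iou_score(a, b) for a, b in pairs]))
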