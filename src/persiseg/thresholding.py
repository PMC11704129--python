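"""Automatic persistence thresholding.

A persistence diagram of a real slice separates into a few high-persistence
classes (the contrasted structures) and a near-diagonal cloud of
low-persistence noise. The selector picks a cutoff between the two:

``max_gap``
    Midpoint of the largest gap between consecutive sorted persistence
    values, with the diagonal (persistence zero) included as an anchor:
    noise classes accumulate near the diagonal, so when the gap from the
    diagonal to the smallest observed value is itself the widest, the
    whole set is treated as signal. On a bimodal persistence set whose
    low cluster sits near the diagonal the cutoff lands strictly between
    the clusters, so the selected cycles are exactly the high cluster; a
    single-valued set yields half the common value and is never emptied.
``fixed``
    A user-supplied cutoff.

An optional ``min_persistence`` floor discards sub-noise classes before the
gap analysis and lower-bounds the returned threshold, so a diagram made of
noise alone selects nothing instead of its largest speckle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .filtration import PersistenceDiagram


@dataclass(frozen=True)
class ThresholdConfig:
    """Selector choice for :func:`optimal_threshold`.

    ``min_persistence`` is on the normalized intensity scale; 0 disables
    the floor.
    """

    selector: str = "max_gap"
    fixed_value: float | None = None
    min_persistence: float = 0.0

    def __post_init__(self) -> None:
        if self.selector not in ("max_gap", "fixed"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if (self.selector == "fixed") != (self.fixed_value is not None):
            raise ValueError("fixed_value must be given iff selector='fixed'")
        if self.min_persistence < 0:
            raise ValueError("min_persistence must be >= 0")


class EmptyPersistenceSetError(ValueError):
    """Raised when a threshold is requested for an empty persistence set."""


def optimal_threshold(
    values: np.ndarray, config: ThresholdConfig = ThresholdConfig()
) -> float:
    """Persistence cutoff separating relevant cycles from noise.

    ``values`` is the multiset of positive persistences of the diagram (or
    of the subfamily under consideration). The result is invariant to
    permutation of the input. Cycles are subsequently kept iff their
    persistence is strictly greater than the returned threshold.
    """
    p = np.sort(np.asarray(values, dtype=float))
    if p.size == 0:
        raise EmptyPersistenceSetError("no persistence values to threshold")
    if np.any(p <= 0):
        raise ValueError("persistence values must be positive")
    if config.selector == "fixed":
        return float(config.fixed_value)  # type: ignore[arg-type]
    floor = config.min_persistence
    p = p[p > floor]
    if p.size == 0:
        # Everything is below the noise floor: select nothing.
        return floor
    anchored = np.concatenate([[0.0], p])
    gaps = np.diff(anchored)
    i = int(np.argmax(gaps))
    return max(float((anchored[i] + anchored[i + 1]) / 2.0), floor)


def select_persistent(diagram: PersistenceDiagram, t: float) -> PersistenceDiagram:
    """Sub-diagram of classes with persistence strictly greater than ``t``."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    kept = tuple(p for p in diagram.pairs if p.persistence > t)
    return _dc_replace(diagram, pairs=kept)
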