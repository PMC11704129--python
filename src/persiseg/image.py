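"""2D intensity images as inputs to the cubical filtration.

A slice of a confocal z-stack is a rectangular grid of scalar intensities.
All downstream topology is computed on intensities normalized to [0, 1];
normalization is min-max per slice and can be disabled for data that is
already calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when an input image violates the intensity-image contract."""


@dataclass(frozen=True)
class IntensityImage:
    """A single 2D grayscale slice.

    Parameters
    ----------
    values
        H x W float array with finite values in [0, 1].
    pixel_size
        Physical edge length of one pixel, in micrometres.
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(f"image must be at least 2x2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("image contains non-finite intensities")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValidationError(
                f"intensities must lie in [0, 1]; range is [{v.min():g}, {v.max():g}]"
            )
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale an array to [0, 1]; a constant array maps to zeros."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("cannot normalize non-finite intensities")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def as_intensity_image(
    values: np.ndarray, pixel_size: float = 1.0, *, normalize_minmax: bool = True
) -> IntensityImage:
    """Wrap a raw array as an :class:`IntensityImage`, normalizing by default."""
    v = np.asarray(values, dtype=float)
    if normalize_minmax:
        v = normalize(v)
    return IntensityImage(v, pixel_size)
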