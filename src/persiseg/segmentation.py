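"""Per-slice segmentation of membrane profile and internal cavities.

The membrane profile Gamma of a slice is obtained from the ascending
filtration: the optimal persistence threshold keeps the most contrasted
bright cycles, and Gamma is the external boundary of the union of their
regions (interior holes are deliberately ignored here — cavities get their
own routine). Internal cavities come from the descending filtration,
restricted to classes whose representative lies inside Gamma, with the
persistence threshold recomputed on that subfamily.

Saddle points make representatives nest (an elder class's region contains
a younger one's). Nested pairs are resolved by a splitting rule on the
filled masks: the inner region is dilated by a disk whose radius is the
directed Hausdorff distance between the two curves, the dilated set is
subtracted from the outer region, and the outer class's representative is
replaced by the external boundary of what remains, which is disjoint from
the inner curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff as _scipy_dh

from .contours import ContourCurve, fill_holes
from .filtration import (
    DEFAULT_REP_LEVEL_FRACTION,
    EIGHT_CONNECTED,
    FiltrationDirection,
    PersistenceDiagram,
    representative_region,
    sublevel_h1_diagram,
    superlevel_h1_diagram,
)
from .image import IntensityImage
from .thresholding import ThresholdConfig, optimal_threshold, select_persistent

logger = logging.getLogger(__name__)


class NoMembraneFoundError(RuntimeError):
    """No persistent bright cycle: the slice has no segmentable membrane."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the per-slice stage.

    ``hausdorff_direction`` chooses which directed distance sets the
    dilation radius of the nested-cycle split; ``inner_to_outer`` carves
    the outer representative away from the saddle. ``inside_gamma_fraction``
    is the fraction of a representative's interior that must lie inside
    Gamma for the class to count as internal (1.0 is brittle to one-pixel
    boundary rasterization). ``pad_border`` adds a one-pixel dark frame so
    bright structures touching the image border can close their cycles.
    """

    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    rep_level_fraction: float = DEFAULT_REP_LEVEL_FRACTION
    inside_gamma_fraction: float = 0.99
    hausdorff_direction: str = "inner_to_outer"
    pad_border: bool = False

    def __post_init__(self) -> None:
        if self.hausdorff_direction not in ("inner_to_outer", "outer_to_inner"):
            raise ValueError("hausdorff_direction must be inner_to_outer or outer_to_inner")
        if not 0.0 < self.inside_gamma_fraction <= 1.0:
            raise ValueError("inside_gamma_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SliceSegmentation:
    """Membrane boundary Gamma plus disjoint cavity contours for one slice."""

    membrane_boundary: ContourCurve
    cavities: tuple[ContourCurve, ...]
    slice_index: int = 0


@dataclass(frozen=True)
class SliceResult:
    """Segmentation of one slice together with the thresholds that produced it."""

    segmentation: SliceSegmentation
    membrane_threshold: float
    cavity_threshold: float | None
    sublevel_diagram: PersistenceDiagram
    superlevel_diagram: PersistenceDiagram | None


def _maybe_pad(image: IntensityImage, config: SegmentationConfig) -> IntensityImage:
    if not config.pad_border:
        return image
    padded = np.pad(image.values, 1, constant_values=0.0)
    return IntensityImage(padded, image.pixel_size)


def _unpad_contour(curve: ContourCurve, shape: tuple[int, int]) -> ContourCurve:
    return ContourCurve(curve.vertices - 1.0, curve.interior_mask[1:-1, 1:-1])


def segment_membrane(
    image: IntensityImage, config: SegmentationConfig = SegmentationConfig()
) -> ContourCurve:
    """External boundary Gamma of the union of selected bright cycles.

    Raises :class:`NoMembraneFoundError` when no cycle survives the
    persistence threshold (e.g. on a constant slice).
    """
    return segment_slice_with_info(image, config, cavities=False).segmentation.membrane_boundary


def detect_cavities(
    image: IntensityImage,
    gamma: ContourCurve,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[ContourCurve]:
    """Dark cycles inside Gamma, persistence-thresholded on that subfamily."""
    work = _maybe_pad(image, config)
    if config.pad_border:
        gamma_mask = np.pad(gamma.interior_mask, 1, constant_values=False)
    else:
        gamma_mask = gamma.interior_mask
    curves = _detect_cavities_impl(work, gamma_mask, config)[0]
    if config.pad_border:
        curves = [_unpad_contour(c, image.shape) for c in curves]
    return curves


def _detect_cavities_impl(
    image: IntensityImage, gamma_mask: np.ndarray, config: SegmentationConfig
):
    diagram = superlevel_h1_diagram(image)
    gamma_area = gamma_mask.sum()
    members: list[tuple[float, np.ndarray]] = []
    for pair in diagram.pairs:
        if not gamma_mask[pair.critical_pixel]:
            continue  # cheap reject: the death-critical cell is outside Gamma
        region = fill_holes(
            representative_region(
                pair, image, FiltrationDirection.SUPERLEVEL, config.rep_level_fraction
            )
        )
        n = region.sum()
        if n > gamma_area:
            continue
        inside = (region & gamma_mask).sum() / n
        if inside >= config.inside_gamma_fraction:
            members.append((pair.persistence, region))
    if not members:
        return [], None
    t = optimal_threshold(
        np.array([m[0] for m in members]), config.threshold
    )
    curves = [
        ContourCurve.from_mask(region) for pers, region in members if pers > t
    ]
    return curves, t


def directed_hausdorff(A, B) -> float:
    """max over a in A of min over b in B of Euclidean distance.

    Accepts :class:`ContourCurve` objects or raw (N, 2) vertex arrays.
    """
    pa = A.vertices if isinstance(A, ContourCurve) else np.atleast_2d(np.asarray(A, float))
    pb = B.vertices if isinstance(B, ContourCurve) else np.atleast_2d(np.asarray(B, float))
    if pa.size == 0 or pb.size == 0:
        raise ValueError("both curves must be nonempty")
    return float(_scipy_dh(pa, pb)[0])


def split_nested_pair(
    inner: ContourCurve,
    outer: ContourCurve,
    config: SegmentationConfig = SegmentationConfig(),
) -> ContourCurve:
    """New representative for the outer class of a nested pair.

    The inner filled mask is dilated by a Euclidean disk whose radius is
    the directed Hausdorff distance between the curves; the external
    boundary of (outer interior minus the dilated set) replaces the outer
    representative. Degenerate cases (the subtraction empties the outer
    region, or leaves only a shell whose filled interior still swallows
    the inner curve) fall back to returning ``outer`` unchanged with a
    warning.
    """
    if not inner.nested_in(outer):
        raise ValueError("inner curve is not nested in outer curve")
    if config.hausdorff_direction == "inner_to_outer":
        radius = directed_hausdorff(inner, outer)
    else:
        radius = directed_hausdorff(outer, inner)
    dist = ndimage.distance_transform_edt(~inner.interior_mask)
    remainder = outer.interior_mask & ~(dist <= radius)
    if not remainder.any():
        logger.warning("nested-cycle split emptied the outer region; keeping outer")
        return outer
    labels, n = ndimage.label(remainder, structure=EIGHT_CONNECTED)
    if n > 1:
        sizes = ndimage.sum_labels(remainder, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        remainder = labels == keep
    candidate = ContourCurve.from_mask(remainder)
    if candidate.overlaps(inner):
        logger.warning(
            "nested-cycle split left an annular shell around the inner curve; keeping outer"
        )
        return outer
    return candidate


def refine_nested(
    cavities: list[ContourCurve], config: SegmentationConfig = SegmentationConfig()
) -> list[ContourCurve]:
    """Split every nested pair (innermost first) until interiors are disjoint.

    The output has the same length as the input. Pairs whose split is
    degenerate are left as-is (with a warning) and not retried; genuine
    non-convergence past ``len(cavities) ** 2`` sweeps raises.
    """
    curves = list(cavities)
    n = len(curves)
    if n < 2:
        return curves
    unresolved: set[tuple[int, int]] = set()
    max_sweeps = max(1, n * n)
    for _ in range(max_sweeps):
        acted = False
        order = sorted(range(n), key=lambda i: curves[i].area)
        for i in order:  # innermost first
            for j in order:
                if i == j or (i, j) in unresolved:
                    continue
                if curves[i].area <= curves[j].area and curves[i].nested_in(curves[j]):
                    new_outer = split_nested_pair(curves[i], curves[j], config)
                    if new_outer is curves[j]:
                        unresolved.add((i, j))
                    else:
                        curves[j] = new_outer
                    acted = True
        if not acted:
            return curves
    # A full sweep still found nested pairs: report what remains nested.
    nested_left = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and (i, j) not in unresolved and curves[i].nested_in(curves[j])
        and curves[i].area < curves[j].area
    ]
    if nested_left:
        raise RuntimeError(
            f"nested-cycle refinement did not converge after {max_sweeps} sweeps; "
            f"still nested: {nested_left}"
        )
    return curves


def segment_slice_with_info(
    image: IntensityImage,
    config: SegmentationConfig = SegmentationConfig(),
    slice_index: int = 0,
    cavities: bool = True,
) -> SliceResult:
    """Full per-slice pipeline, keeping thresholds and diagrams for the log."""
    work = _maybe_pad(image, config)
    sub = sublevel_h1_diagram(work)
    if len(sub) == 0:
        raise NoMembraneFoundError("no bright cycle in the slice (empty diagram)")
    t_mem = optimal_threshold(sub.persistences, config.threshold)
    selected = select_persistent(sub, t_mem)
    if len(selected) == 0:
        raise NoMembraneFoundError(
            f"no cycle with persistence above the threshold {t_mem:g}"
        )
    union = np.zeros(work.shape, dtype=bool)
    for pair in selected.pairs:
        union |= representative_region(
            pair, work, FiltrationDirection.SUBLEVEL, config.rep_level_fraction
        )
    union = fill_holes(union)
    labels, n = ndimage.label(union, structure=EIGHT_CONNECTED)
    if n > 1:
        sizes = ndimage.sum_labels(union, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        logger.warning(
            "selected bright regions form %d components; keeping the largest", n
        )
        union = labels == keep
    gamma = ContourCurve.from_mask(union)

    sup = superlevel_h1_diagram(work) if cavities else None
    cavity_curves: list[ContourCurve] = []
    t_cav = None
    if cavities:
        cavity_curves, t_cav = _detect_cavities_impl(work, gamma.interior_mask, config)
        cavity_curves = refine_nested(cavity_curves, config)
        # Enforce the containment invariant against 1-px rasterization slack.
        clipped = []
        for c in cavity_curves:
            if c.nested_in(gamma):
                clipped.append(c)
            else:
                inter = c.interior_mask & gamma.interior_mask
                if inter.any():
                    clipped.append(ContourCurve.from_mask(inter))
                else:
                    logger.warning("cavity fell entirely outside Gamma; dropped")
        cavity_curves = clipped

    if config.pad_border:
        gamma = _unpad_contour(gamma, image.shape)
        cavity_curves = [_unpad_contour(c, image.shape) for c in cavity_curves]

    seg = SliceSegmentation(gamma, tuple(cavity_curves), slice_index)
    return SliceResult(seg, float(t_mem), t_cav, sub, sup)


def segment_slice(
    image: IntensityImage,
    config: SegmentationConfig = SegmentationConfig(),
    slice_index: int = 0,
) -> SliceSegmentation:
    """Membrane + cavities + nested refinement for one slice."""
    return segment_slice_with_info(image, config, slice_index).segmentation
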