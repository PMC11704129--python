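"""End-to-end pipeline: z-stack in, segmentations + surface mesh out.

Coordinate convention: images are indexed (row, col), 0-based; mesh
coordinates are (x, y, z) = (col * pixel_size, row * pixel_size,
slice_index * axial_spacing), in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .image import IntensityImage
from .reconstruction import (
    ROLE_BASAL,
    ROLE_CAVITY,
    ROLE_LUMINAL,
    ReconstructionConfig,
    TriangleMesh,
    max_interslice_edge,
    reconstruct_mesh,
    remesh_uniform,
    role_crossing_edges,
    taubin_smooth,
)
from .segmentation import (
    NoMembraneFoundError,
    SegmentationConfig,
    SliceResult,
    segment_slice_with_info,
)
from .thresholding import ThresholdConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str | Path = ""
    output_dir: str | Path = "persiseg_out"
    pixel_size: float = 0.16
    axial_spacing: float = 0.3
    normalize: bool = True
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    smooth: bool = True
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.axial_spacing <= 0:
            raise ValueError("pixel_size and axial_spacing must be positive")


def config_from_yaml(path: str | Path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized nested keys include ``threshold.selector``,
    ``threshold.fixed_value``, ``threshold.min_persistence``, plus flat
    keys matching the dataclass fields.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    thr = raw.pop("threshold", {})
    seg_kwargs = raw.pop("segmentation", {})
    rec_kwargs = raw.pop("reconstruction", {})
    if thr:
        seg_kwargs["threshold"] = ThresholdConfig(**thr)
    kwargs = dict(raw)
    if seg_kwargs:
        kwargs["segmentation"] = SegmentationConfig(**seg_kwargs)
    if rec_kwargs:
        if "lumen_direction" in rec_kwargs and rec_kwargs["lumen_direction"] is not None:
            rec_kwargs["lumen_direction"] = tuple(rec_kwargs["lumen_direction"])
        kwargs["reconstruction"] = ReconstructionConfig(**rec_kwargs)
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@dataclass
class PipelineRun:
    """Everything one pipeline execution produced."""

    segmentations: list[SliceResult]
    skipped_slices: list[int]
    mesh: TriangleMesh
    log: dict
    output_dir: Path


def run_pipeline(
    config: PipelineConfig, stack: list[IntensityImage] | None = None
) -> PipelineRun:
    """Segment every slice, reconstruct, smooth, remesh, and write outputs.

    ``stack`` may be passed directly (e.g. a freshly generated phantom);
    otherwise it is read from ``config.input_path``. Slices without a
    segmentable membrane are logged and skipped; fewer than two
    segmentable slices is a hard error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stack is None:
        stack = pio.read_stack(
            config.input_path, config.pixel_size, normalize_minmax=config.normalize
        )
    if len(stack) < 2:
        raise ValueError("need a stack of at least 2 slices")

    results: list[SliceResult] = []
    skipped: list[int] = []
    for k, image in enumerate(stack):
        try:
            res = segment_slice_with_info(image, config.segmentation, k)
        except NoMembraneFoundError as exc:
            logger.warning("slice %d skipped: %s", k, exc)
            skipped.append(k)
            continue
        results.append(res)
    if len(results) < 2:
        raise RuntimeError(
            f"only {len(results)} slices were segmentable; cannot reconstruct"
        )

    contours_index: list[tuple[str, object]] = []
    diagrams_index: list[tuple[str, object]] = []
    for res in results:
        seg = res.segmentation
        k = seg.slice_index
        contours_index.append((f"s{k:03d}_membrane", seg.membrane_boundary))
        for i, cav in enumerate(seg.cavities):
            contours_index.append((f"s{k:03d}_cavity{i}", cav))
        diagrams_index.append((f"s{k:03d}_sub", res.sublevel_diagram))
        if res.superlevel_diagram is not None:
            diagrams_index.append((f"s{k:03d}_sup", res.superlevel_diagram))
        pio.write_label_mask(
            out / f"mask_{k:03d}.tif",
            pio.segmentation_label_mask(seg, stack[k].shape),
        )
    pio.write_contours_csv(out / "contours.csv", contours_index)
    pio.write_diagram_csv(out / "diagrams.csv", diagrams_index)

    rec = dataclasses.replace(
        config.reconstruction, axial_spacing=config.axial_spacing
    )
    mesh = reconstruct_mesh(
        [r.segmentation for r in results], rec, pixel_size=config.pixel_size
    )
    if config.smooth and rec.taubin_iters > 0:
        mesh = taubin_smooth(mesh, rec.taubin_lambda, rec.taubin_mu, rec.taubin_iters)
    if rec.remesh_target_vertices is not None:
        mesh = remesh_uniform(mesh, rec.remesh_target_vertices, seed=config.seed)
    pio.write_mesh_ply(out / "mesh.ply", mesh)
    pio.write_mesh_obj(out / "mesh.obj", mesh)

    audit = {
        "max_interslice_edge_um": max_interslice_edge(mesh),
        "d_max_um": rec.d_max,
        "d_max_satisfied": max_interslice_edge(mesh) <= rec.d_max + 1e-9,
        "cavity_membrane_crossing_edges": (
            role_crossing_edges(mesh, ROLE_CAVITY, ROLE_LUMINAL)
            + role_crossing_edges(mesh, ROLE_CAVITY, ROLE_BASAL)
            if mesh.vertex_roles is not None
            else None
        ),
        "n_vertices": int(len(mesh.vertices)),
        "n_triangles": int(len(mesh.triangles)),
        "n_components": mesh.n_components(),
    }
    log = {
        "n_slices": len(stack),
        "n_segmented": len(results),
        "skipped_slices": skipped,
        "per_slice": [
            {
                "slice": r.segmentation.slice_index,
                "membrane_threshold": r.membrane_threshold,
                "cavity_threshold": r.cavity_threshold,
                "n_cavities": len(r.segmentation.cavities),
            }
            for r in results
        ],
        "mesh_audit": audit,
    }
    (out / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n", newline="\n"
    )
    return PipelineRun(results, skipped, mesh, log, out)
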