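"""Readers and writers for stacks, contours, diagrams, masks, and meshes.

All text outputs use '.' decimal separators and LF line endings and are
written deterministically, so reruns with the same configuration produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .contours import ContourCurve
from .filtration import PersistenceDiagram
from .image import IntensityImage, as_intensity_image
from .reconstruction import ROLE_NAMES, TriangleMesh
from .segmentation import SliceSegmentation


def _fmt(x: float) -> str:
    return f"{float(x):.9g}"


def read_stack(
    path: str | Path, pixel_size: float = 1.0, normalize_minmax: bool = True
) -> list[IntensityImage]:
    """Read a z-stack from a multi-page TIFF or a directory of TIFF slices."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        arrays = [tifffile.imread(f) for f in files]
    else:
        data = tifffile.imread(path)
        arrays = [data] if data.ndim == 2 else list(data)
    out = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if not normalize_minmax and a.max() > 1.0:
            a = a / np.iinfo(np.uint16).max if a.max() > 255 else a / 255.0
        out.append(as_intensity_image(a, pixel_size, normalize_minmax=normalize_minmax))
    return out


def write_stack(path: str | Path, stack: list[IntensityImage]) -> None:
    data = np.stack([im.values for im in stack]).astype(np.float32)
    tifffile.imwrite(path, data)


def write_diagram_csv(
    path: str | Path, diagrams: list[tuple[str, PersistenceDiagram]]
) -> None:
    """CSV of (direction, birth, death, persistence, representative_id).

    ``diagrams`` is a list of (id_prefix, diagram); each pair gets the
    representative id "<prefix>_<index>" matching the contour file.
    """
    lines = ["direction,birth,death,persistence,representative_id"]
    for prefix, diag in diagrams:
        for i, p in enumerate(diag.pairs):
            lines.append(
                f"{diag.direction.value},{_fmt(p.birth)},{_fmt(p.death)},"
                f"{_fmt(p.persistence)},{prefix}_{i}"
            )
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def write_contours_csv(
    path: str | Path, contours: list[tuple[str, ContourCurve]]
) -> None:
    """CSV of (representative_id, vertex_index, row, col)."""
    lines = ["representative_id,vertex_index,row,col"]
    for rid, curve in contours:
        for i, (r, c) in enumerate(curve.vertices):
            lines.append(f"{rid},{i},{_fmt(r)},{_fmt(c)}")
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_contours_csv(path: str | Path) -> dict[str, np.ndarray]:
    """Vertex arrays keyed by representative id (inverse of the writer)."""
    out: dict[str, list[tuple[float, float]]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        rid, _, r, c = line.split(",")
        out.setdefault(rid, []).append((float(r), float(c)))
    return {k: np.asarray(v) for k, v in out.items()}


def segmentation_label_mask(seg: SliceSegmentation, shape: tuple[int, int]) -> np.ndarray:
    """Labeled mask: 0 background, 1 membrane interior, 2+k for cavity k."""
    lab = np.zeros(shape, dtype=np.uint16)
    lab[seg.membrane_boundary.interior_mask] = 1
    for k, cav in enumerate(seg.cavities):
        lab[cav.interior_mask] = 2 + k
    return lab


def write_label_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint16))


def write_mesh_ply(path: str | Path, mesh: TriangleMesh) -> None:
    """ASCII PLY with a per-vertex integer ``role`` property
    (0 luminal, 1 basal, 2 cavity; -1 when roles are absent)."""
    roles = (
        mesh.vertex_roles
        if mesh.vertex_roles is not None
        else np.full(len(mesh.vertices), -1, dtype=np.int64)
    )
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment roles: {', '.join(f'{k}={v}' for k, v in ROLE_NAMES.items())}",
        f"element vertex {len(mesh.vertices)}",
        "property float x",
        "property float y",
        "property float z",
        "property int role",
        f"element face {len(mesh.triangles)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for (x, y, z), r in zip(mesh.vertices, roles):
        lines.append(f"{_fmt(x)} {_fmt(y)} {_fmt(z)} {int(r)}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def write_mesh_obj(path: str | Path, mesh: TriangleMesh) -> None:
    lines = [f"v {_fmt(x)} {_fmt(y)} {_fmt(z)}" for x, y, z in mesh.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")


def read_mesh_ply(path: str | Path) -> TriangleMesh:
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    nv = nf = 0
    for line in it:
        if line.startswith("element vertex"):
            nv = int(line.split()[-1])
        elif line.startswith("element face"):
            nf = int(line.split()[-1])
        elif line == "end_header":
            break
    verts, roles = [], []
    for _ in range(nv):
        parts = next(it).split()
        verts.append([float(x) for x in parts[:3]])
        roles.append(int(parts[3]))
    faces = [[int(x) for x in next(it).split()[1:4]] for _ in range(nf)]
    roles_arr = np.asarray(roles)
    return TriangleMesh(
        np.asarray(verts),
        np.asarray(faces, dtype=np.int64),
        None if (roles_arr < 0).all() else roles_arr,
    )


def write_params_json(path: str | Path, params) -> None:
    """Echo a (possibly nested) dataclass as a sorted JSON sidecar."""
    import dataclasses

    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    Path(path).write_text(
        json.dumps(enc(params), indent=2, sort_keys=True) + "\n", newline="\n"
    )
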