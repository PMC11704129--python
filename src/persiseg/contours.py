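"""Closed planar contours on the pixel grid.

A :class:`ContourCurve` is the crack boundary of a filled pixel region: its
vertices live on the corner grid (half-integer row/col coordinates) and
consecutive vertices are one unit apart, so the polyline is a closed
staircase curve. Storing the boundary on cracks rather than on pixel
centres makes the fill operation exact: rasterizing the polygon by crossing
parity reproduces the pixel region the curve was traced from, which is the
fill-consistency contract the segmentation stage relies on.

Regions are 8-connected (matching the connectivity of strict level-set
components of the max-rule cubical complex) and are hole-filled before
tracing; at pinch corners, where two diagonal region pixels meet, the
tracer takes the right-hand turn so that the whole 8-connected component
stays enclosed by a single closed curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ContourCurve:
    """A closed contour with its filled interior mask.

    ``vertices`` is an (N, 2) float array of (row, col) corner coordinates;
    the curve is closed implicitly (the last vertex connects to the first).
    ``interior_mask`` holds the enclosed pixels, including the region's own
    pixels (the curve runs on the cracks just outside them).
    """

    vertices: np.ndarray
    interior_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 4:
            raise ValueError("a closed contour needs at least 4 (row, col) vertices")
        m = np.asarray(self.interior_mask, dtype=bool)
        v.setflags(write=False)
        m.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "interior_mask", m)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "ContourCurve":
        """Trace the external boundary of a nonempty 8-connected region.

        Interior holes (4-connected background pockets) are filled first,
        so the stored interior is the filled region.
        """
        filled = fill_holes(np.asarray(mask, dtype=bool))
        return cls(trace_external_boundary(filled), filled)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def area(self) -> int:
        """Number of interior pixels."""
        return int(self.interior_mask.sum())

    @property
    def perimeter(self) -> float:
        """Length of the closed staircase polyline (= vertex count, unit steps)."""
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.abs(d).sum())

    def nested_in(self, other: "ContourCurve") -> bool:
        """True iff every interior pixel of self lies in other's interior."""
        return bool(np.all(~self.interior_mask | other.interior_mask))

    def overlaps(self, other: "ContourCurve") -> bool:
        return bool(np.any(self.interior_mask & other.interior_mask))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill 4-connected background pockets of an 8-connected foreground region."""
    return ndimage.binary_fill_holes(mask)


def trace_external_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the closed crack boundary of a filled 8-connected region.

    Returns an (N, 2) array of (row, col) corner coordinates (half-integer
    offsets from pixel centres), ordered so the region lies on the left of
    the walking direction. The region must be nonempty and 8-connected with
    no holes; multi-component masks trace the component containing the
    lexicographically first pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace the boundary of an empty region")
    H, W = mask.shape
    padded = np.zeros((H + 2, W + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    # Directed crack edges, region on the left. Corners are integer points
    # (i, j) standing for (i - 0.5, j - 0.5) in pixel coordinates.
    outgoing: dict[tuple[int, int], list[tuple[int, int]]] = {}

    rows, cols = np.nonzero(mask)
    up = ~padded[rows, cols + 1]
    down = ~padded[rows + 2, cols + 1]
    left = ~padded[rows + 1, cols]
    right = ~padded[rows + 1, cols + 2]
    for r, c, u_, d_, l_, rt in zip(rows, cols, up, down, left, right):
        r, c = int(r), int(c)
        if u_:  # walk west along the top crack
            outgoing.setdefault((r, c + 1), []).append((r, c))
        if d_:  # walk east along the bottom crack
            outgoing.setdefault((r + 1, c), []).append((r + 1, c + 1))
        if l_:  # walk south along the left crack
            outgoing.setdefault((r, c), []).append((r + 1, c))
        if rt:  # walk north along the right crack
            outgoing.setdefault((r + 1, c + 1), []).append((r, c + 1))

    # Start on the top crack of the first region pixel (always external).
    r0, c0 = int(rows[0]), int(cols[0])
    start = (r0, c0 + 1)
    start_next = (r0, c0)

    corners = [start]
    prev, cur = start, start_next
    while cur != start:
        corners.append(cur)
        cands = outgoing[cur]
        if len(cands) == 1:
            nxt = cands[0]
        else:
            # Pinch corner: prefer the right-hand turn so both diagonal
            # pixels of the 8-connected region stay inside one curve.
            din = (cur[0] - prev[0], cur[1] - prev[1])
            right_turn = (cur[0] + din[1], cur[1] - din[0])
            nxt = right_turn if right_turn in cands else next(
                c for c in cands if c != prev
            )
        prev, cur = cur, nxt
    return np.asarray(corners, dtype=float) - 0.5


def fill_contour(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed crack polyline back to its interior pixel mask.

    Uses exact crossing parity over the vertical cracks of the polygon;
    for curves produced by :func:`trace_external_boundary` this inverts the
    tracing exactly.
    """
    H, W = shape
    v = np.rint(np.asarray(vertices, dtype=float) + 0.5).astype(int)
    crossings = np.zeros((H, W + 1), dtype=np.int64)
    nxt = np.roll(v, -1, axis=0)
    for (i0, j0), (i1, j1) in zip(v, nxt):
        if j0 == j1 and abs(i1 - i0) == 1:  # vertical crack segment
            row = min(i0, i1)
            if 0 <= row < H and 0 <= j0 <= W:
                crossings[row, j0] += 1
    return (np.cumsum(crossings, axis=1)[:, :W] % 2).astype(bool)
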