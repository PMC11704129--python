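"""Synthetic confocal phantoms with known ground truth.

The phantom emulates the slice structure of a fluorescently labelled cell
imaged in a z-stack: a bright elliptical membrane band enclosing a dimmer
cytoplasm, dark ellipsoidal cavities (blebs, cytoplasmic voids, the
nucleus) under the luminal side, and an invagination — a dark channel
breaching the band's top and connecting the interior to the outside, as
the luminal opening does in the real cells. Slices are degraded by
Gaussian blur and additive Gaussian noise (clipped to [0, 1]).

Because the channel opens the interior to the background, the cytoplasm is
not itself an enclosed dark cycle of the descending filtration: each
cavity is its own class, with persistence equal to its contrast against
the cytoplasm. Closed-band fixtures (see ``generate_toy_image`` /
``nested_cavities``) instead produce the nested elder-interior
configuration that the refinement stage resolves.

Defaults follow the acquisition geometry of the imaged z-stacks
(0.16 x 0.16 x 0.3 um voxels) at a desk-size field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import IntensityImage


@dataclass(frozen=True)
class MembraneSpec:
    """Elliptical band: outer radii in pixels, constant thickness, mild
    quadratic z-modulation of the radii (factor 1 at mid-stack)."""

    center: tuple[float, float] = (52.0, 64.0)
    outer_radii: tuple[float, float] = (34.0, 48.0)
    thickness: float = 5.0
    intensity: float = 0.95
    z_modulation: float = 0.1


@dataclass(frozen=True)
class InvaginationSpec:
    """Dark channel from the image top through the band into the interior.

    ``depth`` is measured in rows from the top of the image; the default
    reaches the band centre so the channel always breaches the band.
    """

    width: float = 10.0
    depth: float = 52.0


@dataclass(frozen=True)
class CavitySpec:
    """Dark ellipsoid: centre (row, col, z in slices), radii (pixels,
    pixels, slices)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float = 0.15


@dataclass(frozen=True)
class PhantomParams:
    shape: tuple[int, int, int] = (96, 128, 20)  # (H, W, n_slices)
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    invagination: InvaginationSpec | None = field(default_factory=InvaginationSpec)
    cavities: tuple[CavitySpec, ...] = (
        CavitySpec(center=(66.0, 44.0, 5.0), radii=(7.0, 7.0, 8.5)),
        CavitySpec(center=(62.0, 86.0, 14.0), radii=(8.0, 8.0, 8.5)),
    )
    cytoplasm_intensity: float = 0.60
    background_intensity: float = 0.05
    blur_sigma: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0
    pixel_size: float = 0.16
    axial_spacing: float = 0.3

    def __post_init__(self) -> None:
        H, W, n = self.shape
        if H < 2 or W < 2 or n < 1:
            raise ValueError("phantom shape must be at least 2x2x1")
        levels = [self.background_intensity, self.cytoplasm_intensity,
                  self.membrane.intensity] + [c.intensity for c in self.cavities]
        if any(not 0.0 <= x <= 1.0 for x in levels):
            raise ValueError("all intensities must lie in [0, 1]")
        if not all(
            self.background_intensity < c.intensity <= self.cytoplasm_intensity
            for c in self.cavities
        ):
            raise ValueError("need background < cavity <= cytoplasm intensity")
        if not self.cytoplasm_intensity < self.membrane.intensity:
            raise ValueError("need cytoplasm < membrane intensity")
        if any(r <= 0 for r in self.membrane.outer_radii) or any(
            r <= 0 for c in self.cavities for r in c.radii
        ):
            raise ValueError("all radii must be positive")
        cr, cc = self.membrane.center
        ar, ac = self.membrane.outer_radii
        if cr - ar < 0 or cr + ar > H - 1 or cc - ac < 0 or cc + ac > W - 1:
            raise ValueError("membrane ellipse exceeds the image bounds")
        if self.invagination is not None:
            if cc - self.invagination.width / 2 < 0 or cc + self.invagination.width / 2 > W - 1:
                raise ValueError("invagination channel exceeds the image bounds")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Per-slice truth masks plus the expected topology of the stack.

    ``membrane_masks[k]`` is the filled cell profile of slice k (everything
    enclosed by the outer membrane boundary, channel excluded) — the region
    the filled membrane contour Gamma should recover. ``cavity_masks[i][k]``
    is cavity i's cross-section on slice k. ``expected_cavity_counts[k]``
    counts nonempty cavity cross-sections. ``expected_component_count`` is
    the number of connected surface components a reconstruction should
    produce: one membrane surface (the luminal and basal sheets meet at
    their shared split points) plus one tube per cavity."""

    membrane_masks: np.ndarray
    cavity_masks: tuple[np.ndarray, ...]
    expected_cavity_counts: tuple[int, ...]
    expected_component_count: int


def _ellipse_mask(H: int, W: int, center, radii) -> np.ndarray:
    rr, cc = np.ogrid[:H, :W]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def generate_phantom_stack(
    params: PhantomParams = PhantomParams(),
) -> tuple[list[IntensityImage], PhantomGroundTruth]:
    """Rasterize the phantom geometry slice by slice; deterministic in seed."""
    H, W, n = params.shape
    mem = params.membrane
    rng = np.random.default_rng(params.seed)

    stack: list[IntensityImage] = []
    membrane_masks = np.zeros((n, H, W), dtype=bool)
    cavity_masks = [np.zeros((n, H, W), dtype=bool) for _ in params.cavities]

    half = (n - 1) / 2 if n > 1 else 1.0
    for k in range(n):
        f = 1.0 - mem.z_modulation * ((k - half) / half) ** 2 if n > 1 else 1.0
        outer_r = (mem.outer_radii[0] * f, mem.outer_radii[1] * f)
        inner_r = (outer_r[0] - mem.thickness, outer_r[1] - mem.thickness)
        outer = _ellipse_mask(H, W, mem.center, outer_r)
        inner = _ellipse_mask(H, W, mem.center, inner_r)

        u = np.full((H, W), params.background_intensity)
        u[outer] = mem.intensity
        u[inner] = params.cytoplasm_intensity

        for i, cav in enumerate(params.cavities):
            dz = (k - cav.center[2]) / cav.radii[2]
            if abs(dz) >= 1.0:
                continue
            s = np.sqrt(1.0 - dz * dz)
            cmask = _ellipse_mask(
                H, W, cav.center[:2], (cav.radii[0] * s, cav.radii[1] * s)
            )
            if cmask.any():
                u[cmask] = cav.intensity
                cavity_masks[i][k] = cmask

        channel = np.zeros((H, W), dtype=bool)
        if params.invagination is not None:
            inv = params.invagination
            c0 = int(round(mem.center[1] - inv.width / 2))
            c1 = int(round(mem.center[1] + inv.width / 2))
            channel[: int(round(inv.depth)), c0:c1] = True
            u[channel] = params.background_intensity

        membrane_masks[k] = outer & ~channel

        if params.blur_sigma > 0:
            u = ndimage.gaussian_filter(u, params.blur_sigma)
        if params.noise_sigma > 0:
            u = u + rng.normal(0.0, params.noise_sigma, size=u.shape)
        u = np.clip(u, 0.0, 1.0)
        stack.append(IntensityImage(u, params.pixel_size))

    counts = tuple(
        int(sum(cavity_masks[i][k].any() for i in range(len(params.cavities))))
        for k in range(n)
    )
    expected_components = 1 + len(params.cavities)
    return stack, PhantomGroundTruth(
        membrane_masks, tuple(cavity_masks), counts, expected_components
    )


_TOY_BUILDERS = {}


def _toy(name):
    def wrap(fn):
        _TOY_BUILDERS[name] = fn
        return fn

    return wrap


@_toy("ring3")
def _ring3() -> IntensityImage:
    """3x3 bright centre on a dark ring: one ascending pair (0.1, 0.9)."""
    u = np.full((3, 3), 0.1)
    u[1, 1] = 0.9
    return IntensityImage(u)


@_toy("saddle_dumbbell")
def _saddle_dumbbell() -> IntensityImage:
    """Two bright hills (1.0 and 0.75) joined by a 0.3 bridge on black.

    The ascending diagram has an elder class born at 0 (dying at 1.0, its
    representative the whole dumbbell) and a class born at the saddle
    value 0.3 when the shape splits, dying at 0.75.
    """
    u = np.zeros((32, 48))
    bridge = np.zeros_like(u, dtype=bool)
    bridge[13:20, 14:35] = True
    u[bridge] = 0.3
    d1 = _ellipse_mask(32, 48, (16, 14), (8, 8))
    d2 = _ellipse_mask(32, 48, (16, 34), (8, 8))
    u[d1] = 1.0
    u[d2] = 0.75
    return IntensityImage(u)


@_toy("nested_cavities")
def _nested_cavities() -> IntensityImage:
    """Closed bright band with two dark cavities and two faint dots.

    With a sealed interior the elder descending class is the whole
    interior (persistence 0.83) and the younger cavity (persistence 0.57)
    nests inside it; the faint dots (persistence 0.10) form the noise
    cluster that anchors the gap threshold. Cavity detection followed by
    nested refinement yields two disjoint curves.
    """
    u = np.full((64, 64), 0.05)
    u[_ellipse_mask(64, 64, (32, 32), (26, 26))] = 0.95
    u[_ellipse_mask(64, 64, (32, 32), (22, 22))] = 0.75
    u[_ellipse_mask(64, 64, (45, 32), (4.5, 4.5))] = 0.12  # near-wall, elder
    u[_ellipse_mask(64, 64, (32, 19), (4.5, 4.5))] = 0.18  # younger, nested
    u[_ellipse_mask(64, 64, (24, 42), (2, 2))] = 0.65
    u[_ellipse_mask(64, 64, (38, 44), (2, 2))] = 0.65
    return IntensityImage(u)


def generate_toy_image(kind: str) -> IntensityImage:
    """Deterministic small fixture with documented expected behaviour."""
    try:
        return _TOY_BUILDERS[kind]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {kind!r}; available: {sorted(_TOY_BUILDERS)}"
        ) from None
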