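"""Contour tiling, mesh contracts, smoothing, and remeshing."""

import numpy as np
import pytest
import trimesh

from persiseg.contours import ContourCurve
from persiseg.reconstruction import (
    ROLE_BASAL,
    ROLE_CAVITY,
    ROLE_LUMINAL,
    Contour3D,
    ReconstructionConfig,
    TriangleMesh,
    lift_contour,
    max_interslice_edge,
    reconstruct_mesh,
    remesh_uniform,
    role_crossing_edges,
    split_basal_luminal,
    taubin_smooth,
    tile_adjacent_contours,
    triangle_areas,
)
from persiseg.segmentation import SliceSegmentation


def circle3d(radius, z, n=36, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    v = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th), np.full(n, z)]
    )
    return Contour3D(v, "luminal")


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def graded_tube(n_rings=30, n=40, radius=10.0):
    zs = np.insert(np.cumsum(np.geomspace(0.2, 2.0, n_rings)), 0, 0.0)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.column_stack([radius * np.cos(th), radius * np.sin(th)])
    V = np.vstack([np.column_stack([ring, np.full(n, z)]) for z in zs])
    T = []
    for i in range(len(zs) - 1):
        for j in range(n):
            a, b = i * n + j, i * n + (j + 1) % n
            c, d = (i + 1) * n + j, (i + 1) * n + (j + 1) % n
            T += [(a, b, c), (b, d, c)]
    return TriangleMesh(V, np.array(T))


class TestSplitBasalLuminal:
    def test_circle_splits_into_facing_semicircles(self):
        c = circle3d(10.0, 0.0)
        lum, bas = split_basal_luminal(c, lumen_direction=(-1.0, 0.0))
        assert bas is not None
        # lumen toward -row = -y in physical coords
        assert lum.vertices[:, 1].mean() < bas.vertices[:, 1].mean()
        assert not lum.closed and not bas.closed
        # arcs share their two split endpoints
        shared = {tuple(v) for v in lum.vertices} & {tuple(v) for v in bas.vertices}
        assert len(shared) == 2

    def test_cavity_contour_returned_whole_as_luminal(self):
        c = Contour3D(circle3d(3.0, 1.0).vertices, "cavity", cavity_id=0)
        lum, bas = split_basal_luminal(c, lumen_direction=(-1.0, 0.0))
        assert bas is None
        assert lum.role == "luminal" and lum.closed
        assert len(lum.vertices) == len(c.vertices)

    def test_missing_axis_config_raises_instructive_error(self):
        with pytest.raises(ValueError, match="lumen_direction"):
            split_basal_luminal(circle3d(5.0, 0.0), lumen_direction=None)


class TestTiling:
    def test_identical_squares_tile_to_closed_tube(self):
        sq = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        A = Contour3D(np.column_stack([sq, np.zeros(4)]), "luminal")
        B = Contour3D(np.column_stack([sq, np.full(4, 0.3)]), "luminal")
        tris = tile_adjacent_contours(A, B, d_max=1.0)
        assert len(tris) == 8  # 2N triangles
        mesh = TriangleMesh(np.vstack([A.vertices, B.vertices]), tris)
        V, E, F = len(mesh.vertices), len(mesh.edges), len(mesh.triangles)
        assert V - E + F == 0  # Euler characteristic of a tube

    def test_far_contours_produce_no_triangles(self):
        A = circle3d(5.0, 0.0)
        B = circle3d(5.0, 0.3, center=(20.0, 0.0))
        assert len(tile_adjacent_contours(A, B, d_max=1.0)) == 0

    def test_unmatched_cavity_rim_stays_open(self):
        """A cavity ending between slices must not weld to the membrane."""
        shape = (48, 48)
        gamma = ContourCurve.from_mask(disk_mask(shape, (24, 24), 20))
        cav = ContourCurve.from_mask(disk_mask(shape, (24, 24), 4))
        seg0 = SliceSegmentation(gamma, (cav,), 0)
        seg1 = SliceSegmentation(gamma, (), 1)
        mesh = reconstruct_mesh([seg0, seg1], ReconstructionConfig(), pixel_size=0.16)
        assert mesh.vertex_roles is not None
        assert role_crossing_edges(mesh, ROLE_CAVITY, ROLE_LUMINAL) == 0
        assert role_crossing_edges(mesh, ROLE_CAVITY, ROLE_BASAL) == 0
        # the cavity contributes no triangles at all here
        cav_vertices = np.flatnonzero(mesh.vertex_roles == ROLE_CAVITY)
        assert not np.isin(mesh.triangles, cav_vertices).any()


class TestReconstructMesh:
    def test_requires_two_slices(self):
        gamma = ContourCurve.from_mask(disk_mask((32, 32), (16, 16), 10))
        with pytest.raises(ValueError):
            reconstruct_mesh([SliceSegmentation(gamma, (), 0)])

    def test_phantom_contracts(self, phantom_noiseless, phantom_mesh):
        _, gt = phantom_noiseless
        cfg = ReconstructionConfig()
        assert max_interslice_edge(phantom_mesh) <= cfg.d_max + 1e-9
        assert phantom_mesh.n_components() == gt.expected_component_count
        assert role_crossing_edges(phantom_mesh, ROLE_CAVITY, ROLE_LUMINAL) == 0
        assert role_crossing_edges(phantom_mesh, ROLE_CAVITY, ROLE_BASAL) == 0

    def test_stack_of_identical_circles_gives_tube_area(self):
        mask = disk_mask((64, 64), (32, 32), 20)
        curve = ContourCurve.from_mask(mask)
        contours = [lift_contour(curve, k, 1.0, 1.0, "luminal") for k in range(11)]
        tris, verts, off = [], [], 0
        for a, b in zip(contours, contours[1:]):
            t = tile_adjacent_contours(a, b, d_max=2.0)
            n = len(a.vertices)
            tris.append(np.where(t < n, t + off, t - n + off + n))
            off += n
        verts = np.vstack([c.vertices for c in contours])
        tube = TriangleMesh(verts, np.vstack(tris))
        area = triangle_areas(tube).sum()
        expected = curve.perimeter * 10.0  # circumference x height
        assert abs(area - expected) / expected <= 0.05


class TestTaubin:
    def test_zero_iterations_is_identity(self):
        ico = trimesh.creation.icosphere(2)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        out = taubin_smooth(m, 0.5, -0.53, 0)
        assert np.array_equal(out.vertices, m.vertices)

    def test_volume_preserved_within_two_percent(self):
        ico = trimesh.creation.icosphere(3)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        sm = taubin_smooth(m, 0.5, -0.53, 10)
        v0, v1 = m.to_trimesh().volume, sm.to_trimesh().volume
        assert abs(v1 - v0) / v0 <= 0.02
        assert np.array_equal(sm.triangles, m.triangles)

    def test_noisy_sphere_curvature_noise_decreases(self):
        ico = trimesh.creation.icosphere(3)
        rng = np.random.default_rng(0)
        v = np.array(ico.vertices)
        v *= (1.0 + rng.normal(0, 0.03, len(v)))[:, None]  # radial jitter
        m = TriangleMesh(v, np.array(ico.faces))
        sm = taubin_smooth(m, 0.5, -0.53, 10)

        def laplacian_var(mesh):
            # variance of the umbrella-operator magnitude: a discrete
            # proxy for mean-curvature noise
            from scipy import sparse

            e = mesh.edges
            n = len(mesh.vertices)
            adj = sparse.coo_matrix(
                (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
            )
            adj = (adj + adj.T).tocsr()
            deg = np.asarray(adj.sum(axis=1)).ravel()
            lap = adj @ mesh.vertices / deg[:, None] - mesh.vertices
            return float(np.var(np.linalg.norm(lap, axis=1)))

        assert laplacian_var(sm) < laplacian_var(m)

    def test_invalid_lambda_mu_rejected(self):
        ico = trimesh.creation.icosphere(1)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        with pytest.raises(ValueError):
            taubin_smooth(m, 0.5, -0.4, 5)
        with pytest.raises(ValueError):
            ReconstructionConfig(taubin_lambda=0.5, taubin_mu=0.5)


class TestRemesh:
    def test_graded_tube_area_cv_halves(self):
        tube = graded_tube()
        cv0 = triangle_areas(tube).std() / triangle_areas(tube).mean()
        out = remesh_uniform(tube, 600, seed=0)
        cv1 = triangle_areas(out).std() / triangle_areas(out).mean()
        assert cv1 <= 0.5 * cv0
        assert abs(len(out.vertices) - 600) <= 60  # within 10% of target
        assert out.n_components() == tube.n_components()

    def test_already_uniform_sphere_does_not_degrade(self):
        ico = trimesh.creation.icosphere(3)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        cv0 = triangle_areas(m).std() / triangle_areas(m).mean()
        out = remesh_uniform(m, len(m.vertices), seed=0)
        cv1 = triangle_areas(out).std() / triangle_areas(out).mean()
        assert cv1 <= max(cv0, 0.25)

    def test_target_four_on_sphere_stays_closed(self):
        ico = trimesh.creation.icosphere(2)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        out = remesh_uniform(m, 4, seed=0)
        assert len(out.vertices) == 4
        assert out.to_trimesh().is_watertight

    def test_target_beyond_resolution_warns_best_effort(self, caplog):
        ico = trimesh.creation.icosphere(1)
        m = TriangleMesh(np.array(ico.vertices), np.array(ico.faces))
        out = remesh_uniform(m, 10 * len(m.vertices), seed=0)
        assert len(out.vertices) <= len(m.vertices)
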