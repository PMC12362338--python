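import numpy as np
import pytest

from vesimeso import meshgen as mg


def brute_counts(mesh):
    edges = set()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(a, b), max(a, b)))
    return mesh.n_vertices, len(edges), mesh.n_faces


class TestIcosphere:
    @pytest.mark.parametrize("s,expect", [(0, 12), (1, 42), (2, 162),
                                          (4, 2562)])
    def test_vertex_count(self, s, expect):
        assert mg.icosphere(s, 1.0).n_vertices == expect

    @pytest.mark.parametrize("s", [0, 1, 2, 3])
    def test_euler_characteristic(self, s):
        m = mg.icosphere(s, 1.0)
        V, E, F = brute_counts(m)
        assert V - E + F == 2
        m.validate()

    def test_radius(self):
        m = mg.icosphere(3, 2.5)
        r = np.linalg.norm(m.vertices, axis=1)
        assert np.allclose(r, 2.5, atol=1e-12)

    def test_volume_converges_to_sphere(self):
        exact = 4.0 / 3.0 * np.pi
        errs = [abs(mg.enclosed_volume(mg.icosphere(s, 1.0)) - exact)
                for s in (2, 3, 4)]
        assert errs[-1] / exact < 0.005
        assert errs[0] > errs[1] > errs[2]

    def test_guard(self):
        with pytest.raises(ValueError):
            mg.icosphere(8, 1.0)
        with pytest.raises(ValueError):
            mg.icosphere(2, -1.0)


class TestGvCapsule:
    def test_preset_vertex_count(self):
        m = mg.gv_mesh_preset()
        assert m.n_vertices == 1404
        m.validate()

    def test_count_formula(self):
        # rings of equal size n on the cylinder + tapered cone rings + apexes
        n_ring, L, spacing = 12, 4.0, 0.5
        cone = (6, 3)
        m = mg.gv_capsule(1.2, L, n_ring, spacing, cone_ring_sizes=cone)
        n_cyl = int(round(L / spacing)) + 1
        assert m.n_vertices == n_ring * n_cyl + 2 * sum(cone) + 2

    def test_closed_and_oriented(self, gv_small):
        mesh, _ = gv_small
        V, E, F = brute_counts(mesh)
        assert V - E + F == 2
        mesh.validate()

    def test_cylinder_radius(self):
        m = mg.gv_capsule(1.5, 6.0, 16, 0.5, cone_ring_sizes=(8, 4))
        zc = m.vertices[:, 2]
        cyl = np.abs(zc) < 3.0 - 1e-9
        r = np.linalg.norm(m.vertices[cyl, :2], axis=1)
        assert np.allclose(r, 1.5, atol=1e-12)

    def test_staggering(self):
        m = mg.gv_capsule(1.0, 1.0, 8, 1.0, cone_ring_sizes=(4,))
        # two adjacent cylinder rings: phases differ by half angular spacing
        zc = np.unique(np.round(m.vertices[:, 2], 9))
        ring0 = m.vertices[np.abs(m.vertices[:, 2] + 0.5) < 1e-9]
        ring1 = m.vertices[np.abs(m.vertices[:, 2] - 0.5) < 1e-9]
        a0 = np.sort(np.arctan2(ring0[:, 1], ring0[:, 0]))
        a1 = np.sort(np.arctan2(ring1[:, 1], ring1[:, 0]))
        gap = 2 * np.pi / 8
        assert np.allclose((a1 - a0) % gap, gap / 2, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            mg.gv_capsule(-1.0, 2.0, 8, 0.5)
        with pytest.raises(ValueError):
            mg.gv_capsule(1.0, 2.0, 2, 0.5)


class TestRibField:
    def test_unit_and_tangent(self, gv_small):
        mesh, rib = gv_small
        assert np.allclose(np.linalg.norm(rib.m3, axis=1), 1.0, atol=1e-12)
        n = mesh.face_normals(reference=True)
        assert np.abs(np.einsum("ij,ij->i", rib.m3, n)).max() < 1e-10

    def test_cylinder_side_projection(self):
        """On cylinder side faces, m is the in-plane projection of z."""
        m = mg.gv_capsule(1.5, 6.0, 16, 0.5, cone_ring_sizes=(8, 4))
        rib = mg.rib_direction_field(m, [0, 0, 1])
        centroids = m.reference_vertices[m.faces].mean(axis=1)
        cyl = np.abs(centroids[:, 2]) < 2.0
        n = m.face_normals(reference=True)[cyl]
        z = np.array([0.0, 0.0, 1.0])
        expect = z[None] - n * n[:, 2:3]
        expect /= np.linalg.norm(expect, axis=1, keepdims=True)
        dots = np.einsum("ij,ij->i", rib.m3[cyl], expect)
        assert dots.min() > 1 - 1e-10

    def test_face_containing_axis(self):
        # a synthetic flat square split in triangles, normal x: m == z
        verts = np.array([[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1.0],
                          [1, 0.5, 0.5]])
        faces = np.array([[0, 1, 2], [0, 2, 3], [0, 4, 1], [1, 4, 2],
                          [2, 4, 3], [3, 4, 0]])
        m = mg.TriMesh(verts, faces)
        rib = mg.rib_direction_field(m, [0, 0, 1])
        assert np.allclose(np.abs(rib.m3[0]), [0, 0, 1], atol=1e-12)


class TestVolume:
    def test_translation_invariance(self, emb_mesh):
        v0 = mg.enclosed_volume(emb_mesh)
        shifted = emb_mesh.with_vertices(emb_mesh.vertices + [3.0, -1.0, 7.0])
        assert mg.enclosed_volume(shifted) == pytest.approx(v0, rel=1e-12)

    def test_scaling(self, emb_mesh):
        v0 = mg.enclosed_volume(emb_mesh)
        doubled = emb_mesh.with_vertices(emb_mesh.vertices * 2.0)
        assert mg.enclosed_volume(doubled) == pytest.approx(8 * v0, rel=1e-12)


class TestObjRoundTrip:
    def test_vertices_preserved(self, tmp_path, gv_small):
        mesh, _ = gv_small
        path = str(tmp_path / "gv.obj")
        mg.save_obj(mesh, path)
        back = mg.load_obj(path)
        assert back.n_vertices == mesh.n_vertices
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert np.array_equal(back.faces, mesh.faces)
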