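"""Thickness mapping: distances, partitioning, summaries, shape classes."""

import numpy as np
import pytest
import trimesh

from cementum.synthetic import ShapePrimitive, SyntheticSpec, make_root_pair
from cementum.thickness import (
    classify_shape,
    closest_point_distance,
    compute_thickness,
    partition_root,
    summarize,
    third_means,
)


def oracle_min_distance(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Independent all-pairs point-to-triangle minimum distance.

    Plane projection with an inside test, otherwise the minimum over the
    three clamped edge segments — deliberately a different formulation from
    the package's barycentric-region computation.
    """

    def seg_dist(p, a, b):
        ab = b - a
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab),
                    0.0, 1.0)
        return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)

    out = np.empty(len(points))
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    n_unit = n / nn[:, None]
    for i, p in enumerate(points):
        pp = np.broadcast_to(p, a.shape)
        dist_plane = np.einsum("ij,ij->i", pp - a, n_unit)
        proj = pp - dist_plane[:, None] * n_unit
        # inside test via same-side cross products
        s1 = np.einsum("ij,ij->i", np.cross(b - a, proj - a), n_unit)
        s2 = np.einsum("ij,ij->i", np.cross(c - b, proj - b), n_unit)
        s3 = np.einsum("ij,ij->i", np.cross(a - c, proj - c), n_unit)
        inside = (s1 >= -1e-12) & (s2 >= -1e-12) & (s3 >= -1e-12)
        d = np.where(inside, np.abs(dist_plane), np.inf)
        d = np.minimum(d, seg_dist(pp, a, b))
        d = np.minimum(d, seg_dist(pp, b, c))
        d = np.minimum(d, seg_dist(pp, c, a))
        out[i] = d.min()
    return out


class TestDistance:
    def test_matches_brute_force_on_small_mesh(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)  # 320 faces
        assert len(mesh.faces) <= 500
        rng = np.random.default_rng(0)
        points = rng.normal(scale=4.0, size=(200, 3))
        fast = closest_point_distance(mesh, points)
        slow = oracle_min_distance(points, mesh.triangles.view(np.ndarray))
        assert np.allclose(fast, slow, rtol=1e-9, atol=1e-12)

    def test_concentric_spheres_offset(self, sphere_pair):
        inner, outer = sphere_pair
        field = compute_thickness(outer, inner)
        assert abs(field.values_um.mean() - 500.0) < 5.0
        assert np.all(np.abs(field.values_um - 500.0) < 10.0)

    def test_identical_meshes_zero(self, sphere_pair):
        inner, _ = sphere_pair
        with pytest.warns(UserWarning, match="touch or intersect"):
            field = compute_thickness(inner, inner)
        assert np.allclose(field.values_um, 0.0)
        assert field.degenerate

    def test_rigid_motion_invariance(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        rng = np.random.default_rng(1)
        points = rng.normal(scale=4.0, size=(50, 3))
        d0 = closest_point_distance(mesh, points)
        angle = 0.7
        R = trimesh.transformations.rotation_matrix(angle, [1, 2, 3])[:3, :3]
        shift = np.array([2.0, -1.0, 3.0])
        moved = trimesh.Trimesh((mesh.vertices @ R.T) + shift, mesh.faces, process=False)
        d1 = closest_point_distance(moved, (points @ R.T) + shift)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-12)

    def test_synthetic_truth_recovery(self, gradient_analysis):
        field, _, _, truth = gradient_analysis
        assert np.abs(field.values_um - truth).max() < 5.0


class TestPartition:
    def test_axial_thirds(self, uniform_root):
        _, _, cementum, _ = uniform_root
        thirds, _ = partition_root(cementum)
        s = cementum.vertices[:, 2] - cementum.apex_point[2]
        length = cementum.cej_ring_height
        mid = (s > length / 3 + 0.05) & (s < 2 * length / 3 - 0.05)
        assert set(thirds[mid]) == {2}
        apical = s < length / 3 - 0.05
        assert set(thirds[apical]) == {1}

    def test_buccal_reference_side(self, uniform_root):
        _, _, cementum, _ = uniform_root
        _, sides = partition_root(cementum)
        on_ref = cementum.vertices[:, 0] > 0.9 * np.abs(cementum.vertices[:, 1]) + 0.5
        assert set(sides[on_ref]) == {"<"}

    def test_quadrants_roughly_balanced(self, uniform_root):
        _, _, cementum, _ = uniform_root
        _, sides = partition_root(cementum)
        fracs = [np.mean(sides == s) for s in "md<>"]
        assert all(0.2 < f < 0.3 for f in fracs)


class TestSummary:
    def test_uniform_root_not_preferential(self, uniform_root):
        _, dentine, cementum, _ = uniform_root
        field = compute_thickness(cementum, dentine)
        summ = summarize(field, partition_root(cementum))
        assert summ.pref is False
        assert summ.min_side == "No"
        assert summ.max_thi_um == pytest.approx(500.0, abs=5.0)

    def test_gradient_root_preferential_apico_lingual(self, gradient_analysis):
        field, partition, _, _ = gradient_analysis
        summ = summarize(field, partition)
        assert summ.pref is True
        assert (1, ">") in summ.loc_max
        assert summ.min_side == "<"

    def test_quadrant_table_shape(self, gradient_analysis):
        field, partition, _, _ = gradient_analysis
        summ = summarize(field, partition)
        assert list(summ.quadrant_means.index) == ["m", "d", "<", ">"]
        assert list(summ.quadrant_means.columns) == [1, 2, 3]

    def test_third_means_keys(self, gradient_analysis):
        field, partition, _, _ = gradient_analysis
        assert set(third_means(field, partition)) == {1, 2, 3}


def _classified(prim, seed=7, n_theta=64, n_axial=80):
    spec = SyntheticSpec(base_cementum_um=500.0, shape_primitives=(prim,),
                         texture=(100.0, 500.0, 0.0), seed=seed,
                         n_theta=n_theta, n_axial=n_axial)
    dentine, cementum, _ = make_root_pair(spec)
    field = compute_thickness(cementum, dentine)
    partition = partition_root(cementum)
    return classify_shape(field, partition, cementum)


class TestShapeClassification:
    @pytest.mark.parametrize("prim,expected", [
        (ShapePrimitive("NOD", 2, "d", diameter_mm=2.5, height_mm=1.0), "NOD"),
        (ShapePrimitive("Nds", 2, "d", diameter_mm=1.2, height_mm=0.8, count=4), "Nds"),
        (ShapePrimitive("OG", 2, "d", diameter_mm=4.0, height_mm=1.0,
                        angle_offset_deg=45), "OG"),
        (ShapePrimitive("RID", 2, "d", diameter_mm=0.7, height_mm=0.7,
                        length_mm=2.8, count=5), "RID"),
        (ShapePrimitive("LSP", 2, "d", diameter_mm=1.4, height_mm=1.0, count=4), "LSP"),
    ], ids=["node", "nodules", "overgrowth", "ridges", "spike"])
    def test_each_kind_recovered(self, prim, expected):
        assert _classified(prim).kind == expected

    def test_uniform_root_has_no_shape(self, uniform_root):
        _, dentine, cementum, _ = uniform_root
        field = compute_thickness(cementum, dentine)
        shape = classify_shape(field, partition_root(cementum), cementum)
        assert shape.kind == "none" and shape.components == ()

    def test_refinement_invariance(self):
        """The category does not change with mesh resolution."""
        prim = ShapePrimitive("NOD", 2, "d", diameter_mm=2.6, height_mm=1.0)
        coarse = _classified(prim, n_theta=48, n_axial=60)
        fine = _classified(prim, n_theta=80, n_axial=100)
        assert coarse.kind == fine.kind == "NOD"
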