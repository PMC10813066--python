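"""Height-map processing chain and surface-aspect scoring."""

import numpy as np
import pytest

from cementum.synthetic import ASPECT_ARCHETYPES, make_archetype_map, make_height_map
from cementum.topography import (
    AspectScore,
    HeightMap,
    fill_nm,
    level_surface,
    max_vertical_elevation,
    process,
    read_grid,
    remove_form,
    score_aspect,
    write_grid,
)


def _grid(n=96):
    y, x = np.mgrid[0:n, 0:n].astype(float) * 0.65
    return x, y


class TestFillNM:
    def test_no_mask_is_identity(self):
        h = HeightMap(np.arange(24.0).reshape(4, 6))
        out = fill_nm(h)
        assert np.array_equal(out.z, h.z) and out.nm_mask is None

    def test_exact_on_planes(self):
        x, y = _grid()
        plane = 2.0 + 0.3 * x - 0.7 * y
        mask = np.zeros_like(plane, bool)
        mask[40, 50] = mask[10:12, 20] = True
        h = HeightMap(np.where(mask, -999, plane), nm_mask=mask)
        out = fill_nm(h)
        assert np.allclose(out.z, plane, atol=1e-9)

    def test_random_mask_fill_error_small(self):
        truth = make_height_map(300.0, noise_rms_um=1.0, seed=8, shape=(256, 256))
        rng = np.random.default_rng(9)
        mask = rng.random(truth.z.shape) < 0.10
        h = HeightMap(np.where(mask, 0.0, truth.z), nm_mask=mask)
        out = fill_nm(h)
        rms = np.sqrt(np.mean((out.z[mask] - truth.z[mask]) ** 2))
        assert rms < 300.0 / 10

    def test_fully_masked_fails(self):
        h = HeightMap(np.zeros((8, 8)), nm_mask=np.ones((8, 8), bool))
        with pytest.raises(ValueError, match="fully non-measured"):
            fill_nm(h)


class TestFormRemoval:
    def test_tilted_plane_levels_to_zero(self):
        x, y = _grid()
        out = level_surface(HeightMap(5 + 0.4 * x - 0.1 * y))
        assert np.abs(out.z).max() < 1e-8
        assert abs(out.z.mean()) < 1e-10

    def test_paraboloid_removed_exactly(self):
        x, y = _grid()
        para = 0.02 * (x - 20) ** 2 + 0.05 * (y - 31) ** 2 + 0.01 * x * y + x
        out = remove_form(HeightMap(para))
        assert np.abs(out.z).max() < 1e-7

    def test_sinusoid_survives_up_to_its_projection(self):
        x, y = _grid()
        sin = 5 * np.sin(2 * np.pi * x / 8.0)
        para = 0.03 * x**2 - 0.2 * y
        r_both = remove_form(HeightMap(para + sin))
        r_sin = remove_form(HeightMap(sin))
        assert np.allclose(r_both.z, r_sin.z, atol=1e-8)

    def test_idempotent(self):
        h = make_height_map(350.0, seed=4, shape=(128, 128))
        once = remove_form(level_surface(fill_nm(h)))
        twice = remove_form(once)
        assert np.allclose(once.z, twice.z, atol=1e-8)

    def test_chain_invariant_to_degree2_contamination(self):
        base = make_height_map(400.0, seed=13, shape=(128, 128))
        x, y = np.mgrid[0:128, 0:128].astype(float) * 0.65
        rng = np.random.default_rng(3)
        for _ in range(3):
            c = rng.normal(scale=[5, 0.5, 0.5, 0.05, 0.05, 0.05])
            poly = c[0] + c[1] * x + c[2] * y + c[3] * x * x + c[4] * x * y + c[5] * y * y
            contaminated = HeightMap(base.z + poly)
            p0, p1 = process(base), process(contaminated)
            assert np.allclose(p0.z, p1.z, atol=1e-6)
            assert max_vertical_elevation(p1) == pytest.approx(
                max_vertical_elevation(p0), abs=1e-6)

    def test_form_removal_never_raises_amplitude_of_contaminated_input(self):
        base = make_height_map(250.0, seed=14, shape=(128, 128))
        x, y = np.mgrid[0:128, 0:128].astype(float) * 0.65
        contaminated = HeightMap(base.z + 0.1 * (x - 40) ** 2 + 2 * y)
        assert max_vertical_elevation(process(contaminated)) <= max_vertical_elevation(
            contaminated) + 1e-9


class TestMaxVE:
    def test_flat_is_zero(self):
        assert max_vertical_elevation(HeightMap(np.full((16, 16), 3.0))) == 0.0

    def test_single_bump_height(self):
        z = np.zeros((64, 64))
        z[30, 30] = 123.0
        assert max_vertical_elevation(HeightMap(z)) == 123.0

    def test_generator_amplitude_recovered(self):
        h = make_archetype_map("+S2", seed=2, amplitude_um=690.0)
        assert max_vertical_elevation(process(h)) == pytest.approx(690.0, rel=0.05)


class TestAspect:
    def test_flat_scores_low_smooth_sparse(self):
        a = score_aspect(HeightMap(np.zeros((64, 64))))
        assert str(a) == "-S2"

    def test_high_smooth_sparse_nodular_archetype(self):
        h = make_archetype_map("+S2", seed=1, amplitude_um=690.0)
        a = score_aspect(process(h))
        assert str(a) == "+S2"
        assert a.max_ve_um == pytest.approx(690.0, rel=0.05)

    def test_low_smooth_sparse(self):
        a = score_aspect(process(make_archetype_map("-S2", seed=1, amplitude_um=150.0)))
        assert str(a) == "-S2"

    @pytest.mark.parametrize("label", sorted(ASPECT_ARCHETYPES))
    def test_archetypes_score_their_label(self, label):
        hits = sum(
            str(score_aspect(process(make_archetype_map(label, seed=s)))) == label
            for s in range(3)
        )
        assert hits >= 2

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="elevation sign"):
            AspectScore("+", "S", 2, max_ve_um=100.0)


class TestIO:
    @pytest.mark.parametrize("ext", ["csv", "tif"])
    def test_grid_round_trip(self, tmp_path, ext):
        h = make_height_map(200.0, nm_fraction=0.05, seed=6, shape=(64, 64))
        p = tmp_path / f"grid.{ext}"
        write_grid(h, p)
        back = read_grid(p)
        assert np.allclose(back.z[~back.nm_mask], h.z[~h.nm_mask], rtol=1e-5)
        assert np.array_equal(back.nm_mask, h.nm_mask)
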