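"""Atlas-space transforms and surface subregion attribution."""

import numpy as np
import pytest

from amyshape.atlas import (
    SubregionAtlas,
    SurfaceSubregionMap,
    estimate_affine_by_moments,
    invert_affine,
    make_wedge_atlas,
    map_subregions,
    template_subregion_map,
)
from amyshape.radial import RadialShape, make_directions
from amyshape.surface import BinaryVolume
from conftest import rasterize


def sphere_shape(radius=8.0, n=1000):
    return RadialShape(
        subject_id="s", side="left", coi=np.zeros(3),
        radii=np.full(n, radius), alignment=np.eye(4),
    )


def constant_atlas(value_lb=1.0, value_sf=0.0, value_cm=0.0, n=40):
    affine = np.eye(4)
    affine[:3, 3] = -(n - 1) / 2
    return SubregionAtlas(
        probabilities={
            "LB": np.full((n, n, n), value_lb),
            "SF": np.full((n, n, n), value_sf),
            "CM": np.full((n, n, n), value_cm),
        },
        affine=affine,
    )


class TestInvertAffine:
    def test_identity(self):
        assert np.allclose(invert_affine(np.eye(4)), np.eye(4))

    def test_pure_translation(self):
        A = np.eye(4)
        A[:3, 3] = [3.0, -2.0, 5.0]
        inv = invert_affine(A)
        assert np.allclose(inv[:3, 3], [-3.0, 2.0, -5.0])

    def test_random_affine_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = np.eye(4)
            A[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            A[:3, 3] = rng.normal(size=3)
            assert np.allclose(A @ invert_affine(A), np.eye(4), atol=1e-10)

    def test_singular_rejected(self):
        A = np.eye(4)
        A[0, 0] = 0.0
        A[0, 1] = 0.0
        A[1, 0] = 0.0
        A[1, 1] = 0.0
        with pytest.raises(ValueError, match="singular"):
            invert_affine(A)


class TestMomentAffine:
    @staticmethod
    def _blob(scale=1.0, shift=(0.0, 0.0, 0.0), vs=1.0):
        s = np.asarray(shift)
        return rasterize(
            lambda x, y, z: ((x - s[0]) / (9 * scale)) ** 2
            + ((y - s[1]) / (6 * scale)) ** 2
            + ((z - s[2]) / (4 * scale)) ** 2
            <= 1.0,
            16.0,
            vs,
        )

    def test_identical_masks_give_identity(self):
        m = self._blob()
        A = estimate_affine_by_moments(m, m)
        assert np.allclose(A, np.eye(4), atol=1e-6)

    def test_recovers_scale_and_translation(self):
        subject = self._blob(1.0, vs=0.5)
        atlas = self._blob(1.2, shift=(3.0, -2.0, 1.0), vs=0.5)
        A = estimate_affine_by_moments(subject, atlas)
        # map a few subject-surface world points and check they land on the
        # scaled/translated ellipsoid
        scale = np.diag(A[:3, :3])
        assert np.allclose(scale, 1.2, atol=0.02)
        assert np.allclose(A[:3, 3], [3.0, -2.0, 1.0], atol=0.15)

    def test_empty_atlas_rejected(self):
        subject = self._blob()
        empty = BinaryVolume(grid=np.zeros((5, 5, 5), dtype=np.uint8), affine=np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            estimate_affine_by_moments(subject, empty)


class TestMapSubregions:
    def test_uniform_lb_atlas_labels_everything_lb(self):
        m = map_subregions(sphere_shape(), constant_atlas(1.0, 0.0, 0.0))
        assert set(m.labels) == {"LB"}
        assert m.composition == {"LB": 1.0, "SF": 0.0, "CM": 0.0}

    def test_halfspace_split_matches_direction_fractions(self):
        """LB for x<0 and SF for x>=0 on a centred sphere: composition equals
        the sign split of the direction lattice within 2%."""
        n = 40  # even grid: voxel centres at half-integers, boundary at x=0
        affine = np.eye(4)
        affine[:3, 3] = -(n - 1) / 2
        c = np.arange(n) - (n - 1) / 2
        x = c[:, None, None] * np.ones((1, n, n))
        atlas = SubregionAtlas(
            probabilities={
                "LB": (x < 0).astype(float),
                "SF": (x >= 0).astype(float),
                "CM": np.zeros((n, n, n)),
            },
            affine=affine,
        )
        shape = sphere_shape(radius=8.0)
        m = map_subregions(shape, atlas, interpolation="nearest")
        dirs = make_directions(1000).directions
        frac_neg = np.mean(dirs[:, 0] < 0)
        assert m.composition["LB"] == pytest.approx(frac_neg, abs=0.02)
        assert m.composition["SF"] == pytest.approx(1 - frac_neg, abs=0.02)

    def test_all_zero_atlas_warns_and_reports_empty(self):
        with pytest.warns(UserWarning, match="no surface point"):
            m = map_subregions(sphere_shape(), constant_atlas(0.0, 0.0, 0.0))
        assert set(m.labels) == {"none"}
        assert m.composition == {}

    def test_constant_volume_interpolates_exactly(self):
        m = map_subregions(sphere_shape(), constant_atlas(0.37, 0.21, 0.11))
        assert np.allclose(m.probabilities[:, 0], 0.37, atol=1e-12)
        assert np.allclose(m.probabilities[:, 1], 0.21, atol=1e-12)

    def test_points_outside_atlas_get_zero(self):
        m = map_subregions(sphere_shape(radius=50.0), constant_atlas(1.0), )
        assert m.n_outside > 0

    def test_probabilities_stay_in_unit_interval(self):
        atlas = make_wedge_atlas()
        m = map_subregions(sphere_shape(radius=12.0), atlas)
        assert np.all(m.probabilities >= 0.0)
        assert np.all(m.probabilities <= 1.0)

    def test_composition_sums_to_one_over_labeled(self):
        m = map_subregions(sphere_shape(radius=10.0), make_wedge_atlas())
        assert sum(m.composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_lb_precedence_on_exact_tie(self):
        m = map_subregions(sphere_shape(), constant_atlas(0.5, 0.5, 0.0))
        assert set(m.labels) == {"LB"}


class TestTemplateMap:
    def test_identical_maps_unchanged(self):
        m = map_subregions(sphere_shape(), make_wedge_atlas())
        tm = template_subregion_map([m, m, m])
        assert np.allclose(tm.probabilities, m.probabilities)
        assert list(tm.labels) == list(m.labels)

    def test_two_point_probabilities_average(self):
        a = map_subregions(sphere_shape(), constant_atlas(0.2, 0.0, 0.0))
        b = map_subregions(sphere_shape(), constant_atlas(0.8, 0.0, 0.0))
        tm = template_subregion_map([a, b])
        assert np.allclose(tm.probabilities[:, 0], 0.5, atol=1e-12)

    def test_mean_equals_bruteforce_average(self):
        rng = np.random.default_rng(5)
        maps = []
        for _ in range(4):
            p = rng.random((100, 3)) / 3
            maps.append(
                SurfaceSubregionMap(
                    probabilities=p,
                    labels=np.full(100, "LB"),
                    composition={"LB": 1.0, "SF": 0.0, "CM": 0.0},
                )
            )
        tm = template_subregion_map(maps)
        expected = sum(m.probabilities for m in maps) / 4
        assert np.allclose(tm.probabilities, expected, atol=1e-12)

    def test_mismatched_point_counts_rejected(self):
        a = map_subregions(sphere_shape(n=1000), constant_atlas())
        b = map_subregions(sphere_shape(n=500), constant_atlas())
        with pytest.raises(ValueError, match="point counts"):
            template_subregion_map([a, b])
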