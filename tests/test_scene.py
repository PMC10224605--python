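"""Simulator contracts: scene structure, illumination, camera, SPAD, GSD."""

import math

import numpy as np
import pytest

from leaflux.scene import (
    CANOPY,
    PANEL_LABEL_BASE,
    SOIL,
    CameraModel,
    Layout,
    PlacementError,
    RenderError,
    ReflectanceScene,
    gsd,
    make_illumination,
    make_scene,
    make_spad,
    render,
)


class TestMakeScene:
    def test_requested_object_counts(self, small_layout):
        scene = make_scene(12, small_layout, seed=7)
        assert scene.n_plants == 12
        assert set(np.unique(scene.plant_id)) == set(range(13))
        assert len(scene.panels.nominal_reflectance) == 4

    def test_same_seed_identical(self, small_layout):
        a = make_scene(6, small_layout, seed=3)
        b = make_scene(6, small_layout, seed=3)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)
        np.testing.assert_array_equal(a.plant_id, b.plant_id)
        assert a.chlorophyll == b.chlorophyll

    def test_chlorophyll_darkens_red_canopy(self, small_scene):
        """Higher-chlorophyll plants must have lower mean red reflectance."""
        means = {
            p: small_scene.reflectance[small_scene.plant_id == p, 0].mean()
            for p in small_scene.chlorophyll
        }
        chl = small_scene.chlorophyll
        ranked = sorted(chl, key=chl.get)
        reds = [means[p] for p in ranked]
        assert all(a > b for a, b in zip(reds, reds[1:]))

    def test_panels_grey_and_constant(self, small_scene):
        for k, ((r0, c0, r1, c1), rho) in enumerate(
            zip(small_scene.panels.footprints, small_scene.panels.nominal_reflectance)
        ):
            patch = small_scene.reflectance[r0:r1, c0:c1, :]
            assert np.all(patch == rho)
            assert np.all(small_scene.labels[r0:r1, c0:c1] == PANEL_LABEL_BASE + k)

    def test_reflectance_bounds_and_labels(self, small_scene):
        assert np.all(np.isfinite(small_scene.reflectance))
        assert small_scene.reflectance.min() >= 0.0
        assert small_scene.reflectance.max() <= 100.0
        assert set(np.unique(small_scene.labels)) >= {SOIL, CANOPY}
        # every plant id present in the map has a chlorophyll entry
        for p in np.unique(small_scene.plant_id):
            if p:
                assert p in small_scene.chlorophyll

    def test_placement_error_when_too_small(self):
        layout = Layout(height=40, width=40, panel_size_px=12, margin_px=6)
        with pytest.raises(PlacementError):
            make_scene(12, layout, seed=0)

    def test_rejects_zero_plants(self, small_layout):
        with pytest.raises(ValueError):
            make_scene(0, small_layout)


class TestIllumination:
    def test_sunny_uniform(self):
        f = make_illumination("sunny", (64, 64), seed=5)
        assert np.all(f.spatial_field == 1.0)
        assert f.spectral_field is None

    def test_variable_field_range_and_smoothness(self):
        f = make_illumination("variable", (256, 256), seed=3)
        assert f.spatial_field.min() >= 0.2
        assert f.spatial_field.max() <= 1.0
        # smoothness: adjacent-pixel increments are tiny relative to range
        grad = np.abs(np.diff(f.spatial_field, axis=0)).max()
        assert grad < 0.05

    def test_overcast_blue_shifted(self):
        sunny = make_illumination("sunny", (32, 32))
        over = make_illumination("overcast", (32, 32))
        ratio_sunny = sunny.spectral_gain[2] / sunny.spectral_gain[0]
        ratio_over = over.spectral_gain[2] / over.spectral_gain[0]
        assert ratio_over > ratio_sunny
        assert np.all(over.spatial_field == 1.0)

    def test_variable_shadow_tint_blue_shift(self):
        f = make_illumination("variable", (128, 128), seed=1)
        depth = 1.0 - f.spatial_field
        deepest = np.unravel_index(np.argmax(depth), depth.shape)
        px = f.spectral_field[deepest]
        assert px[2] > px[0]  # shadowed pixel is blue-shifted

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            make_illumination("dawn", (32, 32))


class TestCameraAndRender:
    def test_bright_panel_saturates(self, small_scene, camera):
        """The 84.5% panel at unit gain exceeds the 8-bit range: the exact
        inverse response gives round(ln(84.5/1.35)/0.016) = 259, clipped."""
        expected_unclipped = round(math.log(84.5 / 1.35) / 0.016)
        assert expected_unclipped == 259
        illum = make_illumination("sunny", small_scene.shape)
        img = render(small_scene, illum, camera)
        r0, c0, r1, c1 = small_scene.panels.footprints[-1]
        assert np.all(img[r0:r1, c0:c1, 0] == 255)

    def test_uniform_scene_constant_image(self, camera):
        scene = _uniform_scene(32, 15.0)
        illum = make_illumination("sunny", (32, 32))
        img = render(scene, illum, camera)
        for c in range(3):
            assert np.unique(img[..., c]).size == 1

    def test_render_deterministic(self, small_scene, camera):
        illum = make_illumination("variable", small_scene.shape, seed=9)
        a = render(small_scene, illum, camera)
        b = render(small_scene, illum, camera)
        np.testing.assert_array_equal(a, b)

    def test_forward_inverse_within_one_dn(self, camera):
        """Unclipped round trip is accurate to a single quantization step."""
        rng = np.random.default_rng(0)
        e = rng.uniform(2.0, 40.0, size=(200, 3))
        dn = camera.forward(e)
        back = camera.inverse(dn)
        step = e * np.asarray(camera.b)  # radiance change of 1 DN
        assert np.all(np.abs(back - e) <= step)

    def test_monotone_response(self, camera):
        e = np.linspace(2, 60, 100)[:, None] * np.ones(3)
        dn = camera.forward(e).astype(int)
        assert np.all(np.diff(dn, axis=0) >= 0)

    def test_nonpositive_radiance_rejected(self, camera):
        with pytest.raises(RenderError):
            camera.forward(np.array([[0.0, 1.0, 1.0]]))


def _uniform_scene(side: int, rho: float) -> ReflectanceScene:
    from leaflux.scene import PanelSpec

    return ReflectanceScene(
        reflectance=np.full((side, side, 3), rho),
        labels=np.zeros((side, side), dtype=np.int32),
        plant_id=np.zeros((side, side), dtype=np.int32),
        chlorophyll={},
        plant_centers={},
        panels=PanelSpec((20.0,), ((0, 0, 1, 1),)),
        gsd_m=0.0068,
        seed=0,
    )


def _population_scene(n: int, seed: int) -> ReflectanceScene:
    """Scene stub with a large chlorophyll population for SPAD moments."""
    rng = np.random.default_rng(seed)
    scene = _uniform_scene(8, 15.0)
    scene.chlorophyll = {i + 1: float(v) for i, v in enumerate(rng.normal(50, 5, n))}
    return scene


class TestSpad:
    def test_zero_noise_perfectly_correlated(self):
        scene = _population_scene(50, seed=2)
        spad = make_spad(scene, noise_sd=0.0, seed=0)
        chl = [scene.chlorophyll[s.plant_id] for s in spad]
        vals = [s.spad for s in spad]
        assert abs(np.corrcoef(chl, vals)[0, 1]) == pytest.approx(1.0)

    def test_population_moments(self):
        """A large simulated stand reproduces the calibration targets:
        mean about 47.25 and std about 3.0 SPAD units."""
        scene = _population_scene(1000, seed=1)
        spad = np.array([s.spad for s in make_spad(scene, seed=2)])
        assert 46.0 <= spad.mean() <= 48.5
        assert 2.5 <= spad.std(ddof=1) <= 3.5

    def test_deterministic(self):
        scene = _population_scene(20, seed=3)
        a = make_spad(scene, seed=5)
        b = make_spad(scene, seed=5)
        assert [s.spad for s in a] == [s.spad for s in b]

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_spad(_population_scene(5, 0), noise_sd=-1.0)


class TestGsd:
    def test_survey_altitudes(self):
        """A 1-inch sensor at 100 m gives ~2.7 cm/px, at 25 m ~0.68 cm/px."""
        high = gsd(100, 13.2, 8.8, 5472)
        low = gsd(25, 13.2, 8.8, 5472)
        assert abs(high - 2.7) < 0.05
        assert abs(low - 0.68) < 0.01

    def test_linear_in_altitude(self):
        assert gsd(50, 13.2, 8.8, 5472) == pytest.approx(gsd(100, 13.2, 8.8, 5472) / 2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gsd(0, 13.2, 8.8, 5472)
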