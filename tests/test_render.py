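"""Renderer: exposure model, fast-mode physics, Monte-Carlo consistency."""

import math

import numpy as np
import pytest

from sfdi_forge.optics import OpticalProperties, diffuse_reflectance_fx
from sfdi_forge.phantoms import TISSUES, make_flat_scene, make_scc_scene
from sfdi_forge.render import (
    Camera,
    ExposedImage,
    FringePattern,
    Projector,
    Scene,
    exposure_correct,
    illumination_gain,
    render,
    render_phase_stack,
)
from sfdi_forge.sfdi import demodulate
from sfdi_forge.transport import TransportConfig


class TestFringePattern:
    def test_values_bounded_and_three_phases_cancel(self):
        y = np.linspace(0, 50, 500)
        pats = [
            FringePattern(fx=0.2, phase=p)
            for p in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
        ]
        vals = np.stack([p.value(y) for p in pats])
        assert np.all((vals >= 0) & (vals <= 1))
        # three equispaced sinusoids sum to 3x the DC level
        assert np.allclose(vals.sum(axis=0), 1.5, atol=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            FringePattern(fx=-0.1)
        with pytest.raises(ValueError):
            FringePattern(fx=0.1, orientation="z")
        with pytest.raises(ValueError):
            FringePattern(fx=0.1, amplitude=0.8, offset=0.5)


class TestExposure:
    @pytest.mark.parametrize("t, factor", [(0.0, 1.0), (1.0, 2.0), (-1.0, 0.5)])
    def test_correction_multiplies_by_power_of_two(self, t, factor):
        img = ExposedImage(pixels=np.ones((4, 4)), t_exposure=t)
        assert np.allclose(exposure_correct(img), factor)

    def test_missing_metadata_is_an_error(self):
        img = ExposedImage(pixels=np.ones((4, 4)), t_exposure=None)
        with pytest.raises(ValueError, match="exposure"):
            exposure_correct(img)

    def test_render_round_trips_physical_units(self, healthy):
        scene = make_flat_scene(healthy, resolution=(64, 64))
        a = exposure_correct(render(scene, FringePattern(fx=0.1), exposure="auto"))
        b = exposure_correct(render(scene, FringePattern(fx=0.1), exposure=2.0))
        assert np.allclose(a, b, rtol=1e-12)


class TestFastMode:
    def test_flat_field_uniform_after_vignetting_correction(self, healthy):
        scene = make_flat_scene(healthy, resolution=(128, 128))
        img = exposure_correct(
            render(scene, FringePattern(fx=0.0, amplitude=0.0, offset=1.0))
        )
        # oracle: the projector's inverse-square x cosine field
        xc, yc = scene.camera.reference_grid()
        px, py, pz = scene.projector.position
        r2 = (px - xc) ** 2 + (py - yc) ** 2 + pz**2
        vignette = pz / np.sqrt(r2) / r2
        flat = img / vignette
        assert np.ptp(flat) / flat.mean() < 0.02

    def test_demodulated_ratio_matches_model(self, healthy):
        scene = make_flat_scene(healthy, resolution=(128, 128))
        ac, dc = demodulate(render_phase_stack(scene, 0.2))
        expected = diffuse_reflectance_fx(healthy, 0.2) / diffuse_reflectance_fx(healthy, 0.0)
        assert np.median(ac / dc) == pytest.approx(expected, rel=0.03)

    def test_linear_in_projector_power(self, healthy):
        scene = make_flat_scene(healthy, resolution=(32, 32))
        a = exposure_correct(render(scene, FringePattern(fx=0.1)))
        scene.projector = Projector(position=scene.projector.position, power=10.0)
        b = exposure_correct(render(scene, FringePattern(fx=0.1)))
        assert np.allclose(b, 2 * a, rtol=1e-12)

    def test_shadowed_pixels_are_dark_not_errors(self, healthy):
        scene = make_flat_scene(healthy, resolution=(64, 64))
        # a 60 mm cliff with the projector far to its right casts a
        # ~48 mm shadow onto the plain left of the cliff base
        scene.height[:, 40:] = 60.0
        scene.projector = Projector(position=(400.0, 0.0, 500.0))
        img = exposure_correct(
            render(scene, FringePattern(fx=0.0, amplitude=0.0, offset=1.0))
        )
        assert img[32, 36] < 0.05 * img[32, 5]

    def test_camera_angle_offset_barely_moves_calibrated_ratio(self, healthy):
        ratios = {}
        for ang in (4.0, 20.0):
            scene = make_flat_scene(healthy, resolution=(64, 64))
            offset = 500.0 * math.tan(math.radians(ang))
            scene.projector = Projector(position=(offset, 0.0, 500.0))
            ac, dc = demodulate(render_phase_stack(scene, 0.2))
            ratios[ang] = np.median(ac / dc)
        change = abs(ratios[20.0] - ratios[4.0]) / ratios[4.0]
        assert change < 0.10

    def test_specular_lobe_optional(self, healthy):
        scene = make_flat_scene(healthy, resolution=(32, 32))
        base = exposure_correct(render(scene, FringePattern(fx=0.1)))
        scene.specular = {"ks": 0.2, "shininess": 10}
        spec = exposure_correct(render(scene, FringePattern(fx=0.1)))
        assert spec.sum() > base.sum()


class TestStack:
    def test_non_equispaced_phases_rejected(self, healthy):
        scene = make_flat_scene(healthy, resolution=(16, 16))
        with pytest.raises(ValueError, match="equispaced"):
            render_phase_stack(scene, 0.2, phases=(0.0, 1.0, 2.5))
        with pytest.raises(ValueError, match="3 phases"):
            render_phase_stack(scene, 0.2, phases=(0.0, 2.0))

    def test_spheroid_stack_registered_across_phases(self):
        scene = make_scc_scene(resolution=(64, 64))
        stack = render_phase_stack(scene, 0.2)
        # the spheroid's DC footprint (brightness structure) must sit at
        # the same pixels in all three phases: the per-pixel mean over
        # phases is smooth while individual images carry fringes
        dc = stack.images.mean(axis=0)
        assert np.isfinite(dc).all()
        assert stack.images.shape == (3, 64, 64)

    def test_seeded_mc_stack_bit_reproducible(self, healthy):
        scene = make_flat_scene(healthy, resolution=(24, 24))
        cfg = TransportConfig(n_photons=5000, seed=123)
        a = render_phase_stack(scene, 0.1, mode="mc", cfg=cfg)
        b = render_phase_stack(scene, 0.1, mode="mc", cfg=cfg)
        assert np.array_equal(a.images, b.images)


class TestMonteCarloMode:
    def test_matches_fast_mode_on_homogeneous_plane(self, healthy):
        scene = make_flat_scene(healthy, resolution=(64, 64), extent=(60.0, 60.0))
        pat = FringePattern(fx=0.0, amplitude=0.0, offset=1.0)
        fast = exposure_correct(render(scene, pat))
        mc = exposure_correct(
            render(scene, pat, mode="mc", cfg=TransportConfig(n_photons=300_000, seed=9))
        )
        # interior pixels (edges lose photons that random-walk out of frame)
        sel = np.s_[16:-16, 16:-16]
        ratio = mc[sel].mean() / fast[sel].mean()
        # cross-model agreement: MC transport vs diffusion closed form
        assert ratio == pytest.approx(1.0, abs=0.10)

    def test_heterogeneous_scene_rejected(self):
        scene = make_scc_scene(resolution=(64, 64))
        with pytest.raises(ValueError, match="homogeneous planar"):
            render(scene, FringePattern(fx=0.1), mode="mc", cfg=TransportConfig(n_photons=100))


class TestIlluminationGain:
    def test_flat_surface_has_unit_gain(self):
        cam = Camera(resolution=(32, 32))
        gain = illumination_gain(np.zeros((32, 32)), cam, Projector())
        assert np.allclose(gain, 1.0, atol=1e-9)

    def test_raised_plate_gain_is_inverse_square(self):
        cam = Camera(resolution=(64, 64))
        proj = Projector(position=(0.0, 0.0, 500.0))
        gain = illumination_gain(np.full((64, 64), 50.0), cam, proj)
        # central pixel: pure inverse-square, (500/450)^2
        assert gain[32, 32] == pytest.approx((500.0 / 450.0) ** 2, rel=1e-3)
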