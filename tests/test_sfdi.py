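"""Demodulation, calibration and look-up-table inversion."""

import math

import numpy as np
import pytest

from sfdi_forge.optics import OpticalProperties, diffuse_reflectance_fx
from sfdi_forge.phantoms import TISSUES, make_flat_scene, make_reference_scene
from sfdi_forge.render import render_phase_stack
from sfdi_forge.sfdi import (
    ImageStack,
    LookupTable,
    build_empirical_lut,
    build_model_lut,
    calibrate,
    demodulate,
    invert_lut,
    recover_maps,
)
from sfdi_forge.transport import TransportConfig

PHASES = (0.0, 2 * math.pi / 3, 4 * math.pi / 3)


def _synthetic_stack(a=0.3, b=1.0, fx=0.1, shape=(32, 48)):
    y = np.arange(shape[0])[:, None] * np.ones(shape)[None, 0]
    yy = np.broadcast_to(np.arange(shape[0])[:, None], shape).astype(float)
    images = np.stack(
        [b + a * np.sin(2 * math.pi * fx * yy + p) for p in PHASES]
    )
    return ImageStack(images=images, fx=fx)


class TestDemodulate:
    def test_constant_stack_is_pure_dc(self):
        stack = ImageStack(images=np.full((3, 8, 8), 2.5), fx=0.1)
        ac, dc = demodulate(stack)
        assert np.allclose(ac, 0.0, atol=1e-12)
        assert np.allclose(dc, 2.5)

    def test_exact_on_analytic_sinusoid(self):
        ac, dc = demodulate(_synthetic_stack(a=0.3, b=1.0))
        assert np.allclose(ac, 0.3, atol=1e-12)
        assert np.allclose(dc, 1.0, atol=1e-12)

    def test_equals_complex_estimator(self):
        stack = _synthetic_stack(a=0.2, b=0.7)
        ac, dc = demodulate(stack)
        s = np.tensordot(np.exp(-1j * np.asarray(PHASES)), stack.images, axes=(0, 0))
        assert np.allclose(ac, 2 * np.abs(s) / 3, atol=1e-12)

    def test_stack_validation(self):
        with pytest.raises(ValueError):
            ImageStack(images=np.zeros((2, 4, 4)), fx=0.1)
        with pytest.raises(ValueError):
            ImageStack(images=np.zeros((3, 4, 4)), fx=0.1, phases=(0.0, 1.0, 2.0))


class TestCalibrate:
    def test_self_calibration_returns_model_values(self, reference):
        mod = (np.full((8, 8), 0.2), np.full((8, 8), 0.5))
        rd_dc, rd_ac, bad = calibrate(mod, mod, reference, 0.2)
        assert np.allclose(rd_dc, diffuse_reflectance_fx(reference, 0.0))
        assert np.allclose(rd_ac, diffuse_reflectance_fx(reference, 0.2))
        assert not bad.any()

    def test_common_gain_cancels(self, reference):
        s = (np.full((4, 4), 0.1), np.full((4, 4), 0.4))
        r = (np.full((4, 4), 0.2), np.full((4, 4), 0.5))
        a1 = calibrate(s, r, reference, 0.2)[0]
        a2 = calibrate(
            (s[0] * 7.0, s[1] * 7.0), (r[0] * 7.0, r[1] * 7.0), reference, 0.2
        )[0]
        assert np.allclose(a1, a2)

    def test_zero_reference_pixels_masked(self, reference):
        r_dc = np.full((4, 4), 0.5)
        r_dc[0, 0] = 0.0
        _, _, bad = calibrate(
            (np.ones((4, 4)), np.ones((4, 4))), (np.ones((4, 4)), r_dc), reference, 0.2
        )
        assert bad[0, 0] and bad.sum() == 1

    def test_closed_loop_through_renderer(self, healthy, reference):
        sample = render_phase_stack(make_flat_scene(healthy, resolution=(64, 64)), 0.2)
        ref = render_phase_stack(make_reference_scene(resolution=(64, 64)), 0.2)
        s_ac, s_dc = demodulate(sample)
        r_ac, r_dc = demodulate(ref)
        rd_dc, rd_ac, _ = calibrate((s_ac, s_dc), (r_ac, r_dc), reference, 0.2)
        assert np.nanmedian(rd_dc) == pytest.approx(
            diffuse_reflectance_fx(healthy, 0.0), rel=0.03
        )
        assert np.nanmedian(rd_ac) == pytest.approx(
            diffuse_reflectance_fx(healthy, 0.2), rel=0.03
        )


class TestModelLut:
    def test_nodes_query_back_exactly(self, model_lut):
        k = 317
        mu_a, mu_sp, oob = model_lut.query(model_lut.dc[k], model_lut.ac[k])
        assert mu_a == pytest.approx(model_lut.mu_a[k], rel=1e-6)
        assert mu_sp == pytest.approx(model_lut.mu_s_prime[k], rel=1e-6)
        assert not oob

    def test_dc_monotone_in_mu_a_along_rows(self):
        lut = build_model_lut(0.2, shape=(30, 30))
        dc = lut.dc.reshape(30, 30)
        assert np.all(np.diff(dc, axis=0) < 0)

    def test_far_out_of_hull_uses_nearest_and_flags(self, model_lut):
        mu_a, mu_sp, oob = model_lut.query(5.0, 5.0)
        assert oob
        assert np.isfinite(mu_a) and np.isfinite(mu_sp)

    def test_empty_lut_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            LookupTable(dc=[], ac=[], mu_a=[], mu_s_prime=[])

    def test_mc_forward_lut_close_to_diffusion_lut(self):
        # cross-model bound at interior nodes: properties recovered by
        # inverting MC-forward reflectance with the diffusion LUT differ
        # by a bounded, documented amount
        mc_lut = build_model_lut(
            0.2,
            mu_a_range=(0.02, 0.2),
            mu_sp_range=(0.8, 5.0),
            shape=(4, 4),
            forward="mc",
            cfg=TransportConfig(n_photons=30_000, seed=77),
        )
        diff_lut = build_model_lut(0.2)
        rel = []
        for k in range(len(mc_lut.dc)):
            mu_a, mu_sp, oob = diff_lut.query(mc_lut.dc[k], mc_lut.ac[k])
            if oob:
                continue
            rel.append(abs(mu_sp - mc_lut.mu_s_prime[k]) / mc_lut.mu_s_prime[k])
        assert rel and np.median(rel) <= 0.20


class TestEmpiricalLut:
    @pytest.fixture(scope="class")
    def calibration(self):
        cal = []
        for mu_a in (0.08, 0.15, 0.22):
            for mu_sp in (1.4, 3.95, 6.5):
                p = OpticalProperties.from_reduced(mu_a, mu_sp)
                cal.append(
                    (
                        (
                            diffuse_reflectance_fx(p, 0.0),
                            diffuse_reflectance_fx(p, 0.2),
                        ),
                        p,
                    )
                )
        return cal

    def test_grid_is_100_by_100(self, calibration):
        lut = build_empirical_lut(calibration, fx=0.2)
        assert lut.meta["grid_shape"] == (100, 100)
        assert len(lut.dc) == 10_000

    def test_reproduces_calibration_points(self, calibration):
        lut = build_empirical_lut(calibration, fx=0.2)
        for (dc, ac), p in calibration:
            mu_a, mu_sp, _ = lut.query(dc, ac)
            assert mu_a == pytest.approx(p.mu_a, rel=1e-3)
            assert mu_sp == pytest.approx(p.mu_s_prime, rel=1e-3)

    def test_collinear_points_rejected(self):
        cal = []
        for i, mu_a in enumerate((0.08, 0.15, 0.22)):
            for j, mu_sp in enumerate((1.4, 3.95, 6.5)):
                p = OpticalProperties.from_reduced(mu_a, mu_sp)
                cal.append(((float(i + j), 2.0 * (i + j)), p))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            build_empirical_lut(cal)

    def test_non_lattice_points_rejected(self):
        p = OpticalProperties.from_reduced(0.1, 1.0)
        with pytest.raises(ValueError, match="lattice"):
            build_empirical_lut([((0.1, 0.2), p)] * 9)


class TestInvertAndRecover:
    def test_round_trip_interior_pairs(self, rng):
        cal = []
        for mu_a in (0.08, 0.15, 0.22):
            for mu_sp in (1.4, 3.95, 6.5):
                p = OpticalProperties.from_reduced(mu_a, mu_sp)
                cal.append(
                    ((diffuse_reflectance_fx(p, 0.0), diffuse_reflectance_fx(p, 0.2)), p)
                )
        lut = build_empirical_lut(cal, fx=0.2)
        # 50 random property pairs drawn near the calibration lattice
        base = np.array([(p.mu_a, p.mu_s_prime) for _, p in cal])
        picks = base[rng.integers(0, len(base), 50)]
        jitter = 1 + 0.01 * rng.standard_normal((50, 2))
        picks = picks * jitter
        errs = []
        for mu_a, mu_sp in picks:
            dc = diffuse_reflectance_fx(None, 0.0, mu_a=mu_a, mu_s_prime=mu_sp)
            ac = diffuse_reflectance_fx(None, 0.2, mu_a=mu_a, mu_s_prime=mu_sp)
            maps = invert_lut(np.array([dc]), np.array([ac]), lut)
            errs.append(
                (
                    abs(maps.mu_a[0] - mu_a) / mu_a,
                    abs(maps.mu_s_prime[0] - mu_sp) / mu_sp,
                )
            )
        assert np.max(errs) < 0.02

    def test_sample_equals_reference_recovers_reference(self, model_lut, reference):
        ref = render_phase_stack(make_reference_scene(resolution=(48, 48)), 0.2)
        maps = recover_maps(ref, ref, reference, model_lut)
        assert np.nanmedian(maps.mu_a) == pytest.approx(reference.mu_a, rel=0.02)
        assert np.nanmedian(maps.mu_s_prime) == pytest.approx(
            reference.mu_s_prime, rel=0.02
        )

    def test_model_lut_requires_reference(self, model_lut):
        stack = render_phase_stack(
            make_flat_scene(TISSUES["healthy"], resolution=(16, 16)), 0.2
        )
        with pytest.raises(ValueError, match="reference"):
            recover_maps(stack, None, None, model_lut)

    def test_lut_hdf5_round_trip(self, model_lut, tmp_path):
        path = tmp_path / "lut.h5"
        model_lut.save(path)
        back = LookupTable.load(path)
        assert np.allclose(back.dc, model_lut.dc)
        assert back.kind == model_lut.kind
        assert back.interpolation == model_lut.interpolation
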