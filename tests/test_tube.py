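"""Tubular-lumen illumination: pre-distortion, sectioning, sectioned LUTs."""

import math

import numpy as np
import pytest
from scipy.ndimage import uniform_filter1d

from sfdi_forge.optics import OpticalProperties
from sfdi_forge.phantoms import TISSUES, make_calibration_set
from sfdi_forge.profilometry import phase_from_three
from sfdi_forge.sfdi import demodulate
from sfdi_forge.tube import (
    SectionedLUT,
    TubeGeometry,
    TubeScene,
    build_sectioned_luts,
    make_tube_scene,
    normalize_0_255,
    predistort,
    recover_tube_maps,
    render_tube_wall_stack,
    section_by_intensity,
)

FXW = 0.1


@pytest.fixture(scope="module")
def tube():
    return TubeGeometry()


@pytest.fixture(scope="module")
def sectioned(tube):
    """Sectioned + global empirical LUTs from the nine calibration tubes."""
    cal = make_calibration_set(9)
    slut, glut = build_sectioned_luts(cal, FXW, tube, resolution=1024)
    return slut, glut


class TestGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            TubeGeometry(inner_diameter=90.0)
        with pytest.raises(ValueError):
            TubeGeometry(length=-1.0)


class TestPredistort:
    def test_zero_frequency_degenerates_to_smooth_dc(self, tube):
        pat = predistort(tube, 0.0)
        assert np.allclose(pat, 0.5)

    def test_three_phase_offsets_are_120_degrees_apart(self, tube):
        # compare wall-point values: sin arguments must differ by 2 pi/3
        z = np.linspace(5, 245, 50)
        vals = [
            0.5 + 0.5 * np.sin(2 * math.pi * FXW * z + p)
            for p in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
        ]
        assert np.allclose(np.sum(vals, axis=0), 1.5, atol=1e-12)
        pats = [predistort(tube, FXW, phase=p) for p in (0.0, 2 * math.pi / 3)]
        assert not np.allclose(pats[0], pats[1])

    def test_nyquist_violation_reports_admissible_frequency(self, tube):
        with pytest.raises(ValueError, match="admissible"):
            predistort(tube, 5.0, n_px=128)

    def test_realised_wall_frequency_uniform_vs_naive(self, tube):
        # render + per-column phase-slope measurement of the projected
        # frequency along the wall, smoothed over one fringe period
        scene = make_tube_scene()
        n_z = 500
        dz = tube.length / n_z
        win = max(int(round(1.0 / FXW / dz)), 1)
        sel = slice(n_z // 10, 9 * n_z // 10)  # central 80%

        stack = render_tube_wall_stack(
            scene, FXW, pattern_mode="predistorted", resolution=1024, n_z=n_z, n_az=4
        )
        phase = np.unwrap(phase_from_three(stack).phase[:, 0])
        f_loc = uniform_filter1d(np.abs(np.gradient(phase, dz)) / (2 * math.pi), win)
        assert np.all(np.abs(f_loc[sel] - FXW) / FXW < 0.05)

        naive = render_tube_wall_stack(
            scene, FXW, pattern_mode="naive", resolution=1024, n_z=n_z, n_az=4
        )
        phase_n = np.unwrap(phase_from_three(naive).phase[:, 0])
        f_n = uniform_filter1d(np.abs(np.gradient(phase_n, dz)) / (2 * math.pi), win)
        assert f_n[sel].max() / max(f_n[sel].min(), 1e-9) > 2.0


class TestNormalize:
    def test_affine_rescale_to_full_range(self):
        u8, (lo, hi) = normalize_0_255(np.linspace(0.2, 0.6, 100))
        assert u8.min() == 0 and u8.max() == 255
        assert (lo, hi) == (0.2, 0.6)

    def test_unit_range_maps_to_255(self):
        u8, _ = normalize_0_255(np.array([0.0, 0.5, 1.0]))
        assert list(u8) == [0, 128, 255]

    def test_quantisation_error_bounded(self, rng):
        x = rng.random(1000)
        u8, (lo, hi) = normalize_0_255(x)
        back = lo + u8.astype(float) / 255.0 * (hi - lo)
        assert np.abs(back - x).max() <= 0.5 / 255.0 * (hi - lo) + 1e-12

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_0_255(np.full((4, 4), 0.3))


class TestSectioning:
    def test_uniform_image_is_single_section(self, tube):
        with pytest.warns(UserWarning, match="single section"):
            edges = section_by_intensity(np.full((120, 90), 7.0), tube)
        assert len(edges) == 2

    def test_default_tube_yields_five_sections(self, tube):
        scene = make_tube_scene()
        stack = render_tube_wall_stack(scene, FXW, resolution=1024)
        dc = demodulate(stack)[1]
        edges = section_by_intensity(dc, tube)
        assert len(edges) - 1 == 5

    def test_staircase_with_four_steps_splits_at_the_steps(self, tube):
        # four >10-count steps between five flat levels
        levels = np.array([200.0, 150.0, 110.0, 80.0, 55.0])
        profile = np.repeat(levels, 24)  # 120 rings -> 10 candidate rings
        edges = section_by_intensity(profile, tube)
        assert len(edges) - 1 == 5
        assert np.allclose(edges[:5], [0.0, 50.0, 100.0, 150.0, 200.0])


class TestSectionedRecovery:
    def test_five_section_luts_built(self, sectioned):
        slut, _ = sectioned
        assert slut.n_sections == 5
        assert all(len(lut.dc) == 10_000 for lut in slut.luts)

    def test_homogeneous_wall_recovery_beats_global(self, tube, sectioned):
        slut, glut = sectioned
        gslut = SectionedLUT(boundaries=np.array([0.0, tube.length]), luts=[glut])
        n_z = 120
        z = np.linspace(0, tube.length, n_z, endpoint=False) + tube.length / (2 * n_z)
        errs = {}
        for props in (TISSUES["tube_wall"], OpticalProperties.from_reduced(0.15, 3.95)):
            stack = render_tube_wall_stack(
                TubeScene(tube=tube, wall=props), FXW, resolution=1024, n_z=n_z
            )
            for name, sl in (("sectioned", slut), ("global", gslut)):
                maps = recover_tube_maps(stack, sl, tube)
                for k in range(slut.n_sections):
                    sel = (z >= slut.boundaries[k]) & (z < slut.boundaries[k + 1])
                    mu_a = np.nanmedian(maps.mu_a[sel])
                    mu_sp = np.nanmedian(maps.mu_s_prime[sel])
                    errs.setdefault(name, []).append(
                        abs(mu_a - props.mu_a) / props.mu_a
                        + abs(mu_sp - props.mu_s_prime) / props.mu_s_prime
                    )
        assert np.mean(errs["sectioned"]) < np.mean(errs["global"])

    def test_mid_grid_material_recovered_well(self, tube, sectioned):
        slut, _ = sectioned
        props = OpticalProperties.from_reduced(0.15, 3.95)
        stack = render_tube_wall_stack(
            TubeScene(tube=tube, wall=props), FXW, resolution=1024
        )
        maps = recover_tube_maps(stack, slut, tube)
        n_z = maps.mu_a.shape[0]
        z = np.linspace(0, tube.length, n_z, endpoint=False) + tube.length / (2 * n_z)
        proximal = z < 100.0
        assert np.nanmedian(maps.mu_a[proximal]) == pytest.approx(0.15, rel=0.05)
        assert np.nanmedian(maps.mu_s_prime[proximal]) == pytest.approx(3.95, rel=0.05)

    def test_deviating_quadrant_detected_in_expected_direction(self, tube, sectioned):
        slut, _ = sectioned
        dev = OpticalProperties.from_reduced(0.2, 1.5)  # more absorbing, less scattering
        scene = make_tube_scene(deviating_quadrant=dev)
        stack = render_tube_wall_stack(scene, FXW, resolution=1024, n_az=96)
        maps = recover_tube_maps(stack, slut, tube)
        n_az = maps.mu_a.shape[1]
        quadrant = np.s_[:, : n_az // 4]
        others = np.s_[:, n_az // 4:]
        assert np.nanmedian(maps.mu_a[quadrant]) > np.nanmedian(maps.mu_a[others])
        assert np.nanmedian(maps.mu_s_prime[quadrant]) < np.nanmedian(
            maps.mu_s_prime[others]
        )

    def test_sectioned_lut_hdf5_round_trip(self, sectioned, tmp_path):
        slut, _ = sectioned
        path = tmp_path / "slut.h5"
        slut.save(path)
        back = SectionedLUT.load(path)
        assert back.n_sections == slut.n_sections
        assert np.allclose(back.boundaries, slut.boundaries)
        assert np.allclose(back.luts[0].dc, slut.luts[0].dc)

    def test_section_lookup_clips_to_range(self, sectioned):
        slut, _ = sectioned
        assert slut.section_of(np.array([-5.0]))[0] == 0
        assert slut.section_of(np.array([999.0]))[0] == slut.n_sections - 1
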