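"""Phantom module: analytic flow oracle, scatterer kinematics, renderer."""

import numpy as np
import pytest

import echowss as ew
from echowss.phantom import ScattererSet, _LABEL_CODE

from conftest import small_phantom_config, steady_config


def constant(v):
    return lambda t: v * np.ones_like(np.asarray(t, dtype=float))


class TestAnalyticFlow:
    def test_poiseuille_centreline_is_twice_mean(self):
        cfg = PhantomConfigPoiseuille(0.1, 2.7e-3)
        flow = ew.analytic_flow(cfg, 0.0)
        assert flow.u_axial(0.0) == pytest.approx(0.2, rel=1e-12)

    def test_poiseuille_wall_shear_matches_numeric_derivative(self):
        """8 mu v / D against the numerical derivative of u(r) at r=R."""
        cfg = PhantomConfigPoiseuille(0.1, 2.7e-3)
        flow = ew.analytic_flow(cfg, 0.0)
        mu = cfg.blood_viscosity
        tau_closed = 8.0 * mu * 0.1 / 2.7e-3
        assert mu * flow.wall_shear_rate == pytest.approx(tau_closed,
                                                          rel=1e-12)
        h = 1e-6 * flow.radius
        du = (flow.u_axial(flow.radius - h) - flow.u_axial(flow.radius)) / h
        assert mu * du == pytest.approx(tau_closed, rel=1e-3)
        assert mu * du == pytest.approx(1.198, rel=2e-3)

    def test_womersley_dc_limit_equals_poiseuille(self):
        wom = small_phantom_config(mean_velocity_waveform=constant(0.1))
        poi = small_phantom_config(flow_model="poiseuille",
                                   mean_velocity_waveform=constant(0.1))
        for t in (0.0, 0.07, 0.21):
            fw = ew.analytic_flow(wom, t)
            fp = ew.analytic_flow(poi, t)
            assert np.max(np.abs(fw.u_grid - fp.u_grid)) < 1e-9
            assert fw.wall_shear_rate == pytest.approx(fp.wall_shear_rate,
                                                       abs=1e-9)

    def test_womersley_profile_mean_matches_waveform(self):
        cfg = small_phantom_config()
        for t in (0.0, 0.05, 0.11, 0.3):
            f = ew.analytic_flow(cfg, t)
            mean = np.trapezoid(f.u_grid * 2.0 * f.rho_grid, f.rho_grid)
            assert mean == pytest.approx(f.v_mean, abs=5e-6)

    def test_no_slip_at_wall(self):
        cfg = steady_config()
        f = ew.analytic_flow(cfg, 0.01)
        assert abs(f.u_axial(f.radius)) < 1e-6
        assert abs(f.v_radial(f.radius)) < 1e-6  # static wall

    def test_nonpositive_radius_raises(self):
        with pytest.raises(ValueError):
            small_phantom_config(diameter_waveform=constant(-1e-3))

    def test_zero_cycle_period_raises(self):
        with pytest.raises(ValueError):
            small_phantom_config(cycle_period=0.0)


def PhantomConfigPoiseuille(v_mean, diameter):
    return small_phantom_config(flow_model="poiseuille",
                                mean_velocity_waveform=constant(v_mean),
                                diameter_waveform=constant(diameter))


class TestAdvection:
    def test_zero_velocity_leaves_positions_unchanged(self):
        cfg = PhantomConfigPoiseuille(0.0, 2.7e-3)
        sc = ew.initialize_scatterers(cfg)
        out = ew.advect_scatterers(sc, cfg, 0.0)
        np.testing.assert_allclose(out.positions, sc.positions, atol=1e-15)

    def test_centreline_scatterer_moves_twice_mean_displacement(self):
        cfg = PhantomConfigPoiseuille(0.15, 2.7e-3)
        dt = 1.0 / 1500.0
        pos = np.array([[0.0, 0.0], [0.0, 1.0e-3]])
        sc = ScattererSet(pos, np.ones(2),
                          np.full(2, _LABEL_CODE["lumen"]))
        out = ew.advect_scatterers(sc, cfg, 0.0, dt)
        ds_centre = out.positions[0, 0] - pos[0, 0]
        assert ds_centre == pytest.approx(2.0 * 0.15 * dt, rel=1e-9)
        # off-axis displacement follows the local parabola
        flow = ew.analytic_flow(cfg, 0.0)
        assert out.positions[1, 0] == pytest.approx(
            flow.u_axial(1.0e-3) * dt, rel=1e-6)

    def test_wall_crossing_raises(self):
        cfg = small_phantom_config()
        r = float(cfg.radius(0.0))
        sc = ScattererSet(np.array([[0.0, r * 1.001]]), np.ones(1),
                          np.full(1, _LABEL_CODE["lumen"]))
        with pytest.raises(RuntimeError):
            ew.advect_scatterers(sc, cfg, 0.0)


class TestReplenish:
    def test_full_lumen_is_unchanged(self):
        cfg = steady_config()
        rng = np.random.default_rng(0)
        sc = ew.initialize_scatterers(cfg, 0.0, rng)
        sc = ew.replenish_scatterers(sc, cfg, 0.0, rng)
        n = len(sc)
        out = ew.replenish_scatterers(sc, cfg, 0.0, rng)
        assert len(out) == n

    def test_washed_out_inlet_is_repopulated(self):
        cfg = steady_config()
        rng = np.random.default_rng(0)
        sc = ew.initialize_scatterers(cfg, 0.0, rng)
        # remove every lumen scatterer in the left quarter of the vessel
        lum = sc.select("lumen")
        gone = lum & (sc.positions[:, 0] < -1e-3)
        sc_dep = ScattererSet(sc.positions[~gone], sc.amplitudes[~gone],
                              sc.labels[~gone])
        out = ew.replenish_scatterers(sc_dep, cfg, 0.0, rng)
        assert len(out) > len(sc_dep)
        # in-image lumen census restored (replenishment only covers the
        # imaged sub-regions, not the off-screen margin)
        s_img = (cfg.image_extent[1] / 2.0) / np.cos(cfg.angle_rad)

        def in_image_count(s):
            m = s.select("lumen") & (np.abs(s.positions[:, 0]) < s_img)
            return np.count_nonzero(m)

        assert in_image_count(out) >= 0.9 * in_image_count(sc)

    def test_census_stable_over_long_steady_run(self):
        cfg = small_phantom_config(
            flow_model="poiseuille",
            mean_velocity_waveform=lambda t: 0.1 * np.ones_like(
                np.asarray(t, dtype=float)),
            diameter_waveform=lambda t: 1.8e-3 * np.ones_like(
                np.asarray(t, dtype=float)),
            n_cycles=0.6,   # 300 frames at 1500 fps
        )
        res = ew.generate_sequence(cfg)
        census = res.scatterer_census
        assert np.all(census > 0.9 * census[0])
        assert np.all(census < 1.1 * census[0])


class TestRenderer:
    def test_empty_set_zero_noise_gives_zero_image(self):
        cfg = small_phantom_config(noise_std=0.0)
        img = ew.render_frame(ScattererSet(np.empty((0, 2)), np.empty(0),
                                           np.empty(0, dtype=int)), cfg)
        assert not img.any()

    def test_single_scatterer_peaks_at_centre(self):
        cfg = small_phantom_config(noise_std=0.0, beam_to_flow_angle=0.0)
        # offset by half a pixel so the scatterer sits on a pixel centre
        sp_ax, sp_lat = cfg.pixel_spacing
        sc = ScattererSet(np.array([[sp_lat / 2.0, sp_ax / 2.0]]),
                          np.ones(1), np.full(1, _LABEL_CODE["lumen"]))
        img = ew.render_frame(sc, cfg)
        h, w = cfg.image_shape
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert (iy, ix) == (h // 2, w // 2)
        assert img[iy, ix] == pytest.approx(1.0, rel=0.02)

    def test_one_pixel_shift_moves_correlation_peak(self):
        """FFT cross-correlation oracle on two renders of the same set
        shifted by exactly one lateral pixel."""
        cfg = small_phantom_config(noise_std=0.0, beam_to_flow_angle=0.0)
        rng = np.random.default_rng(3)
        n = 400
        pos = np.column_stack([rng.uniform(-8e-4, 8e-4, n),
                               rng.uniform(-8e-4, 8e-4, n)])
        sc = ScattererSet(pos, rng.standard_normal(n),
                          np.full(n, _LABEL_CODE["lumen"]))
        sc2 = ScattererSet(pos + [cfg.pixel_spacing[1], 0.0],
                           sc.amplitudes, sc.labels)
        a = ew.render_frame(sc, cfg)
        b = ew.render_frame(sc2, cfg)
        fa, fb = np.fft.fft2(a - a.mean()), np.fft.fft2(b - b.mean())
        corr = np.fft.ifft2(np.conj(fa) * fb).real
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        assert (iy, ix) == (0, 1)

    def test_rendering_linearity(self):
        cfg = small_phantom_config(noise_std=0.0)
        rng = np.random.default_rng(4)
        n = 200
        pos = np.column_stack([rng.uniform(-1e-3, 1e-3, n),
                               rng.uniform(-2e-3, 2e-3, n)])
        amp = rng.standard_normal(n)
        lab = np.full(n, _LABEL_CODE["lumen"])
        sc_all = ScattererSet(pos, amp, lab)
        sc_a = ScattererSet(pos[:100], amp[:100], lab[:100])
        sc_b = ScattererSet(pos[100:], amp[100:], lab[100:])
        img_all = ew.render_frame(sc_all, cfg)
        img_sum = ew.render_frame(sc_a, cfg) + ew.render_frame(sc_b, cfg)
        np.testing.assert_allclose(img_all, img_sum, atol=1e-10)


class TestSequence:
    def test_frame_count_spans_cycle(self):
        cfg = small_phantom_config(n_cycles=0.06)
        res = ew.generate_sequence(cfg)
        expected = int(np.ceil(0.06 * cfg.cycle_period
                               / cfg.frame_interval))
        assert res.compound.n_frames == expected

    def test_static_steady_ground_truth_wss_constant(self):
        cfg = small_phantom_config(
            flow_model="poiseuille",
            mean_velocity_waveform=lambda t: 0.1 * np.ones_like(
                np.asarray(t, dtype=float)),
            diameter_waveform=lambda t: 1.8e-3 * np.ones_like(
                np.asarray(t, dtype=float)),
        )
        res = ew.generate_sequence(cfg)
        wss = res.truth.wss_pairs
        assert np.ptp(wss) < 1e-12 * max(1.0, abs(wss[0]))

    def test_seeded_runs_are_bit_identical(self):
        cfg_a = small_phantom_config(seed=5)
        cfg_b = small_phantom_config(seed=5)
        ra = ew.generate_sequence(cfg_a)
        rb = ew.generate_sequence(cfg_b)
        for sa, sb in zip(ra.angle_stacks, rb.angle_stacks):
            assert np.array_equal(sa.frames, sb.frames)
        assert np.array_equal(ra.truth.velocity_u, rb.truth.velocity_u)

    def test_mass_conservation_across_sections(self):
        """Steady Poiseuille: the flux integral of the ground-truth
        axial profile agrees between any two lumen cross-sections."""
        cfg = steady_config()
        res = ew.generate_sequence(
            steady_config(n_cycles=0.004))  # 2 frames
        truth = res.truth
        _, d_map = cfg.pixel_vessel_coords()
        ex, ey = cfg.axis_unit
        fluxes = []
        for col in (30, 90):
            u_ax = (truth.velocity_u[0][:, col] * ex
                    + truth.velocity_v[0][:, col] * ey)
            fluxes.append(np.sum(u_ax))  # uniform row spacing
        assert fluxes[0] == pytest.approx(fluxes[1], rel=1e-3)
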