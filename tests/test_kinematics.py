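"""Stroke-plane fitting, Euler poses, cycles, phase averages, AoA and Re."""
import numpy as np
import pytest
from dataclasses import replace

from bristlewing.geometry import Frame
from bristlewing.kinematics import (EulerAngleSeries, StrokePlaneFrame,
                                    angles_from_pose, body_speed, clap_distance,
                                    derive_kinematics, detect_cycles,
                                    fit_stroke_plane, phase_average,
                                    pose_from_angles, resample_uniform,
                                    tip_positions)
from bristlewing.synthetic import ProtocolSpec, make_protocol


def _series(t, theta, phi, psi, part="left_wing"):
    return EulerAngleSeries(part, t, theta, phi, psi)


class TestStrokePlane:
    def test_exact_plane_recovered_with_zero_residual(self, rng):
        n = np.array([0.0, np.sin(0.3), np.cos(0.3)])
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(n, e1)
        pts = (rng.normal(size=(50, 1)) * e1 + rng.normal(size=(50, 1)) * e2)
        sp = fit_stroke_plane(pts, base=(0, 0, 0))
        assert abs(abs(np.dot(sp.normal, n)) - 1.0) < 1e-12
        assert np.abs(pts @ sp.normal).max() < 1e-9

    def test_horizontal_cloud_has_beta_zero(self, rng):
        pts = np.column_stack([rng.normal(size=80), rng.normal(size=80),
                               np.zeros(80)])
        sp = fit_stroke_plane(pts, base=(0, 0, 0))
        assert sp.beta == pytest.approx(0.0, abs=1e-9)

    def test_tilted_noisy_cloud_recovered_within_two_degrees(self, rng):
        beta = np.radians(40.0)
        n = np.array([np.sin(beta), 0.0, np.cos(beta)])
        e1 = np.array([np.cos(beta), 0.0, -np.sin(beta)])
        e2 = np.cross(n, e1)
        R = 493.0
        ang = rng.uniform(0, 2 * np.pi, 400)
        pts = (R * np.cos(ang)[:, None] * e1 + R * np.sin(ang)[:, None] * e2
               + rng.normal(0, 0.02 * R, size=(400, 3)))
        sp = fit_stroke_plane(pts, base=(0, 0, 0))
        assert np.degrees(np.arccos(abs(np.dot(sp.normal, n)))) < 2.0
        assert sp.beta == pytest.approx(40.0, abs=2.0)

    def test_collinear_cloud_rejected(self):
        pts = np.outer(np.linspace(0, 1, 30), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_stroke_plane(pts, base=(0, 0, 0))


class TestPose:
    frame = StrokePlaneFrame(Frame(np.zeros(3), np.eye(3)), 0.0)

    def test_pure_sweep_traces_circle_in_plane(self):
        phi = np.linspace(0, 360, 73)
        tips = tip_positions((np.zeros_like(phi), phi, np.zeros_like(phi)),
                             self.frame, 100.0)
        assert np.abs(tips[:, 2]).max() < 1e-9          # stays in plane
        assert np.allclose(np.linalg.norm(tips, axis=1), 100.0)

    def test_pitch_90_puts_chord_normal_to_stroke_plane(self):
        for phi in (0.0, 37.0, -120.0):
            R = pose_from_angles(0.0, phi, 90.0, self.frame)
            chord = R[:, 1]
            assert abs(abs(chord[2]) - 1.0) < 1e-12

    def test_roundtrip_identity_on_random_grid(self, rng):
        th = rng.uniform(-80, 80, 200)
        ph = rng.uniform(-179, 179, 200)
        ps = rng.uniform(-179, 179, 200)
        R = pose_from_angles(th, ph, ps, self.frame)
        th2, ph2, ps2 = angles_from_pose(R, self.frame)
        assert np.abs(th2 - th).max() < 1e-9
        assert np.abs(ph2 - ph).max() < 1e-9
        assert np.abs(ps2 - ps).max() < 1e-9

    def test_gimbal_lock_flagged(self):
        R = pose_from_angles(90.0, 10.0, 5.0, self.frame)
        with pytest.raises(ValueError, match="gimbal"):
            angles_from_pose(R, self.frame)


class TestResample:
    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 10, 23)
        poly = 0.1 * t**3 - t**2 + 3 * t - 7
        s = _series(t, poly, 2 * poly, -poly)
        out = resample_uniform(s, 0.13)
        expect = 0.1 * out.t**3 - out.t**2 + 3 * out.t - 7
        assert np.abs(out.theta - expect).max() < 1e-9

    def test_sine_resampled_10x_below_1e3_of_amplitude(self):
        t = np.linspace(0, 1, 21)  # 20 intervals per period
        s = _series(t, np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t))
        out = resample_uniform(s, 1 / 200)
        assert np.abs(out.theta - np.sin(2 * np.pi * out.t)).max() < 1e-3

    def test_uniform_series_unchanged_at_nodes(self):
        t = np.arange(0, 2, 0.1)
        s = _series(t, np.cos(t), np.sin(t), t)
        out = resample_uniform(s, 0.1)
        assert np.allclose(out.phi, s.phi)


class TestCycles:
    def test_sine_frequency_recovered_to_1e6(self):
        f = 0.21
        t = np.arange(0, 5 / f, 0.002)
        s = _series(t, np.zeros_like(t), 40 * np.sin(2 * np.pi * f * t),
                    np.zeros_like(t))
        cyc = detect_cycles(s)
        assert cyc.frequency == pytest.approx(f, rel=1e-6)

    def test_constant_phi_rejected(self):
        t = np.linspace(0, 10, 100)
        s = _series(t, np.zeros_like(t), np.full_like(t, 15.0), np.zeros_like(t))
        with pytest.raises(ValueError, match="crossings"):
            detect_cycles(s)

    def test_synthetic_beetle_frequency_within_0p1_percent(self, proto):
        lu = resample_uniform(proto.series["left_wing"], 2.6e-3)
        cyc = detect_cycles(lu)
        assert cyc.frequency == pytest.approx(proto.frequency, rel=1e-3)


class TestPhaseAverage:
    def test_identical_cycles_average_to_single_cycle(self, proto_clean):
        lu = resample_uniform(proto_clean.series["left_wing"], 2.6e-3)
        cyc = detect_cycles(lu)
        avg = phase_average(lu, None, cyc, n_phase=128)
        truth = proto_clean.truth_phase_series("left_wing", 128)
        assert np.abs(avg.phi - truth.phi).max() < 0.05
        assert np.abs(avg.theta - truth.theta).max() < 0.05

    def test_left_right_mirror_symmetry(self, proto_clean):
        """Exactly mirrored sides average to either side's canonical form."""
        lu = resample_uniform(proto_clean.series["left_wing"], 2.6e-3)
        ru = resample_uniform(proto_clean.series["right_wing"], 2.6e-3)
        cyc = detect_cycles(lu)
        one = phase_average(lu, None, cyc, n_phase=128)
        both = phase_average(lu, ru, cyc, n_phase=128)
        assert np.abs(one.psi - both.psi).max() < 1e-9

    def test_noise_reduction_scales_as_inverse_sqrt_2n(self, morph):
        """RMSE of the average ≈ σ/sqrt(2 n_cycles) across seeded replicates."""
        sigma = 2.0
        rmses = []
        for seed in range(12):
            p = make_protocol(ProtocolSpec(seed=seed, noise_sigma_deg=sigma),
                              planform=morph.planform)
            lu = resample_uniform(p.series["left_wing"], 2.6e-3)
            ru = resample_uniform(p.series["right_wing"], 2.6e-3)
            cyc = detect_cycles(lu)
            avg = phase_average(lu, ru, cyc, n_phase=256)
            truth = p.truth_phase_series("left_wing", 256)
            resid = np.concatenate([getattr(avg, n) - getattr(truth, n)
                                    for n in ("theta", "phi", "psi")])
            rmses.append(np.sqrt(np.mean(resid**2)))
        predicted = sigma / np.sqrt(2 * 4)
        assert np.mean(rmses) == pytest.approx(predicted, rel=0.3)


class TestDerivedKinematics:
    def test_edge_on_sweep_has_zero_aoa(self, morph, fluid):
        """ψ = 0: the chord lies along the motion; AoA vanishes."""
        n = 128
        tau = np.arange(n) / n
        s = _series(tau * 4.0, np.zeros(n), 80 * np.sin(2 * np.pi * tau), np.zeros(n))
        frame = StrokePlaneFrame(Frame(np.zeros(3), np.eye(3)), 0.0)
        kin = derive_kinematics(s, frame, morph.planform, fluid, period=4.0)
        assert np.nanmax(np.abs(kin.aoa_deg)) < 1e-6

    def test_flat_on_sweep_has_90_degree_aoa(self, morph, fluid):
        n = 512
        tau = np.arange(n) / n
        s = _series(tau * 4.0, np.zeros(n), 80 * np.sin(2 * np.pi * tau),
                    np.full(n, 90.0))
        frame = StrokePlaneFrame(Frame(np.zeros(3), np.eye(3)), 0.0)
        kin = derive_kinematics(s, frame, morph.planform, fluid, period=4.0)
        assert np.nanmin(np.abs(kin.aoa_deg)) > 89.99  # limited by grid resolution

    def test_mean_re_matches_closed_form_for_sinusoidal_stroke(self, morph, fluid):
        """φ = Φ sin(2πft): mean |U| = 4 Φ f R_g, so Re = 4 Φ f R_g c̄ / ν."""
        n = 4096
        tau = np.arange(n) / n
        f = 0.25  # kHz
        Phi = 70.0
        s = _series(tau / f, np.zeros(n), Phi * np.sin(2 * np.pi * tau), np.zeros(n))
        frame = StrokePlaneFrame(Frame(np.zeros(3), np.eye(3)), 0.0)
        kin = derive_kinematics(s, frame, morph.planform, fluid, period=1 / f)
        rg, cbar = morph.planform.radius_of_gyration, morph.planform.mean_chord
        re_expected = 4 * np.radians(Phi) * f * rg * cbar / fluid.kinematic_viscosity
        assert kin.re_mean == pytest.approx(re_expected, rel=1e-3)

    def test_re_scales_linearly_with_frequency_and_chord(self, morph, fluid):
        n = 512
        tau = np.arange(n) / n
        frame = StrokePlaneFrame(Frame(np.zeros(3), np.eye(3)), 0.0)

        def re_at(f, planform):
            s = _series(tau / f, np.zeros(n), 70 * np.sin(2 * np.pi * tau),
                        np.zeros(n))
            return derive_kinematics(s, frame, planform, fluid, period=1 / f).re_mean

        base = re_at(0.2, morph.planform)
        assert re_at(0.4, morph.planform) == pytest.approx(2 * base, rel=1e-9)
        fat = replace(morph.planform, area=2 * morph.planform.area,
                      mean_chord=2 * morph.planform.mean_chord)
        assert re_at(0.2, fat) == pytest.approx(2 * base, rel=1e-9)


class TestBodySpeed:
    def test_uniform_motion_recovered_exactly(self):
        t = np.linspace(0, 20, 60)
        v = np.array([57.0, 0.0, 39.0])
        bs = body_speed(t, t[:, None] * v, loess_frac=0.0)
        assert np.allclose(bs.velocity, v)
        assert np.allclose(bs.vertical_speed, 39.0)

    def test_vertical_ascent_has_zero_horizontal_component(self):
        t = np.linspace(0, 20, 60)
        track = np.column_stack([np.zeros_like(t), np.zeros_like(t), 30 * t])
        bs = body_speed(t, track, loess_frac=0.3)
        assert np.abs(bs.horizontal_speed).max() < 1e-9

    def test_jittered_motion_smoothed_near_truth(self, rng):
        t = np.linspace(0, 20, 200)
        v = np.array([40.0, 0.0, 10.0])
        jit = rng.normal(0, 1.0, size=(200, 3))
        bs = body_speed(t, t[:, None] * v + jit, loess_frac=0.3)
        mid = slice(30, 170)
        assert np.abs(bs.velocity[mid] - v).max() < 10.0
        assert np.abs(bs.velocity[mid] - v).mean() < np.abs(bs.velocity_raw[mid] - v).mean()


class TestClap:
    def test_touching_mirrored_tips_give_zero(self):
        tips = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        mirrored = tips * np.array([1.0, -1.0, 1.0])
        assert clap_distance(tips, mirrored) == 0.0

    def test_known_closest_approach_recovered(self, proto_clean, morph):
        """The generator's labelled clap distance is recovered from the tip series."""
        R = morph.planform.length
        tl = tip_positions(proto_clean.truth["left_wing"],
                           proto_clean.frames["left_wing"], R)
        tr = tip_positions(proto_clean.truth["right_wing"],
                           proto_clean.frames["right_wing"], R)
        tau = np.mod(proto_clean.truth["left_wing"].t / proto_clean.period, 1.0)
        d = clap_distance(tl, tr, phase=tau,
                          window=proto_clean.labels["clap_windows"][0])
        assert d == pytest.approx(proto_clean.labels["clap_distance_um"], abs=1.0)

    def test_window_without_samples_rejected(self):
        tips = np.zeros((10, 3))
        with pytest.raises(ValueError, match="phase"):
            clap_distance(tips, tips, phase=None, window=(0.1, 0.2))
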