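"""Force series, lift/drag decomposition, surrogate and vertical budget."""
import numpy as np
import pytest

from bristlewing.aeroforces import (CoefficientTable, ForceSeries, decompose,
                                    quasisteady_surrogate, shift_torque_reference,
                                    vertical_breakdown)
from bristlewing.kinematics import derive_kinematics
from bristlewing.synthetic import _in_windows
from bristlewing.units import GRAVITY


def _random_force_series(rng, n=100):
    phase = np.arange(n) / n
    F = rng.normal(size=(n, 3))
    T = rng.normal(size=(n, 3))
    return ForceSeries("x", phase, F, T)


class TestForceSeries:
    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            ForceSeries("x", np.arange(5) / 5, np.zeros((4, 3)), np.zeros((4, 3)))

    def test_torque_reference_shift_roundtrip(self, rng):
        fs = _random_force_series(rng)
        moved = shift_torque_reference(fs, (10.0, -5.0, 3.0))
        back = shift_torque_reference(moved, fs.torque_ref)
        assert np.allclose(back.torque, fs.torque, atol=1e-12)

    def test_addition_requires_common_reference(self, rng):
        a = _random_force_series(rng)
        b = shift_torque_reference(_random_force_series(rng), (1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="reference"):
            a + b


class TestDecompose:
    def test_force_parallel_to_velocity_is_pure_drag(self, rng):
        n = 50
        v = rng.normal(size=(n, 3))
        F = 2.5 * v
        fs = ForceSeries("w", np.arange(n) / n, F, np.zeros((n, 3)))
        dec = decompose(fs, v)
        assert np.allclose(dec.lift, 0.0, atol=1e-12)
        assert np.allclose(dec.drag, F)

    def test_force_perpendicular_to_velocity_is_pure_lift(self):
        n = 40
        v = np.tile([1.0, 0.0, 0.0], (n, 1))
        F = np.tile([0.0, 0.0, 3.0], (n, 1))
        fs = ForceSeries("w", np.arange(n) / n, F, np.zeros((n, 3)))
        dec = decompose(fs, v)
        assert np.allclose(dec.drag, 0.0, atol=1e-12)
        assert np.allclose(dec.lift, F)

    def test_exactness_and_orthogonality_on_random_pairs(self, rng):
        """drag + lift reconstructs the total and lift ⊥ v, to 1e-12 relative."""
        n = 10_000
        v = rng.normal(size=(n, 3))
        F = rng.normal(size=(n, 3))
        fs = ForceSeries("w", np.arange(n) / n, F, np.zeros((n, 3)))
        dec = decompose(fs, v)
        recon = np.abs(dec.drag + dec.lift - F).max() / np.abs(F).max()
        ortho = np.abs(np.einsum("ij,ij->i", dec.lift, v))
        scale = np.linalg.norm(dec.lift, axis=1) * np.linalg.norm(v, axis=1) + 1e-300
        assert recon < 1e-12
        assert (ortho / scale).max() < 1e-12

    def test_zero_velocity_samples_become_gaps(self):
        v = np.array([[1.0, 0, 0], [0.0, 0, 0], [0, 1.0, 0]])
        F = np.ones((3, 3))
        fs = ForceSeries("w", np.arange(3) / 3, F, np.zeros((3, 3)))
        dec = decompose(fs, v)
        assert dec.gaps.tolist() == [False, True, False]
        assert np.isnan(dec.drag[1]).all()


class TestSurrogate:
    def test_zero_velocity_gives_zero_force(self, morph, fluid, proto_clean):
        from bristlewing.kinematics import EulerAngleSeries
        n = 64
        s = EulerAngleSeries("left_wing", np.arange(n) / n * 4.0, np.zeros(n),
                             np.full(n, 10.0), np.zeros(n))
        kin = derive_kinematics(s, proto_clean.frames["left_wing"], morph.planform,
                                fluid, period=4.0)
        fs = quasisteady_surrogate(kin, morph.planform, fluid)
        assert np.allclose(fs.force, 0.0)

    def test_doubling_speed_quadruples_force(self, morph, fluid, proto_clean):
        from dataclasses import replace
        s1 = proto_clean.truth_phase_series("left_wing", 128)
        s2 = replace(s1, t=s1.t / 2)  # same waveform at twice the frequency
        k1 = derive_kinematics(s1, proto_clean.frames["left_wing"], morph.planform,
                               fluid, period=proto_clean.period)
        k2 = derive_kinematics(s2, proto_clean.frames["left_wing"], morph.planform,
                               fluid, period=proto_clean.period / 2)
        c = CoefficientTable(k_re=0.0)  # fixed coefficients isolate the U² law
        f1 = quasisteady_surrogate(k1, morph.planform, fluid, coeffs=c)
        f2 = quasisteady_surrogate(k2, morph.planform, fluid, coeffs=c)
        ratio = np.linalg.norm(f2.force, axis=1) / np.linalg.norm(f1.force, axis=1)
        assert np.allclose(ratio, 4.0, rtol=1e-9)

    def test_drag_component_anti_aligned_with_velocity(self, morph, fluid, proto_clean):
        kin = derive_kinematics(proto_clean.truth_phase_series("left_wing", 128),
                                proto_clean.frames["left_wing"], morph.planform,
                                fluid, period=proto_clean.period)
        fs = quasisteady_surrogate(kin, morph.planform, fluid)
        dec = decompose(fs, kin.tip_velocity, gaps=kin.gaps)
        ok = ~dec.gaps
        proj = np.einsum("ij,ij->i", dec.drag[ok], kin.tip_velocity[ok])
        assert np.all(proj <= 0)

    def test_force_peaks_inside_power_stroke_windows(self, morph, fluid, proto_clean):
        """≥90% of the strongest vertical-force samples lie in power windows."""
        kin = derive_kinematics(proto_clean.truth_phase_series("left_wing", 256),
                                proto_clean.frames["left_wing"], morph.planform,
                                fluid, period=proto_clean.period)
        fs = quasisteady_surrogate(kin, morph.planform, fluid)
        fz = np.abs(fs.force[:, 2])
        strong = fz >= 0.5 * fz.max()
        inside = _in_windows(np.mod(kin.phase, 1.0),
                             proto_clean.labels["power_windows"])
        assert (strong & inside).sum() / strong.sum() >= 0.9

    def test_net_vertical_force_positive_on_default_protocol(self, morph, fluid,
                                                             proto_clean):
        kin = derive_kinematics(proto_clean.truth_phase_series("left_wing", 256),
                                proto_clean.frames["left_wing"], morph.planform,
                                fluid, period=proto_clean.period)
        fs = quasisteady_surrogate(kin, morph.planform, fluid)
        assert fs.force[:, 2].mean() > 0

    def test_negative_coefficients_rejected(self, morph, fluid, proto_clean):
        kin = derive_kinematics(proto_clean.truth_phase_series("left_wing", 64),
                                proto_clean.frames["left_wing"], morph.planform,
                                fluid, period=proto_clean.period)
        bad = CoefficientTable(cd=lambda a: -np.ones_like(a))
        with pytest.raises(ValueError, match="non-negative"):
            quasisteady_surrogate(kin, morph.planform, fluid, coeffs=bad)


class TestVerticalBreakdown:
    def _series(self, Fz, n=100):
        F = np.zeros((n, 3))
        F[:, 2] = Fz
        return ForceSeries("w", np.arange(n) / n, F, np.zeros((n, 3)))

    def test_hover_balance_gives_zero_acceleration(self):
        m_b = 2.43
        fs = self._series(m_b * GRAVITY)
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        bd = vertical_breakdown({"wings": fs}, {"wings": decompose(fs, v)}, m_b)
        assert bd.vertical_acceleration == pytest.approx(0.0, abs=1e-12)
        assert bd.weight_equivalent_ug["total"] == pytest.approx(m_b)

    def test_pure_drag_fixture_gives_full_drag_share(self):
        n = 100
        v = np.tile([0.0, 0.0, -1.0], (n, 1))
        fs = self._series(5.0, n)  # force exactly opposing downward motion
        bd = vertical_breakdown({"w": fs}, {"w": decompose(fs, v)}, 2.43)
        assert bd.drag_share_pct == pytest.approx(100.0, abs=1e-9)
        assert bd.lift_share_pct == pytest.approx(0.0, abs=1e-9)

    def test_injected_one_to_three_ratio_recovered(self):
        """Drag and lift parts injected 1:3 give 25%/75% shares."""
        n = 200
        v = np.tile([1.0, 0.0, -1.0], (n, 1)) / np.sqrt(2)   # down-forward motion
        drag_part = -v                                        # anti-aligned, +z/sqrt2
        lift_part = 3.0 * np.tile([1.0, 0.0, 1.0], (n, 1)) / np.sqrt(2)  # ⊥ v, +3z/sqrt2
        F = drag_part + lift_part
        fs = ForceSeries("w", np.arange(n) / n, F, np.zeros((n, 3)))
        bd = vertical_breakdown({"w": fs}, {"w": decompose(fs, v)}, 2.43)
        assert bd.drag_share_pct == pytest.approx(25.0, abs=1e-6)
        assert bd.lift_share_pct == pytest.approx(75.0, abs=1e-6)

    def test_cycle_average_linearity(self, rng):
        a = _random_force_series(rng)
        b = _random_force_series(rng)
        v = rng.normal(size=(100, 3))
        m_b = 2.43
        bd_a = vertical_breakdown({"w": a}, {"w": decompose(a, v)}, m_b)
        bd_b = vertical_breakdown({"w": b}, {"w": decompose(b, v)}, m_b)
        bd_ab = vertical_breakdown({"w": a + b}, {"w": decompose(a + b, v)}, m_b)
        assert bd_ab.total_mean == pytest.approx(bd_a.total_mean + bd_b.total_mean,
                                                 rel=1e-12)
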