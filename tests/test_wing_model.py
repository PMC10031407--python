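"""Structural model: stiffness field identities, kinematics, dynamics."""

import numpy as np
import pytest

from wingsense.wing_model import (
    DampingSpec, Kinematics, WingSpec, build_stiffness_field,
    damping_coefficient, eigenfrequency, flap_acceleration, flap_angle,
    flap_velocity, simulate_strain,
)
from wingsense._plate import PlateModel


class TestStiffnessField:
    def test_gradient_spans_two_orders_of_magnitude(self):
        spec = WingSpec(gradient="gradient")
        field = build_stiffness_field(spec)
        expected = 26.67 * 0.05 + 26.67 * 0.025   # m_x * span + m_y * chord
        assert field.log10_range == pytest.approx(expected, rel=1e-9)
        assert field.log10_range == pytest.approx(2.0, abs=0.01)

    def test_uniform_field_is_constant(self):
        field = build_stiffness_field(WingSpec(E_mean=3e9))
        assert np.all(field.E == 3e9)

    @pytest.mark.parametrize("E_mean", [0.3e9, 3e9, 30e9])
    def test_discrete_mean_equals_nominal(self, E_mean):
        spec = WingSpec(gradient="gradient", E_mean=E_mean)
        field = build_stiffness_field(spec)
        assert field.E.mean() == pytest.approx(E_mean, rel=1e-3)

    def test_stiffest_at_leading_edge_base_corner(self):
        field = build_stiffness_field(WingSpec(gradient="gradient"))
        assert field.E[0, 0] == field.E.max()      # (y=0, x=0)
        assert field.E[-1, -1] == field.E.min()    # trailing-edge tip

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WingSpec(E_mean=-1.0)
        with pytest.raises(ValueError):
            WingSpec(poisson=0.6)
        with pytest.raises(ValueError):
            WingSpec(zeta=-0.1)


class TestKinematics:
    def test_flap_angle_values(self):
        kin = Kinematics()
        assert flap_angle(0.0, kin) == 0.0
        # at t = 10 ms the second harmonic vanishes and the first peaks
        assert flap_angle(0.01, kin) == pytest.approx(np.pi / 12, rel=1e-12)

    def test_wingbeat_periodicity(self):
        kin = Kinematics()
        t = np.linspace(0, 0.04, 33)
        assert np.allclose(flap_angle(t + 0.04, kin), flap_angle(t, kin),
                           atol=1e-12)

    def test_analytic_derivatives_match_finite_differences(self):
        kin = Kinematics()
        t = np.linspace(0.001, 0.08, 40)
        h = 1e-7
        num_vel = (flap_angle(t + h, kin) - flap_angle(t - h, kin)) / (2 * h)
        num_acc = (flap_velocity(t + h, kin) - flap_velocity(t - h, kin)) / (2 * h)
        assert np.allclose(flap_velocity(t, kin), num_vel, rtol=1e-6)
        assert np.allclose(flap_acceleration(t, kin), num_acc, rtol=1e-5)

    def test_invalid_kinematics_rejected(self):
        with pytest.raises(ValueError):
            Kinematics(rotation_axis="spin")
        with pytest.raises(ValueError):
            Kinematics(rotation_rate=-1.0)
        with pytest.raises(ValueError):
            Kinematics(ramp_cycles=0)


class TestEigenfrequency:
    def test_uniform_plate_matches_cantilever_beam_closed_form(self):
        spec = WingSpec(E_mean=3e9)
        omega, mode = eigenfrequency(spec)
        f1 = omega / (2 * np.pi)
        f_beam = (1.875104**2 / (2 * np.pi)) * np.sqrt(
            spec.E_mean * spec.thickness**2
            / (12 * spec.density * (1 - spec.poisson**2) * spec.span**4))
        assert f1 == pytest.approx(f_beam, rel=0.05)

    def test_omega_scales_as_sqrt_of_modulus(self):
        om1, _ = eigenfrequency(WingSpec(E_mean=3e9), nx=20, ny=10)
        om4, _ = eigenfrequency(WingSpec(E_mean=12e9), nx=20, ny=10)
        assert om4 / om1 == pytest.approx(2.0, rel=1e-6)

    def test_gradient_raises_first_mode(self):
        # the gradient concentrates stiffness at the root, where mode-1
        # curvature is largest, so the first eigenfrequency goes up even
        # though the mean modulus is matched
        om_u, _ = eigenfrequency(WingSpec(), nx=20, ny=10)
        om_g, _ = eigenfrequency(WingSpec(gradient="gradient"), nx=20, ny=10)
        assert om_g > om_u


class TestDamping:
    def test_formula_and_linearity(self):
        d = damping_coefficient(0.0, 1.0, 100.0)
        assert d.c == 0.0
        d1 = damping_coefficient(1.0, 2e-4, 90.0)
        d2 = damping_coefficient(2.0, 2e-4, 90.0)
        assert d1.c == pytest.approx(2 * 1.0 * 2e-4 * 90.0)
        assert d2.c == pytest.approx(2 * d1.c)

    def test_default_plate_mass(self):
        assert WingSpec().mass == pytest.approx(
            0.05 * 0.025 * 127e-6 * 1180, rel=1e-12)

    def test_rigid_motion_damping_force_contract(self):
        """Summed nodal damping force on a rigid velocity equals -c V."""
        spec = WingSpec()
        field_E = np.full((6, 11), spec.E_mean)
        plate = PlateModel(spec.span, spec.chord, spec.thickness,
                           spec.density, spec.poisson, field_E, nx=10, ny=5)
        c = 3.7e-4
        C = (c / plate.mass) * plate.M
        v = np.zeros(plate.n_dof)
        v[0::4] = 1.0                       # rigid unit transverse velocity
        force = -(C @ v)
        assert force[0::4].sum() == pytest.approx(-c, rel=1e-9)


class TestSimulateStrain:
    def test_zero_kinematics_gives_zero_strain(self):
        kin = Kinematics(A1=0.0, A2=0.0, rotation_axis="none")
        out = simulate_strain(WingSpec(), kin, nx=10, ny=5, n_cycles=3)
        assert np.all(out.epsilon_xx == 0.0)

    def test_linearity_in_flap_amplitude(self, tiny_spec):
        k1 = Kinematics(rotation_axis="none")
        k2 = Kinematics(A1=2 * k1.A1, A2=2 * k1.A2, rotation_axis="none")
        s1 = simulate_strain(tiny_spec, k1, nx=10, ny=5, n_cycles=3)
        s2 = simulate_strain(tiny_spec, k2, nx=10, ny=5, n_cycles=3)
        scale = np.abs(s1.epsilon_xx).max()
        assert np.allclose(s2.epsilon_xx, 2 * s1.epsilon_xx,
                           rtol=1e-7, atol=1e-9 * scale)

    def test_zero_rotation_rate_identical_across_axes(self, tiny_spec):
        outs = [simulate_strain(tiny_spec,
                                Kinematics(rotation_axis=ax, rotation_rate=0.0),
                                nx=10, ny=5, n_cycles=3)
                for ax in ("none", "roll", "pitch", "yaw")]
        for o in outs[1:]:
            assert np.array_equal(o.epsilon_xx, outs[0].epsilon_xx)

    def test_steady_periodicity_reached(self, grid_pair):
        _, flap, rot = grid_pair
        assert flap.periodicity_error < 0.01
        i0, i1 = flap.wingbeat_window
        assert i1 - i0 == 200                      # 40 ms at 0.2 ms steps
        assert np.all(np.isfinite(flap.epsilon_xx))

    def test_rotation_perturbation_is_small(self, grid_pair):
        """Rotation adds a strain perturbation orders of magnitude below
        the flapping strain itself."""
        _, flap, rot = grid_pair
        ratio = np.abs(flap.window).max() / np.abs(rot.window - flap.window).max()
        assert ratio > 50

    def test_energy_decays_in_free_vibration(self):
        spec = WingSpec(zeta=1.0)
        field_E = np.full((6, 11), spec.E_mean)
        plate = PlateModel(spec.span, spec.chord, spec.thickness,
                           spec.density, spec.poisson, field_E, nx=10, ny=5)
        om, modes = plate.eigenfrequencies(1)
        c = 2 * spec.zeta * plate.mass * om[0]
        q0 = 1e-3 * modes[plate.free, 0] / np.abs(modes[plate.free, 0]).max()
        rec = plate.integrate(lambda t: 0.0, lambda t: 0.0, 2e-4, 100, c,
                              q0=q0, record_energy=True)
        assert rec.energy[0] > 0
        assert np.all(np.diff(rec.energy) <= 1e-12 * rec.energy[0])

    def test_time_step_convergence_is_first_order(self, tiny_spec):
        """Successive dt halvings shrink the strain change linearly in dt
        (the backward-Euler signature), and the change stays small."""
        kin = Kinematics(rotation_axis="none")
        fields = [simulate_strain(tiny_spec, kin, dt=dt, nx=10, ny=5,
                                  n_cycles=4)
                  for dt in (2e-4, 1e-4, 5e-5)]
        w0, w1, w2 = (f.window for f in fields)
        scale = np.abs(w0).max()
        d01 = np.abs(w0 - w1[:, ::2]).max() / scale
        d12 = np.abs(w1 - w2[:, ::2]).max() / scale
        assert d01 < 0.05
        assert d01 / d12 == pytest.approx(2.0, rel=0.25)

    def test_n_cycles_validation(self, tiny_spec):
        with pytest.raises(ValueError):
            simulate_strain(tiny_spec, Kinematics(), n_cycles=2, nx=10, ny=5)
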