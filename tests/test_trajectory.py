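"""Hanging-strut force balance: kinematics, fits, viscosity curve."""

import math

import numpy as np
import pytest

from strutkit import (
    NonDecayingProfileError,
    PhysicalValidityError,
    PrintConditions,
    RegimeSelectionError,
    StrutTrajectory,
    TrajectoryFit,
    analyze_trajectory,
    elongational_viscosity,
    fit_diameter_profile,
    fit_pitch_angle,
    fit_trajectory,
    select_viscous_regime,
    strain_rate,
    velocity_profile,
)
from strutkit.synthetic import gen_trajectory


def _make_traj(s, x=None, alpha=None, d=None):
    n = len(s)
    return StrutTrajectory(
        s=s,
        x=s if x is None else x,
        alpha=np.zeros(n) if alpha is None else alpha,
        d=np.full(n, 0.4) if d is None else d,
    )


class TestKinematics:
    def test_velocity_hand_value(self):
        prof = velocity_profile(np.array([0.25]), Q=0.25)
        assert prof.v[0] == pytest.approx(4 * 0.25 / (math.pi * 0.0625), rel=1e-9)

    def test_continuity_and_inverse_square_law(self):
        d = np.linspace(0.5, 0.25, 20)
        prof = velocity_profile(d, Q=0.25)
        assert np.allclose(prof.v * prof.A, 0.25, rtol=1e-12)
        # halving d quadruples v
        assert prof.v[-1] / prof.v[0] == pytest.approx(4.0, rel=1e-9)

    def test_constant_diameter_gives_zero_strain(self):
        s = np.linspace(0, 5, 20)
        prof = velocity_profile(np.full(20, 0.4), Q=0.25)
        assert np.allclose(strain_rate(prof, s), 0.0, atol=1e-12)

    def test_closed_form_matches_finite_differences(self):
        """Strain rate of the fitted exponential equals dense numeric dv/ds."""
        d0, d_inf, s_c = 0.5, 0.22, 2.5
        s = np.linspace(0.0, 8.0, 20001)
        d = d_inf + (d0 - d_inf) * np.exp(-s / s_c)
        prof = velocity_profile(d, Q=0.25)
        fit = TrajectoryFit(d0=d0, d_inf=d_inf, s_c=s_c, m=0.1, regime=(0.0, 8.0))
        closed = strain_rate(prof, s, fit=fit)
        numeric = strain_rate(prof, s)
        interior = slice(10, -10)
        assert np.allclose(closed[interior], numeric[interior], rtol=1e-6)

    def test_thinning_profile_positive_strain(self):
        s = np.linspace(0, 6, 30)
        d = 0.22 + 0.28 * np.exp(-s / 2.0)
        prof = velocity_profile(d, Q=0.25)
        assert np.all(strain_rate(prof, s) > 0)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            velocity_profile(np.array([0.3, 0.0]), Q=0.25)


class TestRegimeSelection:
    def test_interior_minimum_located(self):
        s = np.linspace(0, 8, 81)
        d = 0.3 + 0.05 * ((s - 4.0) / 2.0) ** 2  # parabolic-like, min at 4
        traj = _make_traj(s, d=d)
        s0, s1 = select_viscous_regime(traj)
        assert s1 == pytest.approx(4.0, abs=0.15)
        assert s0 == pytest.approx(s[2])

    def test_monotone_decrease_runs_to_last_point(self):
        s = np.linspace(0, 8, 40)
        traj = _make_traj(s, d=0.22 + 0.28 * np.exp(-s / 2.5))
        _, s1 = select_viscous_regime(traj)
        assert s1 == pytest.approx(8.0)

    def test_monotone_increase_rejected(self):
        s = np.linspace(0, 8, 40)
        traj = _make_traj(s, d=0.2 + 0.05 * s)
        with pytest.raises(RegimeSelectionError):
            select_viscous_regime(traj)


class TestFits:
    def test_noiseless_exponential_exact(self):
        s = np.linspace(0, 8, 60)
        d = 0.21 + 0.3 * np.exp(-s / 1.8)
        traj = _make_traj(s, d=d)
        d0, d_inf, s_c = fit_diameter_profile(traj)
        assert d0 == pytest.approx(0.51, rel=1e-8)
        assert d_inf == pytest.approx(0.21, rel=1e-8)
        assert s_c == pytest.approx(1.8, rel=1e-8)

    def test_noisy_exponential_within_5_percent(self):
        s = np.linspace(0, 8, 320)
        rng = np.random.default_rng(11)
        d = 0.22 + 0.28 * np.exp(-s / 2.5) + rng.normal(0, 0.025, len(s))
        traj = _make_traj(s, d=np.clip(d, 0.05, None))
        d0, d_inf, s_c = fit_diameter_profile(traj)
        assert d0 == pytest.approx(0.5, rel=0.05)
        assert d_inf == pytest.approx(0.22, rel=0.05)

    def test_increasing_profile_flagged_non_decaying(self):
        s = np.linspace(0, 8, 40)
        traj = _make_traj(s, d=0.2 + 0.02 * s)
        with pytest.raises(NonDecayingProfileError):
            fit_diameter_profile(traj)

    def test_pitch_angle_exact_and_noisy(self):
        s = np.linspace(0, 8, 40)
        alpha = 0.1 + 0.12 * s
        traj = _make_traj(s, alpha=alpha, d=0.22 + 0.28 * np.exp(-s / 2.5))
        assert fit_pitch_angle(traj) == pytest.approx(0.12, rel=1e-12)
        rng = np.random.default_rng(4)
        noisy = _make_traj(
            s, alpha=alpha + rng.normal(0, np.deg2rad(0.5), 40),
            d=0.22 + 0.28 * np.exp(-s / 2.5),
        )
        assert fit_pitch_angle(noisy) == pytest.approx(0.12, rel=0.05)

    def test_degenerate_x_range_rejected(self):
        s = np.linspace(0, 8, 40)
        traj = _make_traj(s, x=np.zeros(40) + 1.0, d=0.22 + 0.28 * np.exp(-s / 2.5))
        with pytest.raises(ValueError):
            fit_pitch_angle(traj)


class TestViscosity:
    def test_gamma_zero_reduction_identical(self, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 60)
        fit = fit_trajectory(traj)
        with_flag = elongational_viscosity(traj, fit, conditions, include_gamma=True)
        without = elongational_viscosity(traj, fit, conditions, include_gamma=False)
        assert np.array_equal(with_flag.eta_E, without.eta_E)

    def test_axis_s_equals_axis_x_for_linear_pitch(self, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 120)
        fit = fit_trajectory(traj)
        cx = elongational_viscosity(traj, fit, conditions, axis="x")
        cs = elongational_viscosity(traj, fit, conditions, axis="s")
        assert np.allclose(cs.eta_E, cx.eta_E, rtol=1e-6)

    def test_density_linearity_with_zero_gamma(self, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 60)
        fit = fit_trajectory(traj)
        c1 = elongational_viscosity(traj, fit, conditions, include_gamma=False)
        heavy = PrintConditions(v_p=5.0, Q=0.25, density=2000.0, gamma=0.0)
        c2 = elongational_viscosity(traj, fit, heavy, include_gamma=False)
        assert np.allclose(c2.eta_E, 2.0 * c1.eta_E, rtol=1e-12)

    def test_noiseless_pipeline_matches_analytic_curve(self, conditions):
        traj, truth = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 60)
        fit, curve = analyze_trajectory(traj, conditions, include_gamma=False)
        mask = (truth.s >= fit.regime[0]) & (truth.s <= fit.regime[1])
        assert np.allclose(curve.eta_E, truth.eta_E[mask], rtol=1e-6)

    def test_surface_tension_lowers_eta(self):
        cond = PrintConditions(v_p=5.0, Q=0.25, density=1000.0, gamma=0.07)
        traj, _ = gen_trajectory(cond, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 60)
        fit = fit_trajectory(traj)
        with_g = elongational_viscosity(traj, fit, cond, include_gamma=True)
        without = elongational_viscosity(traj, fit, cond, include_gamma=False)
        assert np.all(with_g.eta_E < without.eta_E)

    def test_nonpositive_pitch_slope_is_physical_error(self, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 60)
        bad = TrajectoryFit(d0=0.5, d_inf=0.22, s_c=2.5, m=-0.01, regime=(0.5, 7.0))
        with pytest.raises(PhysicalValidityError):
            elongational_viscosity(traj, bad, conditions)


class TestIO:
    def test_csv_round_trip(self, tmp_path, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 30)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        back = StrutTrajectory.from_csv(p)
        assert np.allclose(back.alpha, traj.alpha)
        assert np.allclose(back.d, traj.d)

    def test_curve_csv_columns(self, tmp_path, conditions):
        traj, _ = gen_trajectory(conditions, 0.5, 0.22, 2.5, 0.08, 0.12, 8.0, 30)
        _, curve = analyze_trajectory(traj, conditions)
        p = tmp_path / "eta.csv"
        curve.to_csv(p)
        header = p.read_text().splitlines()[0]
        assert header == "eps_dot_per_s,eta_E_Pa_s,s_mm"
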