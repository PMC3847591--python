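"""Cross-bridge moment dynamics: chemical input, recruitment, ODE integration."""

import numpy as np
import pytest

from emgforce import (
    PhysioParams,
    PhysioState,
    UniformSeries,
    chemical_drive_from_indicator,
    isotonic_force_velocity,
    make_chemical_input,
    physio_rhs,
    recruitment_alpha,
    simulate_physio,
)
from emgforce.synth import SynthTrialConfig, generate_surface_emg, ramp_plateau_profile


FS = 2048.0


class TestChemicalInput:
    def test_zero_emg_gives_relaxation_rate_everywhere(self):
        raw = UniformSeries(dt=1 / FS, values=np.zeros(4096))
        drive = make_chemical_input(raw, threshold=0.1)
        assert np.array_equal(drive.pi_c.values, np.zeros(4096))
        assert np.allclose(drive.u.values, 10.0)

    def test_loud_emg_gives_contraction_rate(self, rng):
        raw = UniformSeries(dt=1 / FS, values=rng.normal(0, 1.0, 8192))
        drive = make_chemical_input(raw, threshold=1e-4)
        mid = slice(200, -200)  # edges decay through the zero-lag filters
        assert np.all(drive.pi_c.values[mid] == 1.0)
        assert np.allclose(drive.u.values[mid], 5.0)

    def test_burst_interval_matches_threshold_crossings(self, rng):
        prof, _ = ramp_plateau_profile(FS, 0.8, "x", t_pre=0.5, t_ramp=0.3, t_hold=1.0, t_post=0.5)
        cfg = SynthTrialConfig(fs=FS, profile=prof, seed=5)
        raw = generate_surface_emg(cfg)
        drive = make_chemical_input(raw, threshold=0.3 * np.abs(raw.values).max())
        # indicator transitions must align with the envelope crossings
        from emgforce.emg import EnvelopeConfig, rectify, zero_lag_butterworth

        e = EnvelopeConfig()
        env = zero_lag_butterworth(
            rectify(zero_lag_butterworth(raw, e.hp_cutoff, e.hp_order, "high")), 30.0, 2, "low"
        )
        expected = (env.values > drive.threshold).astype(float)
        assert np.array_equal(drive.pi_c.values, expected)

    def test_u_is_exact_mixture(self, make_series):
        pi = make_series([0.0, 1.0, 1.0, 0.0])
        drive = chemical_drive_from_indicator(pi, Uc=5.0, Ur=10.0)
        assert np.array_equal(drive.u.values, [10.0, 5.0, 5.0, 10.0])

    def test_delay_shifts_indicator(self, rng):
        raw = UniformSeries(dt=1 / FS, values=rng.normal(0, 1.0, 4096))
        d0 = make_chemical_input(raw, threshold=1e-3)
        d9 = make_chemical_input(raw, threshold=1e-3, delay_samples=9)
        assert np.array_equal(d9.pi_c.values[9:], d0.pi_c.values[:-9])


class TestRecruitmentAlpha:
    def make(self, p_vals, pi_vals):
        p = UniformSeries(dt=0.01, values=np.asarray(p_vals, float))
        pi = UniformSeries(dt=0.01, values=np.asarray(pi_vals, float))
        return p, pi

    def test_continuous_returns_p(self):
        p, pi = self.make([0.4] * 6, [0, 1, 1, 1, 0, 0])
        out = recruitment_alpha(p, pi, "continuous")
        assert np.array_equal(out.values, p.values)

    def test_hold_modes_against_index_scan_oracle(self, rng):
        n = 400
        p_vals = np.clip(rng.uniform(0, 1, n), 0, 1)
        pi_vals = (rng.uniform(size=n) < 0.6).astype(float)
        p, pi = self.make(p_vals, pi_vals)
        onset = recruitment_alpha(p, pi, "hold_at_onset").values
        phase_max = recruitment_alpha(p, pi, "hold_phase_max").values
        # oracle: explicit index scan over contraction runs
        expect_onset = p_vals.copy()
        expect_max = p_vals.copy()
        i = 0
        while i < n:
            if pi_vals[i] == 1.0:
                j = i
                while j < n and pi_vals[j] == 1.0:
                    j += 1
                expect_onset[i:j] = p_vals[i]
                expect_max[i:j] = p_vals[i:j].max()
                i = j
            else:
                i += 1
        assert np.array_equal(onset, expect_onset)
        assert np.array_equal(phase_max, expect_max)

    def test_ramp_hold_max_freezes_at_one(self):
        p, pi = self.make(np.linspace(0, 1, 10), np.ones(10))
        out = recruitment_alpha(p, pi, "hold_phase_max")
        assert np.allclose(out.values, 1.0)

    def test_length_mismatch_rejected(self):
        p = UniformSeries(dt=0.01, values=np.zeros(5))
        pi = UniformSeries(dt=0.01, values=np.zeros(6))
        with pytest.raises(ValueError, match="time base"):
            recruitment_alpha(p, pi)


class TestPhysioRhs:
    def test_contraction_onset_signs(self, physio_gas):
        kdot, fdot, edot = physio_rhs(
            PhysioState(0.0, 0.0, 0.0), 5.0, 1.0, 0.5, 0.0, physio_gas
        )
        assert edot < 0  # CE starts shortening against the tendon
        assert kdot > 0 and fdot > 0

    def test_rigid_tendon_relaxation_is_pure_exponential(self, gas):
        pp = PhysioParams.from_muscle(gas, kt=gas.kt * 1e6)
        state = PhysioState(kc=1000.0, Fc=500.0, eps_c=0.0)
        kdot, fdot, edot = physio_rhs(state, pp.Ur, 0.0, 0.3, 0.0, pp)
        assert abs(edot) < 1e-4
        assert fdot == pytest.approx(-pp.Ur * state.Fc, rel=1e-3)

    def test_strain_rate_sign_self_consistency(self, physio_gas, rng):
        """sign(edot) equals sign of the numerator T for random valid states."""
        for _ in range(10_000):
            state = PhysioState(
                kc=rng.uniform(0, physio_gas.km0),
                Fc=rng.uniform(0, physio_gas.Fm0),
                eps_c=rng.uniform(-0.2, 0.1),
            )
            u = rng.choice([5.0, 10.0])
            pi = float(u == 5.0)
            al = rng.uniform(0, 1)
            kdot, fdot, edot = physio_rhs(state, u, pi, al, 0.0, physio_gas)
            T = state.Fc * u - al * physio_gas.Fm0 * np.exp(
                -((state.eps_c / physio_gas.b) ** 2)
            ) * pi * physio_gas.Uc
            assert np.sign(edot) == np.sign(T) or T == 0

    def test_denominator_violation_raises(self, gas):
        pp = PhysioParams.from_muscle(gas, kt=1.0)
        with pytest.raises(RuntimeError, match="stability"):
            physio_rhs(PhysioState(0.0, 5000.0, 0.0), 5.0, 1.0, 1.0, 0.0, pp)


def step_drive(dt, n, n_on, Uc=5.0, Ur=10.0):
    pi = UniformSeries(dt=dt, values=np.r_[np.ones(n_on), np.zeros(n - n_on)])
    return chemical_drive_from_indicator(pi, Uc=Uc, Ur=Ur)


class TestSimulatePhysio:
    def test_zero_recruitment_stays_at_rest(self, physio_gas):
        drive = step_drive(1e-3, 500, 500)
        alpha = UniformSeries(dt=1e-3, values=np.zeros(500))
        tr = simulate_physio(drive, alpha, physio_gas)
        assert np.array_equal(tr.Fc.values, np.zeros(500))
        assert np.array_equal(tr.kc.values, np.zeros(500))

    def test_rigid_tendon_rise_and_decay_closed_form(self, gas):
        """kt x1000: Fc(t) = 0.6 Fm0 (1 - e^{-Uc t}), then Ur decay."""
        pp = PhysioParams.from_muscle(gas, kt=gas.kt * 1000)
        dt, n, n_on = 1e-3, 4001, 2000
        drive = step_drive(dt, n, n_on)
        alpha = UniformSeries(dt=dt, values=np.full(n, 0.6))
        tr = simulate_physio(drive, alpha, pp, dt_int=dt)
        t = tr.Fc.times
        rise = 0.6 * pp.Fm0 * (1 - np.exp(-pp.Uc * t[:n_on]))
        mask = rise > 0.01 * pp.Fm0
        assert np.max(np.abs(tr.Fc.values[:n_on][mask] - rise[mask]) / rise[mask]) < 5e-3
        f1 = 0.6 * pp.Fm0 * (1 - np.exp(-pp.Uc * t[n_on]))
        decay = f1 * np.exp(-pp.Ur * (t[n_on:] - t[n_on]))
        mask = decay > 0.01 * pp.Fm0
        rel = np.abs(tr.Fc.values[n_on:][mask] - decay[mask]) / decay[mask]
        assert np.max(rel) < 5e-3

    def test_steady_force_proportional_to_alpha_rigid_tendon(self, gas):
        pp = PhysioParams.from_muscle(gas, kt=gas.kt * 1000)
        dt, n = 1e-3, 3001
        drive = step_drive(dt, n, n)
        steady = []
        for al in (0.25, 0.5, 1.0):
            alpha = UniformSeries(dt=dt, values=np.full(n, al))
            steady.append(simulate_physio(drive, alpha, pp, dt_int=dt).Fc.values[-1])
        assert steady[1] / steady[0] == pytest.approx(2.0, rel=1e-3)
        assert steady[2] / steady[1] == pytest.approx(2.0, rel=1e-3)

    def test_force_nonnegative_throughout(self, physio_gas, rng):
        dt, n = 1e-3, 2000
        pi = UniformSeries(dt=dt, values=(rng.uniform(size=n) < 0.5).astype(float))
        drive = chemical_drive_from_indicator(pi)
        alpha = UniformSeries(dt=dt, values=rng.uniform(0, 1, n))
        tr = simulate_physio(drive, alpha, physio_gas)
        assert tr.Fc.values.min() >= 0.0
        assert tr.kc.values.min() >= 0.0


class TestIsotonicForceVelocity:
    def test_isometric_limit(self, physio_gas):
        (v, fc), = isotonic_force_velocity(physio_gas, kc0=0.0, alpha=0.8, velocity_grid=[0.0])
        assert fc == pytest.approx(0.8 * physio_gas.Fm0)

    def test_monotone_decreasing_in_speed(self, physio_gas):
        grid = np.linspace(0.0, -0.8 * physio_gas.Uc, 10)
        out = isotonic_force_velocity(physio_gas, kc0=0.3 * physio_gas.km0, alpha=0.8, velocity_grid=grid)
        forces = [f for _, f in out]
        assert np.all(np.diff(forces) < 0)

    def test_matches_clamped_velocity_steady_state(self, gas):
        """Algebraic hyperbola vs the dynamic model run to steady state
        under a prescribed constant shortening rate (reference length)."""
        pp = PhysioParams.from_muscle(gas, b=1e6)  # freeze fl at 1
        dt, n = 1e-3, 3001
        for v in (-0.5, -1.5, -3.0):
            drive = step_drive(dt, n, n, Uc=pp.Uc, Ur=pp.Ur)
            alpha = UniformSeries(dt=dt, values=np.full(n, 0.8))
            edot = UniformSeries(dt=dt, values=np.full(n, v))
            tr = simulate_physio(drive, alpha, pp, dt_int=dt, eps_c_dot=edot)
            (_, fc_alg), = isotonic_force_velocity(pp, kc0=tr.kc.values[-1], alpha=0.8, velocity_grid=[v])
            assert tr.Fc.values[-1] == pytest.approx(fc_alg, rel=0.01)

    def test_domain_guards(self, physio_gas):
        with pytest.raises(ValueError, match="kinetic limit"):
            isotonic_force_velocity(physio_gas, 0.0, 0.5, [-physio_gas.Uc])
        with pytest.raises(ValueError, match="concentric"):
            isotonic_force_velocity(physio_gas, 0.0, 0.5, [0.5])
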