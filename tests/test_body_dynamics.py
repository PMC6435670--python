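"""5-DOF body/instrument model: assembly, frequency response, simulation."""

import dataclasses

import numpy as np
import pytest

import bcgsim as b
from bcgsim.experiments import extract_period_force
from bcgsim.force_model import ForceWaveform, compute_force_bcg


def _sine_force(amplitude, freq, dt=1e-3, duration=1.0, phase=0.0):
    t = np.arange(int(round(duration / dt))) * dt
    u = amplitude * np.cos(2 * np.pi * freq * t + phase)
    z = np.zeros_like(u)
    return ForceWaveform(time=t, total=u, ascending_component=u, descending_component=z)


class TestAssembly:
    def test_ground_row_stiffness_sums_scale_and_instrument_springs(self, system):
        # coordinate 5 carries the leg-instrument spring plus the ground spring
        assert system.K[4, 4] == pytest.approx(425.3e3 + 833.0e3)
        assert system.K[4, 4] == pytest.approx(1_258_300.0)

    def test_matrices_symmetric_positive_definite(self, system, rng):
        for M in (system.C, system.K):
            assert np.array_equal(M, M.T)
        assert np.all(np.linalg.eigvalsh(system.K) > 0)
        assert np.all(np.linalg.eigvalsh(system.C) > 0)
        # random positive parameter sets keep K positive definite
        for _ in range(5):
            factors = rng.uniform(0.2, 5.0, size=17)
            params = b.BodyParameters()
            for name, f in zip(
                ("m1", "m2", "m3", "m4", "m5", "k12", "k13", "k14", "k34", "k45",
                 "c12", "c13", "c14", "c34", "c45", "k5", "c5"),
                factors,
            ):
                params = params.with_value(name, getattr(params, name) * f)
            K = b.assemble(params).K
            assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_removing_ground_spring_makes_stiffness_singular(self, body, system):
        nearly_free = b.assemble(body.with_value("k5", 1e-9))
        assert np.min(np.linalg.eigvalsh(nearly_free.K)) < 1e-3
        assert np.min(np.linalg.eigvalsh(system.K)) > 1e2

    def test_config_reader_converts_printed_stiffness_units(self):
        params = b.body_dynamics.read_body_config({"k5": 833.0, "m1": 9.0, "c5": 722})
        assert params.k5 == pytest.approx(833.0e3)
        assert params.m1 == 9.0 and params.c5 == 722.0


class TestFrequencyResponse:
    def test_static_gain_is_reciprocal_ground_stiffness(self, system, body):
        H0 = b.frequency_response(system, "scale_disp", np.array([0.0]))[0]
        assert abs(H0 - 1.0 / body.k5) <= 1e-12 * abs(1.0 / body.k5)
        assert H0.real == pytest.approx(1.20048e-6, rel=1e-5)

    def test_acceleration_static_gain_is_exactly_zero(self, system):
        assert b.frequency_response(system, "wrist_acc", np.array([0.0]))[0] == 0.0

    def test_static_solve_determines_all_dc_gains(self, system, body):
        # every coordinate's DC gain comes from K^-1, not assumption
        x = np.linalg.solve(system.K, system.input_map)
        Hs = b.frequency_response(system, "scale_disp", np.array([0.0]))[0]
        Hw = b.frequency_response(system, "wrist_disp", np.array([0.0]))[0]
        assert Hs.real == pytest.approx(x[4], rel=1e-12)
        assert Hw.real == pytest.approx(x[1], rel=1e-12)
        # the load path compresses the intermediate springs: the wrist sits
        # above the scale statically, so the two DC gains genuinely differ
        assert Hw.real > Hs.real

    def test_matches_first_order_state_space_resolvent(self, rng):
        params = b.BodyParameters()
        for name in ("m2", "c14", "k12", "k5"):
            params = params.with_value(name, getattr(params, name) * rng.uniform(0.5, 2.0))
        sys = b.assemble(params)
        A, B = sys.first_order_matrices()
        for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
            C = sys.output_matrix(ch)
            for w in rng.uniform(0.5, 150.0, size=6):
                H = b.frequency_response(sys, ch, np.array([w]))[0]
                resolvent = np.linalg.solve(1j * w * np.eye(10) - A, B)
                H_oracle = C @ resolvent
                assert H == pytest.approx(H_oracle, rel=1e-9)


class TestTimeSimulation:
    def test_zero_force_zero_response(self, system):
        force = _sine_force(0.0, 1.0)
        out = b.simulate_time(system, force)
        for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
            assert np.max(np.abs(out.channel(ch))) == 0.0

    def test_constant_force_settles_to_static_deflection(self, system, body):
        t = np.arange(12000) * 1e-3
        u = np.full_like(t, 2.0)
        force = ForceWaveform(time=t, total=u, ascending_component=u, descending_component=np.zeros_like(u))
        out = b.simulate_time(system, force)
        assert out.scale_displacement[-1] == pytest.approx(2.0 / body.k5, rel=1e-6)
        assert out.wrist_acceleration[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_adaptive_ode_oracle(self, system, geometry, body):
        gen = dataclasses.replace(b.BPGeneratorParams(), n_beats=4)
        force = compute_force_bcg(b.generate_bp_set(gen), geometry)
        zoh = b.simulate_time(system, force)
        oracle = b.ode_oracle(system, force)
        n = int(round(gen.period / gen.dt))
        for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
            a, o = zoh.channel(ch)[n:], oracle.channel(ch)[n:]
            rel_rms = np.sqrt(np.mean((a - o) ** 2)) / np.sqrt(np.mean(a**2))
            assert rel_rms < 1e-6

    def test_impulse_response_decays(self, system):
        t = np.arange(8000) * 1e-3
        u = np.zeros_like(t)
        u[:5] = 50.0
        force = ForceWaveform(time=t, total=u, ascending_component=u, descending_component=np.zeros_like(u))
        out = b.ode_oracle(system, force, rtol=1e-6, atol=1e-12)
        assert abs(out.scale_displacement[-1]) < 1e-9
        assert abs(out.wrist_acceleration[-1]) < 1e-6

    def test_undamped_system_conserves_energy(self, body):
        sys = b.assemble(body)
        undamped = dataclasses.replace(sys, C=np.zeros((5, 5)))
        t = np.arange(3000) * 1e-3
        u = np.zeros_like(t)
        u[:3] = 100.0  # short kick, then free conservative motion
        force = ForceWaveform(time=t, total=u, ascending_component=u, descending_component=np.zeros_like(u))
        A, B = undamped.first_order_matrices()
        from scipy.integrate import solve_ivp

        def rhs(tt, x):
            k = min(int(tt / 1e-3), len(u) - 1)
            return A @ x + B * u[k]

        sol = solve_ivp(rhs, (0, t[-1]), np.zeros(10), t_eval=t, rtol=1e-10, atol=1e-14, max_step=1e-3)
        q, qd = sol.y[:5], sol.y[5:]
        energy = 0.5 * np.einsum("it,ij,jt->t", q, undamped.K, q) + 0.5 * np.einsum(
            "it,ij,jt->t", qd, undamped.M, qd
        )
        after_kick = energy[10:]
        assert np.ptp(after_kick) / np.mean(after_kick) < 1e-5

    def test_superposition_of_responses(self, system, bp_set, geometry):
        force = compute_force_bcg(bp_set, geometry)
        one = extract_period_force(force, bp_set.period)
        asc = ForceWaveform(one.time, one.ascending_component, one.ascending_component, np.zeros_like(one.total))
        desc = ForceWaveform(one.time, one.descending_component, np.zeros_like(one.total), one.descending_component)
        alpha, beta = 2.0, -0.7
        mix = ForceWaveform(
            one.time,
            alpha * asc.total + beta * desc.total,
            alpha * asc.total,
            beta * desc.total,
        )
        out_mix = b.simulate_time(system, mix)
        out_a = b.simulate_time(system, asc)
        out_d = b.simulate_time(system, desc)
        for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
            lhs = out_mix.channel(ch)
            rhs = alpha * out_a.channel(ch) + beta * out_d.channel(ch)
            scale = np.max(np.abs(lhs))
            assert np.max(np.abs(lhs - rhs)) < 1e-10 * scale

    def test_wrist_acceleration_is_second_difference_of_displacement(self, system, steady_beat):
        out = steady_beat.outputs
        dt = 1e-3
        d2 = (np.roll(out.wrist_displacement, -1) - 2 * out.wrist_displacement + np.roll(out.wrist_displacement, 1)) / dt**2
        err = np.sqrt(np.mean((d2 - out.wrist_acceleration) ** 2)) / np.sqrt(np.mean(out.wrist_acceleration**2))
        assert err < 5e-3  # O(dt^2) discretization error


class TestPeriodicSteadyState:
    def test_single_harmonic_matches_transfer_gain(self, system):
        freq = 1.0
        force = _sine_force(1.5, freq)
        out = b.simulate_periodic(system, force, 1.0)
        w = 2 * np.pi * freq
        for ch in ("scale_disp", "wrist_acc"):
            H = b.frequency_response(system, ch, np.array([w]))[0]
            y = out.channel(ch)
            amp = np.ptp(y) / 2
            assert amp == pytest.approx(1.5 * abs(H), rel=1e-3)  # hold-equivalent gain, O(dt) off continuous
            phase_err = abs(np.angle(np.fft.rfft(y)[1] / H))
            assert phase_err < 2 * np.pi * freq * 1e-3

    def test_dc_only_force_reproduces_static_gain(self, system, body):
        t = np.arange(1000) * 1e-3
        u = np.full_like(t, 3.0)
        force = ForceWaveform(t, u, u, np.zeros_like(u))
        out = b.simulate_periodic(system, force, 1.0)
        assert np.allclose(out.scale_displacement, 3.0 / body.k5, rtol=1e-9)
        assert np.allclose(out.wrist_acceleration, 0.0, atol=1e-12)

    def test_equals_long_run_limit_of_time_simulation(self, system, geometry, body):
        gen = dataclasses.replace(b.BPGeneratorParams(), n_beats=10)
        force = compute_force_bcg(b.generate_bp_set(gen), geometry)
        full = b.simulate_time(system, force)
        one = extract_period_force(force, gen.period)
        ss = b.simulate_periodic(system, one, gen.period)
        n = len(one.total)
        for ch in ("scale_disp", "wrist_disp", "wrist_acc"):
            a, s = full.channel(ch)[-n:], ss.channel(ch)
            rel_rms = np.sqrt(np.mean((a - s) ** 2)) / np.sqrt(np.mean(s**2))
            assert rel_rms < 1e-5

    def test_non_integer_period_rejected(self, system):
        force = _sine_force(1.0, 1.0)
        with pytest.raises(ValueError):
            b.simulate_periodic(system, force, 0.99955)


class TestStability:
    def test_all_modes_strictly_damped(self, system):
        A, _ = system.first_order_matrices()
        assert np.max(np.linalg.eigvals(A).real) < 0

    def test_rigid_instrument_limit_reduces_to_grounded_body(self, body):
        # stiff, heavily damped, massless instrument: m4 behaves as if k45 went to ground
        limit = (
            body.with_value("k5", body.k5 * 1e6)
            .with_value("c5", body.c5 * 1e6)
            .with_value("m5", body.m5 * 1e-6)
        )
        sys5 = b.assemble(limit)
        omega = np.array([2 * np.pi * 3.0])
        Z = -(omega[0] ** 2) * sys5.M + 1j * omega[0] * sys5.C + sys5.K
        x5 = np.linalg.solve(Z, sys5.input_map)
        # 4-DOF oracle built directly: coordinates 1..4, k45/c45 grounded at m4
        base = b.assemble(body)
        M4, C4, K4 = base.M[:4, :4].copy(), base.C[:4, :4].copy(), base.K[:4, :4].copy()
        Z4 = -(omega[0] ** 2) * M4 + 1j * omega[0] * C4 + K4
        x4 = np.linalg.solve(Z4, sys5.input_map[:4])
        assert x5[3] == pytest.approx(x4[3], rel=1e-3)
        # and the scale itself no longer moves
        assert abs(x5[4]) < 1e-3 * abs(x5[3])
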