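"""Ground-truth laws, simulator, kinematics and noise injection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from newtongn import (
    SystemSpec,
    add_position_noise,
    differenced,
    finite_difference_kinematics,
    integrate,
    lj_pair,
    minimum_image,
    pairwise_force,
    pairwise_potential,
    sample_initial_state,
)
from newtongn.systems import ParticleState, net_forces


def _random_pair(rng, d, min_sep=0.3):
    while True:
        r_i, r_j = rng.normal(size=(2, d))
        if np.linalg.norm(r_j - r_i) > min_sep:
            return r_i, r_j


class TestPairLaws:
    @pytest.mark.parametrize(
        "law,kwargs,r_j,expected",
        [
            # separation at rest length -> no spring force
            ("spring", {}, (1.0, 0.0), (0.0, 0.0)),
            # direct evaluation of k (r - L) n with k=2, L=1, r=2
            ("spring", {}, (2.0, 0.0), (2.0, 0.0)),
            # like charges repel: -c q_i q_j n / (r + delta)^2
            ("charge", {"q_i": 1.0, "q_j": 1.0}, (1.0, 0.0), (-1.0 / 1.01**2, 0.0)),
            # zero branch strictly below the threshold
            ("discnt", {}, (1.5, 0.0), (0.0, 0.0)),
        ],
    )
    def test_force_closed_forms(self, law, kwargs, r_j, expected):
        spec = SystemSpec(law=law, d=2)
        F = pairwise_force(spec, np.zeros(2), np.array(r_j), **kwargs)
        np.testing.assert_allclose(F, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "law,kwargs,r,expected",
        [
            ("spring", {}, 1.0, 0.0),
            # m_i m_j ln(r + delta) at r=1
            ("orbital", {"m_i": 1.0, "m_j": 1.0}, 1.0, np.log(1.01)),
            ("discnt", {}, 1.9, 0.0),
        ],
    )
    def test_potential_closed_forms(self, law, kwargs, r, expected):
        spec = SystemSpec(law=law, d=2)
        P = pairwise_potential(spec, np.zeros(2), np.array([r, 0.0]), **kwargs)
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_antisymmetry_and_potential_symmetry(self, rng):
        for law in ("spring", "charge", "orbital", "discnt"):
            spec = SystemSpec(law=law, d=2)
            for _ in range(20):
                r_i, r_j = _random_pair(rng, 2)
                q = rng.uniform(-1, 1, 2)
                m = np.exp(rng.uniform(-1, 1, 2))
                kw = dict(q_i=q[0], q_j=q[1], m_i=m[0], m_j=m[1])
                kw_swap = dict(q_i=q[1], q_j=q[0], m_i=m[1], m_j=m[0])
                F_ij = pairwise_force(spec, r_i, r_j, **kw)
                F_ji = pairwise_force(spec, r_j, r_i, **kw_swap)
                np.testing.assert_allclose(F_ij, -F_ji, rtol=0, atol=1e-14)
                P_ij = pairwise_potential(spec, r_i, r_j, **kw)
                P_ji = pairwise_potential(spec, r_j, r_i, **kw_swap)
                assert P_ij == pytest.approx(P_ji, abs=1e-14)

    def test_force_is_negative_potential_gradient(self, rng):
        """Central-difference check that F = -dP/dr_i for every law."""
        h = 1e-6
        for law in ("spring", "charge", "orbital", "discnt"):
            spec = SystemSpec(law=law, d=2)
            for _ in range(10):
                r_i, r_j = _random_pair(rng, 2, min_sep=0.5)
                if law == "discnt" and abs(np.linalg.norm(r_j - r_i) - 2.0) < 0.05:
                    continue  # stay away from the discontinuity
                kw = dict(q_i=0.7, q_j=-0.4, m_i=1.3, m_j=0.8)
                F = pairwise_force(spec, r_i, r_j, **kw)
                grad = np.empty(2)
                for k in range(2):
                    dr = np.zeros(2)
                    dr[k] = h
                    grad[k] = (
                        pairwise_potential(spec, r_i + dr, r_j, **kw)
                        - pairwise_potential(spec, r_i - dr, r_j, **kw)
                    ) / (2 * h)
                np.testing.assert_allclose(F, -grad, rtol=1e-4, atol=1e-9)

    def test_spring_rejects_coincident_particles(self, spring_spec):
        with pytest.raises(ZeroDivisionError):
            pairwise_force(spring_spec, np.zeros(2), np.zeros(2))

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError):
            SystemSpec(law="gravity", d=2)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError):
            SystemSpec(law="spring", d=2, constants={"k": -1.0})


class TestLennardJones:
    def test_zero_at_sigma_and_minimum(self, lj_spec):
        sigma = lj_spec.constants["sigma"]
        eps = lj_spec.constants["epsilon"]
        V, _ = lj_pair(lj_spec, np.array([sigma, 0.0, 0.0]))
        assert V == pytest.approx(0.0, abs=1e-12)
        r_min = 2 ** (1 / 6) * sigma
        V, F = lj_pair(lj_spec, np.array([r_min, 0.0, 0.0]))
        assert V == pytest.approx(-eps, rel=1e-12)
        np.testing.assert_allclose(F, 0.0, atol=1e-12)

    def test_force_matches_potential_gradient(self, lj_spec, rng):
        sigma = lj_spec.constants["sigma"]
        h = 1e-6 * sigma
        for _ in range(25):
            r = rng.uniform(0.9 * sigma, 3 * sigma)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            disp = r * direction
            _, F = lj_pair(lj_spec, disp)
            # radial derivative of V via central differences
            Vp, _ = lj_pair(lj_spec, (r + h) * direction)
            Vm, _ = lj_pair(lj_spec, (r - h) * direction)
            dVdr = (Vp - Vm) / (2 * h)
            # force on i is +dV/dr along n_ij
            np.testing.assert_allclose(F, dVdr * direction, rtol=1e-5)

    def test_exact_zero_beyond_cutoff(self, lj_spec, rng):
        r_cut = lj_spec.constants["r_cut"]
        for _ in range(10):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            V, F = lj_pair(lj_spec, direction * r_cut * 1.0001)
            assert V == 0.0
            assert np.all(F == 0.0)

    def test_zero_displacement_rejected(self, lj_spec):
        with pytest.raises(ZeroDivisionError):
            lj_pair(lj_spec, np.zeros(3))


class TestMinimumImage:
    def test_wrap_cases(self):
        np.testing.assert_allclose(
            minimum_image(np.array([0.5]), np.array([9.5]), 10.0), [-1.0]
        )
        np.testing.assert_allclose(
            minimum_image(np.ones(3), np.ones(3), 5.0), np.zeros(3)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(1.0, 20.0)
        d = int(rng.integers(1, 4))
        r_i = rng.uniform(0, box, d)
        r_j = rng.uniform(0, box, d)
        wrapped = minimum_image(r_i, r_j, box)
        shifts = np.array(np.meshgrid(*[[-1, 0, 1]] * d)).reshape(d, -1).T * box
        candidates = (r_j - r_i)[None, :] + shifts
        best = candidates[np.argmin(np.linalg.norm(candidates, axis=1))]
        assert np.linalg.norm(wrapped) <= np.linalg.norm(best) + 1e-12
        assert np.linalg.norm(wrapped) <= np.sqrt(d) / 2 * box


class TestSampling:
    def test_mass_bounds_and_determinism(self, spring_spec):
        s1 = sample_initial_state(50, spring_spec, seed=7)
        s2 = sample_initial_state(50, spring_spec, seed=7)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.masses, s2.masses)
        assert s1.masses.min() >= np.exp(-1) and s1.masses.max() <= np.exp(1)
        assert np.all(np.abs(s1.charges) <= 1.0)

    def test_large_sample_statistics(self, spring_spec):
        n = 10**5
        state = sample_initial_state(n, spring_spec, seed=11)
        tol = 3.0 / np.sqrt(n)
        assert np.all(np.abs(state.positions.mean(axis=0)) < tol)
        assert np.all(np.abs(state.velocities.mean(axis=0)) < tol)
        # log-masses should be uniform on [-1, 1]: check mean and variance
        logm = np.log(state.masses)
        assert abs(logm.mean()) < tol
        assert abs(logm.var() - 1.0 / 3.0) < 0.01

    def test_lj_sampling_in_box(self, lj_spec):
        state = sample_initial_state(64, lj_spec, seed=3)
        box = lj_spec.constants["box_length"]
        assert np.all((state.positions >= 0) & (state.positions <= box))
        assert np.all(state.masses == lj_spec.constants["mass"])

    def test_too_few_particles_rejected(self, spring_spec):
        with pytest.raises(ValueError):
            sample_initial_state(1, spring_spec)


class TestIntegration:
    def test_two_body_spring_matches_harmonic_solution(self):
        """Equal masses from rest: separation is L + (s0 - L) cos(w t)."""
        spec = SystemSpec(law="spring", d=2)
        k = spec.constants["k"]
        L = spec.constants["L"]
        m = 1.0
        s0 = 1.6
        state = ParticleState(
            positions=np.array([[0.0, 0.0], [s0, 0.0]]),
            velocities=np.zeros((2, 2)),
            charges=np.zeros(2),
            masses=np.full(2, m),
        )
        omega = np.sqrt(2 * k / m)
        dt = 0.001
        period = 2 * np.pi / omega
        n_steps = int(period / dt) + 1
        traj = integrate(state, spec, n_steps, dt=dt)
        sep = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
        t = np.arange(n_steps) * dt
        expected = L + (s0 - L) * np.cos(omega * t)
        assert np.max(np.abs(sep - expected)) / (s0 - L) < 1e-3

    def test_momentum_conservation(self, rng):
        for law in ("spring", "charge", "orbital"):
            spec = SystemSpec(law=law, d=2)
            state = sample_initial_state(6, spec, seed=5)
            traj = integrate(state, spec, 200, dt=0.01)
            p = (traj.masses[None, :, None] * traj.velocities).sum(axis=1)
            drift = np.abs(p - p[0]).max()
            assert drift < 200 * 1e-10

    def test_energy_drift_bounded_with_velocity_verlet(self):
        """Symplectic integration keeps total spring energy within 1%."""
        spec = SystemSpec(law="spring", d=2)
        state = sample_initial_state(8, spec, seed=2)
        traj = integrate(state, spec, 10_000, dt=0.01)
        energies = []
        for t in (0, traj.n_steps - 1):
            kin = 0.5 * (traj.masses * (traj.velocities[t] ** 2).sum(axis=1)).sum()
            pos = traj.positions[t]
            pot = 0.0
            for i in range(8):
                for j in range(i + 1, 8):
                    pot += pairwise_potential(spec, pos[i], pos[j])
            energies.append(kin + pot)
        assert abs(energies[1] - energies[0]) <= 0.01 * abs(energies[0])

    def test_accelerations_equal_net_force_over_mass(self, rng):
        spec = SystemSpec(law="charge", d=2)
        state = sample_initial_state(5, spec, seed=9)
        traj = integrate(state, spec, 10, dt=0.01)
        for t in (0, 5, 9):
            f = net_forces(spec, traj.positions[t], traj.charges, traj.masses)
            np.testing.assert_allclose(
                traj.accelerations[t], f / traj.masses[:, None], rtol=1e-12
            )

    def test_blowup_aborts(self):
        # a grossly unstable step size amplifies the spring force every step
        spec = SystemSpec(law="spring", d=2)
        state = ParticleState(
            positions=np.array([[0.0, 0.0], [5.0, 0.0]]),
            velocities=np.zeros((2, 2)),
            charges=np.zeros(2),
            masses=np.full(2, 1e-3),
        )
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError):
                integrate(state, spec, 2000, dt=100.0)

    def test_lj_positions_wrapped_and_finite(self, lj_spec):
        state = sample_initial_state(32, lj_spec, seed=4)
        traj = integrate(state, lj_spec, 50, dt=0.5, thermostat="langevin", seed=8)
        box = lj_spec.constants["box_length"]
        assert np.all((traj.positions >= 0) & (traj.positions < box))


class TestKinematics:
    def test_uniform_motion_exact(self):
        t = np.arange(10)[:, None, None]
        v = np.array([[1.5, -2.0]])
        pos = v[None] * t
        vel, acc = finite_difference_kinematics(pos, dt=1.0)
        np.testing.assert_allclose(vel, np.broadcast_to(v, vel.shape))
        np.testing.assert_allclose(acc, 0.0, atol=1e-14)

    def test_quadratic_exact(self):
        t = np.arange(20) * 0.1
        pos = (t**2)[:, None, None]
        vel, acc = finite_difference_kinematics(pos, dt=0.1)
        np.testing.assert_allclose(acc, 2.0, rtol=1e-9)

    def test_sine_second_order_accurate(self):
        dt = 1e-3
        t = np.arange(1000) * dt
        pos = np.sin(t)[:, None, None]
        _, acc = finite_difference_kinematics(pos, dt=dt)
        np.testing.assert_allclose(acc[:, 0, 0], -np.sin(t[1:-1]), atol=1e-5)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            finite_difference_kinematics(np.zeros((2, 1, 1)), dt=0.1)

    def test_periodic_differencing_survives_boundary_crossings(self, lj_spec):
        """Wrapped coordinates must be differenced under minimum image;
        the result should track the integrator's recorded accelerations."""
        state = sample_initial_state(24, lj_spec, seed=13)
        traj = integrate(state, lj_spec, 60, dt=0.02)
        fd = differenced(traj)
        scale = np.abs(traj.accelerations).sum(-1).mean()
        err = np.abs(fd.accelerations - traj.accelerations[1:-1]).sum(-1).mean()
        assert err < 0.05 * scale


class TestNoise:
    @pytest.fixture
    def traj(self, spring_spec):
        state = sample_initial_state(8, spring_spec, seed=1)
        return integrate(state, spring_spec, 300, dt=0.01)

    def test_zero_noise_is_plain_differencing(self, traj):
        noisy = add_position_noise(traj, 0.0, seed=3)
        clean = differenced(traj)
        np.testing.assert_array_equal(noisy.positions, clean.positions)
        np.testing.assert_array_equal(noisy.accelerations, clean.accelerations)
        assert noisy.provenance == "noisy"

    def test_seed_determinism(self, traj):
        a = add_position_noise(traj, 0.01, seed=5)
        b = add_position_noise(traj, 0.01, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_noise_magnitude_tracks_position_spread(self, traj):
        scale = 0.01
        noisy = add_position_noise(traj, scale, seed=7)
        delta = noisy.positions - traj.positions[1:-1]
        target = scale * traj.positions.std(axis=(0, 1))
        observed = delta.std(axis=(0, 1))
        assert np.all(np.abs(observed - target) < 0.05 * target)
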