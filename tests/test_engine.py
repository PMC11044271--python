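"""Toy engine: scaled-energy decomposition, forces, dynamics, restraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swishx.engine import (
    ContactWall,
    GatedCavitySpec,
    InterprobeRepulsion,
    LangevinParams,
    LangevinState,
    OverlapError,
    PairTable,
    ParticleSystem,
    RestraintSet,
    build_gated_cavity_system,
    compute_forces,
    compute_scaled_energy,
    contact_map_cv,
    energy_and_forces,
    langevin_step,
    upper_wall_energy,
)
from swishx.switching import rational_switch


class TestScaledEnergy:
    def test_lambda_one_equals_unscaled_sum(self, random_mixed_system):
        h = compute_scaled_energy(random_mixed_system, 1.0)
        assert h.total_nonbonded == pytest.approx(h.u_ww + h.u_ws + h.u_ss, rel=1e-14)

    def test_linear_scaling_of_ws_pair(self, ws_pair):
        # the pair sits at the LJ minimum: unscaled energy is -eps + shift
        h1 = compute_scaled_energy(ws_pair, 1.0)
        h = compute_scaled_energy(ws_pair, 1.2)
        assert h.total_nonbonded == pytest.approx(1.2 * h1.u_ws, rel=1e-12)
        assert h1.u_ww == 0.0 and h1.u_ss == 0.0

    def test_solute_only_system_independent_of_lambda(self):
        sys_ = ParticleSystem(
            positions=np.array([[0, 0, 0], [1.2, 0, 0], [0, 1.3, 0.2]]),
            roles=["solute_apolar", "solute_polar", "solute_apolar"],
            pair_params=PairTable.uniform(),
        )
        totals = {
            lam: compute_scaled_energy(sys_, lam).total_nonbonded
            for lam in (0.5, 1.0, 1.35)
        }
        assert len(set(totals.values())) == 1

    def test_polar_solvent_pairs_not_scaled(self):
        sys_ = ParticleSystem(
            positions=np.array([[0, 0, 0], [1.1, 0, 0]]),
            roles=["solvent", "solute_polar"],
            pair_params=PairTable.uniform(),
        )
        h = compute_scaled_energy(sys_, 1.35)
        assert h.u_ws == 0.0
        assert h.u_ss != 0.0

    @given(lam=st.floats(0.0, 2.0), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_decomposition_identity(self, lam, seed):
        """total(lam) - total(1) == (lam-1) * U_ws to machine precision."""
        rng = np.random.default_rng(seed)
        pos = []
        while len(pos) < 8:
            cand = rng.uniform(-3, 3, 3)
            if all(np.linalg.norm(cand - p) > 0.8 for p in pos):
                pos.append(cand)
        sys_ = ParticleSystem(
            positions=np.array(pos),
            roles=rng.integers(0, 4, 8),
            pair_params=PairTable.uniform(),
        )
        h1 = compute_scaled_energy(sys_, 1.0)
        h = compute_scaled_energy(sys_, lam)
        lhs = h.total_nonbonded - h1.total_nonbonded
        rhs = (lam - 1.0) * h.u_ws
        assert lhs == pytest.approx(rhs, abs=1e-10 * max(1.0, abs(h1.total_nonbonded)))

    def test_nonfinite_positions_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ParticleSystem(
                positions=np.array([[0, 0, 0], [np.nan, 0, 0]]),
                roles=["solvent", "solvent"],
                pair_params=PairTable.uniform(),
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            ParticleSystem(
                positions=np.zeros((1, 3)),
                roles=["plasma"],
                pair_params=PairTable.uniform(),
            )


class TestForces:
    def test_zero_force_at_pair_minimum(self, ws_pair):
        f = compute_forces(ws_pair, 1.0)
        assert np.abs(f).max() <= 1e-8

    def test_net_force_zero_isolated(self, random_mixed_system):
        f = compute_forces(random_mixed_system, 1.2)
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_finite_difference_gradient(self, random_mixed_system):
        lam = 1.2
        restr = RestraintSet(
            contact_wall=ContactWall(
                pairs=[(0, 3), (1, 4)], r0=1.5, w_max=0.1, kappa=4.0
            ),
            interprobe_repulsion=InterprobeRepulsion(d_rep=3.0, k_rep=2.0),
        )
        _, f = energy_and_forces(random_mixed_system, lam, restr)
        eps = 1e-6
        for i in (0, 3, 7):
            for d in range(3):
                p = random_mixed_system.positions.copy()
                p[i, d] += eps
                up, _ = energy_and_forces(random_mixed_system, lam, restr, positions=p)
                p[i, d] -= 2 * eps
                um, _ = energy_and_forces(random_mixed_system, lam, restr, positions=p)
                fd = -(up.total - um.total) / (2 * eps)
                assert fd == pytest.approx(f[i, d], rel=1e-5, abs=1e-7)

    def test_doubling_lambda_doubles_ws_force(self, ws_pair):
        sys_ = ParticleSystem(
            positions=np.array([[0.0, 0, 0], [1.5, 0, 0]]),
            roles=["solvent", "solute_apolar"],
            pair_params=PairTable.uniform(),
        )
        f1 = compute_forces(sys_, 1.0)
        f2 = compute_forces(sys_, 2.0)
        assert np.allclose(f2, 2.0 * f1)

    def test_overlap_error_names_pair(self):
        sys_ = ParticleSystem(
            positions=np.array([[0, 0, 0], [0.1, 0, 0]]),
            roles=["solvent", "solvent"],
            pair_params=PairTable.uniform(),
        )
        with pytest.raises(OverlapError, match="0 and 1"):
            compute_forces(sys_, 1.0)


class TestLangevin:
    def test_zero_friction_energy_conservation(self):
        """gamma=0 reduces BAOAB to velocity Verlet on a harmonic dimer."""
        k = 10.0
        sys_ = ParticleSystem(
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            roles=["solute_polar", "solute_polar"],
            pair_params=PairTable.uniform(eps=0.0),
        )

        def force_fn(x):
            d = x[1] - x[0]
            r = np.linalg.norm(d)
            u = 0.5 * k * (r - 1.0) ** 2
            f = np.zeros_like(x)
            f[0] = k * (r - 1.0) * d / r
            f[1] = -f[0]
            return u, f

        params = LangevinParams(timestep=0.01, friction=0.0, temperature=1.0, seed=0)
        state = LangevinState.initialize(sys_, params)
        energies = []
        for _ in range(10_000):
            state = langevin_step(state, params, force_fn)
            ke = 0.5 * np.sum(state.velocities**2)
            energies.append(ke + state.potential)
        energies = np.array(energies)
        assert np.ptp(energies) <= 1e-3

    def test_equipartition_harmonic_well(self):
        """Sampled <x^2> = T/k for the 1-D harmonic well (k=1, T=1)."""
        params = LangevinParams(timestep=0.05, friction=1.0, temperature=1.0, seed=3)
        sys_ = ParticleSystem(
            positions=np.zeros((1, 3)),
            roles=["solute_polar"],
            pair_params=PairTable.uniform(eps=0.0),
            tether_k=np.full((1, 3), 1.0),
            tether_ref=np.zeros((1, 3)),
        )

        def force_fn(x):
            return 0.5 * float(np.sum(x**2)), -x

        state = LangevinState.initialize(sys_, params)
        xs = np.empty(200_000)
        for i in range(len(xs)):
            state = langevin_step(state, params, force_fn)
            xs[i] = state.positions[0, 0]
        assert np.var(xs[20_000:]) == pytest.approx(1.0, abs=0.05)

    def test_same_seed_bitwise_identical(self, random_mixed_system):
        params = LangevinParams(timestep=0.002, friction=1.0, temperature=1.0, seed=42)

        def run():
            state = LangevinState.initialize(random_mixed_system, params)
            fn = lambda x: (
                energy_and_forces(random_mixed_system, 1.1, positions=x)[0].total,
                energy_and_forces(random_mixed_system, 1.1, positions=x)[1],
            )
            for _ in range(50):
                state = langevin_step(state, params, fn, random_mixed_system)
            return state.positions

        assert np.array_equal(run(), run())

    def test_blowup_raises_with_advice(self):
        sys_ = ParticleSystem(
            positions=np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            roles=["solvent", "solvent"],
            pair_params=PairTable.uniform(eps=1000.0),
        )
        params = LangevinParams(timestep=5.0, friction=0.1, temperature=1.0, seed=0)
        fn = lambda x: (
            float(1e12 * np.sum(x**2)),
            -2e12 * x,
        )
        state = LangevinState.initialize(sys_, params)
        with pytest.raises(RuntimeError, match="smaller timestep"):
            for _ in range(10):
                state = langevin_step(state, params, fn)


class TestRestraints:
    def test_contact_cv_limits(self):
        pos = np.zeros((4, 3))
        pos[1] = [1e-9, 0, 0]
        sys_ = ParticleSystem(
            positions=pos,
            roles=["solvent"] * 4,
            pair_params=PairTable.uniform(eps=0.0),
        )
        wall = ContactWall(pairs=[(0, 1)], r0=1.0)
        assert contact_map_cv(sys_, wall) == pytest.approx(1.0, abs=1e-6)
        sys_.positions[1] = [500.0, 0, 0]
        assert contact_map_cv(sys_, wall) == pytest.approx(0.0, abs=1e-9)

    def test_contact_cv_three_pairs_value(self):
        """CV at r/r0 in {0.5, 1.25, 10} with n=4, m=8 matches the switch."""
        r0 = 1.0
        pos = np.array(
            [[0, 0, 0], [0.5, 0, 0], [0, 10, 0], [1.25, 10, 0], [0, 20, 0], [10.0, 20, 0]]
        )
        sys_ = ParticleSystem(
            positions=pos,
            roles=["solvent"] * 6,
            pair_params=PairTable.uniform(eps=0.0),
        )
        wall = ContactWall(pairs=[(0, 1), (2, 3), (4, 5)], r0=r0)
        expected = (
            rational_switch(0.5, r0) + rational_switch(1.25, r0) + rational_switch(10.0, r0)
        )
        assert contact_map_cv(sys_, wall) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.941176 + 0.290578 + rational_switch(10.0, r0), abs=1e-5)

    def test_empty_pair_list_rejected(self, random_mixed_system):
        with pytest.raises(ValueError, match="empty"):
            contact_map_cv(random_mixed_system, ContactWall(pairs=[]))

    def test_upper_wall_values(self):
        assert upper_wall_energy(5.0, 5.0, 3.0) == 0.0
        assert upper_wall_energy(7.0, 5.0, 3.0) == pytest.approx(6.0)
        assert upper_wall_energy(4.0, 5.0, 3.0) == 0.0

    def test_upper_wall_gradient_continuous(self):
        eps = 1e-7
        w, kap = 2.0, 3.0
        for cv in (w - 1e-3, w + 1e-3):
            fd = (upper_wall_energy(cv + eps, w, kap) - upper_wall_energy(cv - eps, w, kap)) / (2 * eps)
            analytic = kap * (cv - w) if cv > w else 0.0
            assert fd == pytest.approx(analytic, abs=1e-5)

    def test_restraint_energies_nonnegative(self, random_mixed_system):
        restr = RestraintSet(
            contact_wall=ContactWall(pairs=[(0, 1)], w_max=0.0, kappa=2.0),
            interprobe_repulsion=InterprobeRepulsion(d_rep=5.0, k_rep=1.0),
        )
        h = compute_scaled_energy(random_mixed_system, 1.0, restr)
        assert h.restraint_energy >= 0.0


class TestGatedCavity:
    def test_probe_count_zero_gives_pure_water_analog(self):
        sys_ = build_gated_cavity_system(GatedCavitySpec(n_probe=0, seed=1))
        assert np.sum(sys_.roles == 3) == 0

    def test_same_spec_same_seed_identical(self):
        a = build_gated_cavity_system(GatedCavitySpec(seed=9, n_probe=2))
        b = build_gated_cavity_system(GatedCavitySpec(seed=9, n_probe=2))
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.roles, b.roles)

    def test_zero_barrier_equal_populations(self):
        """Boltzmann check: with no barrier and no neighbors the gate's
        open/closed populations are equal (flat symmetric potential)."""
        spec = GatedCavitySpec(
            gate_barrier=0.0, n_shell=0, n_solvent=0, n_probe=0, seed=2
        )
        sys_ = build_gated_cavity_system(spec)
        from swishx.orchestrator import RunConfig, run_strategy

        cfg = RunConfig(
            n_steps=600_000, dt=0.02, seed=5, wall_enabled=False,
            equilibration_steps=0, sample_stride=5,
        )
        res = run_strategy("unbiased", spec=spec, config=cfg)
        gx = res.replicas[0].gate_x
        s = (gx - sys_.gate.x_mid) / sys_.gate.half_sep
        frac_open = np.mean(s > 0)
        ratio = frac_open / max(1e-9, 1 - frac_open)
        assert 0.9 <= ratio <= 1.1

    def test_higher_lambda_strengthens_attractive_ws(self, gated_system):
        sys_, _ = gated_system
        h1 = compute_scaled_energy(sys_, 1.0)
        h2 = compute_scaled_energy(sys_, 1.35)
        if h1.u_ws < 0:
            assert 1.35 * h1.u_ws < h1.u_ws
            assert h2.total_nonbonded < h1.total_nonbonded
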