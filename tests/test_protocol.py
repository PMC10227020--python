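import numpy as np
import pytest
from scipy.stats import spearmanr

import stressfiber as sf
from stressfiber.chemistry import bind_pair
from stressfiber.observables import overlap_distance
from stressfiber.protocol import PullSpec, apply_pull, build_stress_fiber, run
from stressfiber.state import state_to_dict, validate


class TestBuild:
    def test_default_build_arithmetic(self, default_params):
        state = build_stress_fiber(default_params)
        assert len(state.filaments) == 40
        assert sum(len(f.monomers) for f in state.filaments.values()) == 40
        # each filament seeds one full cylinder from the shared pool
        assert state.free_g_actin == 23000 - 40 * 40
        assert validate(state) == []

    def test_initial_bundles_do_not_touch(self, default_params):
        state = build_stress_fiber(default_params)
        ov, gap = overlap_distance(state)
        assert ov == 0.0 and gap

    def test_fa_sites_symmetric_about_box_centre(self, default_params):
        state = build_stress_fiber(default_params)
        z0 = state.fa_sites[0].position[2]
        z1 = state.fa_sites[1].position[2]
        assert z1 - z0 == pytest.approx(default_params.fa_separation)
        assert 0.5 * (z0 + z1) == pytest.approx(default_params.box[2] / 2.0)

    def test_anchor_lattice_geometry(self, default_params):
        """Anchors reproduce the hexagonal lattice and sit on the FA
        attachment sphere (direct recomputation)."""
        state = build_stress_fiber(default_params)
        site = state.fa_sites[0]
        anchors = np.array([state.filaments[fid].beads[0]
                            for fid in sorted(site.attached)])
        radii = np.linalg.norm(anchors - site.position, axis=1)
        np.testing.assert_allclose(radii, default_params.fa_rest_length,
                                   rtol=1e-9)
        lat = anchors[:, :2] - site.position[:2]
        d = np.linalg.norm(lat[None] - lat[:, None], axis=-1)
        nn = np.sort(d + np.eye(len(lat)) * 1e9, axis=1)[:, 0]
        assert nn.min() == pytest.approx(default_params.anchor_lattice_spacing)

    def test_too_small_box_rejected(self, default_params):
        with pytest.raises(ValueError):
            default_params.replace(box=(1000.0, 1000.0, 2800.0))

    def test_minus_ends_face_inwards(self, default_params):
        state = build_stress_fiber(default_params)
        for fid in state.bundle_filaments(0):
            f = state.filaments[fid]
            assert f.tip[2] > f.beads[0][2]
        for fid in state.bundle_filaments(1):
            f = state.filaments[fid]
            assert f.tip[2] < f.beads[0][2]


class TestRun:
    def test_zero_horizon_records_initial_frame_only(self, tiny_params):
        state = build_stress_fiber(tiny_params)
        traj = run(state, 0.0)
        assert len(traj.rows) == 1
        assert traj.rows[0]["t"] == 0.0

    def test_replay_determinism(self, tiny_params):
        def go():
            state = build_stress_fiber(tiny_params)
            return run(state, 10.0).to_dataframe()

        a, b = go(), go()
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_snapshot_continuation_matches_uninterrupted_run(self, tiny_params):
        state1 = build_stress_fiber(tiny_params)
        traj1 = run(state1, 12.0)

        state2 = build_stress_fiber(tiny_params)
        run(state2, 6.0)
        state2b = state2.copy()           # snapshot round trip mid-run
        traj2 = run(state2b, 12.0)
        end1 = state_to_dict(state1)
        # continued state matches the uninterrupted one bit-for-bit
        state1_df = traj1.to_dataframe()
        tail1 = state1_df[state1_df.t >= 7.0].reset_index(drop=True)
        tail2 = traj2.to_dataframe()
        tail2 = tail2[tail2.t >= 7.0].reset_index(drop=True)
        np.testing.assert_allclose(tail1.to_numpy(dtype=float),
                                   tail2.to_numpy(dtype=float), rtol=1e-12)

    def test_development_couples_energy_and_crosslinking(self):
        """During development E_FA and the bound-crosslinker count rise
        together (positive rank correlation, convex binned trend)."""
        p = sf.desk_scale_parameters(n_filaments_per_bundle=5, seed=3,
                                     t_measure=150.0)
        state = build_stress_fiber(p)
        traj = run(state, 220.0)
        df = traj.to_dataframe()
        rho = spearmanr(df["n_bound_linkers"], df["E_FA"]).statistic
        assert rho > 0

    def test_conservation_and_validity_after_run(self, tiny_params):
        state = build_stress_fiber(tiny_params)
        run(state, 15.0)
        assert validate(state) == []


class TestMotorToy:
    def test_single_motor_contracts_to_stall_plateau(self, default_params):
        """Two antiparallel anchored filaments with one walking motor:
        the FA energy rises monotonically (noise-free) and the motor
        tension saturates at the stall force."""
        from stressfiber.chemistry import (ChemistryEngine, motor_tension,
                                           motor_walk, motor_walk_rate)
        from stressfiber.observables import focal_adhesion_energy
        from stressfiber.state import FASite, Filament, SystemState

        p = default_params.replace(n_motor=1, n_crosslinker=0,
                                   k_off_motor=1e-12, motor_spring_k=2.5)
        state = SystemState(p)
        x0, y0 = 500.0, 500.0
        L = 1000.0
        # filaments overlap over most of their length, 30 nm apart laterally
        a0 = np.array([x0, y0, 2000.0])
        b0 = np.array([x0 + 30.0, y0, 3100.0])
        state.fa_sites = [FASite(0, a0 - [0, 0, 100.0]),
                          FASite(1, b0 + [0, 0, 100.0])]
        for side, start, sign in ((0, a0, 1.0), (1, b0, -1.0)):
            fid = state.new_id()
            n_cyl = 10
            beads = np.array([start + [0, 0, sign * 108.0 * k]
                              for k in range(n_cyl + 1)])
            state.filaments[fid] = Filament(fid, beads, [40] * n_cyl,
                                            attachment=side)
            state.fa_sites[side].attached.append(fid)
        state.total_actin = state.free_g_actin + state.polymerized_monomers()
        f0, f1 = sorted(state.filaments)
        # motor spanning the overlap, near its rest length (200 nm axially)
        mid = bind_pair(state, "motor", (f0, 6), (f1, 6))
        assert state.spring_length(state.motors[mid]) < 250.0

        energies = [focal_adhesion_energy(state)]
        for _ in range(120):
            m = state.motors[mid]
            F = motor_tension(state, m)
            if motor_walk_rate(F, p) <= 0:
                break
            motor_walk(state, mid, 0)
            motor_walk(state, mid, 1)
            sf.minimize(state, force_tol=0.05)
            energies.append(focal_adhesion_energy(state))
        final_tension = motor_tension(state, state.motors[mid])
        # stalls at F_stall, with at most one discrete-step overshoot
        overshoot = 2 * p.motor_spring_k * p.motor_step
        assert final_tension <= p.F_stall + overshoot
        assert final_tension > 0.5 * p.F_stall
        diffs = np.diff(energies)
        assert energies[-1] > 100.0 * max(energies[0], 1e-9)
        # monotone rise up to small elastic-relaxation wiggles
        assert np.all(diffs > -0.01 * max(energies))


@pytest.fixture(scope="module")
def small_equilibrated_fiber():
    p = sf.desk_scale_parameters(n_filaments_per_bundle=5, seed=8,
                                 t_measure=150.0)
    state = build_stress_fiber(p)
    run(state, 200.0)
    return state


class TestPull:

    def test_zero_pull_changes_nothing_but_chemistry(self, tiny_params):
        state = build_stress_fiber(tiny_params)
        run(state, 5.0)
        fa1_before = state.fa_sites[1].position.copy()
        traj, ov0, ov1 = __import__("stressfiber.experiments", fromlist=["x"]
                                    ).pull_response(state, d_pull=0.0)
        np.testing.assert_array_equal(state.fa_sites[1].position, fa1_before)

    def test_fa_site_moves_by_exactly_d_pull(self, small_equilibrated_fiber):
        state = small_equilibrated_fiber.copy()
        z_before = state.fa_sites[1].position[2]
        spec = PullSpec(d_pull=80.0, n_steps=20, duration=1.0, t_pull=state.t)
        apply_pull(state, spec)
        assert state.fa_sites[1].position[2] - z_before == pytest.approx(80.0)
        # only the pulled site moved
        assert state.fa_sites[0].position[2] == pytest.approx(
            state.params.box[2] / 2 - state.params.fa_separation / 2)

    def test_pull_slides_the_bundles_apart(self, small_equilibrated_fiber):
        """A 100 nm pull converts partly into immediate bundle sliding
        (the catch-bonded motors hold the rest back; see methods)."""
        state = small_equilibrated_fiber.copy()
        from stressfiber.experiments import pull_response
        _, ov0, ov1 = pull_response(state, d_pull=100.0)
        assert 5.0 < ov0 - ov1 <= 110.0

    def test_pull_outside_box_rejected(self, small_equilibrated_fiber):
        state = small_equilibrated_fiber.copy()
        spec = PullSpec(d_pull=5000.0, n_steps=10, duration=1.0,
                        t_pull=state.t)
        with pytest.raises(ValueError):
            apply_pull(state, spec)

    def test_pull_spec_validation(self):
        with pytest.raises(ValueError):
            PullSpec(d_pull=-1.0)
        with pytest.raises(ValueError):
            PullSpec(d_pull=10.0, n_steps=0)
        with pytest.raises(ValueError):
            PullSpec(d_pull=10.0, duration=0.0)
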