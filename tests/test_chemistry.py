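import math

import numpy as np
import pytest
from scipy import stats as sps

import stressfiber as sf
from stressfiber.chemistry import (ChemistryEngine, NextReactionScheduler,
                                   bind_pair, depolymerize,
                                   linker_bind_candidates, linker_unbind_rate,
                                   motor_bind_candidates, motor_unbind_rate,
                                   motor_walk, motor_walk_rate, polymerize)
from stressfiber.synthetic import generate_static_bundle


@pytest.fixture()
def params(default_params):
    return default_params


class TestRateLaws:
    def test_linker_zero_force_baseline(self, params):
        assert linker_unbind_rate(0.0, params) == pytest.approx(1.0 / 3.0)

    def test_linker_chi_scaling_gives_fast_turnover(self, params):
        # chi = 10 -> rate 10/3 per s, mean lifetime 0.3 s
        p = params.replace(chi=10.0)
        assert linker_unbind_rate(0.0, p) == pytest.approx(10.0 / 3.0)
        assert 1.0 / linker_unbind_rate(0.0, p) == pytest.approx(0.3)

    def test_linker_bell_form(self, params):
        F = params.kT / params.x_slip
        assert linker_unbind_rate(F, params) == pytest.approx(
            math.e * params.k_off_linker)
        # strictly increasing in force
        assert linker_unbind_rate(10.0, params) > linker_unbind_rate(5.0, params)

    def test_motor_catch_bond(self, params):
        assert motor_unbind_rate(0.0, params) == pytest.approx(params.k_off_motor)
        assert motor_unbind_rate(params.F_catch, params) == pytest.approx(
            params.k_off_motor / math.e)
        assert motor_unbind_rate(10.0, params) < motor_unbind_rate(1.0, params)

    def test_motor_stall(self, params):
        assert motor_walk_rate(0.0, params) == pytest.approx(
            params.v_walk0 / params.motor_step)
        assert motor_walk_rate(params.F_stall, params) == 0.0
        assert motor_walk_rate(2 * params.F_stall, params) == 0.0

    def test_negative_force_rejected(self, params):
        for fn in (linker_unbind_rate, motor_unbind_rate, motor_walk_rate):
            with pytest.raises(ValueError):
                fn(-1.0, params)


class TestBindCandidates:
    def test_far_filaments_have_no_candidates(self, params):
        state = generate_static_bundle(100.0, 2, 5, params=params)
        assert linker_bind_candidates(state) == []

    def test_parallel_filaments_at_rest_spacing(self, params):
        state = generate_static_bundle(35.0, 2, 6, params=params)
        cands = linker_bind_candidates(state)
        # aligned bead rows only: one pair per bead
        assert len(cands) == 6
        expect = params.chi * params.k_on_linker * state.free_linker
        assert all(a == pytest.approx(expect) for _, _, a in cands)

    def test_occupied_sites_excluded(self, params):
        state = generate_static_bundle(35.0, 2, 6, params=params)
        f0, f1 = sorted(state.filaments)
        bind_pair(state, "linker", (f0, 2), (f1, 2))
        cands = linker_bind_candidates(state)
        assert len(cands) == 5
        assert all((f0, 2) not in (si, sj) for si, sj, _ in cands)

    @pytest.mark.parametrize("window_attr,fn", [
        ("linker_binding_window", linker_bind_candidates),
        ("motor_binding_window", motor_bind_candidates),
    ])
    def test_candidates_match_bruteforce_all_pairs(self, params, window_attr, fn):
        rng = np.random.default_rng(42)
        state = generate_static_bundle(40.0, 5, 8, params=params)
        for f in state.filaments.values():
            f.beads = f.beads + 15.0 * rng.standard_normal(f.beads.shape)
        lo, hi = getattr(params, window_attr)
        expected = set()
        pts, labels = state.hinge_points()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if labels[i][0] == labels[j][0]:
                    continue
                d = np.linalg.norm(pts[i] - pts[j])
                if lo <= d <= hi:
                    expected.add(tuple(sorted((labels[i], labels[j]))))
        got = {tuple(sorted((si, sj))) for si, sj, _ in fn(state)}
        assert got == expected


class TestPolymerization:
    def test_single_event_bookkeeping(self, tiny_params):
        state = sf.build_stress_fiber(tiny_params)
        fid = sorted(state.filaments)[0]
        free0 = state.free_g_actin
        rise = tiny_params.monomer_rise
        len0 = state.filaments[fid].contour_length(rise)
        polymerize(state, fid)
        assert state.free_g_actin == free0 - 1
        assert state.filaments[fid].contour_length(rise) == pytest.approx(
            len0 + rise)

    def test_forty_events_make_one_new_cylinder(self, tiny_params):
        state = sf.build_stress_fiber(tiny_params)
        fid = sorted(state.filaments)[0]
        n_beads0 = state.filaments[fid].n_beads
        for _ in range(40):
            polymerize(state, fid)
        f = state.filaments[fid]
        assert f.n_beads == n_beads0 + 1
        assert f.monomers[-1] == 40

    def test_depolymerize_reverses_and_conserves(self, tiny_params):
        state = sf.build_stress_fiber(tiny_params)
        fid = sorted(state.filaments)[0]
        polymerize(state, fid)
        total_before = state.free_g_actin + state.polymerized_monomers()
        depolymerize(state, fid)
        assert state.free_g_actin + state.polymerized_monomers() == total_before
        from stressfiber.state import validate
        assert validate(state) == []

    def test_depolymerize_single_monomer_rejected(self, tiny_params):
        state = sf.build_stress_fiber(tiny_params)
        fid = sorted(state.filaments)[0]
        f = state.filaments[fid]
        f.beads = f.beads[:2]
        f.monomers = [1]
        state.total_actin = state.free_g_actin + state.polymerized_monomers()
        with pytest.raises(ValueError):
            depolymerize(state, fid)

    def test_pool_fixed_point_on_closed_system(self, default_params):
        """Ensemble mean free pool settles at the scalar fixed point
        n_free = k_depoly / k_poly of the pool rate equation."""
        p = default_params.replace(
            n_filaments_per_bundle=2, g_actin_init=400,
            k_poly=0.01, k_depoly=1.0, k_on_linker=1e-300, k_on_motor=1e-300,
            seed=3)
        # fixed point: n_free = 1.0/0.01 = 100
        state = sf.build_stress_fiber(p)
        for t_end in range(50, 451, 50):
            sf.nrm_advance(state, float(t_end))
        tail = []
        for t_end in range(500, 2000, 25):
            sf.nrm_advance(state, float(t_end))
            tail.append(state.free_g_actin)
        mean_free = np.mean(tail)
        se = np.std(tail) / math.sqrt(len(tail) / 4)   # crude autocorr allowance
        assert mean_free == pytest.approx(100.0, abs=max(4 * se, 15.0))


class TestMotorWalk:
    def test_walk_decreases_arc_towards_plus_end(self, params):
        state = generate_static_bundle(200.0, 2, 5, params=params)
        f0, f1 = sorted(state.filaments)
        mid = bind_pair(state, "motor", (f0, 2), (f1, 2))
        arc0 = state.motors[mid].ends[0][1]
        motor_walk(state, mid, 0)
        assert state.motors[mid].ends[0][1] == pytest.approx(
            arc0 - params.motor_step)

    def test_walk_clamps_at_plus_end(self, params):
        state = generate_static_bundle(200.0, 2, 5, params=params)
        f0, f1 = sorted(state.filaments)
        mid = bind_pair(state, "motor", (f0, 0), (f1, 0))
        motor_walk(state, mid, 0)
        assert state.motors[mid].ends[0][1] == 0.0
        # engine gives a stalled-at-end endpoint zero walk propensity
        engine = ChemistryEngine(state)
        assert engine._mw_rate(mid, 0) == 0.0


class TestScheduler:
    def test_no_propensity_advances_clock_without_events(self, tiny_params):
        state = generate_static_bundle(100.0, 2, 3, params=tiny_params)
        state.free_g_actin = 0
        state.total_actin = state.polymerized_monomers()
        p0 = state.params.replace(k_depoly=1e-300, k_on_linker=1e-300,
                                  k_on_motor=1e-300)
        state.params = p0
        n = sf.nrm_advance(state, 50.0)
        assert n == 0
        assert state.t == 50.0

    def test_birth_death_stationary_law_is_poisson(self):
        """Birth at beta, death at delta per molecule: the stationary count
        is Poisson(beta/delta) -- chi-square against the exact pmf."""
        rng = np.random.default_rng(7)
        sched = NextReactionScheduler(rng)
        beta, delta, n = 20.0, 2.0, 0
        sched.add_channel(("birth", 0, 0), beta)
        sched.add_channel(("death", 0, 0), delta * n)
        samples = []
        t_sample = 10.0
        while len(samples) < 20000:
            key = sched.next_event(t_sample)
            if key is None:
                samples.append(n)
                t_sample += 2.0        # ~4 relaxation times between samples
                continue
            n += 1 if key[0] == "birth" else -1
            sched.set_rate(("death", 0, 0), delta * n)
        samples = np.asarray(samples)
        lam = beta / delta
        assert abs(samples.mean() - lam) < 3 * math.sqrt(lam / len(samples)) * 2
        obs = np.bincount(samples, minlength=samples.max() + 1)
        pmf = sps.poisson(lam).pmf(np.arange(len(obs)))
        pmf[-1] += max(0.0, 1.0 - pmf.sum())
        exp = pmf * len(samples)
        keep = exp >= 5
        chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
        p = 1.0 - sps.chi2.cdf(chi2, int(keep.sum()) - 1)
        assert p > 0.005

    def test_nrm_matches_direct_ssa_oracle(self):
        """Event-count distribution over a fixed horizon agrees between the
        NRM scheduler and an independent direct-method SSA."""
        horizon, beta, delta = 4.0, 5.0, 1.0

        def count_events_nrm(seed):
            rng = np.random.default_rng(seed)
            sched = NextReactionScheduler(rng)
            n, events = 0, 0
            sched.add_channel(("b", 0, 0), beta)
            sched.add_channel(("d", 0, 0), 0.0)
            while True:
                key = sched.next_event(horizon)
                if key is None:
                    return events
                events += 1
                n += 1 if key[0] == "b" else -1
                sched.set_rate(("d", 0, 0), delta * n)

        def count_events_direct(seed):
            rng = np.random.default_rng(seed)
            t, n, events = 0.0, 0, 0
            while True:
                a = [beta, delta * n]
                a0 = sum(a)
                t += rng.exponential(1.0 / a0)
                if t > horizon:
                    return events
                events += 1
                if rng.random() * a0 < a[0]:
                    n += 1
                else:
                    n -= 1

        nrm = [count_events_nrm(s) for s in range(3000)]
        ssa = [count_events_direct(10_000 + s) for s in range(3000)]
        # two-sample chi-square: both histograms carry sampling noise
        edges = [0, 15, 18, 20, 22, 24, 26, 28, 31, 35, 200]
        h1, _ = np.histogram(nrm, bins=edges)
        h2, _ = np.histogram(ssa, bins=edges)
        keep = (h1 + h2) > 10
        chi2 = float(np.sum((h1[keep] - h2[keep]) ** 2 /
                            (h1[keep] + h2[keep])))
        dof = int(keep.sum()) - 1
        p = 1.0 - sps.chi2.cdf(chi2, dof)
        assert p > 0.01

    def test_event_order_is_deterministic_per_seed(self, tiny_params):
        def event_log(seed):
            p = tiny_params.replace(seed=seed)
            state = sf.build_stress_fiber(p)
            engine = ChemistryEngine(state, record_events=True)
            engine.advance(5.0)
            return engine.log

        assert event_log(5) == event_log(5)
        assert event_log(5) != event_log(6)


class TestLifetimesAndOccupancy:
    @pytest.mark.parametrize("chi,expected", [(1.0, 3.0), (10.0, 0.3)])
    def test_unloaded_linker_lifetime(self, chi, expected):
        from stressfiber.experiments import linker_lifetime_experiment
        mean, se, n = linker_lifetime_experiment(chi, n_events=4000, seed=1)
        assert n >= 4000
        assert mean == pytest.approx(expected, abs=3 * se)

    def test_chi_leaves_bound_count_unchanged_on_static_lattice(self):
        """Scaling on- and off-rates together changes turnover speed but
        not mean occupancy."""
        means = {}
        for chi in (0.1, 1.0, 10.0):
            p = sf.default_parameters().replace(
                chi=chi, seed=2, k_depoly=1e-12, k_on_motor=1e-300,
                k_off_motor=1e-300)
            state = generate_static_bundle(30.0, 7, 20, params=p, seed=2)
            state.free_g_actin = 0
            state.total_actin = state.polymerized_monomers()
            # burn-in scaled with turnover time, then sample occupancy
            burn = 30.0 / chi
            sf.nrm_advance(state, burn)
            counts = []
            for k in range(200):
                sf.nrm_advance(state, state.t + 3.0 / chi)
                counts.append(len(state.linkers))
            means[chi] = (np.mean(counts), np.std(counts) / math.sqrt(50))
        vals = [means[c][0] for c in (0.1, 1.0, 10.0)]
        errs = [means[c][1] for c in (0.1, 1.0, 10.0)]
        for i in range(2):
            assert abs(vals[i] - vals[i + 1]) < 3 * math.hypot(errs[i], errs[i + 1])


class TestConservation:
    def test_mass_and_species_conserved_through_a_run(self, tiny_params):
        from stressfiber.state import validate
        state = sf.build_stress_fiber(tiny_params)
        traj = sf.run(state, 20.0)
        assert validate(state) == []
        p = tiny_params
        assert state.free_linker + len(state.linkers) == p.n_crosslinker
        assert state.free_motor + len(state.motors) == p.n_motor
        assert state.free_g_actin + state.polymerized_monomers() == \
            state.total_actin
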