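"""Integrator physics, MC chemistry, contact logic, determinism."""

import numpy as np
import pytest
from scipy.stats import chisquare

from phosdyn.engine import (HybridSimulation, SimConfig, SystemTopology,
                            build_toy_validation_system, langevin_step)
from phosdyn.params import (ParameterSet, ResidueParams, load_parameter_set,
                            R_GAS)


def single_bead_system(**cfg_kwargs):
    """One free, non-interacting bead."""
    base = load_parameter_set("hps")
    residues = dict(base.residues)
    residues["L"] = ResidueParams(code="L", mass=110.0, sigma=0.45,
                                  lambda_h=0.0, charge=0.0)
    pset = ParameterSet(residues=residues)
    top = SystemTopology(codes=["L"], chain_id=[0], resids=[1],
                         bonds=np.empty((0, 2), int))
    config = SimConfig(box_side=10.0, **cfg_kwargs)
    return HybridSimulation(top, pset, config)


def bonded_dimer(**cfg_kwargs):
    base = load_parameter_set("hps")
    residues = dict(base.residues)
    residues["L"] = ResidueParams(code="L", mass=110.0, sigma=0.45,
                                  lambda_h=0.5, charge=0.0)
    pset = ParameterSet(residues=residues)
    top = SystemTopology(codes=["L", "L"], chain_id=[0, 0], resids=[1, 2],
                         bonds=np.array([[0, 1]]))
    config = SimConfig(box_side=10.0, **cfg_kwargs)
    return HybridSimulation(top, pset, config), pset


class TestLangevinIntegrator:
    def test_zero_temperature_zero_force_is_static(self):
        sim = single_bead_system(temperature=1e-12, friction=0.1, seed=0)
        sim.vel[:] = 0.0
        x0 = sim.pos.copy()
        sim.advance(1000)
        np.testing.assert_allclose(sim.pos, x0, atol=1e-12)

    def test_free_bead_kinetic_equipartition(self):
        sim = single_bead_system(friction=0.5, seed=1)
        ke = []
        for _ in range(4000):
            sim.advance(10)
            ke.append(0.5 * 110.0 * np.sum(sim.vel[0] ** 2))
        mean_ke = np.mean(ke)
        expect = 1.5 * sim.config.kT
        sem = np.std(ke) / np.sqrt(len(ke) / 20)     # crude decorrelation
        assert abs(mean_ke - expect) < 4 * sem + 0.05 * expect

    def test_free_bead_diffusion_einstein_relation(self):
        # BAOAB long-time diffusion D = kT/(m*gamma)
        gamma, m = 0.2, 110.0
        sim = single_bead_system(friction=gamma, seed=2)
        D_expect = sim.config.kT / (m * gamma)
        n_win, steps = 60, 4000           # 40 ps windows >> 1/gamma = 5 ps
        disp = []
        for _ in range(n_win):
            x0 = sim.pos[0].copy()
            sim.advance(steps)
            disp.append(np.sum((sim.pos[0] - x0) ** 2))
        msd = np.mean(disp)
        t_win = steps * sim.config.dt
        D_est = msd / (6 * t_win)
        assert D_est == pytest.approx(D_expect, rel=0.45)

    def test_bond_length_boltzmann_distribution(self):
        """With MC off, the engine samples the canonical ensemble: the dimer
        bond length follows r^2 exp(-beta U(r)) (chi-square at the 1% level)."""
        sim, pset = bonded_dimer(friction=0.5, seed=3)
        sim.pos[1] = sim.pos[0] + [pset.bond_r0, 0, 0]
        samples = []
        sim.advance(2000)
        for _ in range(4000):
            sim.advance(250)       # ~1.3 vibrational periods: decorrelated
            samples.append(np.linalg.norm(sim.pos[1] - sim.pos[0]))
        samples = np.array(samples)
        beta = 1.0 / sim.config.kT
        edges = np.linspace(samples.min() - 1e-3, samples.max() + 1e-3, 12)
        # bonded pair is excluded from non-bonded terms: U is the bond only
        fine = np.linspace(edges[0], edges[-1], 4801)
        dens = fine**2 * np.exp(-beta * 0.5 * pset.bond_k
                                * (fine - pset.bond_r0) ** 2)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                               * np.diff(fine))])
        cdf /= cdf[-1]
        p = np.diff(np.interp(edges, fine, cdf))
        obs, _ = np.histogram(samples, bins=edges)
        keep = p * len(samples) >= 5
        stat, pval = chisquare(obs[keep], p[keep] / p[keep].sum()
                               * obs[keep].sum())
        assert pval > 0.01

    def test_instability_raises_with_diagnostic(self):
        sim, pset = bonded_dimer(dt=50.0, friction=0.0, seed=4)
        sim.pos[1] = sim.pos[0] + [0.1, 0, 0]     # deep overlap + huge dt
        with pytest.raises(FloatingPointError, match="unstable"):
            for _ in range(100):
                sim.advance(100)


class TestRigidBody:
    def test_zero_temperature_pose_unchanged(self):
        top, pset, config = build_toy_validation_system()
        config.temperature = 1e-12
        config.n_steps = 100
        sim = HybridSimulation(top, pset, config)
        # isolate the body from the substrate
        sim.pos[:3] = [[1, 1, 1], [1.38, 1, 1], [1.76, 1, 1]]
        sim.body_center[0] = [7, 7, 7]
        sim.vel[:] = 0.0
        from phosdyn.engine import _sync_body_beads
        _sync_body_beads(sim.pos, sim.bead_body, sim.bead_ref,
                         sim.body_center, sim.body_quat)
        pose0 = sim.pos[3:].copy()
        sim.advance(500)
        np.testing.assert_allclose(sim.pos[3:], pose0, atol=1e-9)

    def test_rigidity_preserved_over_long_runs(self):
        top, pset, config = build_toy_validation_system()
        sim = HybridSimulation(top, pset, config)
        body = top.rigid_bodies[0]
        ref = {(i, j): np.linalg.norm(sim.pos[i] - sim.pos[j])
               for i in body for j in body if i < j}
        sim.advance(100_000)
        drift = max(abs(np.linalg.norm(sim.pos[i] - sim.pos[j]) - d0)
                    for (i, j), d0 in ref.items())
        assert drift < 1e-6

    def test_orientation_decorrelates(self):
        top, pset, config = build_toy_validation_system()
        config.rotational_drag = 1.0
        sim = HybridSimulation(top, pset, config)
        axis0 = (sim.pos[4] - sim.pos[3]) / np.linalg.norm(sim.pos[4] - sim.pos[3])
        corr = []
        for _ in range(60):
            sim.advance(4000)
            axis = (sim.pos[4] - sim.pos[3])
            axis /= np.linalg.norm(axis)
            corr.append(axis0 @ axis)
        # free-rotor decorrelation: late-time autocorrelation near zero
        assert abs(np.mean(corr[30:])) < 0.35

    def test_degenerate_collinear_body_rejected(self):
        base = load_parameter_set("hps")
        top = SystemTopology(codes=["G", "G", "G"], chain_id=[0, 0, 0],
                             resids=[1, 2, 3], bonds=np.empty((0, 2), int),
                             rigid_bodies=[np.array([0, 1, 2])])
        config = SimConfig(box_side=10.0)
        sim = HybridSimulation.__new__(HybridSimulation)
        with pytest.raises(ValueError, match="collinear"):
            sim_full = HybridSimulation(
                top, base, config,
                positions=np.array([[1.0, 1, 1], [2.0, 1, 1], [3.0, 1, 1]]))


class TestContactDetection:
    def _two_site_system(self):
        base = load_parameter_set("hps")
        residues = dict(base.residues)
        residues["Z"] = ResidueParams(code="Z", mass=110.0, sigma=0.6,
                                      lambda_h=1.0, charge=-0.3)
        pset = ParameterSet(residues=residues)
        top = SystemTopology(
            codes=["S", "G", "S", "Z", "Z", "Z", "G"],
            chain_id=[0, 0, 0, 1, 1, 1, 1],
            resids=[1, 2, 3, 11, 12, 13, 14],
            bonds=np.array([[0, 1], [1, 2]]),
            rigid_bodies=[np.array([3, 4, 5, 6])],
            phosphosites=np.array([0, 2]),
            active_site=np.array([3, 4, 5]))
        config = SimConfig(box_side=12.0, seed=0)
        return HybridSimulation(top, pset, config)

    def _place(self, sim, site_positions, triad_center):
        sim.pos[3:6] = triad_center + np.array(
            [[0.0, 0, 0], [0.4, 0, 0], [0.2, 0.35, 0]])
        sim.pos[6] = triad_center + [0.2, 0.1, 0.4]
        sim.pos[0] = site_positions[0]
        sim.pos[2] = site_positions[1]
        sim.pos[1] = 0.5 * (np.asarray(site_positions[0])
                            + np.asarray(site_positions[1]))

    def test_all_three_distances_rule(self):
        sim = self._two_site_system()
        triad = np.array([6.0, 6.0, 6.0])
        # site 0 at 0.9 nm from all triad beads -> contact
        self._place(sim, [triad + [0.2, 0.15, 0.9], triad + [5, 5, 5]], triad)
        assert sim.detect_contact() == 0
        d = sim.site_distances(0)
        assert np.all(d < 1.0)

    def test_one_distance_over_cutoff_vetoes(self):
        sim = self._two_site_system()
        triad = np.array([6.0, 6.0, 6.0])
        # 0.90 nm from the first triad bead but >1 nm from the other two
        self._place(sim, [triad + [-0.85, 0, 0.3], triad + [5, 5, 5]], triad)
        d = sim.site_distances(0)
        assert d.max() > 1.0 and d.min() < 1.0
        assert sim.detect_contact() is None

    def test_closest_site_wins(self):
        sim = self._two_site_system()
        triad = np.array([6.0, 6.0, 6.0])
        near = triad + [0.2, 0.12, 0.5]
        far = triad + [0.2, 0.12, 0.85]
        self._place(sim, [far, near], triad)
        assert sim.detect_contact() == 1      # site index 1 is closer
        self._place(sim, [near, far], triad)
        assert sim.detect_contact() == 0

    def test_exact_tie_breaks_to_lower_residue_index(self):
        sim = self._two_site_system()
        triad = np.array([6.0, 6.0, 6.0])
        spot = triad + [0.2, 0.12, 0.6]
        self._place(sim, [spot, spot], triad)
        assert sim.detect_contact() == 0

    def test_missing_active_site_annotation(self):
        top, pset, config = build_toy_validation_system()
        top.active_site = np.empty(0, int)
        sim = HybridSimulation(top, pset, config)
        with pytest.raises(ValueError, match="active-site"):
            sim.detect_contact()

    def test_min_image_invariance_of_energy_and_contact(self):
        sim = self._two_site_system()
        triad = np.array([6.0, 6.0, 6.0])
        self._place(sim, [triad + [0.2, 0.15, 0.9], triad + [4, 4, 4]], triad)
        u0, c0 = sim.total_energy(), sim.detect_contact()
        sim.pos += np.array([12.0, 24.0, -12.0])    # lattice translation
        assert sim.total_energy() == pytest.approx(u0, abs=1e-9)
        assert sim.detect_contact() == c0


class TestPhosphoSwap:
    def _yukawa_only_system(self, r, dmu_p=0.0, seed=0):
        """Ser and pSer differ only in charge; one enzyme bead at distance r.

        Then dU of the swap is a closed-form Yukawa energy difference.
        """
        base = load_parameter_set("hps")
        residues = dict(base.residues)
        s = residues["S"]
        residues["p"] = ResidueParams(code="p", mass=s.mass, sigma=s.sigma,
                                      lambda_h=s.lambda_h, charge=-2.0)
        residues["Z"] = ResidueParams(code="Z", mass=110.0, sigma=0.6,
                                      lambda_h=0.0, charge=1.0)
        pset = ParameterSet(residues=residues, epsilon_ah=0.0)
        top = SystemTopology(
            codes=["S", "Z", "Z", "Z", "G"], chain_id=[0, 1, 1, 1, 1],
            resids=[1, 11, 12, 13, 14], bonds=np.empty((0, 2), int),
            rigid_bodies=[np.array([1, 2, 3, 4])],
            phosphosites=np.array([0]), active_site=np.array([1, 2, 3]))
        config = SimConfig(box_side=12.0, dmu_p=dmu_p, seed=seed)
        pos = np.array([[6.0, 6, 6], [6.0 + r, 6, 6], [6.0, 6 + r, 6],
                        [6.0, 6, 6 + r], [6.0 + r, 6 + r, 6 + r]])
        sim = HybridSimulation(top, pset, config, positions=pos)
        return sim, pset

    def test_acceptance_one_when_du_and_dmu_zero(self):
        sim, _ = self._yukawa_only_system(r=5.0)    # beyond all cutoffs
        accepted, du = sim.attempt_phospho_swap(0)
        assert du == pytest.approx(0.0, abs=1e-12)
        assert accepted

    def test_negative_dmu_forward_acceptance_one(self):
        sim, _ = self._yukawa_only_system(r=5.0, dmu_p=-5.0)
        from phosdyn.engine import EventLog
        log = EventLog()
        accepted, _ = sim.attempt_phospho_swap(0, log)
        assert accepted
        assert log.records[0]["acceptance"] == 1.0

    def test_closed_form_acceptance_positive_du(self):
        # three +1e beads at 1.0 nm: dU = 3 * k_e*(-2)/(80) * e^-1
        from phosdyn.params import COULOMB_K
        r = 1.0
        du_expect = 3 * COULOMB_K * (-2.0) * 1.0 / 80.0 * np.exp(-r) / r
        sim, pset = self._yukawa_only_system(r=r, dmu_p=0.0)
        from phosdyn.engine import EventLog
        log = EventLog()
        _, du = sim.attempt_phospho_swap(0, log)
        assert du == pytest.approx(du_expect, rel=1e-9)
        beta = 1.0 / (R_GAS * 300.0)
        assert log.records[0]["acceptance"] == pytest.approx(
            min(1.0, np.exp(-beta * du_expect)), rel=1e-9)

    def test_reverse_move_flips_exponent(self):
        from phosdyn.engine import EventLog
        sim, _ = self._yukawa_only_system(r=1.0, dmu_p=-3.0, seed=5)
        _, du_fwd = sim.attempt_phospho_swap(0)       # may or may not accept
        while sim.codes[0] == "S":
            _, _ = sim.attempt_phospho_swap(0)
        log = EventLog()
        _, du_rev = sim.attempt_phospho_swap(0, log)
        beta = 1.0 / (R_GAS * 300.0)
        assert du_rev == pytest.approx(du_fwd, rel=1e-9)    # same convention
        assert log.records[0]["acceptance"] == pytest.approx(
            min(1.0, np.exp(beta * (du_rev + -3.0))), rel=1e-9)

    def test_local_du_equals_full_system_difference(self):
        top, pset, config = build_toy_validation_system()
        for seed in range(5):
            config.seed = seed
            sim = HybridSimulation(top, pset, config)
            sim.advance(2000)
            u_ser = sim.total_energy()
            du_local = (sim.bead_energy(1, "p") - sim.bead_energy(1, "S"))
            sim._swap_site(0, "p")
            u_pser = sim.total_energy()
            assert du_local == pytest.approx(u_pser - u_ser, abs=1e-9)

    def test_non_phosphosite_rejected(self):
        top, pset, config = build_toy_validation_system()
        sim = HybridSimulation(top, pset, config)
        with pytest.raises(ValueError, match="phosphosite"):
            sim.attempt_phospho_swap(2)


class TestReservoirExchange:
    def test_acceptance_one_for_downhill(self):
        top, pset, config = build_toy_validation_system()
        config.reservoir_enabled = True
        sim = HybridSimulation(top, pset, config)
        # substrate and enzyme at opposite corners: beyond every cutoff
        from phosdyn.engine import _sync_body_beads
        sim.pos[:3] = [[0.5, 0.5, 0.5], [0.88, 0.5, 0.5], [1.26, 0.5, 0.5]]
        sim.body_center[0] = [4.5, 4.5, 4.5]
        _sync_body_beads(sim.pos, sim.bead_body, sim.bead_ref,
                         sim.body_center, sim.body_quat)
        assert sim.site_distances(0).min() > pset.cutoff_yukawa
        from phosdyn.engine import EventLog
        log = EventLog()
        accepted, du = sim.attempt_reservoir_exchange(0, log)
        assert abs(du) < 1e-9
        assert accepted

    def test_eligibility_requires_all_distances_beyond_trigger(self):
        top, pset, config = build_toy_validation_system()
        config.reservoir_enabled = True
        sim = HybridSimulation(top, pset, config)
        sim.pos[1] = sim.pos[3] + [2.0, 0, 0]     # close to the triad
        assert not sim.reservoir_eligible(0)

    def test_trigger_distance_is_half_box_by_default(self):
        config = SimConfig(box_side=50.0)
        assert config.reservoir_distance == 25.0

    def test_disabled_reservoir_raises(self):
        top, pset, config = build_toy_validation_system()
        config.reservoir_enabled = False
        sim = HybridSimulation(top, pset, config)
        with pytest.raises(ValueError, match="disabled"):
            sim.attempt_reservoir_exchange(0)

    def test_multi_site_reservoir_rejected_at_setup(self):
        base = load_parameter_set("hps")
        top = SystemTopology(codes=["S", "G", "S"], chain_id=[0, 0, 0],
                             resids=[1, 2, 3], bonds=np.array([[0, 1], [1, 2]]),
                             phosphosites=np.array([0, 2]))
        config = SimConfig(box_side=10.0, reservoir_enabled=True)
        with pytest.raises(ValueError, match="single-phosphosite"):
            HybridSimulation(top, base, config)

    def test_reservoir_alone_preserves_isolated_boltzmann_ratio(self):
        """With contact MC disabled, reservoir swaps must leave the Ser/pSer
        occupancy at the Boltzmann ratio of the isolated substrate (both
        identities are isoenergetic when unbound -> 50/50)."""
        top, pset, config = build_toy_validation_system()
        config.n_steps = 400_000
        config.contact_cutoff = 0.0       # no catalytic swaps
        config.traj_stride = 100
        config.seed = 9
        sim = HybridSimulation(top, pset, config)
        traj, log = sim.run()
        frame = log.to_frame()
        assert (frame.kind == "phospho_attempt").sum() == 0
        assert (frame.kind == "reservoir_accept").sum() > 100
        pser_fraction = traj.chem[:, 0].mean()
        assert 0.4 < pser_fraction < 0.6


class TestRunLoop:
    def test_same_seed_reproduces_event_log_and_trajectory(self):
        results = []
        for _ in range(2):
            top, pset, config = build_toy_validation_system()
            config.n_steps = 60_000
            config.seed = 17
            sim = HybridSimulation(top, pset, config)
            traj, log = sim.run()
            results.append((traj, log.to_frame()))
        (t1, e1), (t2, e2) = results
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.chem, t2.chem)
        assert e1.equals(e2)

    def test_contact_checks_follow_mc_interval(self, monkeypatch):
        top, pset, config = build_toy_validation_system()
        config.n_steps = 4070
        config.mc_interval = 200
        sim = HybridSimulation(top, pset, config)
        calls = []
        original = HybridSimulation.detect_contact
        monkeypatch.setattr(HybridSimulation, "detect_contact",
                            lambda self: calls.append(1) or None)
        sim.run()
        assert len(calls) == 4070 // 200
        assert sim.time_ps == pytest.approx((4070 // 200) * 200 * config.dt)

    def test_single_step_wrapper(self):
        top, pset, config = build_toy_validation_system()
        sim = HybridSimulation(top, pset, config)
        t0 = sim.time_ps
        langevin_step(sim)
        assert sim.time_ps == pytest.approx(t0 + config.dt)


class TestToySystem:
    def test_exactly_one_phosphosite_three_active_beads(self):
        top, pset, config = build_toy_validation_system()
        assert len(top.phosphosites) == 1
        assert len(top.active_site) == 3
        assert config.reservoir_enabled

    def test_both_bound_and_unbound_visited(self):
        top, pset, config = build_toy_validation_system()
        config.n_steps = 500_000
        config.traj_stride = 100
        sim = HybridSimulation(top, pset, config)
        traj, _ = sim.run()
        mind = traj.site_active_distances(top).min(axis=1)
        assert (mind < 1.0).mean() > 0.005
        assert (mind > 3.0).mean() > 0.05

    def test_detailed_balance_in_aggregate_at_zero_driving(self):
        top, pset, config = build_toy_validation_system()
        config.n_steps = 2_000_000
        config.dmu_p = 0.0
        config.seed = 21
        sim = HybridSimulation(top, pset, config)
        _, log = sim.run()
        frame = log.to_frame()
        fwd = (frame.kind == "phospho_accept").sum()
        bwd = (frame.kind == "dephospho_accept").sum()
        assert fwd + bwd > 50
        # at equilibrium the two directed fluxes balance (Poisson errors)
        assert abs(fwd - bwd) < 4 * np.sqrt(fwd + bwd)
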