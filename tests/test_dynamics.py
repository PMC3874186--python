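"""Polymerase traffic: hand-stepped oracles, conservation, exclusion."""

import math

import numpy as np
import pytest

import ribotraffic as rt
from ribotraffic.damage import DamageRateProfile
from ribotraffic.locus import ConfigurationError


def run_steps(toy, n, rng=None):
    rng = rng or np.random.default_rng(0)
    for _ in range(n):
        rt.advance(toy.population, toy.lesions, toy.params, toy.kinetics, rng)
    return toy


class TestToyOracle:
    """Deterministic 1,000-bp fixture: v = 100 nt/s, dt = 1 s."""

    def test_arrest_one_bp_before_lesion_after_four_steps(self, toy):
        run_steps(toy, 3)
        assert toy.population.copy_state(0).polymerases == [(400.0, "elongating")]
        run_steps(toy, 1)
        assert toy.population.copy_state(0).polymerases == [(499.0, "arrested")]
        assert bool(toy.lesions.tcr_marked[0])
        run_steps(toy, 10)  # stays put without repair or release
        assert toy.population.copy_state(0).polymerases == [(499.0, "arrested")]

    def test_lesion_free_copy_terminates_at_nine_seconds(self, toy):
        run_steps(toy, 8)
        assert toy.population.copy_state(1).polymerases == [(900.0, "elongating")]
        run_steps(toy, 1)
        assert toy.population.copy_state(1).polymerases == []
        assert toy.population.tallies["terminations"] == 1

    def test_arrested_polymerase_resumes_after_repair(self, toy):
        run_steps(toy, 10)
        toy.lesions.repaired[0] = True
        run_steps(toy, 7)
        assert toy.population.copy_state(0).polymerases == []
        assert toy.population.tallies["terminations"] == 2

    def test_spontaneous_release_removes_arrested(self, toy):
        toy = rt.gen_toy_fixture()
        params = toy.params.replace(release_mode="constant", k_release=1e4)
        rng = np.random.default_rng(0)
        for _ in range(5):
            rt.advance(toy.population, toy.lesions, params, toy.kinetics, rng)
        assert toy.population.copy_state(0).polymerases == []
        assert toy.population.tallies["releases_spontaneous"] == 1

    def test_collision_release_needs_contact(self, toy):
        # second polymerase added behind the future arrest point
        pop = toy.population
        pop.pol_copy = np.array([0, 0], np.int64)
        pop.pol_pos = np.array([100.0, 350.0])
        pop.pol_arrested = np.zeros(2, bool)
        pop.n_initial = 2
        params = toy.params.replace(release_mode="collision", k_collision=1e4)
        rng = np.random.default_rng(0)
        for _ in range(2):
            rt.advance(pop, toy.lesions, params, toy.kinetics, rng)
        # leader arrested at 499; follower still 149 bp behind: no contact yet
        assert pop.tallies["releases_collision"] == 0
        for _ in range(4):
            rt.advance(pop, toy.lesions, params, toy.kinetics, rng)
        # follower pressed against the leader released it and took its place
        state = pop.copy_state(0)
        assert pop.tallies["releases_collision"] == 1
        assert state.polymerases == [(499.0, "arrested")]

    def test_conservation_in_toy(self, toy):
        run_steps(toy, 30)
        pop = toy.population
        t = pop.tallies
        assert pop.n_initial + t["initiations"] == (
            t["terminations"] + t["releases_collision"]
            + t["releases_spontaneous"] + pop.n_polymerases
        )


class TestSteadyState:
    def test_polymerases_per_open_copy(self, locus, params):
        pop = rt.initialize_steady_state(locus, params, 0.5, seed=8)
        per_copy = pop.pols_per_copy()
        n_open = int(pop.initially_open.sum())
        assert n_open == 75
        # floor(6900/130) = 53 per copy, +-1 from the phase jitter
        assert set(per_copy[pop.initially_open]) <= {53, 54}
        assert per_copy[~pop.initially_open].sum() == 0

    def test_zero_open_fraction(self, locus, params):
        pop = rt.initialize_steady_state(locus, params, 0.0, seed=8)
        assert pop.n_polymerases == 0
        assert pop.open_fraction() == 0.0

    def test_open_fraction_domain(self, locus, params):
        with pytest.raises(ValueError):
            rt.initialize_steady_state(locus, params, 1.2, seed=8)

    def test_initial_tro_ratios_near_one(self, locus, params):
        import ribotraffic.assays as assays
        from ribotraffic.dynamics import Snapshot

        pop = rt.initialize_steady_state(locus, params, 0.5, seed=8)
        snap = Snapshot(-0.25, pop, rt.LesionMap.empty(150, 6900.0), {})
        tro = assays.tro_readout(snap, locus)
        assert tro.r_5m == pytest.approx(1.0, abs=0.1)
        assert tro.r_53 == pytest.approx(1.0, abs=0.1)


class TestFluxAndStability:
    def test_no_lesion_flux_matches_initiation_rate(self, locus, params):
        """Terminations per open copy per second approach the entry flux."""
        zero = DamageRateProfile.uniform(0.0, locus.gene_length)
        traj = rt.run_scenario(locus, zero, params, rt.RepairKinetics(),
                               [-0.01, 0.0, 0.25], seed=31)
        s = traj.at(0.25)
        n_open = 75
        duration = 0.25 * 3600
        flux = s.tallies["terminations"] / duration / n_open
        target = params.eff_initiation_rate
        se = math.sqrt(s.tallies["terminations"]) / duration / n_open
        assert abs(flux - target) < max(3 * se, 0.1 * target)

    def test_zero_rate_limit_occupancy_unchanged(self, locus, params):
        """Without lesions the post-UV profile equals the pre-UV profile."""
        import ribotraffic.assays as assays

        zero = DamageRateProfile.uniform(0.0, locus.gene_length)
        traj = rt.run_scenario(locus, zero, params, rt.RepairKinetics(),
                               [-0.01, 0.0, 0.5], seed=31)
        for amp in "cdefg":
            val = assays.chip_readout(traj, amp)[0.5]
            assert val == pytest.approx(1.0, abs=0.12)

    def test_monotone_damage_response(self, locus, params, kinetics):
        """More damage never increases mean occupancy downstream of 3 kb."""
        means = []
        for rate in (0.0, 0.35, 0.7, 1.4):
            prof = DamageRateProfile.uniform(rate, locus.gene_length)
            traj = rt.run_scenario(locus, prof, params, kinetics,
                                   [-0.01, 0.0, 0.5], seed=55)
            pop = traj.at(0.5).population
            means.append(((pop.pol_pos >= 3000).sum()) / pop.n_copies)
        assert all(a >= b - 0.5 for a, b in zip(means, means[1:]))

    def test_exclusion_never_violated(self, wt_trajectory, params):
        fp = params.footprint
        for s in wt_trajectory.snapshots:
            pop = s.population
            pc, pp = pop.pol_copy, pop.pol_pos
            same = pc[1:] == pc[:-1]
            gaps = pp[1:][same] - pp[:-1][same]
            assert gaps.size == 0 or gaps.min() >= fp - 1e-6

    def test_conservation_at_every_snapshot(self, wt_trajectory,
                                            rad14_trajectory):
        wt_trajectory.check_conservation()
        rad14_trajectory.check_conservation()


class TestRunScenario:
    def test_fixed_seed_reproducible(self, locus, profile, params, kinetics):
        kw = dict(timepoints_h=[-0.01, 0.0, 0.1], seed=77)
        a = rt.run_scenario(locus, profile, params, kinetics, **kw)
        b = rt.run_scenario(locus, profile, params, kinetics, **kw)
        sa, sb = a.at(0.1).population, b.at(0.1).population
        assert np.array_equal(sa.pol_pos, sb.pol_pos)
        assert np.array_equal(sa.pol_copy, sb.pol_copy)
        assert a.at(0.1).tallies == b.at(0.1).tallies

    def test_snapshots_are_deep_copies(self, locus, profile, params, kinetics):
        traj = rt.run_scenario(locus, profile, params, kinetics,
                               [-0.01, 0.0, 0.1], seed=77)
        pre = traj.pre_uv_snapshot
        assert len(pre.lesions) == 0
        assert pre.population.n_polymerases > 0
        assert len(traj.at(0.0).lesions) > 0

    def test_unsorted_timepoints_rejected(self, locus, profile, params, kinetics):
        with pytest.raises(ValueError):
            rt.run_scenario(locus, profile, params, kinetics,
                            [0.5, -0.25, 1.0], seed=1)

    def test_pre_uv_timepoint_required(self, locus, profile, params, kinetics):
        with pytest.raises(ValueError):
            rt.run_scenario(locus, profile, params, kinetics, [0.0, 1.0], seed=1)

    def test_trajectory_tsv_export(self, toy, tmp_path):
        run_steps(toy, 5)
        from ribotraffic.dynamics import Snapshot, Trajectory

        traj = Trajectory(toy.locus, toy.params, toy.kinetics)
        traj.snapshots.append(Snapshot(0.0, toy.population.copy(),
                                       toy.lesions.copy(),
                                       dict(toy.population.tallies)))
        traj.to_tsv(tmp_path)
        assert (tmp_path / "tallies.tsv").exists()
        assert any(p.name.startswith("population_") for p in tmp_path.iterdir())


class TestParamValidation:
    def test_footprint_must_be_below_spacing(self):
        with pytest.raises(ConfigurationError):
            rt.SimulationParams(footprint=130, steady_spacing=130)

    def test_unknown_release_mode(self):
        with pytest.raises(ConfigurationError):
            rt.SimulationParams(release_mode="teleport")

    def test_dt_bounds(self, toy):
        with pytest.raises(ConfigurationError):
            rt.SimulationParams(dt=6.0)
        with pytest.raises(ValueError):
            rt.advance(toy.population, toy.lesions, toy.params, toy.kinetics,
                       np.random.default_rng(0), dt=10.0)
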