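"""Hydrogen-bond candidate enumeration, the geometric bound-state
criterion, and the occupancy/persistence/stability filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igdyn import hbond_analysis as hb
from igdyn.domain_model import assign_beads
from igdyn.synthetic_data import (
    HBondTriadSpec,
    SyntheticAntibodySpec,
    build_synthetic_topology,
    generate_rigid_motion_trajectory,
    make_schedule,
    plant_hbond_schedule,
)
from igdyn.trajectory_io import TrajectoryFrames


@pytest.fixture(scope="module")
def triad_system(triad_antibody):
    ab = triad_antibody
    _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
    return ab, frag


class TestFindCandidates:
    def test_each_triad_yields_one_candidate_with_prefilter(self, triad_system):
        ab, frag = triad_system
        cands = hb.find_candidate_bonds(
            ab.topology, ab.frame0, frag, max_ha_distance=0.6
        )
        assert len(cands) == 3
        frags = sorted((c.donor_fragment, c.acceptor_fragment) for c in cands)
        assert frags == [("Fab1", "Fc"), ("Fab2", "Fc"), ("Fab2", "Fc")]

    def test_all_pairs_without_prefilter(self, triad_system):
        """3 N-H donors x 6 N/O acceptors minus the 3 same-residue
        donor-N pairs (donor nitrogens also act as acceptors)."""
        ab, frag = triad_system
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag)
        assert len(cands) == 3 * 6 - 3

    def test_exhaustive_enumeration_oracle(self):
        """3 donors x 2 acceptors across fragments -> exactly 6 candidates."""
        spec = SyntheticAntibodySpec(
            seed=77, atoms_per_domain=4, n_frames=4,
            hbond_triads=[
                HBondTriadSpec("Fab2", "Fc"),
                HBondTriadSpec("Fab2", "Fc"),
                HBondTriadSpec("Fab2", "Fc"),
            ],
        )
        ab = build_synthetic_topology(spec)
        _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag)
        # independent oracle: exhaustive product of typed donor/acceptor
        # sets minus same-residue exclusions
        donors = [(a.atom_index, (a.chain_id, a.residue_key))
                  for a in ab.topology.atoms if a.element == "H"]
        acceptors = [(a.atom_index, (a.chain_id, a.residue_key))
                     for a in ab.topology.atoms if a.element in ("N", "O")]
        expected = sum(1 for _, dres in donors for _, ares in acceptors
                       if dres != ares)
        assert len(cands) == expected == 3 * 6 - 3

    def test_no_hydrogens_is_explicit_error(self, small_antibody):
        ab = small_antibody  # pure-carbon pseudo-atoms, no H anywhere
        _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
        with pytest.raises(ValueError, match="explicit hydrogens"):
            hb.find_candidate_bonds(ab.topology, ab.frame0, frag)

    def test_same_residue_pairs_excluded(self, triad_system):
        ab, frag = triad_system
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag)
        for c in cands:
            d = ab.topology.atoms[c.donor_index]
            a = ab.topology.atoms[c.acceptor_index]
            assert (d.chain_id, d.residue_key) != (a.chain_id, a.residue_key)


class TestBoundStateCriterion:
    def _single_bond_traj(self, ha, dha_deg):
        """Minimal N-H...O system with prescribed geometry."""
        from igdyn.trajectory_io import AtomRecord, Topology

        atoms = [
            AtomRecord(0, "N", "N", 14.0, "A", 1, "ARG"),
            AtomRecord(1, "H", "H", 1.0, "A", 1, "ARG"),
            AtomRecord(2, "O", "O", 16.0, "A", 2, "GLU"),
        ]
        top = Topology(atoms, ["A"])
        ang = np.radians(dha_deg)
        # hydrogen at the origin so the H-A distance is exact in floats
        n = np.array([-0.1, 0.0, 0.0])
        if dha_deg == 180.0:  # exact collinear placement
            u = np.array([1.0, 0.0, 0.0])
        else:
            u = np.cos(ang) * np.array([-1.0, 0, 0]) + np.sin(ang) * np.array([0, 1.0, 0])
        X = np.array([[n, np.zeros(3), ha * u]])
        traj = TrajectoryFrames(X, np.zeros(1), top)
        bond = hb.HBondDefinition(0, 1, 2, "Fc", "Fab2")
        return traj, bond

    def test_canonical_bound_geometry(self):
        """H-A 0.20 nm with D-H-A 160 deg satisfies both cutoffs."""
        traj, bond = self._single_bond_traj(0.20, 160.0)
        (s,) = hb.evaluate_bound_states(traj, [bond])
        assert s.bound[0]

    @pytest.mark.parametrize(
        "ha,ang,expected",
        [
            (0.25, 180.0, False),   # distance exactly at cutoff: strict <
            (0.2499, 160.0, True),
            (0.20, 120.0, False),   # angle exactly at cutoff: strict >
            (0.20, 120.01, True),
            (0.40, 160.0, False),
        ],
    )
    def test_strict_cutoff_boundaries(self, ha, ang, expected):
        traj, bond = self._single_bond_traj(ha, ang)
        (s,) = hb.evaluate_bound_states(traj, [bond])
        assert bool(s.bound[0]) is expected

    def test_planted_schedule_recovered_exactly(self, triad_system):
        """Recovered bound-state series equals the planted schedule in
        100% of frames; occupancy exact to 1/F."""
        ab, frag = triad_system
        F = ab.spec.n_frames
        rng = np.random.default_rng(123)
        schedules = np.stack(
            [make_schedule(F, occ, rng, "random") for occ in (0.8, 0.5, 0.125)]
        )
        traj, _ = generate_rigid_motion_trajectory(ab, schedules=schedules)
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(traj, cands)
        by_h = {s.bond.hydrogen_index: s for s in states}
        for t, (n_i, h_i, o_i) in enumerate(ab.triads):
            s = by_h[h_i]
            np.testing.assert_array_equal(s.bound, schedules[t])
            assert s.occupancy == np.count_nonzero(schedules[t]) / F

    def test_counting_occupancy(self, triad_system):
        """Bond bound in frames 0..7 of 10 has occupancy 0.8 exactly."""
        ab, frag = triad_system
        sched = np.zeros((3, 10), dtype=bool)
        sched[:, :8] = True
        traj, _ = generate_rigid_motion_trajectory(ab, n_frames=10, schedules=sched)
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag,
                                        max_ha_distance=0.6)
        for s in hb.evaluate_bound_states(traj, cands):
            assert s.occupancy == 0.8

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_occupancy_invariant_to_frame_order(self, seed):
        rng = np.random.default_rng(seed)
        spec = SyntheticAntibodySpec(
            seed=55, atoms_per_domain=4, n_frames=30,
            hbond_triads=[HBondTriadSpec()],
        )
        ab = build_synthetic_topology(spec)
        _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
        sched = rng.random(30) < 0.5
        traj, _ = generate_rigid_motion_trajectory(ab, schedules=sched[None])
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag)
        occ1 = hb.evaluate_bound_states(traj, cands)[0].occupancy
        perm = rng.permutation(30)
        traj.coordinates = traj.coordinates[perm]
        occ2 = hb.evaluate_bound_states(traj, cands)[0].occupancy
        assert occ1 == occ2

    def test_tightening_cutoffs_never_raises_occupancy(self, triad_system):
        ab, frag = triad_system
        rng = np.random.default_rng(9)
        sched = np.stack([rng.random(ab.spec.n_frames) < p for p in (0.7, 0.4, 0.2)])
        traj, _ = generate_rigid_motion_trajectory(ab, schedules=sched)
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag)
        base = [s.occupancy for s in hb.evaluate_bound_states(traj, cands)]
        for d, a in [(0.22, 120.0), (0.25, 140.0), (0.21, 150.0)]:
            tight = [
                s.occupancy
                for s in hb.evaluate_bound_states(traj, cands, dist_cutoff=d, angle_cutoff=a)
            ]
            assert all(t <= b for t, b in zip(tight, base))


class TestFilters:
    def test_interfragment_filter(self, triad_system):
        ab, frag = triad_system
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(ab_traj(ab), cands)
        kept = hb.filter_interfragment(states, "Fab2", "Fc")
        assert len(kept) == 2
        for s in kept:
            assert {s.bond.donor_fragment, s.bond.acceptor_fragment} == {"Fab2", "Fc"}

    def test_orientation_agnostic(self):
        """Donor in Fc, acceptor in Fab2 is also a Fab2-Fc bond."""
        spec = SyntheticAntibodySpec(
            seed=17, atoms_per_domain=4, n_frames=4,
            hbond_triads=[HBondTriadSpec(donor_fragment="Fc", acceptor_fragment="Fab2")],
        )
        ab = build_synthetic_topology(spec)
        _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(ab_traj(ab), cands)
        assert len(hb.filter_interfragment(states, "Fab2", "Fc")) == 1

    def test_intra_fragment_bond_excluded(self):
        spec = SyntheticAntibodySpec(
            seed=18, atoms_per_domain=4, n_frames=4,
            hbond_triads=[HBondTriadSpec(donor_fragment="Fc", acceptor_fragment="Fc")],
        )
        ab = build_synthetic_topology(spec)
        _, frag = assign_beads(ab.topology, ab.config.beads, ab.config.fragments)
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(ab_traj(ab), cands)
        assert hb.filter_interfragment(states, "Fab2", "Fc") == []

    def test_unknown_fragment_label(self, triad_system):
        with pytest.raises(ValueError, match="unknown fragment"):
            hb.filter_interfragment([], "Fab2", "Fx")

    def test_persistence_definition(self, triad_system):
        """Occupancies {0.9, 0.85, 0.1} -> persistent in 2 replicates,
        hence stable; exactly 0.80 is NOT persistent (strict)."""
        ab, frag = triad_system
        F = 20
        occs = {"E1": [0.9, 0.80, 0.1], "E2": [0.85, 0.5, 0.9], "E3": [0.1, 0.80, 0.85]}
        per_rep = {}
        for rep, plan in occs.items():
            sched = np.stack([make_schedule(F, o) for o in plan])
            traj, _ = generate_rigid_motion_trajectory(ab, n_frames=F, schedules=sched)
            cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag,
                                            max_ha_distance=0.6)
            states = hb.evaluate_bound_states(traj, cands)
            per_rep[rep] = states
        report = hb.persistence_filter(per_rep, ab.topology)
        occ = report.occupancy
        # bond 0: 0.9, 0.85, 0.1 -> persistent in E1+E2 -> stable
        # bond 1: 0.80 occupancy is never persistent (strict threshold)
        # bond 2: 0.1, 0.9, 0.85 -> stable
        key0 = [k for k in occ.index if occ.loc[k, "E1"] == 0.9][0]
        key1 = [k for k in occ.index if occ.loc[k, "E1"] == 0.80][0]
        assert key0 in report.stable
        assert key1 not in report.persistent["E1"]
        assert key1 not in report.stable
        assert len(report.stable) == 2

    def test_missing_bonds_align_as_zero_occupancy(self, triad_system):
        ab, frag = triad_system
        F = 10
        sched = np.stack([make_schedule(F, o) for o in (0.9, 0.9, 0.9)])
        traj, _ = generate_rigid_motion_trajectory(ab, n_frames=F, schedules=sched)
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(traj, cands)
        report = hb.persistence_filter({"E1": states, "E2": states[:1]}, ab.topology)
        # bonds absent from E2 appear with occupancy 0 there
        assert (report.occupancy["E2"] == 0.0).sum() == 2
        assert len(report.stable) == 1

    def test_bond_count_series_matches_schedule_sum(self, triad_system):
        ab, frag = triad_system
        rng = np.random.default_rng(2)
        F = ab.spec.n_frames
        sched = np.stack([rng.random(F) < p for p in (0.5, 0.3, 0.8)])
        traj, _ = generate_rigid_motion_trajectory(ab, schedules=sched)
        cands = hb.find_candidate_bonds(ab.topology, traj.coordinates[0], frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(traj, cands)
        np.testing.assert_array_equal(hb.bond_count_series(states), sched.sum(axis=0))
        assert hb.bond_count_series([]).size == 0

    def test_unique_counts_both_ways(self, triad_system):
        ab, frag = triad_system
        cands = hb.find_candidate_bonds(ab.topology, ab.frame0, frag,
                                        max_ha_distance=0.6)
        states = hb.evaluate_bound_states(ab_traj(ab), cands)
        counts = hb.unique_bond_counts(states, ab.topology)
        assert counts["dha_triples"] == 3
        assert counts["donor_acceptor_pairs"] == 3


class TestAgainstMdtraj:
    def test_baker_hubbard_cross_check(self, triad_system):
        """A fully bound planted system is found by the independent
        mdtraj Baker-Hubbard implementation with the same cutoffs."""
        import mdtraj as md
        from igdyn.trajectory_io import _to_mdtraj_topology

        ab, frag = triad_system
        sched = np.ones((3, 5), dtype=bool)
        traj, _ = generate_rigid_motion_trajectory(ab, n_frames=5, schedules=sched)
        mtop = _to_mdtraj_topology(ab.topology)
        atoms = list(mtop.atoms)
        for n_i, h_i, _ in ab.triads:  # mdtraj finds donors via bonds
            mtop.add_bond(atoms[n_i], atoms[h_i])
        mtraj = md.Trajectory(traj.coordinates.astype(np.float32), mtop)
        triples = md.baker_hubbard(mtraj, freq=0.9, distance_cutoff=0.25, angle_cutoff=120)
        found = {(int(d), int(h), int(a)) for d, h, a in triples}
        assert set(ab.triads) <= found


def ab_traj(ab):
    """Single-frame trajectory at the built frame-0 coordinates."""
    return TrajectoryFrames(ab.frame0[None], np.zeros(1), ab.topology)
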