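"""Hydrogen-bond detection, event lifetimes, summaries, and correlation."""

import math

import numpy as np
import pytest

from _oracles import brute_hbond_pairs, run_length_events
from conftest import make_hbond_triple_trajectory
from ptfluct.core import Atom, BlockSpec, Box, Topology, Trajectory
from ptfluct.errors import CoverageError, DegenerateSummaryError
from ptfluct.fluctuations import MSFResult
from ptfluct.hbonds import (
    HBondCriteria,
    PairLifetime,
    detect_hbonds,
    detect_hbonds_frame,
    fluctuation_lifetime_dataset,
    occupancy_conservation_gap,
    summarize_lifetimes,
    track_events,
)
from ptfluct.synth import (
    TelegraphSpec,
    expected_observed_run_duration,
    generate_hbond_occupancy,
    realize_geometry,
)


def offset_at(distance, angle_deg):
    """H→A offset with given |H···A| and D-H···A angle (D−H along +x)."""
    theta = math.radians(180.0 - angle_deg)  # 180° = collinear extension
    return [distance * math.cos(theta), distance * math.sin(theta), 0.0]


class TestDetection:
    @pytest.mark.parametrize(
        "distance,angle,bonded",
        [
            (2.0, 150.0, True),
            (2.0, 120.0, False),  # angle too sharp
            (2.39, 150.0, True),  # just inside the distance cutoff
            (2.41, 150.0, False),  # just outside
            (2.0, 129.0, False),  # just below the angle cutoff
            (2.0, 131.0, True),  # just above
        ],
    )
    def test_distance_and_angle_cutoffs(self, distance, angle, bonded):
        traj = make_hbond_triple_trajectory([offset_at(distance, angle)])
        pairs = detect_hbonds_frame(traj, 0)
        assert (pairs == {(1, 2)}) is bonded

    def test_distance_cutoff_boundary_is_strict(self):
        # exactly representable geometry: H at x=11.0, A at x=13.5, cutoff
        # 2.5 Å — the H···A distance equals the cutoff exactly, and
        # "smaller than" must exclude it
        crit = HBondCriteria(d_ha_max=2.5)
        at_cut = make_hbond_triple_trajectory([[2.5, 0.0, 0.0]])
        assert detect_hbonds_frame(at_cut, 0, crit) == set()
        inside = make_hbond_triple_trajectory([[2.25, 0.0, 0.0]])
        assert detect_hbonds_frame(inside, 0, crit) == {(1, 2)}

    def test_angle_cutoff_boundary_is_strict(self):
        # a right-angle geometry against a 90° cutoff: D-H…A exactly 90°
        crit = HBondCriteria(d_ha_max=2.5, angle_min=90.0)
        at_cut = make_hbond_triple_trajectory([[0.0, 2.0, 0.0]])
        assert detect_hbonds_frame(at_cut, 0, crit) == set()
        past = make_hbond_triple_trajectory([[1.0, 2.0, 0.0]])  # obtuse
        assert detect_hbonds_frame(past, 0, crit) == {(1, 2)}

    def test_donor_heavy_atom_cannot_accept_from_own_hydrogen(self):
        atoms = [
            Atom(0, "N", "N", 0, "ALA", is_protein=True),
            Atom(1, "H", "H", 0, "ALA", is_protein=True,
                 bonded_heavy_partner=0),
        ]
        coords = np.array([[[10.0, 10, 10], [11.0, 10, 10]]])
        traj = Trajectory(Topology(atoms), coords, [Box.cubic(50.0)])
        assert detect_hbonds_frame(traj, 0) == set()

    def test_bifurcated_bonds_both_reported(self):
        # one hydrogen, two acceptors, both within criteria
        atoms = [
            Atom(0, "N", "N", 0, "ALA", is_protein=True),
            Atom(1, "H", "H", 0, "ALA", is_protein=True,
                 bonded_heavy_partner=0),
            Atom(2, "O", "O", 1, "ALA", is_protein=True),
            Atom(3, "O", "O", 2, "ALA", is_protein=True),
        ]
        h = np.array([11.0, 10.0, 10.0])
        coords = np.array(
            [[[10.0, 10, 10], h, h + offset_at(2.0, 160.0),
              h + np.array(offset_at(2.0, 160.0)) * [1, -1, 1]]]
        )
        traj = Trajectory(Topology(atoms), coords, [Box.cubic(50.0)])
        assert detect_hbonds_frame(traj, 0) == {(1, 2), (1, 3)}

    def test_minimum_image_bond_across_boundary(self):
        # acceptor sits across the periodic wall from the hydrogen
        atoms = [
            Atom(0, "N", "N", 0, "ALA", is_protein=True),
            Atom(1, "H", "H", 0, "ALA", is_protein=True,
                 bonded_heavy_partner=0),
            Atom(2, "O", "O", 1, "ALA", is_protein=True),
        ]
        coords = np.array([[[18.0, 10, 10], [19.0, 10, 10], [1.0, 10, 10]]])
        traj = Trajectory(Topology(atoms), coords, [Box.cubic(20.0)])
        assert detect_hbonds_frame(traj, 0) == {(1, 2)}  # H···A = 2.0 Å

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(77)
        for trial in range(25):
            edge = rng.uniform(12.0, 20.0)
            n_units = 12
            atoms, coords = [], []
            for k in range(n_units):
                base = 3 * k
                d_pos = rng.uniform(0, edge, 3)
                h_dir = rng.normal(size=3)
                h_dir /= np.linalg.norm(h_dir)
                atoms.append(Atom(base, "N", "N", k, "ALA", is_protein=True))
                atoms.append(Atom(base + 1, "H", "H", k, "ALA",
                                  is_protein=True, bonded_heavy_partner=base))
                atoms.append(Atom(base + 2, "O", "O", k, "ALA",
                                  is_protein=True))
                coords += [d_pos, d_pos + h_dir,
                           rng.uniform(0, edge, 3)]
            traj = Trajectory(Topology(atoms), np.array(coords)[None],
                              [Box.cubic(edge)])
            got = detect_hbonds_frame(traj, 0)
            donors = [3 * k + 1 for k in range(n_units)]
            # every polar heavy atom accepts, including donor-heavy N atoms
            acceptors = [3 * k for k in range(n_units)] + [
                3 * k + 2 for k in range(n_units)
            ]
            heavy = {3 * k + 1: 3 * k for k in range(n_units)}
            want = brute_hbond_pairs(traj.coordinates[0], donors, heavy,
                                     acceptors, Box.cubic(edge).vectors)
            assert got == want, f"trial {trial}"


class TestTrackEvents:
    def test_hand_counted_occupancy(self):
        # occupancy 1,1,1,0,0,1,1 → events of 3 ps and 2 ps; τ = 2.5 ps
        sets = [{(1, 2)}] * 3 + [set()] * 2 + [{(1, 2)}] * 2
        events, pairs = track_events(sets, 1.0)
        assert [e.duration for e in events] == [3.0, 2.0]
        assert pairs[0].n_events == 2
        assert pairs[0].tau == 2.5
        assert events[0].truncated  # starts at frame 0
        assert events[1].truncated  # runs to the final frame

    def test_all_zero_occupancy_has_no_pairs(self):
        events, pairs = track_events([set()] * 5, 1.0)
        assert events == [] and pairs == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(CoverageError):
            track_events([], 1.0)

    def test_interior_event_not_truncated(self):
        sets = [set(), {(0, 1)}, {(0, 1)}, set()]
        events, _ = track_events(sets, 1.0)
        assert len(events) == 1 and not events[0].truncated

    def test_gap_tolerance_bridges_short_interruptions(self):
        sets = [{(0, 1)}, set(), {(0, 1)}]
        strict, _ = track_events(sets, 1.0, gap_tolerance=0)
        bridged, _ = track_events(sets, 1.0, gap_tolerance=1)
        assert [e.duration for e in strict] == [1.0, 1.0]
        assert [e.duration for e in bridged] == [3.0]

    def test_matches_run_length_oracle_on_telegraph(self, telegraph_occupancy):
        occ = telegraph_occupancy
        events, pairs = track_events(occ.per_frame_sets, 1.0)
        for p, pair_id in enumerate(occ.pair_ids):
            oracle_runs = run_length_events(occ.occupancy[p])
            got = sorted(
                (e.start_frame, e.end_frame)
                for e in events
                if (e.donor_hydrogen, e.acceptor) == pair_id
            )
            assert got == oracle_runs

    def test_conservation_links_events_to_population(self, telegraph_occupancy):
        occ = telegraph_occupancy
        _, pairs = track_events(occ.per_frame_sets, 1.0)
        assert occupancy_conservation_gap(
            pairs, occ.per_frame_sets, 1.0
        ) == pytest.approx(0.0, abs=1e-9)

    def test_telegraph_lifetime_recovery(self):
        spec = TelegraphSpec(tau_on=25.0, tau_off=25.0, n_pairs=30,
                             duration=20_000.0, seed=13)
        occ = generate_hbond_occupancy(spec)
        _, pairs = track_events(occ.per_frame_sets, 1.0)
        durations = np.concatenate(
            [[p.tau] * 0 for p in pairs]
            + [[e for e in [p.total_time / p.n_events]] for p in pairs]
        )
        all_durs = []
        for p in pairs:
            all_durs += [p.total_time / p.n_events] * p.n_events
        all_durs = np.asarray(all_durs)
        expected = expected_observed_run_duration(25.0, 25.0, 1.0)
        sem = all_durs.std() / np.sqrt(len(all_durs))
        assert abs(all_durs.mean() - expected) < 3 * max(sem, 0.3)

    def test_event_order_invariance(self, telegraph_occupancy):
        occ = telegraph_occupancy
        sets = occ.per_frame_sets
        _, a = track_events(sets, 1.0)
        # re-present the same sets with different internal ordering
        shuffled = [set(sorted(s, reverse=True)) for s in sets]
        _, b = track_events(shuffled, 1.0)
        assert [(p.donor_hydrogen, p.acceptor, p.tau) for p in a] == [
            (p.donor_hydrogen, p.acceptor, p.tau) for p in b
        ]


class TestSummarize:
    def test_two_pair_mean(self):
        sets = [{("a", "b")}] * 4  # population constant at 1
        pairs = [
            PairLifetime("a", "b", 1, 2.0, 2.0),
            PairLifetime("c", "d", 1, 4.0, 4.0),
        ]
        s = summarize_lifetimes(pairs, sets, BlockSpec(2.0, 2))
        assert s.tau_hb == 3.0
        assert s.n_unique_pairs == 2

    def test_exclusion_rule(self):
        sets = [{("a", "b")}] * 4
        pairs = [
            PairLifetime("a", "b", 1, 2.0, 2.0),
            PairLifetime("c", "d", 1, 4.0, 4.0),
            PairLifetime("e", "f", 1, 1500.0, 1500.0),
        ]
        s = summarize_lifetimes(pairs, sets, BlockSpec(2.0, 2))
        assert s.tau_hb == 3.0  # unchanged by the long-lived pair
        assert s.n_unique_pairs == 3
        assert len(s.excluded_pairs) == 1
        assert s.excluded_pairs[0][0] == ("e", "f")

    def test_all_pairs_excluded_is_degenerate(self):
        sets = [{("a", "b")}] * 2
        pairs = [PairLifetime("a", "b", 1, 2000.0, 2000.0)]
        with pytest.raises(DegenerateSummaryError):
            summarize_lifetimes(pairs, sets, BlockSpec(1.0, 1))

    def test_population_counts_every_pair(self, telegraph_occupancy):
        occ = telegraph_occupancy
        sets = occ.per_frame_sets
        _, pairs = track_events(sets, 1.0)
        s = summarize_lifetimes(pairs, sets, BlockSpec(2000.0, 5))
        assert s.n_hb == pytest.approx(np.mean([len(x) for x in sets]))

    def test_brute_force_tau_hb(self, telegraph_occupancy):
        occ = telegraph_occupancy
        sets = occ.per_frame_sets
        _, pairs = track_events(sets, 1.0)
        s = summarize_lifetimes(pairs, sets, BlockSpec(2000.0, 5))
        kept = [p.tau for p in pairs if p.tau <= 1000.0]
        assert s.tau_hb == pytest.approx(sum(kept) / len(kept), rel=1e-10)


def _msf_result_for(acceptors, msf_values):
    acceptors = np.asarray(acceptors)
    vals = np.asarray(msf_values, float)
    return MSFResult(
        atom_indices=acceptors,
        atom_residue_indices=np.zeros_like(acceptors),
        per_atom_per_block=vals[:, None],
        per_atom_mean=vals,
        global_msf=float(vals.mean()),
        global_error=0.0,
        residue_indices=np.array([0]),
        residue_names=np.array(["ALA"]),
        per_residue_mean=np.array([vals.mean()]),
    )


class TestCorrelationDataset:
    def test_single_acceptor_row(self):
        msf = _msf_result_for([2], [0.5])
        pairs = [PairLifetime(1, 2, 4, 10.0, 40.0)]
        rows, _ = fluctuation_lifetime_dataset(msf, pairs)
        assert len(rows) == 1
        assert rows[0]["inv_msf"] == pytest.approx(2.0)
        assert rows[0]["ln_tau"] == pytest.approx(math.log(10.0))

    def test_short_lifetime_filtered(self):
        msf = _msf_result_for([2], [0.5])
        pairs = [PairLifetime(1, 2, 4, 1.5, 6.0)]
        with pytest.warns(UserWarning):
            rows, r = fluctuation_lifetime_dataset(msf, pairs)
        assert rows == [] and math.isnan(r)

    def test_event_weighting_pools_donors(self):
        # acceptor 5 bonded by two donors: 3 events×2 ps and 1 event×10 ps
        msf = _msf_result_for([5], [0.5])
        pairs = [
            PairLifetime(1, 5, 3, 2.0, 6.0),
            PairLifetime(2, 5, 1, 10.0, 10.0),
        ]
        rows, _ = fluctuation_lifetime_dataset(msf, pairs, weighting="event")
        assert rows[0]["tau"] == pytest.approx(16.0 / 4)
        rows_u, _ = fluctuation_lifetime_dataset(msf, pairs, weighting="pair")
        assert rows_u[0]["tau"] == pytest.approx(6.0)

    def test_constructed_inverse_relation_recovered(self):
        # MSF_i ∝ 1/ln τ_i by construction → near-perfect correlation
        rng = np.random.default_rng(19)
        taus = rng.uniform(3.0, 400.0, 60)
        msf_vals = 0.3 / np.log(taus)
        acceptors = np.arange(60) * 3 + 2
        msf = _msf_result_for(acceptors, msf_vals)
        pairs = [
            PairLifetime(int(a) - 1, int(a), 5, float(t), float(5 * t))
            for a, t in zip(acceptors, taus)
        ]
        rows, r = fluctuation_lifetime_dataset(msf, pairs)
        assert len(rows) == 60
        assert r > 0.95


class TestGeometricRealization:
    def test_detector_reproduces_schedule(self):
        spec = TelegraphSpec(tau_on=8.0, tau_off=8.0, n_pairs=6,
                             duration=60.0, seed=23)
        occ = generate_hbond_occupancy(spec)
        traj = realize_geometry(occ)
        assert detect_hbonds(traj) == occ.per_frame_sets
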