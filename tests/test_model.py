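"""Energy model: square-well terms, hydrogen bonds, and bookkeeping.

The total-energy oracle here is an independent implementation: an explicit
double loop over all bead pairs plus a brute-force (enumerative) maximum
matching for the hydrogen bonds, written directly from the interaction rules.
"""

import itertools
import math

import numpy as np
import pytest

from pepdimer.geometry import minimum_image, rotation_matrix
from pepdimer.model import (
    INFEASIBLE,
    System,
    bond_energy,
    delta_energy,
    hbond_eligible,
    pair_energy,
    total_energy,
)
from pepdimer.moves import MoveConfig, PeptideLandscape
from pepdimer.params import load_parameters
from pepdimer.topology import build_topology


class TestBondEnergy:
    def test_ideal_length_feasible(self):
        assert bond_energy(1.46, 1.46, 0.02375) == 0.0

    def test_window_boundaries_inclusive(self):
        assert bond_energy(1.46 * (1 - 0.02375), 1.46, 0.02375) == 0.0
        assert bond_energy(1.46 * (1 + 0.02375), 1.46, 0.02375) == 0.0

    def test_outside_window_infeasible(self):
        assert bond_energy(1.46 * 1.05, 1.46, 0.02375) == INFEASIBLE
        assert bond_energy(0.0, 1.46, 0.02375) == INFEASIBLE


class TestPairEnergy:
    def test_core_overlap_infeasible(self):
        assert pair_energy(1.0, 2.0, 4.0, -0.5) == INFEASIBLE
        assert pair_energy(2.0, 2.0, 4.0, -0.5) == INFEASIBLE

    def test_inside_well(self):
        assert pair_energy(3.0, 2.0, 4.0, -0.5) == -0.5

    def test_beyond_range(self):
        assert pair_energy(4.0, 2.0, 4.0, -0.5) == 0.0
        assert pair_energy(8.0, 2.0, 4.0, -0.5) == 0.0


class TestHBondEligibility:
    def _aligned_geometry(self):
        # donor NH at origin, acceptor CO 4.0 A away along x; both alpha
        # carbons pulled straight back, well outside the auxiliary threshold
        nh = np.zeros(3)
        co = np.array([4.0, 0.0, 0.0])
        donor_ca = np.array([-1.46, 0.0, 0.0])
        acceptor_ca = np.array([5.51, 0.0, 0.0])
        return nh, co, donor_ca, acceptor_ca

    def test_collinear_geometry_within_range_bonds(self, params):
        nh, co, dca, aca = self._aligned_geometry()
        assert hbond_eligible(nh, co, dca, aca, params,
                              same_chain=False, separation=0)

    def test_distance_beyond_well_refused(self, params):
        nh, co, dca, aca = self._aligned_geometry()
        co2 = co + np.array([1.0, 0.0, 0.0])
        assert not hbond_eligible(nh, co2, dca, aca + 1.0, params,
                                  same_chain=False, separation=0)

    def test_sequence_neighbors_refused(self, params):
        nh, co, dca, aca = self._aligned_geometry()
        assert not hbond_eligible(nh, co, dca, aca, params,
                                  same_chain=True, separation=1)
        assert hbond_eligible(nh, co, dca, aca, params,
                              same_chain=True, separation=4)

    def test_occupied_partner_refused(self, params):
        nh, co, dca, aca = self._aligned_geometry()
        assert not hbond_eligible(nh, co, dca, aca, params,
                                  same_chain=False, separation=0,
                                  donor_free=False)

    def test_misaligned_flanking_bead_refused(self, params):
        nh, co, dca, aca = self._aligned_geometry()
        # donor CA pushed right next to the acceptor: alignment violated
        bad_dca = np.array([3.0, 1.0, 0.0])
        assert not hbond_eligible(nh, co, bad_dca, aca, params,
                                  same_chain=False, separation=0)


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_energy(system, coords):
    """Pairwise double loop + enumerative H-bond matching, written from the
    interaction rules without reusing the model's vectorized path."""
    p = system.params
    n = system.n_beads
    L = system.box_edge

    def dist(i, j):
        d = minimum_image(coords[i] - coords[j], L)
        return float(np.linalg.norm(d))

    # bonds
    for bi, bj, lo, hi in zip(system.bond_i, system.bond_j,
                              system.bond_lo, system.bond_hi):
        if not (lo <= dist(bi, bj) <= hi):
            return math.inf

    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r = dist(i, j)
            d_hs = system.hs_matrix[i, j]
            if d_hs > 0 and r <= d_hs:
                return math.inf
            if system.kind_of[i] == "SC" and system.kind_of[j] == "SC":
                ci = system.topologies[system.chain_of[i]].classes[
                    system.residue_of[i]]
                cj = system.topologies[system.chain_of[j]].classes[
                    system.residue_of[j]]
                eps = p.well_depth(ci, cj)
                if eps != 0.0 and d_hs < r < p.sw_range(ci, cj):
                    energy += eps

    # hydrogen bonds: enumerate all eligible pairs, then maximize the number
    # of simultaneous bonds over all subsets with distinct donors/acceptors
    eligible = []
    for di, d in enumerate(system.donors):
        for ai, a in enumerate(system.acceptors):
            same = system.chain_of[d] == system.chain_of[a]
            sep = abs(int(system.residue_of[d]) - int(system.residue_of[a]))
            if hbond_eligible(coords[d], coords[a],
                              coords[system.donor_ca[di]],
                              coords[system.acceptor_ca[ai]],
                              p, same_chain=same, separation=sep,
                              box_edge=L):
                eligible.append((d, a))
    best = 0
    for k in range(len(eligible), 0, -1):
        if k <= best:
            break
        for combo in itertools.combinations(eligible, k):
            donors = {d for d, _ in combo}
            acceptors = {a for _, a in combo}
            if len(donors) == k and len(acceptors) == k:
                best = k
                break
    return energy + p.hbond_energy * best


def _sample_states(landscape, n_moves, seed):
    """Walk the proposal chain accepting every feasible move."""
    rng = np.random.default_rng(seed)
    state = landscape.initial_state(rng)
    states = [state]
    for _ in range(n_moves):
        cand, e = landscape.propose(state, rng)
        if cand is not None:
            state = cand
            states.append(state)
    return states


class TestTotalEnergy:
    def test_separated_extended_chains_have_no_contacts(self, params):
        topo = build_topology("AKA", params)  # H-P-H: no adjacent H-H wells
        system = System([topo, topo], params, 200.0)
        from pepdimer.geometry import build_chain_coords

        single = build_chain_coords(topo, params)
        coords = np.vstack([single, single + np.array([0.0, 50.0, 0.0])])
        e, _, hb, _ = system.evaluate(coords)
        # chains are 50 A apart: no interchain term can reach; intrachain
        # H-H wells need |i-j| >= 2 hydrophobic pairs, here distance > range
        assert math.isfinite(e)
        assert e == pytest.approx(
            brute_force_energy(system, coords), abs=1e-12)

    def test_energy_matches_brute_force_along_a_walk(self, tri_system):
        landscape = PeptideLandscape(tri_system)
        states = _sample_states(landscape, 400, seed=11)
        for state in states[:: max(1, len(states) // 25)]:
            assert state.energy == pytest.approx(
                brute_force_energy(tri_system, state.coords), abs=1e-12)

    def test_dimer_energy_matches_brute_force(self, params):
        topo = build_topology("AAAA", params)
        system = System([topo, topo], params, 40.0)
        landscape = PeptideLandscape(system)
        states = _sample_states(landscape, 400, seed=3)
        for state in states[:: max(1, len(states) // 15)]:
            assert state.energy == pytest.approx(
                brute_force_energy(system, state.coords), abs=1e-12)

    def test_hbond_count_scales_energy(self, params):
        """With all side-chain wells switched off, the energy is exactly
        minus the number of hydrogen bonds."""
        raw = {
            "bond_lengths": dict(params.bond_lengths),
            "pseudobond_lengths": dict(params.pseudobond_lengths),
            "delta": params.delta,
            "hs_diameters": dict(params.hs_diameters),
            "sw_ranges": {},
            "well_depths": {},
            "hbond_range": 4.5,
            "hbond_energy": -1.0,
            "squeeze_factors": dict(params.squeeze_factors),
        }
        p2 = load_parameters(raw)
        topo = build_topology("AAAAA", p2)
        system = System([topo, topo], p2, 60.0)
        landscape = PeptideLandscape(system)
        states = _sample_states(landscape, 600, seed=19)
        for state in states:
            assert state.energy == pytest.approx(-len(state.hb_pairs))

    def test_all_wells_zeroed_gives_zero_energy(self, params):
        raw = {
            "bond_lengths": dict(params.bond_lengths),
            "pseudobond_lengths": dict(params.pseudobond_lengths),
            "delta": params.delta,
            "hs_diameters": dict(params.hs_diameters),
            "sw_ranges": {},
            "well_depths": {},
            "hbond_range": 4.5,
            "hbond_energy": 0.0,
            "squeeze_factors": dict(params.squeeze_factors),
        }
        p2 = load_parameters(raw)
        topo = build_topology("AAA", p2)
        system = System([topo], p2, 60.0)
        landscape = PeptideLandscape(system)
        for state in _sample_states(landscape, 200, seed=5):
            assert state.energy == 0.0


class TestInvariances:
    def test_translation_and_rotation_invariance(self, tri_system):
        landscape = PeptideLandscape(tri_system)
        state = _sample_states(landscape, 200, seed=2)[-1]
        e0, *_ = tri_system.evaluate(state.coords)
        shifted = state.coords + np.array([3.1, -7.2, 11.0])
        e1, *_ = tri_system.evaluate(shifted)
        rot = rotation_matrix(np.array([1.0, 2.0, 3.0]), 0.7)
        rotated = state.coords @ rot.T
        e2, *_ = tri_system.evaluate(rotated)
        assert e1 == pytest.approx(e0, abs=1e-12)
        assert e2 == pytest.approx(e0, abs=1e-12)

    def test_identical_chain_swap_invariance(self, params):
        topo = build_topology("AAAA", params)
        system = System([topo, topo], params, 40.0)
        landscape = PeptideLandscape(system)
        state = _sample_states(landscape, 300, seed=8)[-1]
        n = topo.n_beads
        swapped = np.vstack([state.coords[n:], state.coords[:n]])
        e0, *_ = system.evaluate(state.coords)
        e1, *_ = system.evaluate(swapped)
        assert e1 == pytest.approx(e0, abs=1e-12)

    def test_periodic_image_translation_invariance(self, params):
        topo = build_topology("AAAA", params)
        system = System([topo, topo], params, 40.0)
        landscape = PeptideLandscape(system)
        state = _sample_states(landscape, 100, seed=13)[-1]
        n = topo.n_beads
        shifted = state.coords.copy()
        shifted[n:] += np.array([40.0, 0.0, 0.0])  # exact periodic image
        e0, *_ = system.evaluate(state.coords)
        e1, *_ = system.evaluate(shifted)
        assert e1 == pytest.approx(e0, abs=1e-12)


class TestDeltaEnergy:
    def test_null_move_is_zero(self, tri_system):
        landscape = PeptideLandscape(tri_system)
        state = landscape.initial_state(np.random.default_rng(0))
        d = delta_energy(tri_system, state, np.array([0]), state.coords.copy())
        assert d == 0.0

    def test_incremental_bookkeeping_equals_recomputation(self, params):
        """1000 proposals: the cached energy after each accepted move equals
        a from-scratch evaluation exactly (discrete spectrum)."""
        topo = build_topology("AAAAA", params)
        system = System([topo, topo], params, 60.0)
        landscape = PeptideLandscape(system)
        rng = np.random.default_rng(42)
        state = landscape.initial_state(rng)
        accepted = 0
        for i in range(1000):
            cand, e = landscape.propose(state, rng)
            if cand is not None:
                state = cand
                accepted += 1
                if accepted % 50 == 0:
                    fresh = total_energy(state, system)
                    assert state.energy == fresh
        assert accepted > 50  # the walk actually moved

    def test_registry_has_unique_partners(self, params):
        topo = build_topology("AAAAAA", params)
        system = System([topo, topo], params, 50.0)
        landscape = PeptideLandscape(system)
        for state in _sample_states(landscape, 800, seed=77):
            donors = [d for d, _ in state.hb_pairs]
            acceptors = [a for _, a in state.hb_pairs]
            assert len(donors) == len(set(donors))
            assert len(acceptors) == len(set(acceptors))
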