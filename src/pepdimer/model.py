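"""Square-well energy model for one or two coarse-grained chains in a
periodic box.

Potential-energy terms, all discrete (energies are finite sums of tabulated
well depths, in units of the hydrogen-bond depth eps_HB):

* covalent/pseudo bonds: zero inside the window ``r_ideal * (1 +- delta)``,
  infeasible outside (move rejection);
* hard cores: infeasible at ``r <= d_ij`` for every non-bonded pair, with the
  Lorentz-Berthelot mean diameter scaled by the squeeze factor for the listed
  close-in-sequence pairs;
* side-chain square wells: depth ``eps_ij`` for ``d_hs < r < d_sw``;
* backbone hydrogen bonds: depth -1 for an NH->CO pair within 4.5 A that also
  satisfies the auxiliary alignment criterion (the donor's and acceptor's
  alpha carbons must stay outside a minimum separation from the partner) and
  the intramolecular sequence-separation rule.  Each donor and each acceptor
  may participate in at most one bond; the hydrogen-bond count of a
  configuration is the size of the *maximum* matching of eligible pairs, which
  makes the energy a pure function of the coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import SetupError, build_chain_coords, minimum_image
from .params import ParameterSet, combined_hs_diameter
from .topology import ChainTopology

__all__ = [
    "bond_energy",
    "pair_energy",
    "hbond_eligible",
    "SystemState",
    "System",
    "total_energy",
    "delta_energy",
    "INFEASIBLE",
]

#: sentinel energy for constraint-violating configurations
INFEASIBLE = math.inf


def bond_energy(r: float, r_ideal: float, delta: float) -> float:
    """Square-well bond term: 0 inside the inclusive window, else infeasible."""
    if r_ideal * (1.0 - delta) <= r <= r_ideal * (1.0 + delta):
        return 0.0
    return INFEASIBLE


def pair_energy(r: float, d_hs: float, d_sw: float, eps: float) -> float:
    """Hard-sphere + square-well pair term.

    Infeasible at ``r <= d_hs``; ``eps`` on the open well ``(d_hs, d_sw)``;
    zero at and beyond ``d_sw``.
    """
    if r <= d_hs:
        return INFEASIBLE
    if r < d_sw:
        return eps
    return 0.0


def hbond_eligible(
    nh: np.ndarray,
    co: np.ndarray,
    donor_ca: np.ndarray,
    acceptor_ca: np.ndarray,
    params: ParameterSet,
    *,
    same_chain: bool,
    separation: int,
    box_edge: float = math.inf,
    donor_free: bool = True,
    acceptor_free: bool = True,
) -> bool:
    """Geometric + bookkeeping eligibility of one NH->CO hydrogen bond.

    Requires the NH-CO distance within the bond range, the auxiliary
    alignment criterion (both partner alpha carbons at least ``hbond_aux_min``
    away from the opposite bond partner), the intramolecular sequence
    separation rule, and both partners currently unbonded.
    """
    if not (donor_free and acceptor_free):
        return False
    if same_chain and abs(separation) < params.hbond_min_separation:
        return False

    def dist(a, b):
        d = np.asarray(a, float) - np.asarray(b, float)
        if math.isfinite(box_edge):
            d = minimum_image(d, box_edge)
        return float(np.linalg.norm(d))

    r = dist(nh, co)
    d_hs = combined_hs_diameter(params.hs_diameters["NH"], params.hs_diameters["CO"])
    if not (d_hs < r < params.hbond_range):
        return False
    if dist(donor_ca, co) < params.hbond_aux_min:
        return False
    if dist(nh, acceptor_ca) < params.hbond_aux_min:
        return False
    return True


@dataclass
class SystemState:
    """Coordinates plus cached energy bookkeeping of the whole system."""

    coords: np.ndarray  # (n_beads, 3), Angstrom, unwrapped per chain
    box_edge: float
    energy: float = 0.0
    # integer occupation count per distinct side-chain well depth (aligned
    # with System.sw_depths); keeps incremental bookkeeping exact
    sw_counts: tuple = ()
    hb_pairs: tuple = ()  # ((donor bead, acceptor bead), ...) current registry
    dist: np.ndarray | None = None  # cached minimum-image distance matrix

    def copy(self) -> "SystemState":
        return SystemState(
            coords=self.coords.copy(),
            box_edge=self.box_edge,
            energy=self.energy,
            sw_counts=self.sw_counts,
            hb_pairs=self.hb_pairs,
            dist=None if self.dist is None else self.dist.copy(),
        )


class System:
    """Static interaction tables for a fixed set of chains in a box."""

    def __init__(self, topologies: list[ChainTopology], params: ParameterSet,
                 box_edge: float):
        self.topologies = list(topologies)
        self.params = params
        self.box_edge = float(box_edge)

        offsets = []
        n = 0
        for topo in self.topologies:
            offsets.append(n)
            n += topo.n_beads
        self.offsets = offsets
        self.n_beads = n

        self.chain_of = np.empty(n, dtype=int)
        self.residue_of = np.empty(n, dtype=int)
        self.kind_of = np.empty(n, dtype="<U2")
        for c, topo in enumerate(self.topologies):
            o = offsets[c]
            self.chain_of[o : o + topo.n_beads] = c
            self.residue_of[o : o + topo.n_beads] = topo.residue_of
            self.kind_of[o : o + topo.n_beads] = topo.kind_of

        # --- bonds ---
        bi, bj, lo, hi = [], [], [], []
        bonded = np.zeros((n, n), dtype=bool)
        for c, topo in enumerate(self.topologies):
            o = offsets[c]
            for b in topo.bonds:
                bi.append(o + b.i)
                bj.append(o + b.j)
                lo.append(b.length * (1.0 - params.delta))
                hi.append(b.length * (1.0 + params.delta))
                bonded[o + b.i, o + b.j] = bonded[o + b.j, o + b.i] = True
        self.bond_i = np.array(bi, dtype=int)
        self.bond_j = np.array(bj, dtype=int)
        self.bond_lo = np.array(lo)
        self.bond_hi = np.array(hi)
        self.bonded = bonded
        self.bonds_of_bead = [
            np.nonzero((self.bond_i == k) | (self.bond_j == k))[0] for k in range(n)
        ]

        # --- hard-sphere matrix: per-chain blocks from the shared topology
        # table (squeeze + bond exemptions), plain Lorentz-Berthelot means
        # across chains ---
        d = np.array([params.hs_diameters[k] for k in self.kind_of])
        hs = 0.5 * (d[:, None] + d[None, :])
        for c, topo in enumerate(self.topologies):
            o = offsets[c]
            hs[o : o + topo.n_beads, o : o + topo.n_beads] = topo.hs_matrix(params)
        self.hs_matrix = hs

        # --- side-chain square wells ---
        eps_mat = np.zeros((n, n))
        dsw_mat = np.zeros((n, n))
        sc_idx = np.nonzero(self.kind_of == "SC")[0]
        for a in sc_idx:
            cls_a = self.topologies[self.chain_of[a]].classes[self.residue_of[a]]
            for b in sc_idx:
                if b <= a:
                    continue
                cls_b = self.topologies[self.chain_of[b]].classes[self.residue_of[b]]
                eps = params.well_depth(cls_a, cls_b)
                if eps != 0.0:
                    eps_mat[a, b] = eps_mat[b, a] = eps
                    rng = params.sw_range(cls_a, cls_b)
                    dsw_mat[a, b] = dsw_mat[b, a] = rng
        self.sw_eps = eps_mat
        self.sw_dsw = dsw_mat
        # distinct well depths: energies are tracked as integer occupation
        # counts per depth so that incremental and from-scratch bookkeeping
        # agree exactly (no float accumulation)
        self.sw_depths = np.array(sorted({v for v in eps_mat.ravel() if v}))
        depth_index = np.full((n, n), -1, dtype=np.int8)
        for k, d in enumerate(self.sw_depths):
            depth_index[eps_mat == d] = k
        self.sw_depth_index = depth_index
        iu = np.triu_indices(n, 1)
        self.pairs_iu = iu

        # --- hydrogen-bond bookkeeping ---
        self.donors = np.nonzero(self.kind_of == "NH")[0]
        self.acceptors = np.nonzero(self.kind_of == "CO")[0]
        self.donor_ca = np.array(
            [self._ca_of(b) for b in self.donors], dtype=int
        )
        self.acceptor_ca = np.array(
            [self._ca_of(b) for b in self.acceptors], dtype=int
        )
        same_chain = (
            self.chain_of[self.donors][:, None] == self.chain_of[self.acceptors][None, :]
        )
        sep = np.abs(
            self.residue_of[self.donors][:, None]
            - self.residue_of[self.acceptors][None, :]
        )
        self.hb_allowed = ~(same_chain & (sep < params.hbond_min_separation))
        self.hb_d_hs = combined_hs_diameter(
            params.hs_diameters["NH"], params.hs_diameters["CO"]
        )
        # precomputed gather grids for the matching, and the set of beads
        # whose motion can change hydrogen-bond eligibility at all
        self._hb_ix_da = np.ix_(self.donors, self.acceptors)
        self._hb_ix_ca_a = np.ix_(self.donor_ca, self.acceptors)
        self._hb_ix_d_ca = np.ix_(self.donors, self.acceptor_ca)
        relevant = np.zeros(n, dtype=bool)
        relevant[self.donors] = True
        relevant[self.acceptors] = True
        relevant[self.donor_ca] = True
        relevant[self.acceptor_ca] = True
        self._hb_relevant = relevant

    def _ca_of(self, bead: int) -> int:
        c = self.chain_of[bead]
        return self.offsets[c] + self.topologies[c].bead_index(
            self.residue_of[bead], "CA"
        )

    # ------------------------------------------------------------------
    def distance_matrix(self, coords: np.ndarray) -> np.ndarray:
        dx = coords[:, None, :] - coords[None, :, :]
        dx = minimum_image(dx, self.box_edge)
        return np.sqrt(np.einsum("ijk,ijk->ij", dx, dx))

    def _hbond_matching(self, dist: np.ndarray) -> tuple:
        """Maximum matching of eligible NH->CO pairs; returns pair tuple."""
        D = dist[self._hb_ix_da]
        aux1 = dist[self._hb_ix_ca_a]  # CA_i - CO_j
        aux2 = dist[self._hb_ix_d_ca]  # NH_i - CA_j
        p = self.params
        eligible = (
            self.hb_allowed
            & (D > self.hb_d_hs)
            & (D < p.hbond_range)
            & (aux1 >= p.hbond_aux_min)
            & (aux2 >= p.hbond_aux_min)
        )
        if not eligible.any():
            return ()
        adj = [np.nonzero(row)[0].tolist() for row in eligible]
        match_acc = {}  # acceptor column -> donor row

        def try_assign(row, seen):
            for col in adj[row]:
                if col in seen:
                    continue
                seen.add(col)
                if col not in match_acc or try_assign(match_acc[col], seen):
                    match_acc[col] = row
                    return True
            return False

        for row in range(len(adj)):
            if adj[row]:
                try_assign(row, set())
        return tuple(
            sorted((int(self.donors[r]), int(self.acceptors[c]))
                   for c, r in match_acc.items())
        )

    def evaluate(self, coords: np.ndarray, dist: np.ndarray | None = None):
        """Full energy evaluation.

        Returns ``(energy, sw_energy, hb_pairs, dist)``; energy is the
        INFEASIBLE sentinel when any bond window or hard core is violated.
        """
        if dist is None:
            dist = self.distance_matrix(coords)
        r_b = dist[self.bond_i, self.bond_j]
        if np.any(r_b < self.bond_lo) or np.any(r_b > self.bond_hi):
            return INFEASIBLE, 0.0, (), dist
        iu = self.pairs_iu
        r = dist[iu]
        hs = self.hs_matrix[iu]
        if np.any((hs > 0.0) & (r <= hs)):
            return INFEASIBLE, (), (), dist
        eps = self.sw_eps[iu]
        dsw = self.sw_dsw[iu]
        in_well = (eps != 0.0) & (r > hs) & (r < dsw)
        sw_counts = tuple(
            int(np.count_nonzero(in_well & (eps == d))) for d in self.sw_depths)
        hb_pairs = self._hbond_matching(dist)
        energy = self._assemble_energy(sw_counts, hb_pairs)
        return energy, sw_counts, hb_pairs, dist

    def _assemble_energy(self, sw_counts, hb_pairs) -> float:
        e = self.params.hbond_energy * len(hb_pairs)
        for d, c in zip(self.sw_depths, sw_counts):
            e += d * c
        return e

    def make_state(self, coords: np.ndarray) -> SystemState:
        """Wrap coordinates into a state with verified cached energy."""
        energy, sw_counts, hb, dist = self.evaluate(coords)
        if not math.isfinite(energy):
            raise SetupError("initial configuration violates model constraints")
        return SystemState(
            coords=coords.copy(), box_edge=self.box_edge, energy=energy,
            sw_counts=sw_counts, hb_pairs=hb, dist=dist,
        )

    def initial_state(self, gap: float = 12.0, max_tries: int = 25) -> SystemState:
        """Place extended chains side by side without overlap.

        Chains are embedded by :func:`build_chain_coords` and offset along x
        by increasing gaps until the combined configuration is feasible.
        """
        per_chain = [build_chain_coords(t, self.params) for t in self.topologies]
        if len(per_chain) == 1:
            return self.make_state(per_chain[0])
        for k in range(max_tries):
            g = gap + 2.0 * k
            coords = []
            y0 = 0.0
            for c in per_chain:
                shifted = c.copy()
                shifted[:, 1] += y0
                coords.append(shifted)
                y0 += g
            stacked = np.vstack(coords)
            stacked -= stacked.mean(axis=0)
            try:
                return self.make_state(stacked)
            except SetupError:
                continue
        raise SetupError("no feasible initial placement after bounded retries")

    # incremental evaluation --------------------------------------------
    def evaluate_move(self, state: SystemState, moved: np.ndarray,
                      new_coords: np.ndarray):
        """Energy of a candidate that displaces the beads listed in ``moved``.

        Returns ``(energy, sw_counts, hb_pairs, patched_dist)``; the patched
        distance matrix becomes the candidate's cache if accepted.  Uses the
        cached distance matrix of ``state`` for all unmoved pairs.
        """
        from ._kernels import move_kernel

        moved = np.ascontiguousarray(moved, dtype=np.int64)
        moved_mask = np.zeros(self.n_beads, dtype=np.bool_)
        moved_mask[moved] = True
        patched = state.dist.copy()
        feasible, sw_delta = move_kernel(
            new_coords, moved, moved_mask, self.box_edge, state.dist, patched,
            self.bond_i, self.bond_j, self.bond_lo, self.bond_hi,
            self.hs_matrix, self.sw_depth_index, self.sw_dsw,
            len(self.sw_depths))
        if not feasible:
            return INFEASIBLE, (), (), patched
        sw_counts = tuple(
            int(c) + int(d) for c, d in zip(state.sw_counts, sw_delta))

        # hydrogen bonds: rebuild the matching only when a backbone bead
        # moved (side-chain motion cannot change bond eligibility)
        if np.any(moved_mask & self._hb_relevant):
            hb_pairs = self._hbond_matching(patched)
        else:
            hb_pairs = state.hb_pairs
        energy = self._assemble_energy(sw_counts, hb_pairs)
        return energy, sw_counts, hb_pairs, patched


def total_energy(state: SystemState, system: System) -> float:
    """From-scratch total potential energy (infeasible sentinel on violation)."""
    energy, _, _, _ = system.evaluate(state.coords)
    return energy


def delta_energy(system: System, state: SystemState, moved: np.ndarray,
                 new_coords: np.ndarray) -> float:
    """Energy change of a proposed move (new minus current); INFEASIBLE if the
    candidate violates a constraint."""
    energy, _, _, _ = system.evaluate_move(state, np.asarray(moved, int), new_coords)
    if not math.isfinite(energy):
        return INFEASIBLE
    return energy - state.energy
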