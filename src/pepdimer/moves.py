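"""Monte Carlo move set for the peptide system.

Three symmetric proposal types: (i) local displacement of a single bead by a
vector drawn uniformly in a ball of radius 0.2 A, (ii) pivot rotation of a phi
or psi backbone dihedral by an angle uniform in [-pi/3, pi/3], rotating
everything topologically downstream of the axis rigidly, and (iii) rigid-body
translation or rotation of an entire chain.  Every proposal is checked for
bond-window and steric feasibility; infeasible candidates carry the
infeasibility sentinel and are rejected by the sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import rotation_matrix
from .model import System, SystemState

__all__ = [
    "MoveConfig",
    "propose_displacement",
    "propose_pivot",
    "propose_rigid_body",
    "PeptideLandscape",
]


@dataclass(frozen=True)
class MoveConfig:
    """Proposal amplitudes and mixing weights.

    The reference configuration uses a 0.2 A displacement cap and pi/3 pivot
    cap; the mix and rigid-body amplitudes are conventional choices.
    """

    displacement_max: float = 0.2
    pivot_max: float = math.pi / 3.0
    move_mix: tuple = (0.8, 0.1, 0.1)  # displacement, pivot, rigid-body
    rigid_translation_max: float = 2.0
    rigid_rotation_max: float = math.pi / 6.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.move_mix):
            raise ValueError("move-mix weights must be positive")


def _uniform_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    if n < 1e-300:
        return np.zeros(3)
    return v / n * radius * rng.random() ** (1.0 / 3.0)


def propose_displacement(system: System, state: SystemState,
                         rng: np.random.Generator,
                         max_step: float = 0.2):
    """Displace one uniformly chosen bead by <= ``max_step``; symmetric."""
    bead = int(rng.integers(system.n_beads))
    new_coords = state.coords.copy()
    new_coords[bead] += _uniform_in_ball(rng, max_step)
    return np.array([bead]), new_coords


def _pivot_moves(system: System):
    """Enumerate (chain, residue, 'phi'|'psi') pivots with nonempty targets."""
    out = []
    for c, topo in enumerate(system.topologies):
        n = topo.n_residues
        for r in range(n):
            if r >= 1:
                out.append((c, r, "phi"))
            if r <= n - 2:
                out.append((c, r, "psi"))
    return out


def pivot_targets(system: System, chain: int, residue: int, which: str):
    """Axis bead indices and the downstream bead set of a pivot."""
    topo = system.topologies[chain]
    o = system.offsets[chain]
    if which == "phi":
        a = o + topo.bead_index(residue, "NH")
        b = o + topo.bead_index(residue, "CA")
        downstream = [
            o + i
            for i, (r, k) in enumerate(topo.beads)
            if r > residue or (r == residue and k in ("CO", "SC"))
        ]
    else:
        a = o + topo.bead_index(residue, "CA")
        b = o + topo.bead_index(residue, "CO")
        downstream = [o + i for i, (r, _) in enumerate(topo.beads) if r > residue]
    return a, b, np.array(downstream, dtype=int)


def propose_pivot(system: System, state: SystemState, rng: np.random.Generator,
                  max_angle: float = math.pi / 3.0):
    """Rotate a random phi/psi dihedral by a uniform angle; symmetric."""
    moves = system._pivot_cache if hasattr(system, "_pivot_cache") else None
    if moves is None:
        moves = _pivot_moves(system)
        system._pivot_cache = moves
    chain, residue, which = moves[int(rng.integers(len(moves)))]
    a, b, downstream = pivot_targets(system, chain, residue, which)
    angle = rng.uniform(-max_angle, max_angle)
    new_coords = state.coords.copy()
    if downstream.size:
        axis = state.coords[b] - state.coords[a]
        rot = rotation_matrix(axis, angle)
        pivot_point = state.coords[b]
        new_coords[downstream] = (state.coords[downstream] - pivot_point) @ rot.T \
            + pivot_point
    return downstream, new_coords


def propose_rigid_body(system: System, state: SystemState,
                       rng: np.random.Generator,
                       max_translation: float = 2.0,
                       max_rotation: float = math.pi / 6.0):
    """Translate or rotate one whole chain; intra-chain geometry unchanged."""
    chain = int(rng.integers(len(system.topologies)))
    o = system.offsets[chain]
    n = system.topologies[chain].n_beads
    beads = np.arange(o, o + n)
    new_coords = state.coords.copy()
    if rng.random() < 0.5:
        new_coords[beads] += _uniform_in_ball(rng, max_translation)
    else:
        axis = rng.standard_normal(3)
        angle = rng.uniform(-max_rotation, max_rotation)
        rot = rotation_matrix(axis, angle)
        centroid = state.coords[beads].mean(axis=0)
        new_coords[beads] = (state.coords[beads] - centroid) @ rot.T + centroid
    return beads, new_coords


class PeptideLandscape:
    """Adapter presenting the peptide system to the generic SAMC driver.

    Exposes ``initial_state``, ``propose`` and ``energy``; any object with
    that surface (e.g. the exactly enumerable toy systems) can drive the same
    sampler.
    """

    def __init__(self, system: System, move_config: MoveConfig | None = None):
        self.system = system
        self.config = move_config or MoveConfig()
        w = np.array(self.config.move_mix, dtype=float)
        self._cum = np.cumsum(w / w.sum())

    def initial_state(self, rng: np.random.Generator) -> SystemState:
        return self.system.initial_state()

    def energy(self, state: SystemState) -> float:
        return state.energy

    def propose(self, state: SystemState, rng: np.random.Generator):
        """Return ``(candidate_state_or_None, energy)``; infeasible proposals
        return ``(None, inf)``."""
        u = rng.random()
        cfg = self.config
        if u < self._cum[0]:
            moved, new_coords = propose_displacement(
                self.system, state, rng, cfg.displacement_max)
        elif u < self._cum[1]:
            moved, new_coords = propose_pivot(
                self.system, state, rng, cfg.pivot_max)
        else:
            moved, new_coords = propose_rigid_body(
                self.system, state, rng,
                cfg.rigid_translation_max, cfg.rigid_rotation_max)
        energy, sw_counts, hb, patched = self.system.evaluate_move(
            state, moved, new_coords)
        if not math.isfinite(energy):
            return None, math.inf
        cand = SystemState(
            coords=new_coords, box_edge=state.box_edge, energy=energy,
            sw_counts=sw_counts, hb_pairs=hb, dist=patched,
        )
        return cand, energy
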