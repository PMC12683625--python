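"""Synthetic test systems with exactly known answers.

Three families back-stop the simulation stack:

* discrete k-level systems whose density of states is the degeneracy list,
  for validating the flat-histogram sampler and the canonical analysis
  (two levels give the closed-form Schottky anomaly);
* a square-well dimer of two point beads in a periodic box, the minimal
  continuous system with an analytically known two-level configurational
  density of states (well-shell volume vs. free volume);
* short homopolymer chains under the simplified parameter preset, for
  end-to-end smoke runs of the full peptide pipeline;
* tabulated entropy curves with constructed transition structure (concave,
  convex-intruder with known double-tangent slope, piecewise linear) for the
  microcanonical analysis.

All the generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import minimum_image
from .model import System
from .moves import MoveConfig, PeptideLandscape
from .params import load_parameters
from .topology import build_topology

__all__ = [
    "KLevelSystem",
    "SquareWellDimer",
    "EntropyFixture",
    "HomopolymerFixture",
    "make_k_level_system",
    "make_square_well_dimer",
    "make_homopolymer",
    "make_entropy_fixture",
]


@dataclass
class KLevelSystem:
    """Discrete system: level ``l`` has ``degeneracies[l]`` microstates.

    Proposals jump to a microstate chosen uniformly from all microstates,
    which is trivially symmetric.  ``exact_ln_g[l] = ln(degeneracies[l])``.
    """

    degeneracies: tuple
    level_energies: tuple
    kind: str = "k-level-discrete"

    def __post_init__(self) -> None:
        self.exact_ln_g = np.log(np.asarray(self.degeneracies, dtype=float))
        self._cum = np.cumsum(self.degeneracies)
        self.n_microstates = int(self._cum[-1])

    def _level_of(self, microstate: int) -> int:
        return int(np.searchsorted(self._cum, microstate, side="right"))

    def initial_state(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.n_microstates))

    def energy(self, state: int) -> float:
        return float(self.level_energies[self._level_of(state)])

    def propose(self, state: int, rng: np.random.Generator):
        cand = int(rng.integers(self.n_microstates))
        return cand, self.energy(cand)


def make_k_level_system(degeneracies, gaps) -> KLevelSystem:
    """Build a discrete system from level degeneracies and energy gaps.

    ``gaps[l]`` is the energy increment of level ``l`` over level ``l-1``
    (``gaps[0]`` offsets the ground level, usually 0); the lists must be
    non-empty and of equal length.
    """
    if not len(degeneracies) or len(degeneracies) != len(gaps):
        raise ValueError("degeneracies and gaps must be non-empty, equal length")
    if any(int(d) <= 0 for d in degeneracies):
        raise ValueError("degeneracies must be positive integers")
    energies = tuple(np.cumsum(np.asarray(gaps, dtype=float)))
    return KLevelSystem(tuple(int(d) for d in degeneracies), energies)


@dataclass
class SquareWellDimer:
    """Two point beads in a periodic box interacting by one square well.

    Configurational energy levels: ``eps`` (bound, ``d_hs < r < d_sw``) and 0
    (unbound, ``r >= d_sw``); ``r <= d_hs`` is infeasible.  The exact density
    of states of the relative coordinate is the shell volume for the bound
    level and the remaining free volume for the unbound one.
    """

    d_hs: float
    d_sw: float
    eps: float
    box_edge: float
    step: float = 2.0
    kind: str = "square-well-dimer"

    def __post_init__(self) -> None:
        if not (0 < self.d_hs < self.d_sw < self.box_edge / 2):
            raise ValueError("need 0 < d_hs < d_sw < box_edge/2")
        v_shell = 4.0 * np.pi / 3.0 * (self.d_sw**3 - self.d_hs**3)
        v_free = self.box_edge**3 - 4.0 * np.pi / 3.0 * self.d_sw**3
        if self.eps != 0.0:
            # level order: bound first when attractive
            self.level_energies = (min(self.eps, 0.0), max(self.eps, 0.0))
            lo, hi = (v_shell, v_free) if self.eps < 0 else (v_free, v_shell)
            self.exact_ln_g = np.log(np.array([lo, hi]))
        else:
            self.level_energies = (0.0,)
            self.exact_ln_g = np.log(np.array([v_shell + v_free]))

    @property
    def bound_fraction(self) -> float:
        """Fraction of feasible relative-coordinate volume inside the well."""
        v_shell = 4.0 * np.pi / 3.0 * (self.d_sw**3 - self.d_hs**3)
        v_total = self.box_edge**3 - 4.0 * np.pi / 3.0 * self.d_hs**3
        return v_shell / v_total

    def initial_state(self, rng: np.random.Generator) -> np.ndarray:
        coords = np.zeros((2, 3))
        # start unbound: midway between the well edge and the half-box
        coords[1, 0] = 0.5 * (self.d_sw + self.box_edge / 2.0)
        return coords

    def energy(self, state: np.ndarray) -> float:
        d = minimum_image(state[0] - state[1], self.box_edge)
        r = float(np.linalg.norm(d))
        if r <= self.d_hs:
            return math.inf
        if r < self.d_sw:
            return self.eps
        return 0.0

    def propose(self, state: np.ndarray, rng: np.random.Generator):
        bead = int(rng.integers(2))
        v = rng.standard_normal(3)
        v *= self.step * rng.random() ** (1 / 3) / max(np.linalg.norm(v), 1e-300)
        cand = state.copy()
        cand[bead] += v
        e = self.energy(cand)
        if not math.isfinite(e):
            return None, math.inf
        return cand, e


def make_square_well_dimer(d_hs=2.0, d_sw=4.0, eps=-1.0,
                           box_edge=10.0) -> SquareWellDimer:
    """Default geometry keeps the bound shell a sizeable fraction (~25%) of
    the box so that level transitions are frequent and the sampler's error is
    dominated by the gain schedule, not by mixing."""
    return SquareWellDimer(d_hs=d_hs, d_sw=d_sw, eps=eps, box_edge=box_edge)


@dataclass
class HomopolymerFixture:
    """A ready-to-sample homopolymer system under the simplified preset."""

    sequence: str
    n_chains: int
    box_edge: float
    system: System
    landscape: PeptideLandscape


def make_homopolymer(n_residues: int, residue_letter: str = "A",
                     params_preset: str = "reference-simplified",
                     n_chains: int = 1, box_edge: float = 60.0,
                     move_config: MoveConfig | None = None) -> HomopolymerFixture:
    """A homopolymer of ``n_residues`` identical residues, as monomer or
    dimer, wired into a sampler-ready landscape."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    params = load_parameters(params_preset)
    sequence = residue_letter * n_residues
    topo = build_topology(sequence, params)
    system = System([topo] * n_chains, params, box_edge)
    return HomopolymerFixture(
        sequence=sequence, n_chains=n_chains, box_edge=box_edge,
        system=system, landscape=PeptideLandscape(system, move_config),
    )


@dataclass
class EntropyFixture:
    """Tabulated microcanonical entropy with known transition structure."""

    kind: str
    energies: np.ndarray
    entropy: np.ndarray
    t_star: float | None = None  # double-tangent temperature, if any
    loop_bounds: tuple | None = None  # (E_left, E_right) tangency points


def make_entropy_fixture(kind: str, *, n_points: int = 400,
                         a: float = 5.0, slope: float = 5.0,
                         e1: float = 0.0, e2: float = 2.0) -> EntropyFixture:
    """Analytic entropy curves for the transition-finding machinery.

    ``concave``
        a single concave parabola branch with positive slope: no transition.
    ``convex-intruder``
        the upper envelope of two congruent concave parabolas whose apexes
        are offset so that the line of slope ``slope`` is tangent to both:
        the double tangent bridging the convex intruder then has exactly that
        slope, i.e. T* = 1/slope, with tangency points at
        ``e1 - slope/(2a)`` and ``e2 - slope/(2a)``.
    ``piecewise-linear``
        two linear pieces: T(E) is piecewise constant.
    """
    if kind == "concave":
        E = np.linspace(e1 - 2.0, e1 - 0.05, n_points)
        S = 10.0 - a * (E - e1) ** 2
        return EntropyFixture(kind, E, S)
    if kind == "convex-intruder":
        if not 0 < slope < a * (e2 - e1):
            raise ValueError("need 0 < slope < a*(e2-e1) for a genuine intruder")
        t1 = e1 - slope / (2 * a)
        t2 = e2 - slope / (2 * a)
        lo = t1 - 0.35 * (e2 - e1)
        hi = e2 - 0.02 * (e2 - e1)
        E = np.linspace(lo, hi, n_points)
        S1 = 10.0 - a * (E - e1) ** 2
        S2 = 10.0 + slope * (e2 - e1) - a * (E - e2) ** 2
        return EntropyFixture(kind, E, np.maximum(S1, S2),
                              t_star=1.0 / slope, loop_bounds=(t1, t2))
    if kind == "piecewise-linear":
        E = np.linspace(0.0, 4.0, n_points)
        S = np.where(E < 2.0, 3.0 * E, 6.0 + 1.5 * (E - 2.0))
        return EntropyFixture(kind, E, S)
    raise ValueError(f"unknown entropy fixture kind {kind!r}")
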