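"""Structural observables: gyration shape descriptors, hydrogen-bond counts
and matrices, per-energy-bin accumulation, and canonical reweighting.

During production sampling every visited state contributes its observables to
the energy bin it occupies; the microcanonical mean of observable f at energy
E is the accumulated sum divided by the visit count M(E), and its temperature
dependence follows by reweighting the per-bin means with the canonical
weights g(E) exp(-E/T) (log-sum-exp throughout).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .geometry import minimum_image
from .model import System, SystemState

__all__ = [
    "ShapeDescriptors",
    "HBondMatrix",
    "ObservableAccumulator",
    "ReweightingError",
    "gyration_descriptors",
    "dimer_coordinates",
    "count_hbonds",
    "reweight_to_temperature",
    "hbond_probability_matrix",
    "register_standard_observables",
]


class ReweightingError(RuntimeError):
    """Canonical reweighting requested where the sampling has no coverage."""


def _dos_full_grid(dos):
    """Full grid arrays ``(E, ln_g, support_mask)`` of a DOS container."""
    from .samc import DOSEstimate
    from .thermo import TotalDOS

    if isinstance(dos, DOSEstimate):
        return dos.grid.centers(), dos.ln_g, dos.visited
    if isinstance(dos, TotalDOS):
        return dos.energies, dos.ln_g, np.isfinite(dos.ln_g)
    if len(dos) == 3:
        e, g, mask = dos
        return (np.asarray(e, float), np.asarray(g, float),
                np.asarray(mask, bool))
    e, g = dos
    e = np.asarray(e, float)
    return e, np.asarray(g, float), np.ones(e.size, dtype=bool)


@dataclass(frozen=True)
class ShapeDescriptors:
    """Gyration-tensor summary of a bead cloud.

    ``kappa2 = (l1 - l3) / (l1 + l2 + l3)`` with sorted eigenvalues
    ``l1 >= l2 >= l3``: 0 for a sphere, 1 for a rod, about 0.5 for a random
    coil.  ``r_g**2`` equals the eigenvalue sum (tensor trace).
    """

    gyration_tensor: np.ndarray
    eigenvalues: np.ndarray
    r_g: float
    kappa2: float


def gyration_descriptors(coords: np.ndarray) -> ShapeDescriptors:
    """Mass-uniform gyration tensor, eigenvalues, R_g and kappa^2.

    Coordinates must be unwrapped (no periodic jumps); for dimers use
    :func:`dimer_coordinates` first.  All beads carry equal weight.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    centered = coords - coords.mean(axis=0)
    tensor = centered.T @ centered / coords.shape[0]
    eig = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    eig = np.clip(eig, 0.0, None)
    trace = float(eig.sum())
    rg = math.sqrt(trace)
    kappa2 = 0.0 if trace == 0.0 else float((eig[0] - eig[2]) / trace)
    return ShapeDescriptors(gyration_tensor=tensor, eigenvalues=eig,
                            r_g=rg, kappa2=kappa2)


def dimer_coordinates(system: System, state: SystemState) -> np.ndarray:
    """All-bead coordinates with every later chain shifted to the minimum
    image of its centroid relative to the first chain."""
    coords = state.coords.copy()
    o0 = system.offsets[0]
    n0 = system.topologies[0].n_beads
    ref = coords[o0 : o0 + n0].mean(axis=0)
    for c in range(1, len(system.topologies)):
        o = system.offsets[c]
        n = system.topologies[c].n_beads
        centroid = coords[o : o + n].mean(axis=0)
        shift = minimum_image(centroid - ref, system.box_edge) - (centroid - ref)
        coords[o : o + n] += shift
    return coords


def count_hbonds(state: SystemState, system: System):
    """Partition the hydrogen-bond registry by chain.

    Returns ``(intra, inter)`` where ``intra[c]`` counts bonds whose donor
    and acceptor both sit on chain ``c``.
    """
    intra = [0] * len(system.topologies)
    inter = 0
    for donor, acceptor in state.hb_pairs:
        cd, ca = system.chain_of[donor], system.chain_of[acceptor]
        if cd == ca:
            intra[cd] += 1
        else:
            inter += 1
    return tuple(intra), inter


@dataclass
class ObservableAccumulator:
    """Per-energy-bin visit counts M(E) and running observable sums.

    Observables are registered as ``(name, function, dimension)``; the
    function maps a state to a float or a flat vector.  The microcanonical
    mean is ``sums[name][bin] / visits[bin]`` wherever ``visits > 0``.
    """

    n_bins: int
    visits: np.ndarray = None
    sums: dict = field(default_factory=dict)
    _funcs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visits is None:
            self.visits = np.zeros(self.n_bins, dtype=np.int64)

    @property
    def names(self):
        return list(self.sums)

    def register(self, name: str, func, dim: int = 1) -> None:
        self.sums[name] = np.zeros((self.n_bins, dim))
        self._funcs[name] = func

    def record(self, bin_index: int, state) -> None:
        self.visits[bin_index] += 1
        for name, func in self._funcs.items():
            self.sums[name][bin_index] += func(state)

    def mean(self, name: str) -> np.ndarray:
        """Microcanonical mean per bin; NaN on unvisited bins."""
        out = np.full(self.sums[name].shape, np.nan)
        m = self.visits > 0
        out[m] = self.sums[name][m] / self.visits[m, None]
        return out

    def merge(self, other: "ObservableAccumulator") -> "ObservableAccumulator":
        """Combine two production runs (sum of visits and sums)."""
        if self.n_bins != other.n_bins or set(self.sums) != set(other.sums):
            raise ValueError("accumulators are not compatible")
        out = ObservableAccumulator(self.n_bins)
        out.visits = self.visits + other.visits
        for name in self.sums:
            out.sums[name] = self.sums[name] + other.sums[name]
            out._funcs[name] = self._funcs.get(name) or other._funcs.get(name)
        return out


def reweight_to_temperature(accumulator: ObservableAccumulator, dos, T: float,
                            name: str, *, warn_weight: float = 0.02,
                            error_weight: float = 0.5) -> np.ndarray:
    """Canonical expectation of a recorded observable at temperature ``T``:
    ``f(T) = sum_E fbar(E) g(E) exp(-E/T) / Z(T)`` over covered bins.

    Bins inside the DOS support but never visited in production are excluded;
    if their canonical weight at ``T`` exceeds ``warn_weight`` a coverage
    warning is issued, and above ``error_weight`` the reweighting is refused.
    """
    E, ln_g, support = _dos_full_grid(dos)
    fbar = accumulator.mean(name)
    # accumulator bins correspond one-to-one to the DOS grid used in production
    if E.size != accumulator.n_bins:
        raise ValueError(
            "accumulator was not filled on this DOS grid "
            f"({accumulator.n_bins} bins vs {E.size} grid bins)")
    covered = support & (accumulator.visits > 0)
    w = np.where(support, ln_g - E / T, -np.inf)
    lz = logsumexp(w)
    p = np.exp(w - lz)
    missing = float(p[support & ~covered].sum())
    if missing > error_weight:
        raise ReweightingError(
            f"{missing:.0%} of the canonical weight at T={T} lies in energy "
            "bins never visited during production")
    if missing > warn_weight:
        warnings.warn(
            f"coverage gap: {missing:.1%} of canonical weight at T={T} "
            "is unsampled", RuntimeWarning, stacklevel=2)
    p_cov = p[covered] / p[covered].sum()
    out = p_cov @ fbar[covered]
    return float(out[0]) if out.size == 1 else out


@dataclass
class HBondMatrix:
    """Residue-by-residue hydrogen-bond probabilities at one temperature."""

    intra: list  # per chain, (n_res, n_res)
    inter: np.ndarray  # (n_res, n_res) across the chain pair
    temperature: float


def _hb_indicator_matrices(system: System):
    """Observable functions returning flattened per-residue-pair bond
    indicators (symmetrized over donor direction)."""
    n_chains = len(system.topologies)
    n_res = [t.n_residues for t in system.topologies]

    def intra_func(chain):
        def f(state):
            m = np.zeros((n_res[chain], n_res[chain]))
            for d, a in state.hb_pairs:
                if system.chain_of[d] == chain and system.chain_of[a] == chain:
                    i, j = system.residue_of[d], system.residue_of[a]
                    m[i, j] = m[j, i] = 1.0
            return m.ravel()
        return f

    def inter_func(state):
        m = np.zeros((n_res[0], n_res[min(1, n_chains - 1)]))
        for d, a in state.hb_pairs:
            cd, ca = system.chain_of[d], system.chain_of[a]
            if cd != ca:
                i, j = system.residue_of[d], system.residue_of[a]
                if cd == 0:
                    m[i, j] = 1.0
                else:
                    m[j, i] = 1.0
        return m.ravel()

    return intra_func, inter_func


def register_standard_observables(accumulator: ObservableAccumulator,
                                  system: System) -> None:
    """Register the production observables of the dimerization analysis:
    potential energy, intra/intermolecular hydrogen-bond counts, per-chain
    and whole-system gyration descriptors, and the residue-pair hydrogen-bond
    indicator matrices."""
    n_chains = len(system.topologies)

    accumulator.register("energy", lambda s: s.energy)

    def n_intra(state):
        intra, _ = count_hbonds(state, system)
        return float(sum(intra))

    def n_inter(state):
        _, inter = count_hbonds(state, system)
        return float(inter)

    accumulator.register("hb_intra", n_intra)
    accumulator.register("hb_inter", n_inter)

    def chain_rg2(state):
        vals = []
        for c in range(n_chains):
            o = system.offsets[c]
            n = system.topologies[c].n_beads
            vals.append(gyration_descriptors(state.coords[o : o + n]).r_g ** 2)
        return float(np.mean(vals))

    def chain_kappa2(state):
        vals = []
        for c in range(n_chains):
            o = system.offsets[c]
            n = system.topologies[c].n_beads
            vals.append(gyration_descriptors(state.coords[o : o + n]).kappa2)
        return float(np.mean(vals))

    accumulator.register("rg2_chain", chain_rg2)
    accumulator.register("kappa2_chain", chain_kappa2)

    if n_chains > 1:
        def system_rg2(state):
            return gyration_descriptors(
                dimer_coordinates(system, state)).r_g ** 2

        accumulator.register("rg2_dimer", system_rg2)

    intra_func, inter_func = _hb_indicator_matrices(system)
    for c in range(n_chains):
        n_r = system.topologies[c].n_residues
        accumulator.register(f"hb_map_intra_{c}", intra_func(c), dim=n_r * n_r)
    if n_chains > 1:
        n0 = system.topologies[0].n_residues
        n1 = system.topologies[1].n_residues
        accumulator.register("hb_map_inter", inter_func, dim=n0 * n1)


def hbond_probability_matrix(accumulator: ObservableAccumulator, dos,
                             system: System, T: float) -> HBondMatrix:
    """Reweight the per-residue-pair bond indicators to temperature ``T``.

    Output is on the linear probability scale (log color scaling is a
    rendering choice, not a data one).
    """
    intra = []
    for c in range(len(system.topologies)):
        n_r = system.topologies[c].n_residues
        flat = reweight_to_temperature(accumulator, dos, T, f"hb_map_intra_{c}")
        intra.append(flat.reshape(n_r, n_r))
    if len(system.topologies) > 1:
        n0 = system.topologies[0].n_residues
        n1 = system.topologies[1].n_residues
        inter = reweight_to_temperature(
            accumulator, dos, T, "hb_map_inter").reshape(n0, n1)
    else:
        inter = np.zeros((0, 0))
    return HBondMatrix(intra=intra, inter=inter, temperature=T)
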