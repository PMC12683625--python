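"""Chain topology: bead lists and the square-well bond network.

Every residue contributes the backbone triplet NH-CA-CO plus one side-chain
bead, except glycine which has no side chain.  Bonds comprise the covalent
backbone bonds, the side-chain attachment, and the angle/planarity pseudo-bonds
spanning residue junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AMINO_ACIDS, ParameterSet, residue_class

__all__ = ["ChainTopology", "build_topology"]


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    length: float
    kind: str  # "covalent" | "pseudo"


@dataclass
class ChainTopology:
    """Bead and bond bookkeeping for a single chain.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid sequence.
    beads : list of (residue index, bead kind)
        Topological order: NH, CA, CO, [SC] per residue.
    bonds : list of Bond
        All covalent bonds and pseudo-bonds, indices into ``beads``.
    """

    sequence: str
    beads: list
    bonds: list

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def bead_index(self, residue: int, kind: str) -> int:
        return self._index[(residue, kind)]

    def __post_init__(self) -> None:
        self._index = {rb: i for i, rb in enumerate(self.beads)}
        self.residue_of = np.array([r for r, _ in self.beads])
        self.kind_of = [k for _, k in self.beads]
        self.classes = [residue_class(c) for c in self.sequence]

    def hs_matrix(self, params: ParameterSet) -> np.ndarray:
        """Intra-chain effective hard-sphere diameters (0 where exempt).

        Lorentz-Berthelot means, scaled by the squeeze factor for the listed
        close-in-sequence pairs; pairs joined by a bond or pseudo-bond (and
        the diagonal) are exempt and carry 0.  Both the initial-configuration
        builder and the energy model consult this single table, so a chain
        the builder accepts is feasible for the model by construction.
        """
        n = self.n_beads
        d = np.array([params.hs_diameters[k] for k in self.kind_of])
        hs = 0.5 * (d[:, None] + d[None, :])
        for (ka, kb, off), factor in params.squeeze_factors.items():
            for a in range(n):
                if self.kind_of[a] != ka:
                    continue
                b = self._index.get((self.residue_of[a] + off, kb))
                if b is not None:
                    hs[a, b] = hs[b, a] = 0.5 * (d[a] + d[b]) * factor
        for bond in self.bonds:
            hs[bond.i, bond.j] = hs[bond.j, bond.i] = 0.0
        np.fill_diagonal(hs, 0.0)
        return hs


def build_topology(sequence: str, params: ParameterSet) -> ChainTopology:
    """Map a one-letter sequence onto the four-site-per-residue topology.

    Raises
    ------
    ValueError
        for an empty sequence or a letter outside the 20-letter alphabet.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {sorted(bad)}")

    beads = []
    for r, letter in enumerate(sequence):
        beads.append((r, "NH"))
        beads.append((r, "CA"))
        beads.append((r, "CO"))
        if letter != "G":
            beads.append((r, "SC"))
    index = {rb: i for i, rb in enumerate(beads)}

    bonds = []

    def add(kind_i, r_i, kind_j, r_j, length, bond_kind):
        a = index.get((r_i, kind_i))
        b = index.get((r_j, kind_j))
        if a is not None and b is not None:
            bonds.append(Bond(a, b, length, bond_kind))

    n = len(sequence)
    for r in range(n):
        for (ki, kj, off), length in params.bond_lengths.items():
            add(ki, r, kj, r + off, length, "covalent")
        if sequence[r] != "G":
            add("CA", r, "SC", r, params.sc_bond_length, "covalent")
        for (ki, kj, off), length in params.pseudobond_lengths.items():
            add(ki, r, kj, r + off, length, "pseudo")
    return ChainTopology(sequence=sequence, beads=beads, bonds=bonds)
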