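"""Model parameter sets for the four-bead-per-residue square-well chain model.

The model represents each amino acid by three backbone beads (amide nitrogen
NH, alpha carbon CA, carbonyl carbon CO) plus one side-chain bead (SC) at the
side chain's centre of mass (glycine carries no SC bead).  All covalent and
angle-enforcing pseudo-bonds are square wells centred on ideal lengths with a
relative tolerance ``delta``; non-bonded interactions are hard spheres plus
square wells.  Backbone hydrogen bonds carry the unit well depth, which fixes
the reduced energy scale: energies are in multiples of eps_HB and temperatures
in eps_HB/k_B.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "ConfigurationError",
    "load_parameters",
    "combined_hs_diameter",
    "BACKBONE_KINDS",
    "BEAD_KINDS",
    "COVALENT_BONDS",
    "PSEUDOBONDS",
    "SQUEEZE_PAIR_KINDS",
    "HYDROPHOBIC",
]


class ConfigurationError(ValueError):
    """A parameter source is missing entries or violates a model invariant."""


BEAD_KINDS = ("NH", "CA", "CO", "SC")
BACKBONE_KINDS = ("NH", "CA", "CO")

#: Covalent backbone bond lengths in Angstrom.  Keys are (kind_i, kind_j,
#: residue offset of j relative to i).
COVALENT_BONDS = {
    ("NH", "CA", 0): 1.46,
    ("CA", "CO", 0): 1.51,
    ("CO", "NH", 1): 1.33,
}

#: Angle/planarity-enforcing pseudo-bond lengths in Angstrom.
PSEUDOBONDS = {
    ("NH", "CO", 1): 4.25,
    ("CA", "NH", 1): 2.41,
    ("CO", "CA", 1): 2.45,
    ("CA", "CA", 1): 2.80,
}

#: Bead pairings whose effective excluded volume is reduced by a squeeze
#: factor.  Backbone-backbone pairs are keyed (kind_i, kind_j, offset);
#: side-chain entries pair a backbone bead with the SC bead of the residue at
#: the given offset.
SQUEEZE_PAIR_KINDS = (
    ("CA", "CO", 1),
    ("CA", "NH", 2),
    ("CO", "NH", 2),
    ("NH", "NH", 1),
    ("CO", "CO", 1),
    ("CA", "SC", 1),
    ("CO", "SC", 1),
    ("NH", "SC", -1),
    ("CA", "SC", -1),
    ("CO", "SC", 2),
)

#: Two-class split used by the simplified preset.
HYDROPHOBIC = frozenset("AVLIMFWCY")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ParameterSet:
    """Full interaction table for the coarse-grained chain model.

    Distances are in Angstrom; well depths in units of the hydrogen-bond
    well depth eps_HB (so ``hbond_energy`` is -1.0 in the reference set).
    """

    bond_lengths: Mapping[tuple, float]
    pseudobond_lengths: Mapping[tuple, float]
    delta: float
    hs_diameters: Mapping[str, float]
    sw_ranges: Mapping[frozenset, float]
    well_depths: Mapping[frozenset, float]
    hbond_range: float
    hbond_energy: float
    squeeze_factors: Mapping[tuple, float]
    #: minimum-separation threshold (A) for the four flanking backbone pairs
    #: of a candidate hydrogen bond (auxiliary alignment criterion)
    hbond_aux_min: float = 4.5
    #: minimum intramolecular residue separation |i - j| for a hydrogen bond
    hbond_min_separation: int = 4
    #: side-chain attachment bond length CA-SC (A) in the simplified preset
    sc_bond_length: float = 2.4

    def __post_init__(self) -> None:
        for name in ("hs_diameters",):
            for k, v in getattr(self, name).items():
                if v <= 0:
                    raise ConfigurationError(f"nonpositive diameter for {k!r}")
        for k, v in self.sw_ranges.items():
            if v <= 0:
                raise ConfigurationError(f"nonpositive well range for {set(k)!r}")
        if self.hbond_range <= 0:
            raise ConfigurationError("nonpositive hydrogen-bond range")
        for kind in SQUEEZE_PAIR_KINDS:
            if kind not in self.squeeze_factors:
                raise ConfigurationError(f"missing squeeze entry for pair {kind!r}")

    def well_depth(self, class_i: str, class_j: str) -> float:
        """Square-well depth for a side-chain class pair (symmetric)."""
        return self.well_depths.get(frozenset((class_i, class_j)), 0.0)

    def sw_range(self, class_i: str, class_j: str) -> float:
        return self.sw_ranges.get(frozenset((class_i, class_j)), 0.0)


def residue_class(letter: str) -> str:
    """Two-class mapping used by the simplified preset: H(ydrophobic)/P(olar)."""
    return "H" if letter in HYDROPHOBIC else "P"


def _simplified_reference() -> dict:
    """The bundled two-class test preset.

    Uniform bead sizes, a single hydrophobic-hydrophobic attraction of depth
    -0.2 eps_HB, all squeeze factors 1.  Small backbone cores keep the printed
    bond geometry satisfiable while still forbidding chain crossings.
    """
    return {
        "bond_lengths": dict(COVALENT_BONDS),
        "pseudobond_lengths": dict(PSEUDOBONDS),
        "delta": 0.02375,
        "hs_diameters": {"NH": 2.0, "CA": 2.0, "CO": 2.0, "SC": 3.0},
        "sw_ranges": {("H", "H"): 5.5},
        "well_depths": {("H", "H"): -0.2},
        "hbond_range": 4.5,
        "hbond_energy": -1.0,
        "squeeze_factors": {k: 1.0 for k in SQUEEZE_PAIR_KINDS},
        "hbond_aux_min": 4.5,
        "hbond_min_separation": 4,
        "sc_bond_length": 2.4,
    }


_PRESETS = {"reference-simplified": _simplified_reference}


def _freeze_pair_table(table: Mapping, what: str) -> dict:
    """Validate symmetry of an (a, b) -> value table and key it by frozenset."""
    out: dict = {}
    for key, value in table.items():
        a, b = key
        fs = frozenset((a, b))
        if fs in out and out[fs] != value:
            raise ConfigurationError(
                f"asymmetric {what} table: ({a},{b}) = {value} conflicts with "
                f"({b},{a}) = {out[fs]}"
            )
        out[fs] = value
    return out


def _normalise_keys(table: Mapping, tuple_keys: bool) -> dict:
    """Accept 'NH-CA' / 'NH-CA+1' style string keys from config files."""
    out = {}
    for key, value in table.items():
        if isinstance(key, str) and tuple_keys:
            pair, _, off = key.partition("+")
            if "-" in pair and pair.count("-") >= 1:
                a, b = pair.split("-")[:2]
                offset = int(off) if off else 0
                if off == "" and key.count("-") == 2:  # 'NH-SC--1'
                    a, b, neg = key.split("-")[:3]
                    offset = -int(neg)
                out[(a, b, offset)] = float(value)
                continue
        out[key] = value
    return out


def load_parameters(source) -> ParameterSet:
    """Build a validated :class:`ParameterSet`.

    ``source`` may be a preset name (``"reference-simplified"`` or
    ``"external-prime20"``), a mapping with the ParameterSet schema, or a path
    to a YAML file holding such a mapping.  The external-prime20 schema is a
    loader contract for the full published 20x20 tables, which are not bundled;
    it therefore requires an explicit file.

    Raises
    ------
    ConfigurationError
        on missing entries, asymmetric well-depth tables, or invalid values.
    """
    if isinstance(source, str) and source in _PRESETS:
        raw = _PRESETS[source]()
    elif isinstance(source, str) and source == "external-prime20":
        raise ConfigurationError(
            "the 'external-prime20' preset is a schema, not bundled data: pass "
            "a parameter file with the full pair tables instead"
        )
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"no such preset or parameter file: {source!r}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raise ConfigurationError(f"unsupported parameter source {type(source)!r}")

    required = (
        "bond_lengths",
        "pseudobond_lengths",
        "delta",
        "hs_diameters",
        "sw_ranges",
        "well_depths",
        "hbond_range",
        "hbond_energy",
        "squeeze_factors",
    )
    for key in required:
        if key not in raw:
            raise ConfigurationError(f"parameter source missing required key {key!r}")

    bond_lengths = _normalise_keys(raw["bond_lengths"], True)
    pseudo = _normalise_keys(raw["pseudobond_lengths"], True)
    squeeze = _normalise_keys(raw["squeeze_factors"], True)
    for kind in COVALENT_BONDS:
        if kind not in bond_lengths:
            raise ConfigurationError(f"missing covalent bond entry {kind!r}")
    for kind in PSEUDOBONDS:
        if kind not in pseudo:
            raise ConfigurationError(f"missing pseudobond entry {kind!r}")

    def pairs(table):
        return {
            (tuple(k) if isinstance(k, (list, tuple)) else (k,)): float(v)
            for k, v in table.items()
        }

    return ParameterSet(
        bond_lengths=bond_lengths,
        pseudobond_lengths=pseudo,
        delta=float(raw["delta"]),
        hs_diameters=dict(raw["hs_diameters"]),
        sw_ranges=_freeze_pair_table(pairs(raw["sw_ranges"]), "well-range"),
        well_depths=_freeze_pair_table(pairs(raw["well_depths"]), "well-depth"),
        hbond_range=float(raw["hbond_range"]),
        hbond_energy=float(raw["hbond_energy"]),
        squeeze_factors=squeeze,
        hbond_aux_min=float(raw.get("hbond_aux_min", 4.5)),
        hbond_min_separation=int(raw.get("hbond_min_separation", 4)),
        sc_bond_length=float(raw.get("sc_bond_length", 2.4)),
    )


def combined_hs_diameter(
    d_i: float,
    d_j: float,
    pair_kind: tuple | None = None,
    squeeze_factors: Mapping[tuple, float] | None = None,
) -> float:
    """Lorentz-Berthelot combined hard-sphere diameter with squeeze correction.

    The arithmetic mean of the two bead diameters, multiplied by the squeeze
    factor when ``pair_kind`` appears in the squeeze table (else 1).
    """
    mean = 0.5 * (d_i + d_j)
    if squeeze_factors and pair_kind is not None:
        mean *= squeeze_factors.get(pair_kind, 1.0)
    return mean
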