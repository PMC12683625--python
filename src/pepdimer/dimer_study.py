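"""The desk-scale dimerization study: fixed conditions and driver.

An 8-residue *polar* homopolymer dimer under the simplified two-class
preset in a 60 A periodic box.  Polar-polar side-chain wells are zero in
the preset, so the only attractive interaction is the backbone hydrogen
bond — the interaction that drives aggregation and ordering in the full
model — and the potential energy is exactly minus the bond count.  (A
hydrophobic homopolymer under the same preset is dominated by its many
weak side-chain contacts instead: hydrogen-bonded configurations are an
entropically negligible fraction of each energy bin at this scale, which
buries the signal the study is about.)

The density of states is estimated over the integer-spaced energy window
[-11, 0] eps_HB (unit bins aligned so levels fall at bin centres), with a
pivot-heavy move mix — under the tight bond windows, displacement moves
mostly shuffle side-chain beads, so pivots carry the conformational
diffusion.  The gain stays at 0.3 for the first half of the run and decays
as t0/t afterwards, with the adopted estimate being the tail average over
the second half; production keeps a small refine gain so the walk covers
the full support.

These conditions are the package's scaled-down stand-in for the real
peptide systems; they are fixed here once and imported by the test suite,
the analysis driver, and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import observables as obs
from . import samc, thermo
from .fixtures import make_homopolymer
from .moves import MoveConfig

__all__ = ["CONDITIONS", "run_dimer_study"]

CONDITIONS = dict(
    n_residues=8,
    residue_letter="S",  # polar: hydrogen bonds are the only attraction
    # 40 A: dilute enough that association costs real translational entropy,
    # small enough that re-association is not hopelessly diffusion-limited;
    # safe under minimum image (max intra-chain extent ~28 A keeps image
    # distances beyond the 4.5 A bond range)
    box_edge=40.0,
    bin_width=1.0,
    grid_origin=-0.5,  # integer energy levels at bin centres
    energy_floor=-11.0,
    move_mix=(0.4, 0.4, 0.2),
    # the estimate's bias scales as gain x waiting time of the rarest
    # transition (first binding); a small gain with a 1/t tail keeps that
    # product well below the true per-bond entropy cost
    gamma0=0.01,
    gain_plateau_fraction=0.1,
    estimation_steps=5_000_000,
    n_replicas=2,
    production_steps=1_000_000,
    production_refine_gamma=0.05,
    sample_every=10,
    temperatures=tuple(np.round(np.linspace(0.08, 0.5, 85), 4)),
)


def run_dimer_study(seed: int, *, estimation_steps: int | None = None,
                    production_steps: int | None = None) -> dict:
    """Estimate the dimer's density of states and collect observables.

    Returns a dict with the sampler fixture, the replica-averaged DOS, the
    filled observable accumulator, and the kinetically convoluted total DOS.
    Step counts can be overridden for quick smoke runs; the defaults are the
    study conditions.
    """
    c = CONDITIONS
    est = estimation_steps or c["estimation_steps"]
    prod = production_steps or c["production_steps"]
    hp = make_homopolymer(c["n_residues"], residue_letter=c["residue_letter"],
                          n_chains=2, box_edge=c["box_edge"],
                          move_config=MoveConfig(move_mix=c["move_mix"]))
    replicas = samc.run_estimation(
        hp.landscape, bin_width=c["bin_width"], n_steps=est,
        n_replicas=c["n_replicas"], seed=seed, gamma0=c["gamma0"],
        t0=max(int(est * c["gain_plateau_fraction"]), 1),
        e_min=c["grid_origin"], energy_floor=c["energy_floor"])
    dos = thermo.average_replica_entropy(replicas, quorum=c["n_replicas"])
    accumulator = obs.ObservableAccumulator(dos.grid.n_bins)
    obs.register_standard_observables(accumulator, hp.system)
    samc.run_production(hp.landscape, dos, prod, seed=seed + 1,
                        accumulator=accumulator,
                        sample_every=c["sample_every"],
                        refine_gamma=c["production_refine_gamma"])
    n_dof = 3 * hp.system.n_beads
    total = thermo.convolve_kinetic(dos, n_dof,
                                    t_max=max(c["temperatures"]))
    return {
        "fixture": hp,
        "system": hp.system,
        "replicas": replicas,
        "dos": dos,
        "accumulator": accumulator,
        "total_dos": total,
        "n_dof": n_dof,
    }
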