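"""Run configuration, file formats, and the end-to-end pipeline.

Everything an analysis produces is plain text: DOS checkpoints and series as
TSV, snapshots as PDB records (one atom record per bead), the run
configuration archived as YAML beside its outputs.  All randomness flows from
the config seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from . import observables as obs
from . import samc, thermo
from .model import System, SystemState
from .moves import MoveConfig, PeptideLandscape
from .params import ConfigurationError, load_parameters
from .topology import build_topology

__all__ = [
    "RunConfig",
    "read_sequences",
    "write_pdb_snapshot",
    "write_series_tsv",
    "run_pipeline",
]

log = logging.getLogger("pepdimer")


def read_sequences(source) -> list:
    """Sequences from a FASTA file or a plain one-letter string."""
    path = Path(str(source))
    if path.exists() and path.is_file():
        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return [str(source).upper()]


_PDB_ELEMENT = {"NH": "N", "CA": "C", "CO": "C", "SC": "C"}


def write_pdb_snapshot(system: System, state: SystemState, path) -> None:
    """Write one PDB-format MODEL with one ATOM record per bead.

    The bead kind goes in the atom-name field and the residue index is
    preserved; chains are lettered A, B, ...
    """
    lines = ["MODEL     1"]
    serial = 1
    for c, topo in enumerate(system.topologies):
        o = system.offsets[c]
        chain_id = chr(ord("A") + c)
        for i, (res, kind) in enumerate(topo.beads):
            x, y, z = state.coords[o + i]
            lines.append(
                f"ATOM  {serial:5d} {kind:<4s} {topo.sequence[res]:>3s} "
                f"{chain_id}{res + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{_PDB_ELEMENT[kind]:>2s}"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}       {topo.sequence[-1]:>3s} "
                     f"{chain_id}{topo.n_residues:4d}")
        serial += 1
    lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_series_tsv(path, columns: dict) -> None:
    """Tab-separated series file with a header row (grep/diff friendly)."""
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    lines = ["\t".join(names)]
    for row in zip(*arrays):
        lines.append("\t".join(format(float(v), ".10g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    sequence: str
    n_chains: int = 2
    preset: str = "reference-simplified"
    box_edge: float = 60.0
    bin_width: float = 0.2
    n_steps: int = 1_000_000
    n_replicas: int = 2
    production_steps: int = 500_000
    sample_every: int = 10
    gamma0: float = 1.0
    t0: int | None = None
    production_refine_gamma: float | None = None
    seed: int = 1
    move_mix: tuple = (0.8, 0.1, 0.1)
    temperatures: tuple = tuple(np.round(np.linspace(0.05, 0.5, 91), 4))
    gauge_references: tuple = ()  # ((reduced_T, physical_T_K), ...)
    output_dir: str = "runs/latest"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["move_mix"] = list(self.move_mix)
        d["temperatures"] = [float(t) for t in self.temperatures]
        d["gauge_references"] = [list(map(float, r)) for r in self.gauge_references]
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"missing run configuration file: {path}")
        raw = yaml.safe_load(path.read_text())
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name in ("move_mix", "temperatures"):
                    v = tuple(v)
                if f.name == "gauge_references":
                    v = tuple(tuple(x) for x in v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute estimate -> produce -> thermo -> observables (-> gauge).

    Returns the run directory.  Partial outputs are retained on a stage
    failure, with the failing stage logged.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    (outdir / "run_stamp.json").write_text(json.dumps(stamp, indent=2) + "\n")

    stage = "setup"
    try:
        params = load_parameters(config.preset)
        topo = build_topology(config.sequence, params)
        system = System([topo] * config.n_chains, params, config.box_edge)
        landscape = PeptideLandscape(
            system, MoveConfig(move_mix=tuple(config.move_mix)))

        stage = "estimate-dos"
        replicas = samc.run_estimation(
            landscape, bin_width=config.bin_width, n_steps=config.n_steps,
            n_replicas=config.n_replicas, seed=config.seed,
            gamma0=config.gamma0, t0=config.t0,
            # half-bin origin keeps discrete energy levels at bin centres
            e_min=-config.bin_width / 2.0,
            checkpoint_dir=outdir)
        avg = thermo.average_replica_entropy(replicas, quorum=1)
        samc.write_checkpoint(avg, outdir / "dos_average.tsv")

        stage = "produce"
        accumulator = obs.ObservableAccumulator(avg.grid.n_bins)
        obs.register_standard_observables(accumulator, system)
        samc.run_production(
            landscape, avg, config.production_steps,
            seed=config.seed + 1, accumulator=accumulator,
            sample_every=config.sample_every,
            refine_gamma=config.production_refine_gamma)

        stage = "thermo"
        n_dof = 3 * system.n_beads
        total = thermo.convolve_kinetic(avg, n_dof,
                                        t_max=max(config.temperatures))
        E, T_E = thermo.microcanonical_temperature(total)
        _, C_E = thermo.microcanonical_specific_heat(E, T_E)
        write_series_tsv(outdir / "microcanonical.tsv",
                         {"E": E, "S": total.ln_g[np.isfinite(total.ln_g)],
                          "T": T_E, "C": C_E})
        series = thermo.canonical_series(total, config.temperatures)
        write_series_tsv(outdir / "canonical.tsv",
                         {"T": series.temperatures, "ln_Z": series.log_z,
                          "mean_E": series.mean_energy,
                          "C": series.heat_capacity})
        report = thermo.find_transitions(total, series)
        (outdir / "transitions.txt").write_text(_format_report(report))

        stage = "observables"
        temps = np.asarray(config.temperatures)
        columns = {"T": temps}
        for name in ("hb_intra", "hb_inter", "rg2_chain", "kappa2_chain",
                     "rg2_dimer"):
            if name not in accumulator.sums:
                continue
            vals = []
            for T in temps:
                try:
                    vals.append(float(obs.reweight_to_temperature(
                        accumulator, avg, T, name)))
                except obs.ReweightingError:
                    vals.append(float("nan"))
            columns[name] = np.array(vals)
        write_series_tsv(outdir / "observables.tsv", columns)

        if config.gauge_references:
            stage = "gauge"
            from . import gauge as gauge_mod
            g = gauge_mod.combine_gauges(config.gauge_references)
            peak_lines = []
            for t_star, height in report.canonical_peaks:
                k, dk = gauge_mod.to_kelvin(t_star, g)
                peak_lines.append(
                    f"T* = {t_star:.4g} reduced -> {k:.0f} +- {dk:.0f} K")
            (outdir / "gauge.txt").write_text(
                f"mean factor: {g.mean_factor:.1f} K per reduced unit\n"
                f"uncertainty (half spread / max dev): "
                f"{g.uncertainty:.1f} / {g.uncertainty_max:.1f} K\n"
                f"eps_HB: {g.hbond_energy_physical:.2f} kcal/mol\n"
                + "\n".join(peak_lines) + "\n")

        state = landscape.initial_state(np.random.default_rng(config.seed))
        write_pdb_snapshot(system, state, outdir / "initial.pdb")
    except Exception:
        log.exception("pipeline stage %r failed; partial outputs in %s",
                      stage, outdir)
        raise
    return outdir


def _format_report(report) -> str:
    lines = ["# transition report"]
    for t_star, (e_a, e_b) in report.first_order:
        lines.append(f"first-order\tT*={t_star:.6g}\tloop=[{e_a:.6g},{e_b:.6g}]")
    for t_star in report.second_order:
        lines.append(f"second-order\tT*={t_star:.6g}")
    for t_star, height in report.canonical_peaks:
        lines.append(f"canonical-peak\tT*={t_star:.6g}\tC={height:.6g}")
    return "\n".join(lines) + "\n"
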