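"""Thermodynamic-analysis validation on closed-form systems.

Checks, in order: the canonical two-level (Schottky) heat capacity against
its closed form; the equipartition limit T(E) = 2E/n_dof of the kinetic
convolution; agreement of the fluctuation and derivative forms of C(T); and
recovery of the double-tangent transition temperature (plus the negative
microcanonical specific heat inside the loop) from a constructed
convex-intruder entropy.
"""

import math
import sys
from pathlib import Path

import numpy as np

from pepdimer import samc, thermo
from pepdimer.fixtures import make_entropy_fixture
from pepdimer.io import write_series_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    RESULTS.mkdir(exist_ok=True)
    out = {}

    # Schottky: degeneracies (1, 3), gap 1
    dos = samc.DOSEstimate.empty(-0.5, 1.0, 2)
    dos.ln_g = np.array([0.0, math.log(3.0)])
    dos.histogram = np.ones(2, dtype=np.int64)
    temps = np.linspace(0.05, 3.0, 200)
    series = thermo.canonical_series(dos, temps)
    x = 1.0 / temps
    occ = 3 * np.exp(-x) / (1 + 3 * np.exp(-x))
    closed = x**2 * occ * (1 - occ)
    out["schottky_max_dev"] = float(np.abs(series.heat_capacity - closed).max())
    print(f"Schottky C(T) vs closed form: max deviation "
          f"{out['schottky_max_dev']:.2e}")

    # equipartition after kinetic convolution
    n_dof = 30
    delta = samc.DOSEstimate.empty(-0.25, 0.5, 1)
    delta.ln_g = np.zeros(1)
    delta.histogram = np.ones(1, dtype=np.int64)
    total = thermo.convolve_kinetic(delta, n_dof, t_max=0.5)
    E, T = thermo.microcanonical_temperature(total)
    sel = (E > 6.0) & (E < E.max() - 1.0)
    out["equipartition_max_rel_err"] = float(
        np.abs(T[sel] / (2 * E[sel] / n_dof) - 1).max())
    print(f"ideal-gas T(E) = 2E/n_dof: max relative error "
          f"{out['equipartition_max_rel_err']:.2e}")

    # fluctuation vs derivative C(T)
    rng = np.random.default_rng(0)
    dos2 = samc.DOSEstimate.empty(0.0, 0.5, 12)
    dos2.ln_g = np.cumsum(rng.uniform(0, 1, 12))
    dos2.histogram = np.ones(12, dtype=np.int64)
    temps2 = np.linspace(0.2, 2.0, 400)
    s2 = thermo.canonical_series(dos2, temps2)
    dE = np.gradient(s2.mean_energy, temps2)
    inner = slice(5, -5)
    out["c_forms_max_rel_dev"] = float(np.abs(
        (s2.heat_capacity[inner] - dE[inner])
        / np.maximum(s2.heat_capacity[inner], 1e-12)).max())
    print(f"fluctuation vs derivative C(T): max relative deviation "
          f"{out['c_forms_max_rel_dev']:.2e}")

    # convex intruder: double tangent and negative C(E)
    fixture = make_entropy_fixture("convex-intruder", slope=5.0)
    E, S = fixture.energies, fixture.entropy
    series3 = thermo.canonical_series((E, S), np.linspace(0.05, 1.0, 120))
    report = thermo.find_transitions((E, S), series3)
    t_star, (e_a, e_b) = report.first_order[0]
    _, T3 = thermo.microcanonical_temperature((E, S))
    _, C3 = thermo.microcanonical_specific_heat(E, T3)
    inside = (E > e_a) & (E < e_b)
    out["intruder_t_star"] = float(t_star)
    out["intruder_min_c_inside_loop"] = float(np.nanmin(C3[inside]))
    print(f"convex intruder: double-tangent T* = {t_star:.4f} "
          f"(constructed {fixture.t_star}), min C(E) inside loop = "
          f"{out['intruder_min_c_inside_loop']:.3g} (< 0 expected)")

    write_series_tsv(RESULTS / "toy_thermodynamics.tsv",
                     {k: np.array([v]) for k, v in out.items()})
    print(f"wrote {RESULTS}/toy_thermodynamics.tsv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
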