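"""Reduced-to-physical temperature gauge.

The simulation's temperature unit is the hydrogen-bond well depth over k_B,
so physical units require one experimental anchor: a reduced temperature at
which a simulated observable (here the radius of gyration) matches its
measured value at a known temperature in Kelvin.  Each reference pair
(reduced T, physical T) yields a conversion factor K-per-reduced-unit; the
combined gauge averages the reduced reference temperatures (rounded to three
decimals) and divides the physical reference by that mean.  The factor also
fixes the physical hydrogen-bond energy, eps_HB = factor * k_B.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GaugeResult",
    "conversion_factor",
    "combine_gauges",
    "to_kelvin",
    "to_celsius",
    "hbond_energy_physical",
    "box_concentration",
    "match_reference_temperature",
    "KB_KCAL_PER_MOL_K",
    "AVOGADRO",
]

KB_KCAL_PER_MOL_K = 0.001987204259  # Boltzmann constant, kcal / (mol K)
AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class GaugeResult:
    """A calibrated temperature conversion.

    ``factors`` holds the per-reference conversion factors (K per reduced
    unit); ``mean_factor`` comes from the averaged reduced reference
    temperature.  Two uncertainty conventions are carried: ``uncertainty`` is
    half the max-min spread of the factors, ``uncertainty_max`` the largest
    deviation of any factor from the mean (the more conservative band).
    """

    reference_points: tuple  # ((reduced_T, physical_T_K, label), ...)
    factors: tuple  # K per reduced unit, one per reference
    mean_factor: float
    uncertainty: float
    uncertainty_max: float

    @property
    def hbond_energy_physical(self) -> float:
        return hbond_energy_physical(self)


def conversion_factor(reduced_t: float, physical_t_k: float) -> float:
    """K-per-reduced-unit factor of one reference pair."""
    if reduced_t <= 0:
        raise ValueError("reduced temperature must be positive")
    return physical_t_k / reduced_t


def combine_gauges(references) -> GaugeResult:
    """Combine reference pairs into one gauge.

    ``references`` is an iterable of ``(reduced_T, physical_T_K)`` or
    ``(reduced_T, physical_T_K, label)``.  The reduced reference temperatures
    are averaged and rounded to three decimals before dividing the physical
    reference (all references must share it), reproducing the printed-table
    arithmetic exactly; the result is order-independent.
    """
    refs = []
    for ref in references:
        if len(ref) == 2:
            refs.append((float(ref[0]), float(ref[1]), ""))
        else:
            refs.append((float(ref[0]), float(ref[1]), str(ref[2])))
    if not refs:
        raise ValueError("need at least one reference point")
    physical = {r[1] for r in refs}
    if len(physical) != 1:
        raise ValueError("all references must share the physical anchor")
    phys = physical.pop()
    refs = sorted(refs)
    factors = tuple(conversion_factor(r[0], r[1]) for r in refs)
    mean_reduced = round(sum(r[0] for r in refs) / len(refs), 3)
    mean_factor = phys / mean_reduced
    spread = 0.5 * (max(factors) - min(factors))
    dev = max(abs(f - mean_factor) for f in factors)
    return GaugeResult(
        reference_points=tuple(refs), factors=factors,
        mean_factor=mean_factor, uncertainty=spread, uncertainty_max=dev,
    )


def to_kelvin(reduced_t: float, gauge: GaugeResult) -> tuple:
    """Convert a reduced temperature to Kelvin.

    Returns ``(T_K, uncertainty_K)`` with the uncertainty propagated from
    the conservative (max-deviation) band of the gauge.
    """
    return (reduced_t * gauge.mean_factor, reduced_t * gauge.uncertainty_max)


def to_celsius(reduced_t: float, gauge: GaugeResult) -> tuple:
    k, dk = to_kelvin(reduced_t, gauge)
    return k - 273.15, dk


def hbond_energy_physical(gauge: GaugeResult) -> float:
    """Physical hydrogen-bond well depth, kcal/mol (= factor x k_B)."""
    return gauge.mean_factor * KB_KCAL_PER_MOL_K


def hbond_energy_uncertainty(gauge: GaugeResult) -> float:
    return gauge.uncertainty_max * KB_KCAL_PER_MOL_K


def box_concentration(n_chains: int, box_edge_angstrom: float) -> float:
    """Chain (monomer) concentration in a cubic periodic box, in micromolar."""
    if n_chains < 1 or box_edge_angstrom <= 0:
        raise ValueError("need n_chains >= 1 and a positive box edge")
    volume_l = (box_edge_angstrom * 1e-9) ** 3  # A^3 -> dm^3 (litre)
    return n_chains / (AVOGADRO * volume_l) * 1e6


def match_reference_temperature(temperatures, values, target: float) -> float:
    """Nearest-crossing lookup on a simulated observable curve.

    Given a monotone-sampled curve ``values(temperatures)`` (e.g. R_g(T))
    and an experimental ``target`` value, return the temperature at which
    the curve crosses the target (linear interpolation between the two
    bracketing samples; nearest endpoint if never crossed).  The experimental
    values themselves are user input, not bundled data.
    """
    import numpy as np

    t = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    d = v - target
    sign = np.sign(d)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if crossings.size == 0:
        return float(t[np.argmin(np.abs(d))])
    i = int(crossings[0])
    frac = d[i] / (d[i] - d[i + 1])
    return float(t[i] + frac * (t[i + 1] - t[i]))
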