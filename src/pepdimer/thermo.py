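"""Microcanonical and canonical thermodynamics from a density of states.

The sampler delivers the configurational entropy ln g~(U) up to an additive
constant.  The analysis chain is:

1. average the replica entropies (after aligning their arbitrary additive
   constants over shared energy bins);
2. convolute with the kinetic (ideal-gas momentum) density of states to
   obtain the total-energy entropy S(E) = ln g(E);
3. microcanonical route: T(E) = (dS/dE)^-1 and C(E) = (dT/dE)^-1 by finite
   differences — a back-bending ("convex intruder") region of S(E) makes
   T(E) loop and C(E) negative inside the loop, the small-system signature
   of a first-order transition, whose transition temperature is the slope of
   the double tangent bridging the intruder;
4. canonical route: Z(T) = sum_E g(E) exp(-E/T) by log-sum-exp, with
   C(T) = (<E^2> - <E>^2)/T^2, peaks marking transitions.

The kinetic exponent uses the phase-space-volume convention g_kin(K) ~
K^(n_dof/2), under which the microcanonical temperature of the free system
obeys equipartition T = 2K/n_dof exactly rather than up to O(1/n_dof); for
the bead counts of interest the two conventions differ negligibly but the
exact limit makes the analysis testable against closed forms.

All quantities are invariant under the additive constant of ln g (the
constant only shifts ln Z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.special import logsumexp

from .samc import DOSEstimate, EnergyGrid

__all__ = [
    "TotalDOS",
    "CanonicalSeries",
    "TransitionReport",
    "AnalysisError",
    "average_replica_entropy",
    "convolve_kinetic",
    "microcanonical_temperature",
    "microcanonical_specific_heat",
    "canonical_series",
    "find_transitions",
]


class AnalysisError(RuntimeError):
    """The requested analysis is not defined on the supplied data."""


@dataclass
class TotalDOS:
    """Total-energy density of states after the kinetic convolution."""

    energies: np.ndarray  # bin centers, total energy E
    ln_g: np.ndarray  # ln g(E) = S(E), up to an additive constant
    n_dof: int
    u_min: float | None = None  # lowest visited configurational energy

    @property
    def entropy(self) -> np.ndarray:
        return self.ln_g


@dataclass
class CanonicalSeries:
    """Canonical thermodynamics on a temperature grid (reduced units)."""

    temperatures: np.ndarray
    log_z: np.ndarray
    mean_energy: np.ndarray
    mean_energy_sq: np.ndarray
    heat_capacity: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return 1.0 / self.temperatures


@dataclass
class TransitionReport:
    """Transition temperatures found by both ensembles.

    ``first_order``: (T*, (E_left, E_right)) from the double-tangent
    construction over each convex intruder of S(E).
    ``second_order``: T* at isolated finite maxima of C(E).
    ``canonical_peaks``: (T*, C peak height) from C(T).
    """

    first_order: list
    second_order: list
    canonical_peaks: list


def _dos_arrays(dos):
    """Normalize a DOSEstimate / TotalDOS / (E, ln_g[, mask]) to arrays."""
    if isinstance(dos, DOSEstimate):
        mask = dos.visited
        return dos.grid.centers()[mask], dos.ln_g[mask]
    if isinstance(dos, TotalDOS):
        mask = np.isfinite(dos.ln_g)
        return dos.energies[mask], dos.ln_g[mask]
    if len(dos) == 3:
        e, g, mask = dos
        return np.asarray(e)[mask], np.asarray(g)[mask]
    e, g = dos
    return np.asarray(e, float), np.asarray(g, float)


def average_replica_entropy(replicas: list, quorum: int | None = None
                            ) -> DOSEstimate:
    """Average ln g~(U) over replicas after additive-constant alignment.

    Each replica determines its entropy only up to a constant, so every
    replica is shifted by the mean difference to the first replica over their
    shared visited bins (the least-squares constant), then averaged bin-wise.
    Bins visited by fewer than ``quorum`` replicas (default: a strict
    majority) are dropped.  Histograms are summed over replicas.

    Raises
    ------
    AnalysisError
        if some replica shares no visited bin with the first one.
    """
    if not replicas:
        raise AnalysisError("no replicas supplied")
    width = replicas[0].grid.width
    for r in replicas:
        if not math.isclose(r.grid.width, width):
            raise AnalysisError("replicas use different bin widths")
    e_min = min(r.grid.e_min for r in replicas)
    e_max = max(r.grid.e_min + r.grid.n_bins * width for r in replicas)
    n_bins = int(round((e_max - e_min) / width))
    if quorum is None:
        quorum = len(replicas) // 2 + 1

    ln_g = np.zeros((len(replicas), n_bins))
    visited = np.zeros((len(replicas), n_bins), dtype=bool)
    hist = np.zeros(n_bins, dtype=np.int64)
    for k, r in enumerate(replicas):
        off = int(round((r.grid.e_min - e_min) / width))
        sl = slice(off, off + r.grid.n_bins)
        ln_g[k, sl] = r.ln_g
        visited[k, sl] = r.visited
        hist[sl] += r.histogram

    for k in range(1, len(replicas)):
        shared = visited[0] & visited[k]
        if not shared.any():
            raise AnalysisError(
                f"replica {k} shares no visited energy bin with replica 0")
        ln_g[k] += np.mean(ln_g[0][shared] - ln_g[k][shared])

    counts = visited.sum(axis=0)
    keep = counts >= quorum
    avg = np.full(n_bins, 0.0)
    with np.errstate(invalid="ignore"):
        avg[keep] = (np.where(visited, ln_g, 0.0).sum(axis=0)[keep]
                     / counts[keep])
    hist[~keep] = 0
    out = DOSEstimate(grid=EnergyGrid(e_min, width, n_bins), ln_g=avg,
                      histogram=hist, t=sum(r.t for r in replicas),
                      gamma0=replicas[0].gamma0, t0=replicas[0].t0,
                      seed=replicas[0].seed)
    return out


def convolve_kinetic(config_dos, n_dof: int, *, t_max: float = 0.5,
                     n_extra: int | None = None) -> TotalDOS:
    """Convolute the configurational DOS with the ideal-gas kinetic DOS.

    ``ln g(E) = logsumexp_U [ ln g~(U) + (n_dof/2) ln(E - U) ]`` over visited
    configurational bins with ``U < E``, evaluated on the configurational grid
    extended upwards far enough that canonical averages up to ``t_max`` are
    converged (mean kinetic energy plus several standard deviations).
    """
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    U, ln_gU = _dos_arrays(config_dos)
    if U.size == 0:
        raise AnalysisError("configurational DOS has no visited bins")
    width = float(np.min(np.diff(U))) if U.size > 1 else 0.5
    if n_extra is None:
        k_span = (n_dof / 2.0 + 1.0) * t_max * 4.0 + 10.0 * width
        n_extra = int(math.ceil(k_span / width))
    E = np.concatenate([U, U[-1] + width * (1 + np.arange(n_extra))])
    half_n = 0.5 * n_dof
    ln_g = np.full(E.size, -np.inf)
    for k, e in enumerate(E):
        K = e - U
        ok = K > 0
        if ok.any():
            ln_g[k] = logsumexp(ln_gU[ok] + half_n * np.log(K[ok]))
    return TotalDOS(energies=E, ln_g=ln_g, n_dof=n_dof, u_min=float(U[0]))


def microcanonical_temperature(total_dos, smooth_window: int | None = None):
    """T(E) = (dS/dE)^-1 by centered finite differences.

    Returns ``(E, T)`` over the support; entries where dS/dE <= 0 are NaN.
    ``smooth_window`` applies a cubic Savitzky-Golay filter to S(E) first
    (odd window length >= 5); the raw grid is the default.

    Raises
    ------
    AnalysisError
        with fewer than 3 support points.
    """
    E, S = _dos_arrays(total_dos)
    if E.size < 3:
        raise AnalysisError("need at least 3 entropy points for derivatives")
    if smooth_window:
        S = savgol_filter(S, smooth_window, polyorder=3)
    beta = np.gradient(S, E)
    with np.errstate(divide="ignore"):
        T = np.where(beta > 0, 1.0 / beta, np.nan)
    return E, T


def microcanonical_specific_heat(E: np.ndarray, T: np.ndarray):
    """C(E) = (dT/dE)^-1 by centered finite differences.

    Negative values (inside loop regions) and divergences are reported as-is;
    where dT/dE vanishes the divergence is reported as +-inf.
    """
    E = np.asarray(E, float)
    T = np.asarray(T, float)
    if E.size < 3:
        raise AnalysisError("need at least 3 temperature points")
    dTdE = np.gradient(T, E)
    # treat float-cancellation residue around a flat T(E) as an exact zero:
    # the specific heat diverges there and is reported as inf
    scale = np.nanmax(np.abs(T)) / max(E[-1] - E[0], 1e-300)
    flat = np.abs(dTdE) <= 1e-9 * max(scale, 1e-300)
    with np.errstate(divide="ignore"):
        C = np.where(~flat, 1.0 / np.where(flat, 1.0, dTdE), np.inf)
    return E, C


def canonical_series(dos, temperatures) -> CanonicalSeries:
    """Z(T), <E>(T), C(T) by stable log-sum-exp over the DOS support.

    ``C(T) = (<E^2> - <E>^2)/T^2`` (fluctuation form); all outputs are
    invariant under an additive constant in ln g.
    """
    E, ln_g = _dos_arrays(dos)
    temperatures = np.asarray(temperatures, dtype=float)
    if np.any(temperatures <= 0):
        raise ValueError("temperatures must be positive")
    log_z = np.empty(temperatures.size)
    mean_e = np.empty(temperatures.size)
    mean_e2 = np.empty(temperatures.size)
    for k, T in enumerate(temperatures):
        w = ln_g - E / T
        lz = logsumexp(w)
        p = np.exp(w - lz)
        log_z[k] = lz
        mean_e[k] = float(np.dot(p, E))
        mean_e2[k] = float(np.dot(p, E * E))
    with np.errstate(invalid="ignore"):
        heat = np.maximum(mean_e2 - mean_e**2, 0.0) / temperatures**2
    return CanonicalSeries(temperatures=temperatures, log_z=log_z,
                           mean_energy=mean_e, mean_energy_sq=mean_e2,
                           heat_capacity=heat)


def _upper_concave_hull(E, S):
    """Indices of the upper concave hull vertices of the curve (E, S)."""
    hull = []
    for i in range(E.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (E[i1] - E[i0]) * (S[i] - S[i0]) \
                - (E[i] - E[i0]) * (S[i1] - S[i0])
            if cross >= 0:  # middle point below or on the chord: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def find_transitions(total_dos, series: CanonicalSeries, *,
                     min_loop_depth: float = 1e-6,
                     peak_prominence_frac: float = 0.02,
                     smooth_window: int | None = None) -> TransitionReport:
    """Locate transitions in both ensembles.

    First order: each convex intruder of S(E) (where the upper concave hull
    lies above S by more than ``min_loop_depth``) contributes T* = 1/slope of
    the bridging double tangent, with the hull contact points as loop bounds.
    Second order: finite positive local maxima of C(E) outside loop regions.
    Canonical: local maxima of C(T) with prominence above
    ``peak_prominence_frac`` of the global maximum.
    """
    E, S = _dos_arrays(total_dos)
    first_order = []
    loop_mask = np.zeros(E.size, dtype=bool)
    if E.size >= 3:
        hull = _upper_concave_hull(E, S)
        for a, b in zip(hull[:-1], hull[1:]):
            if b - a <= 1:
                continue
            slope = (S[b] - S[a]) / (E[b] - E[a])
            interior = np.arange(a + 1, b)
            gap = S[a] + slope * (E[interior] - E[a]) - S[interior]
            if gap.max() > min_loop_depth and slope > 0:
                first_order.append((1.0 / slope, (float(E[a]), float(E[b]))))
                loop_mask[a : b + 1] = True

    second_order = []
    if E.size >= 3:
        _, T = microcanonical_temperature((E, S), smooth_window=smooth_window)
        _, C = microcanonical_specific_heat(E, T)
        ok = np.isfinite(C) & (C > 0) & ~loop_mask & np.isfinite(T)
        Cm = np.where(ok, C, -np.inf)
        peaks, _ = find_peaks(Cm)
        for p in peaks:
            second_order.append(float(T[p]))

    canonical_peaks = []
    C_T = series.heat_capacity
    if C_T.size >= 3 and np.nanmax(C_T) > 0:
        peaks, props = find_peaks(
            C_T, prominence=peak_prominence_frac * float(np.nanmax(C_T)))
        for p in peaks:
            canonical_peaks.append(
                (float(series.temperatures[p]), float(C_T[p])))
    return TransitionReport(first_order=first_order,
                            second_order=second_order,
                            canonical_peaks=canonical_peaks)
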