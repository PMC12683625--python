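"""Thermodynamic analysis: replica averaging, kinetic convolution,
microcanonical derivatives, canonical series, and transition finding.

Closed-form oracles: the two-level Schottky anomaly, the ideal-gas
equipartition limit, and entropy fixtures with analytically known
double-tangent slopes.
"""

import math

import numpy as np
import pytest

from pepdimer import samc, thermo
from pepdimer.fixtures import make_entropy_fixture, make_k_level_system


def _dos_from_arrays(e_min, width, ln_g, hist=None):
    n = len(ln_g)
    dos = samc.DOSEstimate.empty(e_min, width, n)
    dos.ln_g = np.asarray(ln_g, dtype=float)
    dos.histogram = (np.asarray(hist, dtype=np.int64) if hist is not None
                     else np.ones(n, dtype=np.int64))
    return dos


class TestReplicaAveraging:
    def test_identical_replicas_are_idempotent(self):
        a = _dos_from_arrays(0.0, 0.5, [1.0, 2.0, 3.0])
        b = _dos_from_arrays(0.0, 0.5, [1.0, 2.0, 3.0])
        avg = thermo.average_replica_entropy([a, b], quorum=2)
        assert np.allclose(avg.ln_g[avg.visited], [1.0, 2.0, 3.0])

    def test_constant_offset_is_gauged_away(self):
        a = _dos_from_arrays(0.0, 0.5, [1.0, 2.0, 3.0])
        b = _dos_from_arrays(0.0, 0.5, [101.0, 102.0, 103.0])
        avg = thermo.average_replica_entropy([a, b], quorum=2)
        out = avg.ln_g[avg.visited]
        assert np.allclose(np.diff(out), [1.0, 1.0])

    def test_averaging_reduces_noise(self):
        """Synthetic replicas = truth + iid noise + arbitrary constants:
        the aligned average is closer to the truth than any single replica
        (after removing the additive gauge)."""
        rng = np.random.default_rng(0)
        truth = np.linspace(0.0, 10.0, 40)
        reps = []
        rmses = []
        for k in range(6):
            noisy = truth + rng.normal(0, 0.4, truth.size) + rng.uniform(-50, 50)
            reps.append(_dos_from_arrays(0.0, 0.5, noisy))
            centred = noisy - noisy.mean() - (truth - truth.mean())
            rmses.append(np.sqrt(np.mean(centred**2)))
        avg = thermo.average_replica_entropy(reps, quorum=6)
        out = avg.ln_g[avg.visited]
        centred = out - out.mean() - (truth - truth.mean())
        assert np.sqrt(np.mean(centred**2)) < min(rmses)

    def test_disjoint_supports_rejected(self):
        a = _dos_from_arrays(0.0, 0.5, [1.0, 2.0], hist=[1, 1])
        b = _dos_from_arrays(5.0, 0.5, [1.0, 2.0], hist=[1, 1])
        with pytest.raises(thermo.AnalysisError, match="share"):
            thermo.average_replica_entropy([a, b])

    def test_quorum_drops_sparsely_visited_bins(self):
        a = _dos_from_arrays(0.0, 0.5, [1.0, 2.0, 3.0], hist=[1, 1, 0])
        b = _dos_from_arrays(0.0, 0.5, [1.0, 2.0, 3.0], hist=[1, 1, 1])
        avg = thermo.average_replica_entropy([a, b], quorum=2)
        assert list(avg.visited) == [True, True, False]


class TestKineticConvolution:
    def test_delta_config_dos_gives_pure_kinetic(self):
        """A single configurational level at U0: the total DOS is the
        kinetic power law shifted by U0."""
        u0, n_dof = -2.0, 12
        dos = _dos_from_arrays(u0 - 0.25, 0.5, [0.0])
        total = thermo.convolve_kinetic(dos, n_dof, t_max=0.3)
        m = np.isfinite(total.ln_g)
        K = total.energies[m] - dos.grid.centers()[0]
        expected = 0.5 * n_dof * np.log(K)
        assert np.allclose(total.ln_g[m] - total.ln_g[m][-1],
                           expected - expected[-1], atol=1e-12)

    def test_equipartition_temperature(self):
        """T(E) = 2(E - U0)/n_dof for the free system."""
        u0, n_dof = 0.0, 30
        dos = _dos_from_arrays(u0 - 0.25, 0.5, [0.0])
        total = thermo.convolve_kinetic(dos, n_dof, t_max=0.5)
        E, T = thermo.microcanonical_temperature(total)
        # interior points only: one-sided differences at the grid edges and
        # the O((h/K)^2) centred-difference error near the kinetic origin
        sel = (E - u0 > 6.0) & (E < E.max() - 1.0)
        assert np.allclose(T[sel], 2.0 * (E[sel] - u0) / n_dof, rtol=4e-3)

    def test_ideal_gas_specific_heat_is_half_n_dof(self):
        u0, n_dof = 0.0, 30
        dos = _dos_from_arrays(u0 - 0.25, 0.5, [0.0])
        total = thermo.convolve_kinetic(dos, n_dof, t_max=0.5)
        E, T = thermo.microcanonical_temperature(total)
        E, C = thermo.microcanonical_specific_heat(E, T)
        sel = (E - u0 > 3.0) & (E < E.max() - 1.5)
        assert np.allclose(C[sel], n_dof / 2.0, rtol=2e-2)

    def test_convolution_commutes_with_constant_shift(self):
        dos_a = _dos_from_arrays(0.0, 0.5, [0.0, 1.0, 0.5])
        dos_b = _dos_from_arrays(0.0, 0.5, [100.0, 101.0, 100.5])
        ta = thermo.convolve_kinetic(dos_a, 6, t_max=0.3)
        tb = thermo.convolve_kinetic(dos_b, 6, t_max=0.3)
        m = np.isfinite(ta.ln_g)
        assert np.allclose(tb.ln_g[m] - ta.ln_g[m], 100.0, atol=1e-9)


class TestMicrocanonicalDerivatives:
    def test_linear_entropy_gives_constant_temperature(self):
        E = np.linspace(0, 5, 50)
        S = 1.0 + 4.0 * E
        Eo, T = thermo.microcanonical_temperature((E, S))
        assert np.allclose(T, 0.25)

    def test_piecewise_linear_entropy_gives_piecewise_constant_t(self):
        fixture = make_entropy_fixture("piecewise-linear")
        E, T = thermo.microcanonical_temperature(
            (fixture.energies, fixture.entropy))
        left = T[E < 1.8]
        right = T[E > 2.2]
        assert np.allclose(left, 1.0 / 3.0, rtol=1e-10)
        assert np.allclose(right, 1.0 / 1.5, rtol=1e-10)

    def test_constant_temperature_reports_divergent_heat(self):
        E = np.linspace(0, 5, 20)
        T = np.full(20, 2.0)
        _, C = thermo.microcanonical_specific_heat(E, T)
        assert np.all(np.isinf(C))

    def test_too_few_points_rejected(self):
        with pytest.raises(thermo.AnalysisError):
            thermo.microcanonical_temperature((np.array([0.0, 1.0]),
                                               np.array([0.0, 1.0])))


def schottky_heat_capacity(T, g0, g1, gap):
    """Closed-form two-level heat capacity."""
    T = np.asarray(T, dtype=float)
    r = g1 / g0
    x = gap / T
    occ = r * np.exp(-x) / (1.0 + r * np.exp(-x))
    return x**2 * occ * (1.0 - occ)


class TestCanonicalSeries:
    def test_single_level_has_zero_heat_capacity(self):
        dos = _dos_from_arrays(0.0, 0.5, [2.0])
        series = thermo.canonical_series(dos, np.linspace(0.1, 2.0, 30))
        assert np.allclose(series.heat_capacity, 0.0)

    def test_two_level_matches_schottky_closed_form(self):
        """Degeneracies (1, 3), gap 1: C(T) equals the closed form to 1e-8."""
        dos = _dos_from_arrays(-0.5, 1.0, [0.0, math.log(3.0)])
        temps = np.linspace(0.05, 3.0, 200)
        series = thermo.canonical_series(dos, temps)
        assert np.allclose(series.heat_capacity,
                           schottky_heat_capacity(temps, 1, 3, 1.0),
                           atol=1e-8)

    def test_fluctuation_and_derivative_forms_agree(self):
        rng = np.random.default_rng(1)
        dos = _dos_from_arrays(0.0, 0.5, np.cumsum(rng.uniform(0, 1, 12)))
        temps = np.linspace(0.2, 2.0, 400)
        series = thermo.canonical_series(dos, temps)
        dE_dT = np.gradient(series.mean_energy, temps)
        inner = slice(5, -5)
        assert np.allclose(series.heat_capacity[inner], dE_dT[inner],
                           rtol=5e-3, atol=1e-6)

    def test_invariance_under_entropy_shift(self):
        dos_a = _dos_from_arrays(0.0, 0.5, [0.0, 1.0, 0.3])
        dos_b = _dos_from_arrays(0.0, 0.5, [100.0, 101.0, 100.3])
        temps = np.linspace(0.1, 2.0, 50)
        sa = thermo.canonical_series(dos_a, temps)
        sb = thermo.canonical_series(dos_b, temps)
        assert np.allclose(sa.mean_energy, sb.mean_energy)
        assert np.allclose(sa.heat_capacity, sb.heat_capacity)
        assert np.allclose(sb.log_z - sa.log_z, 100.0)

    def test_mean_energy_non_decreasing_and_heat_nonnegative(self):
        rng = np.random.default_rng(2)
        dos = _dos_from_arrays(-3.0, 0.5, np.cumsum(rng.uniform(0, 2, 15)))
        series = thermo.canonical_series(dos, np.linspace(0.05, 3.0, 100))
        assert np.all(np.diff(series.mean_energy) >= -1e-12)
        assert np.all(series.heat_capacity >= 0.0)

    def test_nonpositive_temperature_rejected(self):
        dos = _dos_from_arrays(0.0, 0.5, [0.0, 1.0])
        with pytest.raises(ValueError):
            thermo.canonical_series(dos, [0.0, 0.5])


class TestTransitionFinding:
    def test_concave_entropy_has_no_first_order_transition(self):
        fixture = make_entropy_fixture("concave")
        series = thermo.canonical_series(
            (fixture.energies, fixture.entropy), np.linspace(0.05, 1.0, 60))
        report = thermo.find_transitions(
            (fixture.energies, fixture.entropy), series)
        assert report.first_order == []

    def test_intruder_recovers_double_tangent_temperature(self):
        """Constructed intruder with tangent slope 5: T* = 0.2 within the
        grid resolution, and C(E) < 0 somewhere inside the loop."""
        fixture = make_entropy_fixture("convex-intruder")
        E, S = fixture.energies, fixture.entropy
        series = thermo.canonical_series((E, S), np.linspace(0.05, 1.0, 120))
        report = thermo.find_transitions((E, S), series)
        assert len(report.first_order) == 1
        t_star, (e_a, e_b) = report.first_order[0]
        de = E[1] - E[0]
        assert t_star == pytest.approx(fixture.t_star, abs=0.01)
        assert e_a == pytest.approx(fixture.loop_bounds[0], abs=2 * de)
        assert e_b == pytest.approx(fixture.loop_bounds[1], abs=2 * de)
        _, T = thermo.microcanonical_temperature((E, S))
        _, C = thermo.microcanonical_specific_heat(E, T)
        inside = (E > e_a) & (E < e_b)
        assert np.nanmin(C[inside]) < 0.0

    def test_schottky_system_has_one_canonical_peak_and_no_loop(self):
        toy = make_k_level_system((1, 3), (0.0, 1.0))
        E = np.array(toy.level_energies)
        report = thermo.find_transitions(
            (E, toy.exact_ln_g),
            thermo.canonical_series((E, toy.exact_ln_g),
                                    np.linspace(0.05, 3.0, 300)))
        assert report.first_order == []
        assert len(report.canonical_peaks) == 1
        # Schottky peak of the (1,3) gap-1 system sits near T ~ 0.34
        t_peak, _ = report.canonical_peaks[0]
        grid = np.linspace(0.05, 3.0, 3000)
        t_exact = grid[np.argmax(schottky_heat_capacity(grid, 1, 3, 1.0))]
        assert t_peak == pytest.approx(t_exact, abs=0.02)
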