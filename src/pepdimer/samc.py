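"""Stochastic-approximation Monte Carlo (SAMC) estimation of the density of
states, and fixed-DOS production sampling.

SAMC performs a random walk that is accepted with probability
``min(1, g~(U_current) / g~(U_candidate))`` against the *running* estimate
``g~`` of the density of states.  After every step (accepted or not) the
log-estimate of the bin occupied by the current state is raised by the gain
``gamma_t``, which decreases as ``gamma_0 * t_0 / max(t, t_0)`` — a schedule
with divergent sum and convergent sum of squares, the standard sufficient
condition for convergence of the stochastic approximation.  The visited
histogram ``H(U)`` flattens as ``g~`` approaches the true density of states
and serves as the sampling-quality diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "EnergyGrid",
    "DOSEstimate",
    "gamma_schedule",
    "samc_accept",
    "update_dos",
    "run_estimation",
    "run_production",
    "write_checkpoint",
    "read_checkpoint",
]


@dataclass
class EnergyGrid:
    """Uniform energy binning, growable downwards/upwards.

    Bin ``b`` covers ``[e_min + b*width, e_min + (b+1)*width)``.  The window
    is extended automatically when energies outside it are encountered, so a
    burn-in discovering lower minima never aborts a run.
    """

    e_min: float
    width: float
    n_bins: int

    def index(self, energy: float) -> int:
        return int(math.floor((energy - self.e_min) / self.width))

    def centers(self) -> np.ndarray:
        return self.e_min + (np.arange(self.n_bins) + 0.5) * self.width


@dataclass
class DOSEstimate:
    """Running SAMC state: ln g~(U) per bin, visit histogram, schedule clock."""

    grid: EnergyGrid
    ln_g: np.ndarray
    histogram: np.ndarray
    t: int = 0
    gamma0: float = 1.0
    t0: int = 10_000
    seed: int | None = None
    # tail (Polyak-Ruppert) averaging of the running estimate: the centred
    # ln g~ is accumulated over the late phase of the run, which suppresses
    # the O(gamma * residence-time) fluctuation of the raw running estimate
    tail_sum: np.ndarray | None = None
    tail_count: np.ndarray | None = None
    # bins visited when averaging began; their mean fixes the additive gauge
    # of every sample, so bins discovered later still average consistently
    tail_ref: np.ndarray | None = None

    @classmethod
    def empty(cls, e_min: float, width: float, n_bins: int,
              gamma0: float = 1.0, t0: int = 10_000, seed=None) -> "DOSEstimate":
        grid = EnergyGrid(e_min, width, n_bins)
        return cls(grid=grid, ln_g=np.zeros(n_bins),
                   histogram=np.zeros(n_bins, dtype=np.int64),
                   gamma0=gamma0, t0=t0, seed=seed)

    @property
    def gamma(self) -> float:
        return gamma_schedule(self.t, self.gamma0, self.t0)

    @property
    def visited(self) -> np.ndarray:
        """Bins with at least one visit; only these carry information."""
        return self.histogram > 0

    def bin_for(self, energy: float) -> int:
        """Bin index for an energy, growing the grid when needed."""
        b = self.grid.index(energy)
        if b < 0:
            grow = -b
            self.grid.e_min -= grow * self.grid.width
            self.grid.n_bins += grow
            self.ln_g = np.concatenate([np.zeros(grow), self.ln_g])
            self.histogram = np.concatenate(
                [np.zeros(grow, dtype=np.int64), self.histogram])
            if self.tail_sum is not None:
                self.tail_sum = np.concatenate([np.zeros(grow), self.tail_sum])
                self.tail_count = np.concatenate(
                    [np.zeros(grow, dtype=np.int64), self.tail_count])
                self.tail_ref = np.concatenate(
                    [np.zeros(grow, dtype=bool), self.tail_ref])
            b = 0
        elif b >= self.grid.n_bins:
            grow = b - self.grid.n_bins + 1
            self.grid.n_bins += grow
            self.ln_g = np.concatenate([self.ln_g, np.zeros(grow)])
            self.histogram = np.concatenate(
                [self.histogram, np.zeros(grow, dtype=np.int64)])
            if self.tail_sum is not None:
                self.tail_sum = np.concatenate([self.tail_sum, np.zeros(grow)])
                self.tail_count = np.concatenate(
                    [self.tail_count, np.zeros(grow, dtype=np.int64)])
                self.tail_ref = np.concatenate(
                    [self.tail_ref, np.zeros(grow, dtype=bool)])
        return b

    def tail_record(self) -> None:
        """Accumulate one tail-averaging sample of the running estimate.

        Every sample is shifted into a common additive gauge — the mean of
        ln g~ over the *reference* bins (those visited when averaging began)
        — before accumulation.  Bins discovered later therefore average only
        their own post-discovery samples, but in the same gauge as everyone
        else, so the averaged entropy differences stay consistent.
        """
        m = self.visited
        if not m.any():
            return
        if self.tail_sum is None or self.tail_sum.size != self.grid.n_bins:
            self.tail_sum = np.zeros(self.grid.n_bins)
            self.tail_count = np.zeros(self.grid.n_bins, dtype=np.int64)
            self.tail_ref = m.copy()
        shift = self.ln_g[self.tail_ref].mean()
        self.tail_sum[m] += self.ln_g[m] - shift
        self.tail_count[m] += 1

    def tail_estimate(self) -> np.ndarray:
        """Tail-averaged ln g~; bins the tail never sampled fall back to
        the raw estimate re-expressed in the tail gauge."""
        if self.tail_sum is None or not np.any(self.tail_count > 0):
            return self.ln_g.copy()
        out = self.ln_g - self.ln_g[self.tail_ref].mean()
        m = self.tail_count > 0
        out[m] = self.tail_sum[m] / self.tail_count[m]
        return out


def gamma_schedule(t: int, gamma0: float, t0: int) -> float:
    """Gain sequence: flat at ``gamma0`` up to ``t0``, then ``gamma0*t0/t``."""
    if gamma0 <= 0:
        raise ValueError("gamma0 must be positive")
    if t0 < 1:
        raise ValueError("t0 must be >= 1")
    if t <= t0:
        return gamma0
    return gamma0 * t0 / t


def samc_accept(ln_g_current: float, ln_g_candidate: float,
                rng: np.random.Generator) -> bool:
    """Accept with probability ``min(1, g~(U_cur)/g~(U_cand))`` in log space."""
    d = ln_g_current - ln_g_candidate
    if d >= 0.0:
        return True
    return rng.random() < math.exp(d)


def update_dos(dos: DOSEstimate, current_bin: int) -> DOSEstimate:
    """One stochastic-approximation refinement at the bin of the current
    state (after accept/reject): raise ln g~ there by gamma_t, count the
    visit, advance the clock."""
    dos.t += 1
    dos.ln_g[current_bin] += gamma_schedule(dos.t, dos.gamma0, dos.t0)
    dos.histogram[current_bin] += 1
    return dos


def _run_replica(landscape, dos: DOSEstimate, n_steps: int,
                 rng: np.random.Generator, checkpoint_every=None,
                 checkpoint_path=None, tail_start_frac: float = 0.5,
                 tail_every: int = 25, energy_floor: float | None = None):
    state = landscape.initial_state(rng)
    energy = landscape.energy(state)
    b_cur = dos.bin_for(energy)
    tail_start = int(n_steps * tail_start_frac)
    for step in range(n_steps):
        cand, e_cand = landscape.propose(state, rng)
        if cand is not None and energy_floor is not None \
                and e_cand < energy_floor:
            cand = None  # outside the sampling window: reject
        if cand is not None:
            b_cand = dos.bin_for(e_cand)
            if dos.histogram[b_cand] == 0:
                # first visit: seed the new bin at the current bin's level.
                # Starting it at the global initial value instead would trap
                # the walker there for ~ln_g/gamma steps once the estimate
                # has grown, and pile spurious entropy onto every newly
                # discovered low-energy bin.
                dos.ln_g[b_cand] = dos.ln_g[b_cur]
            if samc_accept(dos.ln_g[b_cur], dos.ln_g[b_cand], rng):
                state, b_cur = cand, b_cand
        update_dos(dos, b_cur)
        if step >= tail_start and step % tail_every == 0:
            dos.tail_record()
        if checkpoint_every and dos.t % checkpoint_every == 0 and checkpoint_path:
            write_checkpoint(dos, checkpoint_path)
    # adopt the tail-averaged estimate as the replica's result; the raw
    # running estimate stays available for diagnostics
    dos.raw_ln_g = dos.ln_g.copy()
    dos.ln_g = dos.tail_estimate()
    return state


def run_estimation(landscape, *, bin_width: float, n_steps: int,
                   n_replicas: int = 8, seed: int = 0, gamma0: float = 1.0,
                   t0: int | None = None, e_min: float = 0.0, n_bins: int = 1,
                   energy_floor: float | None = None,
                   checkpoint_every: int | None = None,
                   checkpoint_dir=None) -> list:
    """Estimate ln g~(U) in ``n_replicas`` independent SAMC runs.

    Each replica draws its random stream deterministically from the master
    seed.  The energy window starts at ``[e_min, e_min + n_bins*width)`` and
    extends itself as new energies are discovered; ``energy_floor``
    optionally restricts sampling to energies at or above a floor
    (restricted-window flat-histogram sampling), which shortens the random
    walk's ladder when only the upper part of the spectrum is of interest.
    For models with a discrete energy lattice choose ``e_min`` so the levels
    fall at bin centres — levels sitting on bin edges are split between
    neighbouring bins by floating-point jitter.  Returns one
    :class:`DOSEstimate` per replica.
    """
    if t0 is None:
        t0 = max(n_steps // 10, 1)
    children = np.random.SeedSequence(seed).spawn(n_replicas)
    replicas = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        dos = DOSEstimate.empty(e_min, bin_width, n_bins,
                                gamma0=gamma0, t0=t0, seed=seed)
        path = None
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir) / f"dos_replica{r}.tsv"
        _run_replica(landscape, dos, n_steps, rng,
                     checkpoint_every=checkpoint_every, checkpoint_path=path,
                     energy_floor=energy_floor)
        if path is not None:
            write_checkpoint(dos, path)
        replicas.append(dos)
    return replicas


def run_production(landscape, dos: DOSEstimate, n_steps: int, *,
                   seed: int = 0, accumulator=None, sample_every: int = 1,
                   refine_gamma: float | None = None):
    """Production run at (almost) fixed DOS collecting per-bin statistics.

    With ``refine_gamma=None`` the estimate is frozen and the walk visits
    the known energy bins approximately uniformly — provided ``ln g~`` is
    accurate; residual estimation error makes the walk drift.  Setting
    ``refine_gamma`` to a small constant keeps the stochastic-approximation
    feedback alive on a private copy of the estimate, which holds the
    histogram flat regardless of residual error.  The per-bin observable
    means are unbiased either way: the acceptance depends on the state only
    through its energy bin, so the conditional (within-bin) sampling is
    untouched; only the bin-visiting frequencies M(E) change, and those
    serve purely as normalisation.  Reweighting always uses the estimation
    ``dos``, never the refined copy.

    Candidates falling into bins never visited during estimation are
    rejected, keeping the walk on the support where ``ln g~`` is known
    rather than fabricating entropy.

    Observables are recorded through ``accumulator`` (an
    :class:`~pepdimer.observables.ObservableAccumulator`) every
    ``sample_every`` steps; with no accumulator only the visit counts M(E)
    are returned (as a fresh accumulator with no registered observables).
    """
    from .observables import ObservableAccumulator

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if accumulator is None:
        accumulator = ObservableAccumulator(dos.grid.n_bins)
    known = dos.visited
    ln_g = dos.ln_g.copy()
    state = landscape.initial_state(rng)
    energy = landscape.energy(state)
    b_cur = dos.grid.index(energy)
    if not (0 <= b_cur < dos.grid.n_bins) or not known[b_cur]:
        raise ValueError("initial state lies outside the estimated DOS support")
    for step in range(n_steps):
        cand, e_cand = landscape.propose(state, rng)
        if cand is not None:
            b_cand = dos.grid.index(e_cand)
            if 0 <= b_cand < dos.grid.n_bins and known[b_cand] and \
                    samc_accept(ln_g[b_cur], ln_g[b_cand], rng):
                state, b_cur = cand, b_cand
        if refine_gamma:
            ln_g[b_cur] += refine_gamma
        if (step + 1) % sample_every == 0:
            accumulator.record(b_cur, state)
    return accumulator


# ---------------------------------------------------------------------------
# checkpoint I/O: plain-text three-column table, byte-stable round trip

def write_checkpoint(dos: DOSEstimate, path) -> None:
    lines = [
        "# pepdimer DOS checkpoint",
        f"# seed={dos.seed} t={dos.t} gamma0={_fmt(dos.gamma0)} t0={dos.t0}",
        f"# e_min={_fmt(dos.grid.e_min)} width={_fmt(dos.grid.width)} "
        f"n_bins={dos.grid.n_bins}",
        "# bin_center\tln_g\thistogram",
    ]
    centers = dos.grid.centers()
    for c, g, h in zip(centers, dos.ln_g, dos.histogram):
        lines.append(f"{_fmt(c)}\t{_fmt(g)}\t{int(h)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(x) -> str:
    return format(float(x), ".17g")


def read_checkpoint(path) -> DOSEstimate:
    text = Path(path).read_text().splitlines()
    meta = {}
    rows = []
    for line in text:
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        elif line.strip():
            rows.append(line.split("\t"))
    grid = EnergyGrid(float(meta["e_min"]), float(meta["width"]),
                      int(meta["n_bins"]))
    ln_g = np.array([float(r[1]) for r in rows])
    hist = np.array([int(r[2]) for r in rows], dtype=np.int64)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return DOSEstimate(grid=grid, ln_g=ln_g, histogram=hist,
                       t=int(meta["t"]), gamma0=float(meta["gamma0"]),
                       t0=int(meta["t0"]), seed=seed)
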