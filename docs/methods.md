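# Methods

## The model

Each amino acid is represented by four interaction sites: three backbone
beads — the amide nitrogen (NH), the alpha carbon (CA), and the carbonyl
carbon (CO) — plus one side-chain bead (SC) at the side chain's centre of
mass; glycine carries no SC bead.  All interactions are discontinuous:

* **Bonds and pseudo-bonds.**  Covalent bonds (NH–CA 1.46 Å, CA–CO 1.51 Å,
  CO–NH 1.33 Å across the peptide junction) and the angle/planarity-enforcing
  pseudo-bonds (NH_i–CO_{i+1} 4.25 Å, CA_i–NH_{i+1} 2.41 Å, CO_i–CA_{i+1}
  2.45 Å, CA_i–CA_{i+1} 2.80 Å) are infinite square wells: the pair distance
  must stay within `r_ideal (1 ± Δ)` with Δ = 0.02375.  A configuration
  violating any window is infeasible, and any move producing one is rejected.
* **Excluded volume.**  Every non-bonded pair carries a hard core at the
  arithmetic (Lorentz–Berthelot) mean of the two bead diameters.  For ten
  listed close-in-sequence pair kinds (e.g. CA_i–CO_{i+1}, NH_i–NH_{i+1},
  and the backbone–side-chain contacts of adjacent residues) the effective
  diameter is multiplied by a *squeeze factor* that restores the backbone
  flexibility lost to the coarse mapping.
* **Side-chain wells.**  SC–SC pairs interact through square wells of depth
  ε_ij (in units of the hydrogen-bond depth) and range d_ij^(SW).
* **Hydrogen bonds.**  An NH→CO pair within 4.5 Å forms a bond of depth
  −1.0 — the unit of the reduced energy scale — provided an auxiliary
  alignment criterion holds and the partners are free.  Temperatures are
  therefore measured in ε_HB/k_B.

**Hydrogen-bond state function.**  Flat-histogram sampling needs the energy
to be a pure function of the coordinates.  When several NH→CO pairs are
simultaneously within range, the bond count is defined as the size of the
*maximum* bipartite matching of eligible pairs under the one-bond-per-donor /
one-bond-per-acceptor rule (computed with an augmenting-path matcher; the
problem sizes are tiny).  A greedy or history-dependent assignment would make
the energy depend on the sampling path.

**Auxiliary hydrogen-bond criterion.**  The donor's and the acceptor's alpha
carbons must each stay at least `hbond_aux_min` (default 4.5 Å, i.e. outside
the bond range) from the opposite bond partner.  This enforces a roughly
collinear N–H···O=C arrangement using backbone bead positions only.  The
threshold sits in the parameter set, so a different published criterion can
be dropped in.  Intramolecular bonds additionally require a sequence
separation |i−j| ≥ 4 (configurable), which permits helix-like i→i+4 bonding
while excluding trivially adjacent pairs.

**Boundary conventions.**  Hard-core overlap at r ≤ d^(HS); the attractive
well is the open interval (d^(HS), d^(SW)); bond windows are closed.  These
choices matter only on sets of measure zero but are fixed for determinism.

**Periodic boundaries.**  Chains live in a cubic box under the minimum-image
convention.  Chain coordinates are kept unwrapped, so intra-chain geometry
is always continuous; periodicity enters through pair distances only.

## Parameter presets

The full published residue-specific tables (20×20 side-chain well depths,
diameters, squeeze values) are not reprinted anywhere we could bundle them
from, so the package ships two presets:

* `reference-simplified` — a two-class (hydrophobic/polar) set used by every
  test and analysis: uniform backbone bead diameter 2.0 Å, SC diameter
  3.0 Å, CA–SC bond 2.4 Å, one attractive well (H–H, depth −0.2, range
  5.5 Å), squeeze factors 1.  The small backbone cores keep the printed bond
  geometry satisfiable while still preventing chain crossing; the well depth
  keeps hydrogen bonding (depth −1) the dominant scale, as in the full model.
* `external-prime20` — a loader schema (not data) accepting the complete
  pair tables from a user-supplied file.

## Initial configurations

The bond network leaves roughly two angular degrees of freedom per residue,
so a feasible starting structure is built by exact geometric construction:
each residue's backbone beads are placed on the intersections of the
ideal-length spheres of their bonds and pseudo-bonds (sphere–sphere circles
and three-sphere trilateration), searching the leftover angular freedom
depth-first with steric checks against the same hard-core table the energy
model uses, and preferring extended placements.  Side chains are attached on
clash-free directions afterwards.  The construction is deterministic; for a
dimer the second chain is placed alongside the first at increasing offsets
until feasible.

## Sampling

Stochastic-approximation Monte Carlo estimates the configurational density
of states g(U).  A move from x to x′ is accepted with probability
min(1, g̃(U(x))/g̃(U(x′))) against the running estimate (log-space); after
every step the log-estimate of the bin occupied by the *current* state is
raised by the gain γ_t, and the visit histogram H(U) is incremented.  The
gain follows γ_t = γ₀ min(1, t₀/t), which satisfies Σγ = ∞, Σγ² < ∞.
Energies are binned uniformly and the window extends itself automatically
when lower energies are discovered.  Two details matter for a model whose
spectrum is a discrete lattice (here multiples of 0.2 ε_HB):

* the grid origin is offset by half a bin so that energy levels fall at bin
  *centres* — levels sitting on bin edges get split between neighbouring
  bins by the last-ulp jitter of floating-point energy sums, which
  manufactures near-empty bins and enormous spurious entropy barriers;
* a bin visited for the first time is seeded at the current bin's ln g̃
  value rather than the global initial value, otherwise the walker falls in
  and cannot climb out until the gain has refilled the gap.

An optional energy floor restricts sampling to the part of the spectrum
under study (restricted-window flat-histogram sampling); candidates below
the floor are rejected like any other infeasible move.  Bins never visited
carry no information and are excluded from all analysis rather than
interpolated.  The per-move energy evaluation (distance updates, bond
windows, hard cores, well occupancies) runs in a numba-compiled kernel;
the hydrogen-bond matching stays in Python on the handful of candidate
pairs.

A flat visited histogram is *not* evidence of convergence for an adaptive
sampler — the gain feedback flattens H(U) regardless of the estimate's
quality.  The convergence currency is the number of round trips of the
walker across the sampled energy range, which is why the dimerization
study spends most of its budget on estimation steps.

Moves: single-bead displacements (uniform in a ball of radius 0.2 Å),
pivot rotations of a randomly chosen ϕ or ψ dihedral by an angle uniform
in [−π/3, π/3] (rotating everything topologically downstream rigidly), and
rigid-body translations (≤ 2 Å) or rotations (≤ π/6) of a whole chain.
All proposals are symmetric.  The default mix is 80/10/10
(displacement/pivot/rigid); because the bond windows are narrow (±2.4%),
displacement proposals of interior backbone beads are mostly rejected and
chiefly relax the side-chain beads, so pivots carry the conformational
diffusion — the dimerization study therefore uses a pivot-heavy 40/40/20
mix.

**Tail averaging.**  The raw running estimate fluctuates at scale
O(√γ_t); the adopted per-replica estimate is therefore the average of the
centred ln g̃ over the second half of the run (a Polyak–Ruppert average,
sampled every 25 steps).  The accumulator restarts whenever the visited set
changes, because samples taken over different supports live in different
additive gauges.  On the exactly enumerable fixtures this reduces the error
at fixed step count by roughly an order of magnitude.

**Replicas.**  Independent replicas (deterministic child streams of one
master seed) are aligned by their free additive constant (least-squares over
shared bins) and averaged; bins below the visitation quorum are dropped.

**Production.**  Production runs collect per-energy-bin visit counts M(E)
and observable sums; candidates falling outside the estimated support are
rejected rather than trusted with fabricated entropy.  By default ln g̃ is
frozen; optionally the stochastic-approximation feedback stays alive with a
small constant gain on a private copy of the estimate, which keeps the walk
covering the whole support even when the estimate carries residual error.
This does not bias the observables: the acceptance depends on a state only
through its energy bin, so the conditional within-bin sampling — all that
enters the microcanonical means f̄(E) — is untouched, and M(E) serves only
as per-bin normalisation.  Reweighting always uses the estimation DOS.

## Thermodynamic analysis

The configurational entropy is convoluted with the ideal-gas kinetic density
of states to obtain the total-energy entropy,
`ln g(E) = logsumexp_U [ln g̃(U) + (n_dof/2) ln(E−U)]`, with n_dof = 3 ×
(number of beads) — every bead is treated as a point particle with three
momenta.  The kinetic exponent uses the phase-space-volume convention
K^(n/2) rather than the density convention K^(n/2−1): under it the
microcanonical temperature of the free system obeys equipartition
T = 2K/n_dof exactly instead of up to O(1/n), which makes the
implementation testable against closed forms; the two conventions differ
by less than 1% for the bead counts of interest.

Microcanonical route: T(E) = (∂S/∂E)^(−1) and C(E) = (∂T/∂E)^(−1) by
centred finite differences (an optional Savitzky–Golay smoothing of S(E) is
available but off by default).  A convex intruder of S(E) produces a
back-bending T(E) loop with C(E) < 0 inside and divergences at the loop
edges — the small-system signature of a first-order transition.  Its
transition temperature is the reciprocal slope of the double tangent,
realized deterministically as the upper concave hull of S(E); hull segments
bridging interior points are the loops, and the contact points are the loop
bounds.  Isolated finite maxima of C(E) outside loops are reported as
second-order transition temperatures.

Canonical route: Z(T) = Σ_E g(E) e^(−E/T) by log-sum-exp;
C(T) = (⟨E²⟩−⟨E⟩²)/T² (cross-checked against ∂⟨E⟩/∂T in the tests).  Peaks
of C(T) above a prominence threshold (default 2% of the global maximum) are
reported; weaker shoulders are not counted as peaks.  All canonical
quantities are invariant under the additive constant of ln g.

Observables recorded during production (gyration tensor descriptors,
hydrogen-bond counts, residue-pair bond indicators) are microcanonically
averaged per bin, f̄(E) = Σf/M(E), and reweighted to temperature with the
canonical weights.  Configurational observables are reweighted directly with
the configurational g̃(U) — the kinetic factor of the partition function
cancels from those averages identically, so this equals the total-energy
reweighting without the convolution grid.  If canonically dominant bins were
never visited in production, the reweighting warns (>2% of the weight) or
refuses (>50%) rather than silently extrapolating.

The gyration tensor is mass-uniform (the model has no masses); κ² =
(λ₁−λ₃)/Σλ is 0 for a sphere, 1 for a rod, ≈0.5 for a random coil.  Dimer
descriptors shift the second chain to the minimum image of its centroid
relative to the first before forming the tensor.

## Temperature gauge

Reduced temperatures (ε_HB/k_B) are anchored to Kelvin by matching simulated
R_g(T) curves to experimental values: each reference pair (reduced T,
physical T) yields a factor, the reduced anchors are averaged and rounded to
three decimals before division (reproducing the printed arithmetic: anchors
0.1853 and 0.172 at 300 K give factors 1619 and 1744, mean 0.179 → 1676),
and ε_HB follows as factor × k_B ≈ 3.3 kcal/mol.  Two uncertainty
conventions are carried: half the factor spread (63 K here) and the maximum
deviation from the mean factor (68 K ≈ the quoted ±70); Kelvin error bars
propagate the conservative one.  The experimental R_g values themselves are
user input — a nearest-crossing helper locates the reduced anchor on a
simulated curve — since they are not bundled with the package.

## The synthetic fixtures and what passing them shows

* The k-level discrete system and the square-well point dimer have exactly
  known densities of states (degeneracy lists; shell vs. free volume) and
  validate the sampler end to end.  The square-well dimer's default box
  (10 Å for a 2–4 Å well) keeps the bound shell ~25% of the box so the
  sampler's error is gain-limited, not mixing-limited.
* The constructed entropy curves (two congruent concave parabolas with a
  common tangent of known slope) validate the double-tangent machinery
  analytically.
* The 8-residue *polar* homopolymer dimer is the desk-scale stand-in for
  the real peptide systems.  Polar–polar side-chain wells vanish in the
  simplified preset, so the only attraction is the backbone hydrogen bond —
  the interaction that drives aggregation and ordering in the full model —
  and the potential energy is exactly minus the bond count.  (A hydrophobic
  homopolymer under the same preset is instead dominated by its many weak
  side-chain contacts: hydrogen-bonded configurations are an entropically
  negligible fraction of each energy bin at this scale, which buries the
  signal under study.)  The study exercises the whole pipeline and shows
  the qualitative physics — a single aggregation transition at which
  intermolecular hydrogen bonding and dimer collapse switch on together —
  but none of its numbers (transition temperature, bond counts) are
  comparable to the full-length systems, which require the complete
  residue-specific parameter tables and orders of magnitude more sampling.
  Desk-scale study conditions (`pepdimer.dimer_study`), fixed once: a 40 Å
  box (dilute enough that association costs real translational entropy,
  small enough that re-association is not hopelessly diffusion-limited,
  and safe under minimum image for the ~28 Å maximal chain extent); unit
  energy bins with half-bin origin over the window [−11, 0] ε_HB; move mix
  40/40/20; γ₀ = 0.01 with a 1/t tail from one tenth of the run — the
  adaptive estimate's bias at the association step scales as (gain) ×
  (waiting time of the rarest transition, the first binding event), and
  this schedule keeps that product well below the true per-bond entropy
  cost; 2 replicas × 5×10⁶ estimation steps; 10⁶
  production steps with refine gain 0.05, sampled every 10 steps.

**What the toy does and does not show.**  In the desk-scale dimer the
single dominant specific-heat peak is accompanied by chain collapse
(per-chain R_g and shape anisotropy midpoints within half a grid step of
the peak) and by the bulk of intermolecular bond formation (about
two-thirds of the low-temperature bond count is present at the peak).
*Complete* association — the dimer-level R_g — is a separate, broader
crossover at higher temperature: an 8-mer forms its inter-chain bonds one
at a time, so transient few-bond dimers persist above the main transition.
The full-scale simultaneity of aggregation and ordering rests on
cooperative sheet formation at contact, which needs the complete
residue-specific parameter tables and longer chains.

## Known limitations

* The simplified preset is a two-class caricature; real side-chain
  specificity requires the external table loader.
* Replica counts and step counts in the bundled analyses are desk-scale;
  publication-scale statistics (eight replicas, much longer runs, the
  300 Å box at ~100 µM) use the same code paths but more compute.
* Derivative quantities (T(E), C(E)) amplify residual DOS noise; the raw
  finite differences are reported and smoothing is opt-in.
* In the desk-scale dimer the ordering peak and the association shoulder of
  C(T) carry comparable weight; residual estimation error can make either
  one the global maximum in an independent run, so single-run peak
  positions at this scale carry an uncertainty of roughly the distance
  between the two features.
* The exact published hydrogen-bond angular criterion is not reproduced;
  the configurable flanking-distance criterion stands in for it.
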