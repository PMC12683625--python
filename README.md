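# pepdimer

Coarse-grained simulation and thermodynamic analysis of peptide
dimerization.  The package implements an intermediate-resolution protein
model — four square-well interaction sites per residue (backbone NH, CA, CO
plus one side-chain bead) with hard-sphere excluded volume, squeeze-corrected
close contacts, and directional backbone hydrogen bonds of unit depth — and
estimates its configurational density of states g(U) with stochastic-
approximation Monte Carlo (SAMC), a flat-histogram method.  From ln g(U) it
derives the full thermodynamics of chain collapse and dimer formation in
both ensembles, and converts reduced units to physical ones via an
experimental temperature gauge.

It is aimed at people studying the statistical mechanics of protein
aggregation with discontinuous coarse-grained models: the motivating system
is the parathyroid hormone (PTH), whose N-terminal segment drives reversible
dimer and fibril formation just above physiological temperature.

## What it computes

* **Density of states.**  SAMC with moves (bead displacement ≤ 0.2 Å, ϕ/ψ
  pivot rotations ≤ π/3, rigid-body chain moves), acceptance
  min(1, g̃(U)/g̃(U′)), gain schedule γ_t = γ₀ min(1, t₀/t), replica
  averaging, and Polyak–Ruppert tail averaging of the running estimate.
* **Microcanonical analysis.**  Kinetic convolution to S(E) = ln g(E),
  T(E) = (∂S/∂E)⁻¹, C(E) = (∂T/∂E)⁻¹; first-order transitions from the
  double tangent bridging a convex intruder of S(E) (T* = 1/slope),
  second-order ones from isolated finite C(E) maxima.
* **Canonical analysis.**  Z(T) = Σ g(E)e^(−E/T) by log-sum-exp,
  C(T) = (⟨E²⟩−⟨E⟩²)/T², peak detection.
* **Structural observables.**  Gyration tensor, R_g, shape anisotropy
  κ² = (λ₁−λ₃)/Σλ; intra/intermolecular hydrogen-bond counts and
  residue-pair bond-probability matrices, microcanonically binned and
  canonically reweighted: f(T) = Σ f̄(E) g(E) e^(−E/T) / Z(T).
* **Temperature gauge.**  Reference pairs (reduced T, Kelvin) → conversion
  factor, hydrogen-bond energy in kcal/mol, transition temperatures in
  K/°C, and box concentrations.

## Worked example

The temperature gauge, from the two experimental anchor points of the
84-residue chain (monomer and dimer R_g matched to experiment at 300 K):

```sh
$ pepdimer gauge --references "0.1853:300,0.172:300" --temps "0.157,0.167,0.187"
reference 0.172: factor 1744 K/reduced
reference 0.1853: factor 1619 K/reduced
mean factor: 1676 K/reduced (+- 68)
eps_HB: 3.3 kcal/mol
T=0.157 -> 263 +- 11 K (-10 C)
T=0.167 -> 280 +- 11 K (7 C)
T=0.187 -> 313 +- 13 K (40 C)
```

Reading: the two anchors individually give 1619 and 1744 K per reduced
unit; averaging the reduced anchors gives the working factor 1676, which
puts the model's hydrogen-bond depth at 3.3 kcal/mol.  The low-temperature
transitions of the 42- and 84-residue chains land at 263 K and 280 K, and
the common aggregation transition at 313 K ≈ 40 °C — just above
physiological temperature.

A minimal end-to-end simulation (toy scale, a couple of minutes):

```sh
pepdimer estimate-dos --sequence SSSSSSSS --chains 2 --box-edge 40 \
    --steps 1200000 --replicas 2 --seed 7 --out runs/dimer
pepdimer produce --sequence SSSSSSSS --chains 2 --box-edge 40 \
    --dos runs/dimer/dos_average.tsv --steps 400000 --seed 8 \
    --out runs/dimer/production.tsv
pepdimer analyze thermo --dos runs/dimer/dos_average.tsv --n-dof 192 \
    --out runs/dimer/thermo
```

The numbered scripts under `analysis/` run the package's own studies:
`01_temperature_gauge.py` (unit conversions), `02_sampler_validation.py`
(SAMC vs exactly enumerable systems), `03_toy_thermodynamics.py`
(closed-form thermodynamics checks), and `04_dimerization.py` (the
scaled-down 8-residue homopolymer dimer study).  Each writes its tables
under `results/`.  The dimer study (about 13 minutes on one CPU) prints:

```
canonical C(T): dominant peak at T = 0.145 (height 36.6)
intermolecular H-bonds: 0.77 (high T) -> 7.00 (low T); 71% formed at the peak
chain R_g^2 collapse: 22.0 -> 18.6 A^2, midpoint at T = 0.152 (+0.007 vs the
peak: collapse and bond formation accompany the transition)
complete association (dimer R_g^2 98 -> 33 A^2) is a broader crossover
centred at T = 0.289: at this toy scale bonds form one at a time, so
transient few-bond dimers persist above the main transition
```

i.e. the chains compact and hydrogen-bond to each other at a single
dominant specific-heat peak — the scaled-down analogue of aggregation,
collapse and secondary-structure formation occurring together.

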