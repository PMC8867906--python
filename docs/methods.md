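# Methods

`brushpack` models quasi-2D suspensions of spherical polyelectrolyte
brushes (SPBs) — colloidal cores densely grafted with long, fully charged
dsDNA fragments — across packing fractions, with three coupled pieces: a
Wigner–Seitz cell free energy for a single brush, a 2D Monte Carlo model of
the brush–brush effective interaction, and the structural/dynamical
estimators used to characterize both simulated and tracked configurations.

## Cell model

A brush of core radius `R_PS` carries `f` chains of `N` charged monomers
(charge spacing `b`; for dsDNA `b = 0.17 nm`, two charges per 0.34 nm
base-pair rise, so `N = L_C/b` with `L_C` the contour length).  The brush
plus its `N·f` monovalent counterions occupy a spherical Wigner–Seitz cell
of radius `R_W`, mapped to the packing fraction by `η = R_0³/R_W³` with
`R_0 = R_PS + L_C` the dilute radius.  Counterions partition into
Manning-condensed (`N1`), free-inside (`N2`) and escaped (`N3`)
populations; `N1 = N·f·(1 − 1/ξ)` for Manning parameter `ξ = λ_B/b > 1`,
and `N2` follows from charge neutrality.

The free energy per cell, in units of k_B T, is minimized over the brush
thickness `L` and the escaped count `N3`:

```
F = U_H + F_el + F_Fl − T·S2 − T·S3 + F_p
```

with

* `U_H` — Hartree energy of the net charge profile.  Chains and in-brush
  counterions share the stretched-chain `r⁻²` density, so the net density
  is `−N3` distributed as `r⁻²` inside the brush and `+N3` uniform in the
  outer shell; `U_H = λ_B ∫ q(r)ρ(r) 4πr dr` with `q` the cumulative
  charge.  Both pieces have closed forms; the outer-shell integral is
  factored into a cancellation-free polynomial because the naive
  difference of fifth powers loses all precision as `R → R_W` (this
  failure mode drove the minimizer to a spurious boundary optimum before
  the refactoring).  An adaptive-quadrature evaluation of the same
  integral is kept as an independent cross-check.
* `F_el = (3/2) f L²/(N b²)` — Gaussian stretching of `f` chains of `N`
  bonds of length `b`.
* `F_Fl = (1/2) v_m (N f)²/V_brush` — Flory excluded volume with
  `v_m = (4/3)π R_m³` (one monomer volume) and a uniform monomer density
  over the brush shell.
* `−T·S_i = ∫ n_i [ln(n_i d³/α) − 1] dV` — ideal-gas entropy of the two
  free populations, `d` the counterion diameter; inside the brush the
  accessible volume fraction `α = 1 − N f v_m / V_brush` accounts for the
  chains (states with `α ≤ 0` are rejected as unphysical).
* `F_p = N2 (R/R_W)³` — osmotic insertion cost: the counterions absorbed
  in the surrounding brushes exert a pressure `∝ N2/R_W³` on a brush of
  volume `∝ R³`.  Valid only for `N2 ≫ N3`; a warning flags violations.

The source equations are only printed as display objects in the original
report, so the algebraic normalizations above are the standard forms of
each physical term, pinned down by the qualitative contracts (monotonicity,
scaling exponents, limiting values) the terms must satisfy.  With these
choices the model reproduces the two headline numbers computed in
`scripts/acceptance.py` without any fitted constant: a release fraction
`N3/(Nf) ≈ 2×10⁻⁵` for the experimental geometry (f = 10⁵, N = 2×10⁴,
R_PS = 0.49 μm, water at 298 K, dilute cell) and a dilute equilibrium
diameter ≈ 41% below the measured 2(0.49 + 3.4) μm — the expected accuracy
class of a scaling theory.

**Defaults.** `T = 298 K`, `ε_r = 78.5`, counterion diameter
`d = 0.7 nm`, monomer radius `R_m = 1 nm`; all configurable.  Lengths are
nm, energies k_B T.

**Minimization.** Coarse scan on a 40-point linear grid in
`L ∈ [0.05 L_C, min(L_C, R_W − R_PS)]` × 40-point logarithmic grid in `N3`
(zero included), then Nelder–Mead refinement in `(L, ln N3)`; the
landscape is smooth but spans many decades in `N3`.  The lower bound on
`L` keeps the Flory and entropy terms finite; the minimum is always
interior in practice.  Grid points violating a physical bound (monomer
overfill, cell overflow) evaluate to +∞ rather than aborting the scan.

**Known behavior and limitations.**

* The release fraction is non-monotone in `R_W` at the miniature-brush
  scale (N = 40, R_PS = 10 nm, grafting density matched to the
  experiment): below `R_W ≈ 80 R_m` the thin outer shell makes escape
  electrostatically cheap and the insertion term adds escape pressure, so
  release *falls* as the cell grows; beyond `R_W ≈ 100 R_m` the escaped-
  ion entropy (growing like `3 ln R_W` per ion) dominates the saturating
  separation cost and release *rises*.  The monotone-increase trend suite
  therefore runs on the dilute branch, `R_W/R_m ∈ {150…2400}`, which is
  the regime the single-brush validation data probe.
* The f-sweep runs over `f ∈ [10, 83]` at the miniature geometry: for
  larger `f` the total monomer volume at `R_m = 1 nm` exceeds the fully
  stretched shell volume and the model correctly refuses the geometry.
* The relative size reduction σ(η)/σ(0) predicted for the experimental
  geometry is mild (≈4% by η = 1.17).  The measured reduction is far
  stronger (to 0.70 σ0 at η = 0.73) and non-monotone.  This is the main
  quantitative deviation of the theory component and the reason the
  Monte Carlo scan defaults to the measured σ(η) table (below).

## Monte Carlo model

Disks in a periodic `20σ0 × 20σ0` box (minimum-image convention) interact
through a steep 100–200 Lennard-Jones core-plus-well — the blunt-end
stacking attraction between contacting brushes — plus a repulsive Yukawa
tail for the residual electrostatics of the almost fully neutralized
brushes:

```
U(r)/kT = 4 V1 [(σ/r)^200 − (σ/r)^100] + V2 (σ0/r) exp(−r/λ),  r < r_c
```

truncated (not shifted) at `r_c = 3.5σ`, with `V1 = 1.43`, `V2 = 0.28`,
`λ = 1.5 σ0`.  The written form has its zero crossing at `r = σ` and well
depth `V1` at `r = σ·2^(1/100)`; the alternative normalization
`V1[(σ/r)^200 − 2(σ/r)^100]` (minimum exactly at σ) is selectable via
`lj_convention="well"`.  The η-dependent steric diameter σ defaults to the
measured first-peak positions (`experimental_sigma_table()`) — the
experimentally observed shrinking is fed into the simulation as an input;
the cell-model curve can be substituted but, with its mild shrink, leaves
the η = 1.17 state point at an effective disk area fraction above close
packing.

Sampling is single-particle Metropolis: one sweep = N trial displacements,
each accepted with probability `min(1, e^(−ΔE))`.  ΔE is computed
incrementally over an O(N) neighbor pass; the accumulated incremental
energy agrees with a fresh O(N²) recomputation to ~10⁻¹² relative over
hundreds of sweeps.  The trial amplitude is auto-tuned to 30–50%
acceptance during the first half of equilibration, then frozen.
Initialization is random sequential insertion with rejection below 0.95σ,
falling back to a randomly diluted triangular lattice when the rejection-
radius packing exceeds 0.45.  Coincident particles evaluate to a large
finite sentinel energy, forcing rejection.  Runs are bit-reproducible from
the seed (a single PCG64 stream supplies all trial moves).

The six canonical state points use the particle counts
N = {196, 289, 342, 380, 441, 600} at η = {0.40, 0.57, 0.68, 0.73, 0.87,
1.17}.  Full production uses 10⁵–2×10⁶ sweeps per point; the test suite's
re-entrance check runs a 10⁴–3×10⁴-sweep version (about 7 minutes total on
one CPU), which is sufficient for the *shape* observables it asserts
(non-monotone g_p and ⟨Ψ6⟩ with a dip at 0.7 < η < 0.9, low-coordination
chainlike clusters at η = 0.40) but underestimates coarsening-limited
quantities such as peak heights at the densest points.

## Structure analysis

* `g(r) = N(r)/(2π n r Δr)` per central particle, averaged over
  configurations; default bin width `dr = 0.02 σ0`.  Periodic inputs count
  all minimum-image pairs; non-periodic (microscopy-style) inputs use
  guard-region exclusion — only particles at least `r_max` from every edge
  serve as centers — which is unbiased without pair-count corrections.
* First peak: first local maximum above 1, refined parabolically over the
  three surrounding bins.  A fluid with no peak above 1 (e.g. the
  salt-screened system) returns an explicit absent-peak result.
* Neighbor cutoff: `σ + (r_min − r_p)/2`.  The first-shell minimum is the
  argmin of the 3-bin-smoothed g(r) within one diameter beyond the peak.
  A windowed argmin is used instead of pointwise extremum detection
  because in weakly structured fluids the minimum is shallow and
  pointwise rules latch onto single-bin noise, collapsing the cutoff onto
  the peak; the window makes the estimator stable across fluids, chains
  and crystals with one rule.
* `Ψ6^i = (1/N_b) Σ_j e^(i·6θ_ij)`; reported `⟨Ψ6⟩` is the average of the
  per-particle magnitudes (matching per-particle map coloring); the
  modulus of the complex mean is available as an option.  Particles
  without neighbors score 0.  Note that particles with a single neighbor
  score exactly 1, so sparse chainlike states carry elevated ⟨Ψ6⟩; dips
  in ⟨Ψ6⟩ across a density scan are therefore interpreted jointly with
  g_p and ⟨N_b⟩.

## Dynamics analysis

Stage drift is removed by subtracting the cumulative frame-to-frame
ensemble-mean displacement of co-tracked particles (median available);
subtracting an N_p-particle mean biases the corrected MSD down by ~1/N_p,
negligible for typical fields of view and bounded in the tests.  The MSD
is time- and ensemble-averaged over all (t₀, particle) pairs at integer
frame lags up to a quarter of the track length (variance control), and
`D_eff = MSD(Δt)/4Δt` is read at the sampled lag closest to the 55 s
reference (the division uses the actual lag, so a pure Brownian curve
returns its true D).

## Synthetic data

Generators provide the oracles the analyses are tested against: triangular
lattices (Ψ6 = 1, g(r) shells at 1:√3:2), Poisson gases (g ≡ 1, low Ψ6),
chainlike aggregates (self-avoiding strings with ±30° bond-angle wander,
geometric length distribution of mean 5 plus 20% singles by default,
interior coordination 2), and 2D Brownian tracks with per-axis step
variance `2D·Δt` and optional uniform drift.  All are deterministic in
their seed.  They emulate ideal reference structures, not microscopy data:
no localization noise, no polydispersity, no tracking gaps — so passing
tests validate the estimators, not robustness to imaging artifacts.

## What the tests do and do not show

The unit and acceptance suites verify: internal consistency of every
free-energy term against independent quadrature/closed-form oracles;
exact Metropolis bookkeeping and determinism; estimator correctness on
analytically known structures; the trapping order of magnitude, the ~40%
dilute-size deficit, the monotone f/R_W/σ(η) trends on their stated
ranges; and the re-entrant dip as a shape property of a reduced-length
scan.  They do not validate the model against the microscopy observables
(r_p(η), experimental ⟨Ψ6⟩, D_eff values), which require the original
image data.
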