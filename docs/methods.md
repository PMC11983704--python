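# Methods

This note documents the models implemented in `vibronic2pa`, their
assumptions, the numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Scope and assumptions

* **Mechanical harmonic approximation, 0 K.** Both electronic surfaces are
  quadratic in mass-weighted Cartesian displacements; only the vibrational
  ground state of the initial surface is populated. Finite temperature,
  anharmonicity and solvent effects are out of scope.
* **Time-independent evaluation.** The spectrum is a sum over final
  vibrational states. At 0 K a converged state sum is mathematically
  identical to the time-dependent generating-function route used by
  large-molecule codes; the TI route was chosen because it is tractable at
  the mode counts this package targets (≲ 15) and exposes line-level
  structure that can be tested against independent oracles.
* **Herzberg–Teller truncation at the linear term.** Diagonal second
  derivatives d²S/dQ² are supported by the differentiation and benchmark
  machinery (electrical anharmonicity is a small correction for rigid
  chromophores), but spectra use S₀ and dS/dQ only. Mixed second
  derivatives ∂²S/∂Q_v∂Q_w (v ≠ w) are not computed.
* **Two identical linearly polarized photons** (F = G = H = 2) by default;
  arbitrary (F, G, H) weights are accepted. Circular polarization ratios
  and two-color experiments are not modeled. Non-Hermitian electronic
  theories are supported by carrying distinct left/right tensors through
  the rotational average.

## Units and conventions

Internal energies are hartree, coordinates Bohr, masses converted from amu
to electron masses, so mass-weighted normal coordinates and frequencies are
pure atomic units (ħ = 1); eV, nm and cm⁻¹ appear only at I/O boundaries.
The cross-section prefactor follows the widely used atomic-unit convention
σ = N·α·a₀⁵·ω²·g(2ω)·δ/c with N = 4π² by default; N is configurable and
recorded in output metadata because conventions differ across codes, and
every shape-level result in this package is prefactor-independent.

The Duschinsky relation is **Q′ = J·Q + K** (final-state coordinates in
terms of initial-state ones), with Q′ = 0 at the excited-state minimum
implied by the model. Consequently for VG the shift is K = +Ω⁻²g, where g
is the excited-state gradient projected on the ground modes: the minimum of
E + g·Q + ½Q^TΩ²Q lies at −Ω⁻²g and K must cancel it. This sign choice
makes AH, VH and VG constructions agree exactly for exactly harmonic
surfaces, which is the package's central consistency property.

**Eckart frame.** All three vibronic models express both surfaces in the
vibrational subspace of the ground-state geometry's Eckart frame — also the
adiabatic model, where `build_AH` by default diagonalizes the excited
Hessian with the ground geometry's translation/rotation projectors. With
per-geometry frames, J = L_eᵀL_g is not orthogonal (the rotational
generators at the two geometries differ at first order in the displacement)
and the AH ≡ VH identity for harmonic surfaces fails at O(|K|²/I). A caller
who wants the conventional per-geometry frame can pass a precomputed
`es_basis`.

**Mode sign gauge.** Each normal mode's sign is fixed so that its
largest-magnitude Cartesian component is positive. Quantum-chemistry codes
return arbitrary phases; a deterministic gauge is required before derivative
sets from different codes can be compared (cross-code matching additionally
goes through `align_mode_phases`, which pairs modes by maximal absolute
overlap and flips candidate signs where the matched overlap is negative,
refusing matches below 0.5).

## Franck–Condon / Herzberg–Teller engine

Overlaps ⟨m|n′⟩ under Q′ = J·Q + K are evaluated by a two-sided recursion
in normalized form, seeded from the closed-form ⟨0|0′⟩ (a Gaussian
integral, evaluated in log space). The recursion is the
Sharp–Rosenstock/Doktorov family expressed through three precomputed
matrices (P⁻¹Λ′JΩ⁻¹, I − 2P⁻¹ and the shift vector P⁻¹Λ′K with
P = I + Λ′JΩ⁻¹JᵀΛ′). The HT matrix element uses the initial-state ladder
identity Q_v|0⟩ = (2ω_v)^(−1/2)|1_v⟩, so it is a plain overlap with one
initial quantum — no separate recursion.

Two equivalent evaluation paths exist and are tested against each other to
round-off:

* a **memoized per-state recursion** used for class-restricted enumerations
  (at most `max_excited_modes` simultaneously excited modes, default 4,
  per-mode cap default 10);
* a **dense vectorized grid** used automatically when the class limit does
  not bind (full product enumeration), filling the whole quanta grid axis
  by axis with numpy slice arithmetic.

A third, fully independent **quadrature oracle** (`quadrature_oracle`,
≤ 2 modes) integrates explicit harmonic wavefunction products on dense
trapezoid grids (401 points/dimension, ±7.5 σ around both minima, with a
grid-norm convergence check) and shares only the downstream averaging code.

Line energies are E₀₀ + Σ n_j ω′_j with E₀₀ = adiabatic gap + ΔZPE. For
vertical models the adiabatic gap is estimated as vertical gap minus the
model's reorganization energy ½KᵀΩ′²K. Lines weaker than 10⁻¹² of the
analytic closure total are dropped; the captured fraction (completeness) is
always reported so users can tighten the caps.

Sum rules asserted by the test suite: Σ lines = δ^FC + δ^HT for the
combined spectrum (cross terms cancel by ⟨0|Q_v|0⟩ = 0, although individual
lines interfere); total(FC+HT) = total(FC) + total(pure HT); rotational
invariance of every line under a common rotation of all tensors; exact
AH = VH = VG agreement for frequency-preserving harmonic pairs.

## Romberg differentiation

Properties are evaluated on the geometric mesh ±2ᵏΔ, k = 0…4 (10 displaced
points). Central differences D[k][0] are refined by
D[k][l+1] = (4^(l+1)·D[k][l] − D[k+1][l])/(4^(l+1) − 1), cancelling
successive even powers of the step. The stable value is the entry
minimizing |D[k][l] − D[k+1][l]| over the triangle; that minimal difference
is the error estimate. This operationalizes the "region of stability"
reading of Romberg tables — whether published analyses selected entries
manually or automatically is typically unstated, so the automatic rule is a
documented choice here. A component whose relative error estimate exceeds
4 % (configurable) is flagged and can be excluded from benchmark
statistics; an exactly constant mesh is treated as a clean zero rather than
round-off. The default step along normal modes is 0.01 in dimensionless
units, converted per mode as Δ_v = 0.01/√ω_v, which keeps every mode well
inside its harmonic region regardless of frequency; only the Cartesian
convention (Δ = 0.005 Bohr) has an established literature value, so the
normal-mode step is configurable rather than inferred.

## Benchmark statistics

For candidate x vs reference r over shared (mode, component) keys, with
e = x − r: MAPE = 100·mean(|e|/|r|), MAE = mean|e|, RMSE = √mean(e²),
MAX AE = max|e|, and SDE = the sample (n−1) standard deviation of the
signed errors — "SDE" is rarely given a formula in the literature; the
sample-deviation choice is pinned by the tested identity
RMSE² = SDE²(n−1)/n + mean(e)². Reference values that are exactly zero are
excluded from the MAPE only (an epsilon floor would make the ranking
threshold-dependent). Reports are ordered by increasing MAPE; per-component
summaries give average/median/max of |value| with the arg-max mode index.
The median of an even count is the mean of the two central values.

## Synthetic data: what it emulates, and what a green test establishes

`generate_model_system` builds, from a single seed: a random non-linear
geometry of H/C/N/O-mass atoms; ascending, deliberately well-separated
frequencies in the 200–3500 cm⁻¹ mid-IR window; a random orthonormal mode
basis in the Eckart-projected subspace; and an excited surface defined *by
construction* through (J, K, Ω′) — small-angle Duschinsky mixing (scale
0.15 rad), Gaussian dimensionless shifts (scale 0.4, i.e. Huang–Rhys
factors up to ≈ 0.3, typical of rigid fluorophores), and ≈ 5 % frequency
changes. The Cartesian excited Hessian, gradient at the ground geometry,
excited minimum and both gaps are then *derived* from that surface, so the
AH/VH/VG inputs are exactly consistent and the model-equivalence tests are
exact rather than approximate.

The transition-tensor field is the polynomial
S(Q) = S₀ + Σ B_v Q_v + ½ Σ C_v Q_v², with S₀,xx ≈ 50 a.u. dominating the
other components by an order of magnitude and |B_xx| drawn log-normal
(median 0.02 a.u., σ = 1.8, hence median/mean ≈ 0.2): most modes couple
weakly and a few dominate, the signature of benchmarked push-pull
chromophore data, and the resulting HT share of the total intensity sits at
the few-percent-to-∼20 % scale depending on the tail draw. Because S(Q) is
polynomial, Romberg differentiation must recover B and C exactly — the
full-loop recovery test (generate → displace → evaluate → differentiate →
compare) is an identity check of the whole chain, not a tolerance fit.

What the generator does **not** emulate: real electronic structure (no
functional- or basis-dependence), inter-mode correlations of derivative
magnitudes, anharmonic surfaces, and any specific molecule's values. A
green test suite therefore establishes the correctness of the vibronic,
differentiation and statistical machinery on exactly harmonic ground truth
— not the accuracy of any electronic-structure prediction.

`perturb_derivatives` fabricates "method-like" candidate sets by uniform
scaling, relative Gaussian noise and random sign flips (recorded), matching
the observed pathologies of approximate methods (systematic halving of
derivatives, wrong signs) closely enough to exercise the benchmark
pipeline.

## Degenerate and edge inputs

* More near-zero Hessian eigenvalues than the rigid-body count → explicit
  degenerate-geometry error (no silent mode dropping).
* Linear molecules are detected by moment-of-inertia rank (tolerance
  10⁻⁶ amu·Bohr²) and yield 3N−5 modes.
* VH negative eigenvalues −ω² become +ω with a logged warning carried in
  the model's metadata; the supplied energy gap is kept unchanged, since
  how the energy offset should be reassigned after the flip has no
  established convention.
* VG shifts reject near-zero frequencies (ill-conditioned Ω⁻²).
* Zero reference values in MAPE, empty HT spectra (B = 0), and empty stick
  spectra in broadening all fail loudly or are excluded with warnings, as
  documented on the functions.

## Known limitations

* State enumeration is exponential in the number of strongly displaced
  modes; the class-based caps with completeness reporting make truncation
  visible but the package is not a substitute for TD generating-function
  codes on 100-mode systems.
* The quadrature oracle is limited to two modes by design (dense grids).
* `%HT` and spectra depend on the supplied derivatives; the package
  propagates but cannot detect systematically wrong electronic-structure
  inputs beyond the Romberg stability screen.
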