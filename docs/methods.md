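# Methods

## Scope and data flow

The package models the analysis layer between upstream quantum-chemistry /
MD outputs and observable quantities for chlorophyll pigment clusters in
photosystem II reaction centers. Upstream quantities — Q_y site energies,
excitonic couplings, VEE quadruples, redox-potential shifts — are inputs,
either from the shipped reference parameter sets or from synthetic
generators; nothing here recomputes electronic structure.

## Exciton model

Site basis, one Q_y excitation per pigment: H = diag(ε) + V with ε in eV.
Couplings are symmetric with zero diagonal; asymmetric input is rejected
rather than averaged, because a disagreement between the (i,j) and (j,i)
entries of a coupling table indicates an upstream bookkeeping error.
Diagonalization uses a dense symmetric eigensolver. Eigenvector signs are
fixed by making each state's largest-|coefficient| entry positive (ties
broken toward the lowest site index), so outputs are reproducible across
BLAS builds.

The reference systems carry three sites (P_D1, P_D2, Chl_D1). The
published site-energy table reports a single value for the coupled
special pair; that value is assigned to both P_D1 and P_D2 diagonals.
This preserves the printed gap arithmetic exactly and is the documented
approximation of these fixtures. The published coupling range
180–192 cm⁻¹ covers both P_D2-substitution models without attribution;
the fixtures assign 180 (Chl d) and 192 (Chl f) as an arbitrary split of
that range.

**Point-dipole couplings.** V = 5034.1 · f · κ · μ₁μ₂/R³ (cm⁻¹) with
μ in Debye and the Mg–Mg (or centroid) distance R in Å. The default
screening factor f = 0.72 is the common empirical choice for
pigment–protein couplings; it is a tunable, not a fitted value. The
estimator refuses R ≤ 2 Å, where the approximation is meaningless. The
Q_y dipole magnitude defaults to 4.0 D for every chlorin type — an
effective in-protein value; no published magnitudes exist for Chl d/f, so
this is a documented placeholder, overridable per chemical type, not a
fit.

**Oscillator strengths.** f_k = 4.702·10⁻⁷ · Ẽ_k(cm⁻¹) · |μ_k|²(D²).
States below f = 10⁻⁴ are labelled dark. The coefficient orthonormality
guarantees Σ_k|μ_k|² = Σ_i μ_i², which the tests exercise as a sum rule.

**Units.** eV internally everywhere; 1 eV = 8065.544 cm⁻¹,
hc = 1239.84193 eV·nm, fixed in `constants.py` and versioned for
provenance. Reported wavelengths round to integer nm, energies to three
decimals, matching the field's reporting style.

## Spectra

Gaussian lineshape, default FWHM 0.06 eV — a visual-width choice for
chlorophyll Q bands, since no broadening is prescribed by the upstream
data. Default grid 1.4–2.2 eV with 2000 points; broadening refuses grids
that do not span every stick ± 3 FWHM. Static disorder is i.i.d. diagonal
Gaussian noise on the site energies (no off-diagonal disorder); a seeded
generator makes ensembles bit-reproducible. The ensemble emulates the
inhomogeneous broadening of an MD-sampled spectrum but none of its
dynamics: no vibronic structure, no temperature-dependent lineshape, no
correlated site fluctuations — so agreement of ensemble widths with the
injected σ validates the averaging machinery, not any claim about real
protein dynamics.

Alignment translates the grid so the local maximum nearest the reference
coincides with it (tie toward higher energy), recording the shift in the
metadata. Pairwise peak separations are invariant by construction.

## Tuning ledger

With the four VEEs v₁ = gas@gas-geometry, v₂ = gas@protein-geometry,
v₃ = protein monomer, v₄ = multimer:

- strain = v₂ − v₁ (geometry distortion by the pocket)
- electrostatic = v₃ − v₂ (protein field and hydrogen bonding)
- coupling/polarization = v₄ − v₃ (inter-pigment mixing and mutual
  polarization)

The components telescope exactly to v₄ − v₁; the ledger type enforces
this to 10⁻¹² eV. Negative = redshift. Components within ±0.001 eV are
classified neutral — below the precision at which such decompositions are
reported. The Chl f reference fixture embeds a zero
coupling/polarization component because no value is published for it; its
baseline (1.820 eV) is back-computed so the in-protein monomer VEE equals
the published 1.897 eV site energy, as is the Chl d baseline (1.910 eV).

## Charge separation

**Redox bookkeeping.** E_CT = E_ref − Δε_ox/1000 (eV, shift in mV). The
convention is that a reported *increase* of the donor-site oxidation
potential stabilizes the charge-separated state — this matches the
published numeric arithmetic (1.715 eV reference, +145 mV → 1.570 eV)
even though an increased oxidation potential would, on the usual
electrochemical sign convention, destabilize cation formation. The
tension is flagged in the `RedoxShift` docstring and deliberately not
resolved beyond the documented arithmetic. The 1.715 eV white-light
reference is itself back-computed from that arithmetic, not a published
number.

**Rates.** Marcus nonadiabatic form
k = (2π/ħ)V²(4πλk_BT)^(−1/2) exp(−(ΔG+λ)²/4λk_BT), with
ħ = 6.58212·10⁻¹⁶ eV·s, k_B = 8.61733·10⁻⁵ eV/K, T default 298.15 K.
Backward rates always come from detailed balance,
k_back = k_fwd·exp(ΔG/k_BT), so closed networks relax to the Boltzmann
distribution of their state energies — property-tested on random ladders.

**Default cascade.** Five states: S1 (1.72 eV) → primary radical pair
(1.57 eV) → special-pair⁺/Q_A⁻ (1.45 eV) → Y_Z-oxidized (1.35 eV) →
Mn-oxidized/Q_B⁻ (1.25 eV). The two intermediate energies are
interpolations between the 1.57 and 1.25 eV anchors. Forward rates
(3.0·10¹¹, 3.47·10⁹, 1.0·10⁷, 2.31·10³ s⁻¹) are a calibration to the
well-studied PSII kinetics — the final step carries the slow Q_A → Q_B
electron transfer — not a prediction; Marcus parameters are exposed for
users who prefer to construct rates from (λ, V) pairs. The white-light
variant shares the rate table and downstream anchors and differs in the
first two energies (S1 at 1.82 eV, one 0.10 eV higher-energy photon;
radical pair at the 1.715 eV reference).

**Propagation.** P(t) = exp(Gt)P(0) on a log-spaced grid (default
10⁻¹³–10⁻¹ s, 400 points). The generator is diagonalized once and
populations evaluated in the eigenbasis: with rates spanning fourteen
orders of magnitude, repeated squaring in a direct matrix exponential
accumulates ~10⁻⁵ conservation error, while the eigenbasis route is exact
up to the eigenvalue accuracy. A connected network has exactly one
stationary mode, so the smallest-magnitude eigenvalue (numerically
perturbed by ~ε‖G‖) is clamped to exactly zero and remaining real parts
capped at zero; an ill-conditioned eigenbasis (condition number > 10⁸)
falls back to scaling-and-squaring. Populations are clipped at zero
before the conservation check (tolerance 10⁻⁶).

**Halftimes.** Formation: first time the population reaches half its
global maximum; decay: first time after the maximum it falls back to
half-maximum. Crossings are interpolated log-linearly in time between
grid points; a state that never exceeds 10⁻⁹ population is an error.
Whether a published halftime refers to formation of a state or decay of
its precursor is ambiguous in general; this package reports formation,
consistent with "creating a transient state with a t½".

## Synthetic generators

Idealized chlorins: planar rings with Mg at the center, four pyrrole
nitrogens at the 2.05 Å Mg–N distance, sixteen carbons on a 3.4 Å outer
circle, random rigid orientation per pigment, centers on a line at the
configured Mg–Mg spacing (> 3 Å enforced). Sufficient to exercise the
geometry, dipole and coupling code paths; not real chlorophyll
coordinates. Every generator takes an explicit seed and uses one private
RNG stream, so outputs are bit-reproducible; PDB round-trips are exact to
the format's 10⁻³ Å coordinate precision.

`make_vee_set` is the exact right inverse of the ledger decomposition,
and `make_network` produces irreversible chains with log-uniform rates —
both exist so the analysis operations can be tested against inputs with
known embedded answers.

## Problem sizes and numerical tolerances

The shipped reference systems are three-site; the default cascade has
five states and a 400-point time grid; disorder-recovery checks use 2000
ensemble members on a monomer. These sizes keep the full suite and the
reproduction script within seconds while leaving every check's tolerance
dominated by the method, not the sampling: exciton eigenvalues verify
against the 2×2 closed form to 10⁻¹⁰ eV, broadening conserves area to
0.5% (grid quadrature), equilibrium distributions match Boltzmann to
10⁻⁶, halftimes match closed forms to well under the 5% band set by the
grid's log-linear interpolation.

## Known limitations

- No charge-transfer-state mixing in the exciton Hamiltonian, no
  transition-density or fragment-based coupling schemes (point-dipole
  only; published couplings enter as data).
- Single-structure geometry only: MD-ensemble-averaged distances and
  hydrogen-bond statistics are out of scope.
- No vibronic progressions, CD spectra or temperature-dependent
  lineshapes.
- The kinetic model is a linear chain; branching or recombination
  pathways require assembling a custom generator matrix.
- Idealized ring geometry means absolute point-dipole couplings from
  synthetic clusters are illustrative, not structure-predictive.
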