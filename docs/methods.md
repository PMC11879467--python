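# Methods

This note records the models implemented in `beamkin`, their assumptions,
the numerical choices behind them, and what the synthetic-data tests do and
do not demonstrate about real beam data.

## Units and constants

All energetics are carried in eV (1 cm⁻¹ = 1.239842×10⁻⁴ eV,
k_B = 8.61733×10⁻⁵ eV/K), frequencies in cm⁻¹, masses in amu, cross
sections in Å², dipoles in Debye, polarizability volumes in Å³. The
Coulomb constant e²/(4πε₀) = 14.3996 eV·Å makes ion–dipole and
ion–induced-dipole potentials dimensionally closed in these units; every
conversion lives in `beamkin.constants`. Two temperatures are kept
deliberately distinct: 298.15 K for thermochemical enthalpies, and 310 K
for the internal temperature of beam-thermalized ions; they are separate
parameters everywhere and are never conflated.

## Species energetics

Species are rigid rotors with independent harmonic oscillators. Zero-point
energies are scaled by 0.975 to compensate harmonic-DFT stiffness; the
scale applies to the ZPE only, not to thermal vibrational energies — the
thermal population of a mode is governed by its (unscaled) spacing, and
scaling both would double-count the correction. Thermal enthalpy
corrections sum the Bose vibrational energy, classical rotation (0, kT, or
3/2 kT by rotor type), 3/2 kT translation, and the kT pressure–volume
term. A transition state's imaginary frequency is stored separately from
the real modes, so it can never leak into thermal corrections or state
counts. Electronic energies are user-supplied relative values on a
declared reference; mixing references in one reaction is a configuration
error, and the package performs no electronic-structure computation.

Linearity is read off the number of rotational constants (one or two =
linear, three = nonlinear) rather than inferred from the optional
geometry, since geometries are frequently absent.

Spin projection removes contamination from broken-symmetry singlet
energies by linear extrapolation in ⟨Ŝ²⟩ through the singlet and triplet
points, evaluated at ⟨Ŝ²⟩ = 0. Gas-phase acidities and basicities fed to
the proton-transfer cycle are used exactly as supplied — whether they are
0 K or 298 K quantities is the caller's bookkeeping, because sources
rarely state it and the package cannot repair that ambiguity.

## Collision models

- **Langevin**: σ_L = π√(2αq²C/E), the capture cross section of the
  ion–induced-dipole potential.
- **Ion–dipole capture**: the trajectory-parametrized enhancement factor
  over Langevin, a function of the reduced dipole parameter
  x = μ_D/√(2αk_BT) evaluated at the neutral's rotational temperature.
  The parametrization is an energy-independent multiplier; at x = 0 it
  equals 1 to five decimal places, and the dipole-free case short-circuits
  exactly to Langevin. A locked-dipole upper bound is selectable.
- **Hard sphere**: each partner's orientation-averaged projected area A
  (Monte Carlo over uniform random rotations — quaternions drawn as
  normalized 4-D Gaussians — with the union-of-disks area computed by
  polygonal buffering at ~2.5×10⁻⁵ relative accuracy, far below the MC
  standard error; a single or fully nested disk is returned exactly as
  πr²) defines an effective radius r = √(A/π), combined as
  σ_hs = π(r_a + r_b)². The combination rule is isolated in one function
  precisely because it is a convention, not a derivation. Van der Waals
  radii default to a bundled Bondi-style table, overridable per call.
- **σ_collision = max(capture, hard sphere)**, and reaction efficiency is
  σ_total/σ_collision.
- **Beer–Lambert**: number density from the ideal-gas law at the cell
  temperature (default 310 K, configurable — the cell's own temperature is
  rarely stated); the thin-target form is the default because at
  ≤0.015 mTorr attenuation is ≪1%, where it agrees with the exact
  logarithmic form to well under 1%.

## Threshold law and beam broadening

The modified line-of-centers law
σ(E) = σ₀(E + E_vib + E_rot − E₀)ⁿ/E is evaluated per Monte Carlo draw —
internal energies are sampled, not replaced by their means, so the
convolution is exact within sampling error. Per sample the simulation
draws:

1. a lab-frame ion energy from a Gaussian of the stated FWHM
   (σ = FWHM/2.3548; the distribution shape is an assumption, as beam
   profiles are characterized only by their width);
2. a neutral velocity vector from Maxwell–Boltzmann at T_neutral, with the
   relative collision energy recomputed exactly — Doppler broadening by
   construction rather than through an analytic width, which unifies the
   beam-spread and thermal-motion smearing in one mechanism;
3. vibrational quanta per mode from the geometric (quantum Boltzmann)
   distribution and classical rotational energies from Γ(dof/2, k_BT);
4. optionally, a detection-probability weight 1 − exp(−k(E)·τ) when a rate
   function is supplied — the kinetic shift for slow reactions, with τ
   defaulting to 10⁻⁴ s, the order of the ion's time of flight.

Negative lab-energy draws are clipped to zero (they correspond to ions
that cannot reach the cell). The per-grid-point mean is returned with its
Monte Carlo standard error.

## Threshold fitting

σ₀ enters the model linearly, so it is profiled out analytically and each
exponent n on the scan grid (default step 0.1) leaves a one-dimensional
optimization in E₀: a 17-point coarse scan over ±0.8 eV around the onset
guess, then bounded Brent refinement to 10⁻³ eV. Every objective
evaluation reuses one fixed simulation seed (common random numbers), which
makes the noisy Monte Carlo objective a deterministic, smooth function of
E₀. The default 1024 samples per evaluation put the objective's own noise
well below the data noise at 5% measurement scatter.

Weights are 1/σ_err² when uncertainties are provided, else uniform.
Quoted errors are floored at 1% of the largest error before inversion:
below-threshold points carry vanishing or numerically meaningless
uncertainties, and without the floor they can dominate the objective by
many orders of magnitude (in testing this displaced fitted thresholds by
up to 0.3 eV). The floor caps the weight span at 10⁴ and leaves all
significant points untouched.

The E₀ uncertainty has two components reported separately: half the
spread of fitted E₀ over "acceptable" exponents (those within 10% of the
minimum objective — the acceptance criterion is a convention and 10% is
this package's), and the energy-scale uncertainty of the E_CM grid
(default 0.05 eV). A quadrature combination is also reported, since
whether the two should be merged in quadrature or additively is itself a
convention.

## RRKM kinetics

Sums and densities of states come from the Beyer–Swinehart direct-count
recursion, which is exact for harmonic oscillators on the grain lattice
(each frequency is rounded to an integer number of grains; the default
grain is 10 cm⁻¹, and halving it changes toy-system rates by far less than
the fit uncertainties). Hindered rotors and anharmonicity are out of
scope. k(E) = σ·W‡(E−E₀)/(hρ(E)) with reaction-path degeneracy σ
defaulting to 1. An energy bin with zero reactant density is an error, not
a zero — it means the energy lies below any countable reactant state,
which for realistic (incommensurate, many-mode) frequency sets only
happens below the ZPE.

Barrierless channels use an orbiting transition state at the centrifugal
barrier L⁴/(8αq²Cμ²) of the ion–induced-dipole potential, with
L = μ·v·√(σ_collision/π) evaluated at the nominal collision energy (an
energy- or angular-momentum-averaged L would require a J-resolved
treatment that is deliberately not attempted). Setting σ_collision to the
Langevin cross section places the barrier exactly at the collision energy;
this closed-form identity is used as an end-to-end validation of the unit
chain.

Wigner factors 1 + (1/24)(hν‡/k_BT)² are evaluated at 298 K by default —
the conventional temperature for quoting thermal tunneling corrections,
and the printed reference values round identically at 298 and 310 K.
Kinetic isotope effects are pointwise ratios of rate grids, with
zero-denominator points flagged NaN rather than fatal. Adduct populations
are density-of-states fractions at fixed energy.

## Synthetic data

The generator emulates the study conditions: ions of 165 amu with a
51-mode frequency set and neutrals of 34 amu with 15 modes (uniform draws
over 50–3500 cm⁻¹, the span of organic fundamentals), both thermalized to
310 K, a 0.65 eV lab-frame FWHM, and LOC curves with n = 2.4 carrying 5%
multiplicative Gaussian noise — the quoted relative uncertainty scale of
repeated cross-section measurements. Rotational constants scale as 1/m²,
landing nucleobase-sized ions near 0.05 cm⁻¹.

What the synthetic loop demonstrates: that the fitting machinery recovers
known thresholds through the full broadening chain at realistic noise
(median |ΔE₀| ≈ 0.01 eV over 20 replicates, bounded at 0.05 eV in the
test suite — stricter than the ±0.1–0.2 eV such fits carry in practice).
What it does not demonstrate: recovery of the study's own fitted
thresholds (1.5, 0.6, 1.3 eV), which would require the measured excitation
functions that exist only as figures; systematic errors of a real beam
(drifting energy zero, mass discrimination, non-Gaussian tails); or the
study's absolute rate constants and kH/kD values, which require its
optimized frequency sets. For the latter, the rrkm/kie tools accept
user-supplied one-number-per-line frequency files as an optional
validation path.

## Problem sizes

The shipped tests and analyses use 25-point energy grids, 1000–2000
Monte Carlo samples per point for data generation, 1024 per objective
evaluation for fits, 8–20 fit replicates, ≤4-mode systems for exhaustive
state-count enumeration, and ~2000 orientations for projected areas —
sizes chosen so every statistical comparison has comfortable margin while
the whole suite stays interactive.

## Known limitations

Single-channel fits only (channels are fitted independently; competition
between channels is not modeled). No phase-space-theory threshold laws, no
master-equation pressure dependence, no Eckart or small-curvature
tunneling beyond Wigner, no rovibrational coupling, no conformer handling.
The ion–dipole capture factor is a parametrization of classical trajectory
results, not a statistical-adiabatic-channel calculation; Langevin and
locked-dipole alternatives bracket it from below and above.
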