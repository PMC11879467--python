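# beamkin

Kinetics and energetics analysis for gas-phase ion–molecule chemistry in a
guided ion beam, built around the model system that probes DNA–protein
crosslinking: one- and two-electron oxidized 9-methylguanine cations
(9MG•⁺ at m/z 165, [9MG − H]⁺ at m/z 164) reacting with methylamine — a
stand-in for the lysine side chain — under single-collision conditions.

The package is for experimentalists and modelers who extract 0 K reaction
thresholds from energy-resolved cross sections and interpret them with
statistical rate theory. It implements:

- **Threshold fitting.** Endothermic excitation functions follow the
  modified line-of-centers law
  σ(E) = σ₀ (E + E_vib + E_rot − E₀)ⁿ / E. A Monte Carlo convolution
  samples everything that smears the collision energy in a real beam —
  Gaussian lab-frame energy spread (FWHM ≤ 0.65 eV), Maxwell–Boltzmann
  motion of the target gas (Doppler broadening), Boltzmann vibrational and
  rotational energies of both reactants at 310 K, and the kinetic shift
  from a ~100 μs detection window — and E₀ is extracted by weighted least
  squares with the exponent n scanned over a plausible interval.
- **RRKM kinetics.** Exact harmonic sums and densities of states by the
  Beyer–Swinehart direct count; microcanonical rates
  k(E) = σ W‡(E−E₀)/(h ρ(E)); orbiting transition states at the
  centrifugal barrier of the ion–induced-dipole potential with
  L = μ·v·√(σ_collision/π); Wigner tunneling factors
  1 + (1/24)(hν‡/k_BT)²; kinetic isotope effects as pointwise rate ratios;
  density-of-states adduct populations.
- **Collision models.** Langevin and ion–dipole (trajectory-parametrized)
  capture cross sections, orientation-averaged projected-area hard-sphere
  cross sections, σ_collision = max(capture, hard sphere), reaction
  efficiencies, and Beer–Lambert absolute cross sections from beam
  attenuation.
- **Thermochemical cycles and diradical energetics.** CT endothermicity
  from adiabatic ionization potentials, PT thresholds from gas-phase
  acidity/basicity, scaled-ZPE + RRHO reaction enthalpies, and Yamaguchi
  approximate spin projection for broken-symmetry singlets.
- **Synthetic data.** Reproducible toy species, isotopologues, and
  noisy LOC-shaped curves under the study's beam conditions, so the whole
  chain is testable without the (unpublished) measured curves.

## Worked example

Thermochemical thresholds from the bundled printed constants:

```text
$ beamkin thermo-cycle
# thermo_cycle
               channel  threshold_eV
       charge transfer          1.41
 proton transfer (N1H)          0.68
proton transfer (N2Ha)          0.58
proton transfer (N2Hb)          0.78
```

Charge transfer is endothermic by AIP(CH₃NH₂) − AIP(9MG) =
9.04 − 7.63 = 1.41 eV, matching the measured threshold of 1.5 ± 0.2 eV;
the three deprotonation sites bracket proton transfer between 0.58 and
0.78 eV against a measured 0.6 ± 0.1 eV.

Fitting a synthetic excitation function generated under the same beam
conditions recovers its threshold:

```text
$ beamkin synth --out demo --seed 3
$ beamkin fit-threshold --data demo/curve.tsv --conditions demo/beam.yaml \
      --n-min 2.4 --n-max 2.4 --samples 512 --seed 1
# fit
  sigma0    e0_eV   n  ...  e0_uncertainty_eV
2.077945 1.520484 2.4  ...               0.05
```

The curve was generated with σ₀ = 2, E₀ = 1.5 eV, n = 2.4 and 5%
multiplicative noise; the fit returns σ₀ = 2.08, E₀ = 1.52 eV. Over 20 such
replicates the median |E₀ error| stays below 0.05 eV (see
`tests/test_acceptance.py` and `analysis/04_threshold_recovery.py`).

The numbered scripts under `analysis/` run the full narrative —
thermochemical cycles, tunneling factors and isotope effects, collision
cross-section models, and the threshold-recovery study — writing their
tables to `results/`.

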