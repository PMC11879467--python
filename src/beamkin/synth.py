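"""Synthetic species and cross-section curves for end-to-end testing.

The measured excitation functions of the study system exist only as plotted
figures, so every stage of the analysis chain is exercised on synthetic
data instead: toy species with realistic harmonic frequency sets, their
isotopologues, and line-of-centers-shaped cross-section curves generated
under the beam conditions of the experiment (310 K thermalization, <=0.65 eV
lab-frame FWHM, masses 165/34 amu, single-collision regime).  All
generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np

from .constants import T_ION
from .fixtures import FixtureTable, study_constants  # noqa: F401  (re-exported)
from .loc import BeamConditions, CrossSectionCurve, LOCParams, simulate_convolved_sigma
from .species import Species

__all__ = [
    "gen_species",
    "gen_isotopologue",
    "gen_curve",
    "study_conditions",
    "study_constants",
    "FixtureTable",
]


def gen_species(
    seed: int,
    n_modes: int = 30,
    freq_range: tuple[float, float] = (50.0, 3500.0),
    mass: float = 165.0,
    charge: int = 1,
    name: str | None = None,
) -> Species:
    """A reproducible pseudo-random species with a plausible frequency set.

    Frequencies are drawn uniformly from ``freq_range`` (the span of
    organic-molecule fundamentals) and sorted ascending; rotational
    constants scale as 1/mass^2 — which lands nucleobase-sized ions in the
    few-hundredths-of-cm^-1 regime — with fixed anisotropy ratios;
    polarizability scales weakly with mass.  ``n_modes == 0`` yields an
    atom-like species.
    """
    if n_modes < 0:
        raise ValueError("n_modes must be >= 0")
    if freq_range[0] <= 0 or freq_range[1] < freq_range[0]:
        raise ValueError("freq_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    freqs = np.sort(rng.uniform(freq_range[0], freq_range[1], size=n_modes))
    if n_modes == 0:
        rot: tuple[float, ...] = ()
    else:
        base = 1000.0 / mass**2
        rot = tuple(base * r * rng.uniform(0.9, 1.1) for r in (1.8, 1.0, 0.7))
    return Species(
        name=name or f"toy-{seed}",
        mass=mass,
        charge=charge,
        frequencies=tuple(freqs),
        rotational_constants=rot,
        polarizability=0.09 * mass,
    )


def gen_isotopologue(
    species: Species,
    scale_indices: Sequence[int],
    ratio: float = 1.0 / math.sqrt(2.0),
    mass_increment: float = 0.0,
) -> Species:
    """Heavy isotopologue: selected modes scaled down, mass incremented.

    The default ratio 1/sqrt(2) is the harmonic limit for an H -> D
    stretch; softer coupled modes fall less (the methyl-H abstraction TS
    modes of the study system drop 169 -> 140 cm^-1, a ratio of ~0.828).
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    freqs = list(species.frequencies)
    for i in scale_indices:
        if not 0 <= i < len(freqs):
            raise IndexError(f"mode index {i} out of range for {len(freqs)} modes")
        freqs[i] *= ratio
    return Species(
        name=f"{species.name}-heavy",
        mass=species.mass + mass_increment,
        charge=species.charge,
        frequencies=tuple(sorted(freqs)),
        imaginary_frequency=species.imaginary_frequency,
        rotational_constants=species.rotational_constants,
        symmetry_number=species.symmetry_number,
        polarizability=species.polarizability,
        dipole=species.dipole,
        geometry=species.geometry,
        electronic_energy=species.electronic_energy,
        energy_reference=species.energy_reference,
    )


def study_conditions(seed: int = 0) -> BeamConditions:
    """Beam conditions emulating the study: 310 K, 0.65 eV FWHM, 165/34 amu.

    The ion gets a 51-mode toy frequency set (a 19-atom nucleobase analog)
    and the neutral a 15-mode set (a 7-atom methylamine analog); both
    nonlinear rotors.
    """
    ion = gen_species(seed, n_modes=51, mass=165.0, name="toy-nucleobase-cation")
    neutral = gen_species(seed + 1, n_modes=15, mass=34.0, charge=0, name="toy-amine")
    return BeamConditions(
        m_ion=ion.mass,
        m_neutral=neutral.mass,
        t_ion=T_ION,
        t_neutral=T_ION,
        fwhm_lab=0.65,
        ion_frequencies=ion.frequencies,
        neutral_frequencies=neutral.frequencies,
        ion_rotational_model="nonlinear",
        neutral_rotational_model="nonlinear",
    )


def gen_curve(
    params: LOCParams,
    conditions: BeamConditions,
    grid,
    noise_cv: float = 0.05,
    n_samples: int = 1000,
    seed: int = 0,
) -> CrossSectionCurve:
    """A synthetic measured curve: convolved model plus multiplicative noise.

    Gaussian noise with coefficient of variation ``noise_cv`` multiplies the
    convolved model curve (mimicking the few-percent run-to-run scatter of
    repeated cross-section measurements); ``sigma_err`` is set to
    ``noise_cv * sigma`` of the noise-free model.  Deterministic for a
    fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    seq = np.random.SeedSequence(seed)
    sim_seed, noise_seed = (int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(2))
    model = simulate_convolved_sigma(params, conditions, grid, n_samples, sim_seed)
    sigma = model.sigma.copy()
    if noise_cv > 0:
        rng = np.random.default_rng(noise_seed)
        sigma = np.clip(sigma * (1.0 + noise_cv * rng.normal(size=sigma.shape)), 0.0, None)
    return CrossSectionCurve(model.e_cm, sigma, noise_cv * model.sigma)
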