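"""Microcanonical (RRKM) kinetics: state counting, orbiting TS, KIE, tunneling.

The rate of a unimolecular step at internal energy E is

    k(E) = sigma * W'(E - E0) / (h * rho(E)),

with W' the sum of states of the transition state above its own zero point,
rho the density of states of the reactant, E0 the 0 K barrier, and sigma
the reaction path degeneracy.  Harmonic sums and densities are obtained by
the Beyer-Swinehart direct-count recursion, which is exact for harmonic
oscillators.  Barrierless (capture) channels use an orbiting transition
state located at the centrifugal barrier of the long-range ion-induced-
dipole potential, with the orbital angular momentum taken from the
collision cross section; this closes the unit chain against Langevin
capture theory exactly.  Wigner factors supply the lowest-order tunneling
correction, and pointwise rate ratios give kinetic isotope effects.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import (
    AMU_TO_KG,
    CM1_TO_EV,
    COULOMB_EV_ANG,
    EV_TO_J,
    H_EV_S,
    KB_EV,
)

__all__ = [
    "StateCount",
    "OrbitTS",
    "beyer_swinehart",
    "orbital_L",
    "centrifugal_barrier",
    "rrkm_k",
    "kie_ratio",
    "wigner_factor",
    "adduct_population",
    "survival_weight",
    "load_frequencies",
]


@dataclass(frozen=True)
class StateCount:
    """Harmonic sums and densities of states on a uniform energy grain.

    ``energies`` are bin lower edges in eV measured above the species' own
    zero-point level (so ``energies[0] == 0`` and ``sums[0] >= 1``);
    ``sums`` is the cumulative number of states W(E) and ``densities`` the
    density rho(E) in states per eV.
    """

    grain: float
    energies: np.ndarray
    sums: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        for name in ("energies", "sums", "densities"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.grain <= 0:
            raise ValueError("grain must be > 0")
        if not (len(self.energies) == len(self.sums) == len(self.densities)):
            raise ValueError("energies, sums, densities must have equal length")
        if np.any(np.diff(self.sums) < 0):
            raise ValueError("sums of states must be nondecreasing")
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0")

    @property
    def e_max(self) -> float:
        return float(self.energies[-1] + self.grain)

    def _index(self, energy: float) -> int:
        if energy >= self.e_max:
            raise ValueError(
                f"energy {energy:.4f} eV exceeds the counted range ({self.e_max:.4f} eV)"
            )
        # tiny relative nudge so bin boundaries are not lost to float jitter
        return int(energy / self.grain + 1e-9)

    def sum_at(self, energy: float) -> float:
        """W(E); 0 below the zero-point level."""
        if energy < 0:
            return 0.0
        return float(self.sums[self._index(energy)])

    def density_at(self, energy: float) -> float:
        """rho(E) in states/eV; 0 below the zero-point level."""
        if energy < 0:
            return 0.0
        return float(self.densities[self._index(energy)])


def beyer_swinehart(
    frequencies: Sequence[float], grain: float = 10.0, e_max: float = 40000.0
) -> StateCount:
    """Exact harmonic sum/density of states by direct count.

    ``grain`` and ``e_max`` are in cm^-1 (the natural resolution unit for
    vibrational ladders); the returned :class:`StateCount` stores energies
    in eV above ZPE.  The recursion seeds one state (the zero-point level)
    in the first bin and folds each mode's ladder in turn; it is exact for
    harmonic oscillators at the grain's resolution.  A grain coarser than
    the lowest frequency loses resolution and triggers a warning, not an
    error.
    """
    if grain <= 0:
        raise ValueError("grain must be > 0")
    if e_max < grain:
        raise ValueError("e_max must be >= grain")
    freqs = [float(f) for f in frequencies]
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be > 0")
    if freqs and grain > min(freqs):
        warnings.warn(
            f"grain {grain} cm^-1 exceeds the lowest frequency {min(freqs)} cm^-1; "
            "state counts lose resolution",
            stacklevel=2,
        )
    n_bins = int(e_max / grain) + 1
    counts = np.zeros(n_bins)
    counts[0] = 1.0
    for f in freqs:
        step = max(int(round(f / grain)), 1)
        for i in range(step, n_bins):
            counts[i] += counts[i - step]
    grain_ev = grain * CM1_TO_EV
    return StateCount(
        grain=grain_ev,
        energies=np.arange(n_bins) * grain_ev,
        sums=np.cumsum(counts),
        densities=counts / grain_ev,
    )


# ---------------------------------------------------------------------------
# Orbiting transition state
# ---------------------------------------------------------------------------

def orbital_L(reduced_mass_amu: float, velocity: float, sigma_collision: float) -> float:
    """Collision orbital angular momentum L = mu * v * b_max in SI (J*s).

    ``b_max = sqrt(sigma_collision / pi)`` identifies the maximum impact
    parameter with the collision cross section (A^2).
    """
    if reduced_mass_amu < 0 or velocity < 0 or sigma_collision < 0:
        raise ValueError("inputs must be >= 0")
    b_max = math.sqrt(sigma_collision / math.pi) * 1e-10  # m
    return reduced_mass_amu * AMU_TO_KG * velocity * b_max


def centrifugal_barrier(
    L: float, polarizability: float, charge: float, reduced_mass_amu: float
) -> float:
    """Height (eV) of the centrifugal barrier of the ion-induced-dipole
    potential ``V(r) = -alpha q^2 C / (2 r^4) + L^2 / (2 mu r^2)``.

    The maximum of V(r) is ``L^4 / (8 alpha q^2 C mu^2)``; with L from
    :func:`orbital_L` at the Langevin cross section this reproduces the
    collision energy exactly, which pins down the whole unit chain.
    """
    if polarizability <= 0:
        raise ValueError("polarizability must be > 0")
    if charge <= 0:
        raise ValueError("charge must be > 0")
    if reduced_mass_amu <= 0:
        raise ValueError("reduced mass must be > 0")
    c_jm = COULOMB_EV_ANG * EV_TO_J * 1e-10  # J*m
    alpha_m3 = polarizability * 1e-30
    mu_kg = reduced_mass_amu * AMU_TO_KG
    barrier_j = L**4 / (8.0 * alpha_m3 * charge**2 * c_jm * mu_kg**2)
    return barrier_j / EV_TO_J


@dataclass(frozen=True)
class OrbitTS:
    """An orbiting transition state for a barrierless capture channel.

    ``L`` is the orbital angular momentum in SI (J*s), ``polarizability``
    the neutral's polarizability volume in A^3, ``charge`` in elementary
    charges, ``reduced_mass`` in amu.  The effective threshold is the
    centrifugal barrier.
    """

    L: float
    polarizability: float
    charge: float
    reduced_mass: float

    @property
    def barrier(self) -> float:
        """Centrifugal barrier height in eV."""
        return centrifugal_barrier(self.L, self.polarizability, self.charge, self.reduced_mass)


# ---------------------------------------------------------------------------
# Rates and corrections
# ---------------------------------------------------------------------------

def rrkm_k(
    energy,
    e0: float,
    reactant_count: StateCount,
    ts_count: StateCount,
    symmetry: float = 1.0,
):
    """Microcanonical rate constant k(E) in 1/s.

    ``k(E) = symmetry * W'(E - E0) / (h * rho(E))``; returns 0 for E < E0.
    Energies are measured above the reactant's zero-point level and E0 is
    the 0 K barrier (including the ZPE difference).  A zero reactant
    density at E is an error — the energy lies below any reactant state.
    """
    if symmetry <= 0:
        raise ValueError("reaction path degeneracy must be > 0")
    scalar = np.isscalar(energy)
    energies = np.atleast_1d(np.asarray(energy, dtype=float))
    if np.any(energies < 0):
        raise ValueError("energy must be >= 0")
    out = np.zeros_like(energies)
    for i, e in enumerate(energies):
        rho = reactant_count.density_at(e)
        if rho == 0.0:
            raise ValueError(
                f"reactant density of states vanishes at E={e:.4f} eV; "
                "energy below the reactant zero-point level"
            )
        if e < e0:
            continue
        out[i] = symmetry * ts_count.sum_at(e - e0) / (H_EV_S * rho)
    return float(out[0]) if scalar else out


def kie_ratio(k_light, k_heavy):
    """Pointwise kinetic isotope effect k_light / k_heavy on a common grid.

    Points where the heavy rate vanishes are undefined and returned as NaN
    (with a warning) rather than raising, so a partial grid stays usable.
    """
    kl = np.asarray(k_light, dtype=float)
    kh = np.asarray(k_heavy, dtype=float)
    if kl.shape != kh.shape:
        raise ValueError("rate grids must share a common energy grid")
    undefined = kh == 0.0
    if np.any(undefined):
        warnings.warn(
            f"KIE undefined at {int(undefined.sum())} grid point(s) with zero heavy rate",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(undefined, np.nan, kl / np.where(undefined, 1.0, kh))
    return float(ratio) if ratio.ndim == 0 else ratio


def wigner_factor(imag_freq: float, temperature: float = 298.0) -> float:
    """Wigner tunneling factor ``1 + (1/24) (h nu' / kB T)^2`` (>= 1).

    ``imag_freq`` is the magnitude of the transition state's imaginary
    frequency in cm^-1.  The default 298 K matches the convention for
    thermally averaged tunneling corrections.
    """
    if imag_freq < 0:
        raise ValueError("imaginary frequency magnitude must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    u = imag_freq * CM1_TO_EV / (KB_EV * temperature)
    return 1.0 + u**2 / 24.0


def adduct_population(candidate_counts: Sequence[StateCount], energy: float) -> np.ndarray:
    """Statistical population fractions of isomeric adducts at energy E.

    Each candidate's share is ``rho_i(E) / sum_j rho_j(E)``; the fractions
    sum to 1 and are invariant under a common rescaling of the densities.
    All candidates must share one grain.
    """
    counts = list(candidate_counts)
    if not counts:
        raise ValueError("need at least one candidate")
    grains = {round(c.grain, 12) for c in counts}
    if len(grains) > 1:
        raise ValueError("candidates must share a common energy grain")
    rhos = np.array([c.density_at(energy) for c in counts])
    total = rhos.sum()
    if total == 0.0:
        raise ValueError(f"all candidate densities vanish at E={energy:.4f} eV")
    return rhos / total


def survival_weight(k, window: float):
    """Probability that a reaction with rate k completes within the
    detection window: ``1 - exp(-k * window)``."""
    if window <= 0:
        raise ValueError("window must be > 0")
    kk = np.asarray(k, dtype=float)
    if np.any(kk < 0):
        raise ValueError("rate must be >= 0")
    out = -np.expm1(-kk * window)
    return float(out) if np.isscalar(k) else out


def load_frequencies(path: str | Path) -> list[float]:
    """Read a one-number-per-line frequency file (cm^-1); '#' comments allowed.

    This is the entry point of the optional validation path: users with
    their own optimized frequency sets can feed them to the rrkm/kie tools
    to reproduce system-specific rate constants and isotope effects.
    """
    out: list[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        try:
            out.append(float(text))
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: not a frequency: {line!r}") from exc
    return out
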