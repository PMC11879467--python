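"""Molecular species data model and rigid-rotor/harmonic-oscillator energetics.

A :class:`Species` bundles everything the rest of the package needs to know
about one reactant, product, or transition state: mass, charge, harmonic
vibrational frequencies, rotational constants, and optionally a geometry,
a polarizability volume, a dipole moment, and a relative electronic energy.
Electronic energies are *inputs* — the package performs no electronic
structure computation; they are relative values on a reference the caller
declares, and mixing references in one reaction is an error.

Energetics helpers implement scaled zero-point energies, rigid-rotor
harmonic-oscillator (RRHO) thermal corrections, reaction enthalpies,
approximate spin projection for singlet diradicals, and the gas-phase
thermochemical cycles (charge-transfer endothermicity from adiabatic
ionization potentials; proton-transfer enthalpy from acidity and basicity).
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import CM1_TO_EV, KB_EV, T_ENTHALPY
from .errors import ConfigurationError, ParseError

__all__ = [
    "Atom",
    "Species",
    "SpinPair",
    "ThermoConstants",
    "read_xyz",
    "write_xyz",
    "zpe",
    "rrho_thermal_correction",
    "spin_project",
    "ct_endothermicity",
    "pt_threshold",
    "reaction_enthalpy",
    "load_species_config",
    "dump_species_config",
]

#: One atom: (element symbol, x, y, z) with coordinates in Angstrom.
Atom = tuple[str, float, float, float]

#: Default ZPE scale factor for the harmonic frequencies used here.
ZPE_SCALE = 0.975


@dataclass(frozen=True)
class Species:
    """A molecular species in the gas phase.

    Parameters
    ----------
    name : str
        Identifier used in configs and reports.
    mass : float
        Mass in amu; must be positive.
    charge : int
        Charge in elementary charges.
    frequencies : sequence of float
        Real harmonic vibrational frequencies in cm^-1, all positive.
    imaginary_frequency : float, optional
        Magnitude of the single imaginary frequency of a transition state,
        cm^-1.  Kept separate from ``frequencies`` so that thermal
        corrections and state counts never include it.
    rotational_constants : sequence of float
        1-3 rotational constants in cm^-1.  One or two constants mark a
        linear rotor, three a nonlinear one; an empty tuple marks an atom.
    symmetry_number : int
        Rotational symmetry number, >= 1.
    polarizability : float, optional
        Polarizability volume in A^3.
    dipole : float, optional
        Permanent dipole moment in Debye.
    geometry : sequence of Atom, optional
        Cartesian geometry in Angstrom.
    electronic_energy : float, optional
        Electronic energy in eV relative to ``energy_reference``.
    energy_reference : str
        Label of the common reference the electronic energy is measured
        against.  Reactions may only combine species sharing one reference.
    """

    name: str
    mass: float
    charge: int = 0
    frequencies: tuple[float, ...] = ()
    imaginary_frequency: float | None = None
    rotational_constants: tuple[float, ...] = ()
    symmetry_number: int = 1
    polarizability: float | None = None
    dipole: float | None = None
    geometry: tuple[Atom, ...] | None = None
    electronic_energy: float | None = None
    energy_reference: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(float(f) for f in self.frequencies))
        object.__setattr__(
            self, "rotational_constants", tuple(float(b) for b in self.rotational_constants)
        )
        if self.geometry is not None:
            object.__setattr__(
                self,
                "geometry",
                tuple((str(el), float(x), float(y), float(z)) for el, x, y, z in self.geometry),
            )
        if self.mass <= 0:
            raise ValueError(f"species {self.name!r}: mass must be > 0, got {self.mass}")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError(f"species {self.name!r}: all real frequencies must be > 0")
        if self.imaginary_frequency is not None and self.imaginary_frequency <= 0:
            raise ValueError(
                f"species {self.name!r}: imaginary frequency magnitude must be > 0"
            )
        if self.symmetry_number < 1:
            raise ValueError(f"species {self.name!r}: symmetry number must be >= 1")
        if len(self.rotational_constants) > 3:
            raise ValueError(f"species {self.name!r}: at most 3 rotational constants")
        if any(b <= 0 for b in self.rotational_constants):
            raise ValueError(f"species {self.name!r}: rotational constants must be > 0")

    @property
    def rotational_model(self) -> str:
        """'atom', 'linear' (1-2 constants), or 'nonlinear' (3 constants).

        Linearity is read off the number of rotational constants supplied —
        a linear rotor has a single B (possibly listed twice) — rather than
        inferred from the optional geometry.
        """
        n = len(self.rotational_constants)
        if n == 0:
            return "atom"
        return "linear" if n <= 2 else "nonlinear"

    @property
    def is_linear(self) -> bool:
        return self.rotational_model == "linear"

    def zpe(self, scale: float = ZPE_SCALE) -> float:
        """Scaled harmonic zero-point energy in eV."""
        return zpe(self.frequencies, scale)


@dataclass(frozen=True)
class SpinPair:
    """Broken-symmetry singlet / high-spin triplet energies and <S^2> values.

    Input to Yamaguchi's approximate spin projection.  Energies in eV on a
    common reference; the spin expectation values are dimensionless with
    ``s2_hs > s2_bs >= 0``.
    """

    e_bs: float
    e_hs: float
    s2_bs: float
    s2_hs: float

    def __post_init__(self) -> None:
        if self.s2_bs < 0:
            raise ValueError("s2_bs must be >= 0")
        if self.s2_hs <= self.s2_bs:
            raise ValueError("require s2_hs > s2_bs")


@dataclass(frozen=True)
class ThermoConstants:
    """Scalar thermochemical constants for one cycle, all in eV.

    ``gas_phase_acidity`` is keyed by deprotonation site (e.g. ``"N1H"``).
    """

    aip: dict[str, float] = field(default_factory=dict)
    gas_phase_acidity: dict[str, float] = field(default_factory=dict)
    gas_phase_basicity: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.aip, self.gas_phase_acidity, self.gas_phase_basicity):
            for key, value in table.items():
                if value <= 0:
                    raise ValueError(f"thermochemical constant {key!r} must be > 0")


# ---------------------------------------------------------------------------
# XYZ file handling
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> list[Atom]:
    """Read a standard XYZ file: count line, comment line, element x y z rows.

    Returns atoms in file order with coordinates in Angstrom.  Raises
    :class:`ParseError` naming the offending line on malformed input.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}, line 1: expected an atom count, got {lines[0]!r}") from exc
    atoms: list[Atom] = []
    for i in range(n_atoms):
        lineno = i + 3
        if lineno - 1 >= len(lines):
            raise ParseError(
                f"{path}, line {lineno}: expected {n_atoms} atom rows, file ended after {i}"
            )
        parts = lines[lineno - 1].split()
        if len(parts) < 4:
            raise ParseError(
                f"{path}, line {lineno}: expected 'element x y z', got {lines[lineno - 1]!r}"
            )
        try:
            atoms.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ParseError(
                f"{path}, line {lineno}: non-numeric coordinate in {lines[lineno - 1]!r}"
            ) from exc
    return atoms


def write_xyz(path: str | Path, geometry: Iterable[Atom], comment: str = "") -> None:
    """Write a geometry as a standard XYZ file (coordinates in Angstrom)."""
    atoms = list(geometry)
    out = [str(len(atoms)), comment.replace("\n", " ")]
    out += [f"{el} {x:.10f} {y:.10f} {z:.10f}" for el, x, y, z in atoms]
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Energetics
# ---------------------------------------------------------------------------

def zpe(frequencies: Sequence[float], scale: float = ZPE_SCALE) -> float:
    """Scaled harmonic zero-point energy, ``scale * sum(h nu / 2)``, in eV.

    The scale factor (default 0.975) compensates the systematic stiffness of
    harmonic DFT frequencies; it is applied to the ZPE only, not to thermal
    vibrational energies.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size and np.any(freqs <= 0):
        raise ValueError("all frequencies must be > 0")
    if not 0 < scale <= 1.2:
        raise ValueError(f"scale must be in (0, 1.2], got {scale}")
    return float(scale * 0.5 * freqs.sum() * CM1_TO_EV)


def rrho_thermal_correction(species: Species, temperature: float = T_ENTHALPY) -> float:
    """Thermal enthalpy correction H(T) - H(0) in eV, rigid-rotor/harmonic.

    Sums the harmonic vibrational thermal energy ``sum h nu/(exp(h nu/kT)-1)``
    over real modes (a transition state's imaginary frequency is excluded by
    construction), the classical rotational energy (0 for an atom, kT for a
    linear rotor, 3/2 kT otherwise), the translational 3/2 kT, and the kT
    pressure-volume term of the enthalpy.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    kt = KB_EV * temperature
    vib = 0.0
    for f in species.frequencies:
        hv = f * CM1_TO_EV
        vib += hv / math.expm1(hv / kt)
    rot = {"atom": 0.0, "linear": kt, "nonlinear": 1.5 * kt}[species.rotational_model]
    return vib + rot + 1.5 * kt + kt


def spin_project(pair: SpinPair) -> float:
    """Approximately spin-projected singlet energy in eV.

    Removes spin contamination from a broken-symmetry singlet using the
    high-spin (triplet) energy and the <S^2> expectation values::

        E = [S2_HS / (S2_HS - S2_BS)] * E_BS - [S2_BS / (S2_HS - S2_BS)] * E_HS

    Geometrically this is the line through (S2_BS, E_BS) and (S2_HS, E_HS)
    evaluated at S^2 = 0.
    """
    denom = pair.s2_hs - pair.s2_bs
    if denom == 0:  # unreachable through SpinPair, kept for raw callers
        raise ValueError("spin projection undefined for s2_hs == s2_bs")
    return (pair.s2_hs * pair.e_bs - pair.s2_bs * pair.e_hs) / denom


def ct_endothermicity(aip_neutral: float, aip_parent: float) -> float:
    """0 K charge-transfer enthalpy from adiabatic ionization potentials.

    For ``A+ + B -> A + B+`` the endothermicity is ``AIP(B) - AIP(A)``;
    the result may be negative (exothermic transfer).
    """
    if aip_neutral <= 0 or aip_parent <= 0:
        raise ValueError("ionization potentials must be > 0")
    return aip_neutral - aip_parent


def pt_threshold(acidity: float, basicity: float) -> float:
    """Proton-transfer enthalpy: gas-phase acidity of the donor minus
    gas-phase basicity of the acceptor, in eV."""
    if acidity <= 0 or basicity <= 0:
        raise ValueError("acidity and basicity must be > 0")
    return acidity - basicity


def reaction_enthalpy(
    reactants: Sequence[Species],
    products: Sequence[Species],
    temperature: float = T_ENTHALPY,
    zpe_scale: float = ZPE_SCALE,
) -> float:
    """Reaction enthalpy (products minus reactants) in eV at ``temperature``.

    Each species contributes electronic energy + scaled ZPE + RRHO thermal
    correction.  All species must carry an electronic energy on one common
    declared reference, otherwise a :class:`ConfigurationError` is raised.
    """
    everything = list(reactants) + list(products)
    refs = {s.energy_reference for s in everything}
    if len(refs) > 1:
        raise ConfigurationError(
            f"species mix electronic-energy references: {sorted(refs)}"
        )
    missing = [s.name for s in everything if s.electronic_energy is None]
    if missing:
        raise ConfigurationError(f"species lack electronic energies: {missing}")

    def h(s: Species) -> float:
        assert s.electronic_energy is not None
        return (
            s.electronic_energy
            + zpe(s.frequencies, zpe_scale)
            + rrho_thermal_correction(s, temperature)
        )

    return sum(h(s) for s in products) - sum(h(s) for s in reactants)


# ---------------------------------------------------------------------------
# Species config files (one block per species, keyed by name)
# ---------------------------------------------------------------------------

_FIELDS = (
    "mass",
    "charge",
    "frequencies",
    "imaginary_frequency",
    "rotational_constants",
    "symmetry_number",
    "polarizability",
    "dipole",
    "geometry",
    "electronic_energy",
    "energy_reference",
)


def load_species_config(path: str | Path) -> dict[str, Species]:
    """Load species from a YAML config: a mapping of name -> field block.

    Units are fixed package-wide: amu, cm^-1, A^3, Debye, Angstrom, eV.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: expected a mapping of species name -> fields")
    out: dict[str, Species] = {}
    for name, block in raw.items():
        if not isinstance(block, dict):
            raise ParseError(f"{path}: species {name!r} is not a mapping")
        unknown = set(block) - set(_FIELDS)
        if unknown:
            raise ParseError(f"{path}: species {name!r} has unknown keys {sorted(unknown)}")
        if "geometry" in block and block["geometry"] is not None:
            block = dict(block)
            block["geometry"] = [tuple(row) for row in block["geometry"]]
        out[name] = Species(name=name, **block)
    return out


def dump_species_config(path: str | Path, species: Iterable[Species]) -> None:
    """Write species to a YAML config readable by :func:`load_species_config`."""
    blocks: dict[str, dict] = {}
    for s in species:
        block: dict = {"mass": s.mass, "charge": s.charge}
        if s.frequencies:
            block["frequencies"] = list(s.frequencies)
        if s.imaginary_frequency is not None:
            block["imaginary_frequency"] = s.imaginary_frequency
        if s.rotational_constants:
            block["rotational_constants"] = list(s.rotational_constants)
        if s.symmetry_number != 1:
            block["symmetry_number"] = s.symmetry_number
        if s.polarizability is not None:
            block["polarizability"] = s.polarizability
        if s.dipole is not None:
            block["dipole"] = s.dipole
        if s.geometry is not None:
            block["geometry"] = [list(atom) for atom in s.geometry]
        if s.electronic_energy is not None:
            block["electronic_energy"] = s.electronic_energy
            block["energy_reference"] = s.energy_reference
        blocks[s.name] = block
    Path(path).write_text(yaml.safe_dump(blocks, sort_keys=False))
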