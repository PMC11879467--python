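"""Printed constants of the 9-methylguanine(+*) / methylamine study system.

The crosslinking chemistry this package models — one- and two-electron
oxidized 9-methylguanine cations reacting with (deuterated) methylamine in
a guided ion beam — comes with a small set of printed scalar constants:
reactant masses, ionization potentials, gas-phase acidities and basicity,
transition-state imaginary frequencies, beam conditions, and the headline
fitted/derived values.  They are collected here as a typed table so tests
and example analyses all draw on one source, and every entry carries a
provenance string saying what kind of quantity it is and where such a
number comes from.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass

import pandas as pd

__all__ = ["FixtureEntry", "FixtureTable", "study_constants"]


@dataclass(frozen=True)
class FixtureEntry:
    name: str
    value: float
    units: str
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"fixture {self.name!r} lacks a provenance string")


class FixtureTable(Mapping[str, FixtureEntry]):
    """Immutable mapping of named constants with units and provenance."""

    def __init__(self, entries: dict[str, FixtureEntry]):
        self._entries = dict(entries)

    def __getitem__(self, name: str) -> FixtureEntry:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def value(self, name: str) -> float:
        return self._entries[name].value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"name": e.name, "value": e.value, "units": e.units, "provenance": e.provenance}
                for e in self._entries.values()
            ]
        )


def _e(name: str, value: float, units: str, provenance: str) -> tuple[str, FixtureEntry]:
    return name, FixtureEntry(name, value, units, provenance)


def study_constants() -> FixtureTable:
    """The complete table of printed study constants used in the test suite."""
    entries = dict(
        [
            # --- masses -------------------------------------------------
            _e("mass_9mg_radical_cation", 165.0, "amu",
               "m/z of the 9-methylguanine radical cation reactant ion"),
            _e("mass_9mg_deprotonated_cation", 164.0, "amu",
               "m/z of the doubly oxidized, N2-deprotonated 9-methylguanine cation"),
            _e("mass_cd3nh2", 34.0, "amu",
               "mass of the d3-methylamine neutral target"),
            _e("mass_ch3nh2", 31.0, "amu",
               "mass of unlabeled methylamine"),
            # --- thermochemistry -----------------------------------------
            _e("aip_9mg", 7.63, "eV",
               "literature adiabatic ionization potential of 9-methylguanine"),
            _e("aip_ch3nh2", 9.04, "eV",
               "literature adiabatic ionization potential of methylamine"),
            _e("acidity_9mg_cation_N1H", 10.0, "eV",
               "G4(MP2)-6X gas-phase acidity of the N1-H site of the 9MG radical cation"),
            _e("acidity_9mg_cation_N2Ha", 9.9, "eV",
               "G4(MP2)-6X gas-phase acidity of the N2-Ha site of the 9MG radical cation"),
            _e("acidity_9mg_cation_N2Hb", 10.1, "eV",
               "G4(MP2)-6X gas-phase acidity of the N2-Hb site of the 9MG radical cation"),
            _e("basicity_ch3nh2", 9.32, "eV",
               "NIST-listed gas-phase basicity of methylamine"),
            _e("ct_endothermicity", 1.41, "eV",
               "0 K charge-transfer enthalpy from the two adiabatic ionization potentials"),
            _e("pt_threshold_N2Ha", 0.58, "eV",
               "proton-transfer enthalpy, N2-Ha acidity minus methylamine basicity"),
            _e("pt_threshold_N2Hb", 0.78, "eV",
               "proton-transfer enthalpy, N2-Hb acidity minus methylamine basicity"),
            # --- transition-state imaginary frequencies -------------------
            _e("imag_freq_methyl_ha_ch3nh2", 169.0, "cm^-1",
               "imaginary frequency of the methyl-H abstraction TS with CH3NH2"),
            _e("imag_freq_methyl_ha_cd3nh2", 140.0, "cm^-1",
               "imaginary frequency of the methyl-H abstraction TS with CD3NH2"),
            _e("imag_freq_amine_ha", 857.0, "cm^-1",
               "imaginary frequency of the N7 amine-H abstraction TS"),
            _e("imag_freq_amine_ha_deprotonated", 446.0, "cm^-1",
               "imaginary frequency of the amine-H abstraction TS of the deprotonated cation"),
            _e("wigner_methyl_ha_ch3nh2", 1.03, "",
               "Wigner tunneling factor at 169 cm^-1, printed to two decimals"),
            _e("wigner_methyl_ha_cd3nh2", 1.02, "",
               "Wigner tunneling factor at 140 cm^-1, printed to two decimals"),
            _e("wigner_amine_ha", 1.7, "",
               "Wigner tunneling factor at 857 cm^-1, printed to one decimal"),
            # --- beam conditions -----------------------------------------
            _e("fwhm_elab", 0.65, "eV",
               "retarding-potential upper bound on the lab-frame ion energy FWHM"),
            _e("ecm_spread", 0.1, "eV",
               "resulting spread of the nominal center-of-mass collision energy"),
            _e("t_ion", 310.0, "K",
               "ion internal temperature after collisional thermalization"),
            _e("pressure_min", 0.01, "mTorr",
               "lower end of the single-collision target gas pressure range"),
            _e("pressure_max", 0.015, "mTorr",
               "upper end of the single-collision target gas pressure range"),
            _e("cell_length", 11.0, "cm",
               "effective scattering-cell length around the octopole guide"),
            _e("detection_window", 1e-4, "s",
               "ion time-of-flight through the spectrometer, of order 100 microseconds"),
            _e("zpe_scale", 0.975, "",
               "harmonic zero-point-energy scale factor"),
            # --- fitted / derived headline values ------------------------
            _e("e0_ct", 1.5, "eV",
               "fitted 0 K threshold of charge transfer (+/- 0.2 eV)"),
            _e("e0_pt", 0.6, "eV",
               "fitted 0 K threshold of proton transfer from the radical cation (+/- 0.1 eV)"),
            _e("e0_pt_deprotonated", 1.3, "eV",
               "fitted 0 K proton-transfer threshold of the deprotonated cation (+/- 0.1 eV)"),
            _e("loc_n_best", 2.4, "",
               "line-of-centers exponent at which the best fits were achieved (2.4-2.5)"),
            _e("sigma_total_max", 17.0, "A^2",
               "maximum total product cross section; printed with an ambiguous unit "
               "(a bare angstrom), recorded here as A^2"),
            _e("efficiency_max_radical_cation", 0.07, "",
               "maximum reaction efficiency of the radical cation channel"),
            _e("efficiency_max_deprotonated", 0.19, "",
               "low-energy reaction efficiency of the deprotonated cation channel"),
            _e("rrkm_k_low", 8e8, "1/s",
               "crosslinking rearrangement rate constant at 0.05 eV collision energy"),
            _e("rrkm_k_high", 3e9, "1/s",
               "crosslinking rearrangement rate constant at 0.3 eV collision energy"),
            _e("kie_methyl_ha_low", 4.0, "",
               "methyl-H abstraction kH/kD at the low end of 0.05-0.3 eV"),
            _e("kie_methyl_ha_high", 5.0, "",
               "methyl-H abstraction kH/kD at the high end of 0.05-0.3 eV"),
        ]
    )
    return FixtureTable(entries)
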