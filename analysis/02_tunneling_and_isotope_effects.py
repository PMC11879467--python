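#!/usr/bin/env python
"""Wigner tunneling factors and a worked microcanonical isotope effect.

Hydrogen-abstraction transition states carry imaginary frequencies from
~140 to ~860 cm^-1 in this chemistry; the Wigner correction says which of
them tunnel appreciably.  The second half builds a toy light/heavy
isotopologue pair (a C-H stretch softened to C-D) and shows the RRKM
machinery producing the expected near-threshold kH/kD > 1.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beamkin.fixtures import study_constants
from beamkin.rrkm import beyer_swinehart, kie_ratio, rrkm_k, wigner_factor

RESULTS = Path(__file__).resolve().parents[1] / "results"


def wigner_table() -> pd.DataFrame:
    fx = study_constants()
    names = [
        ("imag_freq_methyl_ha_ch3nh2", "methyl-H abstraction (light amine)"),
        ("imag_freq_methyl_ha_cd3nh2", "methyl-H abstraction (d3 amine)"),
        ("imag_freq_amine_ha", "amine-H abstraction"),
        ("imag_freq_amine_ha_deprotonated", "amine-H abstraction (deprotonated ion)"),
    ]
    return pd.DataFrame(
        [
            {
                "transition_state": label,
                "imag_freq_cm1": fx.value(name),
                "wigner_298K": wigner_factor(fx.value(name), 298.0),
            }
            for name, label in names
        ]
    )


def toy_kie() -> pd.DataFrame:
    grain, e_max = 10.0, 30000.0
    shared = [90.0, 140.0, 230.0, 370.0]
    light = beyer_swinehart(shared + [3000.0], grain, e_max)
    heavy = beyer_swinehart(shared + [2200.0], grain, e_max)
    ts = beyer_swinehart([110.0, 160.0, 260.0, 410.0], grain, e_max)
    # common TS: the ZPE difference of the isotopic stretch shifts E0
    cm = 1.239841984e-4
    zpe = lambda fs: 0.5 * sum(fs) * cm
    barrier_el = 1.0
    e0_light = barrier_el + zpe([110.0, 160.0, 260.0, 410.0]) - zpe(shared + [3000.0])
    e0_heavy = barrier_el + zpe([110.0, 160.0, 260.0, 410.0]) - zpe(shared + [2200.0])
    grid = np.linspace(e0_heavy + 0.05, e0_heavy + 0.6, 8)
    k_l = rrkm_k(grid, e0_light, light, ts)
    k_h = rrkm_k(grid, e0_heavy, heavy, ts)
    return pd.DataFrame(
        {"E_eV": grid, "k_light_per_s": k_l, "k_heavy_per_s": k_h, "kie": kie_ratio(k_l, k_h)}
    )


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    wt = wigner_table()
    wt.to_csv(RESULTS / "wigner_factors.tsv", sep="\t", index=False)
    print(wt.to_string(index=False))
    print(
        "\nOnly the 857 cm^-1 amine-H abstraction TS tunnels appreciably "
        f"(factor {wt['wigner_298K'].max():.2f}); the soft methyl-H TSs sit at ~1.03."
    )
    kt = toy_kie()
    kt.to_csv(RESULTS / "kie_toy.tsv", sep="\t", index=False)
    print("\n" + kt.to_string(index=False))
    print(
        f"\nNear threshold the light channel runs {kt['kie'].iloc[0]:.1f}x faster; "
        "the effect fades with excess energy, the usual microcanonical KIE shape."
    )


if __name__ == "__main__":
    main()
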