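#!/usr/bin/env python
"""Collision cross-section models and reaction efficiency vs energy.

Compares Langevin, ion-dipole capture, and a hard-sphere cross section
from orientation-averaged projected areas for a nucleobase-cation /
methylamine-like pair (alpha = 4.0 A^3 and dipole = 1.31 D, literature
values for methylamine), then converts a representative total reactive
cross section into an efficiency against max(capture, hard sphere).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beamkin.collisions import (
    capture_sigma,
    collision_sigma,
    langevin_sigma,
    projected_area_sigma,
    reaction_efficiency,
)
from beamkin.fixtures import study_constants

RESULTS = Path(__file__).resolve().parents[1] / "results"

ALPHA, DIPOLE, CHARGE, T = 4.0, 1.31, 1.0, 310.0

# crude stand-in geometries: a flat 6-ring plus substituents for the ion,
# a C-N skeleton for the amine (synthetic; only their projected areas matter)
ION_GEOM = [
    ("C", 0.0, 0.0, 0.0), ("N", 1.35, 0.0, 0.0), ("C", 2.05, 1.2, 0.0),
    ("N", 1.35, 2.4, 0.0), ("C", 0.0, 2.4, 0.0), ("C", -0.7, 1.2, 0.0),
    ("O", -2.0, 1.2, 0.0), ("N", 2.05, 3.6, 0.0), ("C", 3.5, 1.2, 0.0),
]
NEUTRAL_GEOM = [("C", 0.0, 0.0, 0.0), ("N", 1.47, 0.0, 0.0)]


def main() -> None:
    fx = study_constants()
    hard_sphere = projected_area_sigma(
        ION_GEOM, None, NEUTRAL_GEOM, None, n_orientations=1024, seed=0
    )
    rows = []
    for e in np.round(np.geomspace(0.05, 2.0, 9), 3):
        cap = capture_sigma(ALPHA, DIPOLE, CHARGE, T, e)
        coll = collision_sigma(cap, hard_sphere)
        rows.append(
            {
                "E_CM_eV": e,
                "langevin_A2": langevin_sigma(ALPHA, CHARGE, e),
                "capture_A2": cap,
                "hard_sphere_A2": hard_sphere,
                "collision_A2": coll,
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "collision_models.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    crossover = table[table["capture_A2"] < table["hard_sphere_A2"]]["E_CM_eV"]
    note = (
        f"capture falls below the {hard_sphere:.0f} A^2 hard-sphere area above "
        f"~{crossover.iloc[0]:.2f} eV" if len(crossover) else
        "capture dominates over the whole energy range"
    )
    low_e = table.iloc[0]
    eff = reaction_efficiency(fx.value("sigma_total_max"), low_e["collision_A2"])
    print(
        f"\nAt low energy the dipole-enhanced capture dominates; {note}. "
        f"A {fx.value('sigma_total_max'):.0f} A^2 total reactive cross section at "
        f"{low_e['E_CM_eV']} eV against the {low_e['collision_A2']:.0f} A^2 collision "
        f"cross section gives an efficiency of {eff:.0%} — the few-percent regime "
        "characteristic of these reactions."
    )


if __name__ == "__main__":
    main()
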