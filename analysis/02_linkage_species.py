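#!/usr/bin/env python
"""Species populations of the five-species linkage model.

Solves the coupled equilibria for the engineered-variant fixture across
protein concentration and temperature, writing the per-monomer fractions
of N, S, U, hexamer and dodecamer. Writes results/species_vs_conc.csv
and results/species_vs_temp.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from foldlink import config
from foldlink.linkage import Conditions, monomer_fraction, solve_species

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

lp = config.linkage_params("ci2_eng")

rows = []
for C in np.logspace(-6, -2.2, 25):
    st = solve_species(lp, Conditions(C_tot=float(C), T=298.0))
    rows.append({"C_tot_M": C, "T_K": 298.0, **st.fractions(),
                 "monomer_fraction": monomer_fraction(st)})
conc = pd.DataFrame(rows)
conc.to_csv(OUT / "species_vs_conc.csv", index=False)

rows = []
for T in np.arange(285.0, 381.0, 1.0):
    st = solve_species(lp, Conditions(C_tot=6e-4, T=float(T)))
    rows.append({"C_tot_M": 6e-4, "T_K": T, **st.fractions(),
                 "monomer_fraction": monomer_fraction(st)})
temp = pd.DataFrame(rows)
temp.to_csv(OUT / "species_vs_temp.csv", index=False)

c_half = conc.loc[(conc.monomer_fraction - 0.5).abs().idxmin(), "C_tot_M"]
t_peak = temp.loc[(temp.H + temp.H2).idxmax(), "T_K"]
print(f"At 298 K assembly reaches half-saturation near {c_half*1e3:.1f} mM "
      "(millimolar threshold at room temperature).")
print(f"At 0.6 mM the assembled fraction peaks at {t_peak:.0f} K and then "
      "dissolves into unfolded monomers at higher temperature.")
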