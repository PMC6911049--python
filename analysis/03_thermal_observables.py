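#!/usr/bin/env python
"""Thermal observables of the linkage model: optical melts and DSC.

Computes fluorescence-style melts and DSC thermograms of the
engineered-variant fixture across protein concentrations, extracting the
apparent native midpoint and the DSC peak positions (T1, T2). Writes
results/melt_curves.csv, results/dsc_traces.csv, results/dsc_peaks.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from foldlink import config
from foldlink.linkage import apparent_native_midpoint
from foldlink.observables import SignalBasis, dsc_thermogram, melt_curve

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

lp = config.linkage_params("ci2_eng")
T = np.arange(285.0, 385.0, 0.5)
CONCS = [6e-6, 6e-5, 2e-4, 6e-4]

melts, peaks, traces = [], [], []
for C in CONCS:
    tab = melt_curve(lp, SignalBasis(), C, 0.0, T)
    melts.append(tab.frame.assign(C_tot=C))
    mid = apparent_native_midpoint(lp, C, 0.0, T)
    tr = dsc_thermogram(lp, C, 0.0, T, prominence_frac=0.05)
    traces.append(tr.to_frame().assign(C_tot=C))
    peaks.append(
        {"C_tot_M": C, "native_midpoint_K": mid,
         "T1_K": tr.peak_temperatures[0] if tr.peak_temperatures else None,
         "T2_K": tr.peak_temperatures[-1] if len(tr.peak_temperatures) > 1 else None}
    )

pd.concat(melts).to_csv(OUT / "melt_curves.csv", index=False)
pd.concat(traces).to_csv(OUT / "dsc_traces.csv", index=False)
peaks = pd.DataFrame(peaks)
peaks.to_csv(OUT / "dsc_peaks.csv", index=False)
print(peaks.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
print(
    "\nRaising protein concentration destabilizes the native fold (midpoint "
    "falls) and splits the single DSC transition into two peaks that move "
    "apart: the early fold-switch/assembly transition and the late "
    "dissolution into unfolded monomers."
)
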