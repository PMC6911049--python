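# foldlink

Thermodynamic linkage analysis of protein assembly controlled by a
monomer fold switch.

Some engineered proteins assemble not by optimizing an interface on the
native fold, but by switching the monomer into an alternate, metastable
fold that exposes a sticky surface. The chymotrypsin inhibitor 2 (CI2)
scaffold is the canonical example: an engineered variant interconverts
between the native fold (N), a fold-switched conformation (S) and the
unfolded state (U), and six S monomers assemble into a hexameric ring (H)
that stacks into a dodecamer (H2). A short C-terminal peptide (P) binds
the native fold and acts as a negative allosteric effector. `foldlink`
implements this five-species linkage model together with the standard
two-state folding machinery around it, for anyone who wants to simulate,
fit or reason quantitatively about fold-switch coupled assembly:

* **Two-state closed forms** — linear extrapolation model
  (dG(D) = dG0 − m·D), Gibbs–Helmholtz stability curves
  (dG(T) = dHm(1 − T/Tm) + dCp[(T − Tm) − T ln(T/Tm)]), and chevron
  kinetics (λ(D) = kf0·e^(mf·D/RT) + ku0·e^(mu·D/RT)).
* **The linkage solver** — mass-action equilibrium of
  {N, NP, S, U, H, H2} at any (C_tot, T, P_tot), solved by bisection on
  ln[N] with log-space evaluation of the x⁶ and x¹² terms.
* **Observables** — optical melts, DSC excess heat capacity with peak
  extraction, species distributions, apparent native midpoints, peptide
  rescue curves.
* **Competitive enzyme inhibition** — V0 = Vmax·S/(Km_app + S) with
  Km_app = Km(1 + I/Ki).
* **Seeded synthetic-data generators and a fitting layer** — weighted
  nonlinear least squares with multi-start, global linkage fits across
  condition series, and replicate parameter-recovery studies.
* **Composition and geometry** — average sequence masses (monomer,
  hexamer, dodecamer) and a D6 double-ring coordinate builder.

## Worked example

Generate a noisy chemical-denaturation curve from the wild-type
parameters and refit it, then solve the linkage model at assembly
conditions:

```python
import numpy as np
import foldlink as fl
from foldlink import config

# two-state folding: simulate at 2% noise, refit
wt = config.chem_params("ci2_wt")          # dG0 = 30.9 kJ/mol, Cm = 4.07 M
curve = fl.gen_chem_denaturation(wt, np.linspace(0, 7, 25), 298.0,
                                 fl.NoiseSpec(sd=0.02, seed=1))
fit = fl.fit_lem(curve)
print(fit["dG0"], fit.extras["Cm"])        # 29.93 kJ/mol, 4.03 M

# the five-species linkage model at 0.6 mM and 320 K
lp = config.linkage_params("ci2_eng")
state = fl.solve_species(lp, fl.Conditions(C_tot=6e-4, T=320.0))
print({k: round(v, 3) for k, v in state.fractions().items()})
# {'N': 0.127, 'NP': 0.0, 'S': 0.002, 'U': 0.0, 'H': 0.159, 'H2': 0.711}
```

At 298 K the same 0.6 mM sample is >99% native monomer; a 22-degree jump
drives 87% of the monomers into assembled rings — temperature is a
positive effector of assembly, the diagnostic opposite of a conventional
native-state oligomer.

The numbered drivers under `analysis/` run the full analyses and write
tables under `results/`:

```
01_twostate_folding.py      simulate + refit equilibrium and chevron data
02_linkage_species.py       species populations vs concentration and T
03_thermal_observables.py   melts, DSC peaks T1/T2 vs concentration
04_peptide_control.py       C-peptide rescue at 298 vs 310 K
05_recovery_study.py        100-replicate parameter-recovery benchmark
06_composition_geometry.py  variant masses and the D6 toroid model
```

For example, `03_thermal_observables.py` prints the concentration
dependence of the DSC structure — one peak at 6 µM (337.4 K), splitting
into two peaks (307.2/360.8 K) at 600 µM — and `06_composition_geometry.py`
prints the engineered monomer at 7332.6 Da with hexamer 44.0 kDa and
dodecamer 88.0 kDa.

A thin CLI covers the common one-off tasks:

```bash
foldlink generate --kind chem --variant ci2_wt --seed 1 --out wt.csv
foldlink fit --model lem wt.csv
foldlink mass src/foldlink/data/sequences.fasta
foldlink toroid --out toroid.pdb
```

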