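# Methods

## The system and the model

`foldlink` models an engineered protein whose monomer interconverts
between three conformations — the native fold **N**, a metastable
fold-switched conformation **S**, and the unfolded state **U** — and
whose S conformation self-assembles into a hexameric ring **H** that can
stack into a dodecamer **H2**. A short C-terminal peptide **P** binds the
native fold only (**N + P <-> NP**), pulling the linked equilibria back
toward the monomer. The chymotrypsin inhibitor 2 (CI2) scaffold and its
engineered variants are the concrete instance: the packaged sequences and
two-state parameters describe the wild type and the fold-switching
variant, and the toroidal particle geometry (65 x 55 A, 15 A channel, D6
symmetry) describes the assembled state.

The five coupled equilibria, all under thermodynamic control on the 1 M
standard state:

    N <-> S        K_S(T)              (fold switch)
    N <-> U        K_U(T)              (unfolding)
    6 S <-> H      K_H(T)   [M^-5]     (ring assembly)
    2 H <-> H2     K_H2(T)  [M^-1]     (ring stacking)
    N + P <-> NP   K_P(T)   [M^-1]     (peptide binding)

Each constant is K = exp(-dG(T)/RT). Conformational steps use the
Gibbs-Helmholtz form dG(T) = dHm (1 - T/Tm) + dCp [(T - Tm) - T ln(T/Tm)]
(parameters Tm [K], dHm [kJ/mol], dCp [kJ/mol/K]); association and
binding steps use the van't Hoff form anchored at a reference temperature
(dG_ref, dH_ref at T_ref, optional dCp). Temperatures are kelvin,
energies kJ/mol, concentrations molar; R = 8.314462618e-3 kJ/mol/K is
defined once in `foldlink.constants`.

This linkage structure is what produces allosteric control: raising
temperature favors S (and hence assembly) before it favors U; raising
total protein mass-action-drives 6S -> H; adding peptide sequesters N and
dissolves the assembly. The model reproduces the diagnostic signatures:
the apparent native midpoint *falls* with protein concentration (the
opposite of a native-state oligomer), the DSC endotherm splits into two
concentration-dependent peaks that move apart, and peptide rescue
requires more peptide at higher temperature.

## Solving the coupled equilibria

With x = [N], every species is a closed-form monomial in x:
[S] = K_S x, [U] = K_U x, [H] = K_H (K_S x)^6,
[H2] = K_H2 K_H^2 (K_S x)^12, [NP] = P_tot K_P x / (1 + K_P x).
The monomer mass balance total(x) = C_tot is strictly increasing in x, so
the root is unique and bracketed in (0, C_tot]. The solver bisects on
ln x with the bracket [ln(C_tot) - 32.2, ln(C_tot)] (extended downward in
32-unit steps if the monomer pool is K-dominated), terminating when the
bracket is narrower than 1e-12 in ln x (capped at 300 iterations, which
monotonicity makes unreachable in practice). The x^6 and x^12 terms are
evaluated in log space with an explicit overflow guard (exponents above
700 map to infinity, which bisection handles correctly). Bisection was
chosen over Newton because it is unconditionally safe on a monotone
function and its cost (~60 iterations of a cheap scalar evaluation) is
negligible; a Newton accelerator would only complicate the failure
analysis. The returned state satisfies monomer and peptide mass balance
to better than 1e-9 relative and detailed balance to 1e-8, verified on
randomized parameter draws against an independent two-stage grid-scan
oracle.

## Observables

* **Optical melts** are population-weighted sums of per-species linear
  baselines, y(T) = sum_i f_i(T) (a_i + b_i T). The default basis mimics
  tryptophan fluorescence of the native tertiary environment: N and NP
  bright on a common baseline, S/U/H/H2 dark, because the first
  transition extinguishes the fluorescence signal.
* **Excess enthalpy** per mole monomer is referenced to N: S and U carry
  their step enthalpies dH(T); assembled monomers add the per-monomer
  share of the association enthalpies (dH_H/6; the dodecamer additionally
  dH_H2/12); NP carries the binding enthalpy.
* **DSC thermograms** differentiate the excess enthalpy by central
  differences with step dT = 0.02 K (grid spacing must be >= 2 dT;
  truncation error is negligible against transition widths of several
  kelvin). Peaks are interior local maxima above a prominence threshold
  (default 1% of the trace maximum; the analyses here use 5% to ignore
  shoulder structure), with three-point parabolic refinement of the peak
  position. No smoothing is applied: synthetic traces are noise-free
  unless the generators add noise.

A deliberate point of physics: for a pure two-state step with dCp = 0 the
excess-Cp maximum does *not* sit exactly at Tm. Because df/dT carries a
1/T^2 factor, the maximum is shifted cold by approximately
4 R^2 Tm^3 / dHm^2 (about 0.12 K for dHm = 300 kJ/mol, Tm = 337 K). The
implementation reproduces this analytic shift to ~1e-3 K, and the peak
height matches dHm^2/(4 R Tm^2) within 0.5%. Excess Cp is emitted
positive for endothermic transitions; sign conventions for "exothermic"
presentations are left to the caller.

## Two-state models and the fitting layer

Chemical denaturation uses the linear extrapolation model
dG(D) = dG0 - m_eq D with linear native/unfolded baselines (baselines are
conventional, not measured). Chevron kinetics uses
ln k(D) = ln k0 + m D / RT for each arm, with the observed relaxation
rate kf + ku; kinetic m-values are interpreted as slopes of R T ln k
versus denaturant, in kJ/mol/M as printed.

The published kinetic and equilibrium parameters of this system are not
mutually consistent: R T ln(kf0/ku0) reproduces the equilibrium dG0
within 0.5 kJ/mol for the wild type (30.6 vs 30.9 kJ/mol), but the
kinetic m-values imply an equilibrium m-value (mu - mf ~ 1.3 kJ/mol/M)
several-fold smaller than dG0/Cm, and a chevron minimum near 25 M
denaturant for the wild type. The package therefore treats kinetic and
equilibrium parameter sets strictly per-model and never cross-constrains
them; the synthetic chevron grids span [0, 2 x D_min] computed from each
parameter set so that both arms carry information, even where that range
exceeds physically attainable denaturant concentrations.

All fitters share one pattern: heuristic initialization from the data
(baseline levels from the curve ends, midpoint from the half-signal
crossing, arm slopes from end-segment regressions), bounded
Levenberg-Marquardt least squares (lmfit), and additional Latin-hypercube
restarts within the bounds up to a cap (default 20), stopping early once
the residual sum of squares reaches the noise floor (2n for
sigma-weighted residuals, twice the summed noise variance otherwise).
Chevron fits run in ln-rate space with homoscedastic weights, matching
the log-normal error structure of measured rates; rate constants are
parameterized as logs. Standard errors come from the local quadratic
approximation; bootstrap is deliberately omitted from the default path.
Noise-free data are recovered to 1e-6 relative by every fitter.

The global linkage fit shares one `LinkageParams` across a stacked
condition series (melts at several concentrations, or a peptide
titration) with a free/fixed mask addressed by dotted names
("step_NS.Tm", "assoc_H.dG_ref", "bind_P.dG_ref"). Association or
binding parameters are refused when the series contains a single
condition, since one concentration cannot separate conformational from
association steps. Two-state limits are exactly nested: with assembly
disabled, the global fit reproduces the dedicated two-state thermal fit.

Michaelis-Menten analysis implements classical competitive inhibition:
V0 = Vmax S / (Km_app + S) with Km_app = Km (1 + I/Ki), and
Ki = I / (Km_app/Km - 1) for the inverse. Validity note: the assay this
models uses inhibitor (200 nM) only ~4-fold above enzyme (53 nM), near
the tight-binding regime where the free-inhibitor approximation
I_free ~ I_total begins to bias Ki downward; the classical form is used
regardless because it is the form the data were analyzed with. The
Morrison quadratic is out of scope.

## Synthetic data

Generators add Gaussian noise to the exact forward-model curves:
additive and homoscedastic for optical signals (sd given in signal units
or, by default, as a fraction of the clean-signal range — 2% of range is
the default convention, since real noise magnitudes are instrument
dependent and unreported), and additive on ln(rate) for relaxation rates.
Every dataset's stream is derived from the master seed plus a SHA-256
hash of the generator configuration, so identical (config, seed) pairs
are bit-reproducible and replicate suites never collide streams. The
generators emulate curve shapes and noise only; they do not model
instrument artifacts (mixing dead time, scan-rate lag, baseline drift
beyond linear), sample heterogeneity, or slow-equilibration hysteresis,
so passing recovery tests demonstrates estimator correctness under the
assumed noise model, not robustness to real-instrument systematics.

## Fixtures

`ci2_wt.json` / `ci2_eng.json` carry the published two-state equilibrium
(dG0, Cm) and chevron (kf0, ku0, mf, mu) parameters. The linkage
fixtures are different in kind: no enthalpies or free energies were ever
published for the switch, assembly or binding steps, so
`linkage_ci2_eng.json` and `linkage_ci2_1_58.json` are tuning constants
chosen once by mass-action balance to place the system in the observed
qualitative regime — native unfolding near 337 K at low concentration, a
millimolar assembly threshold at room temperature, two DSC peaks
separating with concentration, peptide rescue of an 80 uM sample at
hundreds of micromolar peptide. For the engineered variant: switch step
Tm = 359 K, dHm = 100 kJ/mol (dG ~ +17 kJ/mol at 298 K, metastable);
unfolding Tm = 337 K, dHm = 300 kJ/mol; hexamerization dG_ref = -166
kJ/mol per hexamer with dH_ref = +120 kJ/mol (entropy-driven, so heat
promotes assembly); ring stacking dG_ref = -28 kJ/mol. dCp values are
zero in the fixtures because nothing constrains them; the code supports
nonzero dCp throughout. These values are illustrative model instances,
not estimates of the real system.

## Known limitations

* Only S assembles, hexamerization is all-or-none (no intermediate
  oligomers), and the peptide binds only N — the minimal scheme that
  reproduces the observed species inventory (M, H, H2).
* Assembly kinetics, domain-swapped cross-ring linkage, crowding and
  activity corrections are out of scope.
* The toroid builder emits coarse pseudo-atom placeholders with exact
  construction symmetry, intended for geometry/symmetry reasoning and
  size comparisons, not for density fitting.
* Proline-isomerization slow phases and three-state chevron rollover are
  not modelled.
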