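# Methods

## Thermodynamic model

The package treats thermal unfolding as one or two sequential two-state
equilibria (F⇌U, or F⇌I⇌U) characterised per transition by the enthalpy
change at the midpoint ΔH(*T*_m), a temperature-independent heat-capacity
change ΔCp, and the melting temperature *T*_m. Under constant ΔCp the
stability curve follows the Gibbs–Helmholtz equation

ΔG(T) = ΔH(*T*_m)·(1 − T/*T*_m) − ΔCp·[(*T*_m − T) + T·ln(T/*T*_m)],

which vanishes exactly at *T*_m and has slope −ΔH(*T*_m)/*T*_m there (the
van't Hoff slope). ΔCp is in reality weakly temperature dependent; the
constant-ΔCp form is a good approximation for the short extrapolations
(30–40 K around *T*_m) the workflow uses, and no curvature term is
implemented. The unfolding equilibrium constant is K = [U]/[F] =
exp(−ΔG/RT); positive ΔG means the fold is favoured. All energies are in
kcal/mol, heat capacities in kcal/(mol·K), temperatures in K, with
R = 1.987×10⁻³ kcal/(mol·K).

For a sequential pathway the global ΔG and ΔCp are sums over transitions.
Per-transition standard errors combine in quadrature by default
(transitions estimated from independent simulations); a "sum" mode is
available for conservative reporting, and the replica-difference SE
(below) uses the sum convention by default for the same reason.

### Error propagation

SEs of ΔG(T) come from the first-order delta method with independent
errors in ΔH, ΔCp and *T*_m; the partial derivatives are analytic and are
cross-checked against finite differences in the tests. When all input SEs
are zero the propagated SE is exactly zero.

### Holoproteins

A tightly bound cofactor stabilises the fold by the free energy of
emptying the binding site. With free-ligand concentration [L] and
association constant K_b(T),

ΔG_holo(T) = ΔG_apo(T) + RT·ln(1 + K_b(T)·[L]),

which reduces to the apo stability at [L] = 0; a saturating variant
RT·ln(K_b[L]) is available for K_b[L] ≫ 1. K_b(T) follows the integrated
van't Hoff relation with ΔH_bind(T) linear in temperature (constant
ΔCp_bind); a constant-ΔH variant is selectable, and all variants coincide
at the reference temperature. Because the van't Hoff description assumes
an intact binding site, holo stabilities above the first apo melting
temperature are flagged unreliable: the scalar API warns, the curve API
returns an explicit boolean mask. The holo ΔCp_unf can be estimated as
ΔCp_apo + ΔCp_diss with ΔCp_diss = −ΔCp_bind.

### Populations and thermograms

State fractions come from the sequential partition function
Q = 1 + K₁ + K₁K₂ (two-state: 1 + K), evaluated in log space via a
softmax over −ΔG_cum/RT so that stabilities of ±50 kcal/mol and beyond
neither overflow nor lose row-normalisation (rows sum to 1 within 1e−12).

The calorimetric thermogram is reported as the apparent excess heat
capacity: the transition excess plus the population-weighted baseline
Σχᵢ·ΔCp_cum,ᵢ (folded-state Cp taken as the zero reference, matching how
DSC excess thermograms are baselined). The excess term is evaluated
analytically as the Boltzmann variance of the cumulative excess enthalpy,
Var_χ(H)/(RT²) — algebraically identical to Σ(dχᵢ/dT)·Hᵢ and, for a
two-state system, to χ_F·χ_U·ΔH(T)²/(RT²). The analytic curve is checked
against a 0.01 K central-difference derivative of the population-weighted
enthalpy to 1e−4 kcal/(mol·K).

## Replica statistics

Each replica contributes one time-averaged enthalpy (frames with time
strictly greater than the equilibration cut; default cut 0, as productive
trajectories are assumed equilibrated — note a frame at exactly t = 0 is
then excluded). Replica means are ensemble-averaged with sample SD (n−1)
and SE = SD/√n. ΔH is the difference of ensemble means at a common
temperature; its SE defaults to the sum of the two ensemble SEs
(quadrature optional, and never larger). Energies declared in kJ/mol at
ingestion are converted to kcal/mol (÷4.184).

ΔCp is the slope of an unweighted OLS line through the (T, ΔH) points —
three temperatures in the standard workflow. Two points give the exact
slope with SEs flagged as undefined (returned as 0 with `exact_fit=True`).
When per-point SEs are known (they always are, from the replica spread),
the slope/intercept SEs are obtained by propagating those known errors
through the OLS estimator rather than from the residuals: with three
points the residual variance has a single degree of freedom and its ±3·SE
interval covers far less than the nominal level, while the propagated
version is well calibrated. Residual-based SEs remain the default when no
per-point SEs are supplied. ΔH at *T*_m comes from evaluating the fitted
line, with the exact prediction SE from the OLS covariance.

The sample-size planner inverts SE = SD/√n: n = ⌈(SD_pilot/SE_target)²⌉,
floored at 1. It reproduces the study's replica counts (e.g. a pilot SD
of ~63 kcal/mol and a 10 kcal/mol target give 41 ≈ the 40-replica folded
ensembles; noisier unfolded boxes need ~100).

The overcompaction check fits Rg versus time by OLS and converts the
slope into a relative change over the window (slope·span/mean Rg); a
relative decrease beyond 5% (default) fails. The threshold is a package
default — published analyses report only that no significant compaction
occurs, without a numeric criterion.

## Ensemble geometry

The molecular diameter is the maximum pairwise inter-atom distance, over
all atoms by default (a CA-only mode exists for speed). The O(n²)
brute-force distance matrix is the reference; for larger models the pair
search is restricted to convex-hull vertices, which is exact and verified
against brute force in the tests. Extended-conformer filtering removes
models whose diameter lies strictly above the nearest-rank percentile
threshold (default: top 10%), so tied diameters are never removed and an
ensemble of identical conformers survives intact; a fixed-cutoff mode is
available. The cubic box edge is the largest post-filter diameter plus
the solvent margin on both sides (default 1 nm per side); only cubic
boxes are produced, box geometry being otherwise unconstrained here. Rg
is mass-weighted about the centre of mass, with unit masses as fallback.
Box composition matching compares protein/water/ion/cofactor counts
exactly — enthalpy differences are meaningful only between boxes with
identical molecular inventories.

PDB ensembles (MODEL/ENDMDL) are read and written through biotite; a
directory of single-model files is accepted equivalently.

## Synthetic generators

The replica-enthalpy generator draws folded means from
N(base(T), sd_f) and unfolded means from N(base(T) + ΔH(T), sd_u) with
ΔH(T) = ΔH(T_ref) + ΔCp·(T − T_ref) and base(T) linear in T. Defaults
mirror the study conditions: 40 folded / 100 unfolded replicas at three
temperatures spanning 20 K around T_ref = 320 K, base enthalpy of order
−10⁵ kcal/mol, ΔH(T_ref) = 80 kcal/mol, ΔCp = 1.5 kcal/(mol·K), and
noisier unfolded boxes (sd 60 vs 20 kcal/mol) since unfolded
conformations require larger solvent boxes. Normal noise is the minimal
assumption consistent with mean ± SE reporting. What the generator does
*not* emulate: autocorrelation within trajectories, force-field bias,
finite-size/solvent artefacts — so parameter-recovery tests demonstrate
the statistical pipeline, not MD accuracy.

Chain ensembles are self-avoiding random walks with fixed 3.8 Å steps
(the trans-peptide CA–CA virtual bond) and a 4.0 Å excluded-volume cutoff
between non-adjacent residues, grown by per-step rejection with chain-level
regrowth on dead ends. They are CA-only and geometrically, not
energetically, realistic: sufficient to exercise diameter filtering and
box sizing, not a coil-library ensemble.

## Assessment

Method accuracy is summarised by OLS of calculated (y) on experimental
(x) values per quantity, with R² the squared Pearson correlation. The
bundled benchmark table carries the published in-text values for ten
systems plus outlier rows (four T4 lysozyme systems and nuclease at
pH 4.1) that are excluded from fits by flag, not auto-detection — the
outlier designation follows the published analysis by inspection. Cells
not available in the source compilation (e.g. the holoflavodoxin
calculated ΔH for the specific cofactor parametrisation, and absolute
lysozyme values) are left empty and excluded from fits; the ΔH fit is
therefore reported over nine systems, while the ΔCp and ΔG fits use the
full ten.

## Numerical choices and limitations

- Overflow safety: populations via log-sum-exp; ln(1 + K_b[L]) via log1p.
- Thermogram derivative cross-check step: 0.01 K central difference.
- Nearest-rank percentile with strict-inequality removal (ties kept).
- min_sample_size guards exact squares against float fuzz (50/10 → 25).
- Not covered: fitting experimental DSC traces, temperature-dependent
  ΔCp, pressure effects, autocorrelation/block averaging of trajectories,
  and anything upstream of replica enthalpies (force fields, solvation,
  sampling).
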