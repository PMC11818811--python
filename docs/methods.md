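# Methods

`calixtherm` implements the complete data-analysis chain of a host–guest
binding-thermodynamics study: a macrocyclic receptor (a lower-rim
functionalised calix[4]arene carrying two tertiary-amide and two
phenanthridine donor groups) binding alkaline-earth cations (Mg²⁺, Ca²⁺,
Sr²⁺, Ba²⁺) in acetonitrile, methanol and ethanol. This note records the
models, the numerical choices, and what the synthetic data do and do not
establish.

## Equilibrium model and speciation

Binding models are sets of components (ligand L, cations) and complex
species with cumulative stability constants β on a log₁₀ scale. Constants
are concentration quotients (mol dm⁻³ standard state); activity
coefficients are not applied, consistent with the dilute, inert-electrolyte
working conditions of the experiments being modelled. Only 1:1-type and
competitive models are in scope; the stoichiometry matrix admits small
integer coefficients but no ionic-strength corrections.

Speciation solves the component mass balances

  T_j = f_j + Σ_s ν_sj · 10^{log β_s} · Π_k f_k^{ν_sk}

for the free concentrations f. The iteration runs in log-free-concentration
space (positivity by construction) with a damped Newton step: the log-step
is capped at 3 and halved until the worst relative residual decreases.
Components with zero analytical total are eliminated together with every
species that contains them. Convergence is declared at a relative residual
of 10⁻¹² (default; 200 iterations maximum), relative to each component's
total.

Pure 1:1 models bypass Newton entirely via the closed-form quadratic,
written to avoid cancellation at large K:

  [ML] = 2 T_L T_M / (b + √D),  b = T_L + T_M + 1/K,
  D = (T_L − T_M)² + 2(T_L + T_M)/K + 1/K²

The expanded discriminant D matters: the textbook form b² − 4 T_L T_M loses
roughly half the mantissa once K(T_L + T_M) ≫ 1, which is exactly the
regime (K ≈ 10¹¹) these titrations live in. Note that free concentrations
reported at near-complete binding are differences of near-equal numbers and
are accurate in an absolute, not relative, sense.

Titration totals follow two volume models. Cuvette mode is simple mixing
into a growing volume, c_i = (c_cell·V₀ + c_tit·V_i)/(V₀+V_i). Displacement
(perfusion) mode models a fixed-volume calorimeter cell where each
injection expels an equal volume of cell content:
c ← c(1 − v/V₀) + c_syr·(v/V₀). Units are mol dm⁻³ and cm³ throughout (ITC
injections in mm³).

### Equivalence-break detection

Titration curves of very stable complexes are linear up to the equivalence
point and flat after it. The break is located by continuous two-segment
piecewise-linear least squares (grid search plus bounded refinement, ties
resolved toward molar ratio 1). A break is only reported when the
two-segment model beats a single line in an F-test at α = 0.01. The
confidence interval is a pairs (case-resampling) bootstrap — residual
resampling was rejected because the two-segment model is deliberately
misspecified for smooth low-K curves, and resampling its residuals as
i.i.d. noise understates the break uncertainty exactly where the flag
matters. Intervals wider than 0.2 in molar ratio are flagged weak.

## Multiwavelength titration fitting

Global fits of UV-absorption or fluorescence titrations use variable
projection. For a trial value of the free log K, species concentrations
along the titration come from the speciation solver; the molar responses
(Beer–Lambert ε for absorbance, linear emission coefficients for
fluorescence) are the conditionally optimal linear least-squares solution;
the outer optimiser minimises the Frobenius residual over the constant
alone. Non-negativity of molar spectra is enforced by default (physical for
absorption spectra; switch it off for difference spectra). Unit weights are
used across wavelengths and titration points.

The one-dimensional outer problem is solved on log₁₀ K ∈ [−2, 16] by a
0.5-unit grid pass followed by bounded scalar minimisation; the grid pass
is not an optimisation nicety but a correctness requirement, because the
profile is flat over decades in the steep-isotherm regime and a bare
bounded search can stall on the flat shelf. Several free constants fall
back to Nelder–Mead.

Standard errors come from the numerical second derivative of the profile
sum of squares (step 0.05 log units): Var(log K) = 2σ̂²/(d²SSQ/dθ²) with σ̂²
the residual mean square. A constant is flagged unidentifiable when its SE
exceeds 1 log unit, or when the SSQ at either search bound lies within the
95% likelihood-ratio band (3.84 σ̂²) of the minimum — the latter catches the
one-sided flat profiles of very stable complexes where local curvature at
the (noise-determined) optimum is misleading. This reproduces the
experimental finding that direct titrations cannot determine constants
around 10¹¹ at 10⁻⁴ mol dm⁻³ ligand, while competitive titrations against
a fixed reference complex (the Na⁺ complex, log K = 10.50) can.

Fluorescence data are fitted with the same linear-response model;
excitation/emission overlap is handled by subtracting a least-squares
scaled blank spectrum within a user-declared window (no inner-filter
model). Replicates are fitted separately and summarised as mean ± standard
error of the mean, mirroring the experimental practice (N = 3–5).

## Isothermal titration calorimetry

The heat of injection i in a displacement cell is

  q_i = V₀ · Σ_s ΔH_s · ([s]_i − [s]_{i−1}(1 − v_i/V₀)) + offset

summed over all complex species — the (1 − v/V₀) factor accounts for
complex expelled with the displaced volume. Heats are mJ internally;
enthalpies convert to kJ mol⁻¹ at the reporting boundary; T defaults to
298.15 K. The first injection is discarded by default (standard practice
for syringe-diffusion artefacts); the dilution offset is a fitted constant
per injection, and measured blank titrations can be subtracted instead.

`fit_itc_1to1` runs bounded nonlinear least squares over (log K, ΔH,
offset[, n]); n is fixed at 1 by default because the 1:1 stoichiometry is
established independently by the spectroscopic break analysis. Standard
errors come from the Gauss–Newton covariance σ̂²(JᵀJ)⁻¹. K is flagged
unidentifiable when the Wiseman c-value (K·c_cell·n) exceeds 10⁴ or
SE(log K) > 1: the isotherm is then a step whose shape carries no
information on K, although ΔH (the step height) remains well determined.
`fit_enthalpy_only` implements the pre-equivalence estimator: below a
cumulative-ratio cutoff (default 0.8) of a steep isotherm, every mole of
delivered titrant binds, so q_i per mole injected estimates ΔH directly;
it warns when a supplied K implies a c-value under 10³, where the estimate
biases low. Competitive ITC holds the reference complex's (log K, ΔH)
fixed — the reference enthalpy is not in the published tables and is a
required configuration input.

Note one subtlety of the displacement cell: unbound ligand washed out
before it binds is lost, so the cumulative heat at saturation equals
V₀·c_L·ΔH only in the small-injection (concentrated-syringe) limit; with a
syringe only ~10× the cell concentration the loss term reaches several
percent.

## Thermodynamic quantities

ΔrG° = −RT ln10 · log K with R = 8.31446 J K⁻¹ mol⁻¹ and T = 298.15 K
unless overridden; ΔrS° = 1000(ΔH − ΔG)/T; TΔS = ΔH − ΔG. Linear error
propagation treats log K and ΔH as independent: σ(ΔG) = RT ln10 σ(log K),
σ(ΔS) = 1000·√(σ(ΔH)² + σ(ΔG)²)/T (validated against Monte-Carlo
propagation in the tests). Report tables round as the experimental
literature does (ΔG/ΔH to one or two decimals, ΔS to the integer).
Reproducing published tables from their rounded mean log K can move the
last printed digit of ΔG by one unit, because the originals were averaged
per replicate before rounding; the bundled reference table carries both
the measured inputs and the printed derived values for this reason.

Selectivities are K ratios, optionally rounded to the nearest power of
ten. Stability-ordering strings join cations with "≈" when their constants
differ by less than max(2 × combined SE, 0.2 log units). The 0.2-unit
practical-equivalence margin is a deliberate addition: published standard
errors of competitive titrations are a few hundredths of a log unit, far
below between-method repeatability, and a 1.6-fold difference in K is not
a meaningful selectivity. With this rule the package reproduces the
qualitative orderings reported for all three solvents.

## MD trajectory post-processing

Trajectories are role-labelled (cation, 4 ether O, 2 carbonyl O, 2
phenanthridine N, solvent head/tail atoms, other), which keeps the
analysis independent of any force field or engine; the counts per role are
configurable. No periodic-image search is applied by default (the complex
is whole in the box); distances are Å, frames 0-indexed.

- **Coordination**: a donor coordinates the cation within a per-role
  cutoff, default 3.0 Å for O/N–cation contacts (no cutoff is given in the
  source protocols; 3.0 Å covers typical first-shell M²⁺–O/N distances).
  Time averages carry block-averaged standard errors (5 blocks) to respect
  serial correlation.
- **Coordination matrix**: per frame, the 2 cation–carbonyl-O distances, 4
  cation–ether-O distances, 2 cation–phenanthridine-N distances, plus 2
  carbonyl angles. The angle convention is the vertex at the carbonyl
  carbon between the C=O bond and the C→cation direction, chosen because
  it captures how the carbonyl dipole points at the ion; the carbonyl
  carbon is identified as the nearest bonded carbon ('other' role) to each
  carbonyl oxygen.
- **Inclusion state**: the cavity (aromatic cone) is the side of the
  ether-oxygen least-squares plane opposite the cation. A solvent molecule
  occupies it when both tagged atoms are within 7.5 Å of the cation and on
  the cone side; orientation is HEAD_IN when the head atom (nitrile N or
  hydroxyl O) is nearer the cation than the methyl tail, TAIL_IN otherwise
  (ties → TAIL_IN with a warning). Multiple simultaneous candidates keep
  the nearest and warn. Exchanges are changes of occupant identity with
  EMPTY gaps bridged, so a molecule leaving and returning is not an
  exchange.
- **Representative structures**: the coordination matrix is column-centred
  and decomposed by SVD; k-means (20 restarts, fixed seed) runs on the
  first two principal-component scores with k chosen by silhouette over
  k ∈ 1..6 (k = 1 scores 0; ties take the smaller k). Each cluster's
  representative is the frame nearest its centroid in score space,
  reported in descending population order. The clustering algorithm and k
  are not specified in the source protocols; these are this package's
  declared defaults.
- **Plane geometry**: total-least-squares (orthogonal-regression) planes
  via SVD of the centred points — the normal is the smallest principal
  direction; collinear point sets are rejected. Geometry reports give
  unsigned distances from the ether-oxygen plane to the cation and to the
  solvent centre of mass (mass-weighted), plus the cation–solvent
  distance, and verify the triangle inequality
  |d(plane,solvent) − d(plane,cation)| ≤ d(cation,solvent). Distances are
  reported unsigned, matching the published table convention.

## Synthetic data

The generators define the study conditions used by the test and acceptance
suites; all are seeded and byte-reproducible, and every dataset carries a
serialisable ground-truth sidecar.

- **Titration spectra**: ligand spectrum as two Gaussian bands (330 and
  357 nm); each complex inherits them red-shifted and intensified
  (bathochromic + hyperchromic response, default +10 nm and ×1.35), with
  later complexes in a model getting geometrically smaller shifts so that
  competing species stay spectrally distinguishable — the premise on which
  competitive determinations rest. Responses follow Beer–Lambert from the
  speciation forward model with homoscedastic Gaussian noise (no noise
  model is published; 0.2–0.3% of the maximum response mimics a good
  benchtop spectrophotometer). Default protocol: 1.2×10⁻⁴ mol dm⁻³ ligand,
  V₀ = 2.2 cm³, ~10× titrant, 16–20 points to 2 equivalents — the cuvette
  conditions of the study.
- **ITC**: delegates to the calorimetric forward model; V₀ = 1.42 cm³,
  ~25 × 12 mm³ injections. The instrument-validation system
  (18-crown-6 + Ba²⁺: K = 5772 dm³ mol⁻¹, ΔH = −32.2 kJ mol⁻¹) is the
  canonical round-trip target; 1% noise is interpreted per-injection
  (relative) for that benchmark.
- **Trajectories**: donors placed at template distances (ether/carbonyl O
  2.4 Å, N 2.6 Å) around a cation 0.8 Å below the ether plane, carbonyl
  carbons 1.23 Å beyond their oxygens, with Gaussian positional jitter;
  the occupant solvent sits on the cone axis (head 2.8 Å/tail 4.3 Å from
  the cation, or swapped for TAIL_IN) and idle solvent molecules are
  parked outside the cavity rule. The schedule of states and occupant
  identities is exact ground truth.

What passing on these data shows — and does not. The generators share the
forward models with the fitting code by design (round-trip testing), so
recovery tests establish correctness of the estimators under the stated
model, not robustness to real-data pathologies: baseline drift, wavelength
miscalibration, heteroscedastic photon noise, inner-filter effects,
incomplete baseline separation of ITC peaks, force-field artefacts or
genuinely diffuse cavity occupancy are all outside what these tests can
certify. The identifiability flags, by contrast, are statements about
information content and transfer directly.

## Problem sizes

The default suites use 16–40-point titrations over ~50 wavelengths, 25
injection thermograms, and 100 synthetic trajectories of 40 frames — sizes
chosen to exercise every code path with comfortable statistical margins
while the full test suite and the acceptance script each run in well under
a minute on one CPU.

## Known limitations

- No polynuclear or higher-order species beyond what the stoichiometry
  matrix expresses; no ionic-strength or activity corrections.
- Factor-analysis rank estimation, multi-state photophysics and
  quantum-yield modelling are out of scope for the spectral fits.
- ITC inputs are integrated per-injection heats; baseline integration of
  raw power thermograms and multi-site models are not provided.
- The MD analysis post-processes labelled coordinates only; it neither
  runs dynamics nor computes energies, and published DFT-derived distance
  tables are treated as reference inputs, not reproducible outputs.
- The enthalpy-only ITC estimator assumes effectively stoichiometric
  binding; its bias warning depends on the user supplying an approximate
  K.
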