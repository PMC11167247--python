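# Methods

This note documents the models implemented in `patchscreen`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Solvent-accessible surface and patches

SASA uses the Shrake–Rupley dot method: for each atom, dots are placed on
the sphere of radius (vdW + probe) and a dot is retained iff it lies
outside every other atom's expanded sphere. Defaults: probe 1.8 Å, 960
dots/atom, Bondi-style element radii (C 1.70, N 1.55, O 1.52, S 1.80, …;
unknown elements 1.70 Å with a warning). Each retained dot carries an area
weight of (sphere area)/(dots per atom); atom SASA is the summed weight,
residue SASA the sum over its atoms. Doubling the dot density moves totals
by well under 0.5 % on the test fixtures.

Dot lattices (a deterministic golden-spiral construction) are oriented per
atom in a frame built from two molecule-intrinsic vectors — centroid→atom
and atom→nearest-neighbour (index tie-break) — so the retained dot set, and
therefore every area downstream, is exactly equivariant under rigid
rotation and translation of the input. The only exception is perfectly
collinear arrangements, where the frame falls back to an arbitrary
perpendicular.

Surface values: each dot inherits its residue's hydrophobicity from a
shipped Black–Mould normalised scale shifted so Gly = 0 (apolar residues
positive, polar negative); the hydrophobic patch cutoff of 0.09 operates on
this scale. Electrostatic values are a bare Coulomb sum φ = Σ 332.06·qᵢ/(ε·dᵢ)
kcal/mol/e over formal charges at pH 6 (Asp/Glu −1, Lys/Arg +1, His +0.1,
termini ±1 on annotated chain ends), each placed on a representative
side-chain atom (NZ, CZ, CG, CD, NE2) with CA/first-atom fallback for
coarse models. The dielectric is distance-dependent (ε = 4d) by default; a
constant value can be supplied instead, which is what the examples use for
one-bead toy structures where 4d suppresses all charge patches. This
Coulombic model is a deliberate simplification — it is not a
Poisson–Boltzmann surface and absolute potentials should not be
over-interpreted; only the thresholding/clustering logic downstream is
meant to be quantitative.

Patch detection thresholds dots per class (hydrophobic ≥ 0.09 kcal/mol;
positive φ ≥ +30; negative φ ≤ −30 kcal/mol/e; thresholds inclusive),
single-linkage clusters them with adjacency radius 1.9·√(mean dot weight)
(auto-scaled to dot density, overridable), and drops clusters below 30 Å².
Positive and negative classes are mutually exclusive by sign; a dot may
belong to a hydrophobic and one charge patch. Clustering is verified
against an exhaustive connected-components oracle over random fixtures.

## Charge descriptors

Net charge is the standard Henderson–Hasselbalch sum with the EMBOSS pKa
set (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1; N-term 8.6,
C-term 3.6), termini included by default since each Fv chain is treated as
a free polypeptide. The isoelectric point is the unique root of the
monotone charge–pH curve, found by Brent's method on [0, 14] to 1e-6.
FvCSP is the exact product of the chain charges and Fv_chml their exact
difference; both are computed at formulation pH 6 by default. The
structure-derived descriptors the screen computes itself are the patch
areas/counts and the normalised hydrophobic score Σres_hyd/Σres_ASA ∈ [0,1].
External descriptors without open definitions (aggregation-propensity
scores, zeta potential, buried interface area, ensemble charge, literature
viscosity models) are not re-implemented; they join the descriptor table as
pass-through columns and participate in ranking when present.

## Mutation design

Residues are ranked per patch class by their class contribution, terminal
residues excluded (they are trivially flexible and chain termini carry
their own charges), ties broken by chain then file order for
reproducibility. Defaults propose: hydrophobic {F,W,Y,L,V,I,M} → {L, Q}
(L never proposed onto itself), positive {K,R} → {E, G}, negative with the
paired rule D → N, E → Q (isosteric amide swaps). `top_n` (default 5 per
class) has no canonical value; it is a config knob.

Structural recomputation after mutation is deliberately naive: the residue
is relabelled and its side chain truncated past Cβ, then SASA/patches are
recomputed with the new residue's scale and charge values. No rotamer is
built, so mutant patch areas are screening-grade approximations; the
sequence-level descriptor path (net charges, FvCSP, Fv_chml, pI) is exact.

## Triage ranking

Each scored descriptor column is min–max normalised over the panel
(undefined for constant columns, which are dropped with a warning — a
constant carries no ranking information; columns with missing values are
likewise dropped panel-wide so all scores share one scale). The score sums
NDV for positive-direction descriptors and (1 − NDV) for negative-direction
ones, each times a weight (default 1). Scores lie in [0, Σ weights], are
invariant to affine rescaling of any raw column, and the panel is ranked
ascending with ties sharing a rank and ordered by variant id. The default
direction set used by the structure screen contains the two descriptors the
screen computes itself (normalised hydrophobic score and hydrophobic area,
both positive-direction); the full eight-descriptor direction map ships as
`triage.DEFAULT_DIRECTIONS` for panels that carry the external columns.

## Measurement models

**Diffusion interaction parameter.** D_app = D₀(1 + k_D·c) is fit by
ordinary least squares; because the model is multiplicative in k_D, the
slope equals D₀·k_D and k_D = slope/intercept, with first-order error
propagation for its standard error. Internally k_D is mL/mg; it is also
reported in mL/g against the customary −15 mL/g attractive-interaction
threshold (strict inequality: a fit at exactly −15 mL/g is not flagged).
Fits with non-positive intercepts are rejected.

**Viscosity.** η = Y₀·e^(kC) is fit by nonlinear least squares on the cP
scale, initialised from a log-linear regression, with weights 1/η²
(rheometer error is proportional to the reading). The weighting keeps the
fit on the stated linear-scale model while making the reported standard
errors calibrated under relative noise: joint 95 % t-intervals (df = n−2)
cover the generating parameters in ≈91 of 100 simulated series at 5 %
noise, versus ≈56 of 100 for the unweighted covariance. The concentration
at which the fit crosses 30 cP ("acceptable viscosity") is reported as
ln(30/Y₀)/k when defined, 0 when Y₀ ≥ 30 cP, and absent for k ≤ 0.
Shear-rate dependence is not modelled; series are treated as
shear-independent apparent viscosities.

**AC-SINS.** Traces are smoothed with a moving average (window 5 nm,
converted to an odd number of grid points), the peak located at the grid
argmax and refined by 3-point quadratic interpolation so shifts are not
quantised to the 1 nm grid. Δλ = λmax(sample) − λmax(control); Δλ > 10 nm
flags self-association risk; a control peaking at ≥ 535 nm invalidates the
assay; a peak on the grid boundary raises an unreliable-peak error.

**nanoDSF.** The 350/330 ratio is smoothed (5-point moving average) and
differentiated (central differences). Melting temperatures are derivative
peaks with prominence above max(5 % of the derivative range, 6·MAD of the
derivative) — the robust MAD floor keeps instrument ripple out of the peak
list without affecting clean traces; at most three are reported, ascending.
T_onset is the lowest temperature at which the derivative first reaches
10 % of the first peak's height; T_agg comes from the scattering channel by
the same rule. A flat trace yields an empty result, not an error.

**Correlations.** Pearson R per descriptor × measurement pair over complete
pairs (≥ 3 required, else the cell is undefined), |R| ≥ 0.8 flagged strong,
pair counts reported.

## Synthetic data

Generators are pure functions of (parameters, seed) and each returns the
ground truth alongside the dataset; at zero noise every analysis operation
recovers its generator's parameters exactly (to float/optimizer tolerance).

Toy structures place one Cα-like bead per residue (3 Å radius) on a
spherical Fibonacci lattice of radius 9 Å (or an ideal helix), background
residues Ser, cluster members Trp/Lys/Asp by class, clusters grown as
contiguous lattice neighbourhoods from mutually distant seeds. A buried
neutral core atom fills the shell interior so the lattice presents a single
closed outer surface. Designed hydrophobic clusters are recovered exactly
by patch detection (hydrophobicity is a per-residue value); charge patches
contain the designed residues plus whatever neighbourhood the Coulomb
potential reaches, so tests assert containment rather than equality.
Measurement generators invert the fitted models: D_app lines with additive
Gaussian noise scaled by D₀, exponential viscosity curves with relative
Gaussian noise, Gaussian plasmon peaks on the 450–650 nm / 1 nm grid, and
sums of logistic transitions on the 20–95 °C / 0.5 °C ramp with an optional
scattering channel. Default simulation settings mirror the measurement
protocols (DLS at 0.5–20 mg/mL, ~2 % noise; viscosity to 120 mg/mL, ~5 %
noise; Monte-Carlo checks use 100–200 replicates).

What the generators do **not** emulate: real antibody geometry and packing
(one bead per residue), conformational coupling between mutations and
patches, instrument drift or outliers (noise is i.i.d. Gaussian), and any
relationship between descriptors and measured viscosity — closure tests
therefore demonstrate that the analysis recovers what the models generate,
not that the screen's predictions hold for real molecules.

## Known limitations

* Antibody numbering (Kabat) is not computed; CDR/FWR region maps are
  supplied as CSV. Region-dependent outputs are only as good as that map.
* The hydrophobic and electrostatic surface values are simple per-residue
  projections; absolute patch areas depend on the structure-preparation
  protocol of whatever produced the input PDB and are not comparable across
  preparation pipelines.
* The naive Cβ-truncation mutant mode underestimates steric rearrangement;
  it is a triage device, not a modelling replacement.
* The per-chain charge model treats each Fv chain as a free polypeptide
  with both termini; for chains that continue into constant domains the
  termini switch should be turned off.
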