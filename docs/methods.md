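# Methods

## Models

**Thermal decomposition of B-factors.**  Each response y (a B-factor in Å²
or a displacement in Å) is regressed on the data-collection temperature T
(Kelvin) with one of two forms: linear, `y = a + k·T` (ordinary least
squares), or single-exponential, `y = A·e^(k·T)`, fitted by nonlinear least
squares on the *untransformed* residuals.  The exponential amplitude A is
the value extrapolated to zero Kelvin (written B0 when y is a B-factor);
k is the thermal constant (K⁻¹).  The log-linear fit of (T, ln y) serves
only as the initializer: points with y ≤ 0 are dropped from the seed but
retained in the objective.  Refinement is a damped Gauss–Newton
(Levenberg–Marquardt) iteration on the 2×2 normal equations, solved in
closed form per series and vectorised across series, so per-residue fits
over hundreds of residues and dozens of structures run in one pass.
Convergence: relative loss change below 1e-10 (configurable), cap 200
iterations; the damping factor divides by 3 on an accepted step and
multiplies by 10 on a rejected one.  A series whose seed is inadmissible
(fewer than two positive observations) or that stalls at maximal damping
is reported with `converged = False` rather than dropped.

Replicates enter every fit as separate points: pre-averaging would shrink
n and distort the confidence intervals.

**Reported statistics.**  For linear fits the Pearson r is that of (T, y);
for exponential fits it is between observed and model-predicted values
(the natural analogue of a goodness-of-fit r for a nonlinear model — the
alternative, r(T, y), is monotone-transform-sensitive and is exported
alongside by the correlation stage where needed).  All correlation CIs use
the Fisher z-transform (95%), and two-tailed p-values come from the
t-distribution on n−2 df.  No multiple-testing correction is applied; the
p-values are descriptive.

**Normalization.**  `B_norm = B_obs / B_avg`, computed within one selection
of one structure (side chains normalized by the side-chain average, etc.).
The profile mean of B_norm is exactly 1 and the transform is invariant to
rescaling B by any positive constant.  Consequence used throughout: if all
residues share one thermal constant and the spatial B0 profile does not
change with temperature, the normalized profiles are temperature-invariant
and the per-residue exponential fits of B_norm return k ≈ 0.  A flat
norm-k profile is therefore the fingerprint of a uniform (rigid-body-like)
thermal response.

**Superposition and displacement.**  Rigid alignment is the closed-form
SVD (Kabsch) solution restricted to proper rotations (determinant
correction); fitting is unweighted on Cα atoms by default (backbone
optional).  Atoms pair by (chain, residue number, insertion code, atom
name) and must agree in residue name — mutated residues are skipped and
logged, which is what makes the same code usable on heterogeneous
depositions.  Per residue, `d_calpha` is the distance between paired Cα
atoms and `d_side_chain` the unweighted mean of per-atom distances over
matched side-chain heavy atoms (mean of distances, not distance of
centroids: robust to partially modelled side chains).  Glycine contributes
no side-chain value.

Note an intrinsic property of superposition-based displacement fields: the
rigid refit absorbs the net (mean) component of any planted displacement
field, so recovered per-residue displacements deviate from a planted field
by up to roughly the norm of its mean vector (≈ |field|/√n_residues for
random directions).  The tests account for this; users comparing to
external ground truth should too.

**Atom classification.**  Amino-acid N/C/O (and OXT by default) are
backbone, CA is its own class, remaining amino-acid heavy atoms are side
chain; HOH/WAT oxygens are waters; single-atom ionic residues (CA, MG, …)
are ions; any other het group is a ligand; hydrogens are classified as
such and excluded from every downstream selection.  Altloc groups collapse
to one record before analysis — highest occupancy wins, ties go to the
lexicographically smallest altloc ID (deterministic).  B-factor averages
are unweighted and exclude zero-occupancy atoms (they carry no density
evidence); occupancy weighting is deliberately not applied, mirroring the
convention of the standard B-averaging tools, and the exclusion rule is a
config flag.

**Water tracking.**  After alignment, water oxygens pair by mutual nearest
neighbour within a cutoff (default 1.0 Å — below a hydrogen-bond length,
so adjacent waters cannot swap identities; configurable).  Mutual-NN pairs
are one-to-one by construction; accepting them in ascending distance order
makes the table deterministic.  A reference water is *conserved* when
matched in every structure of the series (a relaxed fraction is
available).  Component fits regress the per-structure mean B of a
component (all waters, conserved waters, ions, ligand atoms) on T with the
exponential model.

## The synthetic-data generator

The generator emulates a multi-temperature crystallographic study: default
design 9 temperatures (100–300 K, 25 K steps) × 3 replicates.  Ground
truth per residue: B0 log-normal (median 6 Å², σ_ln 0.4); k either drawn
uniformly in [0.004, 0.006] K⁻¹ or fixed at 0.005 K⁻¹ (the uniform-k null
mode); displacement coefficient δ half-normal (sd 0.0015 Å·K⁻¹) with a
fixed random unit direction per residue.  Side-chain atoms carry 1.3× the
residue B0 (side chains run hotter than backbones).  Waters get per-water
B0 (log-normal, median 8 Å²); ion and ligand B0 are constants; all
non-protein atoms share k = 0.005 K⁻¹.  Noise: isotropic coordinate noise
(sd 0.05 Å, roughly the coordinate uncertainty of a well-refined 1.5 Å
structure) and multiplicative B noise (sd 5%).  Each replicate sits in its
own rigid frame (rotation up to 15°, shift up to 4 Å), as independently
mounted crystals would.

Water retention follows a schedule p(T), linear from 1.0 at the lowest to
0.5 at the highest temperature.  Retention is implemented as a nested
threshold model: each water draws one order parameter u ~ U(0,1) and is
present at temperature T iff u ≤ p(T).  Marginally this is Bernoulli(p(T))
per structure; across the series it makes water loss ordered — the same
weakly-bound waters disappear first, as in real crystals — so the
conserved-water set is the fraction surviving at the top temperature
rather than the near-empty intersection independent drops would give.

In *planted* mode the displacement coefficient is tied to the B0 field
(δ = 0.01·log₁₀(B0) Å·K⁻¹) instead of drawn independently.  This mode is a
positive control for the correlation stage; its amplitude is set well
above the displacement measurement noise floor (slope uncertainty
≈ 2e-4 Å·K⁻¹ at the default coordinate noise) so that the control tests
detection, not noise.

**Geometry.**  The base structure is a coarse-grained poly-alanine-like
chain: backbone N/CA/C/O plus a one-atom CB side chain (every 8th residue
is glycine), laid out on a gently coiled curve (curvature radius 25 Å —
self-avoiding and far from collinear, so Cα-only superposition is well
posed), with a six-atom benzamidine-like ring, one calcium ion, and
2×n_residues waters rejection-sampled ≥ 2.4 Å from all other atoms.
Pseudo-bond lengths are ≥ 2.0 Å: the model is a stand-in for the analysis
geometry (atom classes and positions), not for covalent stereochemistry —
no stage of the pipeline consumes bond lengths or angles.

In-memory models are quantized to PDB fixed-column precision (coordinates
1e-3 Å, B and occupancy 1e-2) whether or not files are written, so results
never depend on the file round trip.  Given the same configuration and
seed, output files are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: anisotropic/TLS displacements, the ~210 K
glass-transition break in B(T) (a single-exponential world by
construction), correlated motions between residues, radiation damage,
crystal-contact effects, altloc disorder, and real solvent structure.
Tests against the generator certify that the pipeline recovers the
parameters of its stated model, not that the model is complete for any
particular crystal.

## Numerical choices and degenerate inputs

- PDB B-field quantization (0.01 Å²) bounds achievable recovery: over a
  200 K span this corresponds to ~1e-4 K⁻¹ on k, and test tolerances are
  derived from that bound, not machine epsilon.
- A constant response under the linear model returns slope 0 with
  `converged = False` (r is reported as 0; the correlation is undefined).
- Zero variance in either variable makes a Pearson correlation an error,
  not a silent NaN.
- Residues present in fewer than two-thirds of the structures (threshold
  configurable) are omitted from per-residue fits and logged.
- Kabsch refuses fewer than 3 paired atoms; the reflection branch of the
  SVD optimum is excluded by the determinant correction.
- Exponential fits clamp k·T at ±600 inside the model evaluation to avoid
  overflow during line search; the clamp is far outside any physical k.

## Problem sizes

The test suite and the acceptance script run the full design (9 × 3) at
chain lengths of 40–60 residues for stage-level checks, 220–223 residues
for the correlation-stage nulls and the headline recomputation — the
length of the study protein — with 100 seeded repetitions for the
independence null and 200 for exponential parameter recovery.

## Known limitations

- Single-exponential only; no two-regime or multi-exponential fits, no
  TLS decomposition.
- Wilson B is read from file headers, never recomputed from intensities.
- PDB format only (no mmCIF), first MODEL only, no symmetry expansion.
- Water matching is positional; it will conflate distinct waters that
  trade places at distances below the cutoff.
- The deposited-series reproduction test requires the referenced PDB
  entries as local files; the library performs no network retrieval.
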