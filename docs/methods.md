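# Methods

## The adsorption model

Nonspecific adsorption of rAAV particles onto solid surfaces is driven
by two interactions: hydrophobic contact (stronger on high-contact-angle
surfaces) and electrostatics (attraction of the net-negative capsid to
positive surfaces, plus residual adsorption to negative surfaces
mediated by localized positive charge patches on the capsid). The
pipeline encodes this as an ordinary least-squares model of the
adsorption ratio A (% titer loss, clamped at 0):

    A = β0 + β1·θ + β2·ζpos + β3·ζneg + β4·S_hydrophobic + β5·S_hydrophilic

Three nested variants are fitted and reported together — S1 {θ, ζ},
S2 {θ, ζpos, ζneg}, final (adds the SASA descriptors) — because the
increase in R² across them is the evidence that sign-split
electrostatics and capsid surface chemistry each matter. Since ζ is a
linear combination of ζpos and ζneg, and the final variant is a column
superset of S2, R² is non-decreasing across variants on any dataset;
this is asserted as a property test.

### Zeta encodings

ζ is split into at most one nonzero component per observation. Two
encodings are supported and span the same model space (identical R²;
the ζneg coefficient flips sign):

* `magnitude` (default for fitting/reporting): ζ = −61.7 mV → ζneg =
  61.7. Both features are non-negative; the sign convention matches
  reporting "absolute values of positive and negative zeta potentials".
* `signed`: ζ = −61.7 mV → ζneg = −61.7.

Every coefficient report records which encoding produced it. The
synthetic-data generator evaluates the true response under the signed
encoding, because its default coefficient vector (ζneg coefficient
−0.42 %/mV) only produces physically plausible panels — moderate
adsorption on strongly negative surfaces, decreasing with ionic
strength — when ζneg carries its sign.

## Capsid outer-surface SASA descriptor

The capsid descriptor is the side-chain SASA of one viral protein (VP)
*in situ*, restricted to the particle exterior:

1. **Assembly expansion.** The deposited VP coordinates are replicated
   under the biological-assembly transforms (REMARK 350 BIOMT, or a
   plain-text transform file of 12 numbers per row). Parsed rotations
   are snapped to the nearest orthonormal matrix, since BIOMT records
   carry only 6 decimals; a deviation beyond 1e-4 is treated as a real
   error. The capsid center is the centroid of the full expanded
   assembly.
2. **Neighborhood selection.** The reference copy (default copy 0, the
   deposited orientation) plus every copy with a heavy atom within 6 Å
   of it. This captures all touching VPs while keeping the SASA problem
   tractable; the cutoff is configurable.
3. **SASA.** Shrake–Rupley quadrature over the whole neighborhood, so
   inner atoms and neighbor copies occlude realistically.
4. **Outer-shell sums.** Per-atom areas of the *reference copy's*
   side-chain atoms strictly farther than 105 Å from the capsid center
   are accumulated by residue category: hydrophobic (PHE, ILE, LEU,
   TYR, TRP, VAL, MET, PRO, CYS, ALA), acidic (ASP, GLU), basic (LYS,
   ARG). S_hydrophilic = acidic + basic; this merge is justified when
   the acidic and basic sums are strongly correlated across serotypes
   (`acidic_basic_correlation`, merge threshold |r| > 0.9 by
   convention). All other residues (SER, THR, ASN, GLN, HIS, GLY) are
   excluded from every category: the category lists are exhaustive by
   design, and category conservation (sum of categories ≤ total outer
   side-chain SASA) is a tested invariant.

The 105 Å threshold is a visual-inspection convention for AAV-sized
capsids (outer radius ~110–130 Å) and is a parameter, not a constant;
SASA is computed on the full neighborhood first and the radial filter
is applied only to the sums, so buried inner atoms still occlude.

### SASA engine numerics

* Quadrature: deterministic golden-spiral point set, default 960
  points/atom; probe radius 1.4 Å (water). Single-sphere areas are
  exact (no occlusion → accessible fraction 1); two-sphere
  configurations agree with the spherical-cap closed form to well
  under 1 % at 960 points.
* Radii: one frozen Bondi-type element table (C 1.70, N 1.55, O 1.52,
  S 1.80 … Å); crystal structures carry no hydrogens, so the
  convention is heavy-atom-only throughout. Unknown elements fall back
  to 1.70 Å with a logged notice.
* Side chain: every heavy atom except N, CA, C, O, OXT; GLY contributes
  nothing.
* Frames: with the point set fixed in the lab frame (default), SASA is
  exactly monotone under atom addition and exactly translation
  invariant, but rotation invariant only to quadrature resolution
  (~0.1–0.5 % at 960 points). `align_frame=True` first rotates the
  cluster into a deterministic principal-axes frame (axis signs fixed
  by the data's projection skewness, so the frame co-rotates exactly
  with the cluster), which makes results rotation invariant to floating
  point — at the cost of exact monotonicity, because adding an atom
  perturbs the canonical frame. Both properties cannot hold exactly at
  finite quadrature; the default favors monotonicity because assembly
  orientations are fixed by the input file. Degenerate principal-axis
  spectra (exactly symmetric clusters) make the canonical frame
  ill-defined.
* Coincident atom centers with identical radii are rejected
  (deduplication error) rather than silently double-counted.
* This is a solvent-accessible surface engine; absolute areas can
  differ from reduced-surface programs (e.g. MSMS) by a few percent.
  The contract downstream is the descriptor vector, and the regression
  is invariant to small consistent rescalings of it.

## Electrokinetics

* Zeta from mobility via Smoluchowski: ζ = μη/(ε0εr), valid for thin
  double layers (κa ≫ 1, satisfied at ≥ 10 mM ionic strength for
  ~26 nm particles). Reported in mV; linear in μ and sign-preserving.
* Net charge via the Einstein relation: Q = μ·kB·T/(e·D), in elementary
  charges. This is a reconstruction of the standard
  mobility-plus-diffusion route; it is isolated behind one function so
  a Henry-corrected variant can be swapped in.
* Solvent defaults (25 °C water: η = 8.9×10⁻⁴ Pa·s, εr = 78.4,
  T = 298.15 K) live in `constants.py` and are never hard-coded in the
  conversions.

## Adsorption statistics

* A = 100·(titer_before − titer_after)/titer_before, clamped below at
  0: a negative ratio means the post-incubation titer measured higher
  than the control, which is measurement error, not desorption. The
  clamp is applied **per replicate**, before averaging — the ratio
  equation and the 0 % rule are defined at the ratio level. (Clamping
  the mean instead would differ only when replicates straddle 0.)
* Replicate summaries: arithmetic mean ± sample sd (n−1 denominator,
  matching standard statistical software), n = 3 by convention.
* Group comparisons: two-tailed unpaired Student's t-test with pooled
  variance (deliberately not Welch), stars at p < 0.05/0.01/0.001.
  Degenerate case: two constant equal groups → t = 0, p = 1. The
  empirical type-I error at α = 0.05 under a simulated null is within
  Monte-Carlo error of nominal (tested).

## Regression numerics

* Fits use OLS with an intercept; t = β/se with df = n − k − 1,
  two-sided p from the t distribution, R² about the response mean. A
  constant response (SStot = 0) reports R² = 0.
* Collinearity: the design (with intercept) is rejected when its
  smallest singular value is < 1e-10 of the largest, and the error
  names near-perfectly correlated column pairs and constant columns.
* Standardized coefficients z-score all variables including the
  response (sample sd); the refit route and the algebraic identity
  βstd_j = β_j·sd(x_j)/sd(y) agree to 1e-10 (tested).
* Predictions are reported both raw and clamped to [0, 100] %, because
  the assay cannot observe values outside that range; validation R² is
  available both as squared Pearson correlation (default) and as
  1 − SSres/SStot, which differ when predictions are biased.

## Synthetic data: what it emulates and what it does not

`simulate_panel` reproduces the *statistical shape* of the adsorption
study: 4 serotypes × 3 surfaces × 2 ionic strengths = 24 surfactant-free
conditions, each measured in triplicate. Defaults:

* Surfaces: untreated polypropylene (θ = 90°, ζ = −85.9 mV) and
  hydrophilic coatings with negative (30°, −61.7 mV) and positive
  (30°, +37.2 mV) charge — the measured panel values. At the higher
  ionic strength ζ is attenuated by ×0.6 (double-layer compression);
  contact angles are unchanged.
* Generating coefficients: the fitted adsorption-model coefficients
  scaled to the percent response, (0.41, 0.32, 2.47, −0.42, −2.587e−4,
  8.661e−5), with ζneg entering signed. This is a simulation default
  that makes panels study-shaped, not ground truth about real rAAV.
* Capsid descriptors: S_hydrophobic ~ U(1.0e5, 1.3e5) Å² (narrow —
  hydrophobic outer SASA varies little between serotypes) and
  S_hydrophilic ~ U(1.5e5, 2.5e5) Å². These bands keep every
  noise-free linear predictor inside (0, 100) %, so that clamping stays
  rare (< 10 % of draws, tracked as `clamp_fraction`); heavy clamping
  would bias the parameter-recovery tests. The acidic/basic split of
  S_hydrophilic is near-even (U(0.45, 0.55)), making the two strongly
  correlated across serotypes as observed for real capsids.
* Noise: i.i.d. Gaussian, default sd 2 percentage points per replicate
  on the ratio scale, motivated by few-percentage-point replicate
  scatter in this kind of assay; replicate titers are back-computed
  from the clamped ratios around a nominal pre-titer of 5.5×10¹⁰ vg/mL
  with 2 % lognormal jitter.

What passing tests on these panels shows: the estimator recovers known
coefficients exactly without noise, with near-nominal CI coverage at
realistic noise, and the variant structure behaves as the theory says.
What they do not show: that real adsorption is linear in these
descriptors, that the error is Gaussian or homoscedastic, or anything
about surfactant-containing buffers, serotypes, or surfaces outside the
simulated ranges.

`generate_toy_capsid` builds pseudo-atomic shells (rotational copies of
a point set at known radii, placed in ±z mirror pairs so the assembly
centroid is exactly the origin) whose atoms are all separated beyond
the occlusion range 2(r + probe); every atom's SASA is then the
isolated-sphere closed form and the per-category outer sums are known
exactly by construction. It exercises the radial filter, category
tally, assembly and file round-trip logic — not realistic molecular
packing (occlusion correctness is covered by the closed-form sphere
fixtures instead).

## Problem sizes

Default test/validation sizes are chosen to give tight Monte-Carlo
error at interactive runtimes: 100 random clusters for monotonicity,
100 random designs for the OLS oracle, 500 replicate panels for CI
coverage (binomial se ≈ 1 percentage point), 2000 simulations for the
t-test null. Toy capsids default to 12 copies × 20 atoms; the engine
handles full 60-copy assemblies the same way.

## Known limitations

* No reduced-surface or solvent-excluded surface; absolute SASA is
  quadrature-resolution dependent.
* Smoluchowski only (no Henry/Ohshima correction) and no double-layer
  modelling; the net-charge route is the Einstein-relation
  reconstruction.
* The regression offers exactly the three printed variants: no
  regularization, interactions, or mixed effects; no multiple-testing
  correction in the pairwise tests.
* Digital-PCR titer estimation is out of scope; titers are inputs.
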