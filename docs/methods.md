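# Methods

This note documents the models implemented in `mlgblup`, the numerical
choices behind them, what the simulator does and does not emulate, and the
known limitations.

## Relationship algebra

**A-side.** The numerator relationship matrix is handled through its
factorisation A = T D T′ (T the gene-flow matrix, D the Mendelian sampling
variances).  Inbreeding comes from the Meuwissen–Luo recursion and equals
diag(A) − 1 exactly; A⁻¹ is assembled by Henderson's rules with inbreeding
(at most 9 contributions per animal); A₂₂ for a subset is computed by
Colleau's indirect method — one backward and one forward triangular sweep
per subset animal, O(n) each — and is the exact principal submatrix of A.
Unknown parents contribute as unrelated, non-inbred base animals.
Internal codes are 0-based and topologically sorted; reports are 1-based.
A truncation utility drops animals born before a cutoff year and re-founds
orphans as base animals of their line; this is an interpretation (whether
ancestors should instead be retained is not settled) and is therefore a
separate opt-in function, not part of any pipeline default.

**Unknown-parent groups.** Group assignment routes every missing parent
slot to the group of the animal's line (one group per line by default; a
crossbred line is its own group).  Q is the expected base-group
contribution matrix from the recursion q_i = ½(q_sire + q_dam) with unit
rows for group references.  A\* is assembled over animals ⊕ groups by the
same Henderson rules with each missing parent's −½ coefficient routed to
its group column (the QP transformation); Mendelian variances keep the
plain unknown-parent convention.  A\* is singular by construction (rows of
the gene-flow residual sum to zero), which makes the UPG mixed-model
equations consistent-but-singular; the solvers below handle this.

**Metafounders.** Γ holds relationships within (diagonal) and across
(off-diagonal) metafounders on the 0.5-centred scale.  It is estimated
from markers: per group, the base allele frequency is the GLS mean of
half-dosages, p̂ = (1′A₂₂ₖ⁻¹1)⁻¹ 1′A₂₂ₖ⁻¹ M/2, using the within-group
pedigree relationships of that group's genotyped animals; then
Γ = 8 × the covariance across markers of the p̂ vectors taken around 0.5
(a `center="mean"` switch uses per-marker means instead; 0.5 is the
default because it is the reference frequency the 0.5-centred G pairs
with).  A(Γ) is the ordinary tabular recursion over the MF-augmented
pedigree with founder block Γ; its inverse is M′D̃⁻¹M with a dense Γ⁻¹
block for the metafounders and 1/dᵢ for animals, where
dᵢ = aᵢᵢ − (a_ss + 2a_sd + a_dd)/4 from the augmented recursion.  The
dense recursion is O(n²) and intended for desk scale (≤ ~10⁴ animals).
Γ must be positive definite for the inverse; the error reports the
smallest eigenvalue.  Metafounder rows are kept as pseudo-animal equations
by default; a Schur-complement `absorb=True` collapses them onto animals.

## Genomic relationships

G follows VanRaden's method 1 with dosages in {0,1,2}: centring by 2pᵢ and
denominator 2Σpᵢ(1−pᵢ) with observed pooled frequencies, or centring at 1
with denominator m/2 in the 0.5-centred mode the metafounder theory pairs
with.  Residual missing dosages are mean-imputed to 2pᵢ before centring
(zero contribution to relationships).  An optional diagonal weight matrix
D implements weighted ssGBLUP; when all weights are 1 the weighted path is
bitwise identical to the unweighted one.

Quality control removes markers by call rate (< 0.90), monomorphism, minor
allele frequency (< 0.01 chip, < 0.023 sequence), and heterozygote
frequency deviating from the Hardy–Weinberg expectation by more than 0.15;
animals with > 10 % missing genotypes are dropped; with a pedigree
supplied, a genotyped animal whose opposite-homozygote rate against a
genotyped parent exceeds 1 % of comparable markers is removed as a
parent–progeny conflict (the removal rule is standard; the 1 % cutoff is a
package choice, configurable).

**Compatibility and blending.** Before entering H, the observed-frequency
G is put on the pedigree base by the affine adjustment a + bG that matches
its mean diagonal and mean off-diagonal to A₂₂ — the standard single-step
compatibility step, applied by default for the standard/UPG1/UPG2 flavors
and *not* for the MF flavor, where Γ provides compatibility by theory.
G is then blended with 5 % of A₂₂ (or A₂₂(Γ)) to guarantee full rank.
Blending is applied to the full G before APY partitioning; a per-block
variant is possible at large scale but is not the default.

**APY.** The core size is the smallest number of leading eigenvalues of
(blended) G explaining 98 % of its total variation; core animals are then
sampled uniformly at random within line with counts round(n_core × line
proportion), seeded.  The inverse uses the exact core-block inverse, the
noncore conditional variances mᵢᵢ = gᵢᵢ − g_i,c G_cc⁻¹ g_c,i, and the
standard bordered assembly; it supports matvec and dense materialisation.
With all animals core it equals the dense inverse.

## Mixed-model equations

The multi-trait model is y = Xb + Wc + Zu (+ ZQg) + e with categorical
contemporary groups (and optional covariates) per trait, random litter
effects, and additive effects under one of four H⁻¹ flavors:

* standard: H⁻¹ = A⁻¹ + [0, 0; 0, G⁻¹ − A₂₂⁻¹]
* UPG1: A\* plus the correction [D, −DQ₂; −Q₂′D, Q₂′DQ₂], D = G⁻¹ − A₂₂⁻¹
* UPG2: A\* plus [D, −A₂₂⁻¹Q₂; −Q₂′A₂₂⁻¹, Q₂′A₂₂⁻¹Q₂]
* MF: A(Γ)⁻¹ over animals ⊕ metafounders plus G₀.₅⁻¹ − A₂₂(Γ)⁻¹ on the
  genotyped block; no group columns (the metafounders live inside A(Γ)).

The UPG equations are printed-form literal.  Note that UPG2's group
couplings do not vanish when G = A₂₂, so UPG1 and UPG2 are *not*
equivalent in that limit; only UPG1 reduces to the plain grouped pedigree
model.  Group equations stay inside the coefficient matrix; GEBV are
reconstructed afterwards as Qg + u (UPG) or read directly as u
(standard/MF).  No variance-component rescaling by (1 + γ̄/2 − …) is
applied in the MF flavor; components are taken as configured.

Unknowns are ordered fixed effects (trait-major), then litters and
additive levels level-major with traits fastest, so the penalties are the
Kronecker products C₀⁻¹ ⊗ I and H⁻¹ ⊗ G₀⁻¹.  Records with missing traits
contribute through the inverse of the residual covariance restricted to
their observed pattern.  The dense genomic correction blocks are kept as
indexed blocks; the sparse part and the blocks together define a
matrix-free operator.

Solvers: `direct` materialises the sparse LHS and factorises it
(SuperLU); if the factorisation fails or the residual is poor — as with
the singular UPG systems — it falls back to a dense least-squares solve
(minimum-norm solution; GEBV are estimable so they are unique).  `pcg`
runs Jacobi-preconditioned conjugate gradients on the matrix-free
operator, relative tolerance 1e-10 by default; it never materialises the
dense blocks and handles consistent singular systems.  Both are
deterministic.  Desk-scale guidance: direct up to ~2·10⁴ unknowns, PCG
beyond.  (A per-level t×t block-Jacobi preconditioner would be the
natural refinement for strongly correlated traits; with the diagonal-
dominant systems exercised here plain Jacobi converges comfortably.)

## Variant preselection

The multi-line GWAS behind the published panels lives in a companion
study; the package ships a stand-in whose claims are about the selection
machinery, not GWAS power fidelity: phenotypes are pre-adjusted for fixed
(and optionally litter) effects, line labels are projected out of
phenotype and dosages, and each marker is tested by single-marker
regression (t-test).  The discovery set must not overlap the test set.

Panels: windows tile each chromosome as [0, 55 kb), [55, 110 kb), …;
Top40k keeps the argmin-p marker per nonempty window; TopSign does the
same among markers with p ≤ 10⁻⁶ (Bonferroni at 0.05 treating chip
markers as independent) and may keep none; ties break to the lower bp.
LDTags prunes greedily left-to-right within chromosome, keeping a marker
unless its squared dosage correlation with an already-kept marker within
1 Mb exceeds 0.1.  ChipPlusSign = TopSign ∪ Chip; AllComb = LDTags ∪
Top40k ∪ TopSign ∪ Chip; trait-specific selections are merged per model.
All unions are deduplicated and map-sorted.

## BayesR weighting

SNP effects follow the canonical four-component mixture with variances
(0, 10⁻⁴, 10⁻³, 10⁻²) × σ²_g.  The Gibbs chain samples the intercept,
each SNP's class (marginal-likelihood Bayes factors) and effect, the
mixture proportions (flat Dirichlet, pseudo-count 1), σ²_g and σ²_e
(scaled inverse chi-square, 4 prior degrees of freedom anchored at the
initial values).  Dosages are centred at 2p.  Each iteration records β²
per SNP; the posterior SNP variance is the post-burn-in average, and
weights are those variances floored at 10⁻⁸ and rescaled to trace(D) = m.
Default chain 25,000/5,000 iterations is a desk-scale default; the tests
use shorter chains.  Phenotypes are expected pre-adjusted (two-stage,
e.g., with the ssGBLUP fixed/litter solutions); both raw and deregressed
responses are accepted — the sampler does not care, the caller decides.

A caveat established while validating: on pure-noise data the 10⁻⁴ class
is statistically indistinguishable from the null class at desk scale, so
the class *labels* diffuse between them and the null-class proportion is
not a reliable null diagnostic; the identifiable null behaviour is that
markers collectively receive almost no posterior variance.

## LR validation

Test sets mimic selection-candidate evaluation: genotyped members of
last-generation litters (operationalised as maximum birth year) with at
least five genotyped full sibs; training keeps genotyped animals whose
pedigree relationship with every test animal is strictly below 0.5
(screened with exact A columns).  The reduced evaluation removes the
validation animals' phenotypes only, never their genotypes.  Statistics
over validation animals: acc = √(cov(û_w, û_r)/((1 − F̄)σ̂²_u)) (reported
as 0 with a flag if the covariance is negative), standardised bias
(ū_r − ū_w)/σ_u with the configured additive SD, and b₁ =
cov(û_w, û_r)/var(û_r).  Fewer than 10 validation animals is an error.
The σ²_u used is the configured (whole-data) component; a per-line
component can be passed instead.

## The simulator

The generator emulates the statistical structure the evaluation assumes:

* **Line divergence.** Ancestral frequencies p ~ Uniform(0.05, 0.95); each
  line's base frequency from the Balding–Nichols Beta(p(1−F)/F,
  (1−p)(1−F)/F) with drift F = 0.1 by default, making the implied
  Γ analytic.  Each line base is realised as a finite pool of 40 ancestral
  haplotypes; founder (and immigrant) gametes are recombinant mosaics of
  that pool (switch rate 4/Morgan).  The pool gives line bases the LD of a
  finite ancestral population (Ne ≈ 20) — without it, chip markers carry
  no information about off-chip causal variants beyond family
  co-segregation, an unrealistic worst case for genomic evaluation.  The
  truth container reports the realised pool frequencies, so Γ-recovery
  checks are exact.  With drift = 0 all lines share one pool (no
  divergence at all).
* **Pedigree.** Discrete generations per line (default 80 founders + 8
  generations of 48 single-litter dams × litter size 5 ≈ 2,000 per line),
  random mating, no selection; 2 % of parent slots are recorded unknown
  (the gamete then comes from the line base, consistent with
  unknown-parent-group semantics).  A crossbred line (TL1 sires × TL2
  dams) appears in the last two generations.  The last two generations are
  genotyped.
* **Genome.** 5 chromosomes × 100 Mb at 1 cM/Mb by default; 5,000
  sequence markers thinned to a 1,000-marker chip; 100 QTL drawn from the
  sequence markers and excluded from the chip by default (so chip-vs-
  sequence panel comparisons are meaningful; a `qtl_on_chip` switch lifts
  the exclusion).  Gene dropping recombines with Poisson crossovers.
* **Traits.** QTL effects are drawn correlated across traits (default: a
  purebred trait and its crossbred counterpart, genetic correlation 0.7)
  and scaled so the mean *within-line base* additive variance equals the
  configured σ²_u — that, not the ancestral variance, is the component the
  pedigree model sees, and it is what the simulator writes into the model
  config it emits.  Phenotypes add contemporary-group effects (line ×
  generation, SD 0.5), litter effects, and residuals (defaults 0.3/0.1/0.6,
  h² = 0.3).  Crossbreds are recorded only for crossbred traits.

What the simulator does **not** emulate: sequencing and imputation error
(genotypes are exact), selection and assortative mating, overlapping
generations, maternal effects, genotype-by-environment interaction, and
sequence-scale marker density.  Passing tests therefore show the
machinery is correct under the assumed statistical structure, not that
real sequence-based evaluations will reach any particular accuracy.

## Calibration study and problem sizes

The replicated calibration study (`pipeline.lr_calibration_study`) runs 20
independent default-sized three-line populations (single purebred trait,
no crossbred line, ~5,900 animals, ~1,440 genotyped) with whole/reduced
standard-flavor ssGBLUP and averages the LR statistics; expectations are
b₁ = 1 and bias = 0 under correct specification.  Because the 100 QTL are
off-chip, the chip G is an imperfect proxy for the causal covariance and
the realised mean b₁ sits slightly below 1 (≈ 0.96–0.99 depending on the
seed) with a standard error of ≈ 0.02 over 20 replicates; the mean
standardised bias is within ±0.01 of 0.  These problem sizes (and the
shorter BayesR chains and small fixtures in the test suite) are the
package's chosen desk-scale defaults; everything scales up by
configuration.

## Known limitations

* Dense A(Γ) recursion and dense G inverses bound the MF flavor and
  non-APY runs to ~10⁴ genotyped animals.
* The UPG mixed-model equations are singular (group/fixed-effect
  confounding); only estimable functions (GEBV = Qg + u) are meaningful.
* Γ estimation assumes each group has ≥ 2 genotyped descendants and
  polymorphic markers; time-stratified groups and maximum-likelihood Γ
  are out of scope.
* The GWAS stand-in is a calibrated single-marker scan, not a multi-line
  mixed-model GWAS; panel contents on real data would differ.
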