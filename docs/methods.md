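# Methods

This note documents the models, the numerical choices, and what the
synthetic data can and cannot establish.

## Synthetic populations

**Pedigree.**  The default design mirrors a perennial introgression
program: 3 inbred commercial founders ("Catuaí group") and 3 inbred donor
founders ("HdT group") are crossed to 5 F1 hybrids; 13 families of 15
individuals are derived as resistant backcrosses (hybrid × donor parent,
4 families), susceptible backcrosses (hybrid × commercial parent, 5) and
F2 (hybrid selfed, 4), giving 195 individuals.  Hybrids and backcross
parents are assigned by cycling over the founder pools, which fixes the
layout deterministically.

**Genotypes.**  Founders are treated as fully inbred lines — the species
being emulated is an allotetraploid whose meiosis is effectively disomic,
and the parents are cultivar lines/accessions.  Offspring are produced by
gene dropping with independent Mendelian segregation per marker.  Linkage
is deliberately not modeled: no stage of the analysis uses map distances,
and unlinked markers keep the segregation model transparent.  Marker
ascertainment is emulated by resampling founder alleles until the minor
allele is carried by at least two founder lines, mimicking discovery
panels selected for cross-accession polymorphism; without this the
population MAF spectrum acquires an unrealistically heavy low-frequency
tail.  Panel artefacts are injected on top: a configurable fraction of
markers is forced invariant (half of them heterozygous in every
individual — the homeolog "false SNP" signature), a small fraction gets
an elevated missing rate (~15 %), and background dropout applies
everywhere (default 1 %).  Under the defaults, standard QC removes
~2–3 % of markers, matching the scale reported for real panels of this
kind.

**Phenotypes.**  For each trait, `n_qtl` markers are drawn from the
segregating panel; effects are standard normal, then rescaled so the
realized breeding-value variance across the 195 individuals equals the
specified genetic variance exactly — this makes realized heritability a
controlled quantity for recovery tests.  Permanent-plant,
population-type, plot, family-by-year and residual deviations are drawn
independently normal with their specified variances; year means are
added.  The interaction is simulated at the family-by-year level because
an individual-by-year effect would be confounded with the residual in a
one-record-per-year design.  Plots are cross-family field blocks: plant
*r* of every family sits in block *r*, matching the use of the 15 plants
per family as replications.  Score-scale traits cut the latent continuous
value at its empirical quantiles into 2–10 ordered classes of roughly
equal occupancy (the data provide no generative model for scores; the
quantile construction guarantees every class is populated).  Default
trait parameters (18 traits, heritabilities 0.16–0.46, QTL counts
149–17,758 capped by the panel) are set to the magnitudes typical of
complex agronomic traits in such populations.

## Phenotypic mixed model

The observation model is
`y = Xu + Zg + Wp + Vr + Tb + Ri + e` with fixed year means and six
independent random components.  Estimation is EM-REML on Henderson's
mixed-model equations, dense — at ≤ 600 records the coefficient matrix is
a few hundred rows, so each iteration is milliseconds and numerically
exact.

**Identifiability.**  With one plant per genotype, the permanent-plant
effect `p` has the same incidence as the genotype effect `g` (only their
sum is identifiable), and a genotype-by-year interaction has one record
per cell (confounded with `e`).  `build_design` detects aliasing
structurally — identical record partitions, singleton partitions,
single-level factors — and constrains the aliased component to zero,
attributing the identifiable sum to the first factor.  The fitted default
model is therefore year + genotype + population type + plot + residual,
and the reported `σ²_g` is strictly a plant-level repeatability variance
(genetic plus any permanent-plant environment).  The alternative
`genetic_level="family"` places `g` at the family level, `p` at the plant
level and `i` at family-by-year — a fully identifiable progeny-level
variant — for users who want the family decomposition.

**EM details.**  Components stay positive through the EM updates;
convergence is declared when the largest relative change falls below
`tol` (default 1e-6 — near a zero boundary EM's per-iteration relative
change plateaus around 1e-7, so tighter tolerances are unattainable).
Because EM approaches a zero boundary only harmonically, every 25
iterations each component below 1 % of the phenotypic variance is tested
against the boundary: if removing it does not lower the restricted
likelihood, it is projected to exactly 0 and dropped.  This keeps the
restricted likelihood non-decreasing (asserted in tests, which also check
the MME-based likelihood against a direct dense-V evaluation and the full
fit against lme4).

**Derived quantities.**  Individual heritability is
`h² = σ²g/(σ²g+σ²p+σ²r+σ²b+σ²i+σ²e)` (record level).  `h²_phen` is the
heritability of adjusted genotype means: interaction and residual
variances are divided by the harmonic-mean number of records per
genotype, while population-type and plot variances — modeled and removed
by BLUP — do not dilute it.  `r_yy` defaults to the mean per-genotype
`sqrt(1 − PEV/σ²g)` from the inverse coefficient matrix; `sqrt(h²_phen)`
is available as an option and the two track each other closely on
replicated data.  Corrected phenotypes subtract the estimated year mean,
plot BLUP and interaction BLUP from each record and average the records
of each individual.

**Recovery behavior.**  On simulated data at the default scale (195 × 3
years), mean estimated h² recovers the simulated value within ±0.1 for
h² ∈ {0.2, 0.5, 0.8}, with a downward bias that grows with h² (≈ −0.09
at h² = 0.8).  The bias is structural, not numerical: breeding values
genuinely differ between population types in a backcross design, the
population-type random factor absorbs that slice of genetic variance, and
the printed h² formula counts it in the denominator.  This is a property
any analysis of such a design shares.

## Genomic prediction

The marker model `y = Xb + Wm + e` uses dosages 0/1/2 uncentered
(centering only shifts the intercept; a flag exists), an intercept-only
`X` by default (inputs are corrected phenotypes), and ridge shrinkage
`λ = σ²e/(σ²g/nQ)` with `nQ` defaulting to the panel width — the standard
ridge-BLUP equivalence; any other assumed QTL number may be passed.

`solve_direct` solves the MME exactly, switching to the algebraically
identical individual-space (Woodbury) form when markers outnumber
individuals, so 20k-marker panels cost O(n²·p).  `solve_kernel` fits the
equivalent `y = Xb + g + e` with `Var(g) ∝ K` for any PSD kernel — the
genomic relationship matrix (VanRaden centering and scaling) or a
Gaussian kernel whose bandwidth defaults to the median squared
marker distance.  Both routes agree to 1e-8 (tested on random
instances).

`solve_gibbs` samples (b, m) from their Gaussian full conditional — via
the O(n²p) perturbation sampler of Bhattacharya–Chakraborty–Mallick — and
the marker and residual variances from scaled-inverse-χ² full
conditionals with ν₀ = 4 prior degrees of freedom and prior scales taken
from the input variance components.  These priors are this package's own
weakly-informative choice.  With variances held fixed the posterior mean
converges to the MME solution (tested with batch-means Monte-Carlo
errors).

Genomic heritability is estimated by exact REML for the single-kernel
model (eigendecomposition of K, profiled scalar optimization), with K
normalized to unit mean diagonal so `h² = σ²g/(σ²g+σ²e)`.

## Cross-validation and derived statistics

Folds default to 13 random folds of 15 (seeded round-robin after a
permutation); `by_family` assigns each family wholly to one fold.
`r_gy` is the mean across folds of the per-fold Pearson correlation
between validation GEBVs and corrected phenotypes (a pooled correlation
over all validation predictions is reported alongside).  Bias `b`
regresses the phenotype on the GEBV, so b > 1 means under-dispersed
predictions; the direction is a convention and is stated wherever b is
reported.

The design statistics are closed-form: `r_gg = r_gy/√h²` (undefined and
rendered "–" when r_gy ≤ 0), `nQTL = (1−r²)Nh²/r²`,
`Ni = r²·nQTL/((1−r²)h²)` (exact algebraic inverses, property-tested),
and `Ef = r_gg·L_f/(r_yy·L_GS)` with defaults L_f = 24 (four 6-year
phenotypic cycles) and L_GS ∈ {12, 24} (four 3-year GS cycles, or no time
gain).  The h² entering `r_gg` is the genomic heritability of the
predicted trait.  The marker-density experiment subsamples the panel
proportionally within chromosomes (largest-remainder allocation, seeded)
and reruns the same folds per panel size.

## What the synthetic data do and do not show

Passing tests establish internal statistical correctness: solver algebra
against oracles, REML against ANOVA/lme4, calibrated simulation
variances, null-centered and h²-monotone cross-validation, near-unit bias
under a well-specified model, and a rising-then-plateauing density
response.  They do not certify field performance.  In particular,
synthetic populations with unlinked markers, six founders and tight
families make genomic prediction easier than in real data: cross-validated
r_gy routinely exceeds what field studies report at the same heritability,
and can exceed √h²_genomic — in which case the implied r_gg saturates at
1 and nQTL/Ni degenerate toward 0.  Real panels add linkage-disequilibrium
decay, genotype-by-environment structure, and phenotyping error that the
generator does not emulate.  Score traits are analyzed as continuous; a
threshold/GLM analysis is out of scope.  The pipeline assumes complete
genotyping of all phenotyped individuals and biallelic dosage calls.

## Problem sizes

Defaults are chosen so a full pipeline run (195 individuals, 5,000
markers, 3 traits, 13-fold CV, 3 density points) completes in seconds,
and the statistical test suite (hundreds of REML fits and CV replicates)
in a few minutes, on one CPU.  All stages are deterministic given the
master seed; the Gibbs sampler is reproducible given its seed.
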