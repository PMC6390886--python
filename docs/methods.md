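# Methods

`tetraqtl` implements multi-allelic QTL interval mapping for autotetraploid
(2n=4x) bi-parental F1 populations of the kind used in cultivated potato
breeding, together with the trial statistics (variance components,
broad-sense heritability, BLUEs) that prepare the phenotype, and a
tetraploid-meiosis simulator that generates fully known test populations.
This note records the models, the numerical choices, and what the simulator
does and does not emulate.

## The genetic model

At a genomic position, an F1 individual carries two of the four homologues
of each parent. Probabilistic haplotype reconstruction (from SNP dosage
data, external to this package) yields per individual, parent and position a
distribution over the 6 unordered homologue pairs a bivalent meiosis can
transmit ({12,13,14,23,24,34} for parent 1) plus the 4 double-reduction
classes ({11,22,33,44}) in which a gamete carries two chromatid copies of
one homologue. Expected homologue dosages follow linearly:
X1..X4 for parent 1, X5..X8 for parent 2, with X1+X2+X3+X4 = 2 and
X5+X6+X7+X8 = 2 identically.

The single-locus additive model regresses the trait on all eight dosages,

y = mu + a1 X1 + ... + a8 X8 + e,

which the two parent-sum constraints make over-parameterised; dropping one
dosage per parent gives the working model

y = mu' + a2' X2 + a3' X3 + a4' X4 + a6' X6 + a7' X7 + a8' X8 + e.

Which column is dropped per parent is arbitrary and does not change the
fitted subspace (asserted by test); this package drops X1 and X5. Fits are
ordinary least squares; evidence is summarised as
LOD = n/2 log10(RSS0/RSS1) against the intercept-only null and
R^2 = 1 - RSS1/RSS0, which are linked exactly by
R^2 = 1 - 10^(-2 LOD/n).

Genome-wide significance uses phenotype permutation: trait values are
permuted against intact genotype rows (preserving dosage LD), the maximum
LOD over the genome recorded per permutation, and the empirical (1-alpha)
quantile taken as the threshold (defaults: 1000 permutations, alpha = 0.05).
QTL support is the contiguous LOD-2 interval around each above-threshold
peak, truncated to above-threshold positions.

### Homologue effects

At a QTL, per-homologue weighted means
hbar_i = sum_n pi_in y_n / sum_n pi_in with weights pi_in = X_in / 2 are
reported with effects hbar_i - ybar. Since the weights sum to 2 per parent
per individual, the weight-weighted effects sum to zero exactly.

### Bi-allelic model search

Every assignment of a bi-allelic genotype (Q/q) to the 8 homologues — 126
canonical segregating assignments after removing the global Q/q relabelling
and assignments homozygous in both parents — is fitted with an additive
predictor (expected Q dosage) and optionally a dominance predictor
(probability of carrying at least one Q copy, computed exactly from the
gamete-class distributions when available, otherwise by a flagged
product-of-marginals approximation). Models are ranked by the Schwarz
information criterion SIC = n ln(RSS/n) + k ln(n) (k parameters including
the intercept) and reported as Delta-SIC against the best model, with a
runner-up below 2 graded as weak evidence.

Because the parental dosages sum to 2, complementing the Q-set within one
parent maps the additive predictor x to 2 - x per parent — an affine change
with identical RSS and SIC. Such assignments are statistically
indistinguishable under additive coding; the search therefore groups them
into equivalence classes and reports the separation ("Delta-SIC of the best
model outside the winner's class") rather than pretending to resolve them.
Dominance coding breaks the tie in principle but rarely in practice at
realistic effect sizes.

### Cofactor analysis

To find QTLs masked by larger ones, the trait is residualized by OLS on the
model-B columns of a set of cofactor positions jointly (the naive-scan
peaks, frozen at their positions), the residuals are rescanned, and a fresh
permutation threshold is computed on the residuals (cofactor designs are
not refit inside permutations). All non-empty subsets of the naive peaks
are analysed; rescan peaks with no naive peak on the same chromosome within
15 cM are flagged as newly identified. Residualizing on an uninformative
position (all dosages 0.5) provably leaves the profile unchanged, which the
suite asserts to 1e-8.

## Trial statistics

The trait is tuber protein content, derived from soluble protein measured
in potato fruit juice (% w/v) corrected by tuber moisture:
protein = PFJ_protein x (100 - dry_matter)/100. The result is treated as
the dimensionless product of this formula; the % w/w vs % w/v basis of the
underlying measurement convention is not resolved further.

Variance components come from ANOVA mean squares. Within a year
(clones + blocks): sigma2_G = (MS_G - MS_E)/r, sigma2_E = MS_E. Between
years (clones + years + blocks-in-years + clone-by-year):
sigma2_G = (MS_G - MS_GxY)/(r y), sigma2_GxY = (MS_GxY - MS_E)/r. Sums of
squares are type II so mildly unbalanced trials are handled; negative
component estimates are reported raw but floored at zero when entering

H2_within = sigma2_G / (sigma2_G + sigma2_E / r),
H2_between = sigma2_G / (sigma2_G + sigma2_GxY / y + sigma2_E / (r y)).

Worked check: (0.013, 0.039, r=2) gives 0.40 and (0.021, 0.034, r=2) gives
0.55. Note that evaluating the between-years formula at the published
component values (0.042, 0.001, 0.062, r=2, y=2) yields 0.724, while the
source trial reports 0.74; the formulas are implemented exactly as printed
and this discrepancy is documented rather than reconciled.

BLUEs (per-clone adjusted means) come from a mixed model with clone fixed
and year random, fitted by REML (statsmodels MixedLM); with a single year
this reduces to clone means, and in balanced data it equals clone means
after centring on year means.

## The meiosis simulator

The simulator realises tetrasomic inheritance mechanistically so that every
downstream quantity has a known truth.

- **Bivalent meiosis** (default): the four homologues pair uniformly at
  random into one of the 3 possible bivalent pairings (no preferential
  pairing, as none is reported for the varieties this emulates). Each
  bivalent transmits one chromatid that switches between the two partners
  at crossover points drawn from a Poisson process at 0.01 per cM — no
  interference, so recombination fractions follow Haldane's map function
  exactly, including over compound intervals.
- **Quadrivalent meiosis** (probability `quadrivalent_rate` per meiosis per
  chromosome): the two transmitted chromatids may descend from any
  homologue. One chromatid follows a jump process over the four homologues;
  the second follows it through a partner-offset process, except on
  double-reduction tracts — a two-state process with stationary probability
  `double_reduction_rate` (range [0, 0.25]) and switching rate 0.02/cM —
  where it duplicates the first chromatid. The locus-wise double-reduction
  frequency therefore equals the configured rate while DR tracts remain
  contiguous; a flat per-locus rate is used rather than a
  centromere-distance model, since only the representability of DR classes
  matters downstream.
- **Reconstruction uncertainty**: true gamete classes are blurred as
  lam * one-hot + (1 - lam) * uniform over the admissible classes per
  parent (`informativeness` lam; 1 = perfect, 0 = uninformative). This
  mimics the information loss of probabilistic haplotyping with a single
  dial, but not its spatial correlation (real posteriors degrade near
  region ends and between informative markers) nor systematic phasing
  error.
- **Phenotypes**: y = mu + sum_h alpha_h copies_h + d 1[Q carrier] +
  clone polygenic + year + clone-by-year + block-in-year + residual, all
  Gaussian. Default variance magnitudes follow the protein-content trial
  the package emulates: polygenic 0.042, clone-by-year 0.001, residual
  0.062 (trait-squared units); year and block variances are not published
  for that trial and default to 0.001 each, chosen small relative to the
  residual as is typical for well-conducted starch-potato trials; mu
  defaults to 0.93, the published population mean. The raw-measurement
  columns assume a constant tuber dry matter of 22.5% so the trait
  round-trips through the moisture formula; real dry-matter variation and
  any genetic correlation between dry matter and protein are not emulated.

Passing tests on simulated data therefore demonstrate correctness of the
estimators under tetrasomic inheritance with known truth — not robustness
to genotyping error, segregation distortion, spatial field trends, or
non-Gaussian traits.

## Numerical choices

- Dosage grids live on a regular cM grid (default 1 cM, coordinates rounded
  to 0.1 cM, half-open per chromosome from 0). Marker-positioned dosages
  are moved onto the grid by per-homologue linear interpolation; since each
  support row satisfies the parent-sum and [0,2] range constraints and
  linear interpolation is convex, the constraints survive exactly (a
  clamp-and-renormalise pass guards floating-point drift only). A spline
  family would not preserve the constraints without projection.
- OLS uses LAPACK least squares with singular values below 1e-10 (relative)
  truncated, i.e. the minimum-norm solution on rank-deficient designs.
  This keeps uninformative positions (all dosages equal, GIC near 0) in the
  scan with a well-defined LOD of ~0 instead of a position-dependent model
  dimension; without the truncation, an exactly rank-deficient design can
  leak a numerically spurious direction and produce RSS1 > RSS0.
- Permutation scans precompute an orthonormal basis of each position's
  design once and evaluate all permutations as one matrix product, so 1000
  permutations over a few hundred positions take seconds at n ~ 500.
- The permutation threshold uses the `higher` empirical quantile
  (conservative on the discrete permutation distribution); alpha = 1
  returns the minimum of the permuted maxima.
- LOD ties in peak finding break toward the lower cM position; RSS0 = RSS1
  (including 0/0) defines LOD = 0.
- The genotypic information coefficient per homologue treats
  p = min(X, 1) as the carrier probability and reports
  GIC = 1 - 4 mean_n[p(1-p)]: 1 when reconstruction is certain, 0 when all
  carrier probabilities are 1/2. The source literature defines GIC only
  qualitatively; this scaled binomial-variance complement reproduces the
  documented range and monotonicity in informativeness.
- Marker QC tests offspring dosage counts against the bivalent-meiosis
  tetrasomic expectation for the parental dosage pair (hypergeometric
  gamete distributions convolved; simplex x nulliplex 1:1, duplex x
  nulliplex 1:4:1), chi-square at alpha = 0.001. Double reduction perturbs
  these ratios far less than the test's sensitivity at realistic population
  sizes, so the bivalent null is used.

## Problem sizes used in the test suite

The statistical acceptance checks run at the population scale the method
targets (n = 496 for power and model recovery, matching the emulated
cross) with permutation counts and replicate numbers chosen for stable
Monte-Carlo behaviour: 200-permutation thresholds inside replicated
studies, 200 null scans for threshold calibration, 20 replicates for
power/recovery rates, and 400 replicates for variance-component
unbiasedness. Full-size analyses (1000 permutations, 12 chromosomes) use
the same code paths.

## Known limitations

- The simulator's informativeness dial is spatially uniform; it cannot
  produce locally uninformative regions except via quadrivalent/DR
  configuration.
- Dominance predictors require gamete-class probabilities for exactness;
  the marginal approximation ignores within-parent dependence between
  homologue carriage events and is flagged in output when used.
- `compute_blues` treats year as the only random grouping (no
  block-within-year random term), matching the two-term mixed model it
  implements; location effects are not modelled.
- The between-years heritability printed by the emulated trial (0.74) is
  not recovered from its own printed components by the printed formula
  (0.724); see above.
- Additively equivalent bi-allelic assignments cannot be distinguished from
  phenotype data alone; the package reports the equivalence class rather
  than an arbitrary member as "the" model.
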