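# Methods

`plastgwas` dissects the genetic architecture of phenotypic plasticity in a
two-environment (well-watered, WW, vs water-limited, WL) common-garden
design, end to end: plasticity estimation, G×E variance partitioning with
trait retention, four-family genome-wide association scanning, two-stage
consensus retention of associated SNPs, QTL variance accounting, functional
annotation, and allele-direction (antagonistic-pleiotropy) analysis. All
stages are exercised on synthetic multi-family data with planted truth, so
every claim the test suite makes is a recovery statement against known
effects.

## Synthetic study population

The generator emulates a nested association mapping (NAM-like) barley
panel: `n_families` families, each descending from a cross between one
shared recurrent parent and a family-specific donor, advanced to
near-complete inbreeding. Genotypes are coded {0, 2} (homozygous allele
counts; no heterozygotes), which matches advanced-generation inbred
material and keeps kinship and effect algebra simple. Per line and
chromosome, a Poisson number of crossovers (`recombination_rate`, expected
crossovers per meiosis; default 1.5 ≈ a 150 cM chromosome) with uniform
breakpoints produces a founder mosaic, so r² between markers decays with
physical distance. The two founders differ at every marker, which makes
per-family allele frequencies 0.5 in expectation ("founder-balanced").
Missing genotype calls are injected completely at random
(`missing_rate`, default 2%).

Phenotypes follow the additive two-environment model

    y_ijk = mu_t + shift(env_j) + sum_q beta_q(env_j) x_iq + u_i + e_ijk

with `shift(WL) = -env_effect` (default 5 trait units), a line-level
polygenic deviate u_i ~ N(0, sigma2_poly) shared across environments, and
i.i.d. replicate noise e ~ N(0, sigma2_resid). Trait intercepts default to
the published WW means of the barley HEB-25 water-availability trial (grain
yield 18.33 g, maturity 136.8 d, ...) purely so outputs sit on familiar
scales. Planted QTLs come in three kinds: *main* (same effect in both
environments), *plastic* (effect in one environment only), and
*antagonistic* (opposite signs). Effects are scaled on the realized
genotype frequencies so that each locus explains its target fraction of the
single-replicate phenotypic variance in its designated environment; the
brute-force realized fraction is checked to ±0.03 in the tests.

What the generator does **not** emulate: realistic genetic maps (uniform
crossover placement, no interference), selection, mutation, epistasis,
block/spatial field effects, or trait-specific error structures. Passing
recovery tests therefore demonstrate the pipeline's correctness under an
additive polygenic world, not its power on any particular real trial.

## Plasticity estimators

Per genotype and trait, from the replicate means X_WW and X_WL:

* **WW, WL** — the absolute environment means (the extremes of the
  reaction norm).
* **Ratio** = X_WW / X_WL; values above 1 mean reduction under stress.
  Undefined (flagged absent) when X_WL = 0.
* **RDPI** = |X_WW − X_WL| / (X_WW + X_WL); with two environments and
  genotype means, the general pairwise relative-distance index collapses to
  this form. Symmetric, scale-invariant, in [0, 1] for nonnegative traits.
* **CV** — sample (n−1 denominator, a documented repo choice) standard
  deviation of the two environment means over their mean. Computed, and
  almost always removed again by the redundancy screen.
* **Linear** — the Finlay–Wilkinson slope: E_j is the across-genotype mean
  in environment j minus the grand mean (computed over complete-case
  genotypes), and b_i the regression slope of y_ij on E_j. With two
  environments b_i = (y_iWW − y_iWL)/(E_WW − E_WL) and mean(b_i) = 1
  exactly; the tests assert this identity at 1e-10. A degenerate index
  (E_WW = E_WL) is an error, not a NaN.

The environment contrast is confirmed per trait with the two-sided
Wilcoxon signed-rank test on paired genotype means (zeros dropped; exact
null for n ≤ 25 untied differences, tie-corrected normal approximation
above).

The redundancy screen computes pairwise Spearman correlations over the
six-column battery and iteratively drops the lowest-priority member of any
pair with |r| above the threshold (default 0.95), with fixed priority
WW > WL > Linear > RDPI > Ratio > CV. The priority order is a repo
decision: absolute means are the primary data, the slope is the canonical
reaction-norm summary, and CV is the designated redundancy victim. The
retained set is by construction a non-empty subset.

## Variance partitioning and trait retention

The decomposition y_ijk = mu + G_i + E_j + (GE)_ij + e_ijk treats genotype,
environment, and interaction as random. By default (GE) is pooled into the
residual: with a two-level environment the interaction is weakly
identified, and without within-cell replication it is confounded with the
residual (then pooling is forced and flagged). REML is evaluated on the
exact ANOVA strata of the balanced two-way crossed design — the strata are
the eigenspaces of the marginal covariance, so the criterion is

    -2 l_R = sum_s df_s log(lambda_s) + SS_s / lambda_s

over strata s with eigenvalues lambda_s linear in the variance components —
minimized under sigma² ≥ 0 bounds (L-BFGS-B from method-of-moments starts).
In the interior this coincides with the closed-form ANOVA estimators
(asserted to 1e-6 relative); negative method-of-moments solutions become
boundary zeros rather than negative variances. Unbalanced data fall back to
a dense multivariate-normal REML (capped at 4000 observations). Component
significance uses the restricted LRT with the boundary mixture
0.5·(χ²₀ + χ²₁). Because a 2-level random environment variance is
unstable, the fixed-effect environment share of the total sum of squares is
reported alongside (`prop_env_fixed`).

Trait retention drops traits whose genotypic component is not significant
(default alpha 0.05), traits with an environmental share below a floor
(default 5%), and finally the single surviving trait with the largest
residual share. The published nine-trait barley decomposition is shipped as
a worked example: the rules drop GW, HEA and VDW and keep exactly six
traits. The numeric defaults are repo choices — the source analyses name
the excluded traits and the reasons but not the cutoffs.

## Marker QC, kinship, structure, LD

QC removes markers with ≥ 10% missing calls, monomorphic markers, and, for
every pair in complete LD (r² = 1 on pairwise-complete cases, tolerance
1e-12), all but the first in map order. QC is idempotent. Missing values
are mean-imputed for numeric work only; exports keep the original missing
codes. Kinship is the VanRaden genomic relationship matrix
K = WW'/(2Σp(1−p)) on the mean-imputed, frequency-centered matrix. PCA is
the SVD of the centered genotype matrix; LD decay is mean pairwise r² per
half-open physical-distance bin within chromosomes. Positions are 1-based
bp throughout; BED exports use the standard 0-based half-open conversion.

## Association scans

Four method families over each (trait × estimator) response:

* **MLM** — per-marker mixed model y = mu + x beta + g + e with
  g ~ N(0, sigma_g² K). The variance ratio delta = sigma_g²/sigma_e² is
  estimated once on the intercept-only model by profiling the REML
  criterion over log delta in the eigenbasis of K (the
  population-parameters-previously-determined shortcut), then every marker
  is a weighted-least-squares Wald t-test in the rotated basis. With K = I
  the procedure reduces exactly to OLS (asserted at 1e-8).
* **Multilocus** — a FarmCPU/BLINK-family iteration re-derived from its
  published principles, not a port: (i) single-marker fixed-effect tests;
  (ii) pseudo-QTN candidates by ascending p (entry threshold 0.01, a repo
  default — the sources do not state one), skipping candidates with
  r² > 0.7 to an already-selected one; (iii) model size chosen by BIC over
  nested candidate sets; (iv) all markers re-tested with the selected
  pseudo-QTNs as covariates, excluding self and linked covariates; iterate
  to set convergence or 10 rounds.
* **RF / GB** — Random-Forest (scikit-learn, 500 trees, min leaf 2) and
  gradient-boosting (xgboost, 500 rounds, learning rate 0.05, depth 4)
  importance scans. Empirical p-values come from a max-statistic
  permutation null: the response is permuted `n_permutations` (≥ 100)
  times, the maximum importance per permutation pooled, and
  p = (1 + #{maxima ≥ importance})/(n_permutations + 1). The max-null makes
  the procedure family-wise valid and conservative. Everything is
  single-threaded and deterministic given the seed.

Significance calling is Bonferroni, Benjamini–Hochberg FDR (default 0.05
for model-based p), or a direct threshold on empirical p (default 0.05 for
the ML scans); all configurable, since the source analyses do not name
their thresholds.

## Consensus and QTL variance

Stage one keeps, within each method and trait, markers significant for at
least two of the five estimators (the absolute WW/WL values count toward
the tally). Stage two unions per-method survivors and flags ≥ 2-method
support as high confidence. The within-method-first order is the default;
upset-style tables report exact-subset (disjoint) counts, which sum to the
union size by construction. `qtl_variance_explained` fits the response on
the retained marker genotypes by OLS (an environment term, when present, is
attributed first) and reports marker/environment/residual shares of the
total sum of squares; because in-sample shares inflate at small n, an
adjusted-R² analogue and a 5-fold cross-validated R² are reported side by
side.

## Annotation and allele direction

Markers inside the CDS union of a gene are *coding*; inside the gene body
but outside every CDS *intronic* (UTR variants land here — the three-way
scheme has no finer class); otherwise *intergenic* with the distance to the
nearest gene. GO overrepresentation is the one-sided Fisher exact test per
term (equivalently the hypergeometric upper tail, which an exact-rational
enumeration oracle checks in the tests) with BH FDR across terms; genes are
the counting unit, counted once regardless of SNP multiplicity. A marker is
flagged for antagonistic pleiotropy when its estimated effects on the WW
and WL responses have opposite signs and each exceeds k = 2 standard errors
(the noise floor k is a repo default; direction reversal is described only
qualitatively in the sources). A synthetic GFF3 + gene-to-GO generator
(clearly labelled synthetic) makes the annotation stage testable offline;
real GFF3/gene2go files are accepted but never required.

## Problem sizes and numerical choices

The shipped case study and drivers use 4 families × 50 lines, 140 markers
on 7 chromosomes, 2 replicates per environment, ML scans with 100
permutations of 60–100-tree ensembles; recovery checks use up to 400
genotypes (variance components), 300 lines (scan power), and 10–50 seeds
(calibration), sizes at which every planted effect is comfortably inside
the detection regime for a single-CPU desk run. Ties in the redundancy
screen resolve by the fixed priority order; monomorphic markers get absent
(NaN) p-values rather than calls; eigenvalues of K are clipped at 0; the
profile-REML search runs over log delta in [−10, 10].

## Known limitations

Two environments only (the data model stores the environment as a label, so
a third is representable, but RDPI/Ratio/slopes assume the WW–WL pair); no
epistasis, no haplotype tests, no GO-graph ancestor propagation; the
multilocus scan is principle-faithful rather than numerically identical to
any published implementation; the dense REML fallback is quadratic in
memory and capped; real-data idiosyncrasies (spatial trends, shared
controls, genotyping batch effects) are out of scope of both the generator
and the tests.
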