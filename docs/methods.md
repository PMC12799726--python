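# Methods

## The trial model

All phenotype analyses assume a balanced crossed design: `g` genotypes,
`a` years, `b` irrigation treatments (normal N, drought D), `r` replicates,
one plot value per trait and cell. The observation model is

    Y_iknj = mu + y_k + t_n + g_i + r_j + (yg)_ik + (tg)_in + e_iknj

with years, genotypes and replicates treated as random effects and the
irrigation treatment as fixed. Strata not listed — including the three-way
genotype x year x treatment interaction — are pooled into the error term,
which keeps the analysis faithful to the model string above; the pooled
error therefore absorbs any true G x Y x T variance, and the reported
`sigma2_e` is an upper bound on the plot residual in that case.

### Variance components

Components are method-of-moments solutions of the balanced expected mean
squares:

    sigma2_e  = MS_E
    sigma2_gy = (MS_GY - MS_E) / (b r)
    sigma2_gt = (MS_GT - MS_E) / (a r)
    sigma2_g  = (MS_G - MS_GY - MS_GT + MS_E) / (a b r)

Negative estimates (possible by sampling) are clamped to zero for
reporting; the raw values are kept on the result object for diagnostics
and for unbiasedness checks. Broad-sense heritability is on the
entry-mean basis:

    H2 = sigma2_g / (sigma2_g + sigma2_gy/a + sigma2_gt/b + sigma2_e/(a b r))

which is the repeatability of a genotype mean over the whole trial. H2 is
invariant to affine rescaling of the trait.

### F tests

With genotypes and years random there is no single exact denominator for
the genotype mean square, so the test uses the synthesised denominator
`MS_GY + MS_GT - MS_E` with Satterthwaite degrees of freedom. Year is
tested against MS_GY, treatment against MS_GT, replicates and both
interactions against MS_E. These denominator choices follow the
random-effects expected mean squares; other software may print different
conventions, so F values (not the component estimates) can differ between
programs. Stars follow the usual legend: `*` at 0.05, `**` at 0.01.

### Single environments

Within one year x treatment the layout is a randomised complete block
(genotype x replicate): `sigma2_g = (MS_G - MS_E)/r`,
`H2_env = sigma2_g/(sigma2_g + sigma2_e/r)`, genotype tested against MS_E.

### Imbalance

The EMS algebra assumes balance. Missing plot values up to a configurable
fraction (default 10%) are cell-mean imputed with a warning — adequate for
sporadic losses, biased if whole cells vanish (then an error is raised).
Degrees of freedom are not adjusted for imputation; with the default
tolerance the effect on MS_E is second-order.

## Correlations

Phenotypic correlations are Pearson coefficients over genotype entry
means within one environment (pairwise-complete, p from the t
distribution on n-2 df). Genotypic covariances use mean cross products of
the genotype x replicate two-way layout, `cov_g = (MCP_G - MCP_E)/r`, the
bivariate analogue of the RCBD component — the diagonal reproduces the
per-environment `sigma2_g`. Genotypic correlations are the normalised
covariances, clamped to [-1, 1] with a flag when sampling pushes the ratio
outside; no standard errors are attached (none are defined for this
moment estimator without further assumptions). Because the residual
covariance attenuates only the phenotypic estimate, genotypic
correlations exceed phenotypic ones in absolute value on average — the
test suite checks this attenuation property on generator data.

## Drought response

`RDD = (Xn - Xd)/Xn * 100` per trait; negative values mean the trait was
higher under drought. Two per-trait summaries are reported and labelled:
the RDD of the trait means over genotypes (the headline convention, since
the formula operates on trait averages) and the mean of per-genotype RDD
values; they coincide only when Xn is constant across genotypes.
Gravimetric soil moisture converts to volumetric by multiplying with bulk
density (default 1.2 g/cm^3, a typical clay-loam value).

## Selection indices

The Smith-Hazel coefficients solve `P b = G w`, where P and G are the
phenotypic and genotypic trait covariance matrices and w the economic
weights. Conventions:

- **Weights** default to 1 for every trait (no economic values are
  assumed); configurable.
- **P and G** are computed per drought environment from that year's entry
  means (P) and MCP ANOVA (G), since the indices rank genotypes under
  drought within a season.
- **Bending**: estimated G (or P) can be indefinite; negative eigenvalues
  are clamped to 1e-8 of the trace before solving, and a still-singular P
  is an error rather than a silently unstable solve. The solution must
  satisfy `||Pb - Gw||/||Gw|| <= 1e-8`.
- SI uses the spike traits (GYPS, GNPS, NSPS), PI the peduncle traits
  (PW, PD); both sets are configurable.
- `DI = 1/2 (SI/SD_SI + PI/SD_PI)` with sample (n-1) standard deviations
  over genotypes; DI is invariant to separately rescaling SI or PI.

Selection takes the k highest and k lowest DI genotypes per year
(default k = 20), breaking ties lexicographically by genotype id so runs
are deterministic, and flags a tie crossing the boundary; per-year sets
are intersected to find consistently extreme genotypes.

For a population with true covariances (P, G) the index accuracy has the
closed form `corr(b'x, w'g) = sqrt(w'G P^-1 G w / w'G w)`; the acceptance
checks verify the realised accuracy against it and against 100
random-weight competitor indices.

## Marker analyses

- **QC order**: heterozygous calls are masked to missing (inbred-line
  panels; "het loci excluded" is implemented per call so the marker's
  remaining homozygous information is kept), then markers with > 20%
  missing data, then markers with MAF < 5% (exactly 5% is retained —
  strict reading of the rule), then samples with > 20% missing calls.
  MAF is `min(p, 1-p)` over non-missing calls, recomputed after masking.
- **Distinct-SNP screen**: a marker is reported iff every call in group A
  equals one homozygous state and every call in group B the other.
  "Distinct" is operationalised as opposite fixed homozygotes (presence/
  absence of an allele is not well-defined for array calls). The strict
  missing policy (default) disqualifies a marker with any missing call in
  either group; `ignore_missing` evaluates the non-missing calls only.
  The screen is invariant to sample order and to a global allele-label
  swap, and is verified against an exhaustive brute-force oracle.
- **Association** is a two-sided Welch t-test between the two homozygote
  classes. No population-structure covariates are used — a documented
  limitation: with structured panels the single-marker p-values are
  anti-conservative, and the screen/association here is a follow-up tool,
  not a GWAS replacement. The allele effect is the difference of class
  means (not halved per allele copy); the target allele is the class with
  the higher trait or index mean.
- **Thresholds** are reported as fixed p <= 0.001 and suggestive
  p <= 1/N (N = markers tested); no multiplicity correction is applied
  beyond these, by design.
- **LD r^2** is the squared Pearson correlation of {0,1,2} dosages over
  samples non-missing at both markers.

## The synthetic-data generator

`simulate_trial` draws genotype, G x Y, G x T and plot-residual effects
from zero-mean multivariate Gaussians with user-specified trait
covariances, plus fixed year and treatment shifts; treatment is a fixed
shift, matching its fixed-effect role in the model. A single master seed
derives per-component substreams (SeedSequence spawning), so the same
(design, truth, seed) always regenerates the identical table, and any
fixture can be rebuilt from its recorded seed.

`example_truth()` fixes the defaults at study-like values: trait means of
a spring-wheat trial (GYPS 2.8 g, GNPS 63, NSPS 26, PW 0.66 g,
PD 3.5 mm), genetic CVs of 10-15%, moderate positive genetic correlations
within and between the spike and peduncle groups, interaction covariances
Sigma_gy = 0.06 Sigma_g and Sigma_gt = 0.08 Sigma_g, and residual
standard deviations at half the genetic ones with deliberately weaker
residual correlations (0.3 R_g + 0.7 I) — so heritabilities come out
around 0.9 and genotypic correlations exceed phenotypic ones, the regime
the analysis targets. Drought shifts are negative for every trait, sized
so the reductions land near 9% (GYPS), 2.5% (NSPS), 22% (PW) and 16%
(PD).

`simulate_snp_panel` emulates an inbred array panel: independent markers,
per-marker alternate-allele frequency uniform in a MAF window, calls 0/2
(optionally corrupted by het or missing calls for QC testing), planted
group-differentiating markers fixed 2 in group A and 0 in group B, and
planted marker-trait effects returned for recovery tests. What it does
**not** emulate: linkage maps and positional LD (a two-marker correlated
pair generator exists solely to exercise `ld_r2`), population structure,
genotyping batch effects, and ascertainment bias of array MAF spectra.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to structured real-world panels.

The bundled demo dataset (`make_demo_dataset`) couples the two: the three
planted distinct markers act as a tolerance haplotype adding a stable
0.45 g (GYPS) and 0.10 g (PW) per alternate-homozygous call, and the
contrast groups are the 7 highest / 10 lowest genotypes by true aggregate
genotypic value — so the screen, association and selection stages all
have a known right answer.

## Problem sizes and numerical choices

The recovery checks run at the study's scale (200 genotypes, 2 x 2 x 2
design) with 200 simulation replicates for variance components, 50 for
genotypic correlation, 100 random panels for the screen oracle and 1000
null markers for calibration; the pipeline determinism check uses a
30-genotype, 120-marker fixture. These sizes give Monte-Carlo standard
errors comfortably inside the stated tolerances. Ties in selection are
broken by id; covariance bending uses an eigenvalue floor of 1e-8 of the
trace; index solves are verified to a 1e-8 relative residual; negative
variance components are clamped at zero only at the reporting layer.

## Known limitations

- Method-of-moments (not REML) components: requires balance up to the
  imputation tolerance, no spatial field models.
- The genotype F-test denominator convention is one defensible choice
  among several; component estimates do not depend on it.
- Single-marker association without structure correction (see above).
- Genotypic-correlation point estimates carry no standard errors or
  bootstrap intervals.
- VCF support is the minimal GT-only biallelic dialect; multi-allelic
  records are skipped (and counted), not decomposed.
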