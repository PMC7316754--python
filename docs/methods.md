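# Methods

This note documents the models and numerical choices behind gipkit: what is
simulated, what is estimated, and where the design was genuinely open.

## Liability model and synthetic cohorts

Traits are generated under a multivariate liability-threshold model. For T
traits, liability is `L = g + e` with per-SNP effect rows drawn
`β_j ~ N(0, C_G_liab / M)` on the standardized-genotype scale (infinitesimal
architecture: every SNP is causal, matching the polygenicity assumption of
LD Score regression; a `prop_causal` flag provides sparse architectures but
is not the default), `g_i = Σ_j x̃_ij β_j`, and environment rows
`e ~ N(0, C_E_liab)`. `C_G_liab + C_E_liab` has unit diagonal so liabilities
are standardized; binary trait t is `L_t > Φ⁻¹(1 − K_t)` for prevalence
`K_t`. Under this model the observed-scale (0/1) genetic covariance that
LDSC should recover is the standard liability→observed transform

```
C_obs[t,s] = C_G_liab[t,s] · φ(z_t) φ(z_s) / sqrt(K_t(1−K_t) K_s(1−K_s)),
z_t = Φ⁻¹(1 − K_t),
```

whose diagonal inverts exactly through `ldsc.liability_h2` (with sample
prevalence P = K for a population cohort, the case implemented here).

**Genotypes.** SNPs come in independent exchangeable-correlation blocks.
Each individual carries two haplotypes; within a block, haplotype alleles
are indicators of a latent exchangeable Gaussian thresholded at the
allele-frequency quantile. Thresholding attenuates correlation (the phi
coefficient of two indicators is below the tetrachoric correlation), so the
latent correlation is calibrated by inverting the tetrachoric relationship
(Owen's-T closed form + Brent root-finding) until the *allele* correlation —
and hence the dosage correlation — equals the requested block ρ. That makes
the analytic LD scores `l_j = 1 + (B−1)ρ_b²` exact targets for the empirical
estimator. One allele frequency is drawn per block (uniform in `maf_range`),
which keeps the within-block exchangeable structure exact with a single
calibration constant; per-SNP frequency variation across blocks remains.

ρ may vary per block. The `BlockSpec.graded` constructor spaces ρ evenly
from 0 to `r_max` (default 0.9): across-SNP variation in the LD score is
what identifies the LDSC slope, and a single shared ρ would make the
regressor constant. Blocks sit >500 kb apart (1 Mb stride, 1 kb SNP
spacing, 22 pseudo-chromosomes), so ±250 kb clumping can never merge blocks.

**Default study conditions.** The reference simulation uses 4 binary traits,
n = 6000, M = 2000 SNPs (400 graded blocks of 5), liability h² = 0.4,
uniform r_g = 0.7, prevalence 0.15, and environmental correlation 0.3 —
sized so LDSC recovery tests resolve at 2-SE tolerances in seconds. A
separate `default_pain_architecture` reproduces the published envelope of
chronic musculoskeletal pain cohorts (prevalences 9.2–17.9%, observed-scale
h² 2–7%, r_g ≈ 0.7 within the printed 0.56–0.87, environmental correlation
set so realized binary phenotypic correlations land in 0.18–0.28). The
simulator emits age- and sex-like covariates with zero true effect, which
exercises covariate adjustment without confounding recovery tests.

What the simulator does **not** emulate: recombination-map LD decay,
imputation uncertainty, relatedness or population structure, and
case/control ascertainment (sampling prevalence equals population
prevalence). Tests passing on these cohorts therefore validate the
estimators under their own assumptions, not robustness to stratification or
ascertainment.

## Association scans

`assoc.gwas_scan` residualizes phenotype and all dosages on
[intercept | covariates] via a QR decomposition and fits every SNP in one
vectorized pass; SE uses df = n − C − 2 and P comes from the normal law when
df ≥ 100, else the t law (exact on toy fixtures, conventional at GWAS n).
Binary traits are analyzed by linear regression on the (standardized) 0/1
scale — not logistic — which keeps the observed-scale heritability algebra
intact; χ² = (β/SE)² is scale-invariant, so standardizing the phenotype
changes nothing downstream. Monomorphic SNPs yield a flagged sentinel record
(BETA = 0, SE = ∞, P = 1) rather than an error. QC filters (MAF, INFO, call
rate) are strict inequalities, with per-criterion exclusion counts.

## LD Score regression

Univariate: `χ²_j` regressed on `l_j`; slope·M/N = h² on the analyzed scale,
free intercept. Bivariate: `z₁_j z₂_j` regressed on `l_j`; slope·M/√(N₁N₂) =
genetic covariance, free intercept (for fully overlapping cohorts its
expectation is near the phenotypic correlation). Weighting is a fixed,
documented two-pass scheme — pass 1 `1/(2 l_j²)`, pass 2
`1/(2 (a₁ + N·est₁·l_j/M)² l_j)` with the squared predicted mean floored at
0.01 so near-zero bivariate predictions cannot blow up the weights. The
published software's weighting has unstated constants; this scheme is
reproducible and is tested against a noiseless oracle (exact recovery of
slope and intercept to 1e−10).

Standard errors come from a delete-one-block jackknife over contiguous SNP
blocks (default 200, clipped to ≤ M/2), with pass-2 weights held fixed
across deletions so the T(T+1)/2 fits of `build_cov_matrix` share block
boundaries and yield a joint jackknife covariance `J` of vech(C_G)
(column-major lower triangle). Replicate studies at the default conditions
show the jackknife SE within a few percent of the cross-seed SD of the
estimates. Negative or >1 heritability estimates are flagged, never
truncated, so Monte Carlo interval sampling sees honest noise. Empirical LD
scores use the small-sample adjustment `r² − (1−r²)/(n−2)` within a
positional window (default 1 Mb), computed per pseudo-chromosome.

## The GIP decomposition

`GipDecomposition` symmetrizes `C_G` (rejecting asymmetry beyond 1e−8) and
eigendecomposes it; `fit()` returns a results object with loadings,
eigenvalues, explained-variance tables and `summary()`. Conventions where
the mathematics is indifferent:

- columns ordered by descending eigenvalue; ties (|Δλ| < 1e−12) broken by
  descending lexicographic order of absolute loadings, so a scalar matrix
  returns identity loadings;
- sign fixed so each column's loading sum is positive (shared-axis GIPs come
  out all-positive); if the sum is ~0, the largest-magnitude entry is made
  positive;
- negative eigenvalues (noise in an estimated `C_G`) are flagged, retained.

Explained variance: `λ_k/Σλ` in total, `a_tk² λ_k/(C_G)_tt` per trait; both
are exact eigen-identities (rows sum to 1) and are property-tested on random
PSD matrices. Traits are standardized before weighting, so `C_G` is on the
standardized observed scale, loadings are scale-free, and
`h²(GIPk) = λ_k/(a_kᵀ C_P a_k)` is self-consistent with the predicted GIP
phenotypic correlations `a_jᵀ C_P a_k`.

**Loading confidence intervals.** vech(C_G*) is drawn from
MVN(vech(C_G), J) (J projected to the nearest PSD by eigenvalue clipping if
needed, with a warning; 1000 draws by default, seeded); each draw is
symmetrized and eigendecomposed, draw columns are matched to the
point-estimate columns greedily by maximal |inner product| with the sign
flipped positive (guarding against order/sign switching under noise), and
the 2.5/97.5 percentiles across draws form the 95% intervals. These
intervals are only meaningful when eigenvalues are separated relative to
sampling noise: for near-degenerate trailing eigenvalues the eigenvectors
themselves are unidentified and coverage degrades — visible in the
simulation coverage study, which therefore uses a separated spectrum, and a
known caveat when interpreting trailing-GIP loadings on real data.

**Two GWAS routes.** Individual-level: scan the GIP score columns
(standardized traits × frozen loadings) with the same covariates as the
trait GWAS. Summary-level: `β_GIPk = Σ_t a_tk β_t` with
`SE² = Σ_{t,s} a_tk a_sk C_P[t,s] SE_t SE_s`, the standard estimation-error
covariance approximation for one fully overlapping cohort. The two routes
agree on simulation to z-correlation > 0.999; which of them a given
published study used is immaterial under this contract. Replication cohorts
are always scored with discovery loadings — never refitted.

## Post-GWAS processing

- GC correction divides χ² by the per-phenotype LDSC intercept;
  `SE_GC = SE·√intercept`. P-values are computed in log10 space through
  `norm.logsf` (1-df χ² tail = 2Φ(−√x)), surviving P far below 1e−300. At
  desk scale the intercept estimate is noisy (SE ~0.1–0.3), so corrected
  scans can be anti-conservative when the intercept estimate falls below 1;
  the pipeline applies the intercept as estimated, as the source method
  does at biobank scale where it is tightly determined.
- IVW meta-analysis matches records on (CHR, POS), aligns alleles to the
  first cohort carrying each SNP (swap → sign and EAF flip; other pairs
  dropped with a log), and combines over whichever cohorts carry each SNP,
  summing N over contributors.
- Loci are positional: greedily take the smallest-P SNP under the threshold,
  absorb ±250 kb, repeat; ties broken by (CHR, POS). No LD-based clumping —
  the locus definition is purely positional.
- Replication: threshold = α / (total discovery loci across phenotypes);
  a locus replicates iff its lead's meta-analysis P beats the threshold
  **and** the effect sign matches discovery. Sign consistency is a
  deliberate strengthening of the plain Bonferroni rule.
- Study-level genome-wide threshold: 5e−8 divided by the number of GIPs
  (1.25e−8 for four).

## Pipeline and reproducibility

`run_pipeline` executes simulate → trait GWAS → empirical LD scores → LDSC
covariance → GIP fit (loadings frozen) → GIP GWAS → GC → clump →
replication meta → replication gate. Every stochastic step draws its seed
from one root seed through `numpy.random.SeedSequence`; the manifest records
all child seeds, thresholds, intercepts and package versions, and a rerun
from the same config is bit-identical. A null architecture (C_G = 0) runs
through the same path and yields an empty locus table; the
explained-variance table degrades to NaN when the eigenvalue sum is
non-positive rather than aborting the run.

## Known limitations

- OLS stands in for the mixed-model scans used at biobank scale: simulated
  individuals are unrelated, so the relatedness term the mixed model adds is
  unnecessary here. This is the one deliberate methodological substitution.
- No stratified/partitioned LDSC, no constrained-intercept mode, no
  reference-panel LD scores.
- The liability-scale heritability of a GIP is not defined here: a GIP is a
  continuous composite without a prevalence, so no liability transform is
  offered for GIP-level estimates.
- Phenotypic correlations for the summary-only route must be supplied (or
  estimated on a cohort); for non-overlapping cohorts the summary route's SE
  approximation does not apply.
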