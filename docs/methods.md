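# Methods

## The statistic

For SNP *j*, let g₁ⱼ ∈ {0,1,2}ⁿ¹ and g₂ⱼ ∈ {0,1,2}ⁿ² be the additive codes
of the two populations at a common counted allele, and u, v the
genotype-slope estimates from an ordinary per-population OLS of the trait
on intercept, sex, parity and genotype. The cross-population
phenotype-associated variant (XP-PAV) statistic compares the scaled
vectors x = g₁ⱼ·u and y = g₂ⱼ·v with a two-sample t-test. The default is
Welch's unequal-variance form with Welch–Satterthwaite degrees of freedom,
because the two cohorts differ in size and — whenever u ≠ v — in scaled
variance; an equal-variance pooled mode is available behind a flag. Since
mean(x) = u·mean(g₁ⱼ) and var(x) = u²·var(g₁ⱼ), the statistic reduces to

    t_j = (u·ḡ₁ − v·ḡ₂) / sqrt(u²s₁²/n₁ + v²s₂²/n₂),

which the scan evaluates in closed form for all SNPs at once.

Two-sided p-values are used throughout: the hypothesis is "the effect
differs", with no direction. A SNP is *degenerate* — excluded from
standardization and significance — if either beta is unavailable (constant
genotype column in the GWAS) or either scaled vector has zero variance
(monomorphic column, or beta exactly 0). Degenerate records are carried
through every output with `status=degenerate` so that
#ok + #degenerate = #input always holds.

### Genome-wide standardization and the two p modes

The raw per-marker t-test is not usable for significance: the scaled
vectors take only three support points and the cohorts are large, so
nominal p-values collapse toward zero. Significance is therefore judged
against the genome-wide ensemble of t-values, in one pool (no
per-chromosome stratification), in either of two modes:

- **z mode (default):** z_j = (t_j − mean(t))/sd(t) over all ok SNPs
  (sample sd), p_j = 2(1 − Φ(|z_j|)).
- **empirical mode:** p_j = (1 + #{k ≠ j : |t_k| ≥ |t_j|})/m, the add-one
  rank-based two-sided tail probability; the most extreme marker gets 1/m
  and ties share the larger p, so p is never 0.

Both columns appear in every output table.

**Calibration of the two modes differs, and the difference is intrinsic.**
Under a simulated global null (equal allele frequencies, identical true
effects) the genome-wide t distribution is strongly heavy-tailed
(excess kurtosis ≈ 67 at the default calibration scale). The reason: t is
invariant to common rescaling of (u, v), so it depends only on the
*direction* of the estimated effect pair; when one population's estimate is
near zero the statistic approaches ±ḡ√n/s regardless of any real signal.
Standardizing by mean and sd cannot normalize such a distribution, so
z-mode p-values are not uniform — they are conservative in the middle and
anti-conservative in the far tail, although the p < 0.05 mass stays near
0.03–0.05. The empirical mode is exactly uniform on {1/m, …, 1} by
construction and is the mode to use when calibrated type-I error matters.
The z mode is retained as the default because it matches the
standardization described for this statistic and supports thresholds finer
than 1/m. The acceptance suite asserts uniformity of the z mode and is
expected to fail there; `scripts/acceptance.py` reports the measured
Kolmogorov–Smirnov p for both modes so the contrast is visible in numbers.

**Power at calibration scale is limited by GWAS noise.** The same
direction-only character means the scan can only distinguish a divergent
SNP when the *estimated* pair (û, v̂) points measurably away from the û = v̂
diagonal. At the default sizes (400 + 800, h² = 0.3, 50 causal betas of
sd 1) the per-SNP beta standard error is ≈ 0.6, so planted shifts up to
δ = 1.0 are within estimation noise and rejection at planted SNPs is close
to the background rate; the acceptance power-curve test asserts the
steeper ordering and is expected to fail at this scale. This is a
sample-size statement, not an implementation artifact: the original
application used 3,356 + 6,965 individuals, where beta noise is ~3× smaller.

## Allele-coding harmonization

Flipping the counted allele at one population maps g·β to (2−g)·(−β), which
changes t, so harmonization is a hard precondition of the scan (asserted at
runtime and covered by a test). Conventions:

- Panel 1 (population 1) wins every coding conflict; panel 2 columns with a
  swapped allele pair are reflected (g → 2−g) and their alleles swapped.
- No strand flipping is attempted for A/T and C/G SNPs: chip data from one
  platform share strand, and silent flipping is a correctness hazard. An
  allele pair that cannot be reconciled by a swap raises an error naming
  the SNP.
- `intersection` keeps shared SNPs only; `union` (the default, mirroring
  post-QC marker counts that exceed either population's panel) inserts
  all-MISSING columns for one-sided SNPs. The pipeline fills such columns
  from the other population's rounded mean code before the within-panel
  mean imputation — the only deterministic fill available without
  haplotype information.

## Quality control and imputation

Markers with minor allele frequency strictly below 0.05 or missing-call
proportion strictly above 0.05 are removed (boundary values retained —
literal inequality directions). MAF is computed per population, before
harmonization, on non-missing calls as min(p, 1−p) with p = mean(code)/2.
A SNP failing both filters is counted once, under MAF; an all-missing
column falls to the missingness filter. Missing calls are imputed with the
per-SNP rounded mean (numpy round-half-to-even, clamped to {0,1,2}) — a
deterministic stand-in for haplotype-based imputation, documented as
non-equivalent: it preserves per-SNP means to within 0.5/n but ignores LD
entirely.

## GWAS details

The scan residualizes the trait and all genotype columns on the shared
covariate block (intercept + sex + parity) via one thin-QR projection and
then fits each SNP by simple regression on its residualized column
(Frisch–Waugh–Lovell). This is algebraically the full OLS genotype
coefficient; the test-suite checks it against a normal-equations oracle to
1e−10. Standard errors use n − k degrees of freedom (k = intercept +
covariates + genotype). Parity enters as a single numeric covariate, sex as
its 1/2 code; samples with missing trait or covariates are dropped listwise
and counted in `n_used`. Genotypes are used raw (0/1/2, no centering —
centering changes only the intercept). Constant genotype columns yield
`degenerate` records (beta = NaN); zero-residual fits are flagged
`exact_fit` with se = 0. Population structure beyond the breed split is not
modeled (plain linear model, no GRM correction, no PCs) — matching the
method's original usage.

## Population structure check

The realized relationship matrix is VanRaden's first form,
G = ZZ′ / (2Σⱼ pⱼ(1−pⱼ)), with Z the genotype matrix centered at 2pⱼ and
pⱼ the counted-allele frequency; monomorphic SNPs are skipped and counted.
When two breeds are compared, frequencies come from the merged panel (both
breeds plotted in one space). PCA is the eigendecomposition of G;
coordinates are eigenvectors × √eigenvalue, eigenvalues sorted
non-increasing, negative numerical eigenvalues floored at zero for
variance-explained, and each eigenvector's sign fixed so its
largest-magnitude loading is positive (determinism across linear-algebra
backends).

## The simulator

Balding–Nichols, not coalescent: ancestral frequency p ~ Uniform(maf_range)
per SNP; each population's frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = fst (F = 0 degenerates to both equal to p); genotypes Binomial(2, freq)
under HWE. The trait is intercept + sex·sex_effect + parity·parity_effect
+ Σ g·β + Gaussian noise, with noise variance set from the realized genetic
variance so the genetic fraction hits h². Causal betas ~ N(0, effect_sd²)
shared between populations; a chosen subset of causal SNPs gets
β₂ = β₁ + δ (an additive shift, chosen over an independent redraw for
interpretable power curves). `null_dataset` enforces the global null:
no divergent set and *one* frequency draw per SNP used by both populations.

Defaults are the calibration-scale study conditions used by the test-suite
and acceptance script: n₁ = 400, n₂ = 800 (the smaller cohort first,
mirroring the original breeds' imbalance), m = 2,000 SNPs on one autosome
with chip-like 20–80 kb spacing, F_ST = 0.05, maf_range (0.05, 0.95)
(post-QC chip markers), 50 causal SNPs with effect_sd 1.0 in trait units,
20 divergent with δ = 0.5, h² = 0.3, sex effect 10, parity effect 2,
intercept 100. Sex ~ Bernoulli(0.5) coded {1,2}, parity uniform on 1–6.
All randomness flows from one integer seed.

What the simulator does **not** emulate: linkage disequilibrium and sweep
haplotype structure (each SNP is drawn independently — adequate for a
per-marker test, useless for haplotype methods), genotyping error, pedigree
or family structure, and non-Gaussian trait noise. Passing tests therefore
demonstrate correctness of the per-marker computations and calibration
under independence, not robustness to LD or cryptic relatedness in real
chip data.

## Annotation and reporting

Gene intervals come from BED (0-based half-open, converted to 1-based
inclusive on ingestion) or GFF3 (1-based inclusive, `gene` features),
read via pyranges. A SNP maps to every gene whose interval, extended by a
symmetric window (default 0 bp — strict containment; the matching rule in
the original application is unstated), contains its 1-based position;
multi-gene hits preserve annotation order. Disjoint chromosome name sets
between SNPs and genes raise immediately (catches '1' vs 'chr1'
mismatches). Enrichment is not computed: the package emits a ranked gene
list (by best SNP p-value) for external tools. Venn counts partition the
union of the GWAS-significant (raw or Bonferroni) and scan-significant SNP
sets exactly. Manhattan exports use natural chromosome sort and cumulative
offsets equal to prefix sums of per-chromosome maximum positions.

## Numerical and degenerate-input conventions

- Genotypes are int8 with −1 as the missing sentinel; all statistics
  promote to float64.
- GWAS degeneracy threshold: residualized genotype sum-of-squares
  ≤ 4n·eps (codes are O(1)), catching constants and covariate-collinear
  columns without misflagging real variation.
- `welch_t` returns (NaN, NaN) — never propagates NaN silently into a
  scan — when both variances are zero; the scan maps this to
  `status=degenerate`.
- `standardize_t` requires ≥ 2 finite values with nonzero spread and
  errors otherwise (an all-identical scan is not standardizable).
- Empirical p uses ≥ with the add-one correction so ties share the larger
  p and p > 0 always.
- PLINK text filesets cannot carry which allele is counted, so `write_panel`
  emits a reference-allele sidecar (`PREFIX.ref`: snp_id, counted, other)
  alongside `.ped/.map`; `read_panel` honors it when present and otherwise
  falls back to first-seen-allele coding. This makes bed↔ped round trips
  exact, including monomorphic and all-missing columns.
- The pipeline recomputes every stage per run instead of resuming from
  partial outputs: stages hand objects forward in memory, and with a fixed
  seed the run is deterministic end to end, so re-running *is* the resume
  mechanism at this scale.

## Known limitations

- The z-mode p-values are not calibrated under the null (see above); use
  the empirical mode for type-I-error-sensitive work.
- Power at the default calibration sizes is minimal for effect shifts
  within GWAS estimation noise; detecting differential effects of
  realistic size needs cohorts in the thousands.
- Mean imputation is not a substitute for haplotype-based imputation of
  real chip data with substantial missingness.
- No multi-allelic sites, VCF ingestion, strand resolution, LD pruning,
  mixed-model association, or FDR control (the scan's significance rule is
  a raw p < 0.05, by design).
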