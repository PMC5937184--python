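# Methods

`behavarch` implements a two-armed comparative analysis of the genetic
architecture of behavior: (i) a meta-analysis of per-locus effect sizes
compiled from behavioral QTL mapping studies across species, and (ii) a
within-population analysis of an inbred-line mapping panel — SNP
heritability, single-SNP association, pleiotropy, and a trait-pair
directionality test.  This note records the models, the defaults and why
they were chosen, what the synthetic data emulate, and the numerical
choices that matter.

## 1. The compiled-QTL meta-analysis

**Unit of observation.** One significant QTL: its effect size in percent
phenotypic variance explained (PVE, in (0, 100]), a significance score
(LOD or −log10 P), a behavioral category, the cross's species pair and
type (intra- vs interspecific), study sample size, and the cross
parents' divergence in years and generations.

**LOD conversion.** Interval-mapping LOD scores are likelihood-ratio
statistics: `chi2 = 2 ln(10) · LOD` on 1 df, so
`−log10 P = −log10 SF_chi2(2 ln10 · LOD)`.  For 1 df this equals
`−log10[2 Φ(−sqrt(chi2))]`, which we evaluate through the normal
log-survival function — accurate for arbitrarily large LOD where the
direct chi-square tail underflows.

**Category tests.** A focal category is compared to all remaining loci
with a two-group Kruskal–Wallis test (midrank ties correction).  For
tiny tables an exact variant enumerates every assignment of the pooled
values to the two group sizes; the default is the asymptotic chi-square
P, which is what a 1000-locus table calls for.

**Permutation null for category means.** The observed category mean is
compared against means of draws (without replacement, same size) from
the *complementary* loci; `p = #(null > observed) / B` with ties
counting toward the null (a `plus_one` variant gives the
`(k+1)/(B+1)` estimator).  Because the null pool excludes the category
itself, the null center anticorrelates with the observed mean; the
procedure is therefore only asymptotically calibrated as the category
fraction shrinks.  At a 20-vs-80 split the type-I error is ~0.11; at
the proportions the test is actually used at (a ~12% category in a
1007-locus table) it is nominal (measured 0.048 over 500 null
datasets).  Calibration checks accordingly run at table proportions.

**Confounder checks.** Divergence–effect correlation is Pearson's r of
PVE on log10(years diverged) (divergences span orders of magnitude);
interspecific vs intraspecific crosses are compared with the same
two-group rank test.

**Mixed models.** PVE is modeled with behavioral category as the fixed
effect (treatment-coded against the alphabetically first category).
"Sample size" and "generations diverged" are study-level covariates, so
a random slope grouped by study is only well posed jointly with a study
intercept; the implemented random structure is: study intercept +
independent random slopes of z-scored sample size and z-scored
log10(generations) by study, plus optionally a random intercept per
cross type.  The frequentist fit is REML via statsmodels' MixedLM with
variance components; the Bayesian fit is a conjugate Gibbs sampler for
the same design:

- `y = Xb + Σ_k Z_k u_k + e`, `u_k ~ N(0, σ²_k I)`, `e ~ N(0, σ²_e I)`;
- priors: `b ~ N(0, 10^8 I)` (diffuse), `σ² ~ InvGamma(0.001, 0.001)`
  per component (the conventional weakly-informative default);
- blocked draw of `(b, u)` from its multivariate-normal conditional
  (one Cholesky per iteration), then inverse-gamma draws of the
  variances;
- defaults: 300,000 iterations, 10,000 burn-in, thinning 10, five
  independent chains.  Convergence is summarized by the Gelman–Rubin
  PSRF per parameter (warning above 1.1); intervals are 95% highest-
  posterior-density (shortest-interval estimator on the pooled draws).

Candidate random structures (all nonempty subsets of {sample size,
generations, cross type}, each with the study intercept) are ranked by
DIC computed from the conditional deviance: `DIC = 2·D̄ − D(θ̄)`.  With
study-constant covariates the slope terms are near-collinear with the
study intercept, so DIC differences between slope models are
intrinsically small; effects that vary within studies (e.g. cross type)
are where the ranking has real discrimination.

## 2. Panel analyses

**GRM.** Per-SNP standardized estimator
`A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / v_i` with missing
dosages mean-imputed per SNP.  `v_i = 2p_i(1−p_i)` for outbred samples;
for fully inbred lines (dosages {0, 2}) the dosage variance is
`4p(1−p) = 2p(1−p)(1+F)` with F = 1, and using the outbred denominator
would put the diagonal near 2 and bias `h² = Vg/Vp` downward by
roughly a factor two (verified numerically) — so inbred panels default
to the inbred denominator, matching the inbred-GRM mode of standard
GCTA-style tooling for inbred panels.  SNPs at MAF ≤ 0.01 are removed
first (strict inequality, mirroring the usual `--maf` flag semantics).

**GREML.** Single-component REML under
`y ~ N(1μ, Vg·A + Ve·I)`.  The GRM is eigendecomposed once (cached on
the `Grm` object), after which every iteration is O(n): a short EM-REML
warm start (3 iterations), then average-information updates with step
halving — an undamped AI step that overshoots the `Vg ≥ 0` boundary is
clipped and rejected, and without damping the fit stalls in EM crawl on
rank-deficient GRMs (e.g. a single-SNP subset).  Convergence at
|ΔlogL| < 1e-8, max 100 iterations; components floored at `1e-8·Vp`
with boundary solutions flagged.  `SE(h²)` comes from the inverse AI
matrix by the delta method; the test of `Vg = 0` uses
`LRT = 2(logL₁ − logL₀)` against the boundary mixture
`½χ²₀ + ½χ²₁`.  Trait screening keeps LRT P strictly below α = 0.05.
GREML runs intercept-only (no covariates), configurable upstream by
residualizing the phenotype.

**Association scans.** Per SNP, ordinary least squares of the line-mean
phenotype on dosage (intercept + slope), two-sided t on n−2 df, lines
with missing data dropped per SNP, monomorphic SNPs flagged
not-testable.  No relatedness correction, LD pruning, or genomic
control — deliberately the basic quantitative association test.
Significance thresholds are strict (`p < 5e-6` by default; `1e-5` for
cross-battery comparisons; both exposed as flags).

**Pleiotropy and effect matrix.** Hit sets at the threshold are
combined into (a) a binary SNP × trait incidence restricted to SNPs
significant for ≥ 2 traits, with an optional per-gene rollup from a
SNP→gene annotation map, and (b) a dense effect matrix: rows are the
union of hit sets, entry (s, t) is SNP s's β in trait t's scan whether
or not significant there.  Trait structure is summarized by pairwise
Spearman correlation over the matrix rows (pairwise-complete, ≥ 3
shared rows, midranks for ties).

## 3. Trait-pair directionality

For traits x and y with hit sets s1, s2 (each must exceed 3 SNPs), four
effect-size vectors are read off the matrix — xx, xy (betas of x and y
at s1) and yy, yx (betas of y and x at s2) — and

    x_cor = ρ(xx, xy),  y_cor = ρ(yy, yx),  D = |1 − |x_cor − y_cor||.

D near 0 means one cross-correlation is strong and the other absent:
the signature of a mediated architecture (G → P1 → P2), because at the
mediator's hits both traits respond proportionally, while the
downstream trait's own hits say nothing about the mediator.  Symmetric
pleiotropy (P1 ← G → P2) makes both correlations strong and similar,
pushing D toward 1.

Significance: all four vectors are independently permuted `n_perm`
times (1000 by default; a joint mode permuting each hit set's two
vectors together is available), D is recomputed, and
`p = #(D_obs > D_perm)/n_perm` — small when the observed D is unusually
close to 0, with ties favoring the null.  When the vectors are so short
that fewer distinct orderings than `n_perm` exist, the exact null is
enumerated instead (the permutation distribution of a Spearman
correlation depends only on the relative ordering, so it has L! atoms
per side).  P-values are Bonferroni-multiplied by the number of pairs
actually tested.  The asymmetry screen — one |ρ| > 0.5 and the other
< 0.1, on absolute values so strong negative correlations count — is
applied at reporting time; a "significant" pair must pass both the
adjusted-P rule and the screen, and a pair whose reverse ordering also
passes is flagged as directionally ambiguous rather than dropped.

## 4. Synthetic data: what it emulates, and what it does not

**Compiled-QTL table.** 1007 loci in 10 behavioral categories spread
over ~115 studies (~9 loci/study share a species pair, sample size and
divergence).  Effect sizes are exponential with category-specific means
(courtship 23%, feeding 17%, emotion/social 5.5/6.5%, others 8.5% —
chosen so the global mean is ≈9.5%, ~88% of loci fall below 20% PVE,
and the courtship mean is ~3× the rest), truncated to (0, 100] with the
exponential scale solved so the truncated mean equals the configured
mean.  A truncated exponential cannot exceed mean 50, so configured
means clamp at 49.  Divergence enters multiplicatively — mean PVE
scales by 1.9× per decade of years diverged around the panel centre,
renormalized within category — which yields a clearly positive
divergence–effect correlation (marginal r² ≈ 0.1–0.27 across seeds)
and systematically larger interspecific effects.  A stronger marginal
correlation would require shrinking the per-locus exponential
dispersion, i.e. breaking the marginal effect-size distribution; this
trade-off is accepted.  30% of studies are interspecific (divergences
1–500 Myr; intraspecific 0.01–1 Myr); generation times are log-uniform
on 0.1–5 years; ~70% of loci report LOD, the rest −log10 P (generated
consistently via the package's own conversion).

**Genotype/phenotype panels.** Fully inbred biallelic lines: per SNP an
alternate-allele frequency uniform on the configured MAF range, dosages
`2·Bernoulli(p)` (outbred `Binomial(2, p)` supported).  SNPs are drawn
independently — there is **no linkage disequilibrium** — so hit counts
per trait are much smaller than a real dense panel would give, and any
LD-induced confounding of the directionality test is outside what these
simulations can show.  Phenotypes are strictly additive
(`y = Σ β_i x_i + e`, Gaussian noise scaled to the realized genetic
variance so the target h² holds exactly in expectation); no dominance,
epistasis, or GxE.  Effects default to standardized (variance
∝ 1/Var(x_i)), the regime in which a single GRM component captures the
genetic variance; explicit betas are accepted everywhere.

**Pleiotropy patterns.** "Fork" generates both traits from the same
causal loci with one shared beta vector and independent noise.  "Chain"
generates the downstream trait as `a·(mediator) + own component`: the
own component comes from the trait's own (disjoint) architecture when
one is configured, otherwise pure noise.  The own component is
essential — a downstream trait with no independent determinants has
true effects exactly proportional to its mediator's at every SNP, both
cross-correlations approach 1, and the directionality test cannot
detect anything.  The detectable regime mirrors the real mediated
examples (a polygenic behavior influenced by a morphological trait).

**Power-study conditions.** The chain/fork studies run at 2000 lines ×
1500 SNPs with 60 causal loci per trait at h² = 0.92, chain coefficient
0.35, and a per-panel hit threshold of 1e-4 (≈0.15 expected false hits
per scan).  These sizes were chosen so per-trait hit sets reach ~20–35
SNPs — the regime in which the permutation null of D (its correlation
spread scales as 1/√L) is informative, emulating the published
analyses' hundreds of significant SNPs per trait.  At a few hundred
lines with independent SNPs, hit sets cap near 15 SNPs and no effect
size gives the test useful power; that constraint is a property of the
statistic, not of this implementation.  Measured under these
conditions: chain detection ≈ 0.9 at P < 0.05, fork false-positive
rate ≈ 0 (the fork null is conservative because symmetric pairs sit at
D ≈ 1, the far end of the null).

**What passing these simulations does not show about real data:** no
LD, no shared environment or batch structure, no measurement-error
heterogeneity between source studies, no publication bias in the
compiled table (the Beavis effect is emulated only insofar as sample
size is independent of true effects), and inbred lines are perfectly
homozygous.

## 5. Numerical and interface choices

- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator, permutation test, and sampler is bit-reproducible given
  its seed, and seeds are recorded in output metadata and the pipeline
  run summary.
- Strict inequalities at every screening boundary (MAF 0.01, GWAS
  5e-6/1e-5, GREML α = 0.05, >3 hits for directionality); boundary
  values are excluded and tested.
- Positions are 1-based (bim/VCF convention).  The plink bed codec
  (magic `6c 1b`, SNP-major `01`, 2-bit codes 00=hom-a1 / 01=missing /
  10=het / 11=hom-a2) is implemented in `behavarch.io` and round-trips
  bit-exactly.  `.phen` files accept `NA` and `-9` as missing.
- TSV outputs round to 6 significant digits; the JSON run summary keeps
  full precision of counts/seeds/thresholds.
- Validation problem sizes (50 GREML replicates at 1000×5000; 500-
  dataset calibration runs; 25 chain / 200 fork replicates) keep each
  study's Monte-Carlo error comfortably inside the tolerance it is
  compared against while finishing in minutes on one core.

## 6. Known limitations

- The Gibbs sampler updates all location parameters in one block;
  for very large numbers of studies the per-iteration Cholesky grows
  cubically (fine at a few hundred levels, not tuned beyond that).
- DIC uses the conditional (residual-level) deviance; marginal-deviance
  DIC variants would rank differently in principle.
- GREML supports a single genetic variance component; bivariate GREML
  (genetic correlations), dominance, and X-linked models are out of
  scope.
- The directionality statistic compares only the two canonical patterns
  (mediated vs symmetric); it is not causal inference, and with
  correlated phenotypes the estimation errors of the two scans are
  correlated, which inflates y_cor at weakly-powered hits — another
  reason the test needs well-powered hit sets.
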