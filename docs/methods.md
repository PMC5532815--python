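# Methods

This note documents the statistical models, the numerical choices behind
them, the synthetic cohorts the tests run on, and the known limitations.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Editing levels and candidate-site filters

The editing level of a site is Φ = edited/(edited+unedited) from strand-aware
counts: on a `+` site the edited base reads G and the unedited base A on the
reference-forward strand; on a `-` site, C and T. Bases other than the
edited/unedited pair, deletions and unaligned read positions are ignored.
Base- and mapping-quality thresholds default to 0 (plain pileup) and are
exposed as arguments.

Candidate sites for association analysis must satisfy, across the analyzed
individuals: mean edited coverage ≥ 2, mean total coverage ≥ 10, and a Φ
quantile spread q90 − q10 ≥ 0.10; sites at known SNP positions are excluded
(an A/G polymorphism is indistinguishable from editing in RNA reads).
Quantiles are linear-interpolation sample quantiles; all comparisons are
inclusive ("at least"). Individuals with zero coverage contribute to the
coverage means (which are per analyzed individual) but not to the quantiles,
where Φ is undefined; `n_individuals` can override the denominator when zero
rows are omitted from a table.

## edQTL model

For one site and one SNP with dosages g_k ∈ {0,1,2}:

    y_k ~ Binomial(n_k, Φ_k),  logit(Φ_k) = μ + β g_k + u_k,  u_k ~ N(0, σ²).

The per-individual random effect u_k absorbs biological variability beyond
binomial sampling noise; ignoring it (plain logistic regression on the
counts) is anti-conservative whenever σ > 0, which the tests demonstrate.
The marginal likelihood is a product of one-dimensional binomial
logit-normal integrals, evaluated by **adaptive Gauss–Hermite quadrature**:
each integrand is log-concave, so quadrature nodes (default 9) are recentred
and rescaled at the per-observation Laplace mode found by Newton iterations.
Against direct numerical integration the marginal log-likelihood is accurate
to ~1e-8 across count regimes, and the scheme is exact in the σ → 0 limit.
Gradients use the posterior-moment identities ∂logI/∂μ = E[x−μ]/σ² and
∂logI/∂logσ = E[(x−μ)²]/σ² − 1 on the same grid, and (μ, β, log σ) are
maximized with L-BFGS-B; log σ is bounded in [log 1e-6, log 10].
β = 0 is tested by likelihood ratio against χ²₁. `sigma_fixed` pins σ
instead of estimating it (σ = 0 reduces exactly to logistic regression,
which is also the independent oracle in the tests, along with `lme4::glmer`
at matched quadrature order). Optional covariates (population, batch) enter
both the full and the null model as additive fixed effects, and the CLI's
`--by-group` mode runs the scan separately per population subset, mirroring
per-population analyses. Sites need ≥ 2 dosage classes among covered
individuals; otherwise they are reported untestable.

*cis* windows are ± 200 kb around the site, bounds inclusive, with a MAF
floor of 0.05 (configurable) among the analyzed individuals. Per site, the
reported edQTL SNP is the closest among those attaining the minimal p-value,
residual ties broken by lower genomic position.

**Permutation FDR.** Individual labels of the genotype panel are permuted
jointly across all *cis* SNPs of a site (preserving LD between SNPs while
breaking the genotype–phenotype link); 5 permutations per site by default.
The pooled per-site minima form the empirical null, and the cutoff z is the
largest observed best-p such that
[fraction of null ≤ z]/[fraction of observed ≤ z] ≤ f at FDR level f = 0.10.
The fractions use ≤ (the plug-in estimator): with strict < the smallest
candidate would have an empty denominator. Sites with best p ≤ z are called.

## ASED model

Replicate k (a heterozygous individual, or one technical replicate of a
single individual) contributes paired counts for the two alleles:

    I_1k ~ Binomial(n_1k, Φ_1k),  logit(Φ_1k) ~ N(α_k, σ₁²)
    I_2k ~ Binomial(n_2k, Φ_2k),  logit(Φ_2k) ~ N(α_k + δ, σ₂²).

α_k is a free fixed effect shared by the two alleles of the pair, δ the
allelic shift on the logit scale, σ₁², σ₂² per-allele overdispersion across
replicates. Given α_k the double integral factorizes into two 1-D binomial
logit-normal marginals, evaluated by the same adaptive quadrature (default
15 nodes). All of {α_k}, δ, log σ₁, log σ₂ are maximized jointly with
analytic gradients; σ's are bounded below at 1e-3 (variance 1e-6) to avoid
boundary non-identifiability. Starting values: α_k at the clamped logit of
the pooled per-replicate Φ, δ = 0, σ = 0.5; if L-BFGS-B reports failure the
fit is retried from alternative σ starts, and the null optimum is floored at
the full fit's ancillary parameters evaluated at δ = 0 (a failed null line
search must not masquerade as signal). δ = 0 is tested by likelihood ratio
against χ²₁ and sites are called by Benjamini–Hochberg at FDR 10%.

Replicate filters (both alleles covered; pooled Φ = (I₁+I₂)/(n₁+n₂) ≥ 1%,
the pooled reading of the ambiguous per-allele alternative; ≥ 3 surviving
replicates) are applied before fitting. Reads are assigned to alleles only
when aligned across both the SNP and the editing site; reads spanning
several phased heterozygous SNPs with conflicting calls are discarded, and
A/G (equivalently T/C) SNPs are flagged since editing at the SNP itself can
masquerade as allelic signal. Per-replicate, per-allele editing levels are
reported with likelihood-ratio 95% confidence intervals
{Φ₀ : 2[ℓ(Φ̂) − ℓ(Φ₀)] ≤ χ²₁(0.95)} solved by bracketed root finding; at
boundary MLEs the corresponding bound is exactly 0 or 1.

**Known limitation — calibration of the δ LRT.** The estimator maximizes one
free baseline per replicate, so the parameter count grows with the number of
replicates; the variance MLEs are inconsistent (the classical
incidental-parameters effect) and the model-implied uncertainty of δ̂ is
underestimated whenever true overdispersion is present. The measured
consequence (computed by the acceptance suite, not assumed): at 10
replicates, per-allele coverage 50 and σ = 0.3 the empirical type-I error at
nominal 0.05 is ≈ 0.11 rather than 0.05, and the inflation does not vanish
with more replicates or more coverage; with σ = 0 it is ≈ 0.06. Estimates of
δ itself are accurate (median recovery within ~10% down to δ = 0.5), power
is monotone in δ, and the label-swap antisymmetry of the fit holds, so
rankings and effect sizes are reliable while nominal ASED p-values should be
read as optimistic under strong overdispersion. The edQTL GLMM does not
share this defect (its parameter count is fixed) and is calibrated in the
same conditions.

## LD and GWAS linking

r² is computed from phased haplotype frequencies, D = f(AB) − p_A p_B and
r² = D²/(p_A(1−p_A)p_B(1−p_B)), undefined for monomorphic loci. Catalog
records are kept at GWAS p < 10⁻³ (strict), links require r² > 0.8 (strict)
within a 1 Mb search radius (LD beyond that is negligible at this
threshold), and the haplotype panel can be restricted to a population
subset; the original analysis used the four European panels pooled, and
pooling is the default here with per-population subsets available. Catalog
SNPs absent from the genotype panel are skipped and logged.

## Hairpin structure

The Alu element containing the editing site is paired with its nearest
oppositely oriented neighbour within a configurable span (default 20 kb);
elements without an inverted partner are excluded. Orientation classes
follow the facing ends: a `+` element upstream of a `-` element faces
tail-to-tail, the reverse head-to-head.

The internal folding engine maximizes weighted nested pairing (G-C = 3,
A-U = 2, G-U = 1, minimum hairpin loop 3) with the rule that a G-U pair may
not terminate a helix: every wobble pair must be directly stacked between
two other pairs, mirroring the external folder's `--noClosingGU`. The
dynamic program tracks pair states "may be a helix outer end" (Watson–Crick
only) and "covered by a directly stacked outer pair" (wobble allowed if it
also stacks inward), so the constraint is exact rather than post-processed;
tracebacks prefer stacked continuations deterministically. Scores are the
weighted objective; the number of paired bases is carried separately. The
external mode shells out to `RNAfold --noClosingGU` and reports the
minimum free energy in kcal/mol; the `metric` label on every structure
records which engine produced it.

The spatial distance between SNP and editing site is the shortest path in
the graph whose edges are backbone adjacencies and base pairs — the minimal
formalization of distance "within the secondary structure" — measured on the
reference-allele structure. Allele impact is Δpairs and Δscore
(allele 2 − allele 1) from folding both alleles; class distributions
(significant vs control SNPs, default thresholds p < 10⁻¹⁰ vs p > 10⁻³ on
the association p-value) are compared by two-sample Kolmogorov–Smirnov tests
on the absolute values, with the empirical CDFs emitted as plot data.

## Synthetic cohorts

`SimConfig` holds the study conditions. Defaults: 100 individuals, MAF 0.3,
LD correlation length 20 kb, per-site-per-individual coverage Poisson with
mean 50 (negative binomial when a dispersion is set; the models condition on
coverage rather than modelling it), baseline logit editing α₀ = −2
(Φ ≈ 0.12, typical of lowly edited Alu sites), individual noise σ = 0.3,
per-allele ASED noise σ = 0.3, replicate baselines α_k ~ N(α₀, 1).

* **Genotypes**: Markov haplotype copying — allele j repeats allele j−1 with
  probability exp(−d/ld_decay), else is a fresh Bernoulli(maf) draw. This is
  the simplest mechanism with the monotone r²-distance decay the edQTL
  analysis assumes; `ld_decay` is a correlation length in bp and 0 gives
  independent SNPs. Panels are per site (10 SNPs in ±200 kb by default),
  sites 1 Mb apart, the SNP nearest the site designated causal.
* **edQTL counts**: logit Φ = α₀ + β·dosage + N(0, σ_ind²), edited reads
  binomial given the drawn total — the generative twin of the fitted GLMM.
* **ASED counts**: per replicate, α_k ~ N(α₀, 1); allele 1 logit level
  N(α_k, σ₁²), allele 2 N(α_k + δ, σ₂²); per-allele totals drawn with mean
  `coverage_mean` each — the generative twin of the paired model.
* **IRAlu substrates**: two perfectly reverse-complementary arms (≥ 20 nt)
  around a short spacer, an editable A mid-arm, and a SNP whose reference
  allele pairs and whose alternative allele mismatches (a C opposite the
  editing A at offset 0, the geometry repeatedly seen at edited hairpins).

All generators are pure functions of their seed. What the cohorts do *not*
emulate: mapping bias and alignment artifacts (counts are the unit of
analysis), LD structure beyond monotone decay (no recombination hotspots or
population stratification), covariate/batch structure, shared polymorphism
between sites, and real Alu sequence content (arms are random and perfectly
inverted, so folds are cleaner than genomic IRAlus). Passing benchmarks
therefore demonstrate correctness of the statistics under the stated models,
not robustness to those real-data complications.

## Benchmark sizes

The acceptance suite uses 1000 null ASED cohorts for calibration, 200
cohorts per δ ∈ {0.5, 1, 2} for recovery, 400 overdispersed null sites for
GLMM calibration, 50 repetitions of a 30-site 90%-null mixture for realized
FDR, and a 200-individual × 300-site mixture (20% planted with β = 1.5 and
δ = 2, five SNPs per site, five permutations) for end-to-end recovery.
`scripts/acceptance.py` reports the same quantities at reduced sizes
(e.g. 400 null cohorts, 120-site end-to-end) chosen to keep a full
regeneration within a few minutes on one CPU.
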