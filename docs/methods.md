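# Methods

`multigp` implements joint genomic prediction of phenotypes across several
small pig populations with different genetic backgrounds, together with a
synthetic data generator that reproduces the statistical structure such an
analysis assumes. This note records the models, the numerical choices, and
what the synthetic data do and do not establish.

## Corrected phenotypes

All predictors share one response variable: the corrected phenotype

    y_c(i) = EBV(i) + mean over parities of the estimated residuals of sow i,

which avoids double-counting parental information when genotyped sows are
both relatives and trait carriers. EBV come from a single-trait
repeatability model fitted per population (populations share no pedigree
links):

    y = X b + Z a + W pe + e,
    a ~ N(0, A σ²a),  pe ~ N(0, I σ²pe),  e ~ N(0, I σ²e),

with herd–year–season (HYS) as the fixed effect and A the pedigree
numerator relationship matrix (tabular method; unknown parents are
unrelated, non-inbred founders). Identifiability uses an intercept plus
drop-first-level HYS dummies. Sows with records but no genotype contribute
to REML and BLUP; only genotyped sows carry y_c downstream.

### REML

Variance components are estimated by average-information (AI) REML on the
mixed-model equations. Per iteration the coefficient matrix is factorized
once; scores use the standard trace identities through the inverse blocks
(`dpotri` on the Cholesky factor), and the AI matrix is built from working
variates, so one iteration costs one factorization plus one inversion.
Numerical policies:

* **Starting values** — a moment decomposition of within- vs between-sow
  residual variance after an ordinary least-squares fixed-effect sweep;
  falls back to (0.2, 0.1, 0.7) of the phenotypic variance.
* **Boundary handling** — an AI step that would push a variance negative
  has that component clamped to a tenth of its value (geometric decay to
  the boundary) rather than discarding the whole step; a non-invertible AI
  matrix triggers an EM step.
* **Convergence** — change in −2 log restricted likelihood < 1e-8 or
  maximum relative parameter change < 1e-6, where relative change is
  floored at 1e-4 of the phenotypic variance so a component pinned at zero
  cannot stall termination. Cap 200 iterations, then an error carrying the
  trajectory.
* **Single-record designs** — σ²pe is not identifiable without repeated
  records; `fix_pe_at` holds it constant so the model reduces to the plain
  animal model (this is also how the animal-model oracle test is run).

## Genomic relationships, PCA, LD

* **G matrix** (VanRaden method 1): Z = M − 2P, G = ZZ′ / 2Σp(1−p), with
  allele frequencies pooled over all populations in the analysis — one
  joint G keeps cross-population blocks coherent. QC first (MAF ≥ 0.05,
  marker and individual call rate ≥ 0.90, one combined pass), then
  marker-mean imputation of residual missingness. A 1e-6 diagonal
  stabilizer is added before any inversion.
* **PCA** on genotypes standardized per marker by 2p and √(2p(1−p));
  eigenvalues non-increasing.
* **Adjacent-marker LD**: signed r from two-locus haplotype frequencies,
  r = (f(AB) − f(A)f(B)) / √(f(A)f(a)f(B)f(b)). Phased input is counted
  directly; unphased dosages go through a per-pair EM over the
  double-heterozygote ambiguity (marginal allele frequencies are observed;
  only f(AB) is iterated). On 1,000 simulated individuals the EM and phased
  paths agree within 0.02 mean absolute r. LD *consistency* between two
  populations is the Pearson correlation of signed r over shared adjacent
  pairs, per chromosome (≥ 3 defined pairs) and averaged unweighted.

## ST- and MT-GBLUP

ST-GBLUP fits y_c = 1μ + a + e with a ~ N(0, G σ²a) on the joint reference,
AI-REML for (σ²a, σ²e) over the covariance structure V = Gσ²a + Iσ²e, GLS
for μ, and predicts validation animals through the off-diagonal blocks of
the joint G.

MT-GBLUP treats the same trait in different populations as distinct
correlated traits: a ~ N(0, M ⊗ G) with M the between-population genetic
(co)variance matrix. Since no sow is recorded in two populations, the
residual covariances between population-traits are not estimable and are
fixed at zero — the only identifiable reading of the model. Each
individual's prediction is its additive value on its own population-trait.

M is estimated from bivariate fits of every population pair. The bivariate
restricted likelihood is maximized by a bounded quasi-Newton (L-BFGS-B) on
(log σ²a1, log σ²a2, atanh r, log σ²e1, log σ²e2): the correlation then
stays inside (−1, 1), where the record covariance matrix is guaranteed
admissible. An unconstrained AI walk over σa12 can cross |r| = 1 where V
nears singularity and the step-halving safeguard degenerates into a crawl;
the transformed parameterization removes that failure mode while optimizing
the identical criterion. Estimates on the (−1, 1) boundary are clamped to
±0.999 and flagged. The assembled M takes each population's variance as the
arithmetic mean over its bivariate fits and is bent to positive
definiteness by unweighted eigenvalue flooring (floor 1e-4, cap 10,000
passes; positive-definite input is returned unchanged, and bending is
idempotent).

Variance components (ST and MT alike) are estimated once on the complete
dataset and reused across CV folds.

## Bayesian horseshoe regression

y_c = 1μ + Σ x_k β_k + e with β_k ~ N(0, λ_k²τ²), λ_k ~ half-t(ν, 1),
ν ~ Gamma(4, 1), τ ~ half-Cauchy(0, 1/N) with N the marker count, flat
priors on μ and σ²e. All half-t/half-Cauchy scales use their inverse-gamma
scale-mixture representations, making every conditional conjugate except ν,
which gets a random-walk Metropolis step on log ν whose step size is tuned
to a 20–50% acceptance rate during burn-in. Choices worth stating:

* the slab is λ²τ² literally, not scaled by σ²e;
* N in C⁺(0, N⁻¹) is the number of markers, which keeps the total prior
  genetic variance bounded as panels grow;
* λ² draws are floored at 1e-12 (counted and logged);
* the single-site update loop is JIT-compiled and bit-reproducible given a
  seed. Reference schedule 50,000 / 20,000 / thin 50 (600 kept samples);
  desk-scale work uses 5,000 / 2,000 / thin 10.

A vanishing global scale collapses predictions to μ on data without signal;
with strong planted effects the heavy half-t local tails still allow
escape, which is the prior working as designed rather than a sampler
defect (the `fix_tau` argument exists to make this limit checkable).

## Kernel machine-learning predictors

Features are raw 0/1/2 dosages, unstandardized. KRR uses the closed form
α = (K + λI)⁻¹y_c with no intercept; SVR is ε-insensitive support vector
regression (dual box constraints [0, C], intercept from the KKT conditions;
libsvm backend), with ε = 0.1 on the y_c scale by default since the tuned
tables report only C and gamma. AdaBoost.R2 boosts KRR base learners with
the linear max-normalized loss; the per-iteration error rate is
ε_t = L̄_t/(1 − L̄_t), weights update as D·ε_t^(1−L_t), and the ensemble
prediction is the log-weighted **mean** Σ log(1/ε_t) f_t(x) / Σ log(1/ε_t)
(not the weighted median of other AdaBoost.R2 variants). Weighted fitting
is realized by bootstrap resampling under the current distribution, since
the KRR closed form has no native sample weights. Boosting stops early at
L̄_t ≥ 0.5 (a first learner in that state is kept alone with a warning) or
at a perfect fit (kept, with the error rate floored at 1e-10 to cap the
weight). Default 50 learners.

**Population-specific tuning**: each target population's reference set is
split into five groups; per rotation the joint training set is the union of
the target populations' training groups plus whole auxiliary populations.
Candidates are scored by Pearson correlation on each population's held-out
group separately and averaged over rotations; the argmax per population
wins, ties broken by grid order. Correlation-based scoring ranks the ridge
penalty only weakly when the populations share one training model, so
selected hyperparameters can differ between close grid points from seed to
seed — an observed property of the strategy, not an implementation issue.
Default grids: C ∈ {1..5}, gamma ∈ {5e-5, 1e-4, 2e-4},
λ ∈ {1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.5, 1, 2, 2.5, 3, 4, 5}.

## Cross-validation and metrics

Ten replicates of fivefold CV by default. Per replicate, each target
population is partitioned independently (fold sizes within one); the joint
reference of a fold is the union of target training folds plus whole
auxiliary populations; the identical plan serves every method. Metrics per
validation fold per population: Pearson predictive ability, MSE after
centering both vectors by their own fold means, and the OLS slope of y_c on
predictions (1 = unbiased). Point estimates are means over replicate-folds;
the reported SE is the within-replicate across-fold SE averaged over
replicates — per-fold granularity is the only aggregation compatible with
that SE definition. Methods are compared by paired two-sided t-tests on
replicate means (the folds are shared, so pairing is the natural choice),
Bonferroni-adjusted and capped at 1.

## Synthetic data generator

The generator emulates 2–5 Yorkshire-like sow populations:

* **Divergence** — Balding–Nichols frequencies Beta(p(1−F)/F, (1−p)(1−F)/F)
  around one shared ancestral vector; default FST 0.05. PCA separates the
  populations on PC1 and Hudson's estimator recovers the configured FST
  from the founder pools.
* **Ancestral frequencies** — AR(1) in the latent normal (lag correlation
  0.8, restarting per chromosome) mapped into (0.05, 0.95). Adjacent
  markers on real panels sit on shared haplotype backgrounds and have
  similar frequencies; independent draws would cap attainable adjacent r²
  near 0.33, below observed panel values.
* **LD** — founder haplotypes from a first-order copying chain: adjacent
  markers share a latent uniform with probability 1 − s, preserving
  marginal frequencies exactly while making mean adjacent r² monotone in
  the switch probability s. By default s is tied to the recombination rate
  (s = 55·c/(m_chrom − 1), capped at 0.5), calibrated once so the default
  scale realizes mean adjacent r² ≈ 0.35, within the 0.35–0.40 range
  typical of 50K porcine panels.
* **Pedigree** — 3 generations gene-dropped from 200 founder haplotypes per
  population with Haldane-model recombination (Poisson crossovers per
  chromosome); no cross-population matings; the genotyped cohort is the
  final all-female generation. Sires ≈ n/20 and dams ≈ n/4 per generation
  create half- and full-sib families and positive inbreeding.
* **Trait architecture** — 300 shared QTL; per-QTL effect vectors across
  populations are multivariate normal with the configured correlation
  matrix (default off-diagonal 0.62), and each population's column is
  rescaled so its true-breeding-value variance equals σ²a (column scaling
  preserves the correlations). Imperfect cross-population correlation thus
  lives at the effect level, matching the populations-as-traits
  interpretation.
* **Phenotypes** — 3 parities per sow; record = HYS effect + bv + pe +
  residual, with variances solving h² = 0.12 and repeatability 0.20 at
  σ²a = 1.26 (so σ²pe = 0.84, σ²e = 8.40 by default). HYS levels are
  blocks of 20 sows within (population, parity), effects normal with
  variance σ²e.

Everything derives from `SimulationConfig.seed`; identical seeds give
bit-identical outputs.

**What the generator does not emulate**: genotyping error and residual
missingness patterns of real panels (QC is exercised on clean data unless
missingness is injected), selection and mutation across generations,
age/parity trends in HYS effects, and — because the populations' founder
haplotype pools are conditionally independent given their frequencies —
cross-population LD consistency is lower (~0.2) than between truly linked
populations sharing recent haplotypes (~0.4 in 50K panel data). Passing
recovery tests therefore demonstrate correctness of the estimators under
the assumed model, not robustness to real-data artefacts.

## Problem sizes and Monte-Carlo design

Desk scale is 2 populations × 600 genotyped sows, 2,000 SNPs on 5
chromosomes, scaled down from ~3,700 animals × 47,734 SNPs. At this scale
the bivariate genetic-correlation estimate from corrected phenotypes of
reliability ~0.26 has a sampling SD near 0.45 per dataset, so recovery is
judged on means over Monte-Carlo replicates (12 for the correlation, 20 for
the repeatability-model h²); single-run estimates at this size are
informative about sign and magnitude, not the second decimal. The
repeatability-REML recovery design is 1,500 sows × 3 parities under 75
sires, ~12 s per replicate.

## Known limitations

* Dense linear algebra throughout: pedigrees beyond ~10,000 individuals or
  reference sets beyond ~5,000 genotypes need sparse/iterative reworking.
* The bivariate REML reports no standard errors (the paper's SEs come from
  the information matrix; adding them would require the Hessian at the
  transformed optimum).
* EM haplotype frequencies are per-pair; no multi-locus phasing.
* AdaBoost.R2's bootstrap realization of weighted fitting adds Monte-Carlo
  noise to D_t relative to an exact weighted solver.
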