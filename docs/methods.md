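# Methods and conventions

This note records the model, the estimators, and the numerical and
statistical conventions the package commits to.  All problem sizes
quoted here are this package's own desk-scale choices.

## Source populations and architectures

Two populations A and B diverge from an ancestral population under the
Balding–Nichols model: for each locus an ancestral frequency
f0 ~ Uniform(0.001, 0.999) is drawn, then
fA, fB ~ Beta(f0(1−F)/F, (1−f0)(1−F)/F) independently, with divergence
parameter F (default 0.2).  A locus is retained only if both derived
frequencies lie in (0.01, 0.99); rejected loci are discarded entirely
(including f0) and fresh loci drawn until m are retained.  This
drop-locus scheme leaves the retained loci with the model's joint law
conditional on being common in both populations; redrawing (fA, fB) for
a fixed f0 instead would condition extreme-f0 loci into the retention
window and inflate the realized divergence well above F.

Per-locus differentiation defaults to the ancestral-referenced
estimator [(fA−f0)² + (fB−f0)²] / (2 f0(1−f0)), whose expectation is
exactly F before truncation (≈0.207 after, at F=0.2).  Hudson-, Nei- and
plain-style two-population estimators are available via
`per_locus_fst(estimator=...)`.

Effect magnitudes are β_i = 1/sqrt(2 m f̄_i(1−f̄_i)) with
f̄ = (fA+fB)/2, which makes Σ 2β²f̄(1−f̄) = 1 exactly: the genic
variance at the mean frequencies is 1 regardless of m.  Signs are chosen
among n_perm uniform random sign vectors to maximize/minimize either the
directional-LD term or the between-population variance
Vgb = ((ḡA−ḡB)/2)², labelling the result divergent/stabilizing;
`random` keeps the first draw (neutral).  Both criteria share the
sign-dependent quantity (β·Δ)² with Δ = fA−fB, so they select the same
extremes over a common candidate set.

## Admixture simulation

Hybrid isolation (HI): generation 0 is a pulse mixture, each individual
unadmixed A with probability p, else unadmixed B.  Continuous gene flow
(CGF): generation 0 is all B; each generation a fraction
q = 1−(1−p)^(1/T) of the cohort is replaced by unadmixed A migrants, so
E(θ_T) = p.  The per-generation order is migrate (CGF) → mate →
reproduce; migrants mate in their arrival generation.

Mating pairs individuals so the Pearson correlation of partner
ancestries matches the target P: an ancestry-sorted pairing (near-max
correlation) is relaxed by random partner swaps accepted when they move
the correlation toward P, stopping within tolerance 0.01 (relaxed to
0.02 then 0.04 if unattainable; an unattainable target, e.g. V(θ)=0,
falls back to random pairing and is flagged).  Each offspring draws a
couple uniformly with replacement; at each unlinked locus the maternal
and paternal allele ancestries are Bernoulli(θ_parent) and allelic
states Bernoulli(fA or fB) given ancestry.  θ is always recomputed as
the mean of local ancestry γ/2.

Ancestry-moment recursions: E(θ) is constant (HI) or
E_t = q+(1−q)E_{t−1} (CGF); V_t = (1+P)/2 · V⁺ where V⁺ is the
post-migration variance (V_{t−1} for HI;
q(1−q)(1−E_{t−1})² + (1−q)V_{t−1} for CGF).  These treat ancestry as
continuous; with m unlinked loci, Mendelian segregation adds
(E⁺(1−E⁺) − V⁺)/(2m) per generation, a floor of roughly E(1−E)/(m+1)
that dominates at late generations.  `expected_ancestry_moments`
implements the continuous recursion by default and the corrected one
with `n_loci=m`; simulations match the corrected recursion within
Monte-Carlo error.

## Variance decomposition

With Δ_i = f_iA − f_iB and ancestry moments (E(θ), V(θ)):

- term 1: 2E(θ) Σβ²fA(1−fA) + 2(1−E(θ)) Σβ²fB(1−fB)
- term 2: 2E(θ)(1−E(θ)) Σβ²Δ²
- term 3: 2V(θ) Σβ²Δ²
- term 4: 4V(θ) Σ_{i≠j} β_iβ_jΔ_iΔ_j

Genic = 1+2+3; directional-LD contribution = 4; total = V(g).  The
variance explained by local ancestry (effects φ_i = β_iΔ_i) equals
2+3+4.  Population-variance convention (ddof=0) is used throughout.

## GRMs and estimands

Scalings of the centered dosage matrix: standard divides columns by
sqrt(2f(1−f)) with f the sample dosage frequency; variance divides by
the sample SD; LD whitens with the inverse Cholesky factor of the
column covariance (a ridge of 1e−3 × mean diagonal is applied
automatically when m > n).  The estimand table above (README) follows:
standard scaling misses both V(θ) terms, variance scaling recovers the
genic V(θ) term but not the LD term, LD scaling recovers the full V(g),
and projecting ancestry (or equivalently PCs) out targets the
conditional variance (1)+(2)−(3).

Boundary case: at generation 0 the cohort is two discrete unadmixed
clusters, and after conditioning on ancestry the within-cluster
scaled-genotype variance under pooled-frequency scalings is
1 − Δ²/(4f̄(1−f̄)) < 1, so adjusted estimators recover (1)+(2)−(3) only
up to that factor.  The adjusted-cell identity is treated as a property
of admixed cohorts (t ≥ 1), which is where it is tested.

## Estimators

REML: fixed effects (intercept + covariates) are removed by projecting
onto the null space of the design; the projected GRM is
eigendecomposed once and the restricted likelihood profiled over
λ = σg²/σe² on a grid plus Brent refinement.  Unconstrained fits allow
σg² < 0 (λ down to −1/s_max); standard errors come from the inverse
Fisher information.  `RemlWorkspace` caches the projection and spectrum
so many phenotypes can be fit on one (GRM, covariates) pair.

HE regression: slope of phenotype cross-products on GRM entries over
the off-diagonal pairs.  Covariate adjustment projects the residual
maker through both the phenotype and the GRM (M y, M K M).  Standard
errors by delete-a-block jackknife (20 blocks).  Without ancestry
adjustment the HE slope carries an exaggerated directional-LD
component, so under standard/variance scaling its expectation is not an
estimand-table entry; the package tests the predicted bias ordering
(divergent above, stabilizing below) instead.

Marginal GWAS: per-variant OLS after residualizing covariates out of
phenotype and genotypes, with degrees of freedom n − c − 1.
Monomorphic and perfect-fit variants yield flagged NaN records.

LDSC: χ² regressed on ℓ_k = Σ_i r²_ik with a free intercept;
V̂g = slope·m/n.  Loci are unlinked, so admixture LD is global and the
sum runs over all variants; `pcs_to_project` residualizes PCs out of the
standardized genotypes first.  Identifiability note: the model concerns
expectations over random effects, and with a fixed architecture a
single trait's χ² is dominated by that architecture; calibration checks
therefore average χ² over many null traits (by linearity this equals
averaging per-trait fits), and bias experiments average over replicate
architecture draws.  After PC projection of unlinked loci the LD scores
are nearly constant and the free-intercept fit is unidentifiable at
desk scale, so PC-adjusted LDSC is not asserted quantitatively.

## GWAS summary-statistics decomposition

`decompose_summary_stats` treats a harmonized SNP table (snp, alleles,
beta, se, fA, fB) as the architecture and evaluates the four terms at
supplied ancestry moments (an African-American-like preset
E(θ)=0.767, V(θ)=0.018 ships as `ASW_ANCESTRY_MOMENTS`).
`bootstrap_components` resamples β* ~ N(β, se) for percentile CIs; note
E[β*²] = β² + se², so bootstrap means of squared-effect terms exceed the
point estimate by the se²-weighted heterozygosity sum — the CIs are for
uncertainty, not bias correction.  `harmonize_alleles` flips effects
and frequencies to a reference orientation, drops irreconcilable rows
and flags strand-ambiguous A/T and C/G SNPs.

## Reproducibility

Every stochastic routine takes a seed; trajectories spawn one
independent stream per generation from a root `SeedSequence`, so
results are independent of how many generations are retained.
Experiment bundles are stamped with a 12-hex config hash (the output
path is excluded from the hash) and re-running a config with the same
seed reproduces the tables byte-for-byte.

## Limitations

- Loci are unlinked; there is no within-chromosome LD, genetic map or
  physical windowing of LD scores.
- Two source populations only; no three-way admixture.
- The mating search targets the ancestry correlation, not a full
  bivariate mating distribution.
- Fixed-effect adjustment is linear in θ (or PCs); no interaction or
  nonlinear ancestry effects.
- Desk-scale defaults (n ≤ a few thousand, m ≤ a few hundred) are
  chosen so the whole test suite runs in minutes; the algebraic
  identities are scale-free, and the stochastic checks use replicate
  standard errors so reduced scale does not loosen them.
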