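# Methods

`rngwas` implements a two-step genomic reaction-norm GWAS for
genotype-by-environment interaction (GxE) in pedigreed populations, of the
kind used for environmentally sensitive traits in livestock. This note
documents the models, the estimation algorithms and their numerical
choices, what the synthetic-data generator does and does not emulate, and
the problem sizes the test suite runs at.

## The two-step model

**Step 1 — environmental gradient.** Contemporary groups (CGs: herd x year
x season x management) are treated as the unit of environmental
description. An environmental-descriptor trait (a growth trait in the
motivating application) is analysed with a single-step GBLUP animal model

    y = X b + Z a + e,   a ~ N(0, H sigma2_a),   e ~ N(0, I sigma2_e),

where H combines pedigree and genomic relationships (below). The CG BLUEs
are standardized across CGs to mean 0, sample SD 1, giving the
environmental gradient EG in [-3, +3]; solutions outside that range are
flagged and clamped (a drop policy is available). Standardization makes EG
invariant to the descriptor's units and to the fixed-effect constraint
(intercept + sum-to-zero contrasts here).

**Step 2 — reaction norm.** Each analysis-trait record at gradient level
EG_j enters

    y_ij = X b + omega_f phi_f(EG_j) + alpha_fi phi_f(EG_j) + e_ij,

with phi_f the normalized Legendre basis, phi_k(x) = sqrt((2k+1)/2) P_k(x),
on x = EG/3 in [-1, 1]; two coefficients by default, so each animal carries
a genetic intercept and slope with 2x2 covariance K and random-effect law
a ~ N(0, K (x) H). Residuals are iid; heterogeneous residual variance
across gradient classes is out of scope. The genetic variance at gradient
level g is phi(g)' K phi(g), heritability follows by adding sigma2_e, and
the intercept-slope correlation is K01/sqrt(K00 K11).

Because EG is constant within CG and the model carries both CG fixed
effects and fixed regressions on EG, the fixed part is rank-deficient by
construction. The package keeps both terms as specified and drops aliased
columns deterministically (first-come order, reported as NaN, as `lm` does);
breeding values, predictions and variance components are invariant to this
choice. Step-1 uncertainty in the BLUEs is *not* propagated into step 2 —
that is inherent to the two-step design and a known approximation.

Binary traits (coded 1/2) are fitted with the same linear machinery; the
Dempster-Lerner conversion (`h2_obs = h2_liab * z^2 / (p(1-p))`) is
provided to compare liability-scale and observed-scale heritabilities. A
threshold (probit) sampler is deliberately not implemented.

## Relationship matrices

A is built by the tabular method; A^-1 by Henderson's rules with
inbreeding, the Mendelian-sampling variances coming from the tabular
inbreeding coefficients (equivalent to the Meuwissen-Luo recursion at desk
scale; verified by the A * A^-1 = I oracle). G follows VanRaden:
Z Z' / (2 sum p(1-p)) with observed allele frequencies, tuned to the mean
diagonal/off-diagonal of A22 and blended, G* = (1-w) G_t + w A22 with
w = 0.05 by default (the conventional defaults; both are exposed). The
single-step inverse is H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]] on the
genotyped block. Everything is dense: the package targets desk scale
(<= ~5,000 animals), where dense LAPACK beats sparse bookkeeping.

Pedigree depth can be truncated to a configurable number of ancestor
generations (3 by default via `Pedigree.prune`), cutting parent links at
the boundary.

## Variance-component estimation

**REML.** `em_reml` implements the classic EM updates from mixed-model
equation byproducts,

    K[c,d] <- (a_c' H^-1 a_d + sigma2_e tr(H^-1 Caa_cd)) / q
    sigma2_e <- (y'y - b'X'y - a'W'y) / (n - rank X),

which are monotone in the restricted likelihood (asserted by a test) and
respect the parameter space, but converge linearly — and very slowly here,
because with one record per animal the slope genetic variance contributes
only var(phi1(EG)) K11 ~ K11/6 of the phenotypic variance and is weakly
identified. On test fixtures plain EM needed thousands of iterations. The
default algorithm is therefore `ai_reml`: a few EM warm-up steps followed
by average-information updates with step-halving safeguards (a step that
leaves the parameter space or lowers the restricted likelihood is halved;
a collapsed step falls back to one monotone EM update). Proposed K updates
are projected onto the positive-semi-definite cone by eigenvalue flooring,
and iteration stops either on stable parameters or on a stalled
likelihood — REML optima for these data often sit on the singular-K ridge
(intercept-slope correlation +-1), where the likelihood is nearly flat and
unguarded steps zigzag. Two arithmetic arenas are available: the MME
(score and AI terms from equation byproducts, restricted likelihood via
log|V| + log|X'V^-1X| = log|R| + log|K (x) H| + log|C / sigma2_e|) and,
by default whenever there are fewer records than equations, record space —
every quantity computed from the n x n phenotypic covariance
V = (Phi K Phi') o H + I sigma2_e using the Hadamard identity
tr(V^-1 D_c H D_d) = phi_c'(V^-1 o H) phi_d. The record-space path cuts
the per-iteration cost by roughly the cube of the dimension ratio and
makes 2,000-animal REML a matter of seconds. AI-REML reaches the EM
optimum (cross-checked by test) in ~10 iterations.

**Gibbs.** The sampler alternates (i) a *joint* draw of all location
parameters, (ii) K from its conjugate inverse-Wishart full conditional,
(iii) sigma2_e from a scaled inverse chi-square. The location draw uses
the Garcia-Cortes & Sorensen simulation scheme: draw pseudo-data from the
prior, solve a GLS system against the record-space covariance
V = (Phi K Phi') o H + I sigma2_e, and shift — an exact joint draw at
roughly (n_records)^3/3 per sweep instead of (2q)^3/3 for a Cholesky of
the full MME. Chains are reproducible from a seed.

Two prior choices matter and are documented because they bit during
development. First, an inverse-Wishart prior for K with a near-zero scale
matrix concentrates its mass on *singular* K; with a weakly identified
slope variance the chain is captured near the boundary and the intercept
variance is dragged along through the positive-definiteness constraint.
The default prior is therefore a proper IW centred on the starting
covariance with the minimal degrees of freedom (order + 2) for which the
prior mean exists. Second, for recovery experiments the package follows
the conventional two-stage workflow: REML point estimates centre the
priors and start the chain, with the centre's eigenvalues floored at 10%
of its mean diagonal so a boundary REML estimate cannot re-create the
singular trap. Desk-scale chain defaults (20,000 sweeps, 5,000 burn-in,
thinning 5) replace the production-scale chains (hundreds of thousands of
sweeps) that one-record-per-animal data would otherwise demand; the Geweke
diagnostic (z on first 10% vs last 50%, spectral variance at frequency
zero with a Bartlett window) is provided to check stationarity.

## SNP effects and significance

With variance components fixed, marker effects per coefficient c are
back-solved from the genotyped animals' GEBVs,

    u_c = M' [M M']^-1 a_c,

with M the 2p-centred genotype codes. Centring by observed frequencies
makes 1'M = 0, so M M' is always rank-deficient by one; a ridge of
1e-8 tr/n is added (and logged) — it perturbs only the null direction, in
which the GEBVs have no component, and the back-solved effects agree with
ridge SNP-BLUP to < 1e-6 on the oracle fixture. Standard errors propagate
the GEBV sampling covariance Var(a_c) = G sigma2_c - PEV_c (PEV from the
inverse MME) through the same linear map; p-values are two-sided normal.
Declaration combines the fixed -log10(p) > 5 rule with a chromosome-wide
Bonferroni companion alpha/Me, Me = 2 Ne L / ln(4 Ne L) per chromosome
(Ne = 196 by default, L in Morgans at 1 cM/Mb from the map); both columns
are emitted so either policy can be audited, and a marker is called
significant only when it passes both. Genomic inflation is
median(chi2_1(1-p))/0.4549. Significant markers' intercept/slope solutions
are mapped across the gradient as SNP_k = T u_k on a 61-point grid with a
sign-change flag.

## Annotation and enrichment

Significant markers are intersected with user-supplied gene/QTL intervals
(GFF3 as-is, BED converted to 1-based inclusive) inside a symmetric
+/-100 kb window (>= 1 bp overlap). Category over-representation among hit
intervals uses the upper-tail hypergeometric test with the supplied
interval set as the universe — the universe is explicit and user-
controlled, not a genome-wide catalogue — with Benjamini-Hochberg (default)
or Bonferroni adjustment, flagged at adjusted p < 0.10.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
discrete non-overlapping generations under random mating with equal sex
ratio; genotypes gene-dropped from Hardy-Weinberg founders with Haldane
recombination at 1 cM/Mb (marker positions uniform per chromosome); CGs
assigned randomly within generation with a minimum size; CG effects
N(0, cg_effect_sd^2) whose standardization is the *true* gradient; genetic
intercept/slope as the sum of marker-borne QTL effects and a polygenic
remainder sized so the total covariance is K_true, the remainder drawn
along the pedigree (default) or spread infinitesimally over all markers
("markers" mode, used for null calibration so the polygenic term is
exactly marker-borne); phenotypes from the reaction-norm model with iid
residuals; a descriptor trait sharing the CG effects; and a binary trait
thresholding an independent liability at the empirical quantile matching
the requested incidence. Everything is reproducible bit-for-bit from the
seed.

It does *not* emulate: selection or assortative mating, overlapping
generations, distinct CG definitions between descriptor and analysis
traits (a CG-mapping hook exists), genotyping errors or missingness
patterns, linkage disequilibrium beyond what pedigree transmission
creates, or climate covariates. Passing tests therefore demonstrate
internal statistical correctness of the pipeline under its own model, not
robustness to the many ways real data violate it — in particular the
quality of a real environmental descriptor, which the two-step design
depends on, is outside what simulation can establish.

## Problem sizes and tolerances in the test suite

The suite's statistical experiments run at the package's test scale,
chosen so each experiment carries genuine replication while the whole
suite stays interactive: null calibration at 1,000 genotyped animals x
5,000 markers x 5 seeds (pooled lambda asserted within [0.9, 1.1]);
variance-component recovery under K = [[4,1],[1,1]], sigma2_e = 4 with
REML at n = 2,000 x 20 replicates and Gibbs at n = 800 x 8 replicates
(4,500 sweeps, REML-centred priors; the smaller Gibbs population keeps the
per-sweep factorization cheap), each parameter's replicate mean within
3 empirical standard errors of truth; the QTL power check at
n = 600 with qualifying replicates defined by a realized variance share of
at least 10% (the detection premise scales with n x share). Numerical
oracles (dense GLS, dense inverses, SNP-BLUP equivalence, quadrature
orthonormality) are held to 1e-6..1e-12. EM convergence is declared on
relative parameter change (default 1e-8 for the op, looser 1e-3..1e-4
inside the large pipelines where components feed a subsequent fixed-
components solve and third-digit precision is immaterial).

## Known limitations

- Dense algebra bounds practical size to a few thousand animals.
- The Gibbs sampler's variance components mix slowly when a component is
  weakly identified; production-length chains or REML are recommended
  there, and posterior means inherit prior sensitivity at small n.
- The fixed-regression/CG confounding means omega and individual CG
  solutions are not separately interpretable (breeding values are).
- Approximate back-solved p-values are calibrated under the fitted model
  (lambda ~ 1 on null simulations) but are not exact frequentist tests.
- QC is performed on the combined panel, not separately by sex.
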