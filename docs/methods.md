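# Methods

## Model

Observed data are per-SNP association p-values for n phenotypes,
transformed to y_it = Φ⁻¹(1 − p_it) after clipping p to
[1e−300, 1 − 1e−16] (so y is always finite; p = 0.5 maps to y = 0).
Conditional on a binary latent association indicator e_it,

    y_it | e_it ~ e_it · LN(μ_i, σ_i²) + (1 − e_it) · N(0, 1).

The lognormal captures the fact that truly associated SNPs have small
p-values, hence positive y; e_it = 1 is only possible where y_it > 0.

The latent vector e_t = (e_1t, …, e_nt) follows an auto-logistic Markov
random field whose singleton terms are shifted by the SNP's binary
annotations a_t:

    p(e_t | α, γ, β, G, a_t) ∝ exp( Σ_i (α_i + Σ_m γ_im a_mt) e_it
                                    + Σ_{i<j, E(i,j)=1} β_ij e_it e_jt ).

α_i controls the base association rate of phenotype i, β_ij > 0 couples
phenotypes that share genetic architecture (the phenotype graph G), and
γ_im ≥ 0 raises the association propensity of annotated SNPs. The
normalizing constant is a sum over all 2ⁿ binary states; it is computed
exactly in log space, once per distinct annotation pattern (at most
min(T, 2^M) patterns), and the enumeration is refused above n = 15 rather
than silently approximated.

Priors: μ_i ~ N(0, 10⁴); σ_i² ~ IG(0.5, 0.5) (shape/rate);
α_i ~ N(0, 10⁴); spike-and-slab β_ij | E(i,j) with a Gamma(4, 2) slab
(mean 2, thin at zero — included couplings are a priori away from 0) and a
point mass at zero otherwise; independent Bernoulli priors on edges
(probability 0.5 per pair, or 0.8/0.2 for pairs inside/outside a
user-supplied prior phenotype graph — both configurable); spike-and-slab
γ_im with a Gamma(4, 2) slab, Bernoulli(p_u) inclusion and p_u ~ Beta(1, 1).
The nonnegativity of γ encodes that functional annotation can support but
never penalize association.

## Posterior computation

A Metropolis-within-Gibbs sampler sweeps, in order: e (exact Gibbs,
vectorized over SNPs — SNPs are conditionally independent), (μ, σ²)
(conjugate normal / inverse-gamma draws per phenotype; with no associated
SNPs both fall back to their priors), α (Gaussian random-walk Metropolis),
(β, G) and (γ, u) (for each coordinate, a fair coin picks either a
within-model Gaussian walk on the log scale — with the Gamma slab ratio and
log-scale Jacobian in the acceptance probability — or a birth/death move in
which birth proposes from the slab prior, so the acceptance ratio reduces
to the likelihood change times the inclusion-prior odds), and p_u
(conjugate Beta). Every Metropolis ratio includes the change in
Σ_t log C(a_t), evaluated per annotation pattern.

Defaults: 10,000 sweeps, 5,000 burn-in, thinning 5 for traces. Step sizes
(defaults 0.1 for α, 0.15 for log β and log γ) adapt every 50 sweeps toward
a 40% acceptance rate during burn-in only and are frozen afterwards, so the
retained chain is a fixed-kernel Markov chain with the correct invariant
distribution. One seeded generator drives the whole chain; identical seed
and inputs give bitwise-identical output. Initialization: e = 1 where
y > 2, emission parameters from moments of log y over that set, α at the
empirical logit, and an empty graph (edges and annotation effects enter by
birth moves).

Post-burn-in running means accumulate p(E(i,j)|Y), p(β_ij > 0|Y) (identical
by construction, since β_ij > 0 exactly when the edge is present),
conditional means of β and γ given inclusion, p(γ_im > 0|Y), per-SNP
marginals p(e_it = 1|Y) and pairwise joints p(e_it = e_jt = 1|Y) for all
pairs (larger sets on request). Full e trajectories are never stored.

Correctness is established by three kinds of tests: exact oracles
(brute-force enumeration of the normalizing constant; the identity that
flipping one e_it changes the joint log kernel by the log conditional
odds), closed-form checks of every conjugate block, and a 15,000-cycle
successive-conditional (Geweke-style) run in which alternating data
regeneration and parameter updates must reproduce all prior moments — a
whole-sampler calibration check that is sensitive to any error in an
acceptance ratio.

## Decisions

Phenotypes i, j are called genetically correlated when p(E(i,j)|Y) > 0.5
and p(β_ij > 0|Y) > 0.95 (both strict); annotation m is relevant for
phenotype i when p(γ_im > 0|Y) > 0.95. Association lists use the direct
posterior probability FDR rule: rank by posterior association probability
and keep the longest prefix whose average local fdr (1 − probability) is at
most the nominal level; the selection is monotone in the level. Pleiotropic
variants are selected the same way from the pairwise (or higher-order)
joint probabilities, which never exceed the corresponding marginals.

## Preprocessing

- **Probit transform** with the clipping above; strictly decreasing in p.
- **Annotation binarization** at a strict cutoff (default 0.5), for
  continuous functional scores in [0, 1].
- **SNP thinning** keeps rows 1, 1+k, 1+2k, … (default in the CLI: no
  thinning; k = 10 mirrors common practice for reducing LD between
  retained SNPs). Missing-value rows are dropped before thinning.
- **Sample-overlap decorrelation** replaces a chosen phenotype group by
  C^{−1/2} times its columns, with C the group's sample correlation matrix
  and the symmetric (eigendecomposition) inverse square root; eigenvalues
  below 1e−10 raise an error naming the smallest eigenvalue. The transform
  operates on standardized columns and restores each column's location and
  scale afterwards: this makes the output group's sample correlation
  exactly the identity and the operation idempotent, while being
  numerically identical to the plain transform for z-score-scale input.
  In the pipeline it runs after missingness filtering and thinning,
  immediately before model fitting.

## Synthetic data generator

The generator realizes the study design the model is validated against:
n = 6 phenotypes, T = 200,000 SNPs, M = 5 annotations with exactly 10% of
SNPs annotated per column (exactly round(0.1·T) ones, so column sums are
deterministic), graph edges {P1–P2, P1–P3, P2–P3, P3–P4, P4–P5} with
β = (4.0, 1.8, 2.3, 2.5, 5.0), α = (−4.7, −3.0, −5.5, −4.8, −3.6, −2.5),
annotation effects γ = 1 from annotation 1 to P1–P3 and γ = 2 from
annotation 2 to P4–P6, and emissions μ = (1.05, 0.9, 1.0, 1.0, 1.05, 0.95),
σ = (0.4, 0.3, 0.35, 0.3, 0.45, 0.4). Latent indicators are drawn by
single-site Gibbs from the annotation-modified field (1,000 sweeps from an
all-zero start; the empirical state distribution matches exact 2ⁿ
enumeration within Monte-Carlo error). The generator uses the annotation-
modified kernel because the stated γ values would otherwise be inert; P6 is
deliberately annotated but graph-isolated, which is what makes the
annotation-free analysis attach it spuriously to P4/P5.

The generator shares the field code with the fitted model, so
generator/model consistency is structural rather than asserted. What it
does **not** emulate: linkage disequilibrium between SNPs (the model
assumes independent SNPs), sample overlap between studies, effect-direction
information, or continuous/graded annotations. Passing tests therefore
demonstrate correct inference under the model's own assumptions, not
robustness to their violation in real data.

## Problem sizes and numerical choices

End-to-end tests and the acceptance script run the scenario at T = 20,000
SNPs with 10,000 MCMC sweeps — large enough that posterior uncertainty, not
Monte-Carlo error, dominates the credible intervals, while a full fit
completes in a few minutes on one core. The full T = 200,000 replication is
a straight parameter change (`dataclasses.replace(default_scenario(), ...)`)
and scales linearly in T. Log-sum-exp is used for every normalizing
constant; emission likelihood ratios are −∞ off the lognormal support,
which the Gibbs update maps to probability 0; credible intervals for
spike-and-slab coefficients are computed conditional on inclusion (an
always-excluded coefficient reports NaN).

## Known limitations

Single-replicate coverage checks of many 95% intervals at once will miss
occasionally by construction (~1.5 expected misses out of 29 intervals even
for a perfectly calibrated posterior); the recovery test asserts joint
coverage and should be read with that in mind. Exact normalizing constants
limit the method to n ≤ 15 phenotypes; no pseudolikelihood fallback is
provided. The sampler is single-chain; convergence is assessed through
acceptance-rate reports and traces rather than multi-chain diagnostics.
p-values carry no effect direction, so protective and risk effects are
indistinguishable. The update schedule visits all pairs and all (i, m)
coordinates every sweep, which is quadratic in n and linear in M.
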