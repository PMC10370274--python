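# pleiograph

Joint Bayesian analysis of GWAS summary statistics for multiple phenotypes,
with functional annotations, built around a latent Markov-random-field (MRF)
model of pleiotropy.

## The problem

Single-trait GWAS often lacks power for variants of modest effect, and
p-values alone say nothing about *why* a variant matters. When several
phenotypes are genetically correlated, their summary statistics can be
analyzed jointly: a variant associated with one phenotype is more plausibly
associated with a correlated one, and a variant falling in functional
sequence (for a disease-relevant tissue or cell type) is more plausibly
associated at all. `pleiograph` integrates both signals and produces three
outputs:

1. a **phenotype graph** — which phenotype pairs share genetic architecture;
2. **annotation-relevance calls** — which annotations matter for which
   phenotype;
3. **FDR-controlled association lists** — per-phenotype and pleiotropic
   (shared) variants.

## The model

For SNP *t* = 1…T and phenotype *i* = 1…n, p-values are transformed to
*y*ᵢₜ = Φ⁻¹(1 − *p*ᵢₜ). A binary latent indicator *e*ᵢₜ marks true
association, with the emission mixture

> *y*ᵢₜ | *e*ᵢₜ ~ *e*ᵢₜ · LN(μᵢ, σᵢ²) + (1 − *e*ᵢₜ) · N(0, 1).

The vector **e**ₜ over phenotypes follows an auto-logistic MRF modified by
the SNP's binary annotations **a**ₜ = (a₁ₜ…a_Mₜ):

> p(**e**ₜ | α, γ, β, G, **a**ₜ) ∝
> exp( Σᵢ (αᵢ + Σₘ γᵢₘ aₘₜ) eᵢₜ + Σ_{i∼j} βᵢⱼ eᵢₜ eⱼₜ ),

whose normalizing constant is enumerated exactly over all 2ⁿ states (once
per distinct annotation pattern). Edges E(i,j) and annotation effects γᵢₘ
carry spike-and-slab priors (Gamma(4, 2) slabs; γ ≥ 0 so annotation can only
support association); a Metropolis-within-Gibbs sampler explores the joint
posterior, including birth/death moves for edges and annotation inclusions.
Decisions follow the posterior: an edge is called when p(E(i,j)|Y) > 0.5 and
p(βᵢⱼ > 0|Y) > 0.95; annotation m is relevant for phenotype i when
p(γᵢₘ > 0|Y) > 0.95; association lists use the direct posterior probability
FDR rule.

## Worked example

```python
import dataclasses
from pleiograph import PleiotropyMRF, transform_pvalues
from pleiograph.simulate import default_scenario, simulate

# six phenotypes on a five-edge graph, five annotations, scaled to 20k SNPs
scenario = dataclasses.replace(default_scenario(), T=20_000)
truth = simulate(scenario, seed=1)

model = PleiotropyMRF(n_iter=10_000, n_burnin=5_000, random_state=1)
model.fit(transform_pvalues(truth.pvalues), annotations=truth.annotations)

print(sorted(model.decide_graph().edges))
print(model.decide_annotations().query("call")[["phenotype", "annotation"]])
```

A run of this kind (see `scripts/acceptance.py --seed 1`) recovers the
generating five-edge graph exactly and prints, for example:

```
t1: beta posterior mean 4.7996  95% CI (4.5655, 5.0221)   # generated with 5.0
t2: alpha posterior mean -2.8998 95% CI (-3.0002, -2.8039) # generated with -3.0
t5: gamma posterior mean 1.8922 95% CI (1.7663, 2.0074)   # generated with 2.0
```

i.e. posterior means within a few percent of the generating values and
credible intervals of the expected width. Fitting the same data *without*
annotations adds spurious edges attaching the annotated-but-isolated
phenotype P6 to P4/P5 — the cautionary case the annotation-aware model
exists to fix — while fitting with row-shuffled (irrelevant) annotations
yields no annotation calls and leaves the graph and intercepts unchanged.

## Command line

```bash
pleiograph simulate --out-dir sim --t 20000 --seed 1
pleiograph fit --pvalues sim/pvalues.tsv --annotations sim/annotations.tsv \
    --out-dir fit --fdr 0.05 --fdr 0.10
pleiograph summarize --fit-dir fit --p-sign-cut 0.99
```

`fit` accepts raw p-value tables (probit transform, annotation binarization
at 0.5, optional 1-in-k SNP thinning and sample-overlap decorrelation are
applied in-pipeline), and writes edge tables, a DOT graph, annotation calls,
per-SNP posterior probabilities, FDR-flagged association lists, thinned
traces and a provenance record.

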