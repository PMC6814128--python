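# Methods

`provblup` estimates quantitative-genetic parameters from open-pollinated
(OP) provenance/progeny trials — common-garden experiments in which seed
collected from known mother trees in several wild populations
("provenances") is planted together under a replicated field design. This
note describes the statistical models, the numerical machinery, the
synthetic-data generator used for validation, and the design choices made
where the problem left the design open.

## The univariate animal model

For one trait at one site,

```
y = X b + Z g + Z r + Z r(s) + e
```

with `y` the per-tree measurements, `b` fixed effects (intercept plus one
indicator per clonally repeated control lot), `g` the additive genetic
(breeding) value of every pedigree member with `var(g) = A σ²_g` (`A` the
average numerator relationship matrix), `r ~ N(0, I σ²_r)` the replicate
effects, `r(s) ~ N(0, I σ²_r(s))` the set-within-replicate effects, and
`e ~ N(0, I σ²_e)`. The pedigree is maternal: every trial tree has a known
mother and an unknown wind-borne pollen parent.

The provenance structure is handled four ways:

| variant | treatment |
|---|---|
| `ablup_f` | provenance as a fixed factor (reference coding) |
| `ablup_r` | provenance as an i.i.d. random factor, `var = I σ²_p` |
| `ablup_gc1` | contemporary genetic groups in the pedigree: unknown dams point to the provenance group, every unknown sire to one site-wide phantom *pollen* group |
| `ablup_gc2` | genetic groups with both unknown sides on the provenance group |

`ablup_gc1` encodes the biology of long-distance pollen flow: the seed
parent demonstrably survived local selection, the pollen parent need not
have.

### Genetic groups as exact linear algebra

A genetic group represents the mean of a defined set of unknown
ancestors. Writing `Q` for the matrix of expected group-ancestry
fractions (`row(i) = ½ row(dam) + ½ row(sire)`, a group being its own
unit vector), the group model is `g = Q ĝ + a` with unpenalised group
effects `ĝ` and `a ~ N(0, A σ²_g)` over the *base* pedigree (unknown
parents as founders). The package fits exactly this explicit form — the
`Q` columns join the fixed design, with trailing linearly dependent
columns dropped deterministically — and separately provides the sparse
group-augmented A-inverse

```
A*⁻¹ = [ Q'A⁻¹Q   −Q'A⁻¹ ]
       [ −A⁻¹Q      A⁻¹  ]
```

assembled pedigree-recursively: each individual contributes the outer
product of (1 on itself, −½ on each filled parent slot, groups included)
scaled by `1/d_i`, where the Mendelian-sampling variance `d_i` counts
**real** parents only. A phantom group contributes the mean of the
missing ancestors but none of their variance, so pointing a slot at a
group must not reduce `d_i`; the variant that treats groups as known
non-inbred parents (`d = ½` for a founder with two group slots) is a
shortcut used by some production codes but is *not* equivalent to the
explicit model, and the package's dual-route test (augmented sparse
system vs. explicit fit) holds at 1e−6 only with the exact assembly.
Both routes use identical identification constraints (the groups whose
explicit columns were dropped are pinned to zero).

### Equivalences and what AIC comparisons mean

On a pure OP design every phenotyped tree of provenance *p* has the same
group-ancestry pattern, so the fixed column spaces of `ablup_f`,
`ablup_gc1` and `ablup_gc2` coincide and the restricted-likelihood
*profile* is identical — the variance components and heritabilities agree
across the three variants on any dataset (the two-sided group model and
the fixed-provenance model agree to machine precision, a property the
tests assert). The *reported* REML log-likelihood, however, contains
`log|X'V⁻¹X|` evaluated in each model's own fixed-effect basis:
provenance indicators for `ablup_f`, group-ancestry fractions for the
group models. `ablup_gc2`'s fractions are exactly the indicators, so its
logL and AIC coincide with `ablup_f`'s; `ablup_gc1`'s fractional (¼
provenance, ¾ pollen) columns shift `log|X'V⁻¹X|` downward by a
near-constant that depends on the design but not on the trait values,
giving it a systematically better printed AIC. Production REML engines
behave the same way, which is why between-variant AIC differences should
be read as a parameterisation statement, only orderings are stable, and
absolute AIC values are never comparable across engines. Within one
variant, AIC (`−2 logL + 2t`, `t` the number of free variance
parameters) compares nested covariance structures as usual.

### Breeding values, PEV and accuracy

Reported breeding values are group-inclusive under the group variants
(`Q ĝ + â`). The prediction error variance of tree *i* is
`var(q_i'(ĝ−g) + â_i − a_i)`, obtained by solving the mixed-model
coefficient system against the vector carrying `q_i` on the group columns
and 1 on the tree's equation; accuracy is `r = sqrt(1 − PEV/σ̂²_g)`,
summarised as the mean over phenotyped non-control genotypes (the
published summary leaves the individual set unstated; this is the most
common convention). PEV computation is optional (`compute_pev=False`)
since it costs one sparse solve per tree.

## REML engine

Average-information REML on the variance scale. Per iteration the
Henderson coefficient matrix `C = M'R⁻¹M + diag(0, G_k⁻¹/σ²_k)` is
factorised by block elimination: the equations of a pattern-wise mutually
uncoupled subset of the random effects — in OP trials, the terminal
offspring, selected greedily by degree — are absorbed, leaving a dense
Cholesky core of a few hundred to a few thousand equations. The
factorisation yields exact solutions, `log|C|`, and the selected elements
of `C⁻¹` on the sparsity pattern of each `G_k⁻¹`, so the REML score
(via `tr(G_k⁻¹ C^{kk})`) and the average-information matrix are exact —
no finite differences anywhere. Updates are Newton steps on the AI
matrix with step capping and halving, an EM-flavoured fallback when no
AI step improves the likelihood, and an active-set rule that freezes
variance components at the floor (`1e−10 ×` the phenotypic variance,
flagged as boundary) while their gradient points outward. Convergence:
relative logL change < 1e−8 and maximum relative parameter change <
1e−6, cap 200 iterations. The log-likelihood includes all constants of
the standard restricted likelihood (it matches `lme4`'s REML `logLik` to
the printed precision on shared models, a test in the suite). Parameter
sampling covariances come from the inverse AI matrix at convergence and
feed every delta-method standard error.

## Bivariate model

Trait pairs within a site, or one trait across two sites, are stacked
with Kronecker structures `G1 ⊗ A` (unstructured 2×2 additive),
diagonal 2×2 replicate and set structures, and an unstructured 2×2
residual within site (applied only to trees measured for both traits);
across sites no tree is measured twice, so the residual covariance is
dropped from the model and the genetic covariance is identified purely
through families planted on both sites (an error is raised when none
are). The surface is maximised by L-BFGS-B on log-variances and atanh
correlations — a bijection onto the positive-definite 2×2 cone, which
makes the "bending" step of covariance-scale AI updates unnecessary —
started from the univariate fits. The AI matrix on the covariance scale
at the optimum supplies the sampling covariance; the genetic correlation
`r_G = σ_g12 / sqrt(σ²_g1 σ²_g2)` gets a delta-method SE from the
`(σ_g12, σ²_g1, σ²_g2)` block.

## Binary traits

Binary traits are fitted by logit-link penalised quasi-likelihood:
damped working-variate iteration (fixed damping ½; the undamped
fixed-point iteration can run away for an animal model with one binary
record per individual), each step refitting the weighted linear mixed
model with weights `μ(1−μ)` and the working residual variance
parameterised as the over/under-dispersion coefficient `θ` (the
observation-scale residual is reported as 1, by convention).
Heritability uses `h² = σ²_g / (σ²_g + θ π²/3)`. **Caveat:** a single
binary observation per tree carries almost no information about the
liability-scale additive variance; the estimator is deterministic per
dataset but its sampling scatter across datasets is far larger than its
nominal standard errors, and like all PQL variants it attenuates large
liability variances. Binary fits are therefore suitable for the modest
heritabilities typical of acceptability-type traits and are excluded
from numerical acceptance checks; the tests assert the stable properties
(null recovery, directional discrimination, dispersion near 1 without
extra-binomial noise).

## Ordinal traits

Subjectively scored class traits are replaced by Blom normal scores,
`Φ⁻¹((r_i − 3/8)/(n + ¼))` with mid-ranks for ties, computed per site
over all non-missing trees (sites are always analysed separately). The
transform is monotone, approximately centred, and invariant to any
strictly increasing relabelling of the codes.

## Matrix comparison and modularity

Agreement between two variants' trait-correlation matrices is a Mantel
test: Pearson correlation of the off-diagonal upper triangles with a
one-sided permutation p-value (999 joint row/column permutations by
default, seeded). Trait modules are detected on the weighted graph with
edge weights `|r_G|` by greedy agglomerative maximisation of Newman
modularity, starting from singletons and merging the best pair until no
merge gains; a partition scoring below the single-module value falls
back to one module (Q = 0). For small trait sets the tests verify the
greedy optimum against exhaustive enumeration of all set partitions.
Whether the original analysis weighted by `|r|`, positive `r` or `r²` is
not recoverable; `|r|` preserves the strength of negative genetic
correlations, which matter for trait integration.

## Synthetic trials

The generator emulates the motivating trial series: provenances sampled
along a latitudinal gradient (optionally with a deterministic cline in
the provenance means), mothers nested in provenances, OP offspring
assigned to sets (families dealt round-robin so provenances are
represented equally across sets) and spread over replicates, and two
clonally repeated control lots planted in every replicate × set cell.
Defaults are the published design (30 replicates × 7 sets, 238 families,
2 controls) with variance components matching the flagship growth trait
(σ²_p = 140, σ²_g = 212, σ²_r = 45, σ²_r(s) = 15, σ²_e = 671 mm²); the
provenance count (14) is chosen to give the stated equal per-set
representation, as the true count is not published.
`SimulationConfig.from_targets(h2, qst)` rescales to a unit phenotypic
variance for calibration studies.

Pollination is `local` (pollen parent drawn from the mother's own
provenance — the null biology under which provenance-fixed, -random and
two-sided-group models are correctly specified, and under which the
nominal h² and Q_ST equal the model estimands) or `global` (one
site-wide pool with mean `delta_pollen` and variance `pollen_pool_var`,
the long-distance-pollen biology motivating the phantom paternal group).
Offspring additive values are `½ mother + ½ pollen parent + Mendelian
deviate` of variance `σ²_g/2`; ordinal traits threshold the latent value
at equal empirical quantiles, binary traits at the prevalence quantile;
two-site trials draw site-specific genetic effects with a chosen
cross-site correlation and split each family's offspring across sites.
Everything is driven by one seed and exports are byte-reproducible.

What the generator does **not** emulate: spatial autocorrelation within
replicates, mortality/missingness mechanisms that depend on the trait,
genotype-specific competition, and non-Gaussian residuals. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to field realities
outside it.

## Validation problem sizes

The test suite works at desk scale: unit oracles on pedigrees of tens of
individuals, equivalence checks on trials of a few hundred trees, and
parameter-recovery runs of 50 replicates at 30 provenances × 30 mothers
× 10 offspring (≈ 9 400 records each, a few seconds per REML fit via the
absorbed-block factorisation). Cross-site recovery uses ≈ 180 shared
families. These sizes give standard errors small enough for 2-SE
recovery checks while keeping the full suite within minutes.

## Known limitations

* Group models assume every pedigreed founder carries a provenance
  label; unlabelled founders (control lots) are kept out of the group
  structure and handled by the fixed control term.
* The binary PQL fit is an approximation (see above).
* Selfing (dam = sire) is rejected; the trial biology excludes it and
  the Mendelian-variance rules assume distinct parents.
* No spatial residual structures, no dominance or epistatic
  relationship matrices, and at most two traits jointly.
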