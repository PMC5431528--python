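# Methods

Estimator definitions, algorithmic choices, and the reasoning behind the
package's design decisions. Symbols: `n` individuals, `m` diallelic markers,
`K` ancestry components, `g_ij ∈ {0,1,2}` alternate-allele dosages,
`q_i` mixing proportions (rows of `Q`, on the simplex), `f_k` component
allele frequencies (rows of `F`).

## Admixture model and EM

The likelihood is binomial per entry, `g_ij ~ Binomial(2, p_ij)` with
`p_ij = Σ_k q_ik f_kj`; constant binomial coefficients are dropped, so

```
LL = Σ_{ij observed} [ g_ij·ln p_ij + (2 − g_ij)·ln(1 − p_ij) ].
```

Missing entries contribute nothing. The EM updates are the standard
posterior-allocation forms (see `ancestra.admixture.em_step`); frequencies
are clamped to `[1e-9, 1 − 1e-9]` to keep the likelihood finite. For `K = 1`
the maximizer is closed form, `f_j = mean(g_·j)/2`.

`AdmixtureModel.fit` wraps the EM map in **monotone SQUAREM acceleration**:
two EM steps define a secant extrapolation (`α = −‖r‖/‖v‖`, capped at −1),
the extrapolated point is projected back to the feasible region, one
stabilizing EM step is applied, and the result is accepted only if its
likelihood is at least that of the two plain EM steps. The accepted
trajectory therefore never decreases the likelihood — the fixed points and
the ascent guarantee are exactly those of plain EM, only reached in fewer
iterations (roughly 5–10× fewer on the problem sizes used here). With the
acceleration rejected at every step the iterates are bitwise identical to
plain EM.

Convergence: likelihood gain below `tol` (default `1e-6`) between outer
iterations. Initialization: `Q ~ Dirichlet(1)`, `F ~ Uniform(0.05, 0.95)`
from a stage-specific generator (see *Determinism* below).

## Model-order selection

`cv_error` partitions the **observed entries** (not individuals) uniformly at
random into folds. Each fold is masked, the model refit on the remainder,
and held-out entries scored by binomial deviance

```
d = 2·[ g·ln(g/(2p)) + (2−g)·ln((2−g)/(2(1−p))) ]
```

with the `0·ln 0` saturated-model terms evaluated as 0 (`scipy.special.xlogy`).
The CV error is the mean deviance over folds. A fold that would empty an
individual or marker raises rather than silently degrading the refit.

`select_K` offers three summaries of a `(K, replicate)` error table: the K
minimizing the replicate-averaged error (ties to the smaller K), the most
frequent per-replicate argmin, and the `[min, max]` range of per-replicate
argmins.

## Bootstrap ancestry calling

`bootstrap_fit` resamples markers with replacement B times and refits each
replicate **from a fresh random initialization**, then aligns components to
the reference fit by maximum-correlation one-to-one assignment of frequency
rows (Hungarian algorithm). A warm start at the reference solution is
available (`warm_start=True`) but is not the default: warm-started replicates
stay in the reference's basin of attraction and understate the sampling
spread. In a coverage experiment at n=100, m=2000, K=3, B=200, warm-started
95% intervals covered the true proportions for only ≈88% of (individual,
component) cells, while cold-started replicates covered 95.0%.

Calling (`ancestra.calls`): per cell, the bootstrap mean, the replicate
standard deviation (ddof=1) as SE, and `mean ± 1.96·SE` truncated to [0, 1].
A proportion is called absent when the interval reaches 0; survivors are
renormalized. Wald-type intervals are known to be conservative/anticonservative
right at the simplex boundary — rows whose every cell would be zeroed are
kept unzeroed and flagged. Sample-level proportions combine individuals by
inverse-variance weights `1/(SE_i² + τ²)` with the DerSimonian–Laird moment
estimate of the between-individual variance τ²; the same zeroing rule is
applied using the combined SE of the weighted mean.

## F_ST, Mantel, divergence time

*Component F_ST* (frequency vectors known): Hudson-type ratio of sums,
`Σ_j (f_aj − f_bj)² / Σ_j [f_aj(1−f_bj) + f_bj(1−f_aj)]`. One-locus worked
example: frequencies 0.2 and 0.8 give 0.36/0.68 ≈ 0.5294.

*Sample F_ST* (genotypes): Weir–Cockerham (1984) θ for r = 2 populations,
ratio of summed variance components `Σa / Σ(a+b+c)`, with heterozygote
frequencies taken over non-missing individuals and monomorphic/unusable loci
skipped. The implementation is tested against a brute-force transliteration
of the published formulas on exhaustive small instances.

*Matrix stability*: elementwise differences of upper triangles
(median and 2.5–97.5 percentile interval) and a Mantel correlation. The
parametric Mantel p is a Fisher-z χ²(1) test reported as a **bound pair**
computed at the two defensible effective sample sizes — the number of
matrices' rows N and the number of off-diagonal pairs N(N−1)/2 (for N = 18,
153 pairs) — because off-diagonal entries are not independent; a permutation
p (joint row/column permutations) is reported alongside and is the one to
trust near rho0 = 0.

*Power / time*: the smallest reliably detectable differentiation for a study
with m markers and effective per-ancestry sizes n₁, n₂ is
`F_ST* = 1/√(m·harmonic_mean(n₁, n₂))` (phase-transition scaling; effective
sizes are Q column sums). Divergence time under pure drift:
`t = ln(1 − F_ST)/ln(1 − 1/(2·N_e))` generations; `0.0017` at `N_e = 20000`
gives ≈68 generations, i.e. 1,700–2,040 years at 25–30 years per generation.

## Migration graphs

`ancestry_allele_counts` converts a fitted (Q, F) to per-ancestry allele
counts (`N_k = round(2Σ_i q_ik)`, alt = `round(N_k f_kj)`, ref by
subtraction). `frequency_covariance` computes the centered frequency
covariance `W_hat` with the binomial sampling-noise expectation subtracted
(conjugated by the centering projection) and block-jackknife standard errors.

The graph model is TreeMix-style: leaves inherit from root-to-leaf paths;
a migration edge gives the target lineage a fraction `w` from a second
lineage, making each leaf's ancestry a mixture over paths. For fixed
topology, migration placements and weights, the model covariance is
**linear in branch lengths**, so lengths are refit by non-negative least
squares weighted by the jackknife SEs, and the fit is scored by a Gaussian
composite log-likelihood over the upper triangle of `W_hat`. Because the
composite likelihood is a sum of log-densities with small SEs, it crosses
zero as the residuals shrink below the SE scale — which is what makes the
sign-based stopping rule usable; its absolute value has no calibrated
meaning and is never compared across datasets.

Fitting: NJ topology (scikit-bio) on covariance-implied distances
`d_ab = W_aa + W_bb − 2W_ab`, with the leaf input order randomized per run to
expose tie sensitivity; the tree is rerooted on the outgroup's pendant edge.
Migration edges are added greedily: all valid ordered node pairs (no
self/ancestor-descendant pairs, one inbound edge per target) × a weight grid,
then a bounded 1-D polish of the best weight. `stopping_rule` picks the
largest m whose composite log-likelihoods are all non-positive before the
first positive value. `replicate_runs` summarizes outcomes over random leaf
orders; `consensus_tree` builds the strict-majority consensus over
block-bootstrap trees (strict majority guarantees the retained clades nest).

## Language correlations

Point-biserial correlation = Pearson correlation between a sample-level
ancestry proportion and a 0/1 language-family indicator; significance by
`t = r√((n−2)/(1−r²))` on n−2 df. The battery runs many (ancestry, grouping)
hypotheses, records per-row failures (constant indicators, unannotated
samples) without aborting, and applies no multiplicity correction — callers
see raw p-values.

## Synthetic data

Ancestral frequencies evolve from `Uniform(0.05, 0.95)` root values (an
ascertained-common-variant panel) along a rooted binary tree by
Balding–Nichols drift: a branch with drift `c` draws the child frequency from
`Beta(f(1−c)/c, (1−f)(1−c)/c)`, so the drift parameter equals the expected
parent–child F_ST; fixed frequencies propagate. Two sibling leaves at drift
`c` each show pairwise Hudson F_ST ≈ `c` (verified by simulation at 5·10⁵
markers). Individuals draw `q ~ Dirichlet(α)` per labelled sample and
genotypes binomially; entries go missing completely at random. Migration
pulses mix `w` of a source lineage's frequencies into a target. Language
labels follow each sample's majority ancestry, with optional replacement
noise.

Default study sizes in tests and the acceptance script (e.g. K=3–6,
m=2,000–20,000, n=100–300) are the package's own choice: large enough that
estimator behavior is in its asymptotic regime, small enough that the whole
suite runs in minutes on one CPU.

## Determinism

Every stochastic routine takes a `seed`. Stage-level generators derive as
`child_seed(seed, stage) = (seed·2654435761 + crc32(stage)) mod 2³¹`, so
stages are independent, reproducible, and all derived seeds stay below 2³¹.
Identical seeds give bitwise-identical outputs, including across the CLI and
`run_full_analysis`.
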