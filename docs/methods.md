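# Methods

This note documents the statistical machinery in `symbionet`: the models,
their assumptions, the tunable parameters, the synthetic-data generator,
and the numerical choices. Nothing here reports an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model and filtering

The universal input is a taxa × samples table of non-negative integer ASV
read counts, with per-sample metadata (site, substrate: four mosquito
tissues, three environmental substrates, or negative control) and a
taxonomy flagging vertically transmitted *Wolbachia* lineages.

Filtering follows standard amplicon practice: taxa detected in any
negative control are removed as molecular-pipeline contaminants; taxa with
total count below 2 (singletons) are removed; a prevalence filter keeps
taxa detected in at least `ceil(0.05 × n_samples)` samples. The
*Wolbachia* flag drives an exclusion used only on the
environmental-acquisition branch (nestedness and sharing tables): the
question there is whether environmentally acquired symbionts source the
tissue microbiomes, so vertically transmitted endosymbionts are
uninformative. Modularity, specialization and the grouping models retain
them — the tissue modules of interest contain *Wolbachia*.

Rarefaction draws each sample (or each aggregated category column) without
replacement to a fixed depth via the multivariate hypergeometric
distribution; samples below depth are dropped with a warning rather than
raising, since field designs routinely lose a sample. Default depths are
2176 for matrices combining environmental and mosquito categories and
2000 for mosquito-only matrices, applied per aggregated category column
(whether the original analysis rarefied per sample or per column is not
recoverable; per-column is the default here and both are available).

## Nestedness temperature

Aggregated networks are binarized (weight > 0) and packed: rows and
columns are first ordered by marginal totals, then refined by re-ranking
rows/columns by the mean packed position of their presences, keeping the
ordering with the lowest temperature (at most 20 passes; ties break by
input order, so packing is deterministic). On the packed matrix mapped to
the unit square, the isocline of perfect nestedness is the superellipse
`(1−x)^p + (1−y)^p = 1` with `p` solved (Brent, |area error| < 1e−12 via
the closed-form Γ volume) so the expected-presence region equals the
observed fill. Each unexpected cell — a presence outside the region or an
absence inside it — scores `u = (d/D)²`, where `d` is its distance from
the isocline along the corner-to-corner diagonal through the cell
(vectorized bisection, 60 iterations) and `D` that diagonal's length; the
temperature is `100/0.04145 × mean(u)` over all cells, capped at 100.
Degenerate (full or empty) matrices report 0 with a warning.

Significance uses `vaznull` nulls (below), lower tail: nestedness means
the observed matrix is *cooler* than null matrices with the same
dimensions, connectance and total weight. A perfectly nested balanced
staircase scores exactly 0; even-sided checkerboards score far above 50.
One boundary case worth knowing: the 2×2 checkerboard scores 37.7, not
above 50, because its two absences sit exactly on the fill-0.5 isocline.

## Null models

* `vaznull`: preserves dimensions, connectance (number of links), total
  weight, and coverage of every row and column; marginal totals are
  preserved only in expectation. A minimal covering skeleton (one link
  per node on the longer side, anchored to a weighted sample of the
  shorter side) is completed to the observed link count by sampling empty
  cells with probability ∝ r_i c_j; each link gets one weight unit and the
  rest of the weight is distributed over links by a single multinomial
  draw with probability ∝ r_i c_j.
* `r2dtable` (Patefield): integer tables with exactly the observed
  margins, sampled from the margin-conditional (multivariate
  hypergeometric) distribution via `scipy.stats.random_table`. Note this
  distribution is *not* uniform over distinct tables; the constraint and
  distribution tests check against the exact conditional probabilities
  `∏r_i!∏c_j!/(F!∏a_ij!)`.

Empirical p-values use the add-one convention `p = (1+#extreme)/(1+n)`,
so p is never 0; z-scores are reported as NaN when the nulls have no
spread. Defaults: 1000 nulls for nestedness and H2′, 100 for modularity
(each annealing run is itself expensive); both configurable.

## Modularity

Barber-style weighted bipartite modularity is maximized by simulated
annealing over a flat partition of all row and column nodes: single-node
reassignments (to any occupied label or one fresh label) and occasional
module merges, Metropolis acceptance `exp(ΔQ/T)`, geometric cooling
(0.995/step, 10⁴ steps, 5 restarts by default), the initial temperature
calibrated so roughly half the worsening warm-up moves would be accepted.
Each restart ends with a deterministic polish that exploits the structure
of Q: row–row pairs never contribute, so given any column partition each
row attaches optimally (and its best attachment is always ≥ 0 because a
row's cells sum to zero in the modularity matrix); the polish alternates
optimal row attachment with single-column moves until no improvement.
The same observation yields an *exact* oracle for small networks:
enumerate set partitions of the columns only and attach rows optimally.
The annealer is validated against this oracle (≥95% exact on random
≤12-node instances). The flat partition replaces the hierarchical-tree
state space of the original annealing description: the objective is
identical and correctness is testable against the oracle.

## Specialization (H2′)

`H2 = −Σ p_ij ln p_ij` over the interaction proportions. The
standardization bounds are computed over *integer* tables with the
observed margins: greedily (floor of the independence expectation plus
largest-deficit top-ups for the maximum; repeated pairing of the largest
remaining margins for the minimum, plus a bounded 2×2-exchange polish)
or by exhaustive enumeration. The exact method is the default for tiny
tables (F ≤ 16, ≤ 20 cells): the integer minimum-entropy problem has a
subset-sum structure that greedy allocation can miss, in which case the
greedy range is strictly inside the exact range (H2′ biased slightly
upward) — conservative, and irrelevant at data scale where the greedy
bounds are standard practice. `H2′ = (H2max − H2)/(H2max − H2min)`
(defined as 0 when the margins admit only one table), tested upper-tail
against fixed-margin nulls, whose bounds are computed once since all
draws share the margins.

## Tissue-grouping mixed models

For tissue partition g with G groups, read count `y_ts` of taxon t in
sample s follows a zero-inflated negative binomial:

    log μ_ts = β_{g(s)} + offset_s + u_t + v_{t,g(s)}
    u_t ~ N(0, σ_u²),   v_{t,g} ~ N(0, σ_v²)
    logit π_t = z_t,    z_t ~ N(ζ₀, σ_z²)
    y_ts ~ π_t δ₀ + (1−π_t) NB2(μ_ts, θ)

with `offset_s = log` total reads of sample s. The null model keeps only
the intercept, u and the zero-inflation component. The response family is
configurable (NB2 default, Poisson available); the zero-inflation
intercept is a per-taxon random effect by default, bounding the parameter
count. Parameter counts are k = G + 5 (G group means, θ, σ_u², σ_v², ζ₀,
σ_z²) and 5 for the null — exactly the degrees of freedom printed for
this model family in published comparisons (7/8/9 for 2/3/4 groups, 5 for
the null). AICc uses n = taxa × samples (the (sample, taxon) observation
unit).

Estimation: random effects are independent across taxa given the
variances, so the marginal likelihood factorizes into per-taxon blocks of
dimension G+2, each integrated by a Laplace approximation at the joint
mode. Modes are found by damped Newton with analytic gradients and
Hessians (fused numba kernels with an exact numpy fallback, equal to
~1e-13), per-taxon trust region (step norm ≤ 3), backtracking line search
on still-worse taxa only, and inner gradient tolerance 1e−8 (the
objective error is quadratic in this tolerance). A zero-gradient point
can be a saddle — perfectly separated zero patterns (e.g. a
*Wolbachia*-like taxon absent from one tissue group) let the count and
inflation components trade off — so positive-definiteness is checked by
batched Cholesky and offending taxa are kicked along their negative
curvature direction (downhill side) and re-converged, up to 4 rounds,
with an eigenvalue-floored log-determinant as a last resort. The outer
parameters are maximized by L-BFGS-B with finite differences (step 1e−5,
well above the inner noise floor) under bounds (log-variances in
[−8, 4], log θ in [−4, 8]). Within a model comparison, the finest
partition is fit first and warm-starts every other model: group means,
variance components (inflated by the variance of the mapped interaction
modes, since a misgrouped model needs σ_v² to absorb residual block
structure), and the inner modes themselves.

Laplace accuracy was verified against dense 2-D quadrature on the null
model (agreement to ~0.03 log-units on a 3-taxon block) and by parameter
recovery: at 40 taxa × 80 samples the variance components are recovered
with mean relative bias well inside ±20% (σ_v² shows the expected mild
Laplace shrinkage). Conditional modes of v are reported per (taxon,
group); since u absorbs each taxon's average response, the recoverable
signal is the within-taxon contrast across groups.

Comparison output: models sorted by AICc with Δ, Akaike weights
`w_i ∝ exp(−Δ_i/2)`, and interpretation bands (Δ ≤ 2 indistinguishable,
2 < Δ ≤ 7 worse, Δ > 7 rejected). Non-converged fits are excluded with a
warning. The likelihood-ratio test compares nested fits via χ² with
df = Δk.

## Ordination

Bray–Curtis dissimilarities (`Σ|x−y|/Σ(x+y)`) feed nonmetric MDS
(scikit-learn's SMACOF with isotonic regression, stress-1, 20 random
starts by default, best kept), centered and rotated to principal axes
with a deterministic sign convention.

## Synthetic-data generator

The generator emulates the field design: 20 sites; per site one pooled
sample of each of the four tissues (80 tissue samples) and three
replicates of each environmental substrate (180 environmental samples).
Structure, with defaults:

* regional pool of 1000 taxa with log-normal abundances (σ = 1.2),
  perturbed per site (log-normal, σ = 0.8);
* substrate-specific tilt (log-normal, σ = 1.8) plus a 25% per-substrate
  exclusion, so substrate-level taxon sharing lands in the 0.6–0.95 range
  typical of co-occurrence tables rather than saturating;
* tissues sample the local site pool restricted to a colonizer subset
  (20% of taxa — yielding ~150–200 tissue ASVs after filtering, a typical
  tissue-inventory size for this design) with selection weight
  ∝ pool × exp(α·affinity), α = 3; affinities are shared within the
  blocks of the planted partition ("cg-mo" by default: crop+midgut vs
  tubules+ovaries) with a small per-tissue jitter (0.05) — the planted
  partition *means* that within-block tissues share taxon responses;
  taxa assigned to a module (30% of colonizers) are additionally
  up-weighted 8× in that module's tissues;
* two vertically transmitted *Wolbachia*-like taxa injected only into
  Malpighian-tubule and ovary samples at ~35% expected read share;
* per-(taxon, sample) structural zeros with probability 0.25, applied
  before multinomial depth sampling (6000 reads per environmental, 4000
  per tissue sample).

The pool tail (σ = 1.2 rather than heavier) matters for calibration: with
very strong dominance, per-sample "effective depth" for non-dominant taxa
varies in a way a single-dispersion ZINB cannot absorb, and every
grouping model then gains spuriously over the intercept-only model even
without planted structure. At the default, data with no planted structure
(α = 0, no modules, no vertical taxa) keep the null model within 2 AICc
of the best grouping model in most replicates, and nestedness p-values on
connectance-null draws are approximately uniform.

What the generator does **not** emulate: sequence-level error, chimeras,
primer bias, taxon–taxon interactions, phylogenetic structure in the
affinities, and seasonal or spatial autocorrelation beyond the site
effect. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the assumed generative structure, not
robustness to every property of real amplicon data.

## Problem sizes used by the tests

Unit tests run on small fixtures (≤ 30 taxa). The end-to-end recovery
suite uses the full default design (20 sites, 1000 environmental taxa)
with 25 replicates for the planted-structure arm and 10 for the
no-structure arm, 200 null matrices per nestedness test, annealing at
4000 steps × 3 restarts; the oracle-equivalence suite uses 50 random
≤12-node networks and 60 random integer tables with F ≤ 12; the
distribution check uses 10,000 fixed-margin draws. `scripts/acceptance.py`
runs one full pipeline at 200 nestedness/H2′ nulls and 50 modularity
nulls. These sizes are the package's own verification choices; all are
configurable upward.

## Known limitations

* The Laplace approximation mildly shrinks the interaction variance
  (σ_v² ~10–15% low at the default scale); a quadrature refinement is the
  natural extension.
* AICc's parameter count treats each random-effect *variance* as one
  parameter, so partitions with more groups gain whole random-effect
  dimensions cheaply; model selection is calibrated for data compatible
  with the model family (checked by the no-structure suite) but can favor
  finer partitions under strong marginal misspecification.
* The packing refinement is a heuristic; it never worsens the
  marginal-total ordering (the best ordering seen is kept) but does not
  guarantee the globally coolest arrangement.
* vaznull preserves margins only in expectation (by construction); checks
  hold them to ~5% at moderate weight.
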