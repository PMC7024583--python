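# Methods

This note documents the statistical machinery in `spotclust`: the models
and their assumptions, the parameters that matter, what the synthetic
generator does and does not emulate, and the numerical conventions.

## Data model

The analysis unit is a binary spots × samples detection matrix. Technical
replicates are consolidated by a reliability rule before analysis: a spot
is detected in a sample iff it appears in at least two replicates of that
sample, or in one replicate there and at least one replicate of some other
sample. Spots failing the rule in every sample are removed (not zeroed)
and the count logged, so downstream spot totals remain auditable.
Species-level *consensus proteomes* are per-species unions of sample
detections (a protein present in any sample of a species is present in
that species); *occurrence-frequency* matrices record the per-group
detected fraction instead. Both paths are exposed because a binary and a
frequency reading of the species-level analysis are both defensible; they
coincide after thresholding frequencies at zero.

## Dissimilarity and trees

Jaccard dissimilarity 1 − |x∩y|/|x∪y| for binary columns; the Ružička
form 1 − Σmin/Σmax for frequency profiles (it reduces exactly to binary
Jaccard on 0/1 input, which is why it was chosen among "quantitative
Jaccard" variants). A pair with an empty union scores 0 by convention and
triggers a warning — two all-absent profiles are formally identical but
biologically degenerate.

UPGMA uses size-weighted average linkage with node height = merge
distance / 2, so the dendrogram is ultrametric by construction. NJ is
Saitou–Nei with the Studier–Keppler criterion; negative branch-length
estimates on non-additive input are clamped to zero and the clamped
deficit logged. Tie-breaking inside either algorithm follows the
underlying solver's deterministic merge order; to keep results exactly
invariant to input column order, the bootstrap drivers first sort samples
lexicographically. A fit diagnostic (Pearson correlation and normalized
stress √(Σ(d_tree − d)²/Σd²) over leaf pairs) compares UPGMA vs NJ
suitability for a given matrix: on ultrametric data UPGMA attains stress 0.

### Ultrametric projection

For tree comparison, a rooted tree is projected to ultrametric form by
minimising Σ_{i<j} (D_ij − 2·h(mrca(i,j)))² over internal-node heights
h ≥ 0 with h(parent) ≥ h(child), where D is the tree's own cophenetic
matrix. Because every leaf pair has exactly one MRCA the objective is
separable per node (a weighted isotonic regression on the tree partial
order); it is solved by SLSQP from a feasible warm start (running maximum
of the per-node unconstrained optima up the tree), with any residual
constraint violation repaired by a final monotone pass. Already-ultrametric
input is a fixed point. The ultrametric tolerance is 1e-8 absolute on
root-to-tip path-length spread.

## Branch support

**AU (approximately unbiased) p-values by multiscale bootstrap.** Spots —
the features — are resampled with replacement, because the trees cluster
samples/species and the spots are the evidence. At each relative scale
r ∈ {0.5, 0.6, …, 1.4} (ten scales), B replicates of round(r·m) spots are
drawn, samples are reclustered, and each full-data clade's bootstrap
proportion BP(r) is recorded. With ψ(r) = Φ⁻¹(1 − BP(r)), the
two-parameter model ψ(r) = v·√r + c/√r (signed distance v, boundary
curvature c) is fitted by maximum binomial likelihood, with
weighted-least-squares estimates as the starting point and as fallback if
the optimiser fails. Then

    AU = 1 − Φ(v − c),   BP_corrected = 1 − Φ(v + c),

with the AU standard error by the delta method from the binomial Fisher
information. Scales with BP ∈ {0, 1} carry no probit information and are
excluded from the fit; clades with BP ≡ 1 (or ≡ 0) at every scale
short-circuit to AU = 1 (or 0), and with fewer than two informative scales
the plain proportion nearest r = 1 is reported and flagged. Each scale
uses an independent seeded substream, so results do not depend on
execution order. At B = 10,000 the AU standard error of well-supported
clades (AU ≥ 0.9) stays below 0.01; the default pipeline setting B = 1,000
trades ~3× that precision for a tenth of the time.

**Ordinary (Felsenstein) proportions** resample spots at full size and
report, for every non-trivial bipartition of the reference NJ tree (or
clade of the UPGMA tree), the fraction of replicate trees containing it.
Clade identity is label-set based throughout, hence rotation-invariant.

## Clusterwise stability

Samples are resampled with replacement; each bootstrap data set is
reclustered (UPGMA on Jaccard) and cut into k clusters for every requested
k (default 2…12). An original cluster C is scored per iteration by its
best-match Jaccard J = max_D |C∩D|/|C∪D| over bootstrap clusters D, with
both sides restricted to the distinct samples drawn in that iteration
(duplicate draws collapse to sets; a duplicated sample takes the cluster
of its first occurrence). Iterations in which C has no drawn member are
skipped for C rather than scored zero, and the denominator is the number
of evaluated iterations. Reported per cluster: mean J, its SD, the
recovery probability P(J > 0.75) and dissolution probability P(J < 0.5).
Because the "recovery probability" of the source material is ambiguous
between per-iteration and mean-based readings, a composition-level
first-appearance table is emitted as well. An exhaustive mode enumerates
all nⁿ draws for tiny n to validate the Monte-Carlo estimator.

## Indicator-value markers

Each named analysis is a two-group contrast: a target clade's samples vs
all remaining samples — the minimal reading consistent with per-cluster
marker counts. With f_k the spot's occurrence frequency in group k,

    A_g = f₁/(f₁ + f₂)   (group-equalized specificity),
    B   = f₁             (sensitivity),
    IndVal_g = √(A_g · B),

so duplicating complement samples changes nothing — the equalization that
motivates this variant for unbalanced designs. Significance is by free
permutation of group labels, implemented as uniform random target subsets
(the statistic depends only on the subset), with complete enumeration
whenever C(n, n₁) ≤ 20,000 (exact p = tail fraction; otherwise
p = (1 + exceedances)/(1 + n_perm), n_perm default 9,999 for stable
p near the 0.05 boundary). BH step-up adjusts across spots within each
target. The marker table also reports the raw specificity
A = P(target | spot present); a *perfect* marker is a significant spot
with A = 1 and B = 1. All samples participate by default, including
penis-only ones; callers can restrict via the annotation query.

## Tree concordance

- **Robinson–Foulds**: symmetric difference of non-trivial bipartition
  sets, unrooted reading; normalized by 2(n−3) for fully resolved trees
  (else by the total bipartition count).
- **Cophenetic correlation**: Pearson correlation of the upper-triangle
  cophenetic vectors, invariant to rerooting and branch-length scaling.
- **Fowlkes–Mallows profile**: both (ultrametricized) trees are cut into
  k clusters by node height for k = 2…n−2, ties broken by the
  lexicographically smallest descendant tip; from the contingency matrix,
  Bk = Tk/√(PkQk) with Tk = ΣΣm²ᵢⱼ − n, Pk = Σm²ᵢ· − n, Qk = Σm²·ⱼ − n.
  The permutation-null moments are analytic: E[Bk] = √(PkQk)/(n(n−1)) and
  the closed-form variance in Pk, Qk, P′k = Σmᵢ(mᵢ−1)(mᵢ−2), Q′k; both
  were verified against 10,000-permutation Monte-Carlo nulls before use
  (the test suite re-runs this check). The rejection threshold is
  one-sided at α = 0.05 (E + 1.645·sd), matching the FDR convention used
  elsewhere; degenerate cuts (Pk or Qk = 0) are omitted.
- **Normalized cophenetic matrices**: each tree's distances divided by its
  own maximum, for side-by-side reading of relative distances.

Comparisons are reported on the ultrametric projections (the raw-tree
correlation is available by disabling the projection), bracketing the
open question of whether published comparisons rescaled branch lengths.

## Synthetic data generator

The generator emulates the structure the analysis presumes, at the scale
of the motivating survey: 796 spots × 49 samples, 10 species in a fixed
two-genus + subgenus hierarchy. Background spots (600) evolve along the
model tree as a two-state CTMC with gain/loss rates λ01 = λ10 = 0.35 per
unit branch length and Bernoulli(0.5) root state — so Jaccard distances
genuinely reflect tree distances, rather than arising from per-tip
independent noise. Planted markers (160, per species and per named clade)
are present on exactly their clade; factor-block spots (36) are private to
one level of a sample factor (body part "pe", location "UK"), mimicking
non-phylogenetic structure. Samples inherit their species row and flip
cells at false-negative rate 0.02 and false-positive rate 0.005 — a
low-noise regime for consolidated detections. `noiseless_config()` turns
off noise and factor blocks: the perfect-data regime in which the pipeline
must recover the tree (RF = 0), all planted markers and fully stable
species clusters, which the acceptance tests assert.

What the generator does **not** emulate: gel-image artefacts and spot
matching errors, abundance information, correlated detection failures
within a gel, replicate structure (samples are generated at the
consolidated level), and rate heterogeneity across spots. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data pathologies.

## Numerical conventions and problem sizes

- Empty-union Jaccard pairs → distance 0, logged.
- NJ negative branches → clamped to 0, deficit logged.
- Ultrametric tolerance 1e-8; SLSQP ftol 1e-14, ≤ 500 iterations.
- Permutation p-values never drop below 1/(n_perm + 1); exact enumeration
  has no such floor.
- Statistic ties in permutation tests use a 1e-12 absolute tolerance.
- Bootstrap clades/bipartitions are tracked as integer bitmasks; Jaccard
  inside bootstrap loops is computed by BLAS matrix products.
- Default pipeline sizes (B = 1,000 per bootstrap stage, n_perm = 999)
  keep a 796 × 49 run under a minute on one CPU; the stability and AU
  estimators accept B = 10,000 for production precision.

## Known limitations

- AU support assumes the two-parameter (v, c) model; third-order
  refinements are out of scope.
- The FM profile requires meaningful height cuts, hence ultrametric input;
  non-ultrametric trees are projected first.
- Only two-group IndVal contrasts are implemented — not the multi-level
  site-combination variant.
- With fewer than two informative bootstrap scales the AU value degrades
  to a plain proportion (flagged in the output).
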