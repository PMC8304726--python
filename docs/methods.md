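# Methods

This note documents the statistical model behind `rankfuse`, the defaults
and why they were chosen, the numerical decisions that were genuinely open,
and what a green test run does and does not establish.

## Model and assumptions

The pipeline assumes that disease subtypes manifest as subjects whose
*extremal* molecular features — the most and least expressed genes, probes
or miRNAs — are consistent within a subtype across at least some omics
layers, and that subtypes differ in overall survival. It deliberately makes
no distributional assumption about the measurements themselves: every
comparison happens on within-subject ranks, so the method is invariant to
any strictly increasing per-subject transform (the "normalization-free"
property). The cost of this choice is reliance on the extremes of each
profile: pathologically noisy tails can distort signatures, and short
signatures on weakly separated cohorts carry little signal (see
"Limitations").

## Stages, parameters, defaults

**Preprocessing.** Count-like layers (expression, miRNA) take natural
`log(x + pseudo)` with `pseudo = 1`; bounded quantities such as methylation
beta values do not. Zero-variance features are removed *before* z-scoring.
z-scores use the population (1/n) standard deviation. The coefficient of
variation CV = |σ/μ| is computed on post-log, **pre-scaling** values because
σ/μ is degenerate on z-scored rows (μ = 0); features with CV strictly below
the 5th percentile (linear-interpolation definition) are dropped, so an
all-tied CV distribution drops nothing, and μ = 0 features get CV = +∞ and
are never dropped. Missing values are rejected, never imputed.

**Signatures.** Stable decreasing sort; ties break by original feature
order so runs are reproducible. The bottom signature is oriented
most-extreme-first, so the top-weighting of the similarity measure
emphasizes the most extreme features symmetrically on both sides; nothing
downstream depends on the opposite orientation beyond a relabeling of
prefix depths. `n1 = n2` by default but they are independent parameters
and are optimized independently.

**RBO similarity.** The extrapolated form on equal-length lists; no
min-overlap correction is needed because signatures are equal-length by
construction. The persistence p is not set directly: it is solved by
bisection (tolerance 1e-10) so that the prefix-weight function of the RBO
literature assigns the full signature depth k a target mass of 0.8. The
prefix weight is strictly decreasing in p — a longer list carries the same
mass with slower decay, so p grows with k (p ≈ 0.96 at k = 20, ≈ 0.99 at
k = 100), and demanding mass → 1 drives p → 0, not 1. p is recomputed per
signature length and recorded in the matrix metadata. The similarity
measure is pluggable (any callable on two signatures); a Spearman-footrule
reference implementation ships for tests, RBO is the production measure.

**Length selection.** Histograms use 100 equal-width bins on [0, 1] (the
binning is configurable; the choice only needs to be shared between the
distributions entering one divergence). A pseudo-count of 1 is added to
every bin *before* normalizing by the total, so probabilities are strictly
positive and D_KL is always finite; because bin widths are constant, count
normalization equals density normalization up to a constant that cancels in
the ratio. The divergence of each candidate length against the shortest is
computed with base-2 logs; the *smallest* length attaining the maximum
divergence wins, so plateaus and ties resolve early and the shortest
candidate can only win when every divergence is zero. Default candidate
grid (25, 50, 100, 150, 200, 250), capped at half the feature count per
side; n1 and n2 are optimized on top-side and bottom-side matrices
separately and the combined (averaged) matrix is rebuilt at the chosen
pair — how the two optimized sides should be recombined was an open design
point; averaging mirrors the fixed-length path.

**Fusion.** Similarity network fusion re-implemented from the published
update rule: full kernels put half the transition mass on the diagonal and
row-normalize the rest; local kernels keep each row's K nearest neighbors,
row-stochastic; each network is driven toward the average of the others
(P_v ← S_v · mean(P_w, w≠v) · S_vᵀ) for 20 rounds with a unit
identity stabilizer added per round, then averaged and symmetrized.
Defaults K = 20 (capped at n/3) and 20 iterations. RBO matrices are fed to
fusion directly as affinities — no distance conversion, which was reported
to hurt.

**Clustering.** Normalized spectral clustering: bottom-k eigenvectors of
the symmetric normalized Laplacian, row-normalized, then k-means with 50
seeded restarts; labels are canonicalized by first appearance so the
partition is seed-deterministic and permutation-equivariant. When k is not
given, the eigengap of the Laplacian spectrum picks it over [2, 8]; a
degenerate spectrum (all gaps tied, e.g. one uniform block) returns the
minimum with a warning flag. A graph with more connected components than k
is an error rather than an arbitrary split.

**Survival scoring.** Multi-group log-rank with the discrete-time
hypergeometric variance (tie-corrected, covariance over the first k−1
groups, chi-squared with df = k−1). The permutation test shuffles cluster
labels (multiset preserved) with a seeded generator and counts permutations
whose **chi-squared** is at least the observed one; comparing the statistic
rather than the asymptotic p sidesteps ties and is equivalent at fixed df.
The empirical p uses add-one smoothing, (c + 1)/(N + 1), so a zero count
yields the finite cap −log₁₀(1/(N+1)) ≈ 4.477 at N = 30,000. The
printed form of the score formula in the source material inverts the
inequality (it would score the best clusterings near 0); the implemented
direction is the only one consistent with "higher score = better" and is
pinned by a null-calibration test. The permutation loop is vectorized in
batches, so the default 30,000 permutations take well under a second at
n ≈ 100.

**Biomarker.** Signature positions x = 1..n map to (x − min)/max(x − min),
are reversed as 1 − value ("subtracting 1" literally would give negative
scores and invert the ordering), and are divided by the cluster's subject
count. Scores are summed over subjects and both sides; features sort by
descending score with ties broken by id; the top 100 are kept by default
(per layer; a pooled report is a caller-side concatenation). The Wilcoxon
rank-sum filter runs on each candidate's per-subject **rank** within the
full profile — preserving the normalization-free character; testing
preprocessed values instead is a config flag, since which values the test
should see was an open point. Exact enumeration below 25 per group without
ties, normal approximation with tie correction otherwise; Bonferroni over
the candidates actually tested; features constant across both clusters get
p = 1. The cluster pair defaults to the largest Kaplan–Meier median
survival difference, falling back to mean observed time where a median is
never reached.

## Synthetic data: what it emulates, what it does not

The generator plants `k` subject groups. Each layer is i.i.d. Gaussian
noise (sd 1) plus a per-group mean shift (default 3 sd) on a 40-feature
informative block, half shifted up and half down so both signature sides
are informative; blocks are offset per layer so integration is rewarded.
Survival is exponential with per-group hazards halving from 1/300 per day
(clearly separated medians), and a target fraction (default 20%) of
subjects is censored uniformly before their event time, which hits the
requested censoring rate exactly. Defaults: 120 subjects, 3 equal groups,
3 layers of 200 features, seed-determined to the byte.

This emulates group-separable layers with group-dependent survival — the
structure the method assumes — and nothing else: no platform artifacts, no
batch structure, no missingness, no probe naming, no correlated feature
blocks beyond the planted shifts. A green end-to-end test therefore
establishes that the implementation recovers planted structure under the
method's own assumptions, not that it would rank well on any particular
real cohort.

**A hard limit of mean-shift toys.** Per-feature z-scoring maps a balanced
two-group mean shift onto values bounded by |z| = 1, while pure-noise
features keep sd 1 and overshoot it routinely. Very short signatures on a
small balanced cohort are therefore dominated by noise features *no matter
how large the planted shift is*. The shipped 12-subject worked example
consequently uses signatures of length 6 with wide informative blocks
(16 of 40 features per group), a regime where the planted partition is
recovered for every generator seed; 3-item signatures are not reliably
informative in any balanced mean-shift design of this size. Its biomarker
step tests 10 candidates because the exact two-sided rank-sum floor for
6-vs-6 clusters, 2/C(12,6) ≈ 0.0022, cannot pass a Bonferroni factor much
above 20 at α = 0.05.

## Numerical choices

- Bisection for p: tolerance 1e-10 on a strictly monotone function;
  failure to bracket reports k and the requested weight.
- Pairwise RBO uses a vectorized prefix-overlap recurrence (each element
  enters the joint prefix at depth max(own position, position in the other
  list) + 1); it is exactly the closed form, verified against a set-based
  brute-force oracle at 1e-12.
- Histogram edges span [0, 1] regardless of observed range, so
  distributions for different candidate lengths share bins by construction.
- Log-rank variance terms with one subject at risk contribute zero.
- Singular permutation covariance matrices fall back to a pseudoinverse.
- k-means ties and label names are canonicalized by first appearance.

## Limitations

- Reliance on profile extremes: heavy-tailed measurement noise can
  dominate short signatures.
- RBO cost grows with both signature length and cohort size (all pairs);
  the implementation is vectorized but still O(n²k).
- No confounder adjustment or stratified survival models; the score
  measures marginal survival separation only.
- The eigengap heuristic inherits the usual failure modes on overlapping
  or unbalanced clusters; fix k explicitly when it is known.
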