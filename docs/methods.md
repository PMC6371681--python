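# Methods

## The model and the question

All computations assume Jukes–Cantor (JC) nucleotide substitution: equal
base frequencies and equal exchange rates, so a branch is described by a
single parameter, its expected number of substitutions per site, in
[0, ∞]. Sites are independent and identically distributed, so an alignment
of n sites is fully summarized by counts over site-pattern equivalence
classes: five classes for three taxa — `xxx, xxy, xyx, yxx, xyz`
(multiplicities 4, 12, 12, 12, 24) — and fifteen for four taxa (one per
set partition of the taxa; multiplicities sum to 256). The package studies
how maximum likelihood places *long* branches on the two smallest
informative trees: where the branch to a distant taxon C attaches along
the A–B path of a three-taxon tree, and whether two long branches on a
quartet are drawn together.

Likelihoods are reported per specific site pattern (class probability
divided by class multiplicity) in natural log. On that scale the boundary
optima have the closed forms −n log 4 (all branches zero, constant data),
−n log 16 (an identical pair plus a saturated third branch) and −n log 64
(all branches saturated). The multiplicity term is an additive constant
and never affects a maximization.

## Likelihood computation

Writing e = exp(−4d/3) for a branch of length d, the probability that a
branch preserves a base is (1+3e)/4 and the probability of one specific
change is (1−e)/4. Three-taxon class probabilities are obtained by summing
the internal node's state out of the product of branch transition
probabilities, which leaves closed forms *multilinear* in (e_A, e_B, e_C);
e = 0 represents an infinite branch exactly (stationary limit), never a
numerical cap. Quartet class probabilities are computed the same way by
summing over the two internal nodes, for each of the three resolved
topologies; they are multilinear in the five e's.

## Numeric maximization

Because every class probability is linear in each e coordinate separately,
the conditional log-likelihood of one coordinate given the others is a sum
of logarithms of linear functions — concave, with a monotone derivative.
The solver is therefore cyclic coordinate ascent in e-space on the box
(0, 1], with each 1-D subproblem solved by derivative-sign bisection on
ln e to machine precision. Boundary detection is exact: the coordinate is
placed at e = 1 (d = 0) if and only if the conditional derivative is
non-negative there, which is the KKT condition, so zero-length branches
are exact zeros rather than small numbers. A pattern-move acceleration
(line search along each sweep's total displacement) removes the zigzag
that plain cyclic ascent shows on correlated coordinates; replicates whose
log-likelihood improves by less than 1e-10 leave the active set. The
search is batched with numpy across all replicates of an experiment.

Multi-start protocol: a fixed start at 0.1 for every branch plus seeded
log-uniform draws in [1e-3, 5] (five starts by default), and additionally
a per-replicate start at the distance-matrix branch estimates, which track
the ML optimum closely and avoid the saturation plateaus that trap
searches started far away. Quartet fits add a deterministic battery
(near-star, long tips, and "collapsed long tip with a long internal
branch" shapes, plus the Y↔Z mirror of every random start) because those
are the local-optimum geometries of saturated data. The finite cap is 50
substitutions/site; lengths at the cap are only candidates for infinity.

## Analytic boundary maxima and infinite-branch confirmation

On the boundary of the solution space the maxima have closed forms:

* an identical pair of sequences collapses its two branches to zero and
  the third branch takes the JC distance of its match fraction (infinite
  when matches ≤ n/4) — these are known *global* maxima;
* one branch zero: the collapsed taxon sits at the internal node and the
  two free branches take JC estimates of their pair match fractions,
  valid when both match counts exceed n/4;
* one branch infinite: the saturated taxon is uniform noise; only the
  *sum* of the two remaining branches is identified, equal to the JC
  distance of the remaining pair;
* all branches infinite: log-likelihood −n log 64, always a candidate.

After the numeric search, the zero-plane candidates replace the numeric
optimum wherever they are strictly better (numeric searches can miss a
boundary plane when the accompanying free branch is nearly saturated),
and then the infinite-branch candidates are compared against the result:
an analytic candidate within 1e-6 log units confirms the infinity, since
a numeric search can only approach the asymptote. A confirmed infinite
branch has no meaningful position on the tree.

The flat ridge left by a confirmed infinite branch (a + b fixed) is
resolved by the *limit of the finite-length optimum*: the likelihood is
profiled along the ridge with the infinite branch at a large reference
length (d = 12, where the first-order tie-breaking term is numerically
visible but second-order effects are negligible). For most saturated
datasets this limit sits at a ridge *edge*, i.e. one of the remaining
branches is zero — which is why zero-branch counts that include
infinite-branch trees exceed the distance-matrix counts.

## Distance-matrix analysis

JC pairwise distances are D = −(3/4) ln(1 − 4U/3) from the mismatch
fractions U, infinite at U ≥ 3/4. The three-point formulas fit three
distances to three branches exactly; a violated triangle inequality
(D_jk ≥ D_ij + D_ik, ties included, and including one infinite distance)
forces a non-positive branch and predicts a zero branch in the ML tree.
Two infinite distances to the same taxon predict an infinite branch; all
three infinite predict at least two infinite branches. The rows are
applied as a decision list with the infinite rows first. Predictions are
computed from pattern counts, never re-parsed sequences, so the DM and ML
pipelines consume identical sufficient statistics.

Accuracy scoring: the zero-branch predictor is scored against ML outcomes
over replicates whose ML tree has no confirmed infinite branch, because
the zero/non-zero status of a pair on a flat ridge is exactly the
"no meaningful position" artifact; the infinite-branch predictor is scored
separately over all replicates. Zero-branch *frequency* tables, by
contrast, count zero-branch trees among all replicates.

## Variance-based prediction of zero-branch frequency

The mismatch fractions are linear in the multinomial class frequencies,
so their exact covariance (cross-covariances included — the three
distances share sequences) follows from the multinomial covariance
evaluated at the *true* class probabilities. The delta method through the
log transform gives the covariance of the distance estimates, and the
three-point formulas propagate it to d̂_A and d̂_B. Treating each
estimate as normal with mean at the truth, the predicted zero-branch
proportion is P(d̂_A ≤ 0) + P(d̂_B ≤ 0); the two events are mutually
exclusive up to a negligible set when the true lengths are positive. The
delta method is first-order: at n = 300 its covariance undershoots the
empirical covariance by ~7% (the log transform's curvature), shrinking
roughly like 1/n — which is also why the predicted proportions sit
slightly below the simulated ones.

## Simulation

Because sites are iid, an n-site JC dataset is distributionally one
multinomial draw of size n over the exact class probabilities; that
shortcut is the default simulation path. A sequence-level simulator (root
from the stationary distribution, per-branch transition matrices, matrix
exponential for general reversible models) is retained for general models
and end-to-end I/O tests; the two paths are checked for distributional
equivalence by chi-square. One master seed spawns per-replicate child
streams, so replicate r is reproducible independently of chunking. A GTR
parameterization is supported as user configuration (a documented default
ships with equal rates); no published GTR curve is reproduced because the
original parameter values are not printed.

The generator's default conditions are the study's: three-taxon trees
with d_A = d_B ∈ {0.05, 0.1, 0.2, 0.3} and d_C ∈ {0.1, 0.5, 1, 1.25,
1.5, 2}, n = 300 sites, 5000 replicates per condition; quartets with a
W–X path of length 0.1, the long branches to Y and Z attached at 1/3 and
2/3 of the path ("evenly spaced", so the internal branch is 0.1/3),
n = 1000 sites, and 5000 (length-1.5 closeness analysis) or 2000
(length-grid joining analysis) replicates. What the multinomial generator
does *not* emulate: indels and alignment error, rate heterogeneity across
sites, non-JC processes in the JC experiments — so passing tests speak to
ML's intrinsic behavior under the model, not to robustness on real data.

## Quartet topology outcomes

Each replicate is fitted under all three resolved topologies and the best
wins. Outcomes: `c` — the generating topology WY|XZ; `e` — the swapped
topology WZ|XY; `d` — the long branches joined, WX|YZ; `f` — the star
(the winner's internal branch is exactly 0, where all three resolved
topologies coincide). Exact likelihood ties (within 1e-9) are frequent at
saturation because degenerate trees let distinct topologies realize the
same likelihood; ties are split uniformly at random with a seeded stream
and flagged, since any deterministic order provably biases the tied
proportions (the saturated data distribution is exchangeable in Y and Z,
so the correct and swapped topologies must be equiprobable).

Positions along the W–X path: Y's and Z's attachment fractions, and their
signed separation (positive when Z is nearer X, as in the truth; zero for
outcomes d and f). Long-branch closeness is tested by comparing the
separation inferred from the two three-taxon trees (W,X,Y) and (W,X,Z)
with the separation on the winning quartet: points significantly below
the diagonal would indicate attraction. The sign test is a two-sided
exact binomial on points strictly below versus strictly above the
diagonal, ties dropped.

## Numerical choices

* Likelihood convergence tolerance 1e-10 per sweep; topology ties < 1e-9.
* Infinite-branch confirmation tolerance 1e-6 log units — far below the
  curvature of any finite optimum at these sample sizes.
* Optimizer cap 50 substitutions/site; ridge-resolution reference length
  12; bisections run to ~1e-14 relative precision in e.
* Degenerate inputs: n = 0 is rejected; an all-constant alignment returns
  the (0,0,0) optimum; impossible patterns give −∞ likelihood; positions
  are undefined (NaN) for d_A = d_B = 0 and excluded for infinite
  branches.

## Problem sizes used by the checks

The reproduction checks run the full grids at the study's replicate
counts: 5000 replicates per three-taxon cell (six Table-4 cells and the
24-cell accuracy grid), 2000 replicates for the saturated long-branch
quartet condition and 5000 for the length-1.5 closeness condition. On one
CPU the complete acceptance recomputation takes roughly a quarter of an
hour.

## Known limitations

* The interior (non-boundary) three-taxon maximum has no closed form;
  the numeric solver is exact only up to its (machine-level) tolerances.
  It was cross-validated against dense likelihood grids and against
  intensive quasi-Newton multi-start.
* The position correlation between three- and four-taxon fits at length
  1.5 comes out at ~0.99 under this exact solver, higher than the 0.96
  reported from heuristic-search pipelines, whose numeric jitter on a
  nearly flat likelihood attenuates correlations. The direction and
  significance of all asymmetry tests agree.
* The clock-plane (d_A = d_B) optimum is obtained by numeric restriction,
  not a closed form.
* Only 3- and 4-taxon trees; no rate heterogeneity; no amino-acid models.
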