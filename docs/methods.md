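# Methods

This note documents the models, algorithms and numerical choices behind
`sbias`, in the spirit of the methods documentation of simulation packages
like msprime: what is simulated, under which assumptions, which knobs
matter, and what the synthetic data can and cannot tell you.

## Tree model and representation

Trees are rooted ultrametric chronograms. Node **ages** (time before
present) are the canonical state; branch lengths are always derived as
`age(parent) − age(child)`, so the two representations cannot drift apart.
Construction validates: a single root, connectivity, tip ages zero within
`1e-8·H` (then snapped to exactly zero), `age(parent) ≥ age(child)` on
every edge, strictly positive terminal branches, and unique tip labels.
Trees failing ultrametricity are rejected, never repaired. Polytomies are
allowed everywhere except in the gamma statistic and Colless index, which
are defined for binary trees only.

Newick I/O: parsing is delegated to dendropy (branch lengths mandatory,
polytomies and quoted labels supported); serialization is in-package and
prints each branch length with the shortest decimal representation that
round-trips the IEEE double exactly. Parsed ages propagate top-down
(`age(child) = age(parent) − bl`), which makes write→read→write a
bit-exact fixed point — a property the test suite asserts on 100 random
trees.

## Pure-birth simulator

`simulate_pure_birth(n_tips, birth_rate=1)` runs the Yule process forward
from two lineages: waiting times are exponential with rate
`birth_rate × k` (k = current lineage count), the splitting lineage is
uniform. The simulation stops at the birth event creating the n-th lineage
and then extends all lineages by one further exponential waiting time with
rate `n × birth_rate`, so terminal branches are strictly positive and tips
are contemporaneous (simple-stop conditioning). Heights are not rescaled;
`birth_rate` defaults to 1, giving expected heights near `ln n`. Different
conditioning conventions shift the gamma and Colless distributions only
weakly; the calibration checks below use correspondingly wide stochastic
tolerances.

Shape statistics: the Pybus–Harvey gamma (asymptotically standard normal
under pure birth; the suite checks the mean over 500 replicates is within
±0.15 of 0), the Colless imbalance index (with the caterpillar closed form
`(n−1)(n−2)/2` verified exhaustively for n ≤ 12), and the sample standard
deviation of branch lengths (ddof = 1; no root edge exists in this
representation).

## Degradations

**Node collapsing** (polytomic chronograms). Eligible nodes are internal
non-root nodes, either all of them (`all` strategy) or only those in the
tipward half, `age < H/2` (`shallow` strategy; this reading of "shallow"
reproduces the dense terminal polytomies of taxonomy-grafted supertrees —
the rootward alternative is exposed via `eligible_side="rootward"`).
Exactly `k = round(fraction × |eligible|)` nodes (round half away from
zero, platform-stable) are drawn uniformly without replacement; each is
deleted and its children re-attach to the nearest surviving ancestor.
Surviving ages are untouched, so height, tip set and all root-to-tip paths
are preserved — asserted per output tree. The root is never eligible.

**Calibration-node selection.** `[0, H]` is cut into 5 equal time-slices;
the target count `m = round(fraction × #internal-non-root)` is allocated
to slices proportionally to their node counts by largest-remainder
rounding, raised to a minimum of 1 per non-empty slice (excess, if any, is
absorbed from the largest slices, never below 1). Nodes are drawn
uniformly within slices; the root is always fixed at its true age on top
of `m`, which preserves tree height downstream.

**BLADJ-style even interpolation** (pseudo-chronograms). Tips are dated at
0, fixed nodes keep their exact ages. For an undated node v with nearest
fixed ancestor A (age `t_A`, `d_A` edges up), the dated descendant B
(fixed node or tip; the search does not continue past fixed nodes) is
chosen to minimize the per-edge slope `(t_A − t_B)/(d_A + d_B)`, and

    age(v) = t_A − d_A · (t_A − t_B) / (d_A + d_B).

The minimum-slope rule spaces the longest undated chain through v evenly —
on a caterpillar with only the root dated at 10, the two undated internals
get 20/3 and 10/3 — and guarantees algebraically that v is never placed
below any of its fixed descendants. It is order-independent (no
cascading), so results do not depend on traversal order; ties are broken
by the smaller descendant age, then node index. A final pass clamps any
undated child to `age(parent) − ε` (ε = 1e-9·H), logging every clamp;
fixed ages that already violate ancestor–descendant ordering are rejected
up front with the offending pair named. With every internal node fixed the
output equals the input exactly.

The hallmark of these pseudo-chronograms — lower branch-length variability
than the true chronograms — emerges rather than being imposed; the suite
checks the mean SD difference over 100 trees at 5% fixing is negative.

**Combined treatment.** Shallow collapsing applied to a pseudo-chronogram;
calibrated nodes are protected from collapse (collapsing a node whose age
was deliberately fixed would conflate the two treatments).

## Trait simulation

Traits follow Brownian motion on the λ_sim-rescaled tree: x ~ N(a·1,
σ²·C_λ) with `C_λ = λ_sim·C + (1−λ_sim)·diag(C)`. Defaults are the study
conditions: root value a = 0, rate σ² = 1, λ_sim on the grid 0.1–0.9 in
steps of 0.1 (λ_sim = 1 is pure BM, used for the K calibration check).
Sampling goes through a Cholesky factor of the covariance rather than
branch-length tree surgery; the two are distributionally identical on
ultrametric trees and the covariance route is exact for polytomies and
directly testable (the suite verifies tip means, variances and pair
covariances against the analytic values at 3 Monte-Carlo standard
errors). Near-singular covariances fall back to an eigenvalue-clipped
factorization (floor 1e-12, logged); valid chronograms never need it.

Traits are a function of the **true** tree only and are reused unchanged
on every degraded counterpart — the pairing joins on a trait checksum to
enforce this.

## Signal statistics

Both indices run through the VCV matrix, making them valid on polytomic
trees without resolving polytomies into zero-length branches (which would
produce divide-by-zero contrasts). The identity between the GLS
mean-squared error and the variance of standardized Felsenstein contrasts
is verified against an independent pruning implementation to 1e-8 relative
on random binary trees, and K and λ are cross-checked against the
independent phytools `phylosig` implementation (through Rscript) on a
fixture tree.

Numerical design:

* One symmetric eigendecomposition of C per tree. Since `diag C = H`,
  `C_λ = λC + (1−λ)H·I` shares C's eigenvectors, so the entire λ profile
  and all permutation replicates are evaluated in the eigenbasis (O(n) per
  λ; one matrix product per permutation batch). This is what keeps
  1000-tree × 9-trait × multi-treatment runs at desk scale.
* λ maximization: 21-point grid seeding a bounded Brent search (tolerance
  1e-6) in the bracketing interval; boundary maxima are reported as
  exactly 0 or 1. The likelihood uses the ML variance (divisor n), which
  shifts lnL by a constant relative to REML conventions; the LRT is
  unaffected.
* Permutation test: the statistic is MSE (contrast variance); smaller =
  more signal; add-one correction so p ∈ (0, 1]; `perm_stat="k"` permutes
  K itself instead (the two orderings agree closely; MSE is the default
  because it matches the observed-vs-randomized-contrasts description and
  is cheaper).
* The λ LRT clamps the deviance at 0. Because λ̂ sits on the boundary
  under the null, the test is conservative-to-nominal; the suite checks
  the empirical size at α = 0.05 stays ≤ 7%.

## The experiment and its scale

`run_experiment` executes the full factorial design per tree — simulate,
shape stats, all degradations, 9 traits, both tests on every variant with
identical traits — and writes per-replicate results, the paired bias
table, and gamma/Colless decile-stratified tables (percentile with linear
interpolation, ties inclusive; strata below 5 trees warn but compute).
Bias frequencies use all pairs in a cell as the denominator; empty cells
are emitted with `n_pairs = 0`, never dropped. P-values are stored at full
precision so the α levels (defaults 5% accept / 1% reject) can be changed
at analysis time (`sbias tables`).

Seed discipline: a single master seed; every stochastic component
(tree i, trait (i, λ_sim), collapse, calibration draw, permutation block)
derives its generator from `SeedSequence(master, spawn_key=(stream, ...))`
with a fixed stream layout, so any replicate can be regenerated in
isolation and identical configs give byte-identical outputs. Runs are
resumable per tree via on-disk chunks; per-tree failures are logged,
skipped and counted in the manifest.

Default problem sizes are the desk scale the package's own acceptance
analysis uses — 100 trees per set at n ∈ {50, 100, 200} (1000 trees for
the cheap λ-only study at n = 50; 200 replicates for the K and λ̂
calibration means) — chosen so the full analysis completes in minutes on
one CPU while keeping Monte-Carlo error comfortably inside the stated
tolerances. The full published design (1000 trees per set, n up to 1000,
999 permutations everywhere) is supported by configuration and runs in
hours, not minutes.

## What the synthetic data does and does not emulate

The generator reproduces the study conditions: pure-birth chronograms,
λ-rescaled BM traits, random node collapsing, sparse time-sliced
calibration with even interpolation. Real supertrees differ in ways this
deliberately clean setup does not capture: non-Yule branching (real
chronograms are often tippier or stemmier than pure birth), taxonomically
clustered rather than random polytomies, calibration ages that are
themselves estimates with error, and trait evolution far from BM (OU,
rate shifts). Passing tests therefore demonstrate the *directional*
behaviour of the indices under controlled degradation — notably that
pseudo-branch lengths inflate K and its false-positive rate while λ is
largely immune — not quantitative error rates for any particular
empirical tree.

## Known limitations

* Only ultrametric trees; no birth–death or coalescent simulators; no
  Nexus I/O.
* λ is capped at 1 by the rescaling definition, so signal stronger than BM
  is not measurable with it (K has no such cap).
* The BLADJ interpolation rule is a documented reconstruction of the
  published algorithm's behaviour ("place undated nodes evenly between
  dated ones"); the original implementation's tie-breaking is not
  specified anywhere, so exact node-by-node agreement with it on
  pathological inputs is not guaranteed.
* `colless_index` and `gamma_statistic` require binary trees by
  definition; shape stratification therefore always uses the true
  chronograms.
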