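# sbias — do polytomies and pseudo-branch lengths bias phylogenetic signal tests?

Comparative biologists routinely measure *phylogenetic signal* — the
tendency of related species to resemble each other — with Blomberg's *K*
and Pagel's λ. In practice the phylogenies these tests are run on are often
imperfect: supertrees carry unresolved clades (polytomies), and trees dated
with sparse calibrations plus even interpolation of the remaining node ages
(BLADJ-style *pseudo-chronograms*) have artificially homogeneous branch
lengths. `sbias` is a simulation toolkit that quantifies how much these two
defects distort the two indices and, more importantly, their significance
tests, using paired comparisons between each "true" chronogram and its
degraded counterpart.

For whom: researchers in evolutionary ecology and community phylogenetics
who want to reproduce, extend or stress-test these sensitivity analyses, or
simply need fast, polytomy-safe implementations of *K* and λ.

## The statistics

Let C be the phylogenetic variance–covariance matrix of an ultrametric tree
(C_ij = shared root-to-tip path length of tips i and j, diag C = H) and
â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) the GLS ancestral mean of trait x on n tips.

**Blomberg's K** — with MSE0 = (x−â1)ᵀ(x−â1)/(n−1) and
MSE = (x−â1)ᵀC⁻¹(x−â1)/(n−1),

    K = (MSE0 / MSE) / E[MSE0 / MSE],
    E[MSE0 / MSE] = [tr(C) − n/(1ᵀC⁻¹1)] / (n − 1).

K ≈ 1 under Brownian motion, K → 0 with no signal. Significance: a
randomization test permuting x across tips and recomputing MSE (equal to
the variance of standardized independent contrasts on binary trees; the VCV
form extends it to polytomies), p = (1 + #{MSE_perm ≤ MSE_obs})/(1 + n_perm).

**Pagel's λ** — multiply the off-diagonal entries of C by λ ∈ [0, 1]
(C_λ = λC + (1−λ)·H·I for ultrametric trees); maximize the profiled
log-likelihood

    lnL(λ) = −½ [ n ln(2π σ̂²(λ)) + ln det C_λ + n ],
    σ̂²(λ) = (x − â(λ)1)ᵀ C_λ⁻¹ (x − â(λ)1) / n,

over λ and test against λ = 0 with a 1-df χ² likelihood-ratio test. Because
diag C = H, one eigendecomposition of C per tree serves every λ evaluation
and every permutation, which keeps thousand-tree studies at desk scale.

**Paired bias design** — traits with signal graded by a simulation
coefficient λ_sim ∈ {0.1, …, 0.9} (σ² = 1, root value 0) are simulated on
the true tree only and reused on its degraded versions. A pair is a
*type I bias* when the no-signal null is accepted on the true tree
(p > 0.05) but rejected on the degraded one (p < 0.01), and a *type II
bias* in the converse case; the dual α-levels screen out marginal flips.

## Worked example

```python
import sbias as sb

tree = sb.simulate_pure_birth(100, birth_rate=1.0, seed=13)   # true chronogram
x = sb.simulate_trait(tree, lam=0.4, seed=113)                # moderate signal

res_true = sb.signal_tests(x, tree, n_perm=999, seed=0)

# pseudo-chronogram: keep 5% of node ages (root always fixed), interpolate the rest
pseudo = sb.bladj_calibrate(tree, sb.select_fixed_nodes(tree, 0.05, seed=13))
res_ps = sb.signal_tests(x.reorder(pseudo.tip_labels), pseudo, n_perm=999, seed=0)

print(sb.classify_bias(res_true.p_K, res_ps.p_K))
```

Output for this seed:

```
true chronogram:   K=0.102  p_K=0.234   lambda_hat=0.485  p_lambda=5.69e-05
pseudo-chronogram: K=0.328  p_K=0.002   lambda_hat=0.485  p_lambda=6.52e-05
branch-length SD:  true 0.514 -> pseudo 0.486
K-test bias class: typeI
lambda bias class: none
```

The pseudo-chronogram's more homogeneous branch lengths inflate K more than
threefold and flip its test from clearly non-significant (p = 0.234) to a
confident rejection (p = 0.002) — a type I bias — while the λ estimate and
its test barely move. That asymmetry, tabulated over hundreds of trees,
sizes and signal levels, is the study's central result.

The full factorial study (both collapse strategies × collapse fractions
20–80%, fixing fractions 5–35%, the combined treatment, gamma/Colless shape
stratification) runs from the command line:

```sh
sbias run --config config.yaml          # writes results.tsv, bias_table.tsv, ...
sbias collapse --strategy shallow --fraction 0.6 --seed 1 in.nwk out.nwk
sbias bladj --fix-fraction 0.05 --seed 1 in.nwk out.nwk --constraints ages.tsv
sbias signal --tree t.nwk --traits traits.tsv --nperm 999 --seed 1 --out res.tsv
```

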