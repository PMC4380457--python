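# yuledist

Statistics of pairwise time distances between the leaves of a random Yule
(constant-rate birth–death) tree with incomplete leaf sampling — closed-form
densities, a kinetic Monte Carlo simulator that validates them, tree-free
distance-matrix statistics, and robust curve fitting that recovers the
identifiable rate combinations and bounds on the sampling fraction.

## The problem

In macroevolution the raw data behind a phylogeny are often just the pairwise
evolutionary time distances between species — twice the time to each pair's
most recent common ancestor, estimated by a molecular clock.  If speciation
and extinction are modelled as a branching process with constant birth rate
λ and death rate μ run for a time T, and each extant species is included in
the data independently with probability σ (incomplete sampling, or an
equivalent recent random mass extinction), then the expected histogram of
those distances has a simple exact form.  Writing r = λ − μ, the expected
density of pairs separated by time t is a pure exponential,

    N(t | T) = (σ²λ/2) e^{rT} e^{rt/2},        0 ≤ t ≤ 2T,

and similar closed forms exist for the distance to a leaf's n-th nearest
neighbour N_n(t|T), for cherries (reciprocal nearest-neighbour pairs)
N_Λ(t|T), and for the pairwise minimum of nearest-neighbour distances
N_min2(t|T).  All of them depend on (λ, μ, σ, T) only through three
identifiable combinations

    r = λ − μ,      q = λσ,      A = σ e^{rT},

so the individual parameters cannot be recovered from distances alone — but
σ ≤ q/r always, and the mere *shape* of a histogram carries information:
the nearest-neighbour density has an interior maximum only if
σ < (1/3)(1 − μ/λ), the cherry density only if σ < (1/4)(1 − μ/λ), and the
min2 density only if σ < (1/5)(1 − μ/λ).  A hump in one of these histograms
is direct evidence of undersampling.

The package is aimed at people who have ultrametric time trees (or just
distance matrices, e.g. a Bayesian posterior sample of trees) and want to
test the constant-rate model, estimate (r, q, A), and bound σ — without
reconstructing or trusting any single tree topology.

## What is in the box

| module | contents |
| --- | --- |
| `yuledist.analytic` | every closed form: leaf-count law P(M\|T) under sampling, moments, branch lengths, the four density families, unimodality thresholds and maximum locations, small-bin occupancy probabilities and the conditional density Ñ |
| `yuledist.simulate` | kinetic Monte Carlo tree simulator (full genealogy retained), ensemble histogram accumulation with per-bin standard errors, bin-occupancy tallies |
| `yuledist.stats` | tree-free statistics from a bare distance matrix: pairwise / n-th nearest / cherries / min2, and histogram building |
| `yuledist.inference` | robust IRLS fit of the curves in (r, q, A), sampling-fraction bounds σ ≤ q/r, implied σ under an assumed μ/λ, maximum-detection bound claims |
| `yuledist.io`, `yuledist.cli` | Newick (via dendropy), TSV/PHYLIP matrices, histogram TSVs, JSON fit reports; the `yuledist` command with `simulate`, `density`, `stats`, `fit`, `fixtures` subcommands |

## Worked example

Simulate 10 000 trees at λ=6, μ=3, σ=0.1, T=1 (so r=3, q=0.6, A=σe³≈2.009),
fit the pairwise and nearest-neighbour histograms jointly, and bound σ:

```python
from yuledist import (YuleParams, SimulationConfig, ensemble_histograms,
                      PAIRWISE, NMIN1, fit_densities, sigma_upper_bound,
                      implied_sigma)

params = YuleParams(lam=6.0, mu=3.0, sigma=0.1, T=1.0)
res = ensemble_histograms(SimulationConfig(params, n_trees=10_000, seed=1),
                          [PAIRWISE, NMIN1], bins=50)
fit = fit_densities([res.histograms[PAIRWISE], res.histograms[NMIN1]])
print(f"r = {fit.r:.3f} +/- {fit.se_r:.3f}")
print(f"q = {fit.q:.3f} +/- {fit.se_q:.3f}")
print(f"sigma <= {sigma_upper_bound(fit):.3f}")
print(f"sigma at mu/lambda=0.5: {implied_sigma(fit, 0.5):.3f}")
```

prints

```
r = 3.016 +/- 0.028
q = 0.590 +/- 0.006
sigma <= 0.196
sigma at mu/lambda=0.5: 0.098
```

The fitted growth rate recovers λ−μ = 3 within one standard error; the μ=0
bound σ ≤ q/r ≈ 0.2 contains the true σ = 0.1, and assuming the true
turnover μ/λ = 0.5 sharpens it to 0.098.  The nearest-neighbour density for
these parameters has an interior maximum (at t ≈ 0.46), which by the
σ < (1/3)(1−μ/λ) criterion already flags the tree as undersampled before
any fitting.

The same analysis from the shell:

```sh
yuledist simulate --lambda 6 --mu 3 --sigma 0.1 --height 1 \
    --trees 10000 --seed 1 --bins 50 --kinds pairwise,nmin1 --out sim
yuledist fit --in sim.pairwise.tsv --in sim.nmin1.tsv --out report.json
```

Empirical data enter the same way: `yuledist stats --format newick` pools
the distance statistics of a multi-tree file (e.g. 1000 posterior trees,
densities divided by the tree count) into the histogram TSVs that
`yuledist fit` consumes; `--time-scale` converts branch-length units
(e.g. 10⁸ yr) on I/O.

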