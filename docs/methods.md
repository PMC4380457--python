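# Methods

## Model

A rooted tree starts from a single lineage at time 0.  During [t, t+dt]
every living lineage splits into two with probability λ dt and dies with
probability μ dt, independently.  The process is stopped at the height T;
lineages alive at T are *extant leaves*, and each is *observed*
independently with probability σ ∈ [0, 1].  Random incomplete sampling and
a recent random mass extinction are equivalent under this model, so σ
covers both readings.  The pairwise distance between two observed leaves is
2(T − t_MRCA), the total evolutionary time separating them through their
most recent common ancestor; distances therefore live on [0, 2T].

Parameters, units and defaults:

| symbol | meaning | units | constraints |
| --- | --- | --- | --- |
| λ (`lam`) | birth (speciation) rate | 1/time | ≥ 0; > 0 for densities |
| μ (`mu`) | death (extinction) rate | 1/time | ≥ 0 (default 0) |
| σ (`sigma`) | leaf sampling fraction | — | [0, 1] (default 1) |
| T | tree height | time | ≥ 0 (default 1) |

All internal times are dimensionless; the CLI applies a single
`--time-scale` multiplier on input/output only (the bird-family data, for
instance, carry branch lengths in units of 10⁸ yr).

## Closed forms

With r = λ − μ, w = e^{rT} and φ = (e^{rT} − 1)/r, the observed leaf count
is zero-inflated geometric:

    1 − P(0|T) = σ w / (λσφ + 1),       β = λσφ / (λσφ + 1),
    P(M|T) = (1 − P(0|T)) (1 − β) β^{M−1},   M ≥ 1,

which reduces to the classical complete-sampling law at σ = 1 and yields
⟨M⟩ = σe^{rT}, ⟨pairs⟩ = σ²λ e^{rT}(e^{rT}−1)/r, the geometric tail
P(>k) = (1−P0)β^k, and the expected total and reconstructed (observed-leaf
subtree) branch lengths in closed form.

The density families, written in the identifiable combinations r, q = λσ,
A = σe^{rT}, with u = e^{−rt/2} and ψ = (1 − u)/r:

* pairwise: `N = (qA/2) e^{rt/2}` — the integral over [0, 2T] equals the
  expected pair count exactly, which pins the prefactor;
* n-th nearest neighbour:
  `N_n = [n(n+1)/2] A qⁿ ψ^{n−1} e^{−rt} / (qψ + u)^{n+2}`;
* cherry: `N_Λ = (qA/2) e^{−3rt/2} / (qψ + u)⁴`;
* min2 (see the correction below):
  `N_min2 = 2q²A e^{rt/2} φ(r, T−t/2) e^{−2rt} / (qψ + u)⁵ + N_Λ`,
  the only family carrying an explicit extra e^{rT} (so it is the one curve
  that distinguishes parameter sets sharing (r, q, A)).

Unimodality criteria: N₁, N_Λ and N_min2 have an interior maximum iff
σ < (1 − μ/λ)/3, /4, /5 respectively, at
t_max = (2/r) ln[(λ−μ−λσ)/(kλσ)] with k = 2 (nearest) or 3 (cherry); the
min2 maximum is located numerically because of its extra T dependence.

Small-bin occupancy: the number of pairs in [t, t+dt] is zero with
probability 1 − B(1−P(0|t/2))², where B = λe^{r(T−t/2)}dt/2 is the
probability of a branch point in the matching interval, and equals n > 0
with probability B Σ_{d|n} P(d|t/2) P(n/d|t/2) (divisor sum: the two
subtrees of that branch point hold d and n/d observed leaves).  The
conditional density Ñ = N / (1 − Pr₀) = (1 + qφ(r, t/2))²/dt is the right
fitting target for a *single* sparse tree, where most bins are empty and
the pooled mean badly misrepresents the typical nonzero bin.

### A correction to the min2 density

The recursion usually written for N_min2 over the first branching event
counts within-subtree pairs plus cross pairs in which one member's nearest
distance equals t and the other's exceeds t.  That source term omits the
splits with exactly one observed leaf on *both* sides — cherry pairs, whose
min2 value is their mutual distance.  The omitted source is identical to
the cherry recursion's, so the full density is the bare recursion solution
plus N_Λ.  Simulation confirms the correction: against the bare solution
the empirical min2 histogram sits systematically high (mean per-bin z ≈ +2
at 10⁴ trees across parameter sets); with the cherry term the mean z drops
to ≈ 0.  The σ < (1/5)(1−μ/λ) criterion is unaffected (checked numerically
over λ, T grids: the unimodality switch stays at 1/5 because the cherry
component is subdominant there).  `min2_density` returns the corrected
density; the tests validate the bare recursion component separately against
an independent quadrature of the recursion.

## Numerics

Every closed form is expressed through φ-type factors ((e^{rx}−1)/r and
(1−e^{−rt/2})/r) with series branches below |rx| < 10⁻⁵, so the critical
case λ → μ needs no special-casing by the caller; continuity across r = 0
is tested at r = 10⁻¹⁰ vs 10⁻⁶ (relative difference < 10⁻⁴).
`YuleParams.near_critical` flags |r|T < 10⁻⁸·max(1, λT).  Divisor sums use
trial division up to √n with n capped at 10⁶ (bins are tiny; counts are
small).  Densities are defined to be exactly zero outside [0, 2T]; the last
histogram bin is closed on the right.

## Simulator

Kinetic Monte Carlo: with M alive lineages the waiting time to the next
event is Exponential(mean 1/(M(λ+μ))); a uniformly chosen lineage splits
with probability λ/(λ+μ), else dies; the event whose waiting time
overshoots T is discarded and the state frozen at T; extant leaves are then
observed with probability σ.  The complete genealogy (including extinct
subtrees, which are excluded from all statistics) is retained.  One master
seed per run; per-tree substreams are derived by counter through
`numpy.random.SeedSequence`, so ensembles are reproducible and chunkable.
A lineage cap (default 10⁶ alive) aborts explosive parameter choices with a
typed error instead of thrashing.

Statistics are extracted from the genealogy in O(nodes), not O(pairs): a
split node whose child subtrees hold m₁ and m₂ observed leaves contributes
m₁m₂ pairs at distance 2(T − t_split); n-th nearest distances come from
walking each leaf's ancestor path and accumulating opposite-side subtree
counts; a cherry is a split with exactly one observed leaf per side; min2
histograms follow from the sorted nearest-distance list (the k-th smallest
value is the minimum for M−k pairs).  The hot loop is numba-compiled.
Ensembles accumulate per-bin count sums, sums of squares and nonzero-tree
counts, giving the pooled mean density (the estimator of N), its standard
error, and the nonzero-bin conditional mean (the estimator of Ñ), plus
per-bin occupancy tallies and the leaf-count spectrum.

What the generator emulates — and does not.  It produces exactly the model
the closed forms describe: constant rates, ultrametric time distances,
Bernoulli sampling.  Real data violate all three in places (rate shifts and
radiations, clock noise in distance estimates, phylogenetically biased
sampling), so passing simulation tests shows the implementation is
faithful to the model, not that the model fits any particular clade; for
empirical matrices the package deliberately accepts non-ultrametric input
with a warning and fits only inside a user-chosen window where the
constant-rate assumption is tenable.

## Fitting

The curves are fitted jointly in θ = log(r, q, A) (positivity for free) by
iteratively reweighted least squares with bisquare (Tukey) weights, tuning
constant 4.685, convergence when the maximal |Δθ| < 10⁻⁸, at most 100
sweeps, each sweep solving a weighted nonlinear least-squares problem
(`scipy.optimize.least_squares`).  Residuals are standardized per point
before robust weighting: bin densities span orders of magnitude, so the
noise scale is taken from the ensemble per-bin standard error when present
and from a Poisson-count scale sqrt(model/(width·trees)) refreshed each
sweep otherwise.  Standard errors are heteroscedasticity-robust (sandwich)
delta-method values; coverage of the 3 s.e. interval was checked on
Poisson-resampled curves (20/20) and on simulated ensembles.  Initial
values: r and qA from a log-linear regression on the pairwise histogram; q
from the nearest-neighbour peak location via q = r/(1 + 2e^{r t_peak/2}),
falling back to q = r/2 when the curve is monotone (the peak-height
relation is not invertible in closed form).  Zero-count bins are included
for pooled ensembles and dropped in `conditional` mode, which fits Ñ
(independent of A) to a single tree's nonzero bins.  Non-convergence is
flagged on the `FitResult`, never raised; the CLI maps it to exit code 4.
`min2` can be evaluated as a fitted curve (its T comes from the histogram
support) but is excluded from default fitting.

Sampling-fraction output: σ ≤ q/r (capped at 1; tight at μ = 0),
σ(μ/λ) = (q/r)(1 − μ/λ) for an assumed turnover ratio, and maximum-based
bound claims (σ < 1/3, 1/4, 1/5) emitted when the *fitted* curve of the
matching kind has an interior maximum, each carrying the caveat that the
bound assumes μ ≥ 0.

## Test problem sizes and statistical checks

Simulation-vs-theory tests run 10⁴ trees per configuration
(T=1, λ=6, μ∈{0,3}, σ∈{1,0.1}; plus λ=5, σ=0.1 for min2) with 40 bins, and
10⁵ trees for the sparse conditional regime (λ=11, μ=5, σ=0.01, bin width
0.005) and for the tiny-bin occupancy check (t=1.5, dt=10⁻⁵) — sizes chosen
so each check resolves its effect at the 3 s.e. level while the whole suite
stays desk-scale.  Per-bin comparisons use z-scores at |z| ≤ 3 with two
refinements that keep the test calibrated rather than lenient: (i) across
hundreds of bins ~0.3% are expected beyond 3 s.e. by chance, so up to 1% of
bins may exceed 3 (none may exceed 6); (ii) sparse bins fill in clusters
(one tree contributes several equal-rank values), so the error scale is
max(empirical s.e., quasi-Poisson s.e. with the per-bin estimated cluster
size) — the empirical variance from a handful of contributing trees can
undershoot severalfold.  Histograms are compared against *bin-averaged*
curves (midpoint evaluation of a steep exponential biases by more than a
standard error in well-populated bins).

## Known limitations

* Constant rates only; no time-varying or lineage-specific λ, μ, and no
  conditioning on survival or on a fixed leaf count.
* (λ, μ, σ, T) are not individually identifiable from distances — by
  design the fitter reports only (r, q, A) and σ bounds.
* The occupancy formulas are first order in dt; `prob_pair_count_in_bin`
  warns when N(t)dt > 0.1, where they degrade.
* Cherry tie-breaking on rounded empirical matrices is deterministic
  (ascending distance, then lexicographic labels) but any such rule is a
  convention; exact ties are measure-zero under the model itself.
* Cophenetic distances from non-ultrametric trees are accepted as path
  lengths with a warning; no clock correction is attempted.
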