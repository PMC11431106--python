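# Methods

## The two-neuron manifold

The model is the family of joint laws of two binary neurons observed in
a single time bin, `q_mn = P(x1=m, x2=n)` with `Σ q_mn = 1`. The package
works in the mixed coordinates `ξ = (eta1, eta2, theta)`, where
`eta_i` is neuron *i*'s marginal firing probability per bin and `theta`
is the log odds ratio `log(q11·q00/(q10·q01))`. The log-probability is
log-linear in `(x1, x2, x1·x2)`, `theta` is the interaction coefficient,
and the marginal block is Fisher-orthogonal to `theta`. The model is
time-independent (exchangeable across bins): no refractoriness, no
rate drift, no history dependence. These are deliberate restrictions —
they make the distance between two pattern-generating distributions an
exact, controllable quantity.

Coordinate inversion (`law_of`) solves the odds-ratio quadratic
`(A−1)q11² − [(A−1)(eta1+eta2)+1]q11 + A·eta1·eta2 = 0`, `A = e^theta`,
for the unique root inside the Fréchet interval
`[max(0, eta1+eta2−1), min(eta1, eta2)]`; uniqueness follows from the
strict monotonicity of `theta` in `q11` at fixed marginals. The root is
taken with the numerically stable quadratic formula and a 200-step
bisection fallback. Laws with any outcome probability below 1e-12 are
rejected for manifold operations (`theta` and the metric are undefined
there); sampling still accepts them.

## Fisher information and distances

Scores `L_i(x) = ∂ log p(x;ξ)/∂ξ_i` are computed by central finite
differences through `law_of` with step 1e-6 — chosen so that the
truncation error (O(step²)) and the cancellation error (O(eps/step))
are both far below the 1e-6 orthogonality tolerance — and the metric is
the exact expectation of score products over the four outcomes. The
independent-case closed form `g(eta_i, eta_i) = 1/(eta_i(1−eta_i))`
validates the scheme. Coordinates within 1e-4 of the feasibility
boundary are rejected as ill-conditioned (the scores diverge there).
`squared_distance` is the quadratic form `dξᵀ G dξ`; it matches twice
the Kullback–Leibler divergence to first order (verified at relative
accuracy 1% for steps of size 1e-3).

## Pattern generation

Each pattern is `Nbins` i.i.d. categorical draws over the four joint
outcomes, giving a 2×Nbins binary matrix; active bins become spike
times at bin centers `(j+0.5)·tau/Nbins` in a `tau = 16` ms window
(left-edge placement is available; centers keep trains symmetric under
time reversal of the pattern). Defaults `Nbins = 1000` and
`Ntrials = 10` pattern pairs per condition are the study's evaluation
protocol: large enough that standard errors of the index means are a
few thousandths, small enough that a full sweep runs in tens of seconds.

Two sweep constructions produce control/comparison distribution pairs:

* **Correlation sweep** (`build_dtheta_sweep`): marginals fixed with
  `eta2 = 1 − eta1` (total firing rate conserved; requires
  `eta1 ≤ 0.5`), control at `theta = 0`, comparisons generated by
  moving probability `dq11` from the single-neuron outcomes onto both
  coincident outcomes, which leaves the marginals exactly unchanged.
  The default grid is 21 values of `q11` evenly spaced in
  `[0.01, eta1 − 0.01]`; the 0.01 edge keeps the law 10⁻² away from the
  degenerate corners, spanning near-maximal anti-correlation
  (`q11 = q00 = 0.01`) to near-maximal correlation (`q10 = q01 = 0.01`).
* **Rate sweep** (`build_deta_sweep`): independent neurons
  (`theta = 0`, so `q11 = eta1·eta2`), control `eta2 = 0.1`,
  comparisons at `eta2 = 0.1 + d_eta2` with 17 increments evenly spaced
  in `[0, 0.8]` by default.

One master seed per sweep spawns per-(grid point, trial) child seeds
through `numpy.random.SeedSequence`, so any single trial is reproducible
in isolation. The control pattern is re-sampled every trial, so both
members of a pair carry sampling noise — this is what the error bars
measure.

What the generator does *not* emulate: multiple spikes per bin, jitter
within a bin, refractoriness, bursting, rate nonstationarity, and
ensembles larger than two neurons. Conclusions drawn from these
simulations therefore speak to index sensitivity under idealized
equilibrium firing, not to every failure mode real recordings offer.

## The indices

Pearson correlation, cosine similarity and scaling factor operate on the
vectorized (neuron-by-neuron concatenated) binary pattern; the Hamming
distance is the mean absolute bin-wise difference with inactive rows
retained. Degenerate inputs (zero variance or zero norm) yield an
explicit invalid flag; sweep aggregation excludes such trials, reports
the valid count, and never imputes.

**SPIKE similarity** follows the bivariate dissimilarity profile `D(t)`
built from instantaneous inter-spike intervals and corner-spike
distances. Edge convention: auxiliary spikes at `t = 0` and `t = tau`
on both trains, so the preceding/following spikes always exist and a
pair of empty trains has similarity exactly 1. The time integral uses
the midpoint rule on a uniform grid of `16·Nbins` points; midpoints
never coincide with bin-center spike times, where `D` is non-smooth,
and the rule agrees with a 10⁶-point reference quadrature to better
than 1e-3.

**Estimated mutual information** segments each pattern into `N = 50`
equal periods and uses a nearest-neighbor estimator on the N×N tables
of segment distances — per-neuron 1-Wasserstein distances between the
spike-time empirical measures (unit mass per train), summed over
neurons. Conventions: two empty segments are at distance 0; an empty
segment against a non-empty one is at the maximal displacement, the
period length. The joint neighborhood of segment *i* is itself plus its
`h − 1 = 2` nearest other segments under lexicographic
(distance, index) order; the count `C_i` is the overlap of the two
patterns' neighborhoods. Including the segment itself keeps `C ≥ 1`
(the estimate never diverges), makes the estimator exactly symmetric,
and gives identical patterns exactly `log(N/h)`. The price is a bias
floor: statistically independent patterns score near `log(N/h²)`
(≈ 1.71 nats at the defaults) rather than 0. The defaults `N = 50`,
`h = 3` balance segment occupancy (~10 spikes per segment at the
default rates) against table resolution; the identical-pattern identity
holds for every `(N, h)` and is exercised across configurations in the
tests.

**Transfer entropy** is the plug-in conditional mutual information on
the binned representation, in bits: each bin contributes the joint
binary state of the ensemble as a symbol, histories are `k = 1` bins by
default, and the estimate is
`H(target_t | target history) − H(target_t | target + source history)`.
It is non-negative by construction and directional.

**Relative redundancy reduction** is
`(R(T1) − R(T2)) / MI(T1, T2)`, with redundancy
`R(T) = min_i MI(T∖T_i, T_i)`. The expensive per-neuron distance tables
are computed once per pattern and shared by MI, redundancy and the
ratio.

## Characterization of the redundancy-reduction sweep

Across the default correlation sweep the redundancy-reduction mean is
flat at ≈ 0 over the interior of the grid but dips at the extreme ends
(to ≈ −0.2 at the anti-correlated end and ≈ −0.36 at the correlated
end; grand mean ≈ −0.06). The dip is a genuine property of the
estimator on these conditions: a near-maximally correlated comparison
pattern has nearly identical per-neuron trains, so its within-pattern
redundancy approaches the `log(N/h)` ceiling, while the control's stays
at the independence floor — and the denominator, the MI between the two
independently sampled patterns, sits at its own floor `log(N/h²)`. The
effect survives every estimator configuration examined
(`N ∈ {20, 50, 100}`, `h ∈ {3, 5, 7}`); only the degenerate `h = 1`
(constant estimator) removes it.

## Trend summaries and what "flat" means

`summarize_trends` reduces a sweep to one Spearman rank correlation per
index (means vs increment) with a two-sided permutation p-value
(5000 permutations, seeded). For *monotone* claims the rank correlation
is the right instrument. For *flatness* claims it is oversensitive: on
21 noisy means some index will show a small-p trend in a sizable
fraction of runs, with sign and identity changing from seed to seed. The
test suite therefore calls an index flat when its trend is insignificant
(α = 0.01 for the five simultaneously examined indices) *or* its
grid-point means are statistically homogeneous given their trial SEMs
(weighted χ² about the pooled mean at the 0.99 quantile of χ²(n−1));
the rate sweep, where indices genuinely respond, fails that homogeneity
check by two to four orders of magnitude.

## Known limitations

* Two neurons only; the coordinate algebra is specific to the 2×2
  outcome table, and the metric grows exponentially with neuron count.
* Finite (non-infinitesimal) geodesic distances are not integrated;
  `squared_distance` is the local quadratic form.
* The information-theoretic estimators are biased (floors discussed
  above); they are reported raw, with the bias characterized by
  surrogate comparisons in the tests rather than subtracted.
* Transfer entropy uses a discrete-time embedding on bins; no
  continuous-time estimator is provided.
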