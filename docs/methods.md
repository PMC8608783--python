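# Methods

## The model

`ergmotif` tests whether small subgraphs — the feed-forward loop (the
transitive triad 030T), the bi-fan, the bi-parallel — are
over-represented in biological networks, using an exponential random
graph model (ERGM) as the null rather than degree-preserving
randomization.  An ERGM on a fixed node set assigns

    Pr(X = x) ∝ exp( Σ_A θ_A z_A(x) )

where each configuration statistic z_A counts (or geometrically
down-weights) a pattern: ties, reciprocated arcs, sinks and sources,
alternating k-stars, alternating k-two-paths, alternating k-triangles,
self-loops, and attribute effects (sender, receiver, interaction,
categorical matching, with NA matching nothing).  A configuration is
counted wherever its ties occur — it is *not* an induced subgraph —
whereas the triad census and the four-node motif counters use the
induced convention.  Both semantics are implemented side by side
because they answer different questions: a positive alternating
k-triangle parameter says two-paths tend to close, conditional on every
other effect in the model; a motif count compared against the fitted
model's simulated ensemble says whether the exact induced pattern is
more frequent than the model explains.

The alternating statistics use the geometrically weighted closed forms

* k-stars       z = λ² Σ_i [(1−1/λ)^{d_i} − 1 + d_i/λ]
* k-two-paths   z = λ Σ_{pairs} [1 − (1−1/λ)^{tp}]
* k-triangles   z = λ Σ_{ties}  [1 − (1−1/λ)^{sp}]

each provably equal to the corresponding alternating sum over explicit
k-star / k-two-path / k-triangle counts; the test suite enforces that
identity against brute-force enumeration (exhaustively for all
undirected graphs up to six nodes and all digraphs up to four, plus 200
random graphs up to twelve nodes, at 1e−9).  The decay defaults to
λ = 2, the common modelling practice, and is per-effect because
published regulatory-network models override it selectively (e.g.
out-stars at λ = 4.5 with the two-path/triangle pair at λ = 3).  The
directed two-path and triangle variants use ordered pairs with the
transitive convention (intermediaries k with i→k→j for the pair or arc
i→j); the cyclic variant uses return paths j→k→i.  Self-loops are held
out of every structural statistic and counted only by the dedicated
Loop effect.  The normalizing constant is never computed; everything
downstream is Markov chain Monte Carlo.

## Sampling

The Metropolis sampler supports two symmetric proposals: a uniform dyad
toggle (self-loop dyads included exactly when the model permits loops),
and a fixed-density swap that deletes one uniformly chosen present tie
and adds one uniformly chosen absent dyad, conserving the tie count at
every step.  The swap targets the ERGM conditional on the observed tie
count — the purpose the "improved fixed density" samplers of this
method family serve — but does so by exact conditioning, which needs no
auxiliary density parameter and has a one-line correctness argument.
Whether exact conditioning and the approximate auxiliary-parameter
scheme give materially different estimates on real data has not been
checked here.  Proposals that would create a reciprocated arc under the
no-reciprocity constraint are rejected outright, so regulatory-network
models can condition on the observed absence of mutual arcs.  Default
burn-in is ten sweeps (10 × dyad count) and the default sampling
interval one sweep; chains are exactly reproducible from their seed.
Correctness is audited two ways: the incrementally maintained statistic
vector must equal a full recount after any run, and on three nodes the
empirical visit distribution of a long chain must match the exactly
enumerated 64-graph distribution (chi-square).

## Estimation

The maximum-likelihood estimate solves the moment equation
E_θ[z(X)] = z(x_obs).  Estimation proceeds in four phases, all from the
observed network:

1. **Robbins–Monro phases** with gain halving, using
   covariance-whitened (Fisher-scored) updates
   θ ← θ − a Σ̂⁻¹ (z_t − z_obs).  Whitening matters when density and
   closure statistics are strongly correlated — a diagonal scaling
   stalls along the soft direction of that ridge.
2. A **fine-gain servo phase**: frequent small updates pin the chain's
   statistics at the observed values; the time-average of θ over the
   pinned stretch estimates the moment-equation solution, in the
   spirit of equilibrium-expectation estimation.
3. **Newton polish and measurement**: ensembles at the estimate give
   the simulated covariance Σ (the Fisher information of an exponential
   family), damped score corrections θ ← θ − 0.8 Σ⁻¹ (z̄ − z_obs) when
   the residual is still outside tolerance, standard errors
   SE = √diag(Σ⁻¹), and the convergence t-ratios
   t_A = (mean simulated z_A − observed z_A)/sd simulated z_A.  A fit
   is converged when every |t_A| ≤ 0.3.  Because componentwise
   t-ratios do not constrain the soft direction of strongly correlated
   statistics (a residual can satisfy every |t_A| ≤ 0.3 yet sit
   several standard errors away along the density–closure ridge), the
   polish loop also drives the whitened (Mahalanobis) residual below a
   tolerance of 1.0 before accepting.  Full-path averages of z
   (accumulated every proposal) reduce the Monte-Carlo noise of the
   residual at no extra sampling cost.
4. **Pooling** of R independent runs: the pooled estimate is the mean
   over converged runs, and the pooled variance combines mean
   within-run variance with between-run variance, W̄ + (1 + 1/R)B.
   95% intervals are θ̂ ± 1.96 SE, and an effect is significant when
   its interval excludes zero — the reporting convention of the model
   tables this package produces.

Models combining density with positive closure can be
*near-degenerate*: the fitted distribution has a second, dense and
clustered mode, and an unconstrained chain occasionally tips into it.
Three safeguards address this.  During estimation, per-update steps are
clipped and a chain whose tie count runs far beyond the observed one is
reset to the observed network.  During measurement, a two-phase
ensemble (detected by excursions far outside the robust scatter) is
first re-measured conditionally on the observed network's metastable
region.  If free dynamics still cannot be measured, the run falls back
to density-conditioned estimation: structural parameters are estimated
under the fixed-density swap sampler — where triangle terms cannot run
away because the tie count is pinned — and the density parameter is
recovered by a one-dimensional moment match confined to the data's
basin, with standard errors from the joint simulated covariance.  This
mirrors how the density-conditioned samplers used for such models in
practice behave, and runs flagged this way carry a `basin_conditional`
marker.  Fits that remain outside the t-ratio band are reported as
unconverged rather than discarded silently.

Initialization sets the density effect to logit(observed density) and
everything else to zero.  Empty and complete networks are rejected (no
interior MLE).  With an explicit `fixed_density` constraint the density
effect is held at logit(density) and flagged as not moment-matched,
since its statistic is constant under the swap sampler.

## Goodness of fit, Mahalanobis ranking

Fit is judged by simulating (by default) 100 networks from the
estimated model, starting at the observed network, and overlaying the
observed summary statistics on the simulated distributions:
reciprocity, giant (weakly) connected component, global and mean local
clustering (directed networks are clustered on their underlying
undirected graph), in-/out-/total-degree histograms, directed geodesic
distances with an explicit unreachable bin, edge-wise and dyad-wise
shared partners (transitive convention, matching the model statistics),
and the full triad census.  Histograms conserve their population masses
by construction, which the tests assert.

The λ grid search fits one model per grid point — two tied dimensions
over {1.5, 2.0, …, 5.0} give the canonical 64 candidates — and ranks
them by the Mahalanobis distance between the observed summary vector
and the simulated ensemble, under the ensemble sample covariance with a
pseudo-inverse for singular cases.  Degree distributions enter that
vector as the standard deviation and skewness of the in- and out-degree
sequences (their means being pinned by density), alongside reciprocity,
giant-component size, and the two clustering coefficients; the exact
vectorization of "degree distributions" is a design choice an
implementer may revisit.  Each grid point is re-estimated in full; ties
in distance keep grid order; failed estimations are recorded and
excluded from the ranking.

## Motif testing

The triad census classifies all C(n,3) triples into the 16
mutual/asymmetric/null classes with U/D/T/C orientation suffixes,
enumerating only triples that touch a tie and counting the all-null
class by subtraction.  Bi-fan (two sources sharing two targets) and
bi-parallel (two directed two-paths sharing endpoints) counts use the
induced convention with candidate generation from common
out-neighbourhoods; both are tested against full 4-subset enumeration
with explicit isomorphism checks, and the census against an independent
graph library.  Significance against the fitted model's ensemble is
reported as z = (observed − mean)/sd (undefined when the ensemble is
constant) and the add-one upper-tail estimator
p = (1 + #{sim ≥ obs})/(N + 1), which never returns an exact zero.

## Synthetic data

No stable public accession exists for the original study networks, so
the package generates its own study conditions.  The regulatory-like
regime is a sparse digraph (density a few per thousand) with positive
transitive closure and no reciprocated arcs; the interaction-like
regime is undirected with positive closure and a categorical node class
carrying homophily; attributes are drawn i.i.d. with a configurable NA
fraction, emulating incomplete functional annotation.  Model-based
fixtures are single long-run Metropolis samples (50 sweeps by default).
For models combining density with positive closure the sparse phase is
only metastable — it leaks slowly toward a dense clustered phase, so
there is no sparse equilibrium to burn in to; the default burn-in is a
convention sitting inside the window where the sparse draws are
stable, which is the regime the sparse biological networks being
emulated occupy.  Planted bi-fans are placed on
isolated node tuples, so each placement adds exactly one induced
bi-fan and cannot disturb an existing one.  What these fixtures do not
emulate: degree-distribution tails of real interactomes, spatial or
modular structure, and annotation biases — so passing recovery tests
demonstrates estimator correctness under the model, not fidelity of
any real network's fit.

## Scale of the validation experiments

The recovery experiments run at n = 100 (directed, Arc = −4,
alternating transitive triangles = 1) and n = 200 (undirected,
Edge = −4.5, alternating triangles = 1), with 20 data replicates and
2–3 pooled estimation runs per replicate — a deliberate reduction of
the published workflow's 423–2617-node networks and 20–64 parallel
runs, sized so the full suite completes on one core in tens of
minutes.  At these sizes the undirected values place the model in a
moderately dense, strongly clustered regime (density ≈ 0.12) rather
than the sparse regime the same parameters produce at thousands of
nodes; the estimator handles both, which the tests exercise.

## Known limitations

* Near-criticality: for a small fraction of data draws from the
  directed fixture, the fitted closure parameter lands in the unstable
  region; such fits are reported unconverged or carry conditional
  standard errors that understate unconditional uncertainty.  This is
  the familiar degeneracy boundary of triangle-bearing ERGMs, not an
  implementation artifact.
* λ is fixed per fit; estimating it as a curved-ERGM parameter is out
  of scope (the grid search is the provided alternative).
* Exact maximum likelihood (path sampling), Bayesian estimation, and
  missing-data/snowball conditional estimation are out of scope.
* The Rubin-style pooling rule is a documented choice; the published
  workflow does not print its combination rule.
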