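# Methods

## The temporal fitness null model

A temporal contact data set is a multiset of undirected events
`(time, i, j)`.  Fixing a resolution Δ partitions the observation span into
τ = ⌊T/Δ⌋ half-open intervals `(t − Δ, t]`; pair (i, j) is *present* in an
interval if it interacted there at least once, and its aggregate count
m_ij ∈ [0, τ] is the number of intervals containing it.  The null model
assigns each node a constant latent activity a_i ∈ (0, 1] and assumes that
in every interval each pair interacts independently with probability
u = a_i·a_j — a sequence of independent fitness-model draws.  Under this
null, m_ij ~ Binomial(τ, a_i a_j).  The model deliberately contains no
pre-existing network structure, no group labels and no time variation in
overall activity; a tie that survives the test is therefore significant
*relative to node activity alone*, which is what makes the backbone
irreducible rather than a restatement of strengths or degrees.

Data with daily observation sessions (sensor deployments switch off
overnight) would otherwise contribute long empty stretches that the null
would try to explain.  Intervals falling outside sessions are excluded from
τ entirely.  When no session list is supplied, epoch-like timestamps
(≥ 10⁸) default to one session per calendar day from the first to the last
event of the day; small or abstract timestamps default to a single session
over the span.  Session boundaries for irregular schedules are a property
of the data collection, not of the method, so the session list is an
explicit input.  A trailing partial interval is dropped (τ = ⌊span/Δ⌋ per
session); an event at exactly a session start joins the first interval.
Directed records are symmetrized on read; self-interactions are rejected.

## Activity estimation

The log-likelihood of the observed counts (ordered-pair form, so every
unordered pair appears twice — a constant factor that does not move the
optimum) is

    L(a) = Σ_{i≠j} [ m_ij log(a_i a_j) + (τ − m_ij) log(1 − a_i a_j) ] + const,

and the stationarity conditions are the N score equations
H_i(a) = Σ_{j≠i} (m_ij − τ a_i a_j)/(1 − a_i a_j) = 0.  The sum runs over
*all* pairs, including never-interacting ones: silence is also evidence.

The solver is a damped projected Newton iteration on H(a) = 0 with the
analytic Jacobian (∂H_i/∂a_k = a_i (m_ik − τ)/(1 − a_i a_k)², k ≠ i),
started from the configuration-model point
a_i = Σ_j (m_ij/τ) / sqrt(2 Σ_{i<j} m_ij/τ) and kept inside the box
[ε, 1] by clipping with a backtracking line search on the KKT residual.
Components that reach the a = 1 boundary with an outward-pointing score
(H_i > 0, e.g. both endpoints of a pair present in every interval) are
boundary optima: they are frozen out of the Newton system and the remaining
components re-solve their reduced system; such projections are reported in
the result.  Convergence is declared when the largest KKT residual falls
below `tol`.

Defaults and rationale: `tol = 1e-8` on max|H_i| (counts are integers, so
residuals far below 1 carry no extra information; 1e-8 comfortably supports
the exact-recovery property on saturated systems), `max_iter = 500` (typical
runs converge in < 10 iterations; non-convergence is flagged, never raised),
`ε = 1e-12` (open lower boundary of (0, 1]).  Nodes with zero interactions
are excluded from the solve — their likelihood is maximized at the boundary
and they can never host a significant tie — and are assigned a = ε with a
warning.  Two interacting nodes are rejected: a single score equation only
identifies the product a₁a₂.

## Significance of ties and triads

For each pair with m_ij ≥ 1 the observed count is compared with its null
Binomial(τ, a*_i a*_j).  Two tail quantities are stored per tie: the
reported P-value P(X > m_obs) (exclusive tail) and the decision tail
P(X ≥ m_obs).  The default decision rule ("percentile") flags a tie when
its count strictly exceeds the (1 − α)-percentile of the null, i.e.
P(X ≥ m_obs) ≤ α_eff.  On a discrete lattice this is the rule that
guarantees a per-tie false-positive probability ≤ α; thresholding the
exclusive P-value strictly (the "pvalue" rule, also available) flags one
extra lattice point per tail and can exceed the nominal level when τ is
small — the difference between the two rules is exactly the pmf at the
observed count.  Never-interacting pairs are not tested: their absence of
events carries no evidence of a tie, and testing them would flag
low-activity pairs for merely existing.  Bonferroni correction divides α by
the number of tested pairs.  Backbones are nested in α by construction, and
the stored tails allow re-thresholding at any level without re-testing.
The backbone remains a temporal object: the events (or snapshots) of its
ties can be re-emitted as a filtered temporal network.

Simultaneous triads use the same machinery one order up: the per-interval
probability that (i, j, k) forms a full triangle is v = u_ij·u_jk·u_ik, so
the number r_ijk of intervals containing all three edges is
Binomial(τ, v).  Candidates are the triangles of the aggregate network; a
triad with r_obs = 0 is never significant regardless of tails (nothing
simultaneous was ever observed — the aggregate triangle may be an artifact
of asynchronous dyads).  Each triad result records how many of its three
dyads pass the uncorrected tie test at the same α; the two orders genuinely
decouple — three individually unremarkable pairs that always co-occur can
form a wildly significant triad, and three strong but asynchronous pairs
form none.  Triad tests default to no multiple-testing correction
(Bonferroni over the triangle count is exposed as a flag).

## Baselines

The disparity filter tests each aggregate edge against a node-local null in
which an endpoint's strength splits uniformly among its edges:
p = (1 − w/s)^(k−1), with p = 1 for degree-one endpoints.  An edge is kept
when it is significant from at least one endpoint (min of the two
P-values); the stricter both-endpoint convention is a flag, since the
published uses differ.  DP-R applies the filter to each Δ-window weighted
snapshot and keeps pairs significant in at least one window; its only
notion of a significant triad is trivially a window in which all three
edges coexist and are individually significant.  A plain weight-threshold
backbone is included as the crudest comparator.  Enhanced
configuration-model filters are not implemented; the comparison API accepts
any external `pair → p-value` mapping so they can be plugged in.

## Synthetic benchmark

The null generator draws activities from Beta(2, 5) and produces τ
independent snapshots with per-pair presence probability a'_i a'_j.  The
benchmark selects 20% of the pairs with at least one null interaction,
uniformly at random, and gives each an extra independent Bernoulli(0.3)
interaction per interval OR-ed with the null events; the selected pairs are
the ground-truth strong set.  Defaults N = 300, T = 300, Δ = 10 (τ = 30),
strong fraction 0.2 define the validation study.  Beta(2, 5) (right-skewed,
mean 2/7) and boost 0.3 are this package's documented choices: they produce
heterogeneous activities with most pairs interacting at least once, and
strong-pair weights that overlap the null weight range so detection is
non-trivial.  Randomness flows from one master seed through four named
substreams (activities, null events, strong selection, boosts), so layers
can be varied independently and runs are bit-reproducible.

What the generator emulates — and what it does not: data drawn exactly from
the null plus planted signal validates calibration and detection, but real
contact data have circadian/schedule structure, node turnover and
time-varying global activity that the constant-activity null ignores.
Passing these tests shows the estimator and test behave as designed under
the model's own assumptions, not that real backbones are "correct".  On
this benchmark the ST filter at α = 10⁻³ flags ≈ 0.10 of interacting pairs
(below the planted 0.2, with false-positive rate ≲ 10⁻⁴): the missed strong
pairs join highly active nodes whose boosted counts the null still
explains.  Detection varies by a few percent across α ∈ [10⁻⁶, 10⁻³]; how
flat this curve is depends on the activity distribution and boost, so the
suite asserts the robust comparative property (the ST backbone stays large
at levels where the disparity filter retains essentially nothing) rather
than an absolute flatness figure.

## Evaluation metrics

Backbones are compared as edge sets (Jaccard; two empty backbones count as
identical) and as weighted vectors (cosine over the *union* of supports
with zero-fill for absent pairs — the intersection-only reading would
return 1 whenever overlapping weights agree, making the measure blind to
support differences).  Community content is scored by the intra-group edge
fraction, by the AUC of the intra-group-edge prediction task with pairs
ranked by P-value (computed from the continuous ranking rather than a
discrete α sweep; the curve is identical and grid-free, and ties contribute
0.5 by the trapezoidal convention), and by Newman weighted modularity Q of
the partition on the aggregate network (delegated to networkx).  Partitions
are consumed as input; no community detection is performed.

## Numerical notes and limitations

Binomial tails are computed through the regularized incomplete beta
(scipy's survival function), exact to well over 10 significant digits for
τ ≤ 10⁵.  Products a_i a_j are capped at 1 − 10⁻¹² inside the score to keep
denominators finite.  Pair and triple identities are canonically ordered,
so (i, j) and (j, i) are one tie everywhere.  The model assumes constant
activities: time-varying global activity, node insertion/deletion and
within-tie event-level significance are out of scope.  Significance is
assigned to whole ties (all interactions of a pair), not to individual
events.
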