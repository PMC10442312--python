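# Methods

## The identification task

An epidemic starts at a single source node at day 0. The observing agency
is idle until the first hospitalization, at which point it learns that
node's identity and symptom onset (hospital cases are diagnosed without
spending a test). From then on it interacts with the population only
through household queries, contact queries, and budgeted test queries with
one-day latency, while the epidemic continues. A run is *successful* if the
algorithm's final candidate is the true source; a companion metric asks for
the first symptomatic patient instead, since an asymptomatic source is
invisible to onset-based inference.

## Epidemic model

Discrete days; all stage durations deterministic. A node infected on day
`t` is exposed on days `t … t+T_E−1` and infectious from `t+T_E`. With
probability `p_a` the course is asymptomatic: infectious for `T_I` days,
then recovered. Otherwise the node is presymptomatic (and infectious) for
`T_P` days, symptomatic from its onset `t+T_E+T_P`, and then either
hospitalized at `onset+T_H` (probability `p_h`) or recovered at
`onset+(T_I−T_P)`. Every infectious node attacks each susceptible neighbor
independently with probability `p_i` per day; same-day infections land
simultaneously, and the infector is drawn uniformly among that day's
successful attackers. Hospitalized and recovered nodes do not infect.
Transitions happen at day boundaries; a test reflects the node's state on
its submission day.

Defaults (`p_i=0.1, p_a=0.4, p_h=0.083, T_E=3, T_P=2, T_I=14, T_H=7`)
follow the fitted values of the agent-based simulator the synthetic model
emulates: integer-rounded mean stage durations, a population-averaged
hospitalization probability, and `p_i` scaled so that `d_c·p_i = 0.3`
external infections per infectious agent per day at `d_c = 3`.

For the tree analysis we use the no-presymptomatic / no-recovery variant
(`T_P = 0`, `T_I = ∞`). Removing the presymptomatic stage does not affect
what the algorithms can learn by the time of the first hospitalization
(every transmission-path node is past it, since `T_P < T_E + T_H`), and
removing recovery only perturbs the early-phase dynamics that matter here.

## Network models

**Household Network Model (HNM).** `N` nodes in households of exactly
`d_h+1` (cliques); each node carries `d_c` external half-edges, paired
uniformly at random; pairings that would create self-loops or duplicate
edges are discarded, so external degrees can fall slightly below `d_c`.
`N` must be divisible by `d_h+1` with `N·d_c` even — we reject other sizes
rather than allow ragged households, so sweeps nominally at `N=400` and
`N=1000` run at the nearest feasible sizes 402 and 1002 (same 1%-budget).

**Red–Blue tree.** The local approximation of the HNM around the source:
a two-type deterministic branching tree whose red nodes are each
household's earliest-reachable member. The root (red) has `d_c` red and
`d_h` blue children; other red nodes have `d_c−1` red and `d_h` blue
children; blue nodes have `d_c` red children. Level populations satisfy
`r_{l+1} = (d_c−1) r_l + d_c b_l`, `b_{l+1} = d_h r_l` and admit a spectral
closed form with `D = sqrt((d_c−1)^2 + 4 d_c d_h)`. The tree object is
lazily materialized, standing in for the infinite graph.

On a tree each node has a unique potential infector, so the no-recovery
epidemic factorizes into independent per-edge geometric delays
(`parent + T_E + (G−1)`, `G ~ Geom(p_i)`, truncated at the parent's
hospitalization). We exploit this in two ways: the first hospitalized node
is found by best-first exploration in infection order (exact, no horizon
stepping of an exponentially growing cluster), and post-detection queries
are answered lazily from per-node cached randomness keyed by node id, so
answers are consistent regardless of query order.

## Algorithms

**LS.** Maintain the candidate with the earliest revealed onset; each
iteration queues the candidate's household members and backward contacts
(on static networks, all neighbors; the day windows
`[t−(T_E+T_P)−σ, t−(T_E+T_P)+σ]` are computed and logged for interface
parity with temporal data), submits tests under the daily budget, and only
ends when the queue has drained. Terminate when an iteration reveals no
earlier onset. On trees this walks the transmission path exactly, so LS
succeeds if and only if every path node is symptomatic — a property the
test suite checks with zero tolerated counterexamples.

**LS+.** As LS, plus: any positive-without-onset result enqueues that
node's household, and if the node shares the incumbent candidate's
household, also its backward contacts (with the wider window
`[t−(T_P+2T_E+T_I), t−(T_P+2T_E)]` appropriate for an unknown onset). This
hops over an asymptomatic path link whenever some member of its household
is a symptomatic path node; LS+ therefore provably succeeds when every path
household holds a symptomatic path node and the source is symptomatic (it
may also succeed otherwise; only the sufficient direction is asserted).

**v2 variants** cut an iteration at the first candidate improvement and
discard the rest of the queue — cheaper, without the drain guarantee.

**Size-Gain baseline.** Full network knowledge; candidates are filtered by
the deterministic-delay constraint
`|(t_2−t_1) − (d_2−d_1)| < σ(d_1+d_2)`, dropping the absolute value against
negative (lower-bound) and positive-without-onset (upper-bound)
observations. Since the constraint assumes one time unit per hop,
observation times are converted to per-hop units via the mean hop delay
`μ = T_E + (1−p_i)/p_i` days; `σ` defaults to the geometric delay spread
`sqrt(1−p_i)/p_i` days, in the same units. Sensors are placed to minimize
the expected post-observation candidate-set size over a uniform prior of
(source, infection-day) hypotheses; the scanned sensor pool, hypothesis
sample, and day-grid coarsening are config knobs (defaults 30 / 40 / 2)
that keep the scan tractable at a few hundred nodes — the brute-force
equivalence is tested uncapped on a toy graph. Past the deadline
(conventionally the later of LS's and LS+'s finishing days on the same
epidemic) the estimate is a uniform draw from the surviving set; an
emptied set is recorded as an SG failure.

## Theory

With `p = p_a / (p_a + (1−p_a)(1−p_h))` (asymptomatic given not
hospitalized) and `P(d(s,h)=n)` the law of the transmission-path length to
the first hospitalized node,

- LS succeeds with probability `Σ_n (1−p)^n P(d(s,h)=n)` — exact on the
  tree model, and testably consistent with simulation when evaluated on the
  empirical path-length histogram;
- LS+ admits a lower bound obtained by classifying length-`n` paths by how
  they embed in households: `k` lone path nodes, `j = (n+1−k)/2` households
  contributing a red head and a blue child, indicators `α, β` for the
  source/endpoint sharing a household with another path node. Each type
  contributes
  `C(k+j−2, k−2+α+β) · d_h^j (1−p)^{k+j−1} (d_c(1+p))^{j−α−β} · d_c (d_c−1)^{k+α+β−2}`
  divided by the level population at `n`. At `p = 0` the weighted counts
  sum to the level population exactly, which the tests assert — the
  normalization identity that anchors the count.

The path-length law itself is approximated in two steps. First the network
and epidemic collapse into a `(d_r, d)`-ary random exponential tree: time
rescaled to units of `T_E` (`p_i ← 1−(1−p_i)^{T_E}`), root capacity
`d_r = d_c + d_h`, and `d` the RB-tree mean degree under the stationary
red/blue composition of the branching process (`d ≈ 4.646` at the
defaults). "`d`-ary" means `d` child slots per non-root node — the
convention under which the expected level counts
`a_{t,l} = d_r p_i (d p_i)^{l−1} Σ_m C(m, l−1)(1−p_i)^{m−l+1}` and size
`a_t = 1 + d_r((1−p_i+d p_i)^t − 1)/(d−1)` are mutually consistent; both
identities are verified against a 10^5-replicate vectorized simulator.
Second, hospitalization is grafted on through the stopped deterministic
tree: nodes arrive with a prescribed level profile, in uniform within-day
order, each hospitalized with probability `(1−p_a)p_h`, growth stopping at
the first hospitalization; the resulting level law has a closed form, into
which the expected RET profile is substituted (the implementation carries
the substitution out exactly; the two evaluation routes agree to 1e−9).

**Known limit of the approximation.** Substituting the *expected* profile
into the stopping law is a mean-field step: the true stopped-tree law is
the expectation of the stopping functional over random profiles, and the
difference (a Jensen gap) amounts to a total-variation distance of about
0.024 at the default parameters — comparable to, and detectably larger
than, the sampling noise of 10^4 Monte-Carlo runs (bootstrap 99th
percentile ≈ 0.015). The corresponding agreement test in the suite states
the strict criterion and is expected to fail by roughly this margin; the
surrounding identities (profile means within 3 SE, substitution
equivalence, normalization) all hold. Predictions consumed downstream
(LS/LS+ success) inherit an error of a few percentage points, which stays
within the Wilson bands of 1000-run simulations.

All series use double precision with explicit tail cutoffs at
`n_max = 20`, `t_max = 200`; truncated tail weights are below 1e−300 by
construction and every distribution reports its truncation deficit.

## Experiment protocol and sizes

Each run draws a fresh network, a uniform source, and simulates until the
first hospitalization (runs without one inside the horizon, 100 days by
default, are discarded and redrawn; discards are counted). All algorithms
for a run share the same epidemic through separate sealed oracles, so
comparisons are at matched realizations. Success rates carry 95% Wilson
intervals; query counts carry Student-t intervals. The suite sizes its
statistical checks at 400–10^4 runs per property and the acceptance script
uses 500 conditioned runs for the headline accuracy figure; sweep defaults
(4800 realizations/point) reproduce full-scale tables when invoked
explicitly. Seeds derive from a single base seed via `SeedSequence`, and
rerunning any experiment with the same configuration is byte-identical.

## What the generator does and does not emulate

The synthetic testbed reproduces: household clique structure with uniform
external mixing, deterministic stage durations, asymptomatic and
hospitalized courses, budgeted next-day testing. It does not emulate:
variable household sizes, degree heterogeneity, time-varying contacts or
site-mediated transmission, age-dependent hospitalization, reporting noise
or non-compliance (non-complying agents can be treated as asymptomatic
without breaking the algorithms' correctness, but no separate mechanism is
modelled). Passing tests therefore demonstrate correctness of the
algorithms and calculus on this model class, not performance on empirical
contact data.
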