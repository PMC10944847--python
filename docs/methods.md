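# Methods

## Model

A group of `n` agents collectively estimates an unknown true state of
nature. Agent `i` holds an opinion `x_i` and observes a fixed-size
information pool `G(i)` of `k` distinct other agents on a directed graph;
an edge `j -> i` means information flows from source `j` to recipient `i`.
In-degree is exactly `k` for every agent at all times; out-degrees are
unconstrained. Initial opinions are i.i.d. draws from the model's
distribution, and initial wiring is uniform at random and independent of
opinions, so the group starts with full opinion diversity and no
"excessively influential" agents (out-degrees are approximately
Binomial(n−1, k/(n−1)), as in an Erdős–Rényi digraph).

Each round draws a fresh uniform permutation of agents. Agents act
sequentially in that order — each sees all updates made earlier in the same
round — and each acting agent independently draws one of two
discrepancy-reducing actions, where discrepancy is
`sum_{j in G(i)} |x_i − x_j|`:

- **Naïve learning** (probability `1 − β`): adopt
  `argmin_c sum_{j in G(i)} |c − x_j|`, i.e. the median of the source
  opinions. For binary opinions and odd `k` this is the source majority;
  for even `k` the midpoint of the two central order statistics is used
  (any value between them is a minimizer; the midpoint is the
  deterministic, symmetric choice).
- **Selective exposure** (probability `β`): find the source `j*`
  maximizing `|x_i − x_j|` (ties uniform at random). If that maximum is
  zero, do nothing. Otherwise let the candidate set be every agent that is
  not `i`, not currently a source, and *strictly* closer in opinion than
  `j*`; if it is empty the edge is retained, else `j*` is replaced by a
  uniformly drawn candidate. Opinions never change under this action, and
  no fallback to learning occurs when the candidate set is empty.

Sequential (asynchronous) updating is used rather than synchronous
updating: it matches a literal "agents act in a random order" schedule and
avoids the 2-cycles that synchronous median dynamics can enter. Because
each action strictly decreases the acting agent's discrepancy whenever it
is not a no-op, and binary/median updates take values in the current
opinion support, runs terminate quickly in practice.

**Steady state.** A state is steady when every action drawable with
nonzero probability is a no-op for every agent: for `β < 1` every opinion
already equals its source median, and for `β > 0` every rewiring attempt
is a no-op. The rewiring no-op condition is independent of how the
most-discrepant tie is broken, because the distance threshold `|x_i −
x_{j*}|` is the same for every maximizer, so termination does not depend
on tie-breaking. The driver detects steadiness by running the cheap
change flag first and confirming with the full fixed-point test, which
consumes no randomness. Runs are capped at `max_rounds` (default 1,000;
typical runs converge in 5–40 rounds); a capped run is returned with
`converged = False` and counted, never dropped.

## Opinion models

| name | opinions | initial law | aggregation | true state | σ | σ_x̄ (collective SE) |
|---|---|---|---|---|---|---|
| condorcet | binary {1, 0} | Bernoulli(p = .55), n = 101 | majority | True | √(p(1−p)) | — (categorical) |
| galton | continuous | N(0, 1), n = 100 | mean | 0 | 1 | 1/√100 = 0.1 |
| bimodal | continuous | ½N(−2, 1) + ½N(+2, 1), n = 100 | mean | 0 | √5 | √0.05 ≈ 0.2236 |
| exponential | continuous | Exp(λ = 1), n = 101 | median | ln 2 ≈ 0.6931 | 1 | 0.1 (median asymptotics) |

The bimodal dispersion follows the law of total variance
(σ² = Σ q(μ_j − μ)² + Σ q σ_j² = 4 + 1 = 5), held exactly in the model
spec's derived fields. The exponential model aggregates by the median (robust for
the skewed law), so its collective standard error comes from sample-median
asymptotics, var = 1/(8 f(μ̃)² m) with n = 2m + 1 and f(μ̃) = λ/2 — 0.01
at n = 101 — *not* from σ/√n. Jury and median models default to odd `n`
so neither majority nor median needs a tie rule.

**Good decisions.** A continuous decision (individual or collective) is
good iff it falls strictly within two collective standard errors of the
true state, `|v − μ| < 2 σ_x̄`; a binary decision is good iff True. The
band is deliberately the *collective* standard error in both cases: it
standardizes quality across models and group sizes, and makes the
no-influence baseline exactly P(|Z| < 2) = 2Φ(2) − 1 ≈ 0.9545 for every
continuous model, against ≈ 0.8438 (the exact binomial tail) for the jury.
The same 2σ_x̄ band is applied to individual decisions, which makes initial
individual performance small by construction (e.g. 2Φ(0.2) − 1 ≈ 0.159 for
the standard-normal crowd) and leaves room for learning to improve it.

## Measures

Per run, at steady state (and optionally at each round boundary):

- individual performance `p_i`: fraction of agents whose current opinion is
  good (for the jury: fraction voting True);
- collective decision and its good flag; collective performance `P_G` is
  the fraction of good collective decisions across runs;
- opinion diversity `σ_x`: *population* standard deviation of opinions
  (the dispersion of the whole group, not a sample estimate);
- giant-SCC fraction `|C1|`: share of agents in the largest strongly
  connected component (scipy's strong connected-components routine);
- modularity `Q` over the two-level opinion dichotomy (True/False, or
  above/below the true state with ties going below), in two variants.

**Modularity variants.** The default, reported as `modularity_newman`, is
standard directed modularity `sum_d [L_d/m − (k_d_in · k_d_out)/m²]`,
bounded in [−1, 1]. A second variant, `modularity_squared`, computes
`sum_d [L_d/m − (k_d_in · k_d_out/(2m))²]`, a nonstandard form that squares the degree-product null term while
keeping the undirected 2m normalization; it is unbounded below (a single
category on m = 10 edges already yields −24) and cannot be the quantity a
[0, 0.5]-scaled axis shows, but it is kept so results stay comparable
with fragmentation analyses that define Q this way. Both are computed on
every record.

**A note on |C1| at β = 0.** The network never changes under pure naïve
learning, so β = 0 structural measures describe the initial random graph.
At n = 101, k = 5 a given agent is chosen as a source by nobody with
probability (1 − k/(n−1))^(n−1) ≈ 0.006, so a graph typically contains
0–2 such zero-out-degree agents, which sit just outside the giant SCC.
The *mean* giant-SCC fraction is therefore ≈ 1 − 0.6/101 ≈ 0.994 even
though only ≈ 54% of graphs are strongly connected outright; the mean
fraction is the quantity reported (and the one a "size of the giant
component" axis shows). Consensus itself is essentially never blocked:
zero-out-degree agents still learn, they just influence nobody.

## Null models

`null_models` provides the closed-form no-influence baselines the
simulations are judged against: the exact binomial jury tail P(Y > n/2)
(no normal approximation; trivial at n ≤ 401), the CLT normal
N(true_state, σ²/n) for mean aggregation, and the asymptotic normal of the
sample median for the exponential model. The asymptotic median law is
accepted as-is at n = 101; its finite-sample bias is O(1/n) (≈ +0.005
for 101 unit exponentials) and the Monte-Carlo consistency test carries an
explicit 1/n allowance for it.

## Experiments, seeding, and scale

`run_sweep` executes a β grid × replicate factorial; the full study grid
is 51 evenly spaced β values on [0, 1]. Replicate seeds are
`SeedSequence(root_seed, spawn_key=(beta_index, replicate))`, so any cell
can be reproduced (or parallelized) in isolation, and identical configs
give byte-identical result tables. Aggregate rows (mean p_i, P_G, mean
σ_x, mean |C1|, mean Q, rounds, non-convergence counts) are pure functions
of the replicate rows and are recomputable from them at any time.
`run_trajectory` records measures at every round boundary for the first
`trajectory_rounds` rounds (runs still continue to steady state; rounds
past steadiness repeat the steady values), capturing the transient phase
in which most change happens.

Default replication scale is 2,000 runs per condition — the desk scale at
which the binomial standard error of a performance fraction is ≈ 0.5–1
percentage point, sharp enough to separate all the effects of interest;
full-scale runs (e.g. 30,000 per β) are the same configuration with a
larger `reps_per_beta`. The acceptance script runs five quantities at this
scale in ≈ 2 minutes on one CPU.

## What the generator does and does not emulate

Initial opinions are exactly i.i.d. and initial wiring is exactly uniform:
the study conditions deliberately exclude correlated priors, stubborn or
high-centrality agents, weighted ties, and exogenous information sources.
Passing tests therefore demonstrate the mechanism — that rewiring confines
influence within subgroups while median learning propagates it — under
idealized independence, not that real social networks behave this way.
Real groups start with correlated opinions and heavy-tailed influence,
both of which the model excludes by design (the `scale_free` initializer
provides a heavy-tailed out-degree variant for robustness checks only).

## Numerical choices

- Binary opinions are encoded 1.0/0.0 so one median-based learning rule
  serves all models; in the binary case "most discrepant source" reduces
  to a uniformly random disagreeing source and the candidate set to all
  agreeing non-sources.
- Strict inequalities exactly as defined: the good-decision band is open,
  and a rewiring candidate must be *strictly* closer than the removed
  source (so zero-discrepancy pools and uniformly-distant alternatives are
  genuine fixed points).
- Opinion equality tests are exact float comparisons; this is sound
  because learning copies values verbatim (a median of an odd pool is one
  of its members), so steady-state detection never hinges on tolerances.
- Degenerate inputs fail loudly: even-length majority, empty vectors,
  unlabeled agents, k outside [1, n−1], β outside [0, 1].
- Dichotomy ties (continuous opinion exactly at the true state, a
  probability-zero event) are labeled "below".

## Known limitations

- Sequential updating is one concrete reading of "agents act in random
  order"; synchronous updating would need cycle detection and can
  stabilize genuine disagreement inside strongly connected groups, and
  quantitative β = 0 results (e.g. mean p_i ≈ 0.73–0.76 at 2,000
  replicates) can shift by a few thousandths under other schedules. In
  particular, under sequential updating every β = 0 run in practice ends
  in consensus, so mean p_i and P_G coincide run-for-run; schedules that
  leave occasional stable disagreement open a small gap between the two.
- The steady state of a mixed-β run is path-dependent (the dynamics are
  stochastic); only β = 0 and β = 1 have distribution-level
  characterizations (consensus per closed group; k-nearest-opinion
  wiring).
- The exponential model's null is asymptotic; at n = 101 its sample-median
  bias (~0.005) is visible at high replication counts.
- `scale_free` and `regular` initializers are robustness options with
  documented constructions, not calibrated models of any particular
  empirical network.
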