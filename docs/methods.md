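# Methods

## The statistic and its conventions

Lostness scores one navigation segment from its count triple (R, S, N):

```
L = (N/S − 1)² + (R/N − 1)²
```

with S = total node entries, N = distinct entries, R = minimum entries
needed.  The value lies in [0, 2); it is 0 exactly when R = S = N (exhaustively
verified over all triples with 1 ≤ R ≤ N ≤ S ≤ 50, whose supremum is
≈ 1.474, attained at R = 1, N = 7, S = 50).

**Entry counting.**  One convention is used for all three counters, since
only their ratios are meaningful: a counter ticks on node *entries*,
excluding the node a segment starts on (a move to an adjacent node = 1;
re-entering the starting node later does count).  `move` events always
count; `pickup` counts when it changes the current node; `inspect`
(turning an item in hand) never counts.  A configuration switch
(`count_kinds`) can restrict counting to location nodes only; by default
interactable and object nodes count like locations, since they are
ordinary graph nodes the player travels to.

**Task windows (global measure).**  S and N are accumulated from
`task_start` to `task_complete`; events inside overlapping windows are
counted in *every* open window.  That double-counting is a known property
of the task-scoped measure and is preserved deliberately, not corrected:
it is precisely one of the reasons the objective-scoped measure is
preferable, and "fixing" it would change what the measure is.  Incomplete
tasks contribute nothing (strict mode raises instead).  Events after the
final task completion (free exploration) are outside every window.

**Task-level R.**  `min_task_route` computes the minimum *total* entry
count of any route from the task's start node through all target nodes —
exact search over visiting orders up to 8 targets (deterministic
lexicographic tie-break), nearest-neighbour with a warning beyond.  For
*scoring* a window, however, R is the number of *distinct* entries on
that optimal route (`route_entry_counts`).  The two differ whenever the
optimal route must backtrack out of dead-end item nodes: the total count
then exceeds what any real walker can exhibit as unique entries, which
would push the detour ratio R/N above 1 and break the formula's range.
The distinct count cannot exceed a completing walker's N in ordinary
worlds (the walker's own path is a candidate route), and the two
readings coincide on backtrack-free routes.  A manually supplied R (the
analyst's "perfect playthrough" value) always wins; if it undercuts an
elementary lower bound it is accepted with a warning, and if it exceeds
the walker's N the affected window is flagged as unscorable rather than
scored or raised.

**Objective segments (local measure).**  The session is partitioned at
successive `objective_complete` events in actual completion order,
starting from the game start node.  R for a segment is the BFS
shortest-path length from the previous completion node to the node where
this objective completed; S and N reset with each segment.  The summed
triple feeds the formula once.  Degenerate segments (two completions at
one node with no movement between) contribute zeros to the sums and are
*flagged*, never individually scored — otherwise "no navigation" would
read as "perfect navigation".  For any movement-reached segment
R ≤ N ≤ S holds by construction.

**Numeric contract.**  Results carry full double precision; reported
tables round to 3 decimals.

## The simulator

The generator emulates the kind of study this package is built to
support: a cohort of players navigates a node-based discovery game,
then sits a knowledge test and experience questionnaires, and the
analyst asks whether in-game disorientation predicted learning.

**Worlds.**  A connected random tree over `n_locations` rooms plus
~0.35·n shortcut edges (so real detours exist), with door-like
interactable nodes and object item nodes attached as leaves.  Each task
starts at a door whose keyword is the task's first objective — task
starting points are themselves searched-for content — and its remaining
objectives target item nodes elsewhere.  All objective targets are
distinct nodes.  Defaults: 12 locations, 4 tasks, 3 objectives per task.

**Agents.**  Play is modelled with three independent per-player axes,
all zero for a perfect navigator:

* `wander_prob` (ε) — per step, probability of a uniformly random
  neighbour instead of the next shortest-path hop (drawn U(0, 0.6) per
  player; the upper end produces heavily disoriented but still finishing
  play).
* `order_noise` — per task, probability of attacking the objectives in a
  random order rather than the minimum route's order (U(0, 1)).
* `explore_rate` — mean Poisson count of free-roam steps taken before
  heading to each task (U(0, 10)).

ε alone spans perfect navigation to pure random walk, and mean local
lostness is strictly increasing in it; a zero-wander agent scores
L_L = 0 exactly, because every inter-completion leg it walks is a direct
shortest path.  The other two axes exist because the two measures
decouple in real play through exactly these mechanisms: a bad objective
order inflates the task window against its fixed minimum route while the
objective segments' R adapts to the order actually taken, and
between-task exploration falls outside every task window, loading only
the local measure.  With ε alone the two measures are near-deterministic
functions of one parameter (r ≈ 0.95); with the calibrated ranges their
correlation sits near 0.84 and the global measure runs above the local
one, matching the qualitative structure reported for human cohorts this
generator emulates.  The ranges were fixed by that design calibration
and are configuration, not claims about any particular population.

**Cohorts and planted effects.**  Experience scales are truncated
normals on [1, 5] (presence 3.179 ± 0.450, engagement 2.976 ± 0.563,
cognitive interest 3.667 ± 0.693 — the emulated study's combined-sample
descriptives).  A latent knowledge propensity is built from the
*measured* lostness values and drawn covariates:

```
ability = β_local·z(L_L) + β_presence·z(presence) + β_interest·z(interest)
          [+ β_global·z(L_G) + β_engagement·z(engagement)] + σ_e·η
```

with σ_e chosen so the propensity has unit variance.  The planted betas
(defaults −0.667, −0.399, +0.346; the optional two default to 0) are
therefore the *true standardized coefficients* a correctly specified
regression should recover.  With near-independent covariates this fixes
the latent multiple correlation at √(Σβ²) ≈ 0.85; the
`target_multiple_r` setting (default 0.752, the emulated study's
observed value) is a feasibility bound on the planted structure, not an
enforced output — the study's lower observed R arose from its particular
predictor correlation structure, which the generator does not plant, and
no unit-variance construction can hold both the coefficient set and an
arbitrary smaller R simultaneously.  A configuration whose implied R²
exceeds 1 is rejected before any simulation; small-sample fluctuation of
the explained variance past 1 within a drawn cohort is clamped, not
fatal.

**Knowledge scoring.**  The instrument is 24 true/false items (half
keyed true, 8 spatial, randomized positions).  Responses follow a
two-parameter normal-ogive item model: P(correct) = Φ(a₀ + 0.8·q_j +
1.0·ability), with q_j equispaced normal quantiles as item difficulties
and a₀ solved so the population expected proportion correct is 0.576.
The proportion-correct score is therefore an *attenuated* measurement of
the latent propensity (attenuation ≈ 0.94 at these settings), as any
finite test score is; fitted betas on the observed score sit slightly
inside the planted values, which the recovery tolerances account for.
The latent propensity is exported (`knowledge_latent`) so the noiseless
limit can be checked exactly.

**Randomness.**  Everything flows from a single `numpy` Generator seeded
explicitly; cohorts, logs, and worlds are bit-for-bit reproducible under
a fixed seed, and no global random state is touched.

## Validation statistics

Descriptives use the n−1 denominator.  Correlations are Pearson with
two-sided p-values, pairwise-complete; zero-variance variables flag
their pairs as undefined rather than erroring.  The regression is
ordinary least squares on z-scored criterion and predictors, all
predictors entered simultaneously; it reports standardized betas,
two-sided p-values, VIF per predictor, multiple R, and the overall
F-test, with listwise deletion and an explicit singularity error naming
exactly-collinear columns.  Shapiro–Wilk is advisory (the pipeline
proceeds regardless, as regression is robust to the violation at these
scales).  The measure comparison is a paired t with df = n − 1; a
zero-variance difference vector is flagged degenerate rather than
producing a silent NaN.  The outlier screen excludes values strictly
above mean + 2·SD — one-sided, because only an extremely *high* local
lostness marks a participant who never meaningfully engaged; a symmetric
variant exists but is off by default.  No multiple-testing correction is
applied by default; a Holm option covers the correlation family.

## Problem sizes

The Monte-Carlo checks the suite runs were sized to be decisive yet
routine on a laptop: sign recovery uses 500 cohorts of 24 players
(the emulated study's combined sample size), magnitude recovery 50
cohorts of 200, null calibration 1000 cohorts of 24, the BFS oracle
1000 random graphs of ≤ 8 nodes, and the summed-measure identity 10,000
random segment lists.  All replicate loops share one world, as a real
study shares one game.

## Limitations

* The agent is a memoryless ε-greedy walker with a precomputed
  itinerary; it does not learn the map, forget it, or interleave tasks,
  so cohort-level findings here demonstrate the *pipeline's* statistical
  behaviour, not human navigation.  Passing recovery tests show the
  machinery is unbiased at study scale under the planted model; they say
  nothing about whether real lostness causes real learning differences.
* Observed-score descriptives (e.g. the knowledge SD) are wider than a
  real cohort's, a consequence of prioritizing exact planted-coefficient
  semantics over matching every marginal moment.
* Task windows require explicit `task_start` events; loggers that infer
  task activation from a first interaction must emit the event at that
  moment.
* Conditionally traversable links (locked doors that open mid-session)
  are not modelled; the graph is static.  One-way passages are.
* Whether the original hypertext formulation counted a segment's
  starting node is not settled in the literature; the entries-excluding-
  start convention used here is one consistent choice, applied to all
  three counters so the ratios remain comparable.
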