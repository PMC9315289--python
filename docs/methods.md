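# Methods

## Model

### Network

A **logic network** is a directed graph whose nodes are discrete
factors and whose edges are signed influences.

- Each node has `n_levels` ordinal levels `0 .. n_levels - 1`
  (default 3: low / nominal / high). The *nominal* level is
  `n_levels // 2`.
- Nodes are **dynamic** (updated by the rule below) or **input**
  (demographic context: clamped for a whole trajectory, copied
  unchanged by the update). Input nodes cannot receive edges.
- Each edge is an **activation** or an **inhibition** and carries two
  fitted parameters: a perception threshold `θ ∈ {1, ..., L_src - 1}`
  (the source must be at level ≥ θ to be perceived at all) and a
  weight `w ∈ {1, 2}` (ordinary vs. strong influence).
- Some dynamic nodes are flagged **targetable**: clinically actionable
  levers available to the intervention search. One dynamic node is the
  designated **adherence node**; a state is *adherent* when that node
  sits at its maximum level.

The packaged circuit (`adherelogic/data/adherence_network.tsv`) has 18
ternary nodes — 4 inputs (age, education, household income, tumor
stage) and 14 dynamic factors — 43 edges, 8 targetable nodes, and
`adherence` as the outcome node.

### Update rule

All dynamic nodes update synchronously. For node *i* in state *s*:

1. Sum the weights of perceived activators,
   `A = Σ { w_e : e activates i, s[src(e)] ≥ θ_e }`, and likewise `B`
   over perceived inhibitors.
2. If `A > B`, the node moves **one level up** (capped at its maximum);
   if `B > A`, one level down (floored at 0); if `A = B` — including
   the case of no perceived input at all — the node **holds** its
   level.

Changes are deliberately limited to one level per step: psychological
states drift rather than jump. The tie/silence rule is *hold*, so an
unsupported node keeps its current level indefinitely; there is no
built-in decay (add an explicit self-inhibition edge to model decay).
An asynchronous single-random-node variant (`step_asynchronous`) is
provided for exploration but is not part of the main pipeline.

### Attractors

An **attractor** is a state cycle closed under the synchronous update
(period 1 = stable end-state). Its **basin frequency** — the fraction
of initial states that settle into it — measures behavioral inertia.
Two estimators are provided:

- `enumerate_attractors_exact`: follows every state of the full state
  space (refused above 3^10 states) and returns exact basin fractions.
- `sample_attractors`: seeded random restarts, by default **1,000
  initial states × at most 50 steps** each; initial levels are drawn
  uniformly for every node, inputs included. Runs that have not
  reached a previously visited state within the budget are counted in
  `unconverged_fraction`.

Cycle attractors are reported with their period and canonicalized by
rotation; an attractor is adherent only if the adherence node is at
maximum in *every* state of the cycle.

## Fitting

Observed data are **trajectories**: per participant, ≥ 3 assessments
at strictly increasing timepoints, each a vector of node levels with
possible missing entries plus an adherent/non-adherent flag.

With a one-step horizon (`K = 1`, the default), consecutive assessment
pairs give independent per-node constraints: for each dynamic node
observed at the later assessment, the parameters of its in-edges must
make the update rule map the earlier (imputed) state onto the observed
later level. Missing dynamic levels in the *earlier* state are imputed
at nominal; missing *later* levels are simply not scored. Because the
update of a node depends only on its own in-edges, the global search
decomposes exactly into independent per-node constraint-satisfaction
problems (`fit_node_csp`), each solved by vectorized exhaustive
enumeration of its (θ, w) assignments.

`fit_network` composes per-node solutions into network-wide candidate
models, best-first by the number of mismatched constraints, subject to
a **coverage** threshold: the fraction of scored node-transitions the
model reproduces exactly must be at least `coverage_min` (default
**0.75**, tolerating noisy observations; set 1.0 for strict fitting).
The enumeration is capped at `max_models` (default 200) and reports
`exact_space_size`, the exact number of zero-mismatch models, plus
`best_coverage` achievable when no model meets the threshold. For
`K > 1` the decomposition no longer holds and a capped joint search is
used instead.

Model-data discrepancy is the **alignment error**: the Manhattan
distance between predicted and observed levels, summed over scored
observations, with exact per-node and per-observation decompositions
(each sums to the total) to localize badly-modeled factors or
participants.

## Interventions

An intervention clamps 1–2 targetable nodes at an extreme level (`up`
= maximum, `down` = 0), holds the clamp for `hold_steps` synchronous
steps (default **5**), releases it, and lets the network settle (at
most `max_steps = 50` further steps). It succeeds if the settled
end-state is adherent; a *sustained* mode instead keeps the clamp on
permanently. A **minimal intervention set (MIS)** is a successful clamp
combination none of whose strict subsets succeeds; `find_mis` finds all
of them exhaustively up to `max_size` (default **2**, one or two
actionable levers per strategy).

Rankings and aggregation:

- **promptness** — steps from clamp onset until adherence first
  reaches maximum;
- **robustness** — fraction of replicates (default 100) that still
  succeed when every dynamic node is perturbed ±1 level with
  probability `noise_prob` (default 0.05) per step;
- **consensus** — the MIS search is repeated for every candidate model
  and every persistent non-adherent state; strategies are tabulated
  with rescued-state counts per demographic stratum (one column per
  input-node level), model support fractions, and a *unanimous* flag
  (supported by every model that has non-adherent end-states).

## Synthetic data

`simulate_cohort` emulates the observational design: by default **82
participants**, each with a uniformly drawn number of assessments in
**3–7**, one synchronous step between consecutive assessments, random
initial states, and clamped per-participant demographic inputs.
Optional observation noise flips recorded levels ±1 (reflected at the
scale ends) with rate `noise_rate`, and `missing_rate` masks entries at
random; the adherent flag is always consistent with the *recorded*
adherence level. `make_characteristic_set` instead produces 8 idealized
reference courses — four adherence-course shapes (early, mid-course,
and late persistent discontinuation, plus transient discontinuation
with recovery) under all-low and all-high demographic profiles.

What the generator does **not** emulate: real interview content,
instrument scores and their measurement model, informative missingness
or dropout, between-assessment gaps longer than one update step, and
any empirical distribution of factor levels — initial states are
uniform. Raw continuous scores can be brought in separately via
`discretize_scores`, which maps a score to the index of the first
cutpoint it falls strictly below (with `tertile_cutpoints` as a
helper).

## Numerical choices and determinism

- All state handling is vectorized with numpy; exact enumeration
  builds the full successor table in one batch and labels basins by
  path-following, refusing state spaces above 3^10.
- The per-node CSP expands the (θ, w) assignment grid as numpy arrays
  and evaluates all observed constraints against all assignments at
  once; network composition uses best-first depth-first search with a
  suffix-min bound on remaining mismatches.
- Every stochastic stage takes an explicit seed or Generator. The
  pipeline derives one sub-seed per stage from the master seed via
  `numpy.random.SeedSequence` spawning (all derived seeds < 2^31), so a
  fixed configuration and seed reproduce every result table
  byte-identically; the manifest records sha256 digests of all outputs
  (wall-clock timings are the only non-reproducible fields).

## Limitations

- Ternary levels and one-level-per-step updates coarsen real
  psychological dynamics; the synchronous scheme is a modeling
  convenience, and the asynchronous variant can reach different
  attractors.
- The `K = 1` decomposition assumes exactly one update step between
  consecutive assessments; unevenly spaced assessments violate this.
- With sparse data the candidate-model space can be astronomically
  large (`exact_space_size` reports it); the returned sample of at most
  `max_models` models is best-first by mismatch count but otherwise
  arbitrary among ties.
- The hold-on-silence rule means effects never decay unless decay is
  modeled explicitly, which makes released clamps "stick" in circuits
  without self-inhibition.
- The packaged 18-node circuit is a plausible transcription of the
  qualitative structure described for this application domain, intended
  as a realistic default and test fixture, not as a clinically
  validated instrument.
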