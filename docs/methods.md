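# Methods

## The model

`coageing` simulates the demography of *co-ageing*: two cohorts whose ageing
trajectories couple because their members damage each other.  Each
individual of species A (and its antagonist of species B) is a directed
*interdependency network*: nodes are functional components, and a directed
edge from j to i means i depends on j (j is a *dependee* of i).  Node states
are binary — functional or dysfunctional.

### Network growth

Networks are grown one node at a time from a two-node mutually dependent
seed.  Each new node attaches **inwards** to one uniformly chosen existing
node (gaining a dependee) and, independently, **outwards** to another
(gaining a dependent), so every node is connected to the seed in both
directions and no disconnected sub-network can form.  The two picks may
coincide (a 2-cycle); self-edges and parallel edges are impossible because a
new node contributes exactly one fresh edge in each direction.  The seed
structure and the coincidence rule are the package's choices — uniform
("constructively neutral") growth is the only topology model implemented.

A cohort either shares one topology (`topology_mode="shared"`) or regrows an
independent topology per individual (`"randomized"`, same N).  At N = 100 a
single shared topology's idiosyncrasies visibly shift the lifespan
distribution (the antagonist's mean lifespan can vary several-fold between
draws); topology-randomized cohorts average this out, which is why the
reference configuration defaults to `randomized`.

### Dynamics: two rounds per time step

Per discrete time step, species A is updated, then species B.

1. **Round one (intrinsic damage).**  Every functional node is marked
   dysfunctional with probability `d`.  The damage *propagates*: any
   functional node with **strictly more than half** of its dependees
   currently dysfunctional (whenever they failed) fails too, iterated by
   synchronous sweeps to a fixed point.
2. **Repair.**  Every dysfunctional node reverts with probability `r`
   (cause tag cleared; repaired nodes are immediately re-markable).  Repair
   never un-propagates dependants — there are no resurrection cascades.
3. **Round two (co-ageing damage).**  Functional nodes are marked with
   probability `alpha = C * f_opp / N_opp`, the antagonist's functional
   fraction scaled by the co-ageing constant `C` of the *receiving*
   species.  `alpha` is clipped to 1 with a logged warning (the model's
   usual parameter ranges never reach this).  Propagation and repair follow
   as above.

B's update within the step uses A's state *after* A's update.  A network
dies when its functional fraction first drops strictly below `phi_T`
(default 0.10; 0.15 in the chess regime, where small networks retain
self-sufficient residual cliques that blur death at lower thresholds).
Dead networks are frozen and contribute `alpha = 0` from the moment death
is registered — including to the partner's update later in the same step.

### Cause bookkeeping

Every dysfunctional node carries a cause tag.  Directly marked nodes take
the round that marked them: round one = intrinsic, round two = co-ageing.
Propagated nodes inherit the **majority cause among their dysfunctional
dependees**; an exact half-and-half split resolves to intrinsic (a
documented tie-break — the case is not constrained by the model's
definition, and intrinsic is the conservative choice).  At network death the
cause of death is intrinsic if `ns > nc`, co-ageing if `nc > ns`, intrinsic
on a tie.  Because `propagate` never consults the round it runs in, the
operation takes no round argument.

### Demography

Time is discrete.  `S(t)` counts individuals at risk at step t; censored
individuals (simulation survivors at `max_steps`, chess winners) stay in
`S` forever and never enter a death numerator.  Hazards follow the
competing-risks definitions

    mu(t) = [S(t) - S(t+1)] / S(t),      mu_i(t) = d_i(t) / S(t),

with `mu = mu_s + mu_c` exact (the implementation *sums* the cause-specific
quotients so the identity also holds in floating point).  Steps with
`S(t) = 0` report NaN, never zero.  The interval mortality
`1 - (S(tf)/S(ti))^(1/dt)` is provided for interval-census data and reduces
(exactly, by a special case) to the discrete hazard at `dt = 1`.

Parameter-trend comparisons use the **restricted mean survival time**
E[min(T, horizon)] rather than the mean of uncensored death times: the
latter is biased downward when long-lived regimes censor heavily, the
former is monotone under stochastic ordering.

### Bump detection

The co-ageing signature is a *bump*: the hazard rises while the antagonist
cohort is alive, falls as it perishes, then resumes its intrinsic late-life
rise.  `detect_bump` smooths the hazard (centered moving average, odd
window, truncated ends, NaN-tolerant), collapses plateaus, reports interior
extrema, and pairs each local maximum with the next local minimum.  On
Monte-Carlo estimates a (max, min) pair counts as significant only when the
drop exceeds `min_drop`; the package's convention — fixed before any
acceptance measurement — is 3 binomial standard errors of the smoothed
hazard at the peak, evaluated only where `S(t) >= 100`.  At cohort 2000 the
reference world's bump clears this filter comfortably; at cohort <~1000 it
does not, which is a statement about estimator noise, not the model.

### Randomness

All randomness flows from one master seed through counter-based Philox
streams keyed by (master seed, species slot, step, purpose).  Consequences:

* results are independent of any iteration order;
* a species' draws do not depend on whether an antagonist exists, so a
  paired run with `C = 0` is **bitwise identical** to a solo run — the
  strongest possible form of the decoupling reduction;
* sweeps and fits can reuse one seed across parameter values (common random
  numbers), making the fitting loss deterministic given the seed.

Dead individuals are compacted out of the working arrays; with randomized
topologies the block-diagonal dependee matrix is rebuilt only after ≥25% of
materialized rows have died (dead rows are masked meanwhile), trading a
little memory for a large tail speed-up.  Compaction depends only on a
species' own death history, so it preserves the decoupling property.

## Reference parameterization

The exact parameter values behind the co-ageing phenomenology's published
form are not available, so the package fixes its own reference world, chosen
once to realize the described regime — a long-lived focal species whose
frail antagonist dies in its mid-life — and frozen:

| parameter | species A | species B | meaning |
|---|---|---|---|
| N | 100 | 100 | network size |
| d | 0.002 | 0.008 | intrinsic damage / step |
| r | 0.02 | 0.05 | repair / round |
| C | 0.015 (0 for the solo control) | 0.015 | co-ageing constant |
| f0 | 1.0 | 1.0 | initial functional fraction |
| phi_T | 0.10 | 0.10 | death threshold |

With cohort 2000 and randomized topologies this gives tau_B ≈ 50,
tau_A ≈ 430 coupled vs ≈ 890 solo, a mixed intrinsic/co-ageing cause
split for A, and one significant hazard bump whose declining flank
brackets tau_B — stable across master seeds.  `C_A = 0.015` versus `0` is
the model's in-text solo/co-ageing contrast; the antibiotic-style protocol
(`C 0.023 -> 0.013`, all else shared) is used in the worked example and the
paired-condition fit.

## Chess regime

A chess game is two defence networks that damage only each other:
`d = 0`, `r = 0`, `f0 = 1`, equal N, death threshold 0.15, and per-colour
co-ageing constants (the stronger colour *receives* the smaller C).  The
losing colour dies at the game length in full moves (`ceil(ply/2)`); under
the winner-continues-to-live convention the winner is censored alive
forever, so per-colour hazards decline late as decided games accumulate
winners.  Expected outcomes use the Glicko formula
`E_ij = 1/(1 + 10^(-g(RD_i^2+RD_j^2)(r_i-r_j)/400))` with
`g(x) = 1/sqrt(1 + 3 q^2 x / pi^2)`, `q = ln 10 / 400` — the standard
attenuation of the rating gap by combined rating uncertainty.  Archives are
filtered to a narrow expected-outcome band (e.g. [0.7, 0.8]), one base time
control, no draws, and no forfeit-like endings (timeouts count as
forfeit-like by default; configurable).  RD is read from the dialect tags
`WhiteRD`/`BlackRD` when present, else a default (50) is used and logged.

The synthetic archive generator emits fully realistic *tag pairs* but
filler movetext whose only meaningful property is its ply count; it models
a single rating gap with Bernoulli outcomes at exactly the Glicko expected
probability.  It does not emulate rating heterogeneity, length/outcome
correlation, or real opening structure — a green pipeline test establishes
the bookkeeping (counts, filters, censoring, accounting identities), not
realism of play.

## Calibration

No likelihood is defined for this model, so fitting is simulation-based:
a weighted sum of squared hazard differences, weights `S(t)/max S` (the
binomial variance of a hazard estimate scales as `1/S`), evaluated under
common random numbers and minimized by a coarse bounded grid followed by
bounded Nelder–Mead.  Cause-specific targets (`mu_s`, `mu_c`) are fitted
simultaneously with the all-cause curve being their sum by construction.
A `time_scale` (simulation steps per data time unit) aligns the clocks;
it may itself be fitted or fixed.  `paired_condition_fit` fits several
experimental conditions jointly with shared parameters taking one value
across conditions — the protocol for antibiotic-treated vs untreated
cohorts, and for chess expected-outcome bands, where only the co-ageing
constants move.

Evaluations reuse the target's topology seed: the network is part of the
model being calibrated, and letting it vary between target and evaluation
confounds the fitted dynamics parameters at small N.  Loss cohorts and the
evaluation horizon may be smaller than the target's (the survivor weights
make the late tail nearly irrelevant); the acceptance-scale self-fit
(target cohort 5000, truth C_A = 0.015) recovers the truth to a few
percent, well inside the ±30% contract.

## Known limitations

* Node heterogeneity, strategic (non-random) targeting and time-varying
  topology are out of scope, as is any non-uniform growth rule.
* The death threshold matters for small networks (residual self-sufficient
  cliques); the chess regime's 0.15 is a convention, not a fitted value.
* Hazard smoothing is a presentation/detection aid only; all quantitative
  identities are asserted on raw series.
* The mean of uncensored death times is reported as `tau`; use the
  restricted mean for comparisons whenever censoring is non-negligible.
* `simulate_pair` is the cohort engine at cohort 1; per-pair results depend
  on the cohort they are embedded in (draws are keyed per step, not per
  individual), which is the price of exact decoupling plus vectorized speed.
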