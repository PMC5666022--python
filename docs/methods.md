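# Methods

## Model

The world is an unbounded 2-D integer lattice with a single-site rod at
(500, 500).  Per time step, Φ agents (default 1) enter at an entry site (the
rod by default; optionally drawn uniformly from several sites at or up to
two rows below the rod row).  Agents are *active* (mobile) or *inactive*
(attached).  No agent may occupy a row above the rod.

**Movement and settling.**  Each active agent samples one move per step:
−y (prob. 0.9), +x (0.05), −x (0.05).  Updates are synchronous against the
start-of-step attachment pattern.  An agent moving onto a site that holds
no inactive agent and lies strictly below the rod row attaches there
(threshold set to `threshold0`, default 5); otherwise it moves and stays
active (several actives may share a site; at most one inactive per site).
When two actives would attach to the same empty site in one step, a
uniformly drawn winner attaches and the rest stay active there.  The rod
row itself is treated as an entry corridor: agents may walk along it but
never attach on it.  This corridor rule is our resolution of an
under-specified boundary condition; allowing attachment beside the rod
creates short-lived top-row supporters whose supporting areas span the
whole structure, randomly shedding it wholesale, and floods the
unsupported-removal rule with non-rare events (see *Interpretation
decisions*).

**Support and weight.**  The supporting area of inactive k at (x, y) is
{(x', y') : |x' − x| ≤ 1, y' < y}.  Every agent on an occupied site s hangs
from the topmost inactive agents whose areas cover s; its unit mass is
split equally among the agents of that topmost row (m(s) ∈ {1, 2, 3}).  A
single covering supporter therefore bears the total mass of its set, and
the sum of all weights equals the number of agents inside at least one
area — an exact invariant checked in the tests.  Active agents inside an
area count toward the burden.

**Unsupported removal.**  An inactive agent with no inactive agent one row
above within |Δx| ≤ 1 is removed (one synchronous pass per step, before
weight calculation); agents on the row directly below the rod with
|x − rod.x| ≤ 1 are rod-supported.  These removals are structural
corrections, logged separately, and never counted as droplets.

**Warning, coordination, fall.**  An inactive agent signals when
`weight ≥ threshold − 1`; each active agent directly beneath a signaller
climbs to one of the three sites above it that hold an inactive agent
(uniform among occupied candidates; the straight-up candidate is the
signaller itself, so a climb always succeeds), carrying a `moved_up` flag
for the rest of the step.  An inactive agent with a flagged climber within
Chebyshev distance 1 re-tunes its threshold once per step using the
*previous* step's pattern estimate: unstable → `threshold ← weight`;
stable → `threshold ← threshold + 1`.  Patterns are recomputed afterwards
(stable iff a lateral inactive neighbour shares the row; the rod does not
count).  Finally every agent with `threshold ≤ weight` sheds all agents on
occupied sites of its area; breaches are processed in seeded random order,
skipping those already relieved; the trigger survives with weight 0, and
supporters whose areas contained a removed agent have their weights zeroed
(their links to the fallen set break).  All removals in one step form one
droplet event.  A breach over an empty area removes nothing and emits no
event.  Variants: TM applies both coordination rules, TM-stable only the
raise, TM-unstable only the collapse, NTM skips coordination and pattern
calculation entirely.

## Interpretation decisions

Two points of the verbal model admit multiple readings; both were resolved
by requiring the worked three-supporter example (weights 2.5 / 2.0 / 1.5)
to hold exactly *and* the simulation to reach the reported dynamical
regime:

* **Weight sharing.**  Splitting each site's mass among *all* covering
  supporters makes a chain's top agent bear only a harmonic sum (~ln L),
  so weights never reach thresholds and the structure grows without
  falling.  The topmost-row rule adopted here preserves the worked
  example, the conservation law, and the stated property that a set
  connected by a single link loads that single agent with its total
  weight.
* **Rod-row corridor.**  See *Movement and settling* above.

Other resolved details: the breached trigger is not part of the set it
sheds (its weight reset implies persistence); thresholds are real-valued;
a freshly attached agent has no pattern estimate and skips coordination
until its first pattern pass; coordination fires at most once per agent
per step.

## Emergent regime and known discrepancies

With these rules the default TM dynamics alternate between *quiet phases*
(stable patterns raise thresholds, the structure deepens) and *drip
phases* (a collapsed threshold sheds arrivals in rapid small droplets).
This mixture produces the reported headline behaviour: roughly 40–55
droplets per 1000-step trial, a decisive power-law preference for the
increment magnitudes (Akaike weight 1.0) with exponent μ ≈ 1.6 at the
default threshold, persistence of the Lévy tail at threshold 3, tall
narrow structures (height/width ≈ 5), the interval ordering
TM-stable > TM > TM-unstable, and strong suppression of short interdrop
intervals under diffuse descent (threshold 3, movement 0.50/0.25/0.25).

The implementation does not reproduce every published statistic, and the
acceptance tests encoding those checks are deliberately left failing
rather than loosened:

* Drip phases, once entered, persist too long within a trial (arrivals
  attach into the shedding zone before they can act as climbers, so the
  coordination rule that would restore the threshold is starved).  Trials
  therefore split into drip-heavy and quiet ones instead of mixing both
  phases evenly, which inflates the pooled mean droplet size (~22 vs. the
  reported 12.8), makes the pooled increment distribution too bimodal for
  the G-test (rejected where the original reports a non-significant fit),
  and yields μ below the reported values at threshold 7 and three-height
  entry (with the exponential model sometimes preferred there).
* The NTM variant drips very regularly here (exponential rate λ ≈ 0.7 vs.
  the reported 0.29, and small-integer increments that let the power law
  win the AIC comparison spuriously).
* The fluctuation exponent of the interval profile comes out at α ≈ 0.7
  rather than the reported 0.06; the original's exact fluctuation-function
  formula is not stated, and the profile-based estimator used here reads
  the quiet-phase threshold drift as persistence.

Alternative readings that were implemented and measured — the trigger
falling with its set, thresholds restored after a fall, coordination gated
on the agent's own warning state, rod support restricted to the site
directly beneath — each destroy the Lévy signature or the droplet tempo
outright and were rejected; the analysis lives in the test suite's
acceptance layer and this note.

## Statistics

* **Fluctuation function.**  `F(n) = √⟨(Y_{k+n} − Y_k)²⟩` with
  `Y = cumsum(DT − ⟨DT⟩)`; α is the least-squares slope of log F vs log n
  over n ∈ [2, N/4].  i.i.d. input gives α ≈ 0.5 (verified); a constant
  series yields F ≡ 0 and an undefined α (flagged, not fitted).
* **Tail fits.**  Nonzero increment magnitudes with x_min = 1 (the
  smallest nonzero integer increment).  Continuous Pareto:
  `μ̂ = 1 + n/Σ ln(x/x_min)`; shifted exponential:
  `λ̂ = 1/mean(x − x_min)`; both refuse fewer than 5 observations or
  degenerate samples.  AIC = 2 − 2 log L (one parameter each); Akaike
  weights `w_i ∝ exp(−Δ_i/2)`.
* **Goodness of fit.**  G = 2 Σ O ln(O/E) over 8 initial log-spaced bins
  on [x_min, max], expected counts from the fitted model's CDF
  renormalised over that range, bins with E < 1 merged into their
  right-hand neighbour (the last into its left); df = bins − 2; p from the
  χ² upper tail, "significant" at 0.05.  The initial bin count is our
  choice (the original states only the merging rule); 8 bins reproduce the
  reported df range (2–5) after merging.
* **Intervals.**  DT is computed within trials only; increments from
  consecutive DT of the same trial; the aspect ratio of a trial is the
  structure's (width, height) at the step of maximal height, averaged
  across trials (the sampling instant is our choice).

## Problem sizes and determinism

Default experiments use the standard conditions throughout: 1000-step
trials, 100 trials for tempo/geometry/interval distributions, 5 pooled
trials for tail fits, 20 per variant for the ordering check, 30 for the
diffuse-descent geometry.  Per-trial generators are
`default_rng([seed, trial])`, so trial i is reproducible independently of
how many trials are requested; a fixed seed reproduces every artefact
byte-for-byte.
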