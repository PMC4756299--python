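# Methods

## Mass-balance model

The web is a directed carbon-flux network over functional nodes: autotrophs,
heterotrophs, mixotrophs, and non-living pools (particulate detritus, DOC).
All stocks are mgC m⁻², all rates d⁻¹, all flows mgC m⁻² d⁻¹.  The system
is treated as at steady state: the bloom and non-bloom configurations each
persist for weeks while plankton turn over in days, so no biomass-change
term is carried for living nodes.

Per consumer *j*, ingestion Q<sub>j</sub> = α<sub>j</sub>B<sub>j</sub> is
split over prey by diet fractions δ<sub>ij</sub> (columns sum to 1, over
every prey the consumer's layer lets it reach: surface↔surface, deep↔deep,
whole-column↔both).  The balance identity

- respiration ρ<sub>j</sub> = (1 − ε<sub>j</sub>)Q<sub>j</sub> − P<sup>het</sup><sub>j</sub>,
- P<sup>het</sup><sub>j</sub> = (1 − p<sub>φ,j</sub>) μ<sub>j</sub>B<sub>j</sub>,
  with p<sub>φ</sub> = (Ph/Het)/(1 + Ph/Het) the phototrophic share
  (1 for autotrophs, 0 for heterotrophs),

holds exactly by construction; feasibility requires ρ > 0.  Production not
eaten inside the web is other mortality μ0 = (1 − EE)·μB with
EE = predation/production; feces (εQ) and μ0 are routed to the non-living
pools by per-node γ fractions (Σγ ≤ 1), the unrouted remainder counting as
export.  Autotroph production is interpreted as *net* primary production,
so producers carry no respiration term.  Non-living pools hold no rates:
they are the model's closure.  A pool whose consumption exceeds its inputs
is reported as importing (a warning in its budget), never silently
balanced; the surplus case is accumulation/export.

Two printed sums anchor the transcription of the 63-node table: the
living-node Shannon diversities of the two biomass columns and the 12-node
surface-phytoplankton totals (706.9 vs 102.0 mgC m⁻², ratio 6.93).

## Balancing search

Rates are only known within ranges, diets within a variability envelope, so
balancing is constraint satisfaction, not posterior inference.  A
fixed-temperature Metropolis walk (T = 0.02, chosen so that score
differences of order one constraint violation are rarely accepted uphill)
minimizes a violation score summing normalized excesses of: EE above 1,
negative consumer respiration, node residuals, prey→predator transfer
efficiency ≥ 1, and the system-level requirement that total primary
production exceed total consumer production.  The direction of that last
inequality is configurable (`pp_constraint_direction`) because the two
plausible readings disagree; the default is the thermodynamically coherent
one.  Diet links below 10⁻⁴ of a predator's diet sum are pruned and the
column renormalized at every step; pruning is idempotent.

Proposals: an optional coarse phase redraws rates uniformly within their
declared ranges and link weights within ±`link_variability` of their
initial values; the fine phase multiplies every parameter by
Uniform(1 ± 0.05), clipping rates to their ranges and link weights to the
coarse envelope, then renormalizing diets.  The walk collects feasible
candidates until `n_feasible_target` are found or `max_iterations` pass and
returns the one with the smallest residual norm (node imbalances plus
non-living-pool deficits).  Everything is driven by one seed; identical
inputs give identical balanced models.

## Indicators

- **Trophic levels**: TL = 1 for producers and non-living pools; consumers
  sit one step above the flow-weighted mean TL of their food, a mixotroph's
  phototrophic share entering as a TL-1 diet component.  Solved as a linear
  system; a singular system (pure cycle with no TL-1 anchor) is an error.
- **Weighted degree / hubs**: carbon exchanged with other living nodes
  (row + column sums of the living-to-living flow matrix); the top five are
  the hubs, ties broken by lower node id.
- **Mixed trophic impact**: q<sub>ij</sub> = (share of j's ingestion
  supplied by i) − (share of the predation on j exerted by i);
  M = (I − Q)⁻¹ − I.  M equals the Neumann series Σ Q^k when the spectral
  radius is below 1, and always satisfies M = Q(I + M); both serve as test
  oracles.  Overall effect o<sub>i</sub> is the root-sum-square of the
  off-diagonal impact row, scaled to the community maximum; keystoneness
  KS<sub>i</sub> = log₁₀[o<sub>i</sub>(1 − p<sub>i</sub>)] with
  p<sub>i</sub> the living-biomass share.  Zero impact maps to −∞, the
  lowest rank, not an exception.
- **Ascendency**: A = Σ T<sub>ij</sub> log₂(T<sub>ij</sub>T‥/(T<sub>i·</sub>T<sub>·j</sub>)),
  C = −Σ T<sub>ij</sub> log₂(T<sub>ij</sub>/T‥) over the flow matrix
  extended with export and respiration sink columns (and an import source
  row when present).  Only the base- and scale-invariant A/C and per-node
  contributions (attributed to the flow's source node) are reported.
- **Shannon diversity**: natural-log H over living-node biomasses.  The
  living-node convention is adopted because it reproduces both published
  diversity values from the biomass table; including non-living pools does
  not.
- **Mantel test**: Pearson correlation of off-diagonal flux entries, with a
  permutation p-value under simultaneous row/column relabeling,
  (count + 1)/(n + 1).  Structurally-zero pairs are retained (configurable
  by masking before the call); fluxes are compared raw.
- **Predatory cycles**: simple directed cycles in the living-node subgraph
  of positive flows (any path through detritus/DOC is excluded), enumerated
  with an explicit cap and truncation flag.

## Lindeman spine

Canonical trophic aggregation apportions every node over integer trophic
levels: the fraction of a consumer's ingestion arriving at level k+1 is the
flow-weighted share of its food at level k, and node weights blend
ingestion with the phototrophic inflow so each level's ledger balances
exactly.  Path roots separate a grazing chain (anchored at primary
production) from a detritus chain (anchored at the pooled non-living box,
which sits at level 1 of that chain).  Levels are capped at K = 8 — above
the deepest paths observed in these webs — with longer paths (including
cycle tails) folded into the last compartment; the fold preserves the
per-level balance, so total spine throughput equals network throughput
(internal flows + gross primary production) to machine precision, and a
violation of 10⁻⁶ relative raises an error.

TE at step k+1 is transfer(k→k+1)/input(k); steps with no transfer are
missing, not zero.  Overall TEs are input-weighted geometric means over
steps up to TL 4 (arithmetic available as an option), per chain and
combined.

Unused production sums, over consumers, the mortality not routed to
detritus — the EE shortfall available to predators outside the web.  The
fish projection multiplies it by a 10% higher-trophic-level TE and a 9 g DW
per gC conversion, divided by 1000 for mg m⁻² → t km⁻²; results are
conventionally displayed to two decimals (the underlying value is exact,
e.g. 0.195 for the non-bloom input).

## Synthetic data

**GoN fixture.** The 63-node table (names, statuses A/H/M/D, layers s/d/a,
and both biomass columns) is transcribed from the published study.  Its
diet matrix and rate ranges are *not* public, so both are reconstructions
and are labelled as such:

- the template diet matrix assigns each consumer pools of prey consistent
  with its described role (filter feeders on pico/nano plankton, calanoid
  copepods on diatoms + protozooplankton with a ~35–40% protozoan share,
  bacteria on DOC and detritus, chaetognaths on mesozooplankton, a few
  reciprocal protist–protist links that create predatory cycles), splitting
  each pool over members proportionally to biomass (geometric mean of the
  two states, so both states share one matrix);
- guild rate ranges are literature-style defaults (diatom-dominated surface
  phytoplankton up to 2 d⁻¹, deep phytoplankton slower, fast small protists
  at 0.5–2.5 d⁻¹, mesozooplankton at 0.06–0.35 d⁻¹), then calibrated per
  node: each consumer's μ and α ranges are scaled jointly until its most
  binding prey is grazed at 85% of its attainable production when all
  production rates sit at range maxima and all consumption rates at range
  minima.  This reproduces the regime the study describes — few
  parameterizations balance, and those sit at the production-max /
  consumption-min boundary — which is the property the acceptance suite
  checks.  The calibration is anchored (producer and bacterial caps never
  shrink), so it converges; a diet template with a mutually-binding
  predation loop is rejected.

**Toy chains** realize an exact per-step TE by construction (interior EE
= 1, ε = 0) and serve as closed-form ground truth for trophic levels and
the spine.

**Random webs** are generated flows-first so the planted parameterization
balances exactly: consumption is assigned top-down (carnivore →
mesozooplankton → protists → bacteria), each prey's production then covers
the demand on it at a high ecotrophic efficiency (0.90–0.98), producers
receive headroom so total primary production exceeds total consumer
production, and rates/diets are read off the flows.  Declared ranges are
centred on the planted rates with fractional half-width 0.05, matching the
±5% amplitude of the fine search — the regime in which the
parameter-recovery experiment is informative.  Paired states share
structure, diets and non-phytoplankton biomasses; surface phytoplankton
differs by the configured factor (default 7, the observed bloom ratio).

What the generator does *not* emulate: seasonal dynamics, nutrient
limitation, size spectra within guilds, or observation error on biomasses.
Passing tests therefore demonstrate correctness of the accounting, the
search, and the diagnostics under the stated study conditions — not that
the reconstructed diet template matches the real Gulf-of-Naples diets.
Flux-derived outputs (Mantel R, ascendency, TE profiles) are qualitative
analogues of the published ones.

## Numerical choices and limitations

- Violation-score normalization divides each excess by node throughput, so
  large and small nodes weigh equally in the search.
- Parameter recovery is scored on trophic (diet-driven) links.  Closure
  flows carry μ0 = P − predation, a small difference of large numbers at
  the planted EE ≈ 0.95, so their relative error is amplified ~20× and is
  not informative about the search.
- Diet renormalization after clipping can move a fraction slightly outside
  its nominal envelope; the envelope bounds the pre-normalization weights.
- Mantel permutations default to 9,999 (999 in the acceptance script for
  speed); p-values are resolution-limited to 1/(n+1).
- Cycle enumeration is exponential in the worst case; the cap (default
  10⁵) with a truncation flag keeps it bounded.
- `balance_from_rates` builds budgets for *any* rates without enforcing
  feasibility; use `check_feasibility` to score them.
- The acceptance script balances the 63-node webs with 25,000 iterations
  (~10 s per state on one core), a size at which repeated seeds give
  stable qualitative diagnostics.
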