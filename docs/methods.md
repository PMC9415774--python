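# Methods

`floodmig` is an agent-based model of livelihood-driven migration in a
stylized deltaic economy exposed to sea-level-rise (SLR) flooding. This
note documents the model, its parameters and defaults, what the synthetic
world does and does not emulate, and the numerical and design choices.

## The model

### World

A set of `D` districts on an abstract plane, a minority flagged coastal
(clustered in a low-`y` coastline band). Distances are Euclidean and enter
only through moving costs and nothing else. Each district carries *utility
layers* — located income opportunities with a quarterly wage, a finite
capacity (concurrent holders), a one-time access cost, and a time
requirement in {0.25, 0.5, 1.0}. Wages are log-normal; income is the
full-time-equivalent wage scaled by the time requirement.

Two kinds of layer form a livelihood ladder:

- **wage labor** (half of layers): free entry, no access cost — day labor
  requires no capital;
- **investments** (the other half): access costs drawn as 2–8 times the
  layer's quarterly income (land, equipment, training), paying a 1.4×
  wage premium.

Coastal districts have more layers per district (4–6 vs 2–4), a higher
non-agricultural share, and a higher non-agricultural wage location
parameter (log-mean 2.45 vs 2.1) — livelihood alternatives concentrate in
coastal cities. They also have base annual-peak flood depths of 0.3–0.8 m
and flood sensitivities of 1.0–2.0 m of depth per m of SLR, against
0–0.2 m and 0–0.3 for the interior.

The no-argument world preset has 64 districts of which 19 coastal; all
experiments and tests run on the 20-district desk preset (6 coastal),
which preserves the same structure at tractable cost.

### Agents

Agents are individuals (not households) with age, liquid wealth, capital
(cumulative spending on layer access — a crude asset stock), CRRA
curvature ρ drawn U(0.5, 2.0), an annual discount rate (10%), and
per-quarter probabilities of reconsidering their portfolio (U(0.05,
0.15)), interacting (U(0.2, 0.6)) and meeting someone new (U(0.1, 0.3)).
Initial placement is multinomial, proportional to district layer capacity.
Initial adults are *endowed* with a greedily filled home-district
portfolio; its access costs are booked as capital (their historic
spending), not deducted from initial wealth, so collateral-based credit is
meaningful from the first quarter.

### Quarterly loop

Each quarter: (1) at year boundaries, annual peak floods are sampled and
wage damages applied; (2) agents are processed in a freshly shuffled
order — each ages (and may die or give birth), may meet a new contact,
may interact, and may reconsider its livelihood; (3) portfolio incomes are
paid and remembered as observations; (4) network links decay; (5) life
histories are recorded. Every wealth movement is written to an audit
ledger (income, transfers in/out, costs, inheritance) and the identity
`Δwealth = income + transfers_in − transfers_out − costs ± inheritance`
is testable per agent-quarter.

### Demography

Annual fertility/mortality age-band schedules are converted to quarterly
hazards via `q = 1 − (1 − p)^(1/4)`. Defaults are stylized: per-capita
fertility 0.035/yr in ages 15–45 (the model does not track sex), mortality
from 4%/yr in infancy down to 0.2–0.4%/yr in adulthood and 8%/yr above 75.
Newborns start at the parent's district with zero wealth and a
maximal-strength link to the parent; they make no decisions until the
adult age (15, configurable). At death, layer slots are released, links
dissolve, and wealth passes to the strongest-linked survivor (destroyed if
none).

### Hazard and damage

Annual peak flood depth in district *d* in year *y* is

    depth = max(0, b_d + s_d · SLR(y) + ε),   ε ~ Gumbel(0, β)

with β = 0.15 m and SLR(y) the scenario trajectory (defaults linear from
2010: 0.40 / 0.55 / 0.85 m by 2100 for rcp26/rcp45/rcp85 — configuration
defaults, not asserted projections). The Gumbel deviate is shifted to zero
mean so the expected depth is exactly `b_d + s_d·SLR(y)`.

Agents experience a *shock* only above their perceived-normal depth,
`m × expected depth of the reference period` (the expectation at
simulation start), with m ∈ [0.5, 1.5] drawn once per run. Using the
fixed reference-period baseline — what was normal when observation began —
is what makes rising seas produce growing shocks; it also gives the two
orderings the analysis relies on: shocks decrease pointwise in m, and
cumulative shock orders rcp26 ≤ rcp45 ≤ rcp85 at fixed seed.

Shock converts to a saturating wage-damage fraction `1 − exp(−δ·shock)`
with δ = 0.4/m for agricultural and 0.2/m for non-agricultural wages
(agriculture always damaged at least as fast), applied to layer incomes
for 4 quarters; overlapping windows take the maximum fraction, not the
product. Damage hits wages, never wealth stocks directly. Land loss,
salinity and erosion are out of scope: wage damage is the only hazard
channel.

### Social network

Weighted, undirected links with strength in (0, 1]. Per quarter each link
decays by 5% (10% across district boundaries — moorings lose force with
distance) and is pruned below 0.05. Meeting forms one link at strength 0.5
with a partner sampled by category weight (same district 3, else
friend-of-friend 2, else shared sector 2, else 1; rejection sampling). An
interaction strengthens one strength-weighted partner by
`w ← w + 0.3(1 − w)`, propagates the agent's last-year income
observations over every link with probability `0.3 × strength` each, and
shares 10% of the agent's surplus income (above the subsistence need)
across all links proportional to strength. Expected remittances enter
portfolio valuation as the trailing four-quarter mean net transfer, scaled
after a hypothetical move by the fraction of link strength retained
(links to destination residents keep full value, others 0.5).

### Decisions

A reconsidering agent enumerates every feasible (district, layer-subset)
option over its candidate districts: its own district plus the top
`k − 1` others by social pull (total link strength to residents; ties to
nearer, then lower-id districts), k = 4 by default. Feasible subsets
respect capacity, a time budget of 1, and at most 3 layers.

An option's expected quarterly income ŷ is the sum of remembered layer
incomes (own experience plus network-delivered observations, bounded FIFO
of 8 per layer; empty memory falls back to the layer's current
post-damage wage) plus expected remittances. Valuation is
reference-dependent with the *current* portfolio's expected income as the
reference point:

    value = A(r_q, H) · [ u(ŷ) − u(ref) ]            if gain
    value = A(r_q, H) · λ · [ u(ŷ) − u(ref) ]        if loss

with CRRA u, loss aversion λ = 2.25, horizon H = 20 quarters and
quarterly discounting `r_q = 1.1^(1/4) − 1`; A is the annuity factor
(the discounted sum collapses to it because ŷ is constant over the
horizon). The current portfolio therefore always values exactly 0.
Incomes are floored at 0.01 before the CRRA transform. Risk preferences
enter only through ρ and λ; there is no probability weighting, and
valuation uses the mean of remembered incomes, not a risk-adjusted
spread — the curvature of u is the only risk channel.

An option's one-time cost is the sum of access costs for layers not yet
accessed plus, for another district, `c0 + c1 · distance` (5 + 1/unit).
It is affordable if `cost ≤ wealth + creditMultiplier × capital` (the
boundary counts as affordable; zero-cost options are open even to agents
in debt). Adoption pays the cost (wealth may go negative down to the
credit limit), adds the *access* part to capital (moving costs are not
capital), swaps capacity slots, and appends to the move history.

The decision rule: among options with strictly positive value, adopt the
highest-valued affordable one (ties prefer staying, then lower district
id, then the lexicographically smallest layer set). If positive-value
options exist but none is affordable, the agent stays and is tagged
**moored** — the flag reflects the most recent reconsideration, so a
later satisfied or successful reconsideration clears it. Agents with no
better option anywhere are satisfied stayers, never tagged.

### Consumption

Adults consume out of propensity-weighted resources
`r = 0.8·income + 0.05·wealth`: all of r up to the subsistence need
(6 currency units/quarter), plus 60% of r above it, never driving wealth
negative. Poor households compress consumption and converge to a buffer
of roughly four quarters' income; high earners converge to a finite
buffer stock instead of accumulating without bound. Consumption is booked
under costs in the wealth ledger. This is a deliberate modelling
commitment: without a consumption sink, wealth grows linearly for a
century and every liquidity constraint — the machinery behind credit
effects and moored populations — stops binding by mid-century.

## Calibration

Five parameters are decision-sensitive and form the calibration space:
the credit multiplier [0, 2], locations considered k ∈ {1..8}, a scale on
the population ρ distribution [0.5, 1.5], the information-sharing
probability [0, 1], and the mean reconsideration probability
(0.02, 0.20]. A Latin-hypercube sample (default budget 60) is evaluated
by simulating a 4-year historical window (null hazard: zero SLR,
noiseless, m = 1 — calibration predates scenario flooding) with common
random numbers across points, scoring each simulated mean-annual flow
matrix against the observed one by R² on log(1 + flow) off-diagonals
(log1p because flow matrices are heavy-tailed). The null model is
self-contained: the mean floored R² of the observed matrix against 100
random relabelings of its own districts. Real vital-registration flows
are restricted; the harness is exercised by parameter recovery against
flows generated at a known point, where it recovers the credit multiplier
within ±0.5 in at least 4 of 5 seeds.

## Ensembles and headline analyses

An experiment draws, per run: scenario uniformly from {rcp26, rcp45,
rcp85}, m ~ U(0.5, 1.5), credit ~ U(0, 2), and the remaining decision
parameters from design ranges, with seed = seedBase + runIndex. Paired
designs give consecutive runs a common seed and identical draws except
the paired parameter (m stratum [0.5, 1.0) vs [1.0, 1.5], or credit half
[0, 1) vs [1, 2]), isolating its effect from seed-level noise.

Outcome analyses: per-district net migration (in − out, normalized by all
agents ever alive), the largest-fraction flows with a deterministic
counting rule (`ceil(fraction · D(D−1))` cells), moored shares and
moored-cohort covariates (wealth, CRRA, moves before first moored event),
Spearman rank correlation of net in-migration with moored share by
coastal stratum, and random-forest permutation importance (mean decrease
in held-out R² over 20 permutations — robust to scale and correlated
draws, unlike impurity importance) of the drawn parameters.

Problem sizes used throughout the repository: 20-district world, 250
initial agents per ensemble run, 2010–2100 horizon, three 40-run
ensembles per directional question; conservation audits run on a single
2000-agent century; decision-rule verification uses 1000 randomized agent
states on 3-district worlds.

## What the synthetic world does and does not show

The generator emulates the *structure* of the study system — skewed
wages, coastal opportunity density, coastal flood exposure, capacity
limits, credit tied to collateral — not any measured Bangladeshi
quantities. Passing tests show the mechanisms are implemented correctly
and that the qualitative phenomena (coastward net migration; flood
experience modulating it; credit raising wealth) emerge from those
mechanisms under realistic-by-construction conditions. They do not
validate magnitudes against real migration data, which are restricted;
absolute flow counts, wealth levels and moored shares have no empirical
unit attached.

Directional results measured here:

- Net migration is toward the coast in essentially every run, under all
  scenarios and all m: coastal wage premiums and layer density dominate
  accumulated wage damage through 2100.
- Runs that experience flooding as normal (high m) show more coastward
  migration than paired runs that experience it as shocks (low m).
- Higher credit raises mean final **net worth** (liquid wealth plus
  capital). Liquid cash alone is nearly flat in credit, because credit's
  effect is precisely to convert cash into productive assets — net worth
  is the wealth concept used for this analysis.
- Higher credit *lowers* the moored share in this model. With mooring
  defined as "a strictly better option exists but none is affordable"
  (satisfied stayers never tagged) and credit proportional to collateral,
  raising the multiplier weakly enlarges every agent's affordable set;
  within this definition the direction is structural. A mooring concept
  that counts agents who have invested in place and no longer have better
  outside options — agency-rich immobility — would require counting
  satisfied stayers, which this model's definition deliberately excludes.

## Numerical choices and degenerate inputs

- All randomness flows from explicit seeds (`numpy` Generator for
  distributional draws and shuffling, Python `random` for event coins);
  identical seeds give byte-identical event logs.
- Affordability uses ≤ (boundary affordable); fixed for reproducibility.
- CRRA is evaluated as log within 1e−9 of ρ = 1 (continuous limit).
- The wage-damage fraction saturates strictly below 1 for any finite
  shock (up to float resolution of `exp`).
- Degenerate worlds run to completion: a 1-district world produces no
  moves; an empty population produces empty histories; a district with no
  layers values only the empty portfolio (income floored at 0.01).
- Flow matrices from `generate_observed_flows` are rounded to integer
  mean-annual counts.
- A capacity slot taken between enumeration and adoption triggers one
  re-evaluation, then a stay (cannot occur under the sequential
  scheduler; guards future concurrency).

## Known limitations

- Households, marriage and sex-structured fertility are absent; fertility
  is per-capita in a band.
- One hazard channel (wage damage); no land loss, salinity, or assets
  destroyed in place.
- The macro-economy is held constant: wages respond to floods but not to
  labor supply; in-migration saturates capacity but does not move wages.
- Amenity (place-attachment) layers exist in the schema but are off by
  default; nothing quantitative is asserted about them.
- The m-effect and credit–wealth effect are a few percent of population
  and tens of currency units respectively; at desk scale they are
  detectable only with paired designs, which is how they are tested.
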