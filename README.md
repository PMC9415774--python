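# floodmig

Agent-based simulation of migration under sea-level-rise (SLR) flooding in
a stylized deltaic economy, for researchers in environmental migration and
computational demography. Individual agents choose livelihood portfolios
across districts under prospect-theoretic valuation, collateral-based
credit constraints, dynamic social networks and flood-damaged wages. The
package asks the push–pull–mooring question quantitatively: when rising
seas damage coastal wages for a century, does net migration turn away from
the coast — and who becomes unable to move?

## The model in brief

Each district offers *utility layers*: income opportunities with a
quarterly wage, finite capacity, one-time access cost and time
requirement. Every quarter an agent may reconsider its livelihood: it
enumerates feasible (district, layer-subset) options over its current
district plus the `k − 1` districts where its social ties are strongest,
and values each option relative to its current portfolio's expected
income ŷ_ref through a loss-averse CRRA value function,

    V(ŷ) = A(r_q, H) · v( u(ŷ) − u(ŷ_ref) ),     v(g) = g if g ≥ 0 else λg,

with u CRRA (curvature ρ), λ = 2.25, and A the discounted annuity factor
over an H = 20-quarter horizon. The best strictly-better option is adopted
if affordable under `cost ≤ wealth + creditMultiplier × capital`, where
capital is cumulative spending on layer access (credit is collateral-
based). If better options exist but none is affordable, the agent is
tagged **moored**. Annual peak flood depth is `b_d + s_d·SLR(y)` plus
Gumbel noise; depth above `m ×` the reference-period expectation (m ∈
[0.5, 1.5], the perceived-normal multiplier drawn per run) is a shock that
damages wages by `1 − exp(−δ·shock)` for four quarters.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
import numpy as np
import floodmig as fm

world = fm.generate_world(fm.WorldConfig.desk(), seed=1)   # 20 districts, 6 coastal
histories, flows, summary = fm.run_simulation(
    world, fm.default_scenario("rcp45", normal_multiplier=1.0),
    2010, 2100, seed=42, n_agents=500)

coastal = np.array([d.coastal for d in world.districts])
print(summary.total_moves, summary.moored_share_overall)
print(summary.net_migration_by_district[coastal].sum())
```

The same run through `python analysis/02_single_run.py` prints:

```
2010-2100, 1318 agents ever alive, 3114 moves by 984 migrants
net coastal migration: +0.020 of population (toward the coast)
moored share at 2100: 0.053
largest 1% of inter-district flows:
  interior-10 -> coastal-00 (coastal destination): 122 moves
  ...
```

Reading this: over the 91-year projection, 984 of 1318 agents ever alive
moved at least once; net migration summed over coastal districts is +2.0%
of the population — *toward* the rising water, because coastal districts
carry denser and better-paid opportunity than flood damage removes — and
5.3% of surviving adults end the century moored: a better livelihood
exists somewhere they consider, but they cannot afford the access and
moving costs even with credit.

## Analysis chain

The numbered scripts under `analysis/` reproduce the full chain; each
writes its tables to `results/`:

1. `01_build_world.py` — synthetic worlds and district structure
2. `02_single_run.py` — one 2010–2100 projection and its life histories
3. `03_hazard_trajectories.py` — flood depth/shock orderings across
   rcp26/45/85 and perceived-normal multipliers
4. `04_calibration_recovery.py` — Latin-hypercube calibration of the five
   sensitive parameters against synthetic observed flows, with the
   permutation null model
5. `05_ensembles.py` — paired Monte Carlo ensembles over scenarios and
   parameter draws
6. `06_headline_analysis.py` — directional effects (perceived-normal
   flooding on coastward migration; credit on wealth and on mooring),
   parameter importance, coastal/interior correlation of in-migration
   with mooring

There is also a CLI (`floodmig build-world | simulate | calibrate |
experiment | analyze`) wrapping the same library calls.

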