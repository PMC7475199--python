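# ffvpsim

Agent-based simulation of how elementary-school children form preferences
for healthy food under the USDA **Fresh Fruit and Vegetable Program (FFVP)**,
a grant program that provides free fruit/vegetable snacks in high-need
elementary schools. The package is aimed at researchers in nutrition policy
and computational epidemiology who want to explore how the *timing*,
*duration*, and *food-environment context* of an exposure intervention shape
long-run dietary behavior — e.g., whether early exposure beats late
exposure, and whether children in food deserts benefit most.

## The model

Each agent (a student followed from kindergarten through grade 6, 180
school days per year, 1260 steps in total) carries a perceived valuation
V̂<sub>iH</sub> ∈ [0, 1) of healthy food, learned by temporal-difference
updating toward the intrinsic palatability V<sub>H</sub> = β<sub>H</sub> = 1:

  V̂<sub>iH,t+1</sub> = V̂<sub>iH,t</sub> + α<sub>i</sub> (V<sub>H</sub> − V̂<sub>iH,t</sub>)

applied whenever the agent consumes healthy food. The valuation of
unhealthy food is fully formed from the start (V̂<sub>iU</sub> = 1) and
preferences are learned but never forgotten.

Each school day the agent faces one of two situations. With probability γ
only healthy food is available (and is consumed); otherwise the agent
chooses between the two foods with Luce probability
P<sub>iH</sub> = V̂<sub>iH</sub> / (V̂<sub>iU</sub> + V̂<sub>iH</sub>) ≤ 1/2.
The environment probability γ is drawn once per agent-year: uniformly on
(0, p₁) in a food-desert year, on (p₁, p₂) otherwise, and augmented by a
constant *a* (clipped at 1) in a year the student's school holds an FFVP
grant. Because healthy consumption raises V̂<sub>iH</sub>, which raises
P<sub>iH</sub>, which raises consumption, early environments lock in: the
model exhibits the habit-formation "lock-in effect."

Preferences map to behavior through daily servings: a uniform draw
u ∈ (0, V̂<sub>iH</sub>] is pushed through the Poisson(λ) quantile function
(inverse CDF), so servings are integer, stochastically increasing in the
formed preference, and approach a full Poisson(λ) draw as V̂<sub>iH</sub> → 1.
The augmentation constant *a* is calibrated so that one year of FFVP in
kindergarten raises mean daily servings by 1/3 — the empirical one-year
program effect reported for FFVP.

Modules: `core` (learning rule, choice rule, environment draw, servings
map), `cohort` (synthetic stratified cohorts with 7-digit binary exposure
patterns and food-desert histories), `simulate` (daily-step simulator with
per-agent reproducible substreams), `calibrate` (grid search + refinement
on the one-year effect), `report` (grouped Welch-t effect tables, pattern
summaries, preference-trajectory panels), `cli`/`config` (YAML-configured
pipeline).

## Worked example

Simulate a 1:10-scale cohort (3,598 agents with the study's joint
desert-by-FFVP proportions) over the full K-6 schedule and tabulate the
grade-6 FFVP effect by food environment:

```python
from ffvpsim import (CohortConfig, SimulationConfig, generate_cohort,
                     simulate_cohort, effect_table, pattern_summary)

cells = {(False, False): 794, (False, True): 259,
         (True, False): 1760, (True, True): 785}
cohort = generate_cohort(CohortConfig(n_agents=3598, cell_counts=cells, seed=1))
trajs, final = simulate_cohort(cohort, SimulationConfig(seed=2, record_every=60))
print(effect_table(final).round(3).to_string(index=False))
```

which prints (abbreviated):

```
       group  n_unexposed  mean_unexposed  n_exposed  mean_exposed  ffvp_effect       t   p
never_desert          794           2.776        259         2.829        0.053  -6.346 0.0
      desert         1760           2.415        785         2.570        0.154 -19.626 0.0
       total         2554           2.527       1044         2.634        0.106 -13.658 0.0
```

Students who ever received FFVP consume more fruit-and-vegetable servings
by grade 6, and the program effect is about three times larger for students
who ever lived in a food desert (0.154 vs 0.053 servings/day) — the
environment-interaction pattern the model is built to study. All contrasts
are Welch unequal-variance t tests. `pattern_summary(final)` gives the
per-exposure-pattern table behind the bubble plot (servings rise with years
of exposure, and early exposure matters more than late), and
`trajectory_panel` returns mean preference curves per pattern.

The same run from the shell:

```bash
ffvpsim run -c examples/config.yaml          # cohort -> simulate -> report
ffvpsim calibrate -c examples/config.yaml    # refit the augmentation constant
```

Outputs (`cohort.csv`, `final_states.csv`, `trajectories.csv`,
`table2_replica.csv`, `fig1_patterns.csv`, `trajectory_panel.csv`,
`manifest.json`) land in the configured output directory; runs are
byte-reproducible given the master seed.

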