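# Methods

## Model

An agent i carries a perceived valuation `v_hat_H` of healthy food,
initialized at 0 ("completely unformed") and updated by temporal-difference
learning each time healthy food is consumed:

    v_hat_H' = v_hat_H + alpha_i * (beta_H - v_hat_H),

with intrinsic palatability `beta_H = 1` (the true valuations of healthy and
unhealthy food are both normalized to 1, so nothing in the long run favors
either food intrinsically). The unhealthy-food valuation is pinned at
`v_hat_U = 1`: that preference is taken as fully formed before school entry.
There is no forgetting — unhealthy consumption leaves the state unchanged —
so `v_hat_H` is non-decreasing and, after n updates from zero, equals
`1 - (1 - alpha)^n` exactly. It therefore never reaches 1 in finite time,
which the servings map below requires.

Each school day is one of two situations. With probability `gamma` only
healthy food is available and is consumed (one update). Otherwise the agent
chooses, taking healthy food with Luce probability
`v_hat_H / (v_hat_U + v_hat_H)`, which is bounded by 1/2 under the
normalization. An agent at `v_hat_H = 0` never chooses healthy food in a
choice situation — the unformed state is absorbing until a healthy-only day
bootstraps it. This interaction (consumption raises preference, preference
raises consumption) produces the lock-in dynamics the model studies.

`gamma` is drawn once per agent-year, from Uniform(0, p1) in a food-desert
year and Uniform(p1, p2) otherwise; an FFVP year adds the constant `a` to
the draw, clipped at 1. The additive reading of the augmentation follows
the verbal definition of the environment equation (the typeset bounds
suggest a multiplicative form, which would vanish as p1 -> 0 and make the
program useless exactly where food access is worst; the additive form keeps
the program effective in deserts). A per-day redraw of gamma is available
as a configuration switch; the yearly draw is the default because desert
status and FFVP receipt are yearly attributes.

Behavior is observed through daily servings: u ~ Uniform(0, v_hat_H] pushed
through the Poisson(lambda) quantile function, i.e. the smallest integer k
with CDF(k; lambda) >= u. The "inverse Poisson" draw is read as this
inverse-CDF transform — it is stochastic, integer-valued, stochastically
increasing in the formed preference, and diverges at u = 1, which is
precisely why the model constrains v_hat_H < 1. An agent with v_hat_H = 0
consumes 0 servings deterministically. The quantile is evaluated by binary
search on a cached CDF table built from scipy's Poisson distribution (tail
truncated below 1e-15 mass, last entry pinned to 1); a brute-force pmf
summation serves as the test oracle.

## Schedule and cohort

The schedule is 180 school days x 7 academic years (K-6), 1260 steps;
summers and weekends are not simulated. An agent's program history is a
7-digit binary exposure pattern indexed K,1,...,6 (128 possibilities) and a
7-digit food-desert history on the same index.

The synthetic cohort generator emulates the structure of the Arkansas
administrative cohorts the model was built around (2008/09 and 2009/10
kindergarten entrants, 35,981 students): the four
(ever-desert x ever-FFVP) cell counts are realized exactly by stratified
construction — defaults 7,942 / 2,591 / 17,598 / 7,850, giving marginals
70.7% ever-desert and 29.0% ever-FFVP. (The source text elsewhere quotes
45% ever-exposed; the tabulated 0.290 is consistent with the printed cell
counts and is the value adopted here — both figures are surfaced rather
than reconciled silently.)

What the generator does **not** emulate: the true joint distribution of
exposure patterns is unpublished, so ever-exposed agents draw patterns from
a configurable weight table, by default the 28 contiguous-run patterns with
weight proportional to `0.8^(run length - 1)` (schools tend to hold or lose
grants in consecutive years; the full K-6 run gets ~1.4% of exposed agents,
echoing how rare uninterrupted exposure was). Desert histories follow a
symmetric yearly flip chain (default flip probability 0.05, initial desert
probability 0.90 for ever-desert agents, conditioned on at least one desert
year by rejection). School-level clustering, free/reduced-lunch dynamics,
and geography are out of scope. Consequently, passing tests show that the
mechanism reproduces the study's qualitative structure and calibrated
effect under a plausible cohort — not that it reproduces any real
children's consumption; cohort-level servings magnitudes depend on the
unpublished pattern distribution and calibration supplement and are not
reproducible quantities.

## Parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| p1 | upper gamma bound in a desert year | 0.10 | design choice: desert years average a 5% chance of a healthy-only day |
| p2 | upper gamma bound in a non-desert year | 0.35 | design choice: keeps never-exposed non-desert learning incomplete by grade 6, so a grade-6 program contrast remains measurable in every environment |
| a | FFVP augmentation of gamma | 0.1635 | calibrated (below) |
| alpha | learning speed per consumption event | 0.005 | design choice: with ~500-1000 lifetime updates, final valuations land in the high-0.8s to high-0.9s — strong but incomplete learning on the scale the study reports |
| lambda | Poisson servings mean (servings/day) | 3.0 | design choice: puts grade-6 group means on the published 2.1-2.9 servings scale |
| desert_flip_prob | yearly desert-status flip | 0.05 | unpublished; deserts are persistent |
| days_per_year, n_years | schedule | 180, 7 | stated schedule |

## Calibration

The empirical anchor is the one-year program effect: children in FFVP
schools consumed 1/3 cup more fruits and vegetables after one year. The cup
quantity is mapped to 0.333 daily servings on the model scale (the
equivalence is a configuration value, not hard-coded). `one_year_effect`
simulates two arms of kindergarten agents for 180 days — identical desert
mix (default 70.7% desert) and identical random shocks, FFVP on vs off —
and returns the difference in arm-mean daily servings; common random
numbers make the contrast low-variance and exactly zero at a = 0.

`calibrate` minimizes the squared deviation of this effect from the target
by coarse grid search plus local grid refinements (box shrink 0.4 around
the incumbent, all evaluations on one seed, full trace retained, explicit
failure status if no point reaches tolerance). A single scalar target
cannot identify (a, alpha, lambda) jointly, so the default search frees
only `a`, with alpha and lambda pinned at their documented defaults;
ranges for alpha and lambda can be opened in `SearchSpace`, with the
understanding that the fit is then a ridge of near-equivalent solutions.
Running the default calibration (n_rep = 2000, seed 0) gives a = 0.1635
with achieved effect 0.3331; that value is frozen as the package default
and re-derived from scratch by `scripts/acceptance.py`.

## Numerical and design choices

- **Randomness.** One master seed; every agent simulates on its own
  `SeedSequence([seed, agent_id])` substream, so cohort results are
  independent of iteration order and partial reruns match full runs. Each
  simulated day consumes exactly three uniforms (situation, choice,
  servings) regardless of branch, making the scalar single-step API and
  the batched per-year simulator bit-identical on the same stream. Pipeline
  stages derive named sub-seeds from the master seed.
- **End-of-study servings.** Reported as the mean of the 180 daily draws of
  the final year (a single-draw mode exists). The averaged quantity has
  the dispersion of a yearly mean, consistent with the small SDs the study
  tables show for grade-6 servings; the source is silent on this point.
- **Degenerate inputs.** Both-valuations-zero choice returns probability 0;
  v_hat_H = 0 yields 0 servings without consuming extra randomness in the
  scalar path only where documented; empty cohorts and empty report cells
  return empty/NaN outputs rather than raising.
- **Ties and bounds.** The Poisson quantile uses CDF(k) >= u (left
  insertion), so u exactly at a CDF value maps to that k. gamma draws are
  open-interval in law; the FFVP clip at 1 is the only censoring.
- **Welch t.** Computed from summary statistics with the
  Welch-Satterthwaite degrees of freedom and a two-sided p from the t
  distribution; scipy's `ttest_ind_from_stats` is kept as an independent
  cross-check in the tests. Recomputing the published table's t statistics
  from its rounded cells reproduces them to within |Δ| ≤ 0.15.

## Problem sizes

Default test and acceptance runs use scaled cohorts chosen for stable
Monte-Carlo margins: 500-800 agents per pattern or cell for qualitative
contrasts (paired by common cohort seeds so pattern comparisons are
low-noise), 2,000 agents per arm for the calibrated effect, and a
1:10-scale (3,598-agent) default cohort for the simulated effect table;
the full 35,981-agent cohort is generated (cheap) for the marginal checks,
and nothing prevents simulating it in full.

## Known limitations

- The preference scale is behavioral, not biological; "servings" inherit
  meaning only through the calibration anchor.
- Only two foods; no social influence, no forgetting, no within-day
  multiple eating occasions, no school switching — extensions would need a
  different state space.
- The desert-interaction and early-exposure findings are properties of the
  mechanism under the documented defaults; they are hypotheses about real
  cohorts, not estimates from them.
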