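# Methods

## The decision problem

`perioecon` evaluates whether offering smoking-cessation therapy (SCT —
cognitive-behavioural counselling plus nicotine replacement and bupropion)
to smokers with periodontitis is an efficient use of public dental-care
resources, compared with treating the periodontitis alone. Effects are
measured two ways: avoided tooth loss (cost-effectiveness analysis, CEA)
and oral-health-related quality-adjusted life-years (cost-utility analysis,
CUA), from the perspective of the Brazilian public health system.

## Model structure

A decision tree feeds a Markov cohort model. At entry every patient
receives non-surgical periodontal treatment; patients in the SCT arm
additionally receive one course of cessation therapy. A single chance node
then determines whether the patient quits smoking — probability 0.30 with
therapy, 0.07 without — and the quit decision is permanent (no relapse, no
repeat therapy). Each resulting stratum (former vs. current smoker) is a
three-state Markov cohort evaluated in annual cycles over a 30-year
horizon (the life expectancy of the 48-year-old male base case plus
margin):

* `MAINTENANCE` — the index tooth is retained; the patient attends
  periodontal maintenance (2 sessions/year for former smokers, 4 for
  current smokers, reflecting the poorer response of smokers);
* `LOST_NO_REHAB` — tooth lost, not rehabilitated (probability 0.09 given
  loss);
* `LOST_REHAB` — tooth lost and rehabilitated with a removable partial
  prosthesis (implant rehabilitation is a scenario).

One tooth per patient is modelled to avoid within-mouth clustering, so
both LOST states are absorbing. The annual tooth-loss probability is
`RR x p`, where `p = 0.003` is the pooled annual probability in
non-smokers and RR is the tooth-loss risk ratio (1.15 former, 2.16 current
in the base case). `RR x p > 1` is treated as an error, never clamped.

### Reward conventions

* Upfront costs (periodontal treatment in both arms, plus SCT in the
  therapy arm) accrue at t = 0 undiscounted.
* Per-cycle costs: the stratum's maintenance cost accrues in *every*
  state — after a loss the remaining dentition stays in maintenance.
* Per-event costs (extraction alone, or extraction plus rehabilitation)
  accrue once, on the transition flux into the LOST states, discounted at
  the cycle of loss.
* Effects: the CEA effect is the discounted count of cycles with the tooth
  retained (per-cycle indicator 1 in `MAINTENANCE`, 0 once lost). QALYs
  weight each cycle by the state utility: 0.86 in the first maintenance
  cycle (the "after periodontal treatment" value), 0.93 thereafter, 0.61
  without rehabilitation, 0.69 with a partial prosthesis. The
  "untreated periodontitis" utility (0.76) never enters the default
  trajectory — everyone is treated at entry — but is kept in the config
  for sensitivity completeness.
* Both costs and effects are discounted at 5%/year (range 3–7%),
  end-of-cycle accrual with discount exponent equal to the 1-based cycle
  index. A `half_cycle_correction` flag credits state rewards on the
  average of begin- and end-of-cycle occupancy at exponent t − ½, and a
  `discount_effects: false` flag restricts discounting to costs; both are
  explorations, off by default.

### Utilities and the OHIP mapping

Utilities derive from Oral Health Impact Profile (OHIP) scores mapped
linearly onto [0, 1] (`u = 1 − OHIP/OHIP_max`). Because the instrument
variant behind the published state utilities is not recoverable, the
instrument maximum is a config value (default 56, the OHIP-14 range) and
the state utilities themselves are config entries. No published utility
exists for implant rehabilitation; the shipped config carries a synthetic
stand-in (0.76, the upper bound of the partial-prosthesis range) that
should be replaced when data exist.

### Costs and currency

Costs are itemised in Brazilian reais exactly as surveyed (seven bundles:
SCT; periodontal treatment; maintenance for former/current smokers;
extraction without rehabilitation; extraction + partial prosthesis;
extraction + implant) and converted once, at full floating precision, to
purchasing-power-parity US$ at 2.46 R$/US$. Rounding to 2 decimals happens
only in reports: the printed USD components are individually rounded, so
summing them can differ from converting the R$ total by a cent — computing
in R$ first avoids compounding that rounding.

## Probability time-rescaling and pooling

Probabilities observed over multi-year windows are rescaled to annual
cycles with the constant-hazard formula `1 − (1−p)^(1/N)` (a
`time_rescale: proportional` switch offers naive division for sensitivity
checks). The annual non-smoker tooth-loss probability is a pooled
proportion: studies are rescaled to the 1-year scale, then combined by
inverse-variance weighting on the logit scale (variance
`1/(np) + 1/(n(1−p))`, 0.5 continuity correction for zero cells), either
fixed-effect or DerSimonian–Laird random-effects. Which studies produced
the published pooled value 0.003 is not recoverable, so the shipped config
adopts the printed number and the pooling module is exercised on synthetic
study tables.

## Sensitivity analyses

One-way analysis re-runs both arms with a single parameter at the printed
minimum and maximum, everything else at base, and orders parameters by the
spread in incremental cost (tornado ordering; the effect spreads are
reported alongside — the ordering metric is a package choice). Scenario
rows cover implant rehabilitation (cost and utility swapped to the implant
bundle) and the therapy-plus-training cost range, whose published range
sits entirely above the base-case cost, so its lower endpoint doubles as
the row base. The published sensitivity table carries a current-smoker
base RR of 2.60 against the 2.16 point estimate used in the base case;
both are kept, each in its own role.

The probabilistic analysis draws every uncertain parameter independently
(only marginal distributions are published): triangular for costs, the
quit probability, utilities and the non-smoker loss probability
(mode = base value), uniform for the discount rate, and lognormal for the
risk ratios (whose published moments are on the log scale: former
N(0.14, 0.28), current N(0.96, 0.27), i.e. median RRs 1.15 and 2.61).
Each of the 1000 iterations evaluates both arms on the same draw; draws
implying `RR x p > 1` are rejected and redrawn (more than 1000 consecutive
rejections aborts as a mis-specification). Quadrant probabilities on the
CE plane use a deterministic clockwise-from-NE rule for boundary points
(measure-zero under continuous sampling), and the CEAC counts an iteration
as cost-effective at willingness-to-pay λ when
`λ·ΔE − ΔC > 0` strictly — ties count against the intervention, the
conservative choice.

## The microsimulation oracle

`synthetic.microsimulate_arm` re-expresses the model at the individual
level: one Bernoulli quit draw per patient, then per-cycle Bernoulli
transitions with the same rewards and discounting as the cohort engine.
Patient i's uniforms occupy row i of a `(n, T+2)` array (quit draw, one
transition draw per cycle, rehabilitation draw), so trajectories depend
only on `(seed, i)` and enlarging n never reshuffles earlier patients. By
the law of large numbers its means converge to the cohort expectations at
rate 1/√n; the test suite verifies agreement within 4 standard errors at
n = 10⁵–2×10⁵, on the base case and on 20 random valid parameter sets
drawn by `generate_parameter_set`. The microsimulation shares the
parameter derivation code with the cohort engine but none of the
expectation algebra, which is what makes it a useful cross-check; what it
cannot detect is an error in a convention both engines implement (e.g. a
wrong discount exponent applied identically in both).

What the synthetic generator emulates — and does not. Random parameter
sets are drawn uniformly and independently within the deterministic
sensitivity ranges; real parameter uncertainty is correlated (costs move
together with wages) and the utilities of worse states can in reality
never exceed better ones, which independent draws do not enforce. Passing
the equivalence tests therefore demonstrates the engines agree across the
plausible input region, not that the inputs themselves are jointly
realistic.

## Reproducibility and problem sizes

All randomness flows through `numpy.random.default_rng(seed)`; pipeline
reruns with the same config and seed are byte-identical (no timestamps in
any output; CSV numbers carry 6 significant digits, JSON full precision).
The default analysis sizes — 1000 PSA iterations, 10⁵ microsimulated
patients, a 0–1000 US$ CEAC grid in steps of 10 — are the package's
defaults for routine runs; all are parameters.

## Known limitations

* The published aggregate results table prints 30-year effectiveness
  values (55.18 tooth-years, 49.07 QALYs) that exceed the ceiling of 30
  attainable when every cycle contributes at most 1 (discounted), so the
  original software's reward-accumulation convention cannot be recovered
  and the package's absolute effect scale differs from the printed one.
  Consequences that depend on that scale (ICER magnitudes, CEAC
  percentages at a given willingness-to-pay) differ correspondingly; the
  directional findings (dominance of therapy in undiscounted terms, the
  north-east concentration of PSA draws) are preserved and tested.
* At the 5% base discount rate the modelled therapy arm is slightly more
  costly (ΔC ≈ +US$40), not cost-saving as the printed deterministic
  table claims — but consistent with the *probabilistic* means printed
  alongside it, which also show positive incremental cost. The dominance
  direction asserted by the tests is therefore evaluated undiscounted.
* No smoking relapse, no repeat SCT, one tooth per patient, no mortality,
  no patient heterogeneity — structural choices inherited from the model
  being implemented.
* PSA draws are independent across parameters; no correlation structure
  or expected-value-of-information analysis is provided.
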