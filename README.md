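# perioecon

A Markov cohort cost-effectiveness and cost-utility model of implementing
smoking-cessation therapy (SCT) in smokers with periodontitis, from the
Brazilian public-health-system perspective.

Smokers respond worse to periodontal treatment and lose more teeth.
Offering cessation therapy (cognitive-behavioural counselling plus
nicotine replacement and bupropion) raises the one-year quit probability
from 0.07 to 0.30; quitters need fewer maintenance sessions and face a
lower tooth-loss risk. `perioecon` quantifies whether the upfront cost of
therapy is offset by downstream savings and health gains, for health
economists and oral-health researchers who want a tested, reusable,
config-driven implementation rather than a spreadsheet or a proprietary
decision-tree package.

## The model

A decision tree (SCT vs. no SCT; quit vs. continue, no relapse) feeds
three-state Markov cohorts in annual cycles over 30 years:

```
MAINTENANCE  --p-->  LOST_NO_REHAB   (absorbing)
     |        \----> LOST_REHAB      (absorbing)
     p_loss = RR_stratum x p_nonsmokers,  split by p_no_rehab = 0.09
```

with `p_nonsmokers = 0.003` (a pooled annual proportion), `RR = 1.15`
(former) / `2.16` (current smokers). Per-cycle maintenance costs differ by
smoking status; extraction and rehabilitation are one-off event costs;
utilities come from a linear OHIP-score mapping (`u = 1 − OHIP/OHIP_max`).
Costs and effects are discounted at 5%/year. Outcomes per arm are expected
cost (PPP-US$), expected tooth-retention cycle-years (CEA) and expected
oral-health QALYs (CUA); incremental results are classified on the CE
plane (dominant / dominated / trade-off with ICER = ΔC/ΔE). One-way
(tornado) and probabilistic (1000-iteration Monte Carlo) sensitivity
analyses feed quadrant probabilities and cost-effectiveness acceptability
curves via the net-monetary-benefit rule `NMB = λ·E − C`. An
individual-level microsimulation with identical conventions serves as an
independent oracle for the cohort engine. See `docs/methods.md` for
conventions, assumptions and limitations.

## Worked example

```python
import perioecon as pe

ps = pe.load_parameter_set()            # shipped base-case config
inputs = ps.to_model_inputs()
sct = pe.arm_expected_values(inputs, "SCT")
no  = pe.arm_expected_values(inputs, "NO_SCT")
print(pe.incremental_analysis(sct, no, "effect").to_dict())
```

prints

```
{'delta_cost': 39.94224465442858, 'delta_effect': 0.1181520841589645,
 'classification': 'TRADEOFF_NE', 'icer': 338.0578932546748,
 'effect_measure': 'effect'}
```

i.e. at the 5% discount rate the therapy arm costs US$ 39.94 more over 30
years, preserves 0.118 additional discounted tooth-years, and buys a tooth-
loss-avoided-equivalent at US$ 338. Undiscounted, the sign flips and the
therapy dominates (ΔC = −US$ 138.36, ΔE = +0.295): the therapy's cost is
paid at entry while its savings accrue over decades, so the discount rate
decides whether it is cost-saving or merely cheap.

The same pipeline from the shell:

```bash
perioecon run --analyses base_case,dsa,psa,ceac --iterations 1000 \
    --seed 2021 --out outputs/
perioecon validate          # config invariant report (JSON)
perioecon microsim --n 100000 --seed 7
perioecon pool studies.csv --model random_effects
```

`outputs/` then holds arm results and incremental JSONs, per-stratum trace
CSVs, the tornado table, PSA samples, quadrant probabilities, CEAC curves
and a manifest; reruns with the same config and seed are byte-identical.

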