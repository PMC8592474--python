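# switchweight

Weighted log-rank testing and power studies for confirmatory survival trials
with a high proportion of **treatment switching**.

## The problem

In oncology phase III trials, control-arm patients often cross over to the
experimental drug after disease progression (for ethical reasons). Switching
leaves progression-free survival untouched but dilutes the intention-to-treat
contrast on overall survival (OS): as switched patients accumulate in the
control arm, the hazard ratio η(t) = h₁(t)/h₀(t) drifts towards 1 and the
standard log-rank (LR) test loses power — adding events past a certain point
actually *decreases* power.

`switchweight` implements a **modified weighted log-rank test (mWLR)** whose
weights are pre-specified at the design stage from a closed-form switching
model, so that late (diluted) events are down-weighted:

```
w(t) = −log η(t)
```

The hazard-ratio function η(t) comes from an exponential
progression-switching model parametrised by clinically interpretable
quantities: the median OS of each arm (m₀ᴼˢ, m₁ᴼˢ), the control-arm median
PFS (m₀ᴾᶠˢ), and the assumed probability p′ that a control patient switches
immediately after progression. Control patients move through three Markov
states — not progressed, progressed-and-switched, progressed-not-switched —
with exponential transition rates λ = log 2 / median; switchers adopt the
experimental death hazard λ₁ᴼˢ. The state occupation probabilities have a
closed-form solution, yielding

```
h₀(t) = [λ₀ᴼˢ·(Sⁿᵖ + Sᵖⁿˢ) + λ₁ᴼˢ·Sᵖˢ] / S₀(t),      η(t) = λ₁ᴼˢ / h₀(t).
```

With p′ = 0 the weights are constant and mWLR coincides exactly with the
standard LR test. Because the weights are deterministic functions of time
fixed before unblinding, the test preserves the one-sided type-I error.

The package also provides, on the same risk-table core: the unweighted
log-rank test, Fleming–Harrington G(ρ,γ) weighted tests, the Max Combo test
(maximum of the four FH components referred to their joint multivariate
normal null), and the RMST-difference test with minimax truncation — plus a
patient-level trial simulator (uniform accrual, post-progression switching,
analysis at a target death count) and a power/relative-efficiency study
engine with common random numbers.

## Worked example

Simulate one trial shaped like a renal-cell-carcinoma study — 139 control vs
277 experimental patients, 12-month uniform accrual, analysis at the 221st
death, true medians 10/15 months OS and 2 months control PFS, every control
patient switching at progression — and test it:

```python
import numpy as np
import switchweight as sw

medians = sw.ClinicalMedians(m0_os=10, m1_os=15, m0_pfs=2, p=1.0)
config = sw.ScenarioConfig(medians=medians, n0=139, n1=277,
                           accrual_months=12, target_deaths=221, seed=2)
rng = np.random.default_rng(np.random.SeedSequence(entropy=2, spawn_key=(0,)))
trial = sw.simulate_trial(config, rng)

design = sw.rates_from_medians(medians)          # p' = p = 1 here
print(sw.mwlr(trial.sample, design))
print(sw.logrank(sw.build_risk_table(trial.sample)))
```

```
test: mwlr
u: 2.3776
v: 1.1589
z: 2.20859
p_one_sided: 0.0136015
p_prime: 1
lam0_os: 0.0693147
lam1_os: 0.0462098
lam0_pfs: 0.346574
test: lr
u: 10.0842
v: 47.7656
z: 1.4591
p_one_sided: 0.0722685
```

On this replicate the down-weighted test rejects at one-sided α = 0.025
(p = 0.014) while the standard log-rank test does not (p = 0.072): the late
events, mostly contributed by switched control patients, carry almost no
weight. The weight starts at −log(10/15) ≈ 0.405 and decays towards 0 as
the surviving control arm becomes dominated by switchers.

Power and efficiency over replicated trials (common random numbers — every
test sees the same simulated trials):

```python
import dataclasses
study = dataclasses.replace(config, n_sims=2000)
results = sw.run_replicates(study, [sw.TestSpec("lr"),
                                    sw.TestSpec("mwlr", p_prime=1.0)])
print(results.power("lr").power, results.power("mwlr(p'=1.0)").power)
print(results.efficiency("lr", "mwlr(p'=1.0)").efficiency)
```

```
0.136 0.2365
207.96350499060404
```

The relative efficiency
`100·[(z₁₋α + Φ⁻¹(power_mWLR)) / (z₁₋α + Φ⁻¹(power_LR))]²` approximates the
sample-size ratio needed for equal power; values above 100% favour mWLR.
Here the weighted test turns a 13.6% log-rank power into 23.7% — roughly
the gain of doubling the sample size.

The same machinery is available from a shell:

```sh
switchweight simulate --config scenario.yaml --out trial.csv
switchweight test --data trial.csv --method mwlr --p-prime 1 \
    --m0-os 10 --m1-os 15 --m0-pfs 2
switchweight power --config study.yaml
switchweight grid --config grid.yaml --out grid.csv
```

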