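# Methods

This note documents the models, numerical choices and simulation design
behind `switchweight`, and what the test suite does and does not establish.

## The switching model

A control-arm patient is, at time t since randomisation, in one of four
states: not yet progressed (np), progressed and switched to the experimental
drug (ps), progressed not switched (pns), or dead. All transitions are
exponential: progression at rate λ₀ᴾ, death at rate λ₀ᴼˢ from the np and pns
states and λ₁ᴼˢ from the ps state (a switcher adopts the experimental death
hazard from the moment of progression). Immediately after progression the
patient switches with probability p. Rates come from medians via
λ = log 2 / m; the PFS hazard is the sum of its competing components,
λ₀ᴾᶠˢ = λ₀ᴾ + λ₀ᴼˢ, so the progression rate is derived as
λ₀ᴾ = log 2 / m₀ᴾᶠˢ − log 2 / m₀ᴼˢ (which is why m₀ᴾᶠˢ < m₀ᴼˢ is enforced).

The state occupation probabilities solve a linear ODE system in closed form;
`control_survival` is their sum, and because deaths flow out of np/pns at
λ₀ᴼˢ and out of ps at λ₁ᴼˢ,

    h₀(t) = [λ₀ᴼˢ·(Sⁿᵖ + Sᵖⁿˢ) + λ₁ᴼˢ·Sᵖˢ] / S₀(t).

The experimental arm is plain exponential, h₁ ≡ λ₁ᴼˢ, so the hazard-ratio
function is η(t) = λ₁ᴼˢ/h₀(t) and the mWLR weight is w(t) = −log η(t).
Useful identities used as test anchors: h₀(0) = λ₀ᴼˢ, η(0) = m₀ᴼˢ/m₁ᴼˢ,
q = P(ever switch) = (1 − m₀ᴾᶠˢ/m₀ᴼˢ)·p, and invariance of w under a common
rescaling of all medians and times. With p = 0 the model is proportional
hazards, the weights are constant, and mWLR is exactly the log-rank test.

Assumptions worth keeping in mind: switching happens only at progression and
instantaneously; the switch benefit is a full adoption of λ₁ᴼˢ (no partial or
delayed effect); progression in the experimental arm is irrelevant to the
model and is not simulated; all components are exponential (the Weibull
variant below is a robustness device for the *simulator*, not a second
weight model).

## Numerical choices

- **Removable singularity.** The switched-state solution has the factor
  (e^(−λ₁ᴼˢt) − e^(−λ₀ᴾᶠˢt)) / (λ₀ᴾᶠˢ − λ₁ᴼˢ). When
  |λ₀ᴾᶠˢ − λ₁ᴼˢ| < 1e−10·λ₀ᴾᶠˢ the analytic limit p·λ₀ᴾ·t·e^(−λ₀ᴾᶠˢt) is
  used; in a band |Δ·t| < 0.5 around it the difference is evaluated with
  `expm1` to avoid cancellation. Verified against adaptive ODE integration
  (rtol 1e−11) to 1e−8 absolute, including at and near the singular
  configuration.
- **Large times.** The hazard is a ratio of sums of decaying exponentials;
  both are evaluated with the slowest *present* decay rate factored out, so
  h₀(1000 months) is finite instead of 0/0.
- **Variance term with one patient at risk.** The hypergeometric variance
  factor contains (n_j − 1) in the denominator; rows with n_j = 1 contribute
  zero (a lone patient carries no between-arm information).
- **Censoring ties.** A patient censored exactly at an event time is kept in
  the risk set at that time (deaths-before-losses). The simulator produces
  continuous times, so this matters only for hand-built fixtures.
- **Direction convention.** The score is positive when the control arm has
  more deaths than expected; the one-sided p-value is the upper normal tail,
  rejecting when the experimental arm looks better, at α = 0.025 throughout.
- **Max Combo.** Components are the Fleming–Harrington (0,0), (1,0), (0,1),
  (1,1) statistics; their null correlation is estimated from the pairwise
  covariances Σ w⁽ᵃ⁾w⁽ᵇ⁾v_j, and the p-value is the exact joint upper tail
  1 − P(all Z ≤ z_max) of the 4-variate normal, not a Bonferroni bound.
  The cdf uses a randomised lattice with a fixed seed and 25k points
  (~2e−4 absolute accuracy, measured against a 4×10⁶-point evaluation), so
  results are deterministic. A non-positive-definite correlation estimate is
  repaired by eigenvalue clipping with a logged warning. Note: at the
  reference trial size the max-of-four statistic is very slightly
  anti-conservative (measured one-sided level ≈ 0.028 over 25k null
  replicates) — a finite-sample property of the maximum with estimated
  correlations, shared by standard implementations of the combination test.
- **RMST.** Per-arm restricted mean is the area under the Kaplan–Meier step
  function on [0, τ]; the variance is the Greenwood-type sum
  Σ (∫_{t_j}^{τ} Ŝ)² d_j / (n_j(n_j − d_j)), matching R's `survival`
  (`summary(survfit, rmean=τ)`) to 1e−6 on fixtures. The default truncation
  is the minimax observed time: the smaller of the two arms' largest
  observed times. Terms with an exhausted risk set are dropped with a
  warning.
- **Efficiency at boundary powers.** Φ⁻¹ diverges at 0 and 1, so power
  estimates are clamped to (0.5/M, 1 − 0.5/M) with a logged warning.
  Efficiencies are reported with a delta-method standard error propagated
  from the two binomial power estimates.

## The trial simulator

The simulator emulates a two-arm superiority trial shaped like a metastatic
renal-cell-carcinoma study: 139 control / 277 experimental patients (2:1),
uniform accrual over 12 months, and analysis at the calendar time of the
221st death; the reference medians are 15 months experimental OS, 2 months
control PFS, and 5–10 months for the (unobservable because of switching)
control OS. These are the package defaults; the true switching probability
p and the design value p′ are scenario parameters.

Control patients draw independent progression and death times; if
progression comes first the patient switches with probability p and the
death time is re-drawn beyond the switch time under the experimental hazard
(memoryless for the exponential). Experimental patients draw a single death
time, and are drawn *before* the control stream so their latent times do not
depend on p. Event-free patients are censored at cutoff − entry; the rare
patient enrolled after the cutoff is excluded. Event indicators are decided
on the calendar scale, where the comparison with the cutoff (itself a
calendar death time) is exact, so the analysis always contains exactly the
target number of deaths.

For the Weibull robustness variant (shape k in 0.5–1.5), every scale is set
from its median, scale = m/(log 2)^(1/k), and the progression "rate" in the
S(t) = exp(−ρ t^k) parametrisation is again ρ₀ᴾ = ρ₀ᴾᶠˢ − ρ₀ᴼˢ, so PFS keeps
its median by construction. The switch mechanism off-exponential is a
genuine modelling choice: at switch time s the residual death time is drawn
from the experimental Weibull conditional on exceeding s (hazard adoption on
the shared time axis), which reduces to the memoryless re-draw at k = 1.

What the simulator does **not** emulate: dropout other than administrative
censoring, non-uniform accrual, delayed or calendar-time-dependent
switching, switching outside progression, and cure fractions. Passing tests
therefore show calibration and power *under the model's own assumptions*;
they do not certify behaviour under informative censoring or delayed
switch benefit.

## The study engine

Replicate i of a scenario uses an independent RNG substream derived from
(seed, scenario index, i), so grids are reproducible and order-independent,
and every test sees the same simulated trials (common random numbers). This
couples the tests: mWLR with p′ = 0 produces the identical rejection
indicator as the log-rank test replicate by replicate, and paired
comparisons (p-value dominance, power differences across event counts) are
exact couplings rather than independent contrasts. Published comparisons of
this kind may have used independent streams; CRN only reduces the variance
of differences, not the estimands.

Monte-Carlo sizes used: 10⁴ replications per scenario in the acceptance
script (binomial 95% half-width at most ±1.0 percentage point) and 2,000 in
the acceptance-level tests; unit tests use down-scaled trials (tens of
patients, tens of replicates). The null-calibration check runs 10⁴
replicates of a null where both arms follow the experimental distribution
while the mWLR weights are built from the usual (non-null) design anchors —
the weights are a deterministic function of time, so the level is preserved
regardless of p′.

## Known limitations

- The mWLR weight function is only as good as the design anchors; with
  p′ = 1 and little true switching the test is noticeably less efficient
  than the log-rank test (efficiency ≈ 88% at p = 0 for p′ = 0.7). The
  robust recommendation explored in the studies is p′ ≈ 0.7.
- The weights decay quickly under heavy switching (w(10 months) ≈ 0.03 for
  the reference model at p′ = 1), so the effective information is
  concentrated in early events; the mWLR and LR statistics are then only
  moderately correlated (≈ 0.74 in the reference scenario), and on a
  sizeable minority of replicates the log-rank p-value is smaller even when
  mWLR is more powerful on average.
- Max Combo's small anti-conservatism at moderate event counts (above) and
  the normal approximation to the rank statistics are untreated higher-order
  effects.
- The average-hazard-ratio estimate that a weighted test implicitly
  corresponds to is not implemented; the package is about testing, not
  effect estimation under non-proportional hazards.
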