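# Methods

This note documents the models, estimators and numerical choices behind
`enrichjm`, in the package's own terms.  Everything quantitative stated
here is recomputed by the test suite or by `scripts/acceptance.py`.

## 1. The working joint model

For patient *i* in subgroup *j* ∈ {1, 2} (prevalence λ of subgroup 1 in
the full population F):

- latent trajectory `X(v) = b0 + b1·v` with `(b0, b1)` bivariate normal,
  per-subgroup mean `(μ0_j, μ1_j)` and covariance `[[φ1, φ12], [φ12, φ2]]`;
- observed biomarker `D(v) = X(v) + ε`, `ε ~ N(0, σ²)` independent across
  visits;
- hazard `h(t) = h0_j(t)·exp(γ_j·X(t) + θ_j·ψ)` with treatment indicator
  ψ and piecewise-constant baseline hazard (`c_j1` up to one year, `c_j2`
  after).

Default parameter values are a metastatic-breast-cancer calibration
(ctDNA-like trajectories, HER2-defined subgroups): λ = 2/3,
γ = 0.8, σ² = 0.25, (φ1, φ12, φ2) = (2.5, 1.7, 5),
(μ0, μ1) = (4.23, 1.81), c₁ = 0.0085, c₂ = 0.0142 per year.  θ is on the
log-hazard scale, negative = benefit; the design alternative sets
θ1 = −0.5, θ2 = 0.

### Simulation details

- **Time unit** years; week = 7/365.25 y; a scheduling "month" is four
  weeks.
- **Recruitment** deterministic at 2 patients/week; 1:1 allocation by
  alternation within subgroup (zero allocation noise); subgroup membership
  Bernoulli(λ).
- **Visit schedule** entry visit plus every 2 weeks through week 12, then
  every 4 weeks.  The entry visit is included because the prefix
  least-squares fit needs two early measurements before a subject can
  enter risk sets.
- **Event times** by inversion of the cumulative hazard.  Within a
  constant-hazard piece, `H(t) = A·c·(e^{κt} − 1)/κ` with `κ = γ·b1`, so
  inversion is a logarithm per piece, with the linear limit at κ → 0.
  When κ < 0 the total hazard is bounded and a draw can be +∞ (a cure
  fraction; about 12–15% of subjects at the default parameters).  The
  probability-integral-transform and cure-frequency tests pin this down.
- **Loss to follow-up** is exponential and independent of the event
  process.  The default rate 0.0832/year is calibrated (by deterministic
  bisection on one large set of latent event draws) so that ~10% of
  subjects are lost before min(event, 3 years) under the null parameters.
  The 3-year anchor is needed because the cure fraction makes "lost before
  the event" unattainable as a literal target: cured subjects are always
  lost first, whatever the rate.  Any other rate can be set directly on
  `JointModelParams.censor_rate`.
- **Snapshots** administratively censor every subject at the calendar
  time at which a pre-specified event count is reached in a trigger
  population; retained measurements never post-date the observed time.
- One `numpy` Generator drives a whole-trial simulation in fixed-order
  vectorised blocks, so a (seed, n_patients) pair reproduces the trial
  bit-for-bit.

What the generator does *not* emulate: non-linear or treatment-dependent
trajectories, informative dropout, measurement batch effects, delayed or
clustered recruitment, unknown λ.  Passing tests therefore show that the
machinery is correct under the stated working model, not that the design
is robust to violations of it.

## 2. Conditional-score estimation

Per subgroup and analysis, the treatment effect is the root of the
conditional score: each subject's latent `X(t)` is replaced by the prefix
OLS prediction `Xhat(t)` (measurements at or before *t*), and the
sufficient statistic `S(t) = Xhat(t) + γσ²·lev(t)·dN(t)` conditions the
measurement error out, where `σ²·lev(t)` is the OLS prediction variance.
Risk sets require the second measurement by *t* (subjects dying earlier
never contribute).  σ² is estimated by pooling full-prefix OLS residual
sums of squares with (m − 2) degrees of freedom over subjects with at
least three retained measurements.

Numerics: damped Newton on (γ, θ) from (0, 0) with restarts from
θ = ±0.5; convergence ‖U‖∞ < 10⁻⁸·d; central-difference Jacobian with
step 10⁻⁵·max(1, |x|).  Roots with |γ̂| or |θ̂| > 8 are rejected as
spurious (the risk-set weights degenerate far from the truth and create
fake roots, especially below ~20 events).  Ties in event times cannot
occur in simulated data; file-based input is processed in subject order
(Breslow-style handling in the comparators).

### Information estimation

The information `I = 1/Var(θ̂)` comes from the sandwich
`n·[A⁻¹ B A⁻ᵀ]₂₂⁻¹` with A the per-patient-averaged numeric Jacobian.
For B = Var(U)/n three estimators were evaluated against replicate truth
(the observed variance of θ̂ over hundreds of simulated datasets, and of
U at the true parameters):

- the first-order influence decomposition (own event term minus the
  subject's weighted share of every risk-set average) *understates*
  Var(U) — by ~8% at σ² = 0.25 and 20–25% at σ² = 2.25 — because the
  exponential risk-set weights are heavy-tailed lognormals whose
  contribution a linearisation misses;
- a multiplier bootstrap over subjects is lower still (the tail events
  are under-sampled in a typical dataset);
- a **delete-one-group jackknife** (G = 40 groups, the full nonlinear
  score re-evaluated per deletion, averaged over random partitions)
  tracks the replicate truth and errs slightly conservative, which is the
  safe direction for error-rate control.

The jackknife is therefore the default (`b_method="jackknife"`); since
the risk-set weights do not change across deletions, all G deleted scores
of a partition follow from two matrix products, so many partitions are
averaged at negligible cost (10 by default, 20 during design
calibration).  The influence estimator remains available
(`b_method="influence"`), and is used by one diagnostic test as a
low-variance probe of the information-vs-events proportionality.

The standardised statistic is `Z = −θ̂·√I`, so hazard *reduction* maps to
large positive Z; all drifts in the design layer are on this
benefit-positive scale.  Full-population quantities combine the subgroup
fits: `θ̂_F = λθ̂1 + (1−λ)θ̂2`, `I_F = (λ²/I1 + (1−λ)²/I2)⁻¹`.

## 3. Comparator analyses

- **Plain Cox**: treatment-only partial likelihood, all subjects
  eligible, observed information at the root.  Under the null with 1:1
  allocation it reproduces the classical ~4 events per unit information.
  Its estimand is the attenuated marginal hazard ratio, which is why it
  loses power when γ ≠ 0 even though it accrues *more* information per
  event.
- **Cox with time-varying covariate**: partial likelihood in (γ, θ) with
  the observed biomarker carried forward (LOCF) to risk-set times; linear
  interpolation and the prefix-OLS prediction are available as options.
  The OLS-covariate variant is the exact σ² = 0 limit of the conditional
  score, which the tests exploit as a dual-route check; the LOCF variant
  is cross-checked against an independent counting-process implementation.

## 4. Design computation

**Threshold rule.**  With independent interim statistics and the
alternative (effect δ in subgroup 1, none in subgroup 2), the selection
targets give closed forms: ζ = Φ⁻¹(p1/(p1+pF)),
I1(1) = ((ζ + Φ⁻¹(p1+pF))/δ)².  At the default targets (0.6, 0.2) and
δ = 0.5: ζ = 0.6745, I1(1) = 9.194.

**Joint selection densities.**  For w = 1, 2 the density of the selected
statistic is a weighted truncated normal (zero at or below ζ).  For
w = F, Z_F = c1·Z1 + c2·Z2 with c_j² summing to 1; the density restricted
to both components clearing ζ is evaluated in closed form through the
conditional normal law of c1·Z1 given Z_F, and validated against
Monte-Carlo histograms and the product-tail normalisation.  The futility
index carries the constant mass P(W = ∅) and deliberately has no
z-density; passing it to an integral raises an error.  Futility-stopped
trials reject nothing, so the ∅ term is excluded from all rejection
sums; FWER exactness is preserved because the boundaries are solved
against the remaining mass.

**Error spending and boundaries.**  α and β are spent as
min(total·t², total) in the full-population information fraction.  The
stage-2 equations integrate the conditional CJD tail against the stage-1
joint density (the conditional probability alone is not a probability of
a trial event; the stage-1 density weight is required).  Because power is
*conditional on selecting subgroup 1*, the type-2 targets are rescaled by
P(W=1; alternative) before being matched against the unconditional joint
density — without this normalisation the planned total event count for
the base calibration comes out ~15% below its reference value (206 events), with it
~2% above.  Quadrature is fixed-order Gauss–Legendre (160 nodes, exact to
well below the 10⁻⁸ solver tolerance for these smooth integrands), tails
truncated at ±8; boundary equations are solved by Brent's method to
10⁻¹⁰.

**Event-count planning.**  Information is empirically proportional to
the observed event count, I ≈ d/m.  The constants m are calibrated by
simulating datasets of 5000 patients under the design alternative,
progressively right-censoring each at ~30 calendar quantiles of the event
times up to the 300th subgroup-1 event (the operating range of the
design), fitting the analysis method at every cut, and regressing I on d
without intercept; m̂ = 1/slope.  Cuts with fewer than 20 events are
skipped and grossly outlying points dropped (failed variance estimates);
constants are averaged over 8 replicate datasets, leaving a relative
error of ~2–3% on m.  Event counts are always on the *trigger* scale
(all observed events), matching how analyses are timed.  The calibrated
constants satisfy m1 ≈ m2 ≈ mF (information per event is a property of
the estimator, not the subgroup size); interim event counts across
populations then follow the prevalence ratios
d2(1) = (1−λ)·d1(1)/λ, dF(1) = d1(1)/λ.

**Imax.**  Given d1(1) = ⌈m1·I1(1)⌉ and the planning information
sequence Ĩ_j(k), the maximum information solves a2 = b2 by bisection
(tolerance 10⁻⁴), and d(2) = ⌈mF·Imax⌉.  Infeasible spends encountered
while bracketing are mapped to the appropriate sign rather than raised.

## 5. Trial execution

Interim at d1(1) events in subgroup 1 → per-subgroup fits → threshold
selection → early stop against the planned (a1, b1) → if continuing,
stage-2 informations are forward-predicted from *realised* interim
information and event counts (I(2) = d(2)·I(1)/d(1)), the interim spend
is recomputed at the realised information fraction and the final boundary
re-solved → final snapshot at d(2) events in the selected population →
reject iff Z_w(2) > b2.  Only the selected hypothesis is ever tested.

Because the second analysis is terminal, *all remaining* type-1 and
type-2 error is spent there (the information fraction shapes only the
interim spend), the standard convention for fixed-K error-spending tests.
Spending the literal quadratic fraction at the final analysis instead
would leave error unspent whenever the predicted final information
undershoots Imax — which it systematically does here, by ~10%, because
the variance estimator is conservative at interim-sized event counts —
and costs 4–5 points of power (measured 0.85–0.86 against the 0.90
target, versus 0.90–0.91 under the terminal-spend convention, which also
restores the planning identity a2 = b2).  Replicates
whose fits fail are counted and reported, never silently dropped (an
error is raised beyond 5%).  Per-replicate child seeds derive from the
root seed, so different analysis methods see identical trials.

Default replication for operating characteristics is 500 trials of 1000
patients (binomial standard errors ~0.007 at the null rate); the
acceptance script uses these sizes, and all estimates carry their
Monte-Carlo standard errors.

## 6. Known limitations

- The conditional score can fail to find a root, or find only spurious
  ones, when events are few and σ² is large; the planner's 20-event floor
  and the root bound handle this, but designs with interim counts near 20
  events per subgroup should be treated with caution.
- The jackknife information is mildly conservative (a few percent high on
  m), which propagates into slightly conservative FWER and slightly more
  events than the idealised design would need.
- I = d/m is an approximation with mild curvature (information per event
  grows a few percent from 50 to 300 events); calibrating over the
  design's operating range absorbs most of it.
- The CJD across analyses holds only approximately for the conditional
  score; the empirical checks (correlation structure, FWER, power) bound
  the deviation at the default scales but say nothing about very small
  event counts.
- λ is assumed known; mis-specifying it biases both the combination and
  the planned event ratios.
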