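# Methods

`castsim` simulates Bayesian adaptive designs for a four-arm randomised
controlled trial of ankle-sprain treatments (control: tubular bandage;
interventions: Bledsoe boot, Aircast brace, below-knee cast), with the
12-week Foot and Ankle Outcome Score quality-of-life subscale (FAOS QoL,
0–100 points) as the primary outcome. This note records the model, the
design rules, the numerical choices, and the known limitations.

## Outcome model

Observed outcomes in arm *t* are modelled as

y_it | θ_t, σ² ~ N(θ_t, σ²),  θ_t ~ N(50, 20²) independently per arm,
σ² ~ Inverse-Gamma(α = 0.5, β = 200),

one variance shared across the four arms. The prior on each mean is weakly
informative (location 50 FAOS points, SD 20, i.e. roughly one patient's worth
of information); the variance prior centres σ² at 20² with the weight of a
single observation (β/α = 400). Outcomes are simulated as untruncated
normals even though the FAOS lies in [0, 100]: with means near 50–65 and SD
20, less than ~1% of mass falls outside the scale and no truncation rule is
part of the design.

**Sampling.** The model is semi-conjugate. The default sampler draws σ² from
its exact one-dimensional marginal posterior — the arm means integrate out
analytically, leaving a density evaluated on a 240-point log-spaced grid
spanning at least ±8 marginal standard deviations (inverse-CDF sampling with
linear interpolation in log σ²) — and then draws each θ_t from its exact
conditional normal. The draws are therefore i.i.d. joint posterior samples:
no burn-in, no autocorrelation, and roughly an order of magnitude faster
than MCMC, which matters because one operating-characteristics run performs
hundreds of thousands of posterior updates. A two-block Gibbs sampler
(θ | σ² conjugate normal, σ² | θ conjugate inverse-gamma) over the same
model is kept as `method="gibbs"` and serves as an independent cross-check
in the test-suite; with σ² held fixed, both reduce to the conjugate
normal–normal closed form, which the tests verify to Monte Carlo error.

**Decision functionals.** All interim decisions reduce to two posterior
probabilities estimated from the joint draws: `prob_best` (the fraction of
draws in which an arm's mean is the strict maximum of a candidate set; exact
ties, a measure-zero event, go to the lowest-indexed arm so probabilities
sum to one) and `prob_margin` (the fraction of draws in which one arm
exceeds another by a margin; margin 8 is the minimal clinically important
difference, margin 0 plain superiority). With the default 5,000 draws per
analysis, the Monte Carlo standard error of a mid-range decision probability
is about 0.007 — small against decision thresholds spaced 0.05–0.10 apart.

**Baseline adjustment.** For re-execution analyses the model extends to
y_i = θ_arm(i) + b·(x_i − median(x)) + ε with a common slope b ~ N(0, 10²),
x the baseline FAOS score centred at its pooled median (the centring used in
the original trial's analysis). Sampling is two-block Gibbs (all
coefficients jointly conjugate given σ², then σ² conjugate inverse-gamma);
θ draws are arm means at the median baseline. Operating-characteristic
simulations omit the baseline covariate: the scenario grid specifies only
12-week means, and no baseline distribution or slope is part of the design
specification (see Limitations).

## The six designs

| design | adaptation (per 50 due) | control allocation | early stopping |
|---|---|---|---|
| 1 | none | equal | none |
| 2 | none | equal | per 200 due |
| 3 | arm dropping | equal among remaining | per 200 due |
| 4 | RAR | matched to best intervention | per 200 due |
| 5 | RAR | fixed at 40% | per 200 due |
| 6 | RAR over all four arms | none designated | per 200 due |

Response-adaptive randomisation raises each candidate arm's best-arm
probability to the power γ = 0.6 (damping extreme allocations) and
renormalises. The control policy then applies: *matched* sets the control
probability equal to the largest intervention probability and renormalises
everything; *fixed* pins the control at exactly 0.40 with interventions
sharing 0.60 proportionally; design 6 treats the control as a fourth
candidate. Arms whose resulting probability falls below 0.1 are suspended
(probability zero, reversible — they re-enter the candidate set at every
analysis) and the survivors are renormalised; the suspension test is
iterated to a fixed point, guarding the edge case where renormalisation
pushes a second arm below threshold (a single-pass variant is available by
flag). Design 3 instead drops an intervention permanently when its
probability of being the best intervention falls below 0.10; the control
can never be dropped, and the remaining arms revert to equal allocation.

Designs 2–5 stop early for efficacy at 200/400/600 patients due when
Pr(θ_best − θ_control > 8) exceeds 0.75/0.70/0.60 respectively *and* the
best intervention's best-arm probability exceeds 0.9; they stop for
futility when Pr(θ_best > θ_control) < 0.05, and succeed at the final
analysis when Pr(θ_best − θ_control > 8) > 0.5 (strict). "Best
intervention" is resolved per analysis as the intervention with the highest
current best-arm probability, computed over the full intervention set: a
dropped arm's posterior is frozen (no new data accrue) but it stays in the
maximum, exactly as the named-arm form of the decision rules reads —
dropping removes allocation, not the arm's posterior. (Restricting the
candidate set to active arms makes the best-arm gate trivially 1.0 once two
arms are dropped and visibly inflates design 3's early stopping.) Design 6
uses the maximum
best-arm probability over all four arms: futility below 0.1, efficacy above
0.975/0.95/0.925 at the three checks, success above 0.9 at the final
analysis. A trial is counted successful if it stops early for efficacy or
meets its final rule; futility stops are failures. The declared best arm is
always the active arm with the highest best-arm probability at the final
posterior, whether or not the trial succeeded.

The 600-due check runs whenever 600 patients come due, even though the
maximum sample size (643) has usually been fully randomised by then at the
default recruitment rate — such stops save no patients but count as early
efficacy stops, which is what the aggregate stopping proportions and mean
sample sizes of the reference design study imply.

## Trial engine

Patients arrive from an inhomogeneous Poisson process whose intensity rises
linearly from 0 to the steady rate (default 5/week; 25 and 56 supported)
over a 12-week ramp, simulated by inverting the cumulative intensity; a
deterministic equal-quantile spacing option exists for variance-reduction
checks. Each patient is randomised on arrival from the prevailing
allocation state (independent draws by default; permuted blocks of twice
the number of active arms by flag, meaningful for the equal-allocation
designs), drops out with probability 0.20 (randomised, counted in N and in
the patients-due clock, but contributing no outcome), and otherwise yields
a normal outcome at exactly 12 weeks after enrolment.

Because the follow-up lag is constant, the m-th patient due is the m-th
enrolled, so the analysis scheduled at m patients due fires at enrolment
time of patient m plus 12 weeks and sees exactly the non-missing outcomes
of the first m patients — the engine asserts this no-peeking property and
it is tested on trajectories. Equal randomisation applies before the first
interim. On a stop verdict, enrolment halts immediately; patients already
randomised are followed to outcome and enter the final posterior (and the
declared-best-arm selection) but trigger no further decisions. Without a
stop, the trial randomises to the cap of 643 and the final analysis uses
every non-dropout outcome.

## Operating characteristics

`run_replicates` simulates independent trials with counter-derived seed
streams (`SeedSequence(base_seed, spawn_key=(i,))`), so any single replicate
is reproducible in isolation and aggregation is order-independent. Reported
per design × scenario cell: success probability (type I error when no arm
beats control in truth, power otherwise), efficacy/futility/max-N stop
proportions (which partition the replicates), mean and SD of the randomised
sample size, mean per-arm allocation proportions (per-replicate N_arm/N,
averaged; the denominator is the count randomised at stop), mean square
error of the declared-best-arm posterior mean against that arm's true mean
over successful replicates only (NaN when none succeed), and the
correct-selection rate (declared best attains the maximal true mean; any
maximal arm counts under ties).

The default is 1,000 replicates per cell (2,000 for the design-6 null cell
in the acceptance run) against 10,000 in the reference study; tolerances in
the acceptance tests are ±3 binomial standard errors at the replicate count
used, and ±3 standard errors of the mean for sample sizes. A full
acceptance run is a few minutes on one core.

## Virtual re-execution

`virtual_execution` replays a design on the enrolment calendar of a
completed trial dataset. Blocks of 50 enrolment slots keep their original
dates; each slot draws an arm from the current allocation probabilities and
then samples, with replacement, a source patient with that arm randomised
within ±6 weeks of the slot's date (an empty window is doubled once with a
warning, then errors). After each full block the posterior (baseline
adjusted, median-centred) is updated and the design's adaptation applied;
efficacy/futility checks run at 200 and 400 patients and the final analysis
at the full dataset size — the source trial is too small for the 600 check.
Designs 1–2 can also run in a direct mode that replays the dataset's own
allocations without resampling. Stopped-early-for-efficacy runs count as
successful.

Because the real patient-level data are not publicly deposited, the module
ships a synthetic stand-in generator (584 patients; arm sizes
144/149/149/142; control mean 53.5 with intervention contrasts +6.1 boot,
+8.0 brace, +8.7 below-knee cast; baseline N(50, 20²) with slope 0.3 into
the outcome; residual SD 20; 20% missing outcomes). The slope makes
baseline adjustment non-trivial without dominating contrasts. Re-execution
results on synthetic data are checked qualitatively (no futility stops;
declared best concentrated on brace/below-knee cast; contrasts recovered),
not against the reference study's printed re-execution table, which depends
on the unavailable real data. Any dataset in the documented CSV schema
(id, enrol_week, arm, baseline, outcome12, dropout) can be dropped in.

## Numerical and design choices

- σ² grid: 240 log-spaced points centred at (2β + Σ within-arm SS)/(2α + n),
  half-width 8·√(2/(n+1)) + 1 in log-space; with no data, σ² is drawn
  exactly from its inverse-gamma prior. The grid resolves the posterior of
  log σ² to a few percent of its SD even at n ≈ 600.
- Tie-breaks in `prob_best` go to the lowest arm index; ties have measure
  zero for continuous draws and the convention is tested.
- Dropout flags, arrival times and outcome noise are pre-drawn per trial
  from a single generator, so a trial is bit-reproducible from its seed.
- Degenerate inputs are rejected with named-field errors: non-finite
  outcomes, empty candidate sets, all-missing baselines, negative rates,
  out-of-range probabilities, stopping checks off the adaptation grid.
- Config files are flat YAML with a `schema_version`; unknown keys are
  rejected fail-fast. YAML reads the bare scenario name `Null` as a null
  value; the parser maps it back to the null scenario (quoting also works).

## Limitations

- The reference design study was built in commercial trial-simulation
  software whose exact model file is not public. Two details are therefore
  reconstructed by decision rather than known: a single pooled variance
  (the study describes one inverse-gamma prior) and independent arm-mean
  priors. Cross-checks confirm the pooled-variance reading fits the
  published tables better than per-arm variances.
- The published simulations adjusted interim estimates for a baseline
  covariate; its distribution and effect size are not reported, so the
  operating-characteristics simulations here omit it. The omission lowers
  the effective information at each interim relative to the reference
  study. The consequence is visible exactly where interim information
  matters most: design 6's extreme stopping ladder under a half-MCID
  effect ("One works, 5 more") stops early somewhat less often here
  (efficacy-stop proportion ≈ 0.46 vs 0.57 published; success ≈ 60% vs
  68.5%; mean N ≈ 602 vs 589). Re-running with complete outcome
  information at analyses closes the gap on every benchmarked quantity,
  which supports this explanation. All other benchmarked cells, including
  design 6 under the null and under full-MCID effects, agree within ±3
  Monte Carlo standard errors at 1,000–2,000 replicates.
- The synthetic re-execution dataset emulates marginal arm means, a
  baseline association, staggered enrolment and missingness; it does not
  emulate site structure, calendar-time drift, or the real trial's
  follow-up-window variation, so re-execution tests demonstrate pipeline
  correctness, not agreement with the historical trial.
- Committee behaviour, safety outcomes and sample-size re-estimation are
  out of scope; stopping is driven by the primary outcome alone.
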