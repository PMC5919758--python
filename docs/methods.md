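# Methods

This note documents the models, the estimators, the synthetic-data
generators, and the numerical and design choices behind them.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Abstract tuning model

State: a vector of transcriptional activities `E` (arbitrary activity
units, one entry per gene), the realized per-gene change of the previous
step `ΔE_prev`, and the previous fitness.  Fitness is
`F(E) = -||E − E_optimal||₂`, so `F ≤ 0` with equality only at the
optimum.  The update for gene `i` is

```
ΔE_i = k · sgn(ΔF_t · ΔE_prev,i) + η · s_i
```

with `s_i` an independent fair ±1 per gene per step and
`sgn(0) = 0`.  The directed term repeats a change that preceded a fitness
gain and reverses one that preceded a loss; the noise term keeps the
search exploring.  Numerical conventions:

- **ΔF timing.** Fitness is evaluated on the pre-update state: the step
  producing `E_t` uses `ΔF = F(E_{t−1}) − F(E_{t−2})`.
- **First step.** `ΔE_prev` is initialized to 0, so the first update is
  noise-only (`sgn(0) = 0`).
- **Clamping.** Activities are floored at `clamp_min` (default 0 —
  negative transcriptional activity is unphysical); the *realized*
  post-clamp change is what is stored in `ΔE_prev`.
- **Noise form.** Exactly ±η, not Gaussian: the noise is a fixed magnitude
  with a random sign.
- **Defaults.** Initial activities and optima are uniform on [0, 100],
  matching the activity scale of the threshold-gated variant (start 25,
  optimum 80); both configurable.  `k = η = 0.1`.
- **RNG.** One seeded `numpy` generator per simulation; genes are updated
  in a single vectorized operation, so iteration order is fixed.

With `η = 0`, a single gene and a seeded nonzero `ΔE_prev`, the rule
climbs deterministically at `k` per step and then oscillates within a band
of width `2k` around the optimum; the unit tests check this against an
independent scalar re-implementation.

### Threshold-gated (URA3/6AU) variant

All genes but one start at their optimal values; the gated gene starts at
`ura3_init` (default 25) with optimum `ura3_optimal` (default 80).  While
its activity is below `threshold`, the gated gene receives only the noise
term — a competitive inhibitor soaks up sub-threshold product, so its
fitness contribution cannot be sensed — and performs an unbiased random
walk.  At or above threshold it receives the full update.  All other genes
receive the full update (including noise) throughout, so the gated gene's
fitness signal must compete with the expression noise of the rest of the
genome.  A threshold above the gene's optimum is permitted (a saturating
inhibitor) but flagged in the trajectory and the run log.

The map from inhibitor concentration to threshold is not quantified
anywhere we could anchor it, so thresholds are taken directly in activity
units.  First-passage times to the URA3+ level (activity > 75) are
reported per trajectory, with runs that never reach the level returned as
censored at the simulation horizon.  Simulations may stop early once the
gated gene passes a stop level, since the first-passage time is the only
quantity consumed downstream.

**Problem sizes.** The packaged analyses use 100-gene systems, a
2×10⁵-step horizon and the threshold ladder {27, 31, 39}.  The ladder
spaces the sub-threshold walk distances (2, 6, 14 units) geometrically:
the sample median of these heavy-tailed first-passage distributions
carries roughly 30% relative error at 50 trajectories, so adjacent levels
must differ severalfold for the expected ordering to be resolvable.  A
ladder reaching far above the start (e.g. thresholds 60–70) would need
first-passage times of order 10⁶ steps per trajectory and is impractical
interactively; the chosen ladder exhibits the same qualitative behaviour
(slower and more variable tuning with increasing threshold) at tractable
cost.

## Biologically feasible single-cell model

Discrete time, default `dt = 1 s`.  Per gene `i` and step `t`:

```
x_i ← x_i − Binom(x_i, d_i) + Bern(r_i,t)         transcripts
p_i ← p_i − Binom(p_i, e_i) + Binom(x_i, l_i)     proteins
```

With fixed rates the stationary means are `x̄ = r/d` and
`p̄ = (r/d)(l/e)`; the tests verify both against the simulator.

**Kinetic priors** (per-gene parameters, sampled once per replicate):
transcription events per hour ~ Gamma(shape 5, rate 2) (mean 2.5/hr);
transcript half-lives in minutes ~ Gamma(shape 12, rate 0.75);
protein half-lives in hours ~ 1 + 0.382·t(80); log₂ translation rates
(s⁻¹) ~ −5 + 0.5·t(80).  Half-lives convert to per-step probabilities
exactly via `1 − 2^(−dt/t_half)`.  Draws are rejected and redrawn until
strictly positive (bounded loop); this truncation shifts the protein
half-life prior mean ~0.006 hr above 1, which the tests account for by
comparing against the analytic truncated mean.

**Chromatin marks.**  Signed tuning-mark counts `µ` (bounded at ±µ_max)
and stabilizing-mark counts `ν` (unbounded) evolve per step as

```
Δµ = sgn(ΔF)·sgn(µ)·U{1..4}·Bern(p_tunestep)  −  sgn(µ)·Binom(|µ|, p_decay)  +  (±1)·Bern(p_random)
Δν = sgn(µ)·Bern(|µ|·p_s_mark / µ_max)
```

`ΔF` is the mean fitness of the last `n_window` steps minus the mean of
the non-overlapping `n_window` steps before that, maintained as sliding
sums; the directed term is disabled (ΔF treated as 0) until two full
windows exist.  The decay term applies the binomial to `|µ|` with the sign
restored (a binomial on a negative count is undefined).  The uniform
step `U{1..4}` reflects a draw of integers 1–4 (configurable upper bound).

**Transcription rate.** `r = r₀ · α · exp(β)` with
`α = 2(µ/µ_max + 1) ∈ [0, 4]` and `β = m_S·ν`, clamped to [0, 1] because
`r` is used as a Bernoulli probability.  Taken literally, `α = 2` for an
unmarked promoter, so the `r₀` fed to the formula is calibrated as half
the sampled physiological per-step probability — unmarked genes then start
at the sampled rate.  (Whether the formula was intended as, e.g.,
`2^(µ/µ_max)` is an open question; we implement the literal form, with the
calibration above.)

**Fitness reference.** `F = −||p − p_ref||₂`, where `p_ref` is the
per-gene median protein count over the last quarter of a run 10× the
normal length with transcription pinned at the target rates.  The sign
convention (negative distance) makes "fitness increasing" and "cells
becoming healthier" coincide.

**Regimes.** `known_optimum` pins `r` at target rates; `fixed_baseline`
pins `r` at the initial rates; `random_marks` replaces `sgn(ΔF)` with an
independent fair sign per gene per step (only the tuning-mark direction is
randomized — stabilizing marks still follow `µ`); `tuning` is the full
model.  Cells start at the deterministic steady state of their initial
rates (the pre-stress environment), with unmarked chromatin.

**Baseline model parameters** (repo defaults, all config-overridable):
`µ_max = 20`, `p_tunestep = 0.01`, `p_decay = 0.001`, `p_random = 0.001`,
`p_s_mark = 0.01`, `m_S = 0.05`, `n_window = 100`.  The robustness sweep
perturbs each of these (plus `n_window`) twofold up and down, clamping and
flagging any probability pushed above 1 and rounding integer parameters.

**Scoring and problem sizes.** Runs are scored by the median fitness over
the final quarter (ceiling division).  Full-length runs are 3×10⁵ steps
(83.3 simulated hours); the packaged regime-comparison analyses use
5×10⁴-step runs with 10 seeds per regime to stay interactive.  A known
limitation of that reduction: with a target 8-fold *above* the starting
rate, closing the gap requires ~28 stabilizing marks at a maximal accrual
rate of `p_s_mark` per step, so the separation between fitness-directed
and fitness-blind mark dynamics is not yet reliably expressed at 5×10⁴
steps — the distinction emerges clearly only on full-length runs, where
fitness-blind marks also have had time to wander into strongly harmful
states.  The 8-fold-down direction separates already at the reduced
length.

## Estimators

**Poisson credible intervals.** For counts `i_1..i_n` on a common
effective dilution, the Jeffreys prior gives the posterior
`Gamma(0.5 + Σi, n)`; intervals are the central 95% quantiles.  Counts
observed at different dilutions must be rescaled to a common denominator
by the caller before pooling.

**Density overlap and mixing time.** Distribution overlap is the overlap
coefficient `∫ min(f̂_a, f̂_b)` of Gaussian KDEs (Scott bandwidth,
configurable) on a shared grid padded by three bandwidths — symmetric,
bounded in [0, 1], and invariant to common affine rescaling.  (The
alternative reading of "area under both densities" is ambiguous; the
overlap coefficient is the standard quantity for which larger = more
mixed.)  The overlap series is transformed as
`f(t) = (max x − x_t)/x_{t=0}` and fitted with `a·e^(−t/τ)` by unweighted
nonlinear least squares, initialized from a log-linear fit to the positive
`f` values; the half-life is `τ·ln 2`.  Degenerate series — maximum
overlap attained at t = 0, or total rise below 2% of the starting overlap
— are flagged rather than fitted.

**Recovery time.** Per day, counts are pooled across countable spots
(total colonies over total plated cells, with `cells_at_unit_dilution`
plated at dilution 1); a haze (uncountable) spot whose next more dilute
spot shows zero colonies is assigned a count of 1 before pooling, other
haze spots are excluded.  The day at which the rate crosses the threshold
(default 10⁻⁴ colonies per plated cell) is linearly interpolated between
bracketing observations; series that never cross are censored at the last
observed day.  Non-monotone rate series trigger a warning.

**Blanked fold change.** Per-cell fluorescence is divided by FSC^1.5 (an
empirical cell-size correction), an autofluorescence map is fitted by
lowess (default span) on the matched nonfluorescent blank population and
subtracted at each cell's FSC, and the statistic is
`log₂(median_b / median_a)` of the blanked values.  The 95% CI comes from
200 bootstrap resamples of cells (percentile method), with the blank fit
held fixed.

**Hierarchical ΔCt model.** Observations (per-sample-per-day medians
across technical replicates) follow
`ΔCt ~ t(µ_s, σ_rep, ν_rep)`; sample means follow
`µ_s ~ t(µ_c(class), σ_c(class), ν_bio)`.  Priors: flat on all location
parameters, flat-on-positive-scale for σ's (implemented on the log scale
with the Jacobian correction), and weak exponential priors pulling the
degrees of freedom toward moderate values (`ν = 1 + exp(·)`,
prior ∝ e^(−ν/30)).  The posterior is sampled with an affine-invariant
ensemble sampler (32 walkers, 2000 steps, 500 burn-in by default),
initialized from moment estimates; rows are first sorted into a canonical
order so results are bit-reproducible under permutations of the input.
The mean acceptance fraction is reported and a fit with acceptance below
0.05 raises.  Class means µ_c are reported as posterior medians with
central 95% credible intervals.

## Synthetic-data generators

The generators exist to close the loop on every estimator with known
ground truth; they are deterministic under a fixed seed.

- **Mixing series**: lognormal per-cell fluorescence; the top/bottom
  sorted populations sit `delta0` apart in log units and the separation
  relaxes toward the mock population as `e^(−t/τ_true)` (a mean-reverting
  log-scale process — the relaxation mechanism itself is not modelled,
  only the timescale matters).  Optional multiplicative noise perturbs the
  separation per timepoint.  Defaults (`delta0 = 0.8`, 20,000 cells per
  snapshot) were sized so that KDE sampling noise in the overlap series is
  small relative to its dynamic range, making the fitted τ a meaningful
  estimate; the small curvature of the overlap-vs-separation map
  contributes a ~1% bias at this separation.  `τ = ∞` yields a constant
  overlap series, which the fit flags as degenerate.
- **Colony counts**: Poisson counts at each dilution × day, zero before a
  configurable growth day, with spots whose expectation exceeds a
  countability limit marked as haze.
- **ΔCt tables**: sample means drawn t(class mean, σ_c), observations
  drawn t(sample mean, σ_rep).
- **Two-condition fluorescence**: fluorescence scaling with FSC^1.5 plus
  FSC-dependent autofluorescence shared with matched blanks, and a known
  median fold change between conditions.

What these generators do *not* emulate: cytometer optics and gating,
plate-imaging artefacts, qPCR amplification chemistry, cell-cycle and
lineage structure.  Passing closed-loop tests therefore demonstrates that
each estimator recovers its target quantity from data with the assumed
noise structure, not that the assumed structure matches any particular
instrument.

## Known limitations

- Simulation steps are not mapped to wall-clock biological time beyond the
  nominal `dt`; there is no population/colony-level simulation.
- The chromatin marks are generic: no identification with specific histone
  modifications or writer/eraser enzymes is attempted.
- The regime comparisons at interactive problem sizes understate the
  full-length separation between fitness-directed and fitness-blind mark
  dynamics (see above).
- The mixing-time estimator inherits the KDE's boundary and bandwidth
  behaviour; strongly non-lognormal populations may need a custom
  bandwidth.
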