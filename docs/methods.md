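# Methods

## Model

The package implements a minimal feedback model of body-fat regulation on
the timescale of days to weeks (not of individual meals). Three quantities
interact: fat mass `F`, daily food intake `u`, and circulating leptin `L`:

    dF/dt = aF*u − gammaE − gammaF*F
    dL/dt = aL*F*u − gammaL*L
    u     = umax / (1 + (L/KL)^n)

Fat gains by conversion of intake (`aF`), and pays an energy cost split into
a fat-proportional part (`gammaF`) and a body-wide part (`gammaE`). Leptin
is produced in proportion to fat *times recent intake* — the feature that
makes the steady-state leptin–fat relation quadratic rather than linear —
and cleared at `gammaL`. Leptin suppresses intake through a Hill function
with half-effect `KL` (rising `KL` = leptin resistance) and steepness `n`;
`umax` is the satiety-limited maximal intake.

Setting `dF/dt = 0` at controlled intake gives the rising **diet line**
`u = (gammaF*F + gammaE)/aF`. Eliminating leptin at quasi-steady state
(`L = (aL/gammaL)*F*u`; clearance is fast relative to fat turnover) from the
intake rule gives the falling **appetite line**. The **operating point** is
their intersection. In the `n → ∞` limit the appetite rule is `u = umax`
below the critical fat `Fc = KL*gammaL/(aL*umax)` and `u = Fc*umax/F` above
it, and the steady state has two closed-form regimes:

- *above-critical* (`KL < Kcrit`): `Fst` is the positive root of
  `gammaF*F² + gammaE*F − aF*KL*gammaL/aL = 0`, `ust = KL*gammaL/(aL*Fst)`,
  and `Lst = KL` exactly;
- *satiety-capped* (`KL ≥ Kcrit`): `ust = umax` exactly,
  `Fst = (aF*umax − gammaE)/gammaF`, `Lst = (aL/gammaL)*Fst*umax`, where
  `Kcrit = aL*umax*(aF*umax − gammaE)/(gammaL*gammaF)` solves the equality
  of `Fc` with the diet-line fat at `u = umax`.

We derive the above-critical root from the line intersection rather than
transcribing a printed closed form whose denominators do not follow from
that derivation; the solver cross-validates every closed-form solution
against an independent bracketed numeric intersection to a relative 1e-8,
and the two regime solutions agree at the `KL = Kcrit` boundary (assigned to
the above-critical regime by a closed-interval convention). A
positive-fat steady state requires `aF*umax > gammaE`; this is checked and
reported, never silently assumed.

## Units and parameters

All quantities are in the model's arbitrary units; time is a dimensionless
model unit of roughly one leptin turnover. The default parameter set is
`aF=0.02, gammaF=0.025, gammaE=0.00625, aL=1, gammaL=1, KL=0.5, umax=2`,
with `n = ∞` (represented by `math.inf`, an explicit flag) for steady-state
analysis and finite `n` for dynamics. Named presets reproduce every
scenario column of the published parameter table, including swept ranges
kept as `[lo, hi]` pairs. One preset records `KL = 3.6` as printed even
though "twice the critical resistance of the default set" evaluates to 5.4
under that column's own `gammaL = 1`; the printed value is kept verbatim
and this note records the discrepancy.

## Dynamics and transient classification

Simulations integrate the two-variable system with LSODA (rtol 1e-8,
atol 1e-10) at finite steepness, default `n = 100` — steep enough to
approximate the analytic limit with a smooth right-hand side. Leptin
starts at its quasi-steady value for the initial state unless overridden. A
quasi-steady mode eliminates leptin algebraically; the two modes agree on
fat within ~1% once the brief leptin transient (a few time units) has
passed. Intake stays within 5% of the appetite-line value after that
transient — the trajectory "crawls" along the appetite line.

One subtlety: with leptin clearance `gammaL = 1` per model time unit, the
leptin catch-up after a perturbation takes ~1.5 units, during which the
steep Hill can pin intake at `umax` (e.g. after under-feeding). The
"intake jumps to the appetite line" picture is the leptin-equilibrated
response, so jump-value comparisons (first ad-libitum intake vs. the
appetite response at the starting fat) use the quasi-steady mode; the full
ODE resolves the catch-up instead. Both are available via
`SimulationConfig.leptin_mode`.

Refeeding protocols multiply the steady intake by a factor (0.7 / 1.4) and
place starting fat on the diet line. Transients are classified from the
intake time course against the pre-perturbation intake `u_ref`: an
overshoot (undershoot) is an excursion beyond both `u_ref` and the settled
value by more than `eps_rel = 0.01` relative — well below the ~80%
overshoots the model produces, well above integrator noise. A trajectory
whose intake still changes by more than 1e-4 relative over the last 10% of
the horizon is reported `inconclusive`, never guessed. The default horizon
(50 units) matches the published simulation window; classification runs use
200–300 units so the settling criterion is met (the slow eigenvalue at the
default set is ≈0.06 per unit).

## Intervention rules

`classify_intervention` solves the operating points before and after a
parameter change, takes steady-state directions with a 1e-6 relative
threshold, and predicts the transient by testing whether the old operating
point lies on the new appetite line (relative 1e-6): on the line → monotone
dynamics; off it → overshoot if the new appetite response at the old fat
exceeds the new steady intake, else undershoot. Every prediction is
verified by simulating the intervention; disagreement raises a warning and
is recorded, never silently resolved. `aL` and `gammaL` are classified as
appetite-line parameters: they also scale the leptin nullcline, but leptin
is not an axis of the (F, u) portrait. Multi-parameter interventions
report `line_shifted = "both"` and whatever coherence the signs give.

The packaged battery (exercise, thyroid states, temperature shifts, leptin
pathway inhibition/activation, satiety-inducing nutrients, gastric bypass,
diet variety, high-fat chow) runs at `n = 7.1` — the steepness fitted to
the rodent refeeding phase portrait — rather than the illustrative
`n = 100`. At near-infinite steepness the above-critical steady state is
almost exactly insensitive to `umax` (see the sensitivity section), so
satiety-cap interventions would produce transients below any honest
detection threshold; at the rodent-fitted steepness the battery reproduces
every direction and transient entry of the rodent tables, with simulation
confirmation. In the satiety-capped regime, appetite-parameter changes
that keep `KL ≥ Kcrit` leave intake direction 0 and are reported as
`insensitive`.

## Fitting pipelines

A Harris-type experiment (groups tube-fed 40/100/160% of control for 20
days, then ~30 days ad libitum, daily records) is normalized by linear
interpolation of every series to an integer-day grid followed by
element-wise division by the control — removing the shared growth trend and
any common handling effect; the control maps to (1, 1). Diet points pair
each controlled group's phase-mean relative intake (tube feeding is
constant, so the mean is the controlled level) with its end-of-phase
relative fat; appetite points pool (relative fat, relative intake) over all
recovery days and groups, including the control's.

The diet line `F = a*u − b` is fitted by OLS with `F` as the response;
parameter SDs come from the residual covariance when at least three points
exist (two points interpolate exactly and are flagged as having no error
estimate). The appetite line `F = (c/u)(umax/u − 1)^{1/n}` is fitted by
bounded nonlinear least squares, residuals in fat units, with multi-start
over `n ∈ {2, 5, 10, 20}`; each start first profiles `(c, umax)` at fixed
`n` (the `(umax, n)` pair trades off along a near-flat ridge when the data
stop short of the satiety cap, and a free three-parameter start is easily
lost on it) and then polishes all three parameters, keeping the lowest
residual sum of squares. Bounds: `c > 0`, `umax` above the largest
observed intake, `n ≥ 1`.

The leptin–fat population fit compares the no-intercept quadratic
`L = a_q F² + b_q F` with the linear `L = c F` by least squares, AIC in the
Gaussian-RSS form `N ln(RSS/N) + 2k` (no additive constant — only AIC
differences between models on the same data are meaningful, so reports
include ΔAIC), and the squared Pearson correlation between fitted and
observed leptin (computed on `L`, not `log L`).

## Synthetic data: what it emulates, and what passing tests show

`generate_feeding_experiment` simulates the tube-feeding protocol exactly:
clamped intake (closed-form linear fat dynamics) for the controlled phase,
full dynamics at the rodent-fitted `n = 7.1` for recovery, day-mean intake
and fat as the daily records, a shared multiplicative exponential growth
trend on fat and weight (0.5%/day by default — the simplest structure the
normalization provably removes), and median-preserving lognormal noise
(sigma 0.05) on intake, fat and weight. One protocol day spans
`1440/140 ≈ 10.3` model time units — the leptin-turnover unit the parameter
table itself states. This matters: at one unit per day the 20-day
controlled phase would reach only ~40% of the clamped steady state and the
"diet points" would measure a protocol artifact rather than the diet line;
at the stated unit the phase equilibrates to better than 1%.

`generate_leptin_population` draws one varied parameter per individual
(lognormal, default `KL` with sigma 0.5), solves each operating point, and
adds lognormal measurement noise (sigma 0.1) to leptin. Because every
operating point lies on the leptin nullcline, the noise-free scatter traces
the quadratic exactly, and the quadratic model wins the AIC comparison in
essentially every seeded replicate.

What the generators do **not** emulate: tube-feeding aversion (handled, as
in the original analysis, by control normalization rather than mechanism),
fat-free-mass dynamics, adaptive thermogenesis, meal-scale behaviour, and
sparse body-composition sampling (dense fat by default; a sparse-plus-
interpolation option exists). Parameter-recovery results on this data
therefore validate the *pipeline* under the model's own assumptions, not
the model against real rodents.

**A known observability limitation.** Under the stated clock, fat refills
from deep restriction in less than one protocol day, so the intake cap is
visited for under one daily sampling interval: the day-averaged recovery
data carry an apparent cap of ~1.85 fold where the instantaneous `umax` is
2.07 fold. Even noise-free day-averaged points prefer a sharper, lower-cap
curve, and with default noise the `(umax, n)` likelihood ridge is unbounded.
Consequently `a`, `b` and `c` are recovered without bias from the default
design, while `umax` and `n` are not identifiable from daily-sampled
recovery data — the corresponding recovery check is expected to fail and is
kept as an honest negative result. The appetite fit itself recovers
`(c, umax, n)` to ~1e-6 from noise-free on-curve points.

Two further helpers are **labelled synthetic stand-ins** for the digitized
literature datasets: `harris_like_phase_portrait` (three diet points on the
normalized line `F = 1.56u − 0.49`; 39 appetite points on the curve with
`c = 1, umax = 1.38, n = 7.1`, 2% lognormal fat noise) and
`considine_like_scatter` (70 individuals, fat uniform over 8–45% body fat,
leptin on `L = 0.016 F² + 0.062 F` with 25% multiplicative scatter —
serum leptin is positive with level-proportional dispersion). They exist
so the fitting pipeline can be exercised at the scale of the published
normalized fits when the deposited CSVs are not at hand; they are not the
digitized data, and the real files should be preferred wherever available.

## Sensitivity analysis

For each steady-state variable a characteristic residual is built by
eliminating the other variables (all three printed characteristic equations
reduce to `u_diet(x)·(1 + (L(x)/KL)^n) − umax` after clearing denominators),
and the log-sensitivity follows from the implicit function theorem with
partials by central differences (relative step 1e-6; the residual is smooth,
so this is accurate to ~1e-10 — a typo-prone transcription of the long
printed derivative is avoided). Every value is cross-checked against a
central finite difference of the re-solved steady state (relative step
1e-4); the two agree to better than 1e-4 relative across the full grid
(targets × 7 parameters × n ∈ {2, 4, 7, 10, 20, 50, 100} × two regimes).
The high-resistance regime replaces `KL` by `2·Kcrit`. At steep `n` the
profiles reach the analytic patterns: baseline intake is insensitive to
`umax` and leptin tracks `KL` one-for-one; under high resistance intake
tracks `umax` exactly and ignores `KL`.

## Legacy models

The Tam 2009 (no explicit set-point controller) and Jacquier 2015 (constant
receptor density) models are reduced to diet and appetite curves under
plasma-leptin quasi-steady state. Shipped parameter files are synthetic
representative sets — chosen for the structural behaviour (rising diet
curve between its two linear limits for Tam; falling appetite curve;
unique crossing) — because the calibrated tables of the original
publications are not reproduced here; all tests on these curves are
structural, and quantitative work should load the original values from
those papers. Neither model yields the quadratic leptin–fat population
relation, since neither makes leptin production depend on recent intake.

## Numerical choices

- Finite-`n` appetite inversion: bracketed Brent root-finding of the
  monotone fixed-point equation on `(1e-12·umax, umax]`, tolerance 1e-12;
  uniqueness follows from monotonicity.
- Operating points at finite `n`: Brent on the diet/appetite difference,
  bracket expanded multiplicatively if the finite-`n` curve exceeds the
  steep-limit bracket.
- Hill evaluations are overflow-safe (log-space with a logistic).
- Formally negative fat-line values (clamped leptin above `KL` in the steep
  limit) are returned as-is and flagged "diminished" — they represent
  depleted fat stores with lean-mass catabolism, not negative fat.
- Degenerate inputs (all-equal intakes, empty analysis windows, missing
  control coverage, infeasible parameter sets) raise with named gaps.

## Known limitations

No fat-free-mass state variable or adaptive thermogenesis; no meal-scale
feeding; local (not global) sensitivity only; gram/calorie conversion of
intake left to the user; the satiety cap is weakly identified from
daily-sampled recovery data (above); absolute AIC values are
convention-dependent and only differences are reported as meaningful.
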