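# Methods

## Model

The population share vector `p` over `N` territorial units (TUs) is
estimated as the discrete distribution of maximal Shannon entropy
`H(p) = -Σ p_i ln p_i` subject to linear expectation restrictions
`Σ_i p_i g_r(i) = C_r` and the natural restriction `Σ p_i = 1`.  The
restrictions encode the national macro-state:

* **Flow rows.**  For each flow variable (students / electricity / water)
  the row is `g_i = total_i × rate_i` — e.g. `u_i α_i` with
  `α_i = u_i / b_i` — and the target couples the *self-weighted* mean per
  department with the national per-capita rate, e.g. `ū·A` with
  `ū = Σ u_i²/U` and `A = U/B`.  The self-weighted form (each department
  weighted by its own share of the national total, `q_i = u_i/U`) is the
  quantity the derivation of the restriction actually defines, and it is
  the only choice for which the observed shares `p_i = b_i/B` satisfy the
  row identically: `Σ (b_i/B) u_i α_i = Σ u_i²/B = (Σ u_i²/U)(U/B)`.  A
  "simple average per department" would leave the truth infeasible.
* **Moment rows.**  Non-centered moments of the TU index, `g_{m,i} = i^m`,
  `m = 1..m_max`, with targets computed from a reference distribution.  By
  default the reference is the **previous year's** observed shares (the
  restriction represents persistence of the spatial arrangement); a
  `current`-year mode exists because for within-year reconstruction
  experiments the same-year moments are the natural upper bound on what the
  truncated moment set can deliver.

Assumptions: units are fixed over the study window (no boundary changes),
populations are strictly positive, and the flow data are internally
consistent (totals = rate × population up to reporting noise).  Migration
and growth mechanisms are not modelled; persistence enters only through the
moment targets.

## Orderings

Index moments are informative only if populous units occupy predictable
index positions, so units are reindexed before moments are formed:

* `descending` — largest population at index 1; ties broken by ascending
  unit code (deterministic).
* `bell` — largest at the central index `ceil(N/2)`, subsequent units
  alternately to its right and left (right first).  The exact bell
  construction is underdetermined in general; center-outward alternation is
  the symmetric canonical choice.
* `original` — official code order.

The permutation is frozen at the first calibration year and reused for all
years.  Recomputing it annually would make the per-moment target series
incomparable across years, which would invalidate the trend regressions the
forecast depends on.

## Solver

The dual `f(λ) = ln Z(λ) + λ·C`, `Z = Σ_i exp(-λ·g(i))`, is smooth and
convex; its unique minimizer gives `p_i = exp(-λ0 - Σ λ_r g_r(i))` with
`λ0 = ln Z`.  Numerical choices:

* **Newton with Armijo backtracking**, starting from `λ = 0` (uniform
  distribution); deterministic, no randomness anywhere in the solver.
  Near the optimum, when the predicted decrease falls below floating-point
  resolution of the dual value, the full Newton step is accepted (otherwise
  the line search would stall at machine precision).
* **Conditioning.**  Raw moment rows reach `N^m` (≈ 1.5×10¹⁵ for `N = 33`,
  `m = 10`) and would destroy the dual Hessian.  Each row is first rescaled
  to unit max-absolute-value (recorded in `ConstraintSet.scale`), then the
  row set is orthonormalized by QR.  Both are invertible recombinations of
  the constraints, which leave the feasible set — hence the solution —
  unchanged; the returned multipliers are mapped back to the caller's
  original rows so the exponential form holds as stated.  A tiny escalating
  Tikhonov ridge guards the Newton solve; a genuinely rank-deficient row
  set (e.g. duplicated rows) is rejected up front.
* **Convergence** when `max_r |Σ p_i g_r(i) - C_r| / max(1, |C_r|) ≤ tol`,
  measured on the *original* row scale; default `tol = 1e-10`, at most 200
  iterations (6–10 suffice for every model variant in the test suite).
* **Feasibility pre-check.**  Each target must lie strictly inside the open
  range of its row (boundary targets require degenerate distributions,
  which the exponential family excludes); constant rows must match their
  target.  Violations raise before any iteration.
* Degenerate inputs: zero-flow units get rate 0 and row entry 0 — the
  exponential form still assigns them positive mass; `R = 0` returns the
  uniform distribution immediately; `R > N - 1` is rejected (normalization
  consumes one degree of freedom).

## Pipeline

Calibration solves the configured model year by year and scores against the
observed shares with two metrics: `RMSE = sqrt(mean_i (p̂_i - p_i)²)` and
the mean relative error `100 × mean_i |p̂_i - p_i| / p_i` (percent).  The
relative-error formula is the natural reading of "average relative error"
for a share vector; it requires strictly positive truth, which the panel
contract guarantees.  Infeasible or non-convergent years are recorded with
their diagnostic and do not abort the window.

Forecasting beyond the window: per-TU totals (population and the three
flows) are extrapolated by per-TU ordinary least squares over the
calibration years; per-capita rates are frozen at the last calibration
year; per-moment targets follow OLS lines fitted to the calibration target
series (Pearson correlation recorded per moment; constant series are
flagged degenerate with correlation 0).  The national population `B` needed
for the flow targets is taken from the summed per-TU population
extrapolations — totals are the quantity trend regression is reliable for,
and `B` enters only the constraint targets, never the answer directly.  An
extrapolated total ≤ 0 is clamped to its last observed value and a warning
recorded; a forecast year with infeasible predicted targets is reported and
skipped.

## Synthetic data

No national panel is redistributable, so all experiments run on seeded
synthetic panels that emulate the study setting:

* 33 units, years 2000–2015 (plus a lead-in year for previous-year moment
  references), national population 4×10⁷.
* Shares follow a normalized power law over ranks with the exponent solved
  so the top unit holds 0.16 of the population (the dominant-capital share
  of the modelled country); a Dirichlet option exists for unstructured
  shares.  Share-to-unit assignment is shuffled so the official code order
  is uninformative, as in real department codes.
* Per-unit per-capita rates drawn uniformly from plausible national
  magnitudes: enrolment 0.005–0.06 students/inhabitant, electricity
  500–2500 kWh/inhabitant·yr, water 30–120 m³/inhabitant·yr; rates are
  mutually independent.
* Totals grow linearly at unit-specific rates (0.5–2 %/yr of the base).
  Optional multiplicative log-normal noise (mean-one, configurable
  coefficient of variation) on every total, shares renormalized.
  Populations and student counts are rounded to integers by default; rates
  are always recomputed from the stored columns, so panels remain exactly
  self-consistent after rounding.

What the generator does **not** emulate: spatial correlation, migration
flows, age structure, census revisions, or correlation between rates and
unit size.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery and its qualitative behavior
(moment-count convergence, ordering sensitivity, forecast stability), not
predictive skill on real national data.

### Planted truth

Recovery tests need panels whose true shares the pipeline must reproduce
exactly.  Construction: anchor distributions `p_start` (power law) and
`p_end` (blend of `p_start` with the uniform, weight = `drift`); moment
targets interpolate linearly between the anchors' moment vectors — the
attainable moment set is convex, so every interpolated target is feasible —
and the truth at year `t` is the maximum-entropy solution of those targets.
Data are rebuilt from the truth with constant per-unit rates and no
rounding.  Flow rows are satisfied identically by *any* true shares, and a
feasible point that maximizes entropy under a subset of the constraints
also maximizes it under the full set; hence the integrated flow+moment
model recovers the planted truth to solver precision.  Recovery is exact
under `current` moment referencing (or `previous` when `drift = 0`, which
plants a stationary truth).

A second mode (`truth_mode="linear"`) makes the true shares themselves move
along an exact line between the anchors, with the national population held
constant so every per-unit total is exactly linear in the year.  There the
truth is no longer the entropy maximizer of its own truncated moments, so
calibration carries a small moment-truncation error — but trend
extrapolation is exact, making this the right harness for checking that
forecast error stays at the calibration level.

## Experiment sizes

Default experiment sizes — 33 units, 11 calibration years, 5 verification
years, up to 10 moments, 20 random problems per oracle comparison — were
chosen as the smallest sizes at which every qualitative effect of interest
(ordering sensitivity, moment-count convergence, tail-unit error
concentration) is clearly expressed; the whole suite runs in seconds.

## Known limitations

* The moment restrictions dominate the fit; flow rows refine it only
  modestly.  This mirrors the method's own behavior and is a property of
  the restriction design, not of the solver.
* Bell-shaped ordering induces much more ill-conditioned moment systems
  than descending ordering; with many moments it is also a materially worse
  model, which is precisely the ordering experiment's conclusion.
* Relative error against near-zero shares is unstable; the panel contract
  requires positive populations, but very small synthetic units can still
  dominate the mean relative error on noisy panels.
* Forecast quality depends entirely on the linear-trend assumption for
  totals and moment targets; no uncertainty intervals are produced.
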