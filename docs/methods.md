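# Methods

## Model

`virextinct` implements a well-mixed, target-cell-limited model of virus
infection in a compartment of volume `s` (mL).  `N_cells` susceptible target
cells `T` are exposed to `V` infectious virions.  Virions irreversibly commit
to cell entry at per-virion rate `βT/s` and lose infectivity at rate `c`; an
entry yields a productive cell infection with probability `γ ∈ (0, 1]`
(failure leaves the cell unchanged and susceptible).  Newly infected cells
traverse an eclipse phase (no production) and then an infectious phase
producing virions at rate `p`.  Both phase durations are Erlang distributed —
chains of `n_E` (resp. `n_I`) exponential stages with means `τ_E` (`τ_I`) —
so `n_I = 1` gives an exponential infectious phase and large `n_I` a
normal-like one.  Assumptions: no co-infection (virions cannot enter already
infected cells), no immune response, no cell regeneration, no spatial
structure, no defective-interfering particles; failed entries leave no trace
on the cell.

Two matched formulations are provided.  The **mean-field model** is the ODE
system in the README, integrated with a stiff-capable adaptive solver
(LSODA, `rtol = 1e-9`, `atol = 1e-10`), with state ordering
`[T, E_1..E_nE, I_1..I_nI, V]`.  The **stochastic model** advances integer
counts by adaptive tau-leaping: the step is
`Δt = P_events / max(βT/s, c, n_E/τ_E, n_I/τ_I)` (recomputed every step), so
the most likely per-entity event has probability `P_events` (default 0.05).
Per step, stage transitions are binomial, production is Poisson, the virion
fate (decay / entry / neither) is trinomial — realized exactly as
`Binomial(V, p₁)` then `Binomial(V − V_decay, p₂/(1−p₁))` — entry success is
`Binomial(V_enter, γ)`, and the number of *distinct* cells infected is
counted by placing the successful virions uniformly with replacement on the
`T` cells (not approximated by `N_inf = V_suc`).  Bounded draws guarantee
populations never go negative.  A run ends when no event can ever fire again
(`V = 0` and all infected compartments empty); runs reaching the safety
horizon `max_time` (default 1e4 h) are flagged censored, never silently
truncated.

A third, diagnostic formulation — the **expected-value map** — replaces each
stochastic draw by its expectation (including
`E[N_inf] = T(1 − ((T−1)/T)^{V_suc})`) and advances with the simulator's own
step; it agrees with the ODE solution to well under 1% of `N_cells` over a
full infection course, tying the two formulations together.

## Derived quantities

With `B = pτ_I` (mean burst size) and `ratio = c/(βN_cells/s)`:

- `P_V→I = γ/(1 + ratio)`; `R0 = B · P_V→I`.
- Burst size ~ `NB(r = n_I, p_B = B/(n_I+B))` (Poisson production over an
  Erlang lifespan), geometric at `n_I = 1`, Poisson as `n_I → ∞`.
- Single-virion extinction probability: root in `[0, 1)` of
  `P = (1−P_V→I) + P_V→I [B(1−P)/n_I + 1]^{−n_I}`, found by bracketed Brent
  iteration on `[0, 1 − 1e−9]` (the trivial root at 1 is excluded from the
  bracket); returns 1 when `R0 ≤ 1`, and 1 when the non-trivial root is
  numerically indistinguishable from 1 (R0 within ~1e−9 of 1).  For
  `n_I = 1` this equals the closed form `1 − (R0−1)/B` to 1e−12.
- Single-cell extinction: the burst law's generating function at the
  single-virion root; inoculum `(V0, I0)`: the product
  `p_v^{V0} · p_c^{I0}`.
- Critical uninfected fraction `T*/N = ratio/(γB − 1)` (defined only for
  `γB > 1`; signalled explicitly otherwise) and final size
  `1 − T(∞)/N = 1 + (T*/N)·W0(−e^{−N/T*·…})` via the principal Lambert W
  branch (library implementation, residual ≤ 1e−12 with a Halley polish;
  exact −1 returned at the branch point).
- Alternative burst laws (geometric, delta, Poisson, negative binomial) share
  one fixed-point solver on the generating function; the delta law with
  non-integer mean uses the continuous extension `G(P) = P^B`.  With
  `P_VI = 1` and `G(0) = 0` the smallest fixed point is exactly 0.

Antiviral modes multiply exactly one of `β`, `p`, `γ` by `(1−ε)`.  Critical
efficacy is `1 − 1/R0` for `p`/`γ` and a bracketed root for `β`; ε50 is
solved by Brent iteration between 0 and the critical efficacy.  Oracle sums
in the tests truncate the negative binomial where its cumulative mass reaches
`1 − 1e−12`.

## Parameter defaults

The packaged baseline (`czuppon_baseline()`) is the in-host SARS-CoV-2 set
used throughout: `p = 11.2/24` IV/(cell·h), `τ_E = 24/5` h,
`τ_I = 24/0.595` h, `c = 10/24` /h, `n_E = n_I = 1`,
`N_cells = 4×10⁴`, `γ = 1`, `s = 1` mL, `V0 = 1`, with `β` computed from
`R0 = 7.69` by inverting the `R0` formula
(`β = s·c·R0 / [N_cells(γpτ_I − R0)]`).  Treated presets state their exact
condition — a target value of `T*/N_cells` — rather than a rounded efficacy,
because derived quantities are sensitive to the fourth decimal of ε; the
helper `efficacy_for_target_fraction` solves ε in closed form per mode.

`P_events = 0.05` is the production step bound: small enough that ensemble
extinction frequencies and established-run medians agree with the
branching-process and Lambert-W predictions within Monte Carlo error at 10⁴
runs, large enough that a full established infection takes ~10⁴ steps.

## Outcome classification

A finished run is *established* if it consumed more than
`threshold_frac · N_cells` cells.  The default threshold is 0.01% of cells
(`1e−4`).  Near criticality this strict rule undercounts extinction: extinct
lineages then linger and can consume tens to hundreds of cells — still four
orders of magnitude fewer than established runs, whose consumed-cell
distribution is separated from the extinct one by an empty gap.  For
ensemble-versus-theory comparisons the package therefore provides
`gap_threshold_frac(params)`, which places the threshold at half the
predicted established final size; with it, ensemble extinction frequencies
match the branching-process root within binomial error wherever the two
groups are separated at all.  When the groups merge (`T*/N → 1`), no
threshold is meaningful — the distinction itself loses biological meaning.

## What the simulations do and do not show

The stochastic ensembles are self-validating against the package's own
closed forms: single-virion success frequency against `P_V→I`, burst
histograms against the negative binomial, ensemble extinction frequencies
against the fixed-point root, and established medians against the Lambert-W
final size.  Passing these shows the simulator and the analytics describe
the *same model*; it does not validate the model against clinical data.  The
parameter set is one published in-host calibration; absolute numbers (e.g.
"31,873 of 40,000 cells consumed") inherit its uncertainty, and the model
omits immunity, regeneration and spatial structure, all of which would
reduce the cells consumed by established infections.

## Numerical choices and scales

- Ensembles derive per-run child seeds from the master seed via
  `SeedSequence(seed).generate_state(n_runs)`: reproducible and order-stable.
  The compiled (numba) kernel and the trajectory-recording numpy path
  implement identical update rules on distinct RNG streams.
- Test and validation scales: 10⁴-run ensembles for extinction/median
  checks, 10⁵ samples for distribution checks, chosen so Monte Carlo error
  dominates residual discretization error.
- The burst-size sampler defaults to a finer step (per-stage transition
  probability 0.005) than the production simulator, because its comparison
  target — the negative binomial — is the continuous-time law: at a 0.05
  step, tau-leaping's geometric stage residence leaves a relative
  burst-variance deficit of order `P_events` (~1.5% at `n_I = 7`), harmless
  for ensemble quantities but detectable by a chi-square test at 10⁵
  samples.
- The established-median check uses the exact order-statistic
  (`Binomial(n, 1/2)`) 95% confidence interval rather than a percentile
  bootstrap: consumed-cell counts are integers, and bootstrap percentile
  intervals undercover for medians of lattice data.
- Percentiles elsewhere use linear interpolation between order statistics.
- Trajectory CSVs record state at step boundaries (no interpolation to fixed
  checkpoints); the mean-field CSV is a dense interpolation of the adaptive
  solution.

## Known limitations

- `ε50` for inocula initiated with both virions and cells is defined on the
  product establishment probability; published comparisons use `V0`-only or
  `I0`-only inocula.
- The `β`-antiviral critical efficacy has no closed form here and is root
  solved; for `γB ≤ 1 + ratio·0` edge cases a near-total entry block may
  never reach `R0 = 1`, which is raised, not silently clamped.
- Time-varying efficacy, concentration–efficacy (Emax) pharmacology,
  combination therapy and cytotoxicity are out of scope.
- The incubation-horizon variant of the per-virion success probability (a
  finite observation window) is not implemented; the horizon is taken to
  infinity, where the expression is exact.
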