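# Methods

## The model

The package ships a reduced-order kinetic model of human complement
activation covering the lectin and alternative pathways.  Each of the 18
state variables `x_i` (concentrations in nM, time in hours) obeys

    dx_i/dt = tau_i * sum_j sigma_ij * r_j(x, eps, k) * v_j(x)

where `sigma_ij` is the stoichiometric coefficient of species `i` in
reaction `j`, `r_j` a kinetic term, `v_j` in [0, 1] a control term, and
`tau_i` a dimensionless time-scale factor absorbing unmodeled effects.

Three rate laws are used:

* **saturation** — `k_max * eps * x^eta / (K^eta + x^eta)` for enzymatic
  cleavage (lectin-driven C4/C2 cleavage, C3/C5 convertase activity), with
  `eps` the catalyst abundance and `eta` a cooperativity order;
* **mass action** — `k_max * prod x_s^(-sigma_s)` for irreversible binding
  (convertase assembly); no reverse terms are carried;
* **first order** — a one-reactant special case kept explicit in model
  files (tickover, AP convertase formation from C3b, C3a/C5a clearance).

Control terms are built from Hill transfer functions
`f = x^n / (K^n + x^n)` (activating) or `1 - f` (inhibiting), combined by a
`min` or `max` integration rule; a reaction with no modifying factors has
`v = 1`.  The lectin trigger is an activating Hill gate on the initiator
(zymosan) dose, so lectin initiation carries exactly zero flux without
initiator.  C4BP inhibits the CP C3 convertase and factor H the AP C3
convertase, as pure control factors: the regulators are constant states with
identically zero derivatives.  Treating them as control factors rather than
consuming binding reactions keeps each regulator down to a single gain
constant, which is also what lets the network close at 28 free parameters.

### Network

Species (18): C4, C4a, C4b, C2, C2a, C2b, C3, C3a, C3b, C5, C5a, C5b, the
CP and AP C3 convertases, the CP and AP C5 convertases, factor H, C4BP.
Reactions (13): initiator-gated C4 and C2 cleavage; CP C3 convertase
assembly (C4b + C2a); CP C3 convertase activity on C3; first-order tickover
(lumped spontaneous C3 hydrolysis, factor B/D in excess); AP C3 convertase
formation from C3b; AP C3 convertase activity; CP/AP C5 convertase assembly
(C3 convertase + C3b); C5 cleavage by each C5 convertase; first-order C3a
and C5a clearance.  Classical C1 initiation, the C3w/C3wBb intermediate,
factor B/D balances, and MAC assembly are outside the model boundary.

### Parameter index map

Declaration order fixes the 1..28 indices used by the sensitivity and
pairwise analyses:

| # | parameter | # | parameter |
|---|-----------|---|-----------|
| 1–3 | C4 cleavage k, K, eta | 16 | CP C5 convertase formation k |
| 4–6 | C2 cleavage k, K, eta | 17 | AP C5 convertase formation k |
| 7 | CP C3 convertase formation k | 18–20 | CP C5 convertase k, K, eta |
| 8–10 | CP C3 convertase k, K, eta | 21–23 | AP C5 convertase k, K, eta |
| 11 | tickover k | 24 | C3a clearance k |
| 12 | AP C3 convertase formation k | 25 | C5a clearance k |
| 13–15 | AP C3 convertase k, K, eta | 26 | lectin gate gain (mg/ml) |
| | | 27 | C4BP inhibition gain (nM) |
| | | 28 | factor H inhibition gain (nM) |

The Hill orders of the three control transfer functions (gate order 2,
inhibitor orders 1) are structural constants, not free parameters.  Default
bounds are two decades either side of nominal for rate/saturation constants
and gains, and [1, 4] for the cooperativity orders.

### Time-scale factor

`tau_i = z / z*` (reference dose `z* = 1 mg/ml`) applies to the C5a and C5b
balances only, slowing C5 cleavage at sub-reference initiator doses; all
other species have `tau = 1`.  With no initiator (`z = 0`) the factor is
defined as 1: it models initiator-driven unmodeled effects, and the
alternative pathway must still produce C5a in the absence of initiator.
For `0 < z < 1` the factor deliberately breaks C5-lineage mass closure (it
is a surrogate, not a physical rate); the conservation tests therefore run
at `z = 0` and `z = 1` where `tau = 1`.

### Initial conditions and units

Defaults are physiological serum levels (C3 1.2, C4 0.4, C2 0.025, C5
0.075, factor H 0.5, C4BP 0.25 mg/ml) converted to nM with per-species
molecular weights; every fragment and complex starts at zero, and species
omitted from a model file's initial conditions default to zero.  Model
files may declare initial conditions in mg/ml or ug/ml; the loader
converts.  These serum values are standard-reference numbers shipped as
editable data, not assertions about any particular assay.

### Nominal parameters

Nominal rate constants were chosen once so the default network reproduces
the qualitative behavior the model is built around: C3a roughly two to
three orders of magnitude above C5a at matched times, C5a final levels
monotone in initiator dose over 0.001–1 mg/ml, C3a within ~1% of its
plateau at the reference dose by the 6 h default horizon, a slow
tickover-driven alternative-pathway response without initiator, and C5a
robust to C3 knockdown only when the lectin pathway is active.  They are a
synthetic reference parameterization, not fitted constants.

## Simulation

`solve_ivp` with the BDF method (the convertase feedback makes the system
stiff at high initiator doses), rtol 1e-6 / atol 1e-9, 200 output points by
default.  States are clamped at zero inside the right-hand side and the
stored solution is clipped at zero; irreversible mass action can undershoot
by solver tolerance.  AUCs use trapezoids on the output grid with
interpolated endpoints.  Ensemble summaries report the per-time mean, a 99%
t-interval of the mean, and the 0.5/99.5 empirical percentiles; failed
members are skipped and counted, never NaN-filled.

## Training objectives

Each objective min-max scales measurement and simulation over the sampled
time points and sums squared shape differences, plus one squared relative
scale error comparing the largest measured concentration with the largest
simulated value.  The printed form of the scale term has ambiguous
parenthesization; it is implemented as `((M' - max y) / M')^2`, a relative
amplitude error, which is zero exactly when the simulated maximum matches
the measured scale.  Simulations are aligned to measurement times by linear
interpolation.  O1 binds the zero-dose condition, O2 the 1 mg/ml condition,
both scoring C3a and C5a.

## Optimization

Both optimizers search log10 parameter space.

* **Warm start** — a hybrid of multi-swarm particle swarm (3 swarms x 8
  particles, inertia 0.7, cognitive/social 1.5) and dynamically dimensioned
  search (perturb a randomly chosen subset of dimensions that shrinks with
  progress, sd 0.2 of the log-range, reflecting at bounds, greedy
  acceptance).  The default start point is the center of the log bounds.
  The switch happens at 20% of the budget or after 25 stagnant swarm
  iterations: at desk-scale budgets in 28 dimensions the uniform global
  phase contributes little, so it is kept short by design.
* **Pareto ensemble** — simulated annealing: a candidate is accepted
  outright if non-dominated with respect to the archive, otherwise with
  Metropolis probability `exp(-delta/T)` on the summed-objective increase;
  geometric cooling (factor 0.9 every 20 iterations) from the scale of the
  initial objective.  Equal objective vectors count as mutually
  non-dominated.  The archive is re-ranked by layered non-dominated sorting
  and truncated to the target size by (rank, summed objective).  The
  default target size is 100; the desk-scale analyses in this repository
  use 60 with 250 iterations, an explicit scale-down from ensemble sizes in
  the thousands.

AIC is `2 Np + Nm ln(residual / ||M||)` with the residual in natural
concentration units summed over all measured points.  `||M||` is not pinned
down by the usual presentation of this score; it is implemented as the sum
of squared measurements (flag `norm="max_sq"` switches to `Nm * max(M)^2`).
The random-parameter control draws log-uniformly within bounds.

## Global analyses

* **Sobol total-order indices** — Saltelli radial design: a scrambled
  Sobol' sequence in 2d dimensions yields base matrices A and B plus cross
  matrices AB_i/BA_i, `N(2d+2)` parameter sets total (23,200 at the
  full-scale N = 400, d = 28).  Parameters are placed log-uniformly within
  bounds by default.  The total index uses the Jansen estimator
  `mean((f_A - f_ABi)^2) / (2V)` averaged with its mirror on (B, BA_i);
  95% CIs bootstrap the N base rows.  The analyzed output is the training
  residual of one objective; failed integrations are imputed with the worst
  finite residual.  Desk-scale runs use N = 32–64 (about 2,000–4,000
  simulations), a deliberate scale-down of the full design.
* **Pairwise displacement** — every parameter pair increased by 10%
  (diagonal cells apply the compounded (1.1)^2 factor to one parameter);
  the displacement is the euclidean norm between perturbed and nominal full
  trajectories on a common grid (terminal-state distance is available by
  flag; the trajectory version is stricter and dimensionally stable),
  averaged over ensemble members and log10-transformed with a 1e-12 floor.
  Rows are clustered by Ward-linkage hierarchical clustering cut at three
  clusters; high/medium/low labels follow cluster-mean order.  The default
  condition is 1 mg/ml initiator.
* **Robustness coefficients** — `alpha = log10(AUC_perturbed /
  AUC_nominal)` for markers C3a/C5a under knockdowns of the C3 and/or C5
  initial conditions (50/90/99%), with and without initiator, averaged over
  an ensemble subset (default Pareto rank < 5).  A zero nominal AUC raises;
  a zero perturbed AUC maps to -inf.

## Synthetic data

The generator simulates the default network at doses
{0, 0.001, 0.01, 0.1, 1} mg/ml, samples 8 evenly spaced time points over
the 6 h horizon (excluding t = 0), and applies multiplicative log-normal
noise `value * exp(sigma * xi)` with sigma = 0.05 — an immunoassay-like
constant CV, chosen because no published error model exists for this kind
of serum time series.  Doses 0 and 1 are tagged train, the rest validate.
What the generator does *not* emulate: inter-donor variability, assay
detection limits and censoring, non-uniform sampling, or any systematic
model mismatch — synthetic-data tests therefore demonstrate pipeline
correctness and recoverability, not that this network describes any
particular laboratory data set.

## Numerical choices and degenerate inputs

* Hill and saturation terms are evaluated via `(x/K)^n` or its reciprocal,
  whichever ratio is below one, to avoid overflow at extreme states.
* Min-max scaling of a constant series raises a degenerate-scaling error.
* A simulation failure inside an objective returns +inf (optimizers treat
  the point as infeasible); inside ensemble simulation the member is
  skipped and counted; inside the sensitivity scan the evaluation is
  imputed with the worst finite value.
* The C5-knockdown / C3a-marker robustness coefficient is structurally
  zero but computed from two independent adaptive solves, so it is asserted
  to integrator tolerance (1e-6), not to machine precision.
* Knockdown fractions outside [0, 100] and unknown species/parameter
  references raise immediately, with every violation listed when a model
  file is loaded.

## Known limitations

* The reaction list is a reconstruction constrained to 18 states and 28
  parameters; the model file format exists precisely so users can patch the
  network without code changes.
* Fluid phase only: no surface compartments, no membrane regulators
  (MCP/DAF), no MAC, no C2-bypass.
* The tau rule is hard-wired to C5a/C5b; other species cannot currently be
  initiator-scaled from a model file.
* Binding is irreversible; no thermodynamic consistency checks.
* The desk-scale optimizer budgets recover noise-floor fits of the
  28-parameter model from synthetic data, but no identifiability analysis
  is performed; parameters remain collectively underdetermined, which is
  the reason the package works with Pareto ensembles rather than point
  estimates.
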