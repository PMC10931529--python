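# Methods

## Problem setting

`grayode` addresses two inverse problems for ordinary-differential-equation
models in systems biology, given sparse and possibly noisy time series of a
subset of state variables:

1. **Parameter discovery** — infer free rate constants of a fully specified
   model within prescribed search ranges.
2. **Gray-box identification** — a term of the right-hand side is unknown;
   recover it first as a time function, then distil that function into a
   closed-form expression over the state variables.

Two benchmark systems are bundled. The *pharmacokinetics* (PK) model tracks
a single 0.1 μg dose of tetracycline through GI tract `G`, bloodstream `B`
and elimination `U`:

    dB/dt = kg·G − kb·B,   dG/dt = −kg·G,   dU/dt = kb·B,

with absorption `kg = 0.72 h⁻¹` and elimination `kb = 0.15 h⁻¹`; total drug
amount is conserved exactly. Its gray-box variant replaces the entire first
right-hand side by an unknown `h(t)`, whose ground truth reduction is
`0.72·G − 0.15·B`.

The *ultradian glucose–insulin* model has six states — plasma insulin `Ip`,
interstitial insulin `Ii`, glucose `G`, and a three-stage linear delay
filter `h1, h2, h3` — with sigmoidal secretion/utilisation functions
`f1..f4`, an insulin-sensitivity scale κ = (1/C4)(1/Vi + 1/(E·ti)), and an
exogenous meal input `IG(t) = Σⱼ mⱼ·k·exp(k(tⱼ−t))·1[t≥tⱼ]` (the unit step
is a deliberate reading: the printed exponential grows without bound before
the meal, while a delivery *rate* must be causal and bounded). Its gray-box
variant replaces the insulin exchange/clearance terms of the first two
equations by unknowns `f(t)` and `g(t)` with reductions
`f = −(E/Vp + 1/tp)·Ip + (E/Vi)·Ii` and `g = (E/Vp)·Ip − (E/Vi + 1/ti)·Ii`
(coefficients −0.2333/0.0182 and 0.0667/−0.0282 at nominal parameters).

Model time units are explicit (hours for PK, minutes for the endocrine
model) and never converted implicitly. With the nominal parameter table and
the stated initial conditions the endocrine trajectory relaxes to a fixed
point near G ≈ 10,630 with small meal-driven excursions; it does **not**
sustain ultradian oscillations (see "Known limitations").

## Random-projection collocation solver (`grayode.xtfc`)

Each state is written as a *constrained expression*

    u(t) = (σ(t) − σ(t₀))ᵀ β + u(t₀),      du/dt = c σ′(t)ᵀ β,

where σ is one hidden layer of `L` tanh neurons whose input weights and
biases are drawn once, uniformly from `weight_range` (default (−1, 1)), and
never trained — an extreme learning machine. The subdomain `[t₀, t_f]` is
mapped linearly onto the activation interval `[0, 1]`, so the mapping
coefficient is `c = 1/(t_f − t₀)`. The expression equals the initial value
*identically* for every β; unknown terms use the unconstrained form
`h(t) = σ(t)ᵀ β_h`.

The solve stacks, per equation, ODE residuals at `N` equispaced collocation
points and, per observed state, data residuals at the observation times
inside the subdomain, and iterates Gauss–Newton. Numerical choices that
matter:

- **Minimum-norm solutions, not steps.** Each iteration solves the
  linearised system for the next iterate directly, so rank deficiency
  (typical: ~50 residuals vs. hundreds of output weights) resolves to the
  minimum-Euclidean-norm solution through the pseudoinverse. Anchoring the
  *solution* rather than the *update* re-regularises null-space components
  every iteration; without it, interface errors in unobserved states grow
  geometrically (measured gain ≈ |−10| per subdomain on the 1800-point
  endocrine run) and the chain diverges.
- **Row and column scaling.** Residual rows are weighted by the reciprocal
  of a per-state magnitude (from the subdomain's initial condition and
  in-window data) and the minimum-norm objective uses the same scales per
  column, so "small" weights mean small in relative state units. States
  with no data get a 50× looser anchor (`unobserved_loosening`): their
  level must come from the coupled equations, and a stiff anchor to the
  chained initial condition turns small interface errors into a growing
  oscillatory mode (a 10× loosening brings the measured gain from 1.07 to 0.89 per
  subdomain at the reference basis seed; 50× keeps the chain stable across
  all tested basis seeds).
- **Backtracking and damping.** Pure Gauss–Newton steps are halved until
  the residual norm decreases (full steps survive on affine problems, so
  the PK system still converges in one iteration). When free parameters
  with box bounds are present, a Levenberg–Marquardt damping acts on the
  parameter block only — the weakly identified directions stay put while
  the output weights keep their minimum-norm solve — and parameters are
  projected back onto their unit-box scaling of the search range after
  each step. Initial guesses are the midpoints of the search ranges.
- **Convergence** when the step max-norm or the change of ‖residual‖₂
  falls below `tol` (default 1e-6); sustained growth of the residual
  raises an error naming the failing subdomain.
- **Domain decomposition.** The horizon splits into subdomains of length
  `t_step`; the constrained expression's terminal value seeds the next
  subdomain, making the concatenated trajectory continuous by construction.
  Parameters are estimated in the first subdomain and frozen afterwards
  (further subdomains refit states only); forward solves default to
  `t_step = span/10`, which reaches ~1e-9 absolute accuracy on the PK model.
  For noisy data the published protocol uses a single domain (no
  decomposition) to avoid overfitting, and so do we.

Sensitivity worth knowing: accuracy depends strongly on the random-weight
interval. A smooth basis (±1) wins at sparse data (50 points), a richer
basis (±2) wins at dense data (100 points) and for parameter discovery;
the reproduction protocols in `grayode.experiments` therefore carry the
interval as part of each experiment's hyperparameter set, exactly as the
published per-experiment (N, L, t_step) rows do.

## Physics-informed network solver (`grayode.pinn`)

A dense tanh *main* network maps time to all states and a second *aux*
network maps time to the unknown terms. The composite loss is

    L = λ_IC·L_IC + λ_data·L_data + Σ_s λ_ode,s·L_ode,s ,

mean-squared mismatches of initial conditions, data, and collocation
residuals (state derivatives are exact forward-mode tangents propagated
through the network — no finite differences). Residuals are normalised by
the per-state output scales so all components are O(1). λ_data = λ_IC = 1;
the per-equation λ_ode may be trained by gradient ascent (max–min saddle),
clamped at a small positive floor.

Input pipeline: time divided by scale `T` (10 for PK, 100 for the endocrine
model), an optional feature layer `{t̃, sin ωt̃, cos ωt̃}` with ω taken from
the dominant FFT peak of the data when requested, per-state output scales
`k` (data magnitudes for observed states; unobserved states default to the
smallest observed magnitude, since their own level is unknown before the
fit), and an optional anchor that adds the straight line through the first
and last data points with a smooth mask `tanh(t̃/0.05)` vanishing at t₀ so
the initial condition stays exact. Free parameters train as unconstrained
reals mapped onto their search ranges by a scaled sigmoid, initialised at
the range midpoints.

Training is staged — supervised warm-up (data + IC), full loss with Adam,
then an L-BFGS polish (scipy, driven by the same autodiff gradient, with
tolerances tightened so the iteration cap is the binding limit; the default
stopping rule otherwise quits after a handful of steps). The engine is a
small in-repo reverse-mode autodiff over numpy (`grayode.autodiff`); ODE
right-hand sides enter the graph through a custom node whose pull-back uses
the model's analytic state Jacobian.

**Schedules.** The published protocols run 3e4–1e6 Adam iterations on GPUs.
This package uses short-Adam + long-L-BFGS schedules (e.g. 1,000 + 1,000
for PK parameter discovery; 500 + 2,000 + 2,000 for PK gray-box;
500 + 2,000 + 3,000 for the endocrine gray-box), which reach equal or lower
error in a few thousand iterations; `grayode.experiments` records the
exact schedule behind every reported number.

## Symbolic distillation (`grayode.symbolic`)

A genetic-programming engine over expression trees with operators {+, −, ×},
variables, and real constants. The initial population contains the generic
simple structures a ramped initialisation would produce (bare variables,
scaled variables, pairwise scaled sums) plus random trees; evolution uses
tournament selection, subtree crossover, point/subtree/constant mutation,
elitism, and an optional simulated-annealing acceptance schedule for
worsening offspring. Whenever a structure improves the best loss at its
complexity (node count), its constants are refined by Levenberg–Marquardt
least squares — this constant refinement is what reaches the published
4-decimal coefficient precision.

The per-complexity best-loss front is scored by
`score_i = −Δ log(loss)/Δ complexity`, and one candidate is selected either
as the highest score among expressions with loss ≤ 1.5× the minimum
("score band", default) or at the point where loss improvement per added
node stagnates ("loss plateau"). For noisy targets an L1 fitness with a
complexity penalty scaled by `1/s` is available; the printed "identity
matrix over the noise scale" regulariser is not well defined for a scalar
loss, so this package reads it as (1/s)·(node count), switchable off.

Features are the designated state variables (PK: `G, B`; endocrine:
`Ip, Ii`); the fit is over states, not time, so long series are thinned to
400 rows before the search. An `evolve`-compatible external engine can be
substituted by any callable honouring the same table/front contracts; the
built-in engine is the reference implementation and the test target.

## Synthetic data (`grayode.synthetic_data`)

All inputs are manufactured: a tight-tolerance adaptive Runge–Kutta solve
(rtol 1e-10) or the collocation solver produces dense trajectories; `M`
equispaced points (including t₀) of the requested states are subsampled;
noise is uniform multiplicative, `y·(1 + n·ξ)` with ξ ~ U(−1, 1) i.i.d. per
state and time point — the single noise mechanism supported, applied to
every datum including the initial one (solvers that need exact initial
conditions use the model's, not the datum). What this generator does *not*
emulate: measurement schedules with gaps, heteroscedastic or additive
sensor noise, model mismatch between the simulated and fitted dynamics.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated noise model, not robustness to real assay artefacts.

## Problem sizes used for the reported numbers

Data sizes, noise levels, and collocation/neuron counts follow the
published tables exactly (PK: 10–100 points over [0, 50] h; endocrine:
360–1800 points over [0, 1800] min; noise 1–10 %). The network training
schedules are the desk-scale ones above; stochastic results aggregate over
5–10 seeds (median for recovery errors, mean for the 10-seed parameter
protocol).

## Known limitations

- The printed endocrine parameter set yields a damped fixed point, not
  sustained ultradian oscillations; the interstitial-insulin balance term
  `g` nearly cancels there (‖g‖_rms ≈ 0.26), so *relative* errors on `g`
  are ~10× more sensitive than they would be on an oscillatory trajectory.
- The 1800-point endocrine gray-box chain is stable when observation times
  are subsampled from a dense simulation grid, but can destabilise when
  the data spacing is incommensurate with the subdomain length (alignment
  drift between data and collocation points). `grayode.experiments`
  subsamples from the dense reference for this reason.
- Recovery error under multiplicative noise is noise-realisation dependent
  (median ≈ 5 % at 10 % noise for the single-domain PK protocol, range
  roughly 2–10 % across realisations).
- The collocation solver's accuracy is sensitive to the random-weight
  interval; no single interval is best across data densities (see above).
- Unknown terms are recovered as functions of time only; distillation
  assumes the designated feature variables suffice to express them.
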