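# Methods

## The model

`stapaw` models *C. elegans* chemotaxis as a hierarchy with three levels.

**States.** A latent discrete state `z_t` (steer-enriched S or turn-enriched
T; any number of states is supported) follows an input-driven Markov chain.
The transition logit from state `i` to `j != i` is a temporal kernel
`K_ij` applied to the recent history of the experienced concentration
`C`; the diagonal logit is a per-state baseline `b_i` controlling the
self-transition (dwell) probability:

    P(z_{t+1} = j | z_t = i)  ∝  exp( K_ij · C_hist + b_i · 1[i = j] ).

**Turn decision.** Within a state, a Bernoulli variable `q_t` chooses
between emitting a sharp turn (`q = 1`) and weathervaning (`q = 0`)
through a range-limited logistic of filtered concentration and
turn-magnitude history:

    P(q_t = 1 | z)  =  m_z + (M_z - m_z) / (1 + exp(K_C · C_hist + K_h · |dθ|_hist)),

so the turn probability is bounded in `[m_z, M_z]` for any input.  Note
the sign convention: a large *positive* filtered drive pushes the
probability to its minimum.

**Kinematics.** Given `(z, q)`, the heading change `dθ` (radians,
counter-clockwise positive, wrapped to `(-π, π]`) is drawn from

* `q = 1` (turn): a mixture of a uniform circular component (weight
  `α_z`) and a von Mises centered on `π` with concentration `κ_tr`
  (reversals);
* `q = 0` (weathervane): a von Mises with mean `-K_dCperp · dC⊥_hist`
  and concentration `κ_wv`, where `dC⊥` is the concentration difference
  between virtual sensors offset perpendicular to the heading — the
  steering signal.

The step displacement `dr` (cm) is Gamma distributed with a separate
(shape, scale) per `(z, q)`.  Heading change and speed are conditionally
independent given `(z, q)`.

With one state the model reduces to the stateless dPAW model; clamping
the transition kernels to zero gives a plain HMM; additionally removing
the sensory emission kernels gives a sensory-blind null model.  These
reductions are exact (tested by likelihood equality) and define the four
model families used in model comparison.

### Temporal kernels

All kernels are coefficients on a raised-cosine basis (default 4 bumps
over 14 lags ≈ 5 s of history at the 5/14 s step), giving smooth,
low-dimensional filters.  History windows at track starts are
zero-padded, which equals the dataset mean after standardization.
Sensory inputs (`C`, `dC⊥`) are z-scored with dataset-level constants
that are **stored in the parameters**, so that simulation and fitting
apply identical filtering.  This matters more than it may appear: the
kernels carry no intercept terms, so refitting with a shifted
concentration mean silently changes the operating point of any kernel
whose weights do not sum to zero.  Workflows that fit simulated data
therefore pass the generator's standardization into the fit; workflows
on external data estimate the constants from the dataset once and keep
them.

## Inference

Fitting maximizes the marginal log-likelihood by
expectation-maximization.  The E-step is the scaled forward-backward
recursion per track (initial state distribution: stationary law of the
mean transition matrix).  The M-step maximizes the expected
complete-data log-likelihood block-wise under constraints:

* turn-decision block `(m, M, K_C, K_h)`: L-BFGS on logit-transformed
  parameters with analytic gradients.  Two numerical safeguards matter
  here.  First, near `m = M` the kernel gradients vanish (they carry a
  factor `M - m`), making the collapsed input-independent decision a
  saddle; the block therefore also tries a restart with the range
  re-opened and keeps the better optimum.  Second, when the filtered
  drive never reaches the logistic extremes the likelihood is flat in
  the range direction; a weak exponential shrinkage on `M - m`
  (30 nats at full range, applied only to multi-state fits) pins the
  estimate to the identified constant rate instead of letting it wander
  on the ridge.  Identified decision ranges are affected at the
  sub-percent level.
* turn-heading mixture `(α, κ_tr)`: closed-form inner EM with the von
  Mises mean fixed at `π`.
* weathervane block `(K_dCperp, κ_wv)`: L-BFGS with analytic gradients.
* Gamma speed blocks: weighted maximum likelihood (Newton on the shape
  equation, moment start).
* transition block `(b, K_ij)`: multinomial logistic regression on the
  pairwise posteriors — convex given the posteriors — with analytic
  gradients; with transition kernels clamped (HMM family) the baselines
  have a closed form from expected counts.

Each block starts from the current parameters and is kept only if it
improves its objective, so the training log-likelihood is monotone
(enforced with a revert-and-stop guard against optimizer round-off).
Block optimizers run with tight tolerances (`ftol 1e-13`); loose
defaults demonstrably stall EM ~1e-3 nats short of the optimum.

**Initialization** follows the dPAW-anchored scheme: fit the
single-state model (moment-based start, same EM machinery), replicate it
across states, and apply seeded perturbations (0.1 relative scale on
transformed scalars and kernel coefficients; baselines start near a 0.9
stay probability).  The recommended driver `fit_model` additionally
performs up to two *decision-refresh restarts*: observed large heading
changes (|dθ| > 50°) are a near-label for the turn decision, so a
state-marginal-weighted logistic regression of those events on the
decision features re-seeds the decision kernels with the range
re-opened, and EM continues; the restart is kept only if the final
log-likelihood improves.  This reliably escapes the `m = M` collapse
basin described above.

**Convergence**: |Δ log-likelihood| below `1e-4` per 1000 steps of data
(default), at most 100 iterations; fits on the synthetic fixtures
typically converge in 15–40 iterations.

**Model comparison** uses track-level k-fold cross-validation (defaults:
3 folds, 5 seeded initializations per fold, best-training-likelihood
initialization evaluated on the held-out tracks), reporting test
log-likelihood per second of data and its difference to the null model's
mean.

**State labels** are canonicalized after fitting: states are ordered by
their midpoint turn probability, so the steer-enriched state is index 0
and the turn-enriched state is the last index.  Evaluation against known
labels uses Hungarian matching; ties in argmax decoding go to the lower
state index.

## The synthetic-data generator

`simulate.fixture_params` provides documented ground-truth presets; the
closed-loop simulator draws states and kinematics per step (sense →
transition → decide → emit → move, reflecting arena boundary).  The
`paperlike-2state` preset encodes the reported two-state phenomenology:

* dwell times of 4.6 s (T) and 8.1 s (S) under zero sensory drive,
  encoded exactly in the transition baselines;
* mirror-image, derivative-shaped transition kernels — enter T when
  concentration falls, leave it when concentration rises.  The biphasic
  window spans ~2 steps on each flank: exit gating must be commensurate
  with heading persistence inside a turn bout or it averages away.  The
  kernel gain is sized so that run-speed motion along the default linear
  gradient (0–50 mM across 9 cm) shifts the transition logit by ~1.5.
  Derivative-shaped targets are projected onto the raised-cosine basis
  under a zero-sum constraint; the unconstrained projection of a sharp
  biphasic profile leaks a net offset that couples the kernel to the
  absolute concentration level (in a gradient this traps simulated
  animals in runaway turn bouts);
* a steer-enriched state with rare turns at a constant low rate
  (0.04 per step ≈ one per 9 s), active but weak weathervane steering,
  and higher Gamma speed (mean 0.012 cm/step ≈ 0.34 mm/s, roaming-like);
* a turn-enriched state with ~2 turns per bout (matching the reported
  ~1.9 reversals per transition), lower speed, an integrating turn
  kernel (turn more when concentration is low) and a refractory
  heading-history kernel;
* turn mixture weight α = 0.2 and reversal concentrations κ_tr = 3.0/2.5
  — values chosen so every scalar of the recovery fixture is estimable
  at its ~5×10⁴-step size (a recovery validation is only meaningful if
  the generative components are distinguishable).

`hmm-2state` zeroes the transition kernels, `dpaw-1state` is a
single-state control with deliberately mild kernels (its inter-turn
intervals stay close to a single exponential), and `opto-2state` adds
optogenetic kernels driving entry into the turn state.

What the generator does **not** emulate: body posture and undulation,
worm–worm interaction, plate-boundary artifacts, sensory adaptation
beyond the kernel window, slow behavioral drift (roaming/dwelling), or
measurement noise in tracking.  Passing tests therefore validate the
inference and the model's internal logic, not its fit to any particular
real recording.

## Reinforcement-learning model

The RL agent is a two-action POMDP reduction: constant speed, action 0
emits weathervane-like heading changes (von Mises around zero), action 1
emits the turn mixture; the policy is a two-parameter logistic on the
one-step concentration difference experienced while moving, trained by
REINFORCE (discounted return, per-time-step batch-mean baseline — a
variance reduction that leaves the gradient expectation unchanged) with
Adam.  The reward is the negative distance to the source minus a
switching penalty: an exponential filter of the actions (5-step time
constant, unit gain) weighted by λ = 0.1, which discourages pathological
rapid alternation.  Defaults: Gaussian source (amplitude 50, σ = 1.5 cm),
episodes of 400 steps starting 3 cm from the source, 16 episodes per
epoch, learning rate 0.05, discount 0.98, 1000 epochs (validation runs
use 300, by which point the policy has converged).  The weathervane
action carries an optional perpendicular-difference steering term whose
default gain is zero: the reduction deliberately gives the agent no
steering channel, so any performance must come from switching.  The
observation is taken after the move; episodes run to a fixed horizon;
the chemotaxis index counts final positions within 0.5 σ of the source.

Controls: `shuffled` permutes a trained agent's action sequence within
episode (identical aggregate kinematics, sensory-independent timing),
`fixed0`/`fixed1` lock one action, `iid` draws actions at the trained
mean rate.

## Circuit model

Two rate units (S, T) with mutual inhibition (`J_ST = J_TS = -5`,
rectified-linear rates, τ = 1 s, Euler dt = 0.1 s) receive an adapting
ON-type input `I = F - S`, the fast-minus-slow filtered concentration
(α = 0.1, β = 0.5, γ = 0.3 s⁻¹); the S unit receives `+3 I`, the T unit
`-3 I`, so rising concentration favors running — equal input weights on
both units cannot break the S/T symmetry at all.  Unit noise is white
with √dt scaling and amplitude 2.0: the circuit operates in a
noise-dominated regime where an instantaneous readout of the input is
unreliable and the attractor structure created by mutual inhibition acts
as a drift-to-bound integrator.  The more active unit dictates behavior;
argmax ties stick to the current winner.  Behavior per winner: the steer
unit runs at 0.05 cm/s with weak heading jitter; the turn unit initiates
committed reversal maneuvers (probability 0.15 per step, ~1 s arc
through π at low speed) — a turn takes time, as an omega turn does, so
noise-driven flicker into the turn state is costly.  Removing the
inhibition (`J = 0`) leaves the same units, inputs, noise and behavior
map but destroys state persistence; the motif-vs-control comparison
(chemotaxis index from 200 trajectories of 20 minutes) isolates the
contribution of persistent, sensory-gated states.  None of the circuit
constants are claimed to be measured values; they are package defaults
chosen to produce seconds-scale switching and to realize the qualitative
comparison in a robust regime.

The printed equation applies the rate nonlinearity to the postsynaptic
voltage inside the coupling sum; we read it as the standard presynaptic
form `Σ_j J_ij φ(x_j)`.

## Behavioral statistics

* Turn detection: onsets where |dθ| first exceeds 50°; consecutive
  supra-threshold steps yield one event.
* Inter-turn intervals are pooled across tracks (never spanning
  tracks) and fit with single/double exponentials by nonlinear least
  squares on the log-density over 32 log-spaced bins; R² is computed on
  the same log-density (a single exponential fit to two-timescale data
  then fails conspicuously).  The double fit reports the crossing time
  `t_c` of its components, `log(w₁λ₁/w₂λ₂)/(λ₁-λ₂)`, the classical
  pirouette-merging threshold.
* The classical pirouette heuristic merges turns closer than `t_c` into
  bouts spanning first-to-last turn.
* Bearing `B` is the angle between heading and the local gradient,
  folded to [0°, 180°]; "aligned" means strictly `B < 90°` (exactly 90°
  counts as not aligned).  Exit/entry instants are the step on which the
  state changes; single-turn bearings use the post-turn heading at the
  event step.  The aligned-fraction uncertainty uses 50 bootstrap
  resamples of 2000 events.
* The shuffled control permutes turn-angle magnitudes across events and
  replays headings before re-measuring bearings.
* The chemotaxis index is the fraction of tracks ending within a given
  radius of the source.

## Numerical choices and degenerate inputs

* von Mises densities use exponentially-scaled Bessel functions; Gamma
  densities floor the displacement at 1e-4 cm (stationary frames).
* `A(κ) = I₁/I₀` is inverted by a Banerjee start plus Newton steps,
  clipped to [1e-3, 1e4].
* Transition softmax rows subtract their row maximum; forward-backward
  uses per-step scaling, never raw products.
* Angle wrapping maps to the half-open interval `(-π, π]` (so `-π` and
  `π` are the same event, counted once).
* Preprocessing: centered moving average over 5 raw frames (the
  smoothing method is not dictated by the data source; this is the
  minimal parameter-light choice), downsample every 5th frame of 14 Hz
  input (step 5/14 s), differentiate; the first two downsampled points
  carry no defined heading change and are dropped.  Track filters: at
  least 1 cm² bounding-box area and 3 minutes duration.
* The virtual sensor offset for `dC⊥` is 0.05 cm (approximate head-sweep
  scale), configurable.

## Known limitations

* EM finds local optima; the refresh restarts remove the dominant
  failure mode on fixture data, but fits to richer data should still use
  several seeds (the cross-validation driver does).
* The mixture weight α and, to a lesser degree, κ_tr are weakly
  identified when the uniform pedestal and the reversal mode overlap;
  at the fixture's data size their errors are at the ~10% level.
* The decision range upper bound `M` is one-sided unidentifiable when
  the filtered drive never drives the decision toward it; the shrinkage
  prior returns the identified constant rate in that case, which is the
  defensible point estimate but not a substitute for data that explore
  the nonlinearity.
* Transitions are first-order Markov given the filtered input; dwell
  distributions are geometric at fixed drive, not semi-Markov.
* The RL and circuit models are deliberately minimal; neither is fit to
  data, and their quantitative outputs depend on package-chosen
  constants documented above.
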