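# Methods

## Model structure

The ankle is actuated by two antagonistic Hill-type muscle–tendon units: a
lumped mono-articular plantarflexor whose maximal isometric force represents
the combined soleus and both gastrocnemius heads (default 5790 N =
3549 + 1558 + 683), and a dorsiflexor representing the tibialis anterior
(905 N).  Each unit has first-order activation dynamics (τ_act = 15 ms,
τ_deact = 60 ms), an elastic series tendon, a passive parallel element and a
contractile element with active force–length and force–velocity curves.  The
dimensionless curves use the smooth exponential/Gaussian/log
parameterization of De Groote et al. (2016): a tendon stiffness constant of
35, a three-Gaussian active force–length surface peaking near the optimal
fiber length, a passive exponential reaching 1 at 60 % strain, and a
logarithmic force–velocity curve with a bounded eccentric plateau (~1.79).
Pennation follows a constant-muscle-thickness model
(l_m·sin α = l_m,opt·sin α_opt).

Ankle geometry maps the joint angle q (plantarflexion positive, radians) to
musculotendon length by a polynomial lmt(q) = Σ cᵢ qⁱ; the moment arm is the
exact analytic derivative r(q) = −d lmt/dq, so the plantarflexor arm is
positive (~5 cm at neutral) and the dorsiflexor arm negative (~−4 cm).
Default degree-4 coefficients are plausible for a scaled generic lower-limb
model over q ∈ [−30°, +30°] and are plain config inputs — users fitting a
specific musculoskeletal model should regenerate them there.

## Controller

Excitations combine a baseline, delayed (τ_m = 30 ms) local feedback —
positive plantarflexor force feedback (gain G_sol) and dorsiflexor
fiber-length feedback (gain G_ta, offset lm_off) with plantarflexor-force
inhibition (G_sol,ta < 0) — and delayed (τ_com = 60 ms) feedback of the
deviation of forward COM velocity from its steady-state cycle (K_sol > 0 for
the plantarflexor, K_ta < 0 for the dorsiflexor).  A smooth stance gate
K_Fz = 0.5·tanh(10·(F_z/(m·g) − 0.4)) + 0.5 multiplies the force, inhibition
and COM terms; the dorsiflexor length term and both baselines are ungated.
Gains are stored signed — no hidden negation.  Excitations are clamped to
[0.001, 1] before the activation dynamics; delays must be integer multiples
of the integration step.  Setting K_sol = K_ta = 0 (or disabling the COM
path) reproduces the local-reflex-only controller bit-identically.

The ΔĊOM signal for online use comes from a pelvis-marker proxy:
backward-difference velocity, causal Chebyshev-I band-pass (defaults
5–50 Hz, 0.140 dB passband ripple, second order), gait phase from 50 N
threshold crossings of the vertical GRF, and a rolling lookup table (1001
phase points) averaging the six most recent unperturbed cycles.  Perturbed
cycles and the first recovery cycle must not be ingested by the learner.
A caveat the corner defaults inherit from the real-time design: a 5 Hz
high-pass also removes near-DC content of the deviation signal, so the
offline identification path uses unfiltered mocap-derived velocity and the
corners are configurable.

## Forward simulation

Trials are integrated with forward Euler at a fixed 1 ms step (configurable;
halving the step changes the simulated moment by ~0.1 % RMS on the synthetic
steady cycle).  The delayed internal signals (plantarflexor force,
dorsiflexor fiber length) are taken from the rollout's own history —
required, because force feedback is part of the dynamics — with delay lines
pre-filled by the initial sample (steady-state hold).  Initial activations
equal the baseline excitations and initial fiber lengths solve the static
equilibrium at the first frame's angle, which removes start-up transients.
The sequential inner loop is JIT-compiled with numba; a pure-Python rollout
built from the public muscle/reflex operations is asserted against it in the
tests.

Numerical design choices, made after the straightforward alternatives proved
ill-conditioned:

- **Damped fiber equilibrium.**  With a fiber-length state, the textbook
  closed-form inversion of the force–velocity curve has slope ~1/(a·f_act),
  which at low activation on a slack tendon makes the fiber ODE stiff beyond
  what a 1 ms explicit step tolerates; the resulting velocity-clamp chatter
  renders the shooting objective noisy at the 1e−6 parameter scale.  The
  fiber velocity is therefore obtained from the damped equilibrium
  a·f_act·f_v(ṽ) + f_pas + β·ṽ = F_t/(f_max·cos α) (normalized damping
  β = 0.1, Millard-style), solved per step by Newton iteration on a strictly
  increasing function.
- **Smooth regime blending.**  The activation/deactivation time constants
  are blended by a steep tanh of (e − a) (steepness 50; exact at |e−a| = 1),
  and tendon slack is floored by a smooth hinge of width 1e−3 normalized
  force.  Both remove derivative discontinuities that otherwise accumulate
  into a fractal-scale objective landscape and defeat finite-difference
  gradients.

## Parameter identification

Seven gains are free by default (G_sol, K_sol, e_ta,0, G_ta, lm_off,
G_sol,ta, K_ta); e_sol,0 is fixed at 0.027 because baseline drive and force
feedback are strongly interdependent.  The objective is the sum over trials
of the mean squared difference between simulated and target ankle moments,
both multiplied by (70·1.75)/(m·h) so that gains are comparable across
subjects; trials are weighted equally.  The bounded problem (physiological
sign conventions: G_sol ∈ [0, 5e−3] /N, K_sol ∈ [0, 5] s/m,
K_ta ∈ [−5, 0] s/m, G_sol,ta ∈ [−5e−3, 0] /N, G_ta ∈ [0, 100] /m, lm_off
within the fiber-length range, e_ta,0 ∈ [0, 0.3]) is solved by
trust-region-reflective least squares with central finite-difference
Jacobians over the shooting rollout.  Multi-start: 8× the requested number
of seeded uniform draws are ranked by one objective evaluation and the best
are polished — plain uniform starts frequently land on excitation-saturation
plateaus (e.g. e_ta pinned at 1 over most of the G_ta box) where a local
solver stalls.  Everything is deterministic given the seed.

Parameter interdependence is quantified at the optimum from the
finite-difference residual Jacobian: the correlation matrix of the
linearized estimator, normalized from (JᵀJ)⁻¹, with |r| > 0.9 flagged and
zero-sensitivity columns (e.g. COM gains on steady-state-only data) reported
as unidentifiable.  Note a structural near-symmetry: e_ta,0 and lm_off enter
the excitation only through e_ta,0 − G_ta·lm_off; the initial condition
(activation = baseline excitation) is the only term breaking it, so their
separate identification rests on the brief start-up transient and their
correlation is high on any dataset.

Cross-validation holds out one perturbation magnitude (default 12 % body
weight): gains are fitted on the remaining magnitudes plus all steady-state
cycles and the held-out trials are evaluated without refitting.

## Synthetic data generator

The generator emulates the two experimental protocols at desk scale with
fully analytic templates (no downloads): slow walking at 0.62 m/s with a
1.4 s stride, an ankle-angle template (periodic spline through early-stance
plantarflexion ≈ +7°, mid-stance dorsiflexion ≈ −10°, push-off ≈ +15°), and
a vertical-GRF template (smooth stance window times a double-Gaussian
M-shape, peak ≈ 1.1 body weight, calibrated so both legs together support
body weight over a stride).  Perturbations are square pelvis-force pulses —
150 ms at 4/8/12/16 % body weight at contralateral toe-off (~12 % phase) for
the identification protocol, 200 ms at 12 % at heel strike for the
exoskeleton protocol — integrated on a point mass with a first-order
recovery decay (τ = 0.5 s, a plain modelling choice: the generator makes no
claim of matching measured human COM recovery).  The target moment channel
is produced by the forward simulation itself under ground-truth gains
(G_sol = 1.8e−4 /N, K_sol = 0.4 s/m, K_ta = −0.2 s/m, remaining values at
Geyer–Herr-scale magnitudes), chosen once so the steady peak moment is
~1.1 N·m/kg with a clear but bounded push/pull modulation; optional Gaussian
noise can be added to any channel (default 0).

What passing tests on this generator do show: the estimator recovers the
parameters of the model class that generated the data, the COM pathway is
necessary and sufficient for directional moment modulation within that
class, and the pipeline is deterministic and numerically convergent.  What
they do not show: fidelity to any individual's gait, to measured GRF/EMG
waveforms, or to human COM recovery dynamics — conclusions about real data
require fitting real trials through the same interfaces.

## Known limitations

- One lumped plantarflexor: biarticular gastrocnemius kinematics are not
  modelled, matching the mono-articular design of the controller.
- The identification trials are single gait cycles simulated independently
  (shooting per cycle); inter-cycle muscle-state continuity is not enforced.
- The default-model fit on COM-perturbed data absorbs what it can into the
  local gains; its reported deficit is therefore a lower bound on the COM
  pathway's contribution.
- Hill-muscle constants and delays are fixed, not estimated (risk of
  overfitting with only 24 cycles); they are config inputs.
- Real-time concerns of a hardware controller (actuator tracking dynamics,
  sensor dropouts, torque safety limits) are out of scope.
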