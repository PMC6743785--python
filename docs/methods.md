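# Methods

`speechsfc` simulates speech motor control as hierarchical state-feedback
control: speech *tasks* (vocal-tract constrictions) are controlled by a
dynamical point-attractor law, articulators by an inverse-kinematics law,
and both laws act on an internal *estimate* of the articulatory state
produced by an Unscented Kalman Filter (UKF) that fuses an efference copy
of outgoing motor commands with noisy auditory and somatosensory
feedback.  This note documents the model, its parameters and defaults,
the numerical choices, and what the bundled simulations do and do not
show.

## Task level

The state of the vocal tract at the task level is a vector of seven
constriction variables `x` (lip aperture LA, lip protrusion PRO,
tongue-body constriction degree/location TBCD/TBCL, tongue-tip
constriction degree/location TTCD/TTCL, velic aperture VEL) and their
velocities.  Each *gesture* in a gestural score drives one task variable
with an independent second-order critically damped attractor

    ẍ_i = m_i⁻¹ ( −b_i ẋ̃_i − k_i (x̃_i − x0_i) ),

evaluated at the **estimated** task state `x̃ = f(ã)`, `ẋ̃ = J(ã) ȧ̃`
(forward kinematics of the estimated articulatory state).  Gestures are
active on half-open intervals `[onset, offset)`; inactive tasks receive
zero task-space command.  `damping: "critical"` resolves to
`b = 2√(mk)` at score load.

Defaults: `m = 1`, `k = 400 s⁻²` (natural frequency ω = 20 s⁻¹, i.e.
~290 ms to settle within 2% — the upper end of typical speech movement
durations).  The bundled scores use 300–500 ms activation intervals so
each gesture completes its movement.

## Articulatory level

The task command is mapped to articulator accelerations by

    ä = J*(ã) ẍ − J*(ã) J̇(ã, ȧ̃) ȧ̃ + (I − J* Jₐ) u_neutral ,

with `J* = W⁻¹Jₐᵀ(Jₐ W⁻¹Jₐᵀ + εI)⁻¹` the weighted right pseudoinverse of
the active rows of the 7×10 kinematic Jacobian (`W = I`, Tikhonov
`ε = 1e-8`).  The final term is a null-space neutral attractor
(`k_n = 10 s⁻²`, critically damped) pulling uncontrolled degrees of
freedom toward the neutral posture; without it, redundant DOFs drift
without bound under motor noise.  It can be disabled in the
configuration.

Jacobians are computed by central differences (step `1e-6`); `J̇` is the
directional derivative of `J` along `ȧ̃`.

## Surrogate vocal-tract geometry

Ten articulators: jaw angle JA, condyle angle CA, condyle length CL,
tongue-tip angle/length TTA/TTL, upper/lower lip vertical ULV/LLV and
horizontal ULH/LLH, velum VEL.  The geometry is planar: a fixed
temporomandibular joint at the origin, an outline of radius
`R(φ) = 5.0 + 0.8·cos(φ − π/2)` cm, and a circular tongue body (radius
2 cm) centred at polar position `(CL, JA+CA)`:

    TBCL = JA + CA                 TBCD = R(TBCL) − CL − 2
    tip  = centre + TTL·(cos, sin)(JA+CA+TTA)
    TTCL = atan2(tip)              TTCD = R(TTCL) − |tip|
    LA   = ULV − LLV − κ_j (JA − JA₀)      PRO = (ULH + LLH)/2

The jaw participates in both the lip and tongue constrictions, which is
what makes task-specific compensation possible.  `κ_j = 2 cm/rad` so
that, under the identity-weighted pseudoinverse, the jaw route
(jaw-up/condyle-down) and the lip route are equally efficient for lip
closure; the articulator range boxes are sized so neither the condyle
angle nor the lips saturate during a bilabial closure over a low vowel
(a saturated articulator silently removes a redundant strategy and
masks compensation).

## Acoustics

Formants come from a closed-form map of the constriction variables
(`d = max(TBCD, 0)` cm, `ℓ = TBCL`, `c = e^{−d/0.5}`):

    F1 = 500 + 180 cos ℓ · c − 190 sin ℓ · c
    F2 = 1500 + 700 sin ℓ · c − 570 cos ℓ · c
    F3 = 2500 + 200 sin ℓ · c − 150·PRO

The map is smooth and many-to-one in the articulators (it factors
through TBCD, TBCL, PRO).  A tight palatal constriction gives
(310, 2200) Hz; a wide tract relaxes to (500, 1500, 2500) Hz.  This map
replaces a tube-based synthesizer; its formant *gradients* with respect
to the articulators are of order 10–100 Hz/cm — shallower than tube
acoustics near constrictions — which matters for the feedback behavior
discussed under Limitations.

One consequence used in choosing fixtures: the F1 gradient changes sign
at `180 cos ℓ = 190 sin ℓ` (ℓ ≈ 0.757) when the constriction is wide,
so a mid vowel placed exactly there makes perceived F1 uninformative
about the articulators.  The bundled schwa target (TBCD 0.30 cm, TBCL
0.75 rad; formants ≈ 501, 1533 Hz) was chosen to maximize the component
of the F1 gradient that is independent of the F2/F3 gradients over
schwa-like operating points, so that auditory feedback about F1 is
actually usable in the perturbation paradigm.

## Plant, noise, and perturbations

The plant integrates `(a, ȧ)` under the commanded accelerations with
classical RK4 at `dt = 5 ms` (exact for piecewise-constant
acceleration), clamping positions to the articulator range box and
zeroing the velocity of any articulator pinned at a bound.  Trials are
1.2–1.5 s (hundreds of control steps).

All noise is zero-mean Gaussian with standard deviation
`level × channel norm`: motor noise is added to the commanded
accelerations, somatosensory noise to the 20 position/velocity channels,
auditory noise to the 3 formants.  Channel norms are the per-group RMS
(positions, velocities, formants, commands) of a noiseless calibration
run of the same score, computed once per experiment.  Baseline levels:
motor/process `1e-4`, auditory `1e-2`, somatosensory `1e-6`.

Perturbations: a **jaw clamp** freezes JA (position held, velocity
zeroed) from a scheduled onset — the observer is never told; a
**perceived-F1 shift** adds a constant (default +100 Hz) to the auditory
F1 channel after noise, leaving produced acoustics untouched.

## Observer

The articulatory state estimator is an augmented-state UKF.  The
augmented vector stacks the 20-dim state, a 10-dim process-noise
component (added to the efference copy inside the process model) and a
23-dim observation-noise component.  Sigma points use the scaled
unscented transform (`α = 1e-3`, `κ = 0`, `β = 2`); the process model is
the plant integrator *without* the range-box clamp (the clamp is plant
physics, and a non-smooth process model breaks sigma-point propagation
when an articulator rests on a bound); the observation model is the
identity on positions/velocities plus the learned auditory map on
positions.  The innovation is the standard `y − ŷ` applied with `+K`
(a difference written the other way round would need `−K`; the code
notes both conventions).  Feedback conditions (both / somatosensory
only / auditory only / none) delete channels outright rather than
inflating their noise.

Internal noise covariances are identity matrices scaled by the raw
noise *levels* (Q = 1e-4·I, R_somat = 1e-6·I, R_aud = 1e-2·I by
default), with the state covariance initialized at `1e-2·I`.  Note this
is deliberately not the covariance of the injected (norm-scaled) noise:
with fully matched covariances the somatosensory channel (relative
precision ~1e-6) would make auditory information weightless and no
auditory compensation could occur at all.  The internal estimates can
be overridden independently of the true levels for estimate≠truth
experiments.

Two covariance policies are provided.  The default, `static`, resets the
state covariance to its initial value each step, so the filter's
relative channel weighting — and hence every feedback phenomenon — is
stationary across a trial.  The alternative, `filtered`, propagates
`P ← P_prior − K P_yy Kᵀ`; it reduces exactly to the classic Kalman
filter on linear-Gaussian systems (verified to <1e-8 against a textbook
implementation) but collapses the gains within a few steps under the
default covariances (posterior position variance falls to ~`R_somat`
and per-step gains to ~1e-4), leaving the loop effectively
feedback-blind on trial timescales; it is therefore not used for the
speech simulations.

## Learned auditory map

The observation model's auditory branch is learned from internally
generated "babbling": 5·10⁴ articulator samples drawn from smoothed
(AR(1), reflected at the range box) random walks, paired with noise-free
formants.  The learner is a receptive-field local-linear ensemble in the
spirit of locally weighted projection regression: (1) an input metric is
adapted to the map's active subspace, estimated from gradients of local
linear fits at ~50 anchor neighborhoods (this is what defeats the curse
of dimensionality — the formants vary along ~3 of the 10 input
directions); (2) 600 receptive-field centres are placed by mini-batch
k-means in the adapted metric; (3) each centre carries a
Gaussian-weighted ridge linear model (bandwidth 0.7× the median
centre spacing); predictions blend the local models with normalized
kernel weights and are deterministic after fitting.  On a 90/10
held-out split the map reaches ≈1 Hz mean absolute F1 error and ≈3–4 Hz
F2 error, within the 4.2/6.6 Hz budget the simulations assume.  Fit
error is largest where babbled coverage is sparse (verified as a
negative rank correlation between binned sample density and error).

## Closed loop and experiments

Each control step: estimate task state from the articulatory estimate →
task command → inverse kinematics → plant step (noise, perturbations) →
noisy observation → UKF correction.  Trials are bitwise reproducible
from `(config, seed)`.  A trial whose estimate leaves five times the
articulator range box (or goes non-finite) is flagged divergent and
excluded from condition metrics but counted.

* **Feedback conditions**: n trials per condition on the [ǝ a i]
  sequence; metrics are tongue-centre endpoint variability (bootstrap
  95% intervals, 1000 resamples), condyle angle/length endpoint
  variability, and mean articulatory prediction error.
* **Noise sweeps**: single-channel feedback with the channel's true
  noise and the observer's internal estimate varied in tandem.
* **Jaw clamp**: the jaw is fixed from the midpoint of the consonant's
  closing *movement* (the first instant the task variable has covered
  half its distance to target in the unperturbed trial).  Outcomes are
  the extra upper-lip lowering / lower-lip raising relative to the
  unperturbed trial and whether lip closure (< 0.1 cm) is still reached.
* **F1 perturbation**: sustained [ǝ], +100 Hz added to perceived F1
  after a 200 ms stabilization window; compensation is the
  baseline-minus-perturbed mean produced F1 over the final 25% of the
  trial, seed-paired and averaged over ≥20 seeds.

## What the simulations show — and known limitations

The architecture reproduces, with the defaults above: partial auditory
compensation (~5–8 Hz, i.e. ~5–8% of a 100 Hz shift) without any
auditory target; its modulation by somatosensory acuity (more
somatosensory noise → more compensation, less → less); task-specific
jaw compensation (lip recruitment for a bilabial, none for a tongue-tip
consonant, closure still achieved); near-perfect control under
somatosensory feedback with variability falling monotonically as
somatosensory noise falls; and unbounded dead-reckoning drift without
feedback.

Several phenomena reported for tube-based plants do **not** reproduce
under this surrogate map, for reasons that are themselves instructive:

* **Compensation magnitude.**  The F1 and F2 gradients of the
  closed-form map are nearly collinear in articulator space (both factor
  through the same (ℓ, d) coordinates), so an F1-only innovation is
  largely inconsistent with the unchanged F2/F3 channels and the
  filter discounts it.  A fixed-point analysis of the fusion caps
  compensation near 10% over all schwa-like operating points; the loop
  realizes ~6–8%.  Reported values of ~15–20% require a plant whose F1
  carries more F2-independent articulatory information.
* **Auditory-channel behavior.**  The internal auditory covariance
  (1e-2·I) trusts formants to ~0.1 Hz while the injected noise is
  ~17 Hz; combined with the shallow gradients, auditory-only corrections
  inject ~0.3 cm/step estimate jitter.  Auditory-only trials therefore
  diverge at baseline noise (becoming stable only at levels ≤ 1e-4 — the
  *opposite* end of the scale from a steeper-mapped plant), "both"
  exceeds "none" in endpoint variability, and auditory-only error falls,
  rather than rises, as its noise falls.  Lowering the auditory trust
  would stabilize these conditions but would abolish compensation; the
  two regimes cannot be reconciled under this acoustic map.
* **Deterministic equilibria.**  With zero sensory noise the coupled
  filter–controller loop can settle at an equilibrium away from the
  filter's own fusion fixed point (the controller pins the estimate,
  leaving a K·innovation = 0 trap); baseline auditory noise dithers the
  loop toward the fusion solution.  Compensation signs in the noiseless
  limit are therefore not representative of the noisy model.
* The generator's babbled workspace, the surrogate geometry and the
  closed-form acoustics emulate the *structure* of articulatory data
  (smooth redundancy, many-to-one acoustics, contact saturation) but
  none of its anatomical detail; passing tests show the control and
  estimation machinery behaves as specified on this surrogate, not that
  the specific centimetre- or Hertz-scale numbers transfer to a real
  vocal tract.

Other scope limits: no sensory delays of any kind; a kinematic plant
(no gravity, tissue elasticity, or force-level control); no gesture
blending (overlapping gestures on one task variable are rejected); no
waveform acoustics; scores are inputs, not derived from phonology.
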