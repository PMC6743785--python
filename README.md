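# speechsfc

Hierarchical state-feedback control simulation of speech motor control.

Speaking requires moving the vocal tract quickly and precisely even
though the brain never observes the articulators directly: sensory
feedback is noisy (and in reality delayed), and motor commands are
corrupted by noise.  `speechsfc` implements the state-feedback-control
answer to this problem for speech, and the simulation paradigms used to
probe it: a **task-level controller** drives vocal-tract constriction
goals (gestures) as critically damped point attractors,

    ẍ = M⁻¹(−B ẋ̃ − C (x̃ − x₀)),

an **articulatory controller** converts task accelerations to
articulator accelerations through a weighted Jacobian pseudoinverse,

    ä = J*(ã) ẍ − J*(ã) J̇(ã, ȧ̃) ȧ̃,

and both act not on the true state but on an estimate `ã` maintained by
an **Unscented Kalman Filter** that combines an efference copy of the
outgoing command (via an internal copy of the plant integrator) with
noisy auditory (formants F1–F3) and somatosensory (articulator
positions and velocities) feedback, `ã = â + K (y − ŷ)`.  The
articulatory-to-formant observation model is *learned* from internally
generated babbling data by a receptive-field local-linear ensemble.

The plant is a self-contained surrogate vocal tract: a planar geometry
with ten articulators (jaw, condyle, tongue tip, lips, velum), seven
constriction task variables, and a smooth closed-form constriction-to-
formant map.  No external data are needed anywhere.

Bundled experiments: feedback deprivation (both / somatosensory-only /
auditory-only / none), single-channel sensory-noise sweeps, a
mechanical jaw clamp during consonant closures (task-specific lip
compensation), and a +100 Hz perceived-F1 perturbation during a
sustained vowel (partial auditory compensation without any auditory
target).

## Worked example

Train the auditory forward map on 50 000 babbled samples, then measure
the response of the closed-loop model to a +100 Hz perturbation of the
perceived F1 during a sustained [ǝ]:

```python
import speechsfc as s

data = s.babble(50_000, seed=1)
train, held = s.train_test_split_babble(data, seed=1)
amap = s.AuditoryMap(random_state=1).fit(train.positions, train.formants)
fit = s.evaluate_fit(amap, held, train)
print(f"held-out |error|  F1: {fit.mean_abs[0]:.2f} Hz   F2: {fit.mean_abs[1]:.2f} Hz   (n={fit.n})")

score = s.sustained_schwa_score()
config = s.calibrate(score, s.SimConfig(), amap)   # fills channel norms
res = s.f1_perturbation(score, config, amap, shift_hz=100.0, n_seeds=20, seed=0)
print(f"compensation to +100 Hz F1 shift: {res.compensation_hz:.1f} Hz "
      f"({res.compensation_pct:.1f}% of the shift) over {res.n_seeds} seeds")
```

which prints:

```
held-out |error|  F1: 1.15 Hz   F2: 4.03 Hz   (n=5000)
compensation to +100 Hz F1 shift: 6.4 Hz (6.4% of the shift) over 20 seeds
```

The first line says the learned articulatory-to-formant map predicts
held-out formants to ~1 Hz (F1) and ~4 Hz (F2) — accurate enough that
the observer's auditory predictions are limited by sensory noise, not
model error.  The second line is the signature result: even though the
model has **no auditory target** (its goals are constrictions), shifting
the *perceived* F1 up biases the state estimate, the constriction
controllers "correct" the apparent error, and the *produced* F1 drops —
a partial compensation, here ~6% of the shift.  Compensation grows when
somatosensory noise is raised and shrinks when it is lowered, because
the Kalman gain reweights the two sensory channels (see
`docs/methods.md` for what does and does not reproduce under this
surrogate plant, and why).

A command-line interface wraps the same library calls:

```sh
speechsfc train-forward --n 50000 --seed 1 --out map.json
speechsfc simulate --map map.json --feedback both --seed 1 --out traj.csv
speechsfc experiment f1-perturb --map map.json --out results/
speechsfc experiment jaw-perturb --map map.json --consonant b --out results/
```

Trajectories are tidy CSV (one row per 5 ms control step: truth,
estimates, predictions, formants, perturbation flags) with a YAML
config echo alongside for provenance.

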