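# Methods

## Model

The package simulates center-out reaching with a single-hemisphere
population of N cosine-tuned neurons and population-vector (PV) readout.

**Tuning.** Neuron i has a base (unimanual) encoding PD φᵢ ∈ [0°, 360°),
modulation depth dᵢ ≥ 0, and an alive flag. Its noise-free activity for a
reach toward θ is `[dᵢ cos(θ − encᵢ)]₊` with baseline 0 and peak dᵢ
(default 1). The encoding PD in force, encᵢ, is φᵢ in unimanual movement
and φᵢ + δᵢ in the bimanual regimes, with the offsets δᵢ drawn
𝒩(0, σ²) once per condition (quenched) or once per trial (annealed).
The depth-only bimanual variant multiplies dᵢ by quenched log-normal
factors exp(𝒩(0, depth_σ²)) — positive by construction, since the data
only say depths differ between conditions, not how — and leaves PDs alone.

**Noise.** Activity noise is zero-mean Gaussian with variance k·mean,
added to the mean activity and re-rectified at 0. Proportionality of the
variance to the mean is the standard reading of signal-dependent cortical
variability (Fano-factor-like); a silent neuron is exactly silent. Default
k = 0.1.

**Readout.** PV = (1/N) Σ aᵢ (cos ψᵢ, sin ψᵢ) over alive neurons, with
the decoding PD ψᵢ equal to the base PD φᵢ in every regime except the
encoding+decoding-rotation variant (ψᵢ = φᵢ + δᵢ). The denominator is the
original, pre-lesion N, constant across the lesion, so depleting neurons
shrinks the PV norm — the model's account of post-stroke slowing. PV angle
models reach direction, PV norm reach speed. A zero-norm PV has no angle;
it is flagged, and its angular error is scored as the maximal 180°.

**Lesion.** A directional stroke removes every neuron with
|wrap(φᵢ − center)| ≤ fraction·180°. Defaults: center 90°,
fraction 0.5 — the entire half-circle of PDs around the paretic direction
is lost, so reaches toward 90° initially have zero PV norm and maximal
error. This severe lesion is deliberate: it makes the paretic direction
*the* direction of large error and critically reduced speed, the
phenomenology the model exists to study; shallower wedges leave the
lesion-center reach direction nearly unbiased (the wedge is symmetric
about it) with the worst errors at the flanking targets instead.

**Learning.** Each trial draws one of the 8 standard targets (45° apart,
uniform by default), runs the noisy forward pass, and descends the cost

    E = err² + λ Σ aᵢ²     (err in degrees, λ = 0.01)

with respect to the surviving φᵢ, using the trial's own noise realization
(the additive ε is held fixed inside the gradient — learning sees the
activities that produced the movement). The supervised gradient flows
through the encoding dependence only: decoding unit vectors are constants
within a step, because bimanual movement alters neural activity through
inter-hemispheric inhibition without touching cortical-spinal-muscle
connectivity. Decoding PDs are yoked to φᵢ, so they follow between steps
and neurons genuinely migrate. A config flag (`update_targets=
"encoding_and_decoding"`) enables full-path gradients for sensitivity
analysis; note that a *single* neuron can only reduce its error through
the decoding path (its PV angle equals its own ψ), so the lone-neuron
descent demonstration uses that flag. The rectifier contributes
subgradient 0 at zero activity: inactive neurons receive no supervised
gradient that trial. Updates are

    φᵢ ← φᵢ − η_sup ∂(err²)/∂φᵢ − η_unsup λ ∂(Σa²)/∂φᵢ [+ 𝒩(0, drift_σ²)]

with dead neurons, depths and quenched offsets untouched and PDs
re-wrapped. A finite-difference gradient mode (central differences of each
cost term, decoding pinned in encoding-only mode) exists as a slow oracle.

## Default study conditions

| parameter | default | units | why |
|---|---|---|---|
| N | 500 | neurons | large enough for smooth histograms, small enough for second-scale runs |
| PD layout | equally spaced | — | deterministic tests; i.i.d. uniform available |
| lesion center / fraction | 90° / 0.5 | — | see Lesion above |
| k | 0.1 | activity | moderate signal-dependent noise |
| η_sup, η_unsup | 0.1 | deg-scaled | see below |
| λ | 0.01 | — | metabolic term visible but not dominant |
| σ (quenched rotation) | 60° (strong), 30° (moderate) | deg | the strong/moderate regimes the contrasts compare |
| depth_σ | 0.5 | log-units | clearly visible depth scatter |
| drift_σ (annealed_drift) | 2° | deg/step | see below |
| trials / snapshots | 3000 / 1000,2000,3000 | — | reorganization saturates by ~3000 |
| evaluation | 200 reps × 8 targets | — | Monte-Carlo SEs ≲ 0.3° on errors |

The learning rates are degree-scaled: with the exact gradient of the cost
above (which carries a 1/(N·‖P‖²) factor through the PV angle), η = 0.1
moves strongly-driven PDs by ~10⁻²–10⁻¹ degree per trial, so
reorganization completes over a few thousand trials — the regime the
experiments probe. Much smaller rates leave the population visibly frozen
at 3000 trials; much larger ones oscillate.

drift_σ = 2°/step makes the accumulated random walk (≈ 2°·√3000 ≈ 110°)
comparable to the wedge width, which is what lets drift act as search
noise; at 0.5°/step the supervised gradient's restoring force confines the
PDs and no reorganization occurs.

## Metrics and scenarios

Reorganization is summarized by (a) a 36-bin circular histogram of alive
base PDs, (b) **uniformity**, the Shannon entropy of the bin distribution
normalized by log 36 (1 = perfectly equalized), and (c) **wedge_fill**,
the fraction of alive neurons whose base PD has migrated into the original
lesion wedge (exactly 0 right after the lesion). Movement quality is
probed by Monte-Carlo unimanual reaches: per-target mean |angular error|
and mean PV norm with standard errors.

`run_scenario` derives every named experiment from one seed, so paired
scenarios share their base population, lesion, target sequence and noise
stream and differ only in the manipulated factor. Scenario deltas:
unimanual (σ=0); bimanual_quenched; depth_only; enc_dec_rotation;
nonuniform_targets (schedule restricted to the 3 targets nearest the
lesion center, regime taken from the config); supervised_only
(η_unsup=0); unsupervised_only (η_sup=0); bimanual_annealed;
annealed_drift (unimanual condition plus per-step drift).

Two measurement choices deserve flagging:

- **Annealed rotations are judged by uniformity, not wedge_fill.** Pure
  annealed rotations excite a collective mode: the shared error signal
  gives all surviving neurons coherent per-trial kicks, and the intact
  "blob" slowly rotates rigidly (direction seed-dependent). That slides
  some neurons across the wedge boundary (wedge_fill ≈ 0.15) while the
  *shape* of the distribution never equalizes — uniformity stays at its
  post-lesion value and error never recovers (~57°). Uniformity is the
  honest equalization scalar here; wedge_fill is still reported.
- **Speed is not conserved under reorganization, by construction.** With
  depths and the surviving count fixed, total tuning "mass" is conserved,
  so refilling the wedge necessarily thins the opposite side of the
  circle: after strong-σ bimanual rehab the PV norm at the far targets
  drops by ~30%, far beyond its Monte-Carlo SE. The acceptance test that
  asserts no such drop is therefore expected to fail, and is left failing
  on purpose — it marks a real property of this model family (any fixed
  normalization cancels from the comparison), not a bug. Equalization
  buys direction accuracy everywhere at a known price in peak speed.

## Numerical choices

Angles are degrees at every API boundary, radians inside trig; PDs wrap
to [0°, 360°), differences to (−180°, 180°]. Ties at the wedge boundary
(≤) are lesioned. Cosine resultants whose amplitude cancels to rounding
error (≤ 10⁻¹² of the total input amplitude) are flagged as
zero/undefined rather than returning a garbage phase; over-inhibited
neurons (resultant amplitude 0) are reported degenerate, never silently
clipped. Nonfinite gradients reject the whole step. All randomness flows
through named, independently spawned streams (quenched draws, target
schedule, activity noise, drift, annealed redraws, evaluation), so any
sub-experiment is reproducible in isolation; identical seeds give
bit-identical trajectories.

## What the generator does and does not emulate

The synthetic populations are idealized: perfectly cosine-tuned,
homogeneous-depth, rate-based neurons with a sharp wedge lesion and i.i.d.
Gaussian rotation offsets. Passing tests show that the *mechanism* —
quenched encoding-PD rotation as symmetry-breaking search noise for
gradient reorganization — behaves as claimed inside this model family.
They say nothing about spiking dynamics, within-reach trajectories,
muscle/biomechanical constraints on decoding PDs, retention after
rehabilitation ends, or real lesion geometry; estimating inhibition
strength from imaging is likewise out of scope. The inter-hemispheric
inhibition analysis is a static tuning-curve calculation (the right
hemisphere does not learn).
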