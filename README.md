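# pdrehab

A computational model of why **bimanual movement helps stroke rehabilitation**:
a cosine-tuned motor-cortex population with population-vector decoding, a
directional lesion, and trial-by-trial reorganization of the surviving
neurons' preferred directions under supervised + unsupervised learning.

It is written for computational neuroscientists and rehabilitation modelers
who want to simulate, and pull apart, the hypothesis that bimanual movement
works because it **rotates the encoding preferred directions** (PDs) of
motor-cortex neurons — quenched, neuron-specific Gaussian rotations induced
by inter-hemispheric inhibition — while leaving the decoding (readout) PDs
fixed.

## The model

Each of N neurons has an encoding PD φᵢ. A reach toward target θ drives it
through a rectified cosine tuning curve with signal-dependent noise:

    aᵢ = [ dᵢ · cos(θ − φᵢ − δᵢ) ]₊ + εᵢ ,   Var(εᵢ) = k · E[aᵢ]

where dᵢ is the modulation depth and δᵢ the per-neuron rotation offset
(δᵢ = 0 in unimanual movement; δᵢ ~ 𝒩(0, σ²), drawn once — *quenched* — in
bimanual movement). The reach itself is the population vector

    **P** = (1/N) Σᵢ aᵢ · (cos ψᵢ, sin ψᵢ)

over alive neurons, with decoding PDs ψᵢ equal to the *unrotated* base PDs;
the angle of **P** models reach direction, its norm reach speed.

A stroke is a directional lesion: every neuron whose base PD lies within a
wedge around the lesion center (default 90°) is depleted. Rehabilitation is
stochastic gradient descent, one reach per trial, on

    E = err² + λ Σᵢ aᵢ²

(err = wrapped angular error between **P** and θ, in degrees; the second
term is the unsupervised metabolic cost), updating the surviving φᵢ with
rates η_sup and η_unsup and optional Gaussian "synaptic drift" per step.

The headline result the package reproduces: unimanual rehabilitation (σ=0)
gets stuck piling PDs at the wedge edges, while quenched bimanual rotation
(large σ) acts as quenched search noise, re-equalizing the PD distribution
and refilling the depleted wedge. Variants that change modulation depth
only, rotate decoding along with encoding, or redraw the rotations every
trial (annealed) do **not** reorganize — the quenched encoding-only
rotation is the active ingredient. A closed-form cosine-resultant
calculation (`inhibition_rotation`) shows how inter-hemispheric inhibition
of strength c produces exactly such rotations for sparse callosal
connectivity, and why they vanish in the dense large-K limit.

## Worked example

The two-neuron intuition behind reorganization — an equalized pair of
neurons at 30° and 60° stands in for a single neuron tuned to 45°:

```python
import pdrehab as pr

pop = pr.Population(base_pd=[30.0, 60.0])   # encoding = decoding PDs
cond = pr.unimanual()
a = pr.mean_activity(pop, cond, 45.0)       # noiseless activities
pv = pr.population_vector(pop, a, cond)
print(pv.angle, pv.norm)
```

prints

```
45.0 0.9330127018922193
```

— the population vector points exactly at the 45° target (each neuron fires
cos 15° ≈ 0.966 and their unit vectors average to 45°), with a norm smaller
than a single on-target neuron would give (0.933 < 0.966): an equalized
population restores *direction* fully but *speed* only partly.

The full experiment, from the shell:

```sh
pdrehab scenario unimanual          --outdir runs
pdrehab scenario bimanual_quenched  --outdir runs
pdrehab report runs/unimanual runs/bimanual_quenched
```

```
                 run          scenario  seed  final_uniformity  final_wedge_fill
       runs/unimanual         unimanual     0          0.540608          0.012048
runs/bimanual_quenched bimanual_quenched     0          0.944930          0.329317
```

After 3000 trials on a 500-neuron population with half its PDs lesioned,
unimanual rehab leaves the depleted wedge essentially empty (wedge fill
0.012) and the PD distribution strongly clumped (uniformity 0.54 on a 0–1
normalized circular-entropy scale), while quenched bimanual rotation
(σ = 60°) refills a third of the surviving population into the wedge and
nearly equalizes the distribution (0.94). Each run directory contains
`trials.csv`, population snapshots after 1000/2000/3000 trials,
`summary.json` and the fully resolved config; `pdrehab simulate cfg.yaml
--set condition.sigma=30` runs any variant reproducibly from one file.

Other scenarios: `depth_only`, `enc_dec_rotation`, `nonuniform_targets`,
`supervised_only`, `unsupervised_only`, `bimanual_annealed`,
`annealed_drift`.

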