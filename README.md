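# facespace

Self-organizing, rank-based competitive Hebbian models of face and object
recognition, for computational neuroscientists studying how classic
"face-specific" phenomena — holistic tuning, the other-race effect, cortical
category patches — can emerge from visual experience in a single
unsupervised learning system.

## The model

A pool of `N` neurons holds one non-negative, unit-length weight vector
`w_i` each. For a stimulus `x` the pool computes

```
γ_i   = Σ_k x_k w_ik                         activation (inner product)
η_i   = rank of γ_i (1 = most active)
μ_i   = r ((N − η_i)/(N − 1))^α              rank-based learning scale
y_i   = (γ_i − κ γ̄_i) / (γ_max − κ γ̄_i)      graded inhibited output
ε_i   = μ_i y_i x + (1 − μ_i) w_i            Hebbian mixing
w_i   ← ε_i / |ε_i|                          unit-norm renormalization
```

where `γ̄_i` is the mean activation of the (up to ten) most active *other*
neurons and `κ = 0.3`. The winner's output is exactly 1; the learning scale
decays with rank (at `α = N`, the runner-up learns at roughly a third of the
winner's rate) and is zero for the least active neuron.

Three model families are built on this kernel:

* **Spherical face space** (`facespace.sphere`, `facespace.discrimination`)
  — stimuli are unit 3-vectors on the positive octant of a sphere, read in
  an (azimuth, elevation) chart. Used for the holism variance sweep and the
  unequal-exposure (other-race) experiments, with a radial
  distractor-rejection procedure measuring discrimination thresholds in 0.1
  standard-deviation steps along 360 directions around a group mean.
* **Two-layer image hierarchy** (`facespace.hierarchy`) — 256 × 256
  grayscale faces pass through a Laplacian-of-Gaussian front end (smoothed
  at σ = 5 px, rescaled to [0, 1], downsampled to a 64 × 64 working grid),
  a 4 × 4 grid of 9-neuron pools over 16 × 16-pixel patches, and a fully
  connected output pool. Read-outs: unique ranked-order codes,
  Ward/Euclidean clustering, principal-axis projection, and top-n code
  overlap under lower-half deletion/exchange manipulations.
* **Cortical sheet** (`facespace.cortical`) — a 9 × 9 grid of neurons whose
  outputs gain `h` times the average output of their eight grid neighbors,
  which couples learning across the sheet and produces spatially contiguous
  category patches.

All inputs are synthetic and generated by `facespace.synth`: labeled
exemplar clouds on the sphere octant, and a parametric eight-feature face
renderer producing two separable populations ("own" and "other").

## Worked example

```
$ python examples/other_race_effect.py
classifiers preferring the own-race region:   34
classifiers preferring the other-race region: 16
mean threshold, own race:   0.451 s.d.
mean threshold, other race: 0.536 s.d.
```

Fifty classifiers trained on two equal-variance face clouds seen 1000 vs
100 times per epoch split 34 : 16 in favour of the frequently seen region,
and a distractor near the own-race mean changes the winning neuron after
0.45 standard deviations on average, versus 0.54 for the rarely seen group
— poorer other-race discrimination produced by nothing but unequal
exposure. The other examples demonstrate the holism sweep
(`examples/holism_sweep.py`), the image hierarchy and its
holistic-manipulation battery (`examples/face_recognition_hierarchy.py`),
and cortical patch formation (`examples/cortical_patches.py`); each prints
a short interpretation with its numbers.

A thin CLI wraps the shipped experiment presets:

```
facespace presets                       # list available presets
facespace preset cortical_h_sweep --seed 1 --out runs/cortex
```

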