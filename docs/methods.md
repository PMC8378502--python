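# Methods

## Model

The segmenter is a pair of convolutional LSTM chains over the same frame
sequence.  Each cell computes forget/input/output gates and a candidate
memory as same-padded convolutions of the channel concatenation
`[h_{t−1}, x_t]` (concatenation order fixed as `[h, x]` so checkpoints
are portable), updates `c_t = f⊙c_{t−1} + i⊙c̃`, and emits
`h_t = o⊙tanh(c_t)`.  The candidate memory carries its own parameters
`W_c, b_c` — the standard LSTM form; variants that reuse the output-gate
parameters for the candidate are a known source of transcription errors
and are deliberately not reproduced.  Gates are convolutional rather
than fully connected because the model operates on 64×64 frames where a
dense map over 4096 pixels would be both implausible to train and
spatially wasteful.

The compensation chain runs from the zero state over the whole sequence
and its hidden outputs are combined as `h_0 = Σ_i ω_i h′_i`, one
unconstrained scalar per frame (no softmax: the combination is a bare
weighted sum, and normalising it would forbid the useful solution
ω ≡ 0).  `h_0` initialises the main chain's hidden state; the main
chain's initial *memory* stays zero — only the hidden layer is
compensated.  The two chains do not share weights.  A 1×1 convolution +
sigmoid maps each main-chain hidden tensor to a per-pixel wall
probability; this is the minimal head that keeps all spatial reasoning
inside the recurrent cells.  The summand index in the compensation sum
runs over the chain's frames, pairing each ω_i with its own h′_i.

## Loss and training

The loss is per-frame binary cross-entropy, **mean over pixels and
summed over frames** (the per-pixel reduction keeps the loss magnitude
independent of image size), with probabilities clipped to
[1e−7, 1−1e−7].  Optimisation is Adam.  Defaults: learning rate 1e−2,
batch size 4, forget-gate bias initialised to +1, head bias to −2
(the wall occupies a small fraction of each frame), ω_i = 1/n so the
compensated state starts as an average.  The 1e−2 rate was chosen
because the network is small (≈10⁴ parameters) and the intended budgets
are a few hundred iterations; at 1e−3 the model is still far from
converged inside such budgets.  Every random element — initialisation,
batch order, augmentation draws — derives from the single config seed,
so runs are bit-reproducible.

Since no autodiff engine is used, gradients are derived by hand:
backpropagation through the head, the main chain, the compensated
initial state (`∂L/∂ω_i = ⟨∂L/∂h_0, h′_i⟩`, with `ω_i ∂L/∂h_0` injected
into the compensation chain's per-step hidden gradients), and both
chains' cells via the im2col adjoint.  A finite-difference check over
every parameter tensor of a small model pins the derivation in the test
suite; the cell itself is additionally checked against an independently
coded scalar LSTM on 1×1 grids.

Start-frame augmentation cyclically rotates each training sequence to a
random start frame once per draw.  This is sound for the phantom because
its sequences span whole cardiac cycles; for real acquisitions that
start and end mid-cycle it would create a splice artifact at the wrap
point.  The train/held-out split reserves `max(1, round(0.05·n))`
sequences by default; the returned checkpoint is the best held-out
mean-IoU iterate.

## Cardiac-state decoding

Pair indicators `d′_k = 1` iff `Area(f_k) > Area(f_{k+1})` (strict;
ties are "no decrease") are smoothed by an N-term running mean over
indices `k−N/2 .. k+N/2−1`.  Near the ends the window is clamped to the
valid range and divided by the number of terms actually present, so
`s ∈ [0,1]` is an exact mean for every pair.  N defaults to 4: at the
phantom's 18-frame cycle this suppresses one or two isolated
misestimates while delaying transition detection by at most ~2 pairs.

Two decoding conventions exist because the indicator's semantics
(1 = thinning) and a threshold rule of the form "s < 0.5 → diastole"
point in opposite directions.  The default, `consistent`, follows the
indicator: a sustained majority of thinning (s > 0.5) is diastole,
ties decode as contraction.  The `literal` convention applies the
opposite threshold rule unchanged.  Both are exposed; nothing in the
pipeline depends on the choice except the label naming.

## Phantom generator

The phantom emulates what makes the real task hard, not how MRI images
are formed.  Each sequence is a bright annulus (intensity 0.9 on a 0.1
background) whose thickness follows
`base + amplitude·sin(2π·n_cycles·t/T + φ)` — thickening inward with a
fixed outer radius, as the myocardium does — surrounded by static
distractors at the *same* intensity: a thin crescent (the RV free wall,
realistically thinner than the LV wall) and two filled ellipses (the
atria), all clipped away from the LV disk so ground truth is unambiguous.
Zero-mean Gaussian noise (σ = 0.05 by default) is added and the image
clipped to [0,1].  Default geometry at 64×64: outer radius 14 px, wall
4 ± 2 px, one cycle per 18 frames; `scaled_params` shrinks the geometry
proportionally for smaller images.

State labels derive from the sign of the *continuous-model* wall area
`π·th·(2R − th)` between consecutive frames (ties → diastole; the last
frame inherits its predecessor's label).  Pixel-counted areas are not
used for labels because a grid-aligned annulus gains pixels in bursts,
producing spurious plateaus near the sine extrema that have nothing to
do with the modelled motion.  Dataset generation therefore also jitters
the LV centre at sub-pixel scale and draws the cycle phase uniformly —
real hearts are not aligned to the pixel grid, and perfect alignment
makes the pixelated area series artificially stair-stepped.

What the phantom does **not** model: intensity bias fields, Rician noise
statistics, partial-volume effects, k-space artifacts, through-plane
motion, or anatomical shape variability.  Gaussian noise was chosen over
Rician deliberately — the method is intensity-model-agnostic, and
nothing downstream depends on the noise law.  Consequently, passing
results here show that the architecture learns to exploit temporal
thickness dynamics and that first-frame compensation works as designed;
they do not certify accuracy on clinical images.

## Evaluation

IoU = |S∩G| / |S∪G| per frame, with the empty/empty case defined as 1.0
(perfect agreement on absence).  Sequences are reported as mean IoU over
frames and first-frame IoU separately, because the first frame is
precisely where a plain recurrent segmenter is blind.  State-decoding
accuracy compares decoded pair labels with the phantom's frame labels
over pairs.

## Problem sizes and numerics

The standard training study runs 20 sequences of 8 frames at 32×32 with
8 hidden channels for 300 Adam iterations; the ablation comparison uses
150 iterations per arm over 5 seed replicates.  These sizes were chosen
so a full study completes in minutes on one CPU core while leaving the
dense-vs-plain separation far larger than seed-to-seed variation.  All
arithmetic is float64.  Probabilities are clipped at 1e−7 for the loss;
binarisation threshold is 0.5 (configurable).  Checkpoints store every
named tensor plus the JSON run config and its SHA-256 prefix.

## Known limitations

* The compensation vector ω has fixed length n: a trained dense model
  expects inference sequences of the training length (the plain model
  does not).
* Per-frame spatial context grows only with time steps (3×3 kernel per
  step), so very large structures at the first frame are distinguished
  mainly through the compensation path.
* The smoother's transition lag (~N/2 pairs) is inherent; choosing N
  trades isolated-error suppression against turning-point latency.
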