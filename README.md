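# cineseg

Sequential segmentation of the left-ventricle (LV) wall in short cine
image sequences with a **dense two-chain convolutional recurrent
network**, plus decoding of the cardiac state (contraction vs. diastole)
from the segmented wall's area dynamics.

## The problem

In a four-chamber cine view the LV myocardium appears as a bright
annulus surrounded by structures of similar intensity (the thinner
right-ventricular free wall, the atria), and it thickens and thins as the
heart beats.  Segmenting each frame independently throws away the
temporal cues that distinguish the pulsing LV wall from its static
neighbours — but a plain recurrent segmenter has its own weakness: the
*first* frame starts from a zero hidden state, is segmented with no
temporal context, and its poor hidden output then pollutes every later
frame.

## The model

Frames `x_1..x_T` are processed by convolutional LSTM cells

```
f_t = σ(W_f * [h_{t−1}, x_t] + b_f)        i_t = σ(W_i * [h_{t−1}, x_t] + b_i)
c̃_t = tanh(W_c * [h_{t−1}, x_t] + b_c)     o_t = σ(W_o * [h_{t−1}, x_t] + b_o)
c_t = f_t ⊙ c_{t−1} + i_t ⊙ c̃_t            h_t = o_t ⊙ tanh(c_t)
```

where `*` is a same-padded convolution.  Two chains run over the same
sequence: a **compensation chain** exposes hidden outputs `h′_1..h′_n`,
and a learned weighted sum

```
h_0 = Σ_i ω_i h′_i
```

initialises the hidden state of the **main chain**, whose per-frame
hidden outputs pass through a 1×1-conv + sigmoid head to give wall
probabilities.  Training minimises binary cross-entropy
`L = Σ_t [−y_t log ŷ_t − (1−y_t) log(1−ŷ_t)]` (mean over pixels, summed
over frames) end-to-end, including the ω's.  Setting ω ≡ 0 recovers the
plain single-chain baseline exactly — the ablation used in the tests.

Downstream, cardiac state is decoded from the segmented wall areas: the
pair indicator `d′_k = 1` iff `Area(f_k) > Area(f_{k+1})` (wall
thinning), smoothed by an N-frame running mean `s_k`, with a sustained
majority of thinning (`s > 0.5`) decoding as diastole.

Because no public cine dataset accompanies this method, the package
ships a first-class **beating-phantom generator**: a bright annulus
whose thickness follows a sinusoid over the cycle, confusable static
distractors at the same intensity, Gaussian noise, and exact per-frame
masks and state labels.

## Worked example

```python
import numpy as np
from cineseg import PhantomParams, generate_sequence, estimate_states

seq = generate_sequence(PhantomParams(seed=7, noise_sigma=0.0, center=(31.7, 31.3)))
areas = seq.masks.reshape(18, -1).sum(axis=1)
series = estimate_states(seq.masks, N=4)
print("wall areas :", areas.tolist())
print("d'         :", series.d_prime.tolist())
print("decoded    :", [lbl[:4] for lbl in series.labels])
print("truth      :", [lbl[:4] for lbl in seq.state_labels[:17]])
```

prints

```
wall areas : [165, 171, 198, 234, 281, 324, 361, 394, 410, 415, 410, 394, 361, 324, 281, 234, 198, 171]
d'         : [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1]
decoded    : ['cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'dias', 'dias', 'dias', 'dias', 'dias', 'dias', 'dias']
truth      : ['cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'cont', 'dias', 'dias', 'dias', 'dias', 'dias', 'dias', 'dias', 'dias']
```

The wall area rises to frame 9 and falls after; the raw indicators flip
exactly at the peak, and the smoothed decoding matches the ground-truth
state on 16 of 17 adjacent pairs, the single mismatch sitting at the
turning point (the smoother trades a one-pair lag at transitions for
robustness against isolated misestimates elsewhere).

## Command line

```
cineseg simulate --n 10 --frames 18 --size 64 --seed 1 --out data/
cineseg train --data data/ --out run/ --iterations 300
cineseg segment --checkpoint run/checkpoint.npz --images data/seq_000.tif --out seg/
cineseg estimate-state --masks seg/ --window 4 --out states.csv
cineseg evaluate --pred seg/probs.tif --truth data/ --out report.json
```

Every command writes its resolved configuration next to its outputs;
identical configurations reproduce identical outputs.

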