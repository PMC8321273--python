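# toolmotion

Localizing and classifying **similarly shaped surgical tools** — scissors vs
needle holders — in egocentric (head-mounted camera) video of open surgery.
The two instruments are nearly identical in appearance and their tips are
usually occluded in the operating field, so appearance-based detectors cannot
tell them apart. What does differ is the *motion of the hand operating them*:
cutting is a quick back-and-forth, driving a suture needle a slow wrist
rotation. `toolmotion` implements a three-phase pipeline that exploits this:

1. **Localization** — per-frame hand and tool bounding boxes, from any
   detector backend (a detections-JSON exchange format) or from the built-in
   oracle detector over synthetic scenes.
2. **Target-hand selection** — for tool box $b_k^{\text{tool}}$ and candidate
   hand boxes $b_i^{\text{hand}}$, the operating hand is
   $i^\* = \arg\max_i r_{ik}$, where
   $r_{ik} = |b_i^{\text{hand}} \cap b_k^{\text{tool}}| \,/\, |b_i^{\text{hand}} \cup b_k^{\text{tool}}|$
   is the box overlap ratio (IoU). Frames with $\max_i r_{ik} = 0$ yield no
   target hand.
3. **Classification from motion** — $T$ consecutive target-hand crops
   (resized to 252×252; default $T{=}50$, i.e. 2 s at 25 fps) are embedded to
   per-frame features $\psi_t \in \mathbb{R}^{128}$, aggregated causally by a
   single-layer LSTM $\hat\psi_1,\dots,\hat\psi_T = B(\psi_1,\dots,\psi_T)$
   (128-d hidden state, tanh), and mapped per timestep through a one-hidden-
   layer ReLU MLP with a sigmoid output to probabilities $p_1,\dots,p_T$.
   Training minimizes class-weighted binary cross-entropy
   (weights $w_c = N/(K n_c)$) with Adam at $10^{-3}$, batch size 5,
   dropout 0.5. The sequence decision fuses $p_t$ (mean by default).

Because the study's surgical videos are private, the package ships a
**synthetic scene simulator**: egocentric-like frames with one target hand
holding a tool, 0–3 distractor hands, and a detector-noise model (box
jitter, misses, spurious boxes). The two tool classes are rendered with
*identical sprites* and differ only in their motion program, so any
classifier above chance is provably reading motion, not appearance. The
sequence model (LSTM and MLP, Adam, weighted cross-entropy) is implemented
in NumPy and is fully deterministic given a seed.

## Worked example

```python
from toolmotion.pipeline import motion_experiment, selection_experiment
from toolmotion.synthetic import DetectorNoise

# Phase 2 on noise-free synthetic scenes: selection is exact
print(selection_experiment(n_scenes=8, n_frames=50, noise=DetectorNoise(), seed=1))
# {'accuracy': 1.0, 'n_frames': 400}

# Phases 1-3 end to end: 400 appearance-identical clips, T=50, 25% held out
res = motion_experiment(n_clips=400, T=50, seed=1, epochs=15)
print(res.summary())
```

Output:

```
Method                   Accuracy  Recall Precision      F
proposed (LSTM)             0.980   0.960     1.000  0.980
only hand (per-frame)       0.507   0.444     0.508  0.474
ROC AUC (proposed): 0.980
train clips: 300   test clips: 100
```

The sequential model recovers the tool class from hand motion almost
perfectly, while the per-frame baseline — the same features and head without
the recurrent aggregator — stays at the 0.5 chance rate, confirming that the
single crops carry no class signal. `sweep_window_length([25, 50, 100], ...)`
reproduces the window-length comparison table layout.

A command-line interface wires the stages together:

```
toolmotion simulate --config scenes.yaml --out scenes/ --seed 1
toolmotion pipeline --n-clips 400 --t-frames 50 --seed 1 --out report.json
toolmotion sweep-t --t-values 25,50,100 --out sweep.json
```

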