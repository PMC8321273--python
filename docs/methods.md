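# Methods

## Problem and model

Open-surgery video from a head-mounted camera shows several hands and
hand-held instruments whose shapes are nearly indistinguishable (surgical
scissors vs needle holders). The pipeline classifies the instrument from the
*motion of the operating hand* in three phases:

1. **Localization.** Hands and tools are detected per frame as axis-aligned
   boxes with confidence scores. Detection itself is outside this package's
   scope: detections enter either through a JSON exchange format (so any
   external detector can be used without linking it) or from the built-in
   oracle detector over synthetic scenes. The tool *class* is not decided at
   this stage — detections are only "hand" or "tool".
2. **Selection.** For each tool box, the operating hand is the detected hand
   box with maximum intersection-over-union. Boxes are continuous, 0-based
   and half-open, which makes area and IoU closed-form and matches the COCO
   bbox convention after corner conversion. If no hand overlaps the tool the
   frame yields no target hand: an argmax over an all-zero overlap set has no
   meaning, and a non-overlapping hand cannot be operating the tool. Exact
   ties (measure-zero for real boxes, present in tests) break by higher
   detection score, then lower list index, making the result invariant to
   permutations of the hand list. Each tool selects independently; one hand
   may serve two tools.
3. **Classification.** Windows of T strictly consecutive selected frames
   (gap tolerance 0 by default; a max-gap option exists) are cropped to the
   hand box, bilinearly resized to 252×252 (no aspect preservation or
   letterboxing), embedded per frame to 128-d features, aggregated causally
   by a single-layer LSTM (128-d hidden state, tanh cell activation,
   forget-gate bias initialized to 1), and scored per timestep by a
   one-hidden-layer ReLU MLP (64 units) with one sigmoid output. Scissors
   are coded as the positive class — an arbitrary polarity, fixed and
   documented so precision/recall are interpretable.

Defaults: T = 50 frames, i.e. 2 s at 25 fps — long enough to contain at
least one full cycle of either characteristic motion. The crop is the hand
box alone (pad = 0); a fractional pad parameter expands it for cases where
the tool tip lies outside the hand box.

## Training

Class-weighted binary cross-entropy over all T timesteps,
`loss = w_y · mean_t(−[y log p_t + (1−y) log(1−p_t)])`, with probabilities
clipped to [1e−7, 1−1e−7]. Class weights default to inverse frequency,
`w_c = N/(K·n_c)`, whose count-weighted mean is 1, so the loss scale matches
the unweighted case; the loss reduces exactly to plain BCE at unit weights
and scales linearly in the weights (both identities are tested). Optimizer:
Adam at 1e−3, batch size 5, 15 epochs, dropout 0.5 on the LSTM outputs
(inverted dropout), global-norm gradient clipping at 5 for stability. Clips
longer than T contribute a uniformly random T-frame fragment per epoch. One
integer seed drives weight initialization, shuffling, dropout and fragment
sampling; two runs with the same seed are identical.

The per-sequence decision fuses p_1..p_T by their mean (threshold 0.5, ties
going to the positive class); `last` and `max` fusions are available as
config. Mean fusion was chosen as the least committal rule: it uses every
timestep and is the natural sequence-level analogue of the per-timestep
training loss.

The LSTM, MLP head, Adam and the loss are implemented in NumPy with
hand-derived backpropagation; the backward pass is verified against central
finite differences and the recurrence against an independent scalar
re-implementation of the standard cell equations.

## Feature extraction

The extractor is a contract: anything mapping (T, 252, 252, 3) crops to
(T, 128) features. The built-in backend downsamples each crop to 32×32
grayscale and applies a fixed, seeded Gaussian random projection to 128
dimensions — a frozen random-features embedding. It is deterministic, fast
on one CPU, and preserves coarse spatial structure, which is all the
aggregator needs: in the synthetic scenes the classes are
appearance-identical by construction, so all class information is in how
features change over time, not in any single frame's embedding. Features are
standardized per dimension using training-set statistics. A learned deep
backbone (e.g. an 18-layer residual network) can be plugged in behind the
same contract when pretrained weights and a GPU are available; nothing else
changes.

## Synthetic scenes

Each scene renders one target hand (textured ellipse) holding an elongated
tool sprite over a static low-frequency noise background at 480×270 (the
16:9 aspect of 1920×1080 surgical footage, scaled down for speed), 25 fps,
plus 0–3 independently drifting distractor hands. The two classes share
identical sprites and differ only in motion program:

- **oscillate** (scissors): the hand-tool pair translates sinusoidally along
  a random axis, amplitude 22 px, period 12 frames (~0.5 s) — the quick
  back-and-forth of cutting. The tool angle is fixed per scene, drawn
  uniformly.
- **rotate** (needle holders): the hand circles the tool anchor at radius
  34 px, period 40 frames (~1.6 s), the tool always pointing at the anchor —
  the wrist rotation of suturing.

Amplitude and radius were set once to desk-scale realistic values such that
both motions stay well inside the frame and a 50-frame window contains at
least one full cycle of either program. Because the rotation sweeps its
angle uniformly and the oscillation draws its fixed angle uniformly, the
marginal per-frame appearance distribution is the same for both classes;
a two-sample KS test on a frame-intensity statistic cannot separate them
(tested), and a per-frame classifier sits in the 0.40–0.60 chance band.
Distractor hands are placed fully disjoint from the tool's reachable region
(IoU 0 with the tool box in every frame), so the selection ground truth is
unambiguous and noise-free selection accuracy is exactly 1.0; an
`adversarial_distractors` flag relaxes this for stress testing.

The detector-noise model jitters each box corner with N(0, σ²), drops boxes
with a miss probability, and injects Poisson-many spurious low-score boxes
per frame. Zero noise reproduces ground truth exactly with scores 1.0. The
default "realistic" level (σ = 2 px, miss 0.05, 0.3 spurious/frame, score
noise 0.1) yields detection AP and selection accuracy around 0.95 —
imperfect in the way a real first-stage detector is.

What the synthetic scenes do **not** emulate: photorealistic tissue and
glove appearance, lighting changes, motion blur, tool-tip occlusion by
tissue, camera ego-motion, and correlated detector failures. Passing the
motion-vs-appearance experiment therefore shows the architecture can recover
class from motion when appearance is uninformative; it does not certify
accuracy on real surgical footage.

## Experiments and problem sizes

The standard experiments (all seeded, all on one CPU in about a minute):

- **Selection**: 8 scenes × 50 frames, 2 distractors; accuracy is the
  fraction of frames where the selected hand box has IoU ≥ 0.5 with the true
  operating hand (exactly 1.0 without noise).
- **Detection AP**: all-point interpolated AP at IoU 0.5 with greedy
  score-ordered matching, per category, over 6 scenes × 40 frames.
- **Motion vs appearance**: 400 single-window clips (T = 50, one clip per
  scene, balanced classes), 25% held out; the sequential classifier against
  the per-frame baseline (same head, same crops subsampled every 5th frame,
  no recurrence). Expected pattern: sequential accuracy ≥ 0.9, baseline in
  the chance band.
- **Window-length sweep**: the same experiment at T ∈ {25, 50, 100},
  emitting one accuracy/recall/precision/F row per T.

An imbalance option generates class counts in any ratio (e.g. 756:2894) to
exercise the weighted loss.

## Numerical choices and edge cases

- Probability clipping 1e−7 inside the loss; numerically stable sigmoid.
- Undefined metrics (zero denominators) are NaN with a warning, never 0.
- AP uses the all-point interpolation (precision envelope), not the 11-point
  variant.
- Degenerate boxes (zero width/height), negative or non-finite coordinates
  are rejected at construction; jittered boxes are re-sorted and clamped to
  a 2 px minimum extent.
- Runs shorter than T emit no windows; inference windows tile runs at
  stride T (non-overlapping) by default.

## Known limitations

- The frozen random-projection extractor cannot exploit appearance cues;
  on data where appearance *does* separate classes it underuses signal.
- Binary classes only; multi-class tools would need a softmax head.
- No tracking or re-identification across selection gaps: a tool that
  disappears and returns starts a new track.
- The NumPy trainer is single-threaded and desk-scale; it is not intended
  for training on real video corpora.
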