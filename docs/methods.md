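# Methods

## Problem and pipeline

`rowgraph` evaluates how similarly two rowers move. Each rower is
observed as a video-rate sequence of body25 pose keypoints (25 joints,
raw pixel coordinates, per-joint detection confidence), one rower per
video. Every frame becomes a 25-node skeleton graph whose node features
are the joint coordinates and whose 24 edges are the fixed body25 tree
with a constant edge feature of 1. A graph neural network embeds each
frame into a fixed-dimension graph vector `GF`; comparing two rowers
then reduces to Euclidean geometry on the per-frame embedding series:

- per-frame distance `d_i = ||GF_i^(1) - GF_i^(2)||`,
- aggregate dissimilarity `DISSIM_SCORE = sqrt(sum_i d_i^2 / L)`
  (root-mean-square over the L overlapping frames; lower = more
  similar). The squared variant (no root) is also exposed; the two rank
  pairs identically.

Two models share all components:

- **GEM** (graph-embedding model): node/edge MLP encoders, T rounds of
  intra-graph message passing (`Value(j->i) = f_value(h_i, h_j, e_ij)`
  on both directions of every undirected edge; per-node sum of incoming
  messages fed to the `f_node` update core), then a gated aggregation
  `GF = MLP( sum_i sigmoid(MLP_gate(h_i)) ⊙ MLP(h_i) )`.
- **GMN** (graph-matching network): the same, plus a per-round
  cross-graph message. Node i of one graph attends over the 25 nodes of
  the other with softmax weights on `s_h(h_i, h_j)`, and the summed
  cross message has the closed form `h_i - sum_j a(j->i) h_j`. The
  update core then consumes the concatenation of the intra-graph message
  sum and this cross vector. A GMN embedding therefore depends on the
  comparison partner and is recomputed per pair.

`s_h` is the **negative** squared Euclidean distance. The softmax must
concentrate on the *closest* counterpart node — its summed cross message
is described as the difference between `h_i` and its nearest neighbour
in the other graph — and only the negative sign achieves that; a
positive-distance softmax would attend to the farthest node.

## Input spaces

Three node-feature modes exist: `1D-X` (x only), `1D-Y` (y only), `2D`
((x, y)). Detection confidence is not a node feature. The 1D modes are
retained because they demonstrate the motivating failure: two poses that
differ only in the suppressed coordinate embed identically, so their
distance is exactly zero regardless of parameters. The 2D mode resolves
them.

Coordinates stay in raw pixels; no per-sequence normalization is applied
by default (an optional mid-hip-centred, trunk-length-scaled transform
exists in `pose_io` but is off). The encoder divides coordinates by a
fixed `input_scale` constant (default 1000 px, roughly half the frame
diagonal) purely for numerical conditioning: unit-scale MLP weights fed
~10^3-pixel inputs saturate the sigmoid gates and destabilise training.
Because the constant is identical for every rower and frame, it is a
single monotone rescaling of all distances and cannot change any
ranking.

## Architecture defaults

| parameter | default | notes |
| --- | --- | --- |
| node state dim `h` | 32 | small-graph regime; 25 nodes |
| graph vector dim `g` | 128 | |
| propagation rounds `T` | 5 | matches the evaluation setting |
| update core | GRU | `h' = (1-z)·h + z·n`; MLP core selectable |
| encoders | 2-layer MLP (ReLU hidden, linear out) | node: d→h→h, edge: 1→h→h |
| message net `f_value` | MLP 3h→2h→h on concat(h_i, h_j, e_ij) | |
| aggregator | affine gate & transform h→g, output MLP g→g→g | |
| init | uniform ±1/sqrt(fan_in), seeded | biases zero |

All summations (incoming messages, gated node sum) use a fixed
node-index order via `np.add.at`, so embeddings are bit-reproducible for
a given seed, config and input.

Exactness choices in the GMN: attention scores are computed with
`einsum` (index-ordered summation) rather than BLAS matmul on the
inference path, and the transposed score matrix is made contiguous
before its softmax. These choices make `embed_pair(g, g)` return two
bit-identical vectors and make `d(g1, g2) = d(g2, g1)` exact, which the
duplicated-roster and symmetry tests assert at zero tolerance.

## Training

The comparison layer needs embeddings whose distances track pose
similarity. No canonical supervision exists for this task, so training
is contrastive, with pairs built from the data itself:

- **similar**: a frame vs. the same frame plus i.i.d. Gaussian
  coordinate jitter (default 3 px — the order of keypoint-detector
  noise);
- **dissimilar**: frames from two different rowers, or (single-sequence
  fallback) frames of one rower at least a quarter stroke period apart;
- loss: `d^2` for similar, `max(0, margin - d)^2` for dissimilar
  (margin 1.0 on encoder-scaled distances); Adam (lr 1e-3), balanced
  batches of 16 pairs, 5000 iterations by default.

Gradients come from a small reverse-mode tape engine on numpy arrays
(`rowgraph.autodiff`), written for this package's model sizes (a few
MLPs and a GRU cell over 25-node graphs) and verified against central
finite differences in the test suite. One seed governs initialisation,
sampling and jitter; two runs with the same seed produce identical loss
traces.

## Alignment and temporal smoothing

Two videos rarely start at the same stroke phase, so scores are computed
after a start-frame search: over integer offsets `f` in [-100, 100],
minimise the mean embedding distance between a 100-frame window of
sequence 1 starting at `S1` and the window of sequence 2 starting at
`S1 + f`. Ties break toward the smallest |f|, then the negative offset;
a minimiser at ±100 sets a boundary flag (the true shift may lie outside
the range). `S1` defaults to 100 — the search half-width — because
negative offsets index before frame 0 for any smaller start. Both
sequences are then truncated to their aligned overlap before scoring.

For a GMN, evaluating the joint pair embedding at all 201 candidate
offsets would multiply the (already pair-specific) embedding cost by the
search length, so the offset search runs on the model's intra-graph-only
embeddings (cross message zeroed); the final score re-embeds the aligned
frames jointly. For a GEM the two are the same computation.

Time-period similarity (TPS) smooths the framewise distance series into
means over consecutive non-overlapping 100-frame segments (a trailing
partial segment is averaged over its actual length and flagged). For
equal segments the mean of segment means equals the overall mean
exactly.

A planted shift is uniquely recoverable only when the stroke period
exceeds twice the search half-width; otherwise offsets congruent modulo
the period are indistinguishable on a perfectly periodic sequence.
Alignment experiments therefore use a 240-frame period (15 strokes/min,
a slow technique-drill rate).

## The stroke simulator

The simulator stands in for real rowing videos. It is a sagittal-plane
(side-camera) articulated model on an ergometer: the hip slides
horizontally with the stroke, the knee and elbow are placed by two-link
inverse kinematics with constant segment lengths, the trunk pivots from
forward lean (catch) to layback (finish), and the head, feet and the
out-of-plane limbs ride as constant offsets. The stroke cycle is a
piecewise sinusoid in the cycle fraction with an asymmetric drive
fraction (default 0.45 — the drive is faster than the recovery).
Emitted frames are 1920x1080 at 60 fps, matching common recording
settings; the default period of 120 frames is 30 strokes/min, a typical
steady-state rate.

Controllable structure:

- **style** (period, seat travel, trunk lean range, handle lift) —
  distinct styles give distinct coordinate trajectories;
- **phase**, parameterised as a fraction of the cycle so that integer
  frame shifts are exactly representable (alignment ground truth);
- **noise**: i.i.d. Gaussian per coordinate per frame; **dropout** sets
  whole keypoints to (0, 0, 0) as a pose detector does;
- **drift** ("fatigue"): the period lengthens by a fractional rate per
  1000 frames, so an initially synchronised pair desynchronises — the
  qualitative divergence-after-the-early-segment pattern.

Noise-free, drift-free output is exactly periodic (the phase is computed
in closed form, not by accumulation) and all 24 skeleton edge lengths
are constant over time.

What the simulator does **not** model: out-of-plane rotation, detector
confusion between left and right limbs, occlusion-correlated noise,
camera motion, or genuine biomechanics (forces, oar/handle dynamics).
Passing tests therefore show that the pipeline recovers planted
kinematic structure under detector-like noise — not that it matches any
specific real-world recording.

## Experiment driver

`run_experiment` simulates (or ingests) a roster, trains each requested
model variant (GEM/GMN x 1D-X/1D-Y/2D), computes the all-pairs
dissimilarity matrix with alignment, ranks pairings, and writes TPS
curves for the best and worst pair, stamping every output with the
config hash and seed. CSV floats are written with a fixed format so
reruns are byte-identical.

## Problem sizes used in the checks

The property checks run at desk scale, chosen to exercise the full
pipeline in minutes on one CPU: alignment uses 700-frame sequences and a
random-initialised (seeded) GEM — alignment needs embeddings that are
merely injective and continuous, not trained; discrimination trains a
2D-GEM (node dim 16, graph dim 32, T=5) for 500 iterations on six
600-frame rowers over two styles, repeated over 10 seeds; the drift
pattern uses full one-minute (3600-frame) runs over 20 seeds. The
acceptance script (`scripts/acceptance.py`) recomputes the same
quantities from scratch at these sizes.

## Known limitations

- Dissimilarity magnitudes depend on the learned weights and the
  `input_scale` constant; only comparisons and rankings are meaningful
  across models or runs, not absolute values.
- The GMN all-pairs matrix costs one joint embedding per pair (the
  embeddings are partner-specific); GEM embeddings are computed once per
  rower and reused.
- The ±100-frame search window assumes the true phase offset is within
  it; longer offsets surface only as a boundary flag.
- Training supervision is self-constructed (jitter positives); nothing
  guarantees that embedding distance matches a human judge's notion of
  technique similarity beyond the planted-structure checks above.
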