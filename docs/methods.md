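# Methods

## The model

`birdparts` treats fine-grained bird recognition as part detection followed
by score fusion. The detector is a YOLOv5-6.0-style single-stage network:
a CSP backbone (stem Conv, C3 stages, SPPF), a top-down + bottom-up neck
(FPN + PAN), and an anchor-based head predicting, per scale and anchor,
4 box offsets, an objectness logit and one logit per class. Two attention
mechanisms are inserted:

* **Res2Net-CBAM** after each backbone C3 stage. The unit applies a 1×1
  entry convolution, splits the channels into `s` groups and chains 3×3
  convolutions hierarchically (`Y1 = X1`; `Y2 = K2(X2)`;
  `Yi = Ki(Xi + Yi−1)` for `i ≥ 3`), enlarging the receptive-field mix
  within one block. The merged map passes a 1×1 exit convolution, then CBAM
  (channel gate, then spatial gate, each multiplicative), and the block
  input is added back as a residual. The sum `Xi + Yi−1` is taken *inside*
  the convolution, following the original Res2Net formulation; the residual
  connects the block input (before the entry convolution) to the post-CBAM
  output.
* **CBAM** on each of the three neck output scales, before the head.

The class space is the product of species and part: 200 × 4 = 800 classes,
species-major (`class_id = (species − 1)·4 + part`), so the species is
`class_id // 4 + 1`. The head therefore emits 805-channel per-anchor
vectors at full scale.

The classification stage reduces detections to a per-image part table (the
single highest-confidence record per part type, at most four records),
then scores each candidate species by `Σ w_part · confidence` over the
records voting for it. The weight vector (w_head, w_lw, w_rw, w_tail) lies
on the 0.01-step simplex grid — 176,851 vectors — and is chosen by
exhaustive enumeration, maximising accuracy on a labelled validation
table. Abstentions (no positively weighted record) count as errors; exact
score ties resolve to the lower species id, and ties between weight
vectors to the lexicographically smallest vector, so the whole stage is
deterministic and order-free.

## Numerical substrate

The network runs on a compact numpy reverse-mode autodiff engine
(`birdparts.autodiff`): convolution is im2col + GEMM with a col2im
scatter-add backward (k² slice adds, no per-element loops), pooling and
upsampling have exact adjoints, batch normalisation uses batch statistics
in training and running statistics (momentum 0.1, eps 1e-3) in
evaluation, and binary cross-entropy is computed on logits in the stable
`max(z,0) − z·t + log(1+e^−|z|)` form. Optimisation is Adam. Gradients are
verified against central finite differences in the test suite, and
convolution against `scipy.signal.correlate`.

Feature maps are channels-first (`N, C, H, W`) everywhere; the functional
attention API accepts single `(C, H, W)` arrays.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `width_multiple` / `depth_multiple` | 1.0 / 1.0 | channel / repeat scaling of the published full-scale graph; channels round to the nearest multiple of 8 (min 8), repeats to ≥ 1 |
| `res2net_scale` s | 4 | channel groups in the hierarchical unit; must divide the width |
| `reduction_ratio` r | 16 | channel-attention MLP bottleneck, capped so the hidden width is ≥ 1 |
| anchors | (10,13,…,373,326) | pixel anchor priors per scale, as published |
| `conf_threshold` | 0.25 inference / 0.001 for mAP | detection operating points |
| NMS IoU | 0.45 | per-class greedy suppression |
| loss gains | box 0.05, obj 1.0 (scale balance 4/1/0.4), cls 2.0 | composite CIoU + BCE objectness + BCE classification loss |
| lr schedule | peak 0.01, 3-epoch linear warmup, cosine decay to 0.001 | Adam |

The channel-attention MLP uses a ReLU between its two (bias-free) layers
and shares weights between the average- and max-pooled branches; the
spatial gate is a bias-free 7×7 convolution (padding 3) over the stacked
channel-mean/max maps. The classification gain of 2.0 (rather than the
0.5 common for 80-class detectors) reflects that the part×species class
term is the hard part of this task at short schedules: with few hundred
optimisation steps, class discrimination otherwise lags localisation.

Training-time decode follows the standard v5 parameterisation
(`xy = (2σ−0.5+cell)·stride`, `wh = (2σ)²·anchor`); targets match anchors
within a 4× size ratio at the centre cell and its two nearest neighbours,
and the objectness target is the clipped CIoU of the matched prediction.

## Synthetic data: what it does and does not emulate

`generate_scenes` renders one schematic bird per canvas: up to four part
glyphs (disc = head, left/right triangles = wings, square = tail) in
jittered quadrants on a noisy grey background with achromatic clutter
blobs. The glyph colour encodes the species (distinct hues), the shape the
part — a colour × shape product code that makes species separable by
construction (verified by a nearest-template test). Parts are occluded
independently with probability 0.1, mirroring that real part annotations
are sometimes invisible. This preserves the *statistical* structure the
method relies on — parts in consistent spatial arrangements, species
identity recoverable from any single part, partial part visibility — but
none of the photometric difficulty of real bird imagery (pose, deformation,
camouflage, scale variation). Passing the scaled-down end-to-end test shows
the pipeline is implemented coherently, not that it would reach any
particular accuracy on real photographs.

`generate_detection_table` skips the image domain entirely and plants
per-part informativeness directly: a record is correct with probability
`p_part` (default (0.95, 0.5, 0.5, 0.3)), dropped with probability 0.1,
and its confidence is Beta(8,2) when correct, Beta(2,4) when wrong — so
confidence is informative, which is what makes confidence-weighted voting
sensible in the first place.

## Desk-scale study conditions

The end-to-end check trains a 1/8-width, minimum-depth model at 160×160 on
64 scenes of 8 species for 50 epochs (batch 8, ~400 Adam steps, about four
minutes on one CPU core), then evaluates mAP@0.5 on 32 held-out scenes and
runs the full 176,851-vector fusion search on the held-out part table.
Pilot runs of this profile reach mAP@0.5 ≈ 0.5–0.8 and fusion accuracy
0.53–0.72, consistently above the single-best-part baseline. The
full-multiplier graph (≈100 M parameters) is exercised forward-only, to
audit every published layer shape in a single 640×640 pass.

## Design choices where the design was open

* **Class order** species-major, making species recovery integer division.
* **Coordinates** 0-based half-open in memory; VOC files stay 1-based
  inclusive on disk. XML object names are `"<species:03d>_<part>"`.
* **Wing labels under horizontal flip** are swapped by default (a mirrored
  left wing looks like a right wing); exposed as a flag.
* **Brightness augmentation** is multiplicative gain with clipping;
  noise is i.i.d. per channel with σ = 10 on the 0–255 scale; one
  augmented copy per transform.
* **Row-25 neck C3** takes the 640-channel concat as its input width
  (channel consistency over the printed argument pair).
* **mAP** is the arithmetic mean of per-class all-point-interpolated APs
  over classes that have ground truth; classes without ground truth are
  excluded and logged.
* **Tie rules** (confidence ties in the part table: lower class id, then
  smaller box; vote ties: lower species; weight-vector ties:
  lexicographic minimum) exist to make every stage deterministic under
  input permutation.
* Truncated/occluded VOC flags are ignored; no minimum-confidence filter
  is applied before the per-part reduction beyond the detector's own
  inference threshold.

## Known limitations

* The engine is CPU-only and single-process; full-scale *training* of the
  100 M-parameter graph is out of reach (forward-only audits are cheap).
* Nearest upsampling is fixed at 2×; inputs must be multiples of 32.
* No mosaic/mixup augmentation, no multi-GPU, no export formats, no
  COCO-style mAP@[.5:.95], and no spatial-consistency checks between
  detected parts.
* The fusion search optimises accuracy on the table it is given; with
  small validation sets many weight vectors tie and the reported tie
  count should be inspected before interpreting the optimum.
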