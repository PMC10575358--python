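# birdparts

Part-based fine-grained bird species recognition.

Fine-grained categories such as bird species differ in subtle, localised
cues: within-species appearance variation (pose, lighting, background) is
often larger than the between-species differences that matter. `birdparts`
implements a two-stage, part-based approach to this problem:

1. **Part detection.** A single-stage anchor-based detector localises four
   bird parts — head, left wing, right wing, tail — where every
   (species, part) pair is its own detection class: 200 species × 4 parts =
   800 classes, encoded species-major as
   `class_id = (species_id − 1)·4 + part`. The detector is a CSP
   backbone/FPN+PAN neck/three-scale head design augmented with attention:
   a **Res2Net-CBAM** residual unit after every backbone C3 stage and a
   **CBAM** block on each neck output scale.
2. **Species fusion.** Per image, the highest-confidence detection of each
   part is kept (at most four records). Each record votes for its species
   with weight `w_part · confidence`; the species with the largest summed
   score wins. The four part weights live on a 0.01 grid summing to 1 —
   C(103, 3) = 176,851 weight vectors — and the optimal vector is found by
   exhaustive search maximising classification accuracy on a labelled split.

The attention blocks compute

```
Mc(F) = σ( W1·relu(W0·AvgPool(F)) + W1·relu(W0·MaxPool(F)) )     (channel)
Ms(F) = σ( f7×7[ AvgPoolc(F) ; MaxPoolc(F) ] )                   (spatial)
```

applied multiplicatively in sequence, and the Res2Net-CBAM unit chains 3×3
convolutions over `s` channel groups (`Y1 = X1`, `Y2 = K2(X2)`,
`Yi = Ki(Xi + Yi−1)`), applies CBAM to the re-merged map and adds the block
input back as a residual.

The network runs on a small numpy reverse-mode autodiff engine included in
the package (`birdparts.autodiff`): im2col convolution, batchnorm, pooling,
and Adam — no GPU or deep-learning framework required. Detection quality is
scored with the usual precision / recall / all-point-interpolated AP /
mAP@0.5 chain, and the package ships a synthetic scene generator (schematic
birds whose glyph colour encodes the species) so the whole pipeline is
trainable and testable on a desktop CPU in minutes.

## Worked example

Train a small detector on synthetic scenes and classify by part fusion:

```
birdparts synth scenes --out data/train --n-images 64 --n-species 8 --seed 11
birdparts synth scenes --out data/val --n-images 32 --n-species 8 --seed 12 --split val

cat > tiny.yaml <<'YAML'
model: {num_classes: 32, width_multiple: 0.125, depth_multiple: 0.0833,
        input_size: 160, seed: 3}
train: {epochs: 50, batch_size: 8, seed: 3}
eval:  {conf_threshold: 0.25}
YAML

birdparts train  --manifest data/train/manifest_train.txt --out model --config tiny.yaml
birdparts detect --checkpoint model --manifest data/val/manifest_val.txt \
                 --out detections.csv --config tiny.yaml
birdparts parts  --detections detections.csv --out parts.csv
birdparts fuse   --table parts.csv --truth data/val/truth_val.csv \
                 --out fusion.json
```

A run of this profile on one CPU core (about four minutes of training)
prints:

```
final loss 0.5066; checkpoint at model
217 detections -> detections.csv
32 images, max 4 records/image -> parts.csv
best weights [0.04, 0.48, 0.45, 0.03] accuracy 0.7188 -> fusion.json
```

meaning: the training loss fell to 0.51 over 50 epochs; 217 part boxes
survived the 0.25 confidence threshold and NMS on the 32 held-out scenes;
every image kept at most 4 part records; and the exhaustive weight search
found a vector whose weighted vote classifies 71.9 % of held-out scenes
correctly (the single-most-confident-part baseline reaches 65.6 % on the
same table, and the detector's held-out mAP@0.5 at the 0.001 evaluation
threshold is 0.795). Exact numbers vary slightly with seeds and BLAS
builds.

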