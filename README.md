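# richfuse

Multimodal benign/malignant classification from paired pathology images and
coded clinical records, built around three ideas:

1. **Multilevel image features** — a five-stage convolutional backbone
   (full scale: the classic 64-128-256-512-512 / 2-2-3-3-3 16-layer layout at
   224×224 input) whose stage-3/4/5 pre-pooling maps are global-average-pooled
   and concatenated into one vector (1280-d at full scale).
2. **Dimension raising for tabular records** — 29 integer-coded clinical
   features, min-max encoded to [0, 1], are raised to a 580-d code so the
   record modality is not overwhelmed by the image features. Five methods are
   implemented and compared: tiling ("copy"), degree-2 interaction/polynomial
   expansion, a plain autoencoder, a denoising autoencoder (feature-dropout
   corruption at rate 0.2, clean-target reconstruction), and the denoising
   sparse autoencoder (L1 weight penalty) with topology
   29-290-435-580-435-290-29.
3. **Concatenation fusion + three-phase training** — record code (580) ‖
   image feature (1280) → 1860-d vector → fully connected 500-100-2 head.
   Phase 1 fits the autoencoder on records alone, phase 2 trains the backbone
   on images alone, phase 3 freezes both and trains the head.

Everything runs on plain NumPy (no GPU or deep-learning framework needed);
reduced-scale presets make full pipelines runnable on one CPU in minutes. A
synthetic paired-cohort generator emulates the real dataset's layout (185
patients, 82 benign / 103 malignant, 2-10 images each) with controllable,
partly independent class signal per modality, so the fusion-beats-unimodal
and missing-data-robustness properties are testable without any download.

## CLI

```bash
richfuse simulate --preset test --seed 0 --out runs/cohort
richfuse preprocess --images runs/cohort/images --seed 0 --out runs/patches
richfuse train --cohort runs/cohort/cohort.csv --images runs/cohort \
               --config my_config.yaml --seed 0 --out runs/model
richfuse evaluate --model runs/model/model.npz --cohort runs/cohort/cohort.csv \
                  --images runs/cohort --out runs/eval
richfuse compare --seed 0 --n-seeds 5 --missing-rates 0.0,0.2 --out runs/compare
```

Configuration is layered YAML (defaults ← file ← CLI); see
`richfuse.config.DEFAULTS` for every key. One global `--seed` is fanned out
deterministically to every randomized stage; each output directory contains a
`run_manifest.json` with the resolved config, its hash and the derived seeds.

Cohort tables are UTF-8 CSV with header
`patient_id,<29 feature columns>,label` (labels `benign`/`malignant`, blank
cells = missing values). Images are PNG/JPEG/TIFF RGB, indexed to patients by
a `manifest.csv` (`image_id,patient_id,label`).

## Layout

```
src/richfuse/
  emr_schema.py      29-feature schema, validation, [0,1] encoding, cohort CSV I/O
  dim_raising.py     copy / IP / AE / DAE / DAE-L1 dimension raisers
  _nn.py             NumPy NN core (dense + im2col conv, Adam, losses)
  image_backbone.py  5-stage conv backbone, stage taps, multilevel pooling
  preprocessing.py   multiscale patch extraction + augmentation (no stain norm)
  fusion.py          fuse, FC head, three-phase training, model archives
  synthetic.py       paired synthetic cohort generator
  evaluation.py      accuracy / ROC-AUC, patient-level splits, comparison harness
  config.py, cli.py  layered config and the `richfuse` command
```
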