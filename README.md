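# hgtrack

Multi-object tracker for videos of many visually near-identical small agents
with erratic, impulsive motion (sharp turns, sudden accelerations, frequent
crossings and occlusions) under a static camera.  The pipeline decouples
appearance from motion, fuses the two streams through a heterogeneous graph
attention network, and runs unified detection–tracking with learned affinity
association and re-detection of lost identities.

Everything is pure NumPy/SciPy — including a small reverse-mode autodiff
engine (`hgtrack.autodiff`) used to train the model — so the package has no
GPU or deep-learning-framework dependency.

## Pipeline

1. **Motion decoupling** (`hgtrack.motion`) — per-pixel quadratic
   (polynomial-expansion) modelling of each frame, closed-form displacement
   between consecutive frames, polar transform, adaptive trinary
   thresholding (`tau = mu + k*sigma`, k1=1.0 / k2=2.5) and sparse motion
   features rasterised into a 2-channel (magnitude, angle) image.
2. **Dual-stream backbone** (`hgtrack.backbone`) — a size-configurable
   4-stage pyramid transformer per modality (downsampling 4/8/16/32),
   flattened and projected into query matrices with 8-band sinusoidal
   positional encodings.
3. **Heterogeneous graph fusion** (`hgtrack.mhgn`) — typed attention over
   detection queries and trajectory memory: temporal (query ↔ memory, per
   modality), spatial (relative-position MLP bias), heterogeneous
   (cross-modal sum), followed by multi-head deformable decoding of the
   fused grids to refresh per-track memory.
4. **Detection–tracking head** (`hgtrack.head`) — centre heatmap / box /
   offset branches, displacement MLP, pairwise affinity network
   `[U; V; U∘V; |U−V|]`, Hungarian matching, harmonic-mean cross-modal
   confidence fusion, and the five-term multi-task loss (focal + SmoothL1 +
   L1 + IoU + BCE).
5. **Tracker** (`hgtrack.tracker`) — online track lifecycle
   (spawn / match / inactive / revive / terminate) with motion-gated
   association and re-detection of recently lost tracks.  Any callable
   producing detections can replace the learned head (oracle stubs for
   tests and ablations).
6. **Metrics** (`hgtrack.metrics`) — CLEAR-MOT (MOTA, FP/FN/IDSW with
   match-continuity convention), IDF1 via global identity matching, Frag,
   MT/ML.
7. **Simulator** (`hgtrack.simulate`) — deterministic synthetic arena
   (Gaussian-blob agents, Bernoulli impulses, heading jitter, reflective
   walls) with exact MOT ground truth and curated scenarios:
   `easy_separated`, `crossing_pair`, `dense_occlusion`, `erratic`.

## CLI

```sh
hgtrack simulate --scenario crossing_pair --out seq --n-frames 30
hgtrack --config cfg.yaml track --frames seq/img1 --weights ckpt.npz --out pred.txt
hgtrack evaluate --gt seq/gt.txt --pred pred.txt --json-out metrics.json
hgtrack train-tiny --scenario erratic --steps 200 --out ckpt.npz
hgtrack viz --results pred.txt --frame seq/img1/000001.png --out traj.png
```

Global flags: `--config` (YAML, strict keys), `--seed`, `--log-level`.
All defaults (including the training hyperparameters: AdamW, lr 2e-4,
weight decay 0.05, cosine schedule with 1000 warmup steps, batch 16,
300 epochs, 512×512 inputs, flip/±30° rotation augmentation) live in
`hgtrack.config.RunConfig`.

## Scope notes

- The simulator reproduces the statistical regime (similarity, erratic
  motion, occlusion) the method targets; it does not attempt photorealistic
  animal rendering.
- Training here is desk-scale (tiny model profiles, short synthetic
  sequences) to demonstrate the loss and optimisation machinery; no
  pretrained backbone weights are used or required.
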