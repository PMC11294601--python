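# cyclecell

Unsupervised identification of individual cells on noisy, unlabelled
microscopy images — in particular keratinocytes on reflectance confocal
microscopy (RCM) images of the living human epidermis, where bright tube-like
membranes form a honeycomb inside tissue islands separated by dark grooves,
and where annotated ground truth is scarce, expensive and inter-expert
variable.

## The method

The detector is a **dual-task cycle-consistent adversarial network**. Each
task is a cycle-GAN (two generators, two discriminators) translating between
an image domain and a common *prior* domain B of clean synthetic binary
membrane images:

* **Task 1** maps raw images (domain A) to binary membrane maps — it learns
  the noise and texture model of the modality.
* **Task 2** maps membrane-enhanced images (domain C, Gabor-filtered) to the
  same binary maps — it learns the geometric structure of the tissue.

Eight networks in total: generators G<sub>A2B</sub>, G<sub>B2A</sub>,
G<sub>C2B</sub>, G<sub>B2C</sub> and discriminators D<sub>B1</sub>,
D<sub>A</sub>, D<sub>B2</sub>, D<sub>C</sub>. Per task, the binary-producing
generator is trained on a trio of losses

* adversarial: MSE(D(G(x)), 1),
* identity: MAE(G(b), b) for real binary images b (weight λ<sub>id</sub> = 5),
* cycle consistency: MAE(G(G′(b)), b) (weight λ<sub>cyc</sub> = 10, i.e. 10×
  the adversarial term),

and the two tasks are coupled by **soft parameter sharing through the loss**:
the shared objective is max(total₁, total₂), so on each step only the
currently-worse task's binary generator receives gradient, synchronising the
two tasks. Training data are fully unpaired; the binary pool comes from a
ground-truthed simulator (Bezier tissue islands, hard-core seed process,
Voronoi membranes, plus correlated-speckle/blob/illumination rendering), so
no manual annotation is needed anywhere.

At inference, G<sub>A2B</sub> applied to a locally-normalised image gives an
incomplete membrane map, which post-processing turns into cell instances:
alpha-shape closure of the tissue contour, connected-component hole filling,
star-convex instance splitting, and a biological minimum-area filter
(100 px² for stratum granulosum, 50 px² for stratum spinosum at ~1 µm/px).
Detections are scored with **d-accuracy**: one-to-one Hungarian matching of
predicted and true cell centers at radius d (default 10 px), summarised as
precision/recall/F1 with the median F1 reported per image set on a 0–100
scale.

## Worked example

```python
from cyclecell import core, pipeline, evalmetrics

cfg  = core.desk_config(epochs=200, rng_seed=11)       # 64x64 desk recipe
pcfg = pipeline.PipelineConfig(rng_seed=11, gan=cfg)

# 32 unpaired synthetic training images: 12 raw-like, 12 enhanced, 8 binary
pools = pipeline.make_training_pools(pcfg, 12, 12, 8, shape=(64, 64))
val_images, val_centers = pipeline.make_validation_set(pcfg, 6, shape=(64, 64))

checkpoints, log = core.train(cfg, *pools)
nets = core.restore_networks(checkpoints[-1])

results = [evalmetrics.match_detections(
               pipeline.infer_and_extract_centers(img, nets, post=pcfg.post),
               gt, d=10.0)
           for img, gt in zip(val_images, val_centers)]
print(evalmetrics.summarize_images(results)["median_f1"])
```

On this seed the run prints a held-out median F1 of `89.5` (0–100 scale)
after 200 epochs, against `14.4` for the untrained network — the shared loss
falls from 17.2 to 3.1 over training. Numbers vary by a few points with the
seed; the ordering trained ≫ untrained does not.

The same flows are available from the shell:

```bash
cyclecell simulate  --seed 1 -o out/sim          # ground-truthed samples
cyclecell train     --seed 1 -o out/run          # desk-scale training
cyclecell benchmark --seed 1 -o out/bm           # median-F1 report
cyclecell evaluate  --pred pred.csv --gt gt.csv  # d-accuracy scoring
```

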