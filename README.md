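# dzseg — dissection-zone segmentation with visual prompt overlays

During endoscopic submucosal dissection (ESD), the surgeon must cut strictly
inside the *dissection zone*: the band of submucosa that can be excised
safely.  Everything else is the *no-go zone* — contact there risks
muscle-layer injury and perforation.  Telling the two apart on an endoscopic
frame is hard because neighbouring tissue regions look alike and their
boundaries are blurred.  `dzseg` implements an interactive segmentation
approach for this setting, aimed at surgical-AI researchers and engineers:
an experienced mentor draws a quick cue — a point, a short or long scribble,
or a bounding box — and the model turns the cued frame into a per-pixel
dissection-zone / no-go-zone mask.

The central design idea is that the prompt is **burned into the image**:
the cue's geometry is rasterized onto the RGB frame as a fixed colour code
(green strokes, red box outlines), and the prompted frame is fed to an
ordinary segmentation network.  No separate prompt encoder exists.

The network is a ViT encoder with parameter-efficient adaptation and an
All-MLP decoder:

* the frame x ∈ R^{H×W×3} is split into non-overlapping p×p patches,
  embedded to N = HW/p² tokens of width D plus a class token;
* attention in each of the M transformer blocks carries low-rank (LoRA)
  adapters on the query and value projections,
  Q = W_q x + B_q A_q x, V = W_v x + B_v A_v x, with rank-r A, B the only
  trainable encoder weights (B = 0 at init, so the adapted model starts
  exactly equal to the frozen base);
* at selected blocks m the class token is broadcast over the √N×√N patch
  grid, channel-concatenated (2D channels) and upsampled ×4;
* an All-MLP head aligns each stage to a common width C, concatenates,
  fuses n·C → C, and maps C to the N_cls per-pixel logits.

Evaluation follows the segmentation conventions of the task: per-class IoU
and Dice with unweighted class means, plus the boundary metrics ASSD
(average symmetric surface distance) and Hausdorff distance.  The package
also ships the two prompt-availability protocols (prompted:unprompted
ratios such as 6:4, and the 25%-each mixed-prompt-type protocol), five
image-corruption operators (Gaussian noise, motion blur, smoke, contrast,
brightness) at severities 1–5 for robustness studies, and a seeded
synthetic-scene generator so that everything is testable at desk scale
without clinical data.

The network and its training loop run on a small reverse-mode autodiff
engine built on NumPy (see `docs/methods.md`), so the package has no deep
learning framework dependency.

## Worked example

```python
import dzseg as dz

# 1. synthesize ambiguous-boundary scenes (64x64, seeded)
train_scenes = dz.generate_dataset(dz.SceneSpec(), count=32, seed=11)
val_scenes = dz.generate_dataset(dz.SceneSpec(), count=8, seed=12)

# 2. attach a long-scribble prompt to every scene
mix = dz.MixtureSpec(mode="ratio", prompted_fraction=1.0,
                     prompt_kind="long_scribble", seed=0)
train_pairs = dz.build_mixture(train_scenes, mix)
val_pairs = dz.build_mixture(val_scenes, mix)

# 3. tiny scratch backbone (D=32, 2 blocks, patch 8) with rank-4 LoRA
enc = dz.EncoderConfig(**dz.TINY_PRESET["enc"])
dec = dz.DecoderConfig(**dz.TINY_PRESET["dec"])
model = dz.build_model(enc, dz.LoRAConfig(rank=4), dec, seed=0)
print(dz.count_trainable_parameters(model))

# 4. fit LoRA + decoder, cosine-annealed Adam on cross-entropy
cfg = dz.TrainConfig(learning_rate=0.01, input_size=64, epochs=30,
                     batch_size=8, seed=0, val_every=10)
model, log = dz.train(train_pairs, val_pairs, model, cfg)
print(f"epoch {log[-1]['epoch']}: train loss {log[-1]['train_loss']:.3f}, "
      f"val mean IoU {log[-1]['val_mean_iou']:.3f}")

# 5. full metric report on the validation scenes
report = dz.evaluate(model, val_pairs, cfg)
print(f"dissection-zone IoU {report.iou_per_class[1]:.3f}, "
      f"Dice {report.dice_per_class[1]:.3f}, "
      f"ASSD {report.assd:.2f} px, HD {report.hd:.2f} px")
```

Output:

```
{'lora_params': 1024, 'decoder_params': 6306, 'frozen_params': 33696}
epoch 29: train loss 0.294, val mean IoU 0.658
dissection-zone IoU 0.458, Dice 0.617, ASSD 5.02 px, HD 19.46 px
```

The parameter partition shows the fine-tuning regime: 1,024 LoRA weights
(2 blocks × {query, value} × 2·32·4) and the decoder train; the other
33,696 encoder weights stay frozen.  After 30 epochs on 32 scenes the
model localizes the dissection zone on unseen scenes (IoU 0.458 against a
task where a pure luminance threshold barely beats guessing); the boundary
metrics say the predicted outline sits on average ~5 px from the true one,
with a worst-case (Hausdorff) excursion of ~19 px.

A command-line surface wraps the same pipeline
(`dzseg synth | derive-prompts | overlay | train | predict | evaluate |
corrupt | report`); every subcommand writes a resolved-config snapshot next
to its outputs so runs can be reproduced from snapshot + seed.

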