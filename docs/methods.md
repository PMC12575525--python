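# Methods

## Model

The segmentation network is a plain pre-norm ViT encoder feeding an All-MLP
decode head.

**Encoder.** The input frame (8-bit RGB, scaled to [0,1] and standardized
with the ImageNet channel statistics) is cut into non-overlapping p×p
patches, each linearly embedded to width D; a learned class token is
prepended and learned positional embeddings added.  When the spatial grid
differs from the configured one, positional embeddings are bilinearly
interpolated, so any p-divisible input size is accepted.  Each of the M
blocks is multi-head self-attention plus a 4×-wide GELU MLP, both with
residual connections and pre-layer-norm.  Attention uses the standard
per-head scaling 1/√(D/heads).

**LoRA.** Query and value projections carry low-rank adapters:
y = W x + s·B A x with A ∈ R^{D×r} drawn from N(0, 0.02²), B ∈ R^{r×D}
initialized to zero, scale s = 1.  Consequences that the tests pin down:
the adapted network is bit-identical to the frozen base at step 0, and a
backward pass produces gradients only on A, B and decoder weights — every
base encoder weight is frozen (including layer norms; nothing outside the
adapters is trainable in the encoder).  Adapter initialization draws from
an RNG stream separate from the base weights, so enabling or disabling
LoRA never changes the base initialization for a given seed.

**Stage fusion.** At each selected block the class token is broadcast to
every position of the √N×√N patch grid and channel-concatenated, giving 2D
channels, then upsampled ×4.  Broadcasting was chosen among the plausible
class-token fusion schemes (tiling, addition, dropping) as the simplest one
that lets every spatial position see the global summary; the fused channel
count 2D is what the decoder contract expects.

**Decoder.** Three per-position linear layers: align each stage's 2D
channels to a common width C (default 256 at full scale, 32 in the tiny
preset), concatenate the n stages, fuse n·C → C with a GELU, then map C to
the N_cls = 2 logits.  Logits are bilinearly resized to the output
resolution.  All bilinear resampling in the project — stage upsampling,
logit resizing, image preprocessing — uses the align-corners-false
convention, implemented as two 1-D interpolation matrices so the same code
path serves forward and backward passes.

**Checkpoints** are NumPy `.npz` archives of named parameters with a JSON
sidecar holding the three config dataclasses; loading validates every shape
and reports all mismatches at once.

## Numerical substrate

The package carries its own small reverse-mode autodiff engine on NumPy
(`dzseg._autodiff`): dense float64 tensors, the primitives the architecture
needs (broadcast arithmetic, batched matmul, layer norm, softmax, exact
GELU, slicing/concat, the interpolation-matrix resampler, cross-entropy),
and Adam.  Frozen parameters never accumulate gradients, but gradients flow
*through* them, which is precisely the LoRA regime.  Every primitive's
gradient is checked against central differences in the test suite.

## Training

Adam on unweighted per-pixel cross-entropy (the no-go class dominates
~4:1 on synthetic scenes; weighting is deliberately not applied), cosine
annealing from the base learning rate to 0 across the epoch budget, batch
size 8, last-epoch checkpoint (no early stopping).  Prompts are overlaid at
native resolution before the bilinear resize of the image; masks are
resized nearest-neighbour, since bilinear interpolation of labels would
manufacture values outside {0,1}.  Prompt geometry is fixed per sample by
default (`resample_prompts` re-derives it per epoch from an epoch-dependent
seed when enabled).  The full-scale preset keeps learning rate 0.001 at
input size 532 (multiple-of-14 for patch 14); the desk-scale protocol uses
0.01 — with only ~240 optimizer steps the tiny model is still far from
converged at 0.001, and 0.01 was selected by train-loss convergence.

An unprompted model is the identical architecture fed the un-overlaid
frame; "with vs without prompts" differs only in the overlay.

## Prompts

* **point** — uniform draw over dissection-zone pixels; rendered as a
  filled disk (default radius 4 at the 532 px reference scale).
* **bbox** — the tightest axis-aligned rectangle over zone pixels,
  rendered outline-only, stroke 3 (filled mode available); red (255,0,0).
* **scribbles** — expert dissection trajectories are not available outside
  the original annotation workflow, so scribbles are synthesized as the
  longest geodesic path of the zone's morphological skeleton: long keeps
  the central 80% of that path, short the central 25% (hence short ⊂ long
  for the same mask).  For zones whose skeleton degenerates to a point
  (near-circular zones) the path falls back to the principal axis through
  the centroid, clipped to the zone.  Optional seeded jitter emulates
  hand-drawn wobble and snaps vertices back inside the zone; it is off by
  default.  Green (0,255,0), stroke 3 at reference scale.

Stroke widths and the point radius scale with min(H,W)/532 so footprints
stay proportionate across resolutions.  Overlay sets footprint pixels
exactly to the colour code and provably leaves every other pixel
byte-identical.  Colour values themselves are a free design choice (only
their existence, not their values, is fixed by the approach) and are
configurable in `PromptStyle`.

## Metrics

IoU and Dice per class, with "mean" always the unweighted two-class mean.
Both-empty classes score 1.0 (degenerate exact agreement).  Boundary
metrics use the 4-connectivity inner boundary and Euclidean distances
between pixel centers, computed by distance transform (exact for this
definition): ASSD is the symmetrized mean of directed boundary distances,
HD the plain symmetrized maximum (not the 95th-percentile variant).  When
exactly one boundary is empty both distances return the image diagonal as
a finite sentinel.  Dataset-level numbers are means over per-image values
(macro aggregation).  Fast implementations are required by the tests to
match brute-force set/pairwise-distance oracles to 1e-9.

## Corruptions

Five operators at severities 1–5, parameterized after the common-corruption
robustness benchmark on [0,1]-scaled images: Gaussian noise
(σ = .08/.12/.18/.26/.38), motion blur (Gaussian-weighted line kernel at a
seeded angle in ±45°, radius/σ per severity), smoke (a fog-style haze from
a periodic diamond-square plasma fractal — the benchmark's fog-like
operator, which visually matches intra-procedural smoke), contrast scaling
about the mean (factors .4/.3/.2/.1/.05; factor 1 is the identity), and
brightness (+.1…+.5 on the HSV value channel).  Output is always clipped
8-bit of the input shape; stochastic operators are deterministic given the
seed.  Corruption is applied to the clean native-resolution frame *before*
prompt overlay and resizing — it models degraded acquisition, while a
surgeon's prompt is drawn crisply on top; masks are never touched.

## Synthetic scenes

The generator emulates the one property that makes the real task hard:
zones that are nearly indistinguishable from their surroundings.  Each
scene is a single star-convex blob (radial harmonic series, simply
connected by construction, 5–40% of the frame) in reddish tissue hues on a
smooth-noise background; the blob differs from the background only by a
luminance offset scaled by `texture_contrast`, and the transition is blurred
by a Gaussian of radius `boundary_softness` (the label mask stays crisp).

Defaults are the study conditions: 64×64 px, softness 2, contrast 0.10,
five harmonics.  The contrast default was set from the generator's own
separability analysis: sweeping a single luminance threshold (the
brute-force oracle the tests use) gives ~0.83 pixel accuracy at contrast
0.10, barely above the ~0.79 majority-class baseline — i.e. genuinely
ambiguous boundaries — whereas by 0.35 the oracle reaches 0.97 and the task
degenerates into trivial thresholding.  At contrast 1 with no blur the
oracle is exact (100%), which anchors the generator's learnability dial;
accuracy decreases monotonically as contrast drops.

What the generator does **not** model: instruments and smoke in the clean
frames, specular highlights, multiple candidate regions, perspective and
lighting variation, or video correlation.  Desk-scale results therefore
demonstrate that the pipeline's machinery works end to end and that prompt
information is usable by the network — they are not evidence about
clinical-scale accuracy.

## Desk-scale prompt-benefit protocol

Tiny backbone (p=8, D=32, M=2, heads 4, stages {1,2}, C=32), 64 training
and 16 validation scenes at default generator settings, 30 epochs, learning
rate 0.01, three replicate seeds per condition; the statistic is mean
validation dissection-zone IoU with long-scribble prompts versus without
prompts.  Under these conditions the prompted mean exceeds the unprompted
mean by several IoU points (the acceptance script prints the numbers for
its seed).  These problem sizes were chosen so the whole experiment runs in
a few minutes on one CPU core.

## Known limitations

* Published ViT-B/14 foundation-model checkpoints ship in a framework-
  specific serialized format this package does not parse; checkpoint
  loading covers the package's own `.npz` format.  Full-scale presets are
  therefore scratch-initialized unless converted weights are supplied.
* float64 NumPy forward/backward is CPU-bound: the full 532 px ViT-Base
  preset is usable for parameter accounting and architecture checks, but
  training at that scale is impractical here.
* The "optimal dissection trajectory" scribbles are a reproducible
  skeleton-based stand-in, not clinician traces.
* Exact UI crop offsets for 1920×1080 → 1310×1010 acquisition are not
  standardized; `crop_ui` takes the rectangle as configuration.
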