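# Methods

## The model

`trajgan` builds videos in two stages around a single idea: a video is a
smooth trajectory through the latent space of a frozen 2D image generator.

**Stage 1 — frame backbone.** A progressive-growing GAN is trained on
individual frames. The generator `G` starts at 4×4 px and doubles its
resolution in phases; each new resolution block is blended in linearly,
`out = (1−α)·upsample(rgb_prev) + α·rgb_new`, with α ramping 0→1 over the
first part of the phase (the `fade_fraction`). The critic `C` mirrors the
generator and is trained with the WGAN-GP objective

```
L_C = E[f(fake)] − E[f(real)] + λ·E[(‖∇_x f(x̂)‖ − 1)²],   x̂ = u·real + (1−u)·fake
L_G = −E[f(fake)]
```

with λ = 10 (the standard gradient-penalty weight) plus a small drift term
`ε·E[f(real)²]`, ε = 0.001, that keeps the critic's output scale bounded.
After stage 1 both networks are frozen. The critic then plays a second
role: its penultimate activations (the input to its final scalar layer, a
vector of width `F`) are the per-frame features every later component
consumes.

**Stage 2 — plugin and video discriminator.** A small *plugin* network φ
maps one Gaussian noise vector `z` (shared by all frames of a clip) plus a
per-frame time index `t_i` to a latent code. Each of its four layers
concatenates an encoded time scalar onto the running vector and applies a
linear map; ReLU follows the first three layers and the fourth output is
L2-normalized onto the unit hypersphere. At reference scale the widths are
2048→1535, 1536→1023, 1024→511, 512→512 (hidden widths sit one below a
round number so the time concat restores it). Because row `i` depends only
on `(t_i, z)`, a trajectory of any length can be decoded frame by frame:
`video = [G(φ(t_1, z)), …, G(φ(t_n, z))]`.

The *video discriminator* `D` never sees pixels. Each clip window of `n`
frames becomes a single-channel `n × F` map whose rows are the frozen frame
critic's features in temporal order; four valid-mode Conv2D+ReLU layers, a
linear layer sized automatically from the convolution arithmetic, and a
sigmoid produce the probability that the window is a real, correctly
ordered video. At reference scale (8 × 512) the stack
(1,16,(3,10),(1,2)) → (16,8,(3,8),(1,2)) → (8,4,(3,6),(1,2)) →
(4,1,(2,6),(1,2)) shrinks heights 8→6→4→2→1 and widths 512→252→123→59→27,
so the final linear layer is 27→1.

Stage 2 is a standard GAN game in which only φ and D learn: D minimizes
binary cross-entropy pushing real windows toward 1 and generated windows
toward 0; φ minimizes, by default, the non-saturating form (BCE of D(fake)
toward 1). The saturating minimax form is available by configuration but
the non-saturating form trains far better early on, when D easily rejects
fakes. Both use Adam with lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999, for 50 epochs.
One D update is followed by one φ update per step, with fresh noise for
each fake batch; the training timeline is fixed to `[0, …, n−1]`.

## Numerical foundation

No GPU tensor library is used: the networks run on a small reverse-mode
automatic-differentiation engine over NumPy arrays (`trajgan.autodiff`).
Every primitive's vector-Jacobian product is itself composed of the same
primitives, so gradients carry their own graph and can be differentiated
again — which is exactly what the gradient penalty needs (its loss contains
`∇_x f(x̂)`, and training differentiates *that* with respect to the critic's
weights). Convolution is im2col (`unfold`) plus one matrix product; the
adjoint pair `unfold`/`fold` is linear, so second derivatives through
convolutions are exact. All network arithmetic is float32; the metric stack
(below) is float64.

Correctness is pinned by finite-difference gradient checks on every
primitive family and by two closed forms: a constant critic gives penalty
exactly λ, and a linear critic `f(x) = ⟨w, x⟩` gives λ(‖w‖−1)² at every
interpolate.

## Evaluation stack

FID (frames) and FVD (clips) are the Fréchet distance between Gaussians
fitted to embedded samples,

```
d = ‖μ_R − μ_G‖² + Tr(Σ_R + Σ_G − 2(Σ_R Σ_G)^{1/2}),
```

with sample means and (N−1)-divisor covariances. The matrix square root is
computed through the symmetrized product `√Σ_R · Σ_G · √Σ_R`
(eigendecomposition, negative eigenvalues clipped at 0), which keeps the
whole computation real — no complex residue to discard — and agrees with
`scipy.linalg.sqrtm` on the cross-product form to machine precision (this
agreement is asserted in the tests, where scipy serves as the independent
reference, not as the implementation). The result is clamped at 0.

The Inception Score is `exp(E_x KL(p(y|x) ‖ E_x p(y|x)))` per split,
natural log with `0·log 0 := 0`, reported as mean ± population std over
splits; it always lies in `[1, K]`.

Embedders are pluggable because no pretrained Inception-v3 or I3D weights
are bundled (or downloadable at run time). Built-ins: the frozen frame
critic's features (frame mode), the same features mean-pooled over time and
augmented with the mean absolute temporal difference (clip mode — so frame
order affects the embedding, as a video embedder's should), and a seeded
random pixel projection that needs no training at all. Externally computed
feature matrices can be loaded from a plain-text file with a JSON sidecar.
A seeded linear-softmax head stands in for the classifier behind the
Inception Score; it is a fixed random function, not a trained model, and is
labelled as such.

The evaluation protocol generates `n_clips` clips of `clip_len` frames,
computes FVD once on whole clips, then pools every frame of both sets,
randomly partitions the frames into `n_splits` disjoint parts and reports
FID and IS as mean ± std across parts (defaults: 5 splits, 16-frame clips).

## Synthetic data

Real training corpora for this method are action-video categories and
clinical colonoscopy recordings; neither can ship with a test suite, so the
package generates two families of toy scenes that reproduce the one
property the method depends on — temporal coherence, i.e. adjacent frames
differ less than random frame pairs:

* **moving shapes** — 2–3 textured discs/squares translating at
  `motion_amplitude` px/frame over a smooth background, reflecting off the
  frame edges (wrapping would cause a discontinuous jump and break
  coherence);
* **tunnel** — a fly-through of a reddish tube: concentric rings receding
  from a dark central lumen, angular wall texture, slow drift of the
  viewing axis — the motion signature of an endoscope sliding through a
  colon.

The coherence score of a clip is the mean |Δ| over adjacent frame pairs
divided by the mean |Δ| over an equal number of seeded random non-adjacent
pairs; identical frames define the 0/0 case as 1.0. Every default clip of
both families scores well below 1 while i.i.d.-noise control clips score
≈ 1. Defaults: `motion_amplitude` 2 px/frame (visible but unsaturated
motion at 32 px), `texture_detail` 3 harmonics, 3 channels, 16 frames.

What the toy scenes do *not* reproduce: real-image statistics (cameras,
lighting, occlusion), scene diversity within a category, specular
highlights and fluid motion of endoscopy, or any clinically meaningful
anatomy. Passing tests therefore demonstrate that the machinery — two-stage
training, freezing, feature-space discrimination, metrics — works end to
end at toy scale, not that the model produces clinically usable video.

Frames are float arrays in [−1, 1] everywhere (matching the tanh-output
generator); PNG I/O maps linearly to [0, 255] with round-half-even, so a
write/read round trip is exact up to one 8-bit quantization step (2/255).
Frame files are zero-padded (`frame_00012.png`) and clip folders are read
in lexicographic order, so ordering never depends on the filesystem.

## Problem sizes and defaults

The reference configuration reproduces the published architecture exactly
(512-dim latents, the four plugin layers above, the four-conv video critic,
batch 8 up to 256 px then 4, Adam 2·10⁻⁴/0.5/0.999, 50 epochs) and is what
an empty config file resolves to. Training runs in the test suite and the
acceptance script use a scaled-down instance chosen to exercise every
mechanism on a single CPU core: 64 tunnel clips of 16 frames at 32 px,
channel schedule {4:16, 8:12, 16:8, 32:6}, 64-dim latents and features, a
127-dim plugin noise with widths [95, 79, 63, 64], a proportionally
shrunk video-critic conv stack, 30 steps per progressive phase in stage 1,
and the full 50-epoch stage 2 (400 steps). The acceptance run reports,
among other quantities, the trained video critic's mean score on ordered
real clips versus frame-shuffled versions of the same clips; the ordered
score comes out higher, which is the designed check that the feature-space
discriminator actually uses temporal order.

## Design choices where the design was open

* **Plugin depth.** Three fully connected layers and four linear layers are
  both defensible readings of the source material; the four-layer form with
  the exact widths above is implemented, since it is the one specified in
  detail.
* **Noise dimension.** The first-layer width 2048 is read as 2047 noise
  dimensions plus one time slot; the concat arithmetic (2048→1535) only
  works out this way.
* **Time encoding.** `t_i` is mapped to `i/(n_ref−1)` with `n_ref = 8` by
  default (keeping activations scale-stable for any clip length); raw
  integer indices are available by configuration.
* **Hypersphere.** Plain L2 normalization to radius 1, guard
  `max(‖h‖, 1e−8)`; an all-zero pre-norm vector maps to the zero vector
  (finite, documented degenerate case).
* **Critic features.** The feature boundary is the input to the critic's
  final scalar linear layer. Minibatch-stddev is off by default so the
  feature extractor is a pure per-sample map (no cross-sample coupling);
  a flag enables it. Pixelwise feature normalization and equalized learning
  rate are on by default (standard progressive-GAN stabilizers), both
  switchable.
* **16-frame clips vs an 8-frame critic.** The video critic's window is
  fixed by its conv arithmetic; longer clips are scored and trained on
  8-frame windows (contiguous, uniformly placed during training).
* **Stage-2 real batches.** Contiguous n-frame windows at uniform random
  starts of uniform random videos. Real-clip feature maps are precomputed
  once per run — the frame critic is frozen, so they never change.
* **Checkpoints.** Single `.npz` files holding every parameter array plus a
  JSON metadata block (configs, phase pointers, flags, RNG state). The
  stage-2 checkpoint embeds the full backbone and its parameter hash, so it
  is self-contained and tamper-evident.
* **Probability outputs.** The video critic's sigmoid is clamped into the
  open interval at float32-representable bounds, so "strictly in (0,1)"
  holds at finite precision; training uses logits throughout
  (softplus-based BCE), so the clamp never affects gradients in practice.

## Known limitations

* The backbone stays frozen in stage 2 by construction; if stage 1 missed
  modes of the frame distribution, no trajectory can reach them.
* Everything is CPU-bound NumPy; the reference 1024 px scale is
  config-reachable but far outside sensible CPU budgets.
* The built-in embedders make FID/FVD/IS values internally consistent and
  comparable across runs of this package, but not comparable to published
  numbers computed with pretrained Inception/I3D networks.
* The ordered-vs-shuffled separation at toy scale is consistently positive
  but small in absolute terms; the toy discriminator's strongest signal
  remains real-vs-fake.
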