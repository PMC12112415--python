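"""Train a small progressive frame GAN and inspect its phase schedule.

The generator starts at 4x4 pixels and doubles its resolution phase by
phase; new blocks are blended in with a fade-in coefficient alpha.  The
critic is trained with the Wasserstein loss plus a gradient penalty that
pushes its input-gradient norm toward 1.
"""

import numpy as np

from trajgan import FrameDataset, FrameGANConfig, SceneSpec, extract_features, \
    generate_tunnel, train_frame_gan
from trajgan.autodiff import Tensor

clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 16, seed=0)
config = FrameGANConfig(
    latent_dim=32,
    max_resolution=16,
    channels_schedule={4: 16, 8: 12, 16: 8},
    feature_dim=32,
    steps_per_phase=10,
)
gen, critic, history = train_frame_gan(FrameDataset.from_clips(clips), config, seed=0)

print("phase schedule (resolution/phase/steps):")
seen = {}
for rec in history:
    seen.setdefault((rec["resolution"], rec["phase"]), 0)
    seen[(rec["resolution"], rec["phase"])] += 1
for (res, phase), n in seen.items():
    print(f"  {res:3d}px {phase:7s} {n} steps")
print(f"final losses: critic {history[-1]['d_loss']:.3f}  "
      f"generator {history[-1]['g_loss']:.3f}  penalty {history[-1]['penalty']:.3f}")

z = np.random.default_rng(1).standard_normal((4, 32)).astype(np.float32)
frames = gen(Tensor(z))
feats = extract_features(critic, frames.data)
print(f"generator: 4 latents -> frames {frames.shape}, values in "
      f"[{frames.data.min():.2f}, {frames.data.max():.2f}]")
print(f"critic-as-feature-extractor: frames -> {feats.shape} "
      "(the penultimate activations the video discriminator will consume)")
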