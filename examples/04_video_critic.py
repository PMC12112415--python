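"""The video discriminator sees stacked frame features, not pixels.

Eight frames are turned into eight 512-dimensional frame-critic feature
vectors and stacked into a single-channel 8x512 "image" (time on the height
axis).  Four valid-mode Conv2D+ReLU layers reduce it to 27 values that feed
one linear unit and a sigmoid: the probability the clip is a real,
correctly ordered video.
"""

import numpy as np

from trajgan import VideoCriticConfig, conv_output_size, infer_flatten_dim
from trajgan.video_critic import VideoCritic

config = VideoCriticConfig()  # reference: 8 frames x 512 features
h, w = config.n_frames, config.feature_dim
print("conv arithmetic through the reference stack:")
for ci, co, (kh, kw), (sh, sw) in config.conv_layers:
    h2, w2 = conv_output_size(h, kh, sh), conv_output_size(w, kw, sw)
    print(f"  Conv2D({ci:2d} -> {co:2d}, kernel ({kh},{kw:2d}), stride ({sh},{sw})): "
          f"{h}x{w} -> {h2}x{w2}")
    h, w = h2, w2
print(f"flattened width feeding the final linear layer: {infer_flatten_dim(config)}")

critic = VideoCritic(config, seed=0)
fmap = np.random.default_rng(0).normal(size=(3, 1, 8, 512)).astype(np.float32)
probs = critic(fmap).data.ravel()
print(f"three random feature maps -> probabilities {np.round(probs, 4)} "
      "(strictly inside (0, 1); untrained, so uninformative)")
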