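"""The plugin network: one noise vector -> a latent trajectory -> a video.

At reference scale the plugin takes a 2047-dimensional Gaussian noise vector
shared by all frames; for each frame index it concatenates an encoded time
scalar and applies four linear layers (2048->1535, 1536->1023, 1024->511,
512->512, ReLU between the first three), then L2-normalizes each output onto
the unit hypersphere.  Each row depends only on (t_i, z), so a frozen image
generator can decode trajectories of any length into video.
"""

import numpy as np

from trajgan import PluginConfig, plugin_forward, sample_video_noise
from trajgan.plugin import Plugin

config = PluginConfig()  # reference scale
plugin = Plugin(config, seed=0)
z = sample_video_noise(seed=42, z_dim=config.z_dim)
trajectory = plugin_forward(plugin, z, np.arange(8))

print(f"layer input widths : {config.layer_in_widths} (noise/hidden + 1 time slot)")
print(f"trajectory shape   : {trajectory.shape} (8 frames x 512 latent dims)")
norms = np.linalg.norm(trajectory.data, axis=1)
print(f"row norms          : max deviation from 1 = {np.abs(norms - 1).max():.2e}")

row3_alone = plugin_forward(plugin, z, [3]).data[0]
print("per-frame rule     : row 3 recomputed alone is bit-identical ->",
      bool(np.array_equal(row3_alone, trajectory.data[3])))

long_traj = plugin_forward(plugin, z, np.arange(32))
step = np.linalg.norm(np.diff(long_traj.data, axis=0), axis=1)
print(f"32-frame trajectory: consecutive latent steps {step.mean():.3f} +/- {step.std():.3f} "
      "(a smooth curve on the hypersphere, not i.i.d. noise)")
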