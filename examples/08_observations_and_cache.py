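"""Observation pipeline: synthesis, preprocessing, noise, and offline caching.

Shows the path an observation takes from a renderer to an agent: procedural
per-state textures, resizing/normalization, Gaussian corruption, multisensory
combination with a pose channel, and the offline cache that renders each
observation exactly once.
"""

import numpy as np

from navrl.observations import (
    NoiseSpec,
    add_noise,
    build_offline_cache,
    combine_observations,
    flatten_observation,
    pose_observation,
    preprocess_image,
    synthesize_state_images,
)

obs_set = synthesize_state_images(n_states=12, image_size=(16, 16), seed=7,
                                  n_headings=4)
img = obs_set.get(state=3, heading=1)
print(f"texture shape {img.shape}, range [{img.min():.2f}, {img.max():.2f}]")

small = preprocess_image(img, 8, 8)
noisy = add_noise(small, NoiseSpec(sigma=0.05), np.random.default_rng(0))
print(f"downscaled to {small.shape}; noisy range "
      f"[{noisy.min():.2f}, {noisy.max():.2f}] (clipped to [0, 1])")

multi = combine_observations([("vision", noisy),
                              ("pose", pose_observation((0.3, 0.7, 1.2)))])
print(f"multisensory keys: {list(multi)}; flattened length "
      f"{flatten_observation(multi).size}")

calls = {"n": 0}
def render(state, heading):
    calls["n"] += 1
    return obs_set.get(state, heading)

cache = build_offline_cache(render, states=range(12), headings=range(4))
for _ in range(1000):
    cache.query(5, 2)
print(f"render calls after 1000 queries: {calls['n']} "
      f"(one per (state, heading) entry, {len(cache)} total)")
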