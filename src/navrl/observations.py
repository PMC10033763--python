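"""Observation generation, preprocessing, corruption, combination and caching.

These utilities stand between an environment's raw sensory output and the
agent: images are resized and normalized to [0, 1], optionally corrupted with
noise to emulate the imprecision of biological observations, and multiple
modalities can be combined into a keyed multisensory observation whose keys
route each modality to a named network input.  A procedural texture renderer
provides visually distinct per-(state, heading) images where no external
renderer is available, and an offline cache stores rendered observations for
cheap retrieval during long simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


@dataclass
class NoiseSpec:
    """Additive observation noise. Only Gaussian noise is currently provided."""

    kind: str = "gaussian"
    sigma: float = 0.0
    clip: bool = True

    def __post_init__(self):
        if self.kind != "gaussian":
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def preprocess_image(image: np.ndarray, target_height: int, target_width: int) -> np.ndarray:
    """Resize an image and normalize pixel values to [0, 1].

    Integer images are scaled by their dtype maximum before resizing.
    Downscaling by integer factors uses exact area (block) averaging;
    everything else uses bilinear interpolation.
    """
    if target_height < 1 or target_width < 1:
        raise ValueError("target size must be positive")
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(image.dtype).max
    else:
        img = img.astype(float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    h, w, c = img.shape
    if (h, w) == (target_height, target_width):
        out = img
    elif h % target_height == 0 and w % target_width == 0:
        fh, fw = h // target_height, w // target_width
        out = img.reshape(target_height, fh, target_width, fw, c).mean(axis=(1, 3))
    else:
        out = _sk_resize(img, (target_height, target_width), order=1,
                         anti_aliasing=False, preserve_range=True)
    out = np.clip(out, 0.0, 1.0)
    return out[..., 0] if squeeze else out


def add_noise(obs: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Corrupt an observation with i.i.d. Gaussian noise (optionally clipped)."""
    if noise.sigma == 0:
        return np.asarray(obs, dtype=float).copy()
    out = np.asarray(obs, dtype=float) + rng.normal(0.0, noise.sigma, np.shape(obs))
    if noise.clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def combine_observations(entries) -> dict[str, np.ndarray]:
    """Combine keyed observation modalities into one multisensory observation.

    ``entries`` is a sequence of ``(key, observation)`` pairs (or a dict).
    Keys must be unique; they identify the network input each modality feeds.
    """
    if isinstance(entries, dict):
        entries = entries.items()
    out: dict[str, np.ndarray] = {}
    for key, obs in entries:
        if key in out:
            raise ValueError(f"duplicate observation key {key!r}")
        out[key] = np.asarray(obs)
    return out


def flatten_observation(obs) -> np.ndarray:
    """Flatten a (possibly multisensory) observation into one feature vector."""
    if isinstance(obs, dict):
        return np.concatenate([np.ravel(v) for v in obs.values()])
    return np.ravel(np.asarray(obs, dtype=float))


def pose_observation(pose, degrees: bool = False) -> np.ndarray:
    """Pose observation: x-y position plus wrapped heading direction.

    Heading wraps to [0, 360) degrees or [0, 2*pi) radians.
    """
    x, y, heading = pose
    period = 360.0 if degrees else 2.0 * np.pi
    return np.array([x, y, heading % period], dtype=float)


def synthesize_state_images(
    n_states: int,
    image_size: tuple[int, int] = (16, 16),
    seed: int = 0,
    n_headings: int = 1,
) -> "ObservationSet":
    """Procedurally render a distinct deterministic texture per (state, heading).

    Each texture is a smooth pseudo-random pattern (a low-resolution random
    field upsampled bilinearly) plus a heading-dependent bright band, giving
    visually distinct, reproducible stand-ins for renderer output.  Values lie
    in [0, 1]; the same seed always produces a bit-identical set.
    """
    h, w = image_size
    images: dict[tuple[int, int], np.ndarray] = {}
    for state in range(n_states):
        for heading in range(n_headings):
            rng = np.random.default_rng(np.random.SeedSequence([seed, state, heading]))
            coarse = rng.uniform(0.0, 1.0, (4, 4))
            img = _sk_resize(coarse, (h, w), order=1, anti_aliasing=False,
                             preserve_range=True)
            band = int(round(heading * w / max(n_headings, 1))) % w
            img[:, band] = 1.0
            images[(state, heading)] = np.clip(img, 0.0, 1.0)
    return ObservationSet(images, n_states, n_headings, seed)


@dataclass
class ObservationSet:
    """Complete mapping (state, heading) -> image, with provenance seed."""

    images: dict[tuple[int, int], np.ndarray]
    n_states: int
    n_headings: int
    seed: int

    def get(self, state: int, heading: int = 0) -> np.ndarray:
        return self.images[(state, heading)]


class ObservationCache:
    """Offline observation cache: render once, retrieve from memory afterwards.

    ``query`` is bit-identical to calling ``render_fn`` directly.  Queries
    outside the cached domain either raise (``on_missing='error'``) or fall
    back to an on-demand render (``on_missing='render'``).
    """

    def __init__(self, render_fn, states, headings=(0,), on_missing: str = "error"):
        if on_missing not in ("error", "render"):
            raise ValueError("on_missing must be 'error' or 'render'")
        self.render_fn = render_fn
        self.on_missing = on_missing
        self.render_calls = 0
        self._store: dict[tuple, np.ndarray] = {}
        for s in states:
            for hd in headings:
                self._store[(s, hd)] = self._render(s, hd)

    def _render(self, state, heading):
        self.render_calls += 1
        return np.asarray(self.render_fn(state, heading))

    def __len__(self) -> int:
        return len(self._store)

    def query(self, state, heading=0) -> np.ndarray:
        key = (state, heading)
        if key not in self._store:
            if self.on_missing == "error":
                raise KeyError(f"observation {key} not cached")
            self._store[key] = self._render(state, heading)
        return self._store[key]


def build_offline_cache(render_fn, states, headings=(0,), on_missing="error") -> ObservationCache:
    """Pre-render every (state, heading) observation into an :class:`ObservationCache`."""
    return ObservationCache(render_fn, states, headings, on_missing)
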