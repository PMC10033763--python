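"""Synthetic ground-truth fixtures for the analysis pipeline.

These generators plant known spatial structure into activity maps so that the
place-field detector can be validated against exact ground truth.  Everything
is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


def gaussian_bump_map(
    shape: tuple[int, int],
    center: tuple[float, float],
    sigma: float = 2.0,
    peak: float = 1.0,
) -> np.ndarray:
    """Isotropic Gaussian bump on a bin grid, ``peak`` at ``center`` (row, col)."""
    rows, cols = np.indices(shape)
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    return peak * np.exp(-d2 / (2.0 * sigma**2))


def planted_field_maps(
    n_units: int = 64,
    n_bumps: int = 7,
    shape: tuple[int, int] = (25, 25),
    sigma: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit maps with exactly ``n_bumps`` planted place fields.

    Returns ``(maps, truth)`` where ``maps`` is (n_units, rows, cols) and
    ``truth`` is the boolean ground-truth place-cell flag per unit.  Bump
    units carry a single compact Gaussian field; the remaining units cycle
    through realistic non-place patterns that a correct detector must reject:
    silent maps, spatially uniform activity, unstructured noise, a pair of
    equal disjoint bumps, an over-broad field, and a sub-bin speck.
    """
    rng = np.random.default_rng(seed)
    maps = np.zeros((n_units, *shape))
    truth = np.zeros(n_units, dtype=bool)
    margin = int(np.ceil(3 * sigma))
    bump_units = rng.choice(n_units, size=n_bumps, replace=False)
    for u in bump_units:
        center = (rng.uniform(margin, shape[0] - 1 - margin),
                  rng.uniform(margin, shape[1] - 1 - margin))
        maps[u] = gaussian_bump_map(shape, center, sigma)
        truth[u] = True
    distractors = ("silent", "uniform", "noise", "two_bumps", "broad", "speck")
    j = 0
    for u in range(n_units):
        if truth[u]:
            continue
        kind = distractors[j % len(distractors)]
        j += 1
        if kind == "silent":
            maps[u] = 0.0
        elif kind == "uniform":
            maps[u] = rng.uniform(0.5, 0.9)
        elif kind == "noise":
            maps[u] = rng.uniform(0.0, 1.0, shape)
        elif kind == "two_bumps":
            c1 = (shape[0] * 0.25, shape[1] * 0.25)
            c2 = (shape[0] * 0.75, shape[1] * 0.75)
            maps[u] = np.maximum(gaussian_bump_map(shape, c1, sigma),
                                 gaussian_bump_map(shape, c2, sigma))
        elif kind == "broad":
            maps[u] = gaussian_bump_map(shape, (shape[0] / 2, shape[1] / 2),
                                        sigma=10.0)
        else:  # speck: single hot bin
            m = np.zeros(shape)
            m[int(rng.integers(shape[0])), int(rng.integers(shape[1]))] = 1.0
            maps[u] = m
    return maps, truth
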