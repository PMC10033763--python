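"""Spatial-representation analysis: activity maps, place fields, SR heat maps.

Spatial activity maps are built by artificially moving the agent over a
rectangular probe grid spanning the arena and recording unit activations at
every grid point, separately for each heading direction.  Place-field
identification runs on the heading-averaged map of a unit: the unit is
flagged as place-cell-like when its activity is confined to a single compact
region.  The concrete criterion (relative threshold, connectivity, area
bounds, out-of-field ratio) is a package default, exposed in
:class:`PlaceFieldParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .agents.dsr import SRModel, dsr_q
from .envs.gridworld import GridworldSpec


@dataclass
class SpatialActivityMap:
    """Per-unit, per-heading activity over a rectangular probe grid.

    ``data`` has shape (n_units, n_headings, rows, cols); ``extent`` is
    (xmin, xmax, ymin, ymax) in arena coordinates, with map row 0 at ymin.
    """

    data: np.ndarray
    headings: tuple[int, ...]
    extent: tuple[float, float, float, float]

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def resolution(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def heading_averaged(self, unit: int | None = None) -> np.ndarray:
        """Arithmetic mean over headings, for one unit or all units."""
        if unit is None:
            return self.data.mean(axis=1)
        return self.data[unit].mean(axis=0)


def probe_grid(extent, resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Probe point coordinates: ``resolution x resolution`` grid centers."""
    xmin, xmax, ymin, ymax = extent
    xs = np.linspace(xmin, xmax, resolution)
    ys = np.linspace(ymin, ymax, resolution)
    return xs, ys


def compute_activity_maps(
    activation_fn,
    extent,
    resolution: int = 25,
    headings: tuple[int, ...] = (0,),
) -> SpatialActivityMap:
    """Record unit activity on a rectangular probe grid, per heading.

    ``activation_fn(points, heading)`` receives an (n, 2) array of probe
    coordinates and returns an (n, n_units) activation matrix; it can wrap a
    network probe (see :func:`network_probe`) or any closed-form unit model.
    Maps can be computed during training or afterwards; the probe order does
    not influence the result.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    xs, ys = probe_grid(extent, resolution)
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])
    per_heading = []
    for hd in headings:
        acts = np.asarray(activation_fn(points, hd))
        per_heading.append(acts.T.reshape(-1, resolution, resolution))
    data = np.stack(per_heading, axis=1)
    return SpatialActivityMap(data, tuple(headings), tuple(extent))


def network_probe(network, obs_fn, layer: int = -2):
    """Adapt a Q-network into an ``activation_fn`` for :func:`compute_activity_maps`.

    ``obs_fn(x, y, heading)`` builds the probe observation vector for an
    arbitrary arena position; ``layer`` selects which activation layer to
    record (default: the last hidden layer, the units preceding the output
    action-selection layer).
    """

    def fn(points, heading):
        X = np.stack([np.ravel(obs_fn(x, y, heading)) for x, y in points])
        return network.activations(X)[layer]

    return fn


@dataclass
class PlaceFieldParams:
    """Concrete place-field criterion (package defaults, tunable).

    A unit is place-cell-like iff (i) its peak activity exceeds
    ``activity_floor``; (ii) the largest 4-connected component of bins at or
    above ``rel_threshold * peak`` has an area within ``area_bounds`` (bins);
    (iii) mean activity outside that field is below ``out_field_ratio * peak``;
    and (iv) the field is unique: the second-largest component is smaller than
    ``secondary_ratio`` times the largest.
    """

    activity_floor: float = 1e-3
    rel_threshold: float = 0.5
    area_bounds: tuple[int, int] = (9, 200)
    out_field_ratio: float = 0.3
    secondary_ratio: float = 0.5


@dataclass
class PlaceFieldReport:
    """Result of place-field identification for one unit."""

    unit: int
    peak: float
    field_mask: np.ndarray | None
    field_area: int
    centroid: tuple[float, float] | None  # (row, col) in bins
    is_place_cell: bool


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def identify_place_fields(
    map2d: np.ndarray, params: PlaceFieldParams | None = None, unit: int = 0
) -> PlaceFieldReport:
    """Classify one heading-averaged activity map (see :class:`PlaceFieldParams`)."""
    params = params or PlaceFieldParams()
    m = np.asarray(map2d, dtype=float)
    if m.size == 0:
        raise ValueError("empty activity map")
    peak = float(m.max())
    if peak <= params.activity_floor:
        return PlaceFieldReport(unit, peak, None, 0, None, False)
    above = m >= params.rel_threshold * peak
    labels, n_comp = ndimage.label(above, structure=_FOUR_CONN)
    areas = ndimage.sum_labels(np.ones_like(m), labels, index=range(1, n_comp + 1))
    order = np.argsort(areas)[::-1]
    largest = order[0]
    field = labels == largest + 1
    area = int(areas[largest])
    centroid = ndimage.center_of_mass(field)
    ok = params.area_bounds[0] <= area <= params.area_bounds[1]
    if ok and n_comp > 1 and areas[order[1]] >= params.secondary_ratio * area:
        ok = False  # more than one candidate field
    if ok:
        outside = m[~field]
        if outside.size and outside.mean() >= params.out_field_ratio * peak:
            ok = False
    return PlaceFieldReport(unit, peak, field, area, tuple(centroid), ok)


def count_place_cells(
    maps: SpatialActivityMap | np.ndarray, params: PlaceFieldParams | None = None
) -> int:
    """Number of units flagged as place cells in a checkpoint's maps."""
    arr = maps.heading_averaged() if isinstance(maps, SpatialActivityMap) else np.asarray(maps)
    return sum(identify_place_fields(arr[u], params, unit=u).is_place_cell
               for u in range(len(arr)))


def place_cell_trajectory(
    checkpoints: list[SpatialActivityMap | np.ndarray],
    params: PlaceFieldParams | None = None,
) -> list[int]:
    """Place-cell counts across training checkpoints."""
    return [count_place_cells(cp, params) for cp in checkpoints]


def sr_heatmap(
    sr_model: SRModel, probe_state: int, spec: GridworldSpec
) -> np.ndarray:
    """SR heat map of a probe state over the environment's grid coordinates.

    Uses the successor map of the greedy action at the probe state; each grid
    cell shows the learned cumulative discounted occupancy of the state at
    that cell, NaN for cells with no state.
    """
    greedy = int(np.argmax(dsr_q(sr_model, probe_state)))
    row = sr_model.psi[greedy, probe_state]
    return sr_row_to_grid(row, spec)


def sr_row_to_grid(row: np.ndarray, spec: GridworldSpec) -> np.ndarray:
    """Scatter a length-|S| vector onto the (height, width) grid via coordinates."""
    grid = np.full((spec.height, spec.width), np.nan)
    for s, (x, y) in enumerate(spec.coordinates):
        grid[int(y), int(x)] = row[s]
    return grid
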