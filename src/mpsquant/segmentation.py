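"""Image segmentation into square subregions and neurite orientation.

The image is split into non-overlapping square tiles of physical side
``l_sr`` (1 um by default).  Each tile is flagged as containing neuronal
material from the discrimination mask, and the local axon/dendrite
direction ``theta_N`` is estimated by detecting straight edges of the mask
with a progressive probabilistic Hough transform and clustering their
angles on the 180-degree circle.  Tiles whose segment angles do not form a
single dominant cluster (> 50% of segments) are discarded from the
downstream correlation analysis: they typically hold strongly curved or
crossing neurites for which a single direction is meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import probabilistic_hough_line

__all__ = [
    "GridSpec",
    "TileBounds",
    "HoughParams",
    "OrientationEstimate",
    "segment_grid",
    "flag_neuronal",
    "estimate_direction",
]


@dataclass(frozen=True)
class GridSpec:
    l_sr: float      # subregion side, nm
    tile_px: int     # side in pixels
    n_rows: int
    n_cols: int


@dataclass(frozen=True)
class TileBounds:
    """Half-open pixel bounds [row0, row1) x [col0, col1) of one tile."""
    row: int         # grid row index
    col: int         # grid col index
    row0: int
    row1: int
    col0: int
    col1: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass(frozen=True)
class HoughParams:
    """Progressive probabilistic Hough settings (fractions of tile side)."""
    min_len_frac: float = 0.25
    max_gap_frac: float = 0.10
    threshold: int = 10
    cluster_tol_deg: float = 15.0
    length_weighted: bool = False
    seed: int = 0


@dataclass(frozen=True)
class OrientationEstimate:
    valid: bool
    theta_n: float | None      # degrees mod 180, defined only when valid
    cluster_fraction: float    # fraction of segments in the main cluster
    n_lines: int


def segment_grid(image_shape, pixel_size: float, l_sr: float) -> tuple[list[TileBounds], GridSpec]:
    """Split an image into complete square tiles of side ``l_sr`` nm.

    Only complete tiles are produced; the remainder at the right/bottom
    edges is discarded.  Tiles are returned in row-major order.
    """
    if pixel_size <= 0 or l_sr <= 0:
        raise ValueError("pixel_size and l_sr must be positive")
    tile_px = int(round(l_sr / pixel_size))
    if tile_px < 4:
        raise ValueError(f"l_sr={l_sr} nm is under 4 pixels at {pixel_size} nm/px")
    rows, cols = image_shape
    n_rows, n_cols = rows // tile_px, cols // tile_px
    if n_rows == 0 or n_cols == 0:
        warnings.warn(f"subregion size {l_sr} nm exceeds the image; no tiles produced")
    spec = GridSpec(l_sr=float(l_sr), tile_px=tile_px, n_rows=n_rows, n_cols=n_cols)
    tiles = [
        TileBounds(r, c, r * tile_px, (r + 1) * tile_px, c * tile_px, (c + 1) * tile_px)
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return tiles, spec


def flag_neuronal(tile: TileBounds, mask: np.ndarray, min_fraction: float = 0.2) -> bool:
    """True iff the mask covers at least ``min_fraction`` of the tile area."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    sub = mask[tile.slices()]
    return bool(sub.mean() >= min_fraction)


def _mask_edges(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(mask, border_value=1)
    return mask & ~eroded


def _circular_clusters(angles: np.ndarray, tol: float) -> list[np.ndarray]:
    """Group angles (deg, period 180) by splitting at circular gaps > tol.

    Equivalent to single-linkage clustering at threshold ``tol`` for 1D
    circular data.  Returns index arrays into ``angles``.
    """
    n = angles.size
    order = np.argsort(angles, kind="stable")
    a = angles[order]
    gaps = np.diff(a)
    wrap_gap = a[0] + 180.0 - a[-1]
    cut = np.flatnonzero(gaps > tol)
    if wrap_gap > tol:
        # circle is cut at the wrap point: clusters are runs between cuts
        bounds = np.concatenate(([0], cut + 1, [n]))
        return [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    if cut.size == 0:
        return [order]
    # wrap-around merges the first and last runs
    bounds = np.concatenate(([0], cut + 1, [n]))
    runs = [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    runs[0] = np.concatenate((runs[-1], runs[0]))
    return runs[:-1]


def _circular_mean_180(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean direction of axial data (period 180 deg) via angle doubling."""
    a2 = np.deg2rad(angles * 2.0)
    if weights is None:
        s, c = np.sin(a2).mean(), np.cos(a2).mean()
    else:
        w = weights / weights.sum()
        s, c = (w * np.sin(a2)).sum(), (w * np.cos(a2)).sum()
    return float(np.mod(np.rad2deg(np.arctan2(s, c)) / 2.0, 180.0))


def estimate_direction(tile_mask: np.ndarray, params: HoughParams | None = None) -> OrientationEstimate:
    """Estimate the neurite direction in one tile from its binary mask.

    Pipeline: mask boundary extraction -> progressive probabilistic Hough
    line detection -> angles mod 180 -> gap clustering with a fixed angular
    tolerance.  The estimate is valid only when the largest cluster holds
    strictly more than half of the detected segments; its axial circular
    mean is then ``theta_N``.  Angles follow the package convention:
    counter-clockwise from the column (x) axis, with y along rows.
    """
    if params is None:
        params = HoughParams()
    tile_mask = np.asarray(tile_mask).astype(bool)
    side = min(tile_mask.shape)
    edges = _mask_edges(tile_mask)
    if not edges.any():
        return OrientationEstimate(valid=False, theta_n=None, cluster_fraction=0.0, n_lines=0)

    rng = np.random.default_rng(params.seed)
    segments = probabilistic_hough_line(
        edges,
        threshold=params.threshold,
        line_length=max(2, int(round(params.min_len_frac * side))),
        line_gap=max(1, int(round(params.max_gap_frac * side))),
        rng=rng,
    )
    if not segments:
        return OrientationEstimate(valid=False, theta_n=None, cluster_fraction=0.0, n_lines=0)

    # probabilistic_hough_line yields ((c0, r0), (c1, r1)) endpoints
    p0 = np.array([s[0] for s in segments], dtype=float)
    p1 = np.array([s[1] for s in segments], dtype=float)
    d = p1 - p0
    angles = np.mod(np.rad2deg(np.arctan2(d[:, 1], d[:, 0])), 180.0)
    lengths = np.hypot(d[:, 0], d[:, 1])

    clusters = _circular_clusters(angles, params.cluster_tol_deg)
    if params.length_weighted:
        sizes = np.array([lengths[idx].sum() for idx in clusters])
        total = lengths.sum()
    else:
        sizes = np.array([idx.size for idx in clusters], dtype=float)
        total = float(len(segments))
    best = int(np.argmax(sizes))
    frac = float(sizes[best] / total)
    if frac <= 0.5:
        return OrientationEstimate(valid=False, theta_n=None, cluster_fraction=frac,
                                   n_lines=len(segments))
    idx = clusters[best]
    theta_n = _circular_mean_180(angles[idx], lengths[idx] if params.length_weighted else None)
    return OrientationEstimate(valid=True, theta_n=theta_n, cluster_fraction=frac,
                               n_lines=len(segments))
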