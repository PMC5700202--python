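"""Masked two-dimensional Pearson correlation against the reference pattern.

The presence of the periodic structure in a subregion is scored by the
pixel-by-pixel Pearson correlation coefficient between the subregion image
``I`` and the rendered reference pattern ``Pat``, computed only over the
neuronal pixels of the discrimination mask::

    R_P = sum (I - <I>)(Pat - <Pat>) / sqrt( sum (I - <I>)^2 * sum (Pat - <Pat>)^2 )

with sums and means over masked pixels.  R_P is 1 for images identical up
to an affine intensity scaling, near 0 for uncorrelated images, and -1 for
anti-correlated ones.  Since the structure's orientation and phase are not
known a priori, the coefficient is maximized over a grid of pattern
orientations theta (a +/-20 deg window around the pre-estimated neurite
direction theta_N) and phases phi (full 2*pi range); the grid maximum is
the subregion's characteristic score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pattern import PatternParams

__all__ = ["CorrelationResult", "masked_pearson", "scan"]


@dataclass(frozen=True)
class CorrelationResult:
    best_rp: float
    best_theta: float | None      # deg mod 180
    best_phi: float | None        # rad in [0, 2pi)
    thetas: np.ndarray | None     # scanned theta grid (deg)
    curve: np.ndarray | None      # max-over-phi R_P per theta (diagnostics)
    n_pixels: int
    degenerate: bool = False


def masked_pearson(sub_image: np.ndarray, pattern_image: np.ndarray,
                   mask: np.ndarray, min_pixels: int = 2) -> tuple[float, bool]:
    """Masked Pearson coefficient between a subregion and a pattern image.

    Returns ``(coefficient, degenerate)``.  The result is degenerate (and
    the coefficient defined as 0) when fewer than ``min_pixels`` pixels are
    masked or either input has zero variance over the mask.
    """
    sub_image = np.asarray(sub_image, dtype=float)
    pattern_image = np.asarray(pattern_image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if not (sub_image.shape == pattern_image.shape == mask.shape):
        raise ValueError("image, pattern and mask must share one shape")
    i = sub_image[mask]
    p = pattern_image[mask]
    if i.size < max(2, min_pixels):
        return 0.0, True
    di = i - i.mean()
    dp = p - p.mean()
    denom = np.sqrt((di @ di) * (dp @ dp))
    if denom == 0.0:
        return 0.0, True
    return float((di @ dp) / denom), False


def _pearson_vs_many(values: np.ndarray, patterns: np.ndarray) -> np.ndarray:
    """Pearson of one masked pixel vector against rows of ``patterns``."""
    di = values - values.mean()
    dp = patterns - patterns.mean(axis=1, keepdims=True)
    num = dp @ di
    denom = np.sqrt((di @ di) * np.einsum("ij,ij->i", dp, dp))
    out = np.zeros_like(num)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def scan(sub_image: np.ndarray, mask: np.ndarray, theta_n: float,
         pattern: PatternParams, pixel_size: float, *,
         theta_halfrange: float = 20.0, theta_step: float = 1.0,
         n_phi: int = 20, min_mask_fraction: float = 0.1,
         origin: tuple[float, float] = (0.0, 0.0)) -> CorrelationResult:
    """Maximize the masked Pearson coefficient over a (theta, phi) grid.

    theta runs over ``[theta_n - theta_halfrange, theta_n + theta_halfrange]``
    in steps of ``theta_step`` degrees; phi over ``n_phi`` uniform steps in
    ``[0, 2pi)``.  The pattern is re-rendered analytically for every theta
    (phases enter through a vectorized evaluation), never rotated by
    resampling.  Ties break toward the first grid point in scan order
    (theta ascending, then phi ascending).

    ``origin`` places the tile inside a larger image so the matched phase
    is expressed in the global coordinate frame.
    """
    sub_image = np.asarray(sub_image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if sub_image.shape != mask.shape:
        raise ValueError("image and mask must share one shape")
    min_pixels = max(2, int(np.ceil(min_mask_fraction * mask.size)))
    n_masked = int(mask.sum())
    if n_masked < min_pixels:
        return CorrelationResult(0.0, None, None, None, None, n_masked, degenerate=True)

    values = sub_image[mask]
    if values.std() == 0.0:
        return CorrelationResult(0.0, None, None, None, None, n_masked, degenerate=True)

    n_theta = int(round(2 * theta_halfrange / theta_step)) + 1
    thetas = theta_n - theta_halfrange + theta_step * np.arange(n_theta)
    phis = 2.0 * np.pi * np.arange(n_phi) / n_phi

    best = (-np.inf, 0, 0)
    curve = np.full(n_theta, -np.inf)
    for it, th in enumerate(thetas):
        # the projected coordinate is shared by every phase at this theta;
        # all n_phi patterns are evaluated on it in one vectorized pass
        u = _projected(sub_image.shape, pixel_size, th, origin)[mask]
        arg = np.pi * u / pattern.T
        pats = pattern.A + pattern.B * np.sin(arg[None, :] + phis[:, None]) ** pattern.P
        rp = _pearson_vs_many(values, pats)  # flat patterns score 0 there
        curve[it] = rp.max()
        iphi = int(np.argmax(rp))
        if rp[iphi] > best[0]:
            best = (float(rp[iphi]), it, iphi)

    if not np.isfinite(best[0]):
        return CorrelationResult(0.0, None, None, thetas, curve, n_masked, degenerate=True)
    best_rp, it, iphi = best
    return CorrelationResult(
        best_rp=best_rp,
        best_theta=float(np.mod(thetas[it], 180.0)),
        best_phi=float(phis[iphi]),
        thetas=thetas,
        curve=curve,
        n_pixels=n_masked,
    )


def _projected(shape, pixel_size, theta_deg, origin):
    from .pattern import _projected_coordinate
    return _projected_coordinate(shape, pixel_size, theta_deg, origin)
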